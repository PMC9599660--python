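"""Read, write, validate and normalize genome-scale metabolic models.

The in-memory container is :class:`ModelDocument`, a plain stoichiometric
model: metabolites, reactions with bounds and a gene-protein-reaction (GPR)
rule, genes, and a linear objective.  Two serializations are supported:

* COBRA-community JSON (``metabolites`` / ``reactions`` / ``genes`` arrays
  with ``lower_bound`` / ``upper_bound`` / ``gene_reaction_rule`` keys),
  written deterministically so that identical models give identical bytes;
* SBML Level 3 with the ``fbc`` package (bounds, GPR, objective), through
  cobrapy / libsbml.

Identifier normalization follows the BiGG-style conventions needed by
downstream kinetic-parameter tooling: ``(e)`` compartment tags become
``_e``, stereo-descriptor dashes (``-D``, ``-L``, ``-R``) become double
underscores, and any remaining dash becomes an underscore.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

from .errors import FormatError, InvalidIdentifierError, ValidationError

DEFAULT_BOUND = 1000.0

#: Prefixes that mark boundary (exchange / demand / sink) reactions.
EXCHANGE_PREFIXES = ("EX_", "DM_", "SK_")


@dataclass(frozen=True)
class MetaboliteRecord:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: signed stoichiometry, flux bounds (mmol/gDCW/h), GPR text."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr_text: str = ""
    ec_numbers: tuple[str, ...] = ()
    annotations: dict = field(default_factory=dict)
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions: single-metabolite stoichiometry or EX_/DM_/SK_ prefix."""
        return self.id.startswith(EXCHANGE_PREFIXES) or len(self.stoichiometry) <= 1


@dataclass
class ModelDocument:
    metabolites: list[MetaboliteRecord]
    reactions: list[ReactionRecord]
    genes: list[str]
    objective: dict[str, float]
    gene_annotations: dict[str, dict] = field(default_factory=dict)
    id: str = "model"

    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def reaction_ids(self) -> set[str]:
        return {r.id for r in self.reactions}

    def get_reaction(self, rid: str) -> ReactionRecord:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def replace_reaction(self, rid: str, new: ReactionRecord) -> "ModelDocument":
        reactions = [new if r.id == rid else r for r in self.reactions]
        return replace_reactions(self, reactions)

    def copy(self) -> "ModelDocument":
        return ModelDocument(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            genes=list(self.genes),
            objective=dict(self.objective),
            gene_annotations={g: dict(a) for g, a in self.gene_annotations.items()},
            id=self.id,
        )


def replace_reactions(model: ModelDocument, reactions: list[ReactionRecord]) -> ModelDocument:
    out = model.copy()
    out.reactions = list(reactions)
    out.objective = {k: v for k, v in model.objective.items() if k in {r.id for r in reactions}}
    return out


# ---------------------------------------------------------------------------
# identifier normalization
# ---------------------------------------------------------------------------

# Longest pattern first, so "-D(e)" cannot be corrupted by the residual rule.
_METABOLITE_RULES = (
    ("(e)", "_e"),
    ("-D", "__D"),
    ("-L", "__L"),
    ("-R", "__R"),
    ("-", "_"),
)


def normalize_metabolite_id(raw: str) -> str:
    """Normalize a metabolite identifier.

    Applies, in order: ``(e)`` -> ``_e``; ``-D``/``-L``/``-R`` -> ``__D``/
    ``__L``/``__R``; any remaining ``-`` -> ``_``.  Idempotent.
    """
    if not raw:
        raise InvalidIdentifierError("empty metabolite identifier")
    out = raw
    for pat, repl in _METABOLITE_RULES:
        out = out.replace(pat, repl)
    # strip any other parenthesised compartment tag, e.g. "(c)" -> "_c"
    while "(" in out and out.endswith(")"):
        head, _, tag = out.rpartition("(")
        out = head + "_" + tag[:-1]
    return out


def normalize_reaction_id(raw: str) -> str:
    """Normalize a reaction identifier: every ``-`` becomes ``__``."""
    if not raw:
        raise InvalidIdentifierError("empty reaction identifier")
    return raw.replace("-", "__")


def normalize_model(model: ModelDocument) -> tuple[ModelDocument, list[tuple[str, str]]]:
    """Normalize all metabolite and reaction ids in *model*.

    Returns the normalized model and the list of ``(old, new)`` renames.
    """
    renames: list[tuple[str, str]] = []
    met_map: dict[str, str] = {}
    new_mets = []
    for m in model.metabolites:
        nid = normalize_metabolite_id(m.id)
        met_map[m.id] = nid
        if nid != m.id:
            renames.append((m.id, nid))
        new_mets.append(replace(m, id=nid))
    new_rxns = []
    rxn_map: dict[str, str] = {}
    for r in model.reactions:
        nid = normalize_reaction_id(r.id)
        rxn_map[r.id] = nid
        if nid != r.id:
            renames.append((r.id, nid))
        new_rxns.append(
            replace(
                r,
                id=nid,
                stoichiometry={met_map[k]: v for k, v in r.stoichiometry.items()},
            )
        )
    out = model.copy()
    out.metabolites = new_mets
    out.reactions = new_rxns
    out.objective = {rxn_map[k]: v for k, v in model.objective.items()}
    return out, renames


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _gpr_genes(gpr_text: str) -> set[str]:
    tokens = gpr_text.replace("(", " ").replace(")", " ").split()
    return {t for t in tokens if t.lower() not in ("and", "or")}


def validate_model(model: ModelDocument) -> None:
    """Check every structural invariant; raise :class:`ValidationError` listing all offenders."""
    problems: list[str] = []
    met_ids = [m.id for m in model.metabolites]
    if len(met_ids) != len(set(met_ids)):
        dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
        problems.append(f"duplicate metabolite ids: {dupes}")
    rxn_ids = [r.id for r in model.reactions]
    if len(rxn_ids) != len(set(rxn_ids)):
        dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        problems.append(f"duplicate reaction ids: {dupes}")
    met_set = set(met_ids)
    gene_set = set(model.genes)
    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            problems.append(f"reaction {r.id}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}")
        missing = set(r.stoichiometry) - met_set
        if missing:
            problems.append(f"reaction {r.id}: unknown metabolites {sorted(missing)}")
        if not r.stoichiometry and not r.is_exchange:
            problems.append(f"reaction {r.id}: empty stoichiometry on non-exchange reaction")
        unknown_genes = _gpr_genes(r.gpr_text) - gene_set
        if unknown_genes:
            problems.append(f"reaction {r.id}: GPR references unlisted genes {sorted(unknown_genes)}")
    rxn_set = set(rxn_ids)
    for rid in model.objective:
        if rid not in rxn_set:
            problems.append(f"objective references unknown reaction {rid}")
    if problems:
        raise ValidationError(problems)


# ---------------------------------------------------------------------------
# JSON serialization (COBRA-community dialect)
# ---------------------------------------------------------------------------


def model_to_json_dict(model: ModelDocument) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr_text,
                "objective_coefficient": model.objective.get(r.id, 0.0),
                "annotation": {
                    **({"ec-code": list(r.ec_numbers)} if r.ec_numbers else {}),
                    **r.annotations,
                },
            }
            for r in model.reactions
        ],
        "genes": [
            {"id": g, "name": g, "annotation": model.gene_annotations.get(g, {})}
            for g in model.genes
        ],
        "compartments": {c: c for c in sorted({m.compartment for m in model.metabolites if m.compartment})},
    }


def _model_from_json_dict(doc: dict) -> ModelDocument:
    try:
        mets = [
            MetaboliteRecord(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=m.get("formula") or None,
            )
            for m in doc["metabolites"]
        ]
        objective: dict[str, float] = {}
        rxns = []
        for r in doc["reactions"]:
            ann = dict(r.get("annotation", {}))
            ec = ann.pop("ec-code", [])
            if isinstance(ec, str):
                ec = [ec]
            coeff = r.get("objective_coefficient", 0.0)
            if coeff:
                objective[r["id"]] = float(coeff)
            rxns.append(
                ReactionRecord(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                    gpr_text=r.get("gene_reaction_rule", ""),
                    ec_numbers=tuple(ec),
                    annotations=ann,
                )
            )
        genes = [g["id"] if isinstance(g, dict) else g for g in doc.get("genes", [])]
        gene_ann = {
            g["id"]: dict(g.get("annotation", {}))
            for g in doc.get("genes", [])
            if isinstance(g, dict) and g.get("annotation")
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed model JSON: {exc!r}") from exc
    return ModelDocument(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective=objective,
        gene_annotations=gene_ann,
        id=doc.get("id", "model"),
    )


# ---------------------------------------------------------------------------
# cobra interop (SBML path)
# ---------------------------------------------------------------------------


def to_cobra(model: ModelDocument):
    """Convert to a :class:`cobra.Model` (used for SBML export and as an LP cross-check)."""
    import cobra

    cm = cobra.Model(model.id)
    comps = {m.compartment or "c" for m in model.metabolites}
    cm.compartments = {c: c for c in sorted(comps)}
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c", formula=m.formula)
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    for g in model.genes:
        gene = cobra.Gene(g)
        cm.genes.append(gene)
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr_text:
            cr.gene_reaction_rule = r.gpr_text
        if r.ec_numbers:
            cr.annotation["ec-code"] = list(r.ec_numbers)
    cm.objective = {cm.reactions.get_by_id(k): v for k, v in model.objective.items()}
    for g, ann in model.gene_annotations.items():
        if g in cm.genes:
            cm.genes.get_by_id(g).annotation.update(ann)
    return cm


def from_cobra(cm) -> ModelDocument:
    from cobra.util.solver import linear_reaction_coefficients

    mets = [
        MetaboliteRecord(id=m.id, name=m.name or "", compartment=m.compartment or "", formula=m.formula or None)
        for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        ec = r.annotation.get("ec-code", [])
        if isinstance(ec, str):
            ec = [ec]
        rxns.append(
            ReactionRecord(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: v for m, v in r.metabolites.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr_text=r.gene_reaction_rule or "",
                ec_numbers=tuple(ec),
            )
        )
    objective = {r.id: c for r, c in linear_reaction_coefficients(cm).items()}
    gene_ann = {g.id: dict(g.annotation) for g in cm.genes if g.annotation}
    return ModelDocument(
        metabolites=mets,
        reactions=rxns,
        genes=[g.id for g in cm.genes],
        objective=objective,
        gene_annotations=gene_ann,
        id=cm.id or "model",
    )


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------


def read_model(path, format: str | None = None) -> ModelDocument:
    """Read a model from SBML (``.xml``/``.sbml``) or COBRA JSON (``.json``).

    The returned document is validated; a structurally inconsistent file
    raises :class:`ValidationError` listing every offender.
    """
    path = str(path)
    fmt = format or ("sbml" if path.endswith((".xml", ".sbml")) else "json")
    if fmt == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}") from exc
        model = _model_from_json_dict(doc)
    elif fmt == "sbml":
        import cobra

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cm = cobra.io.read_sbml_model(path)
        except Exception as exc:  # libsbml raises a zoo of types
            raise FormatError(f"{path}: SBML parse failure: {exc}") from exc
        model = from_cobra(cm)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    validate_model(model)
    return model


def write_model(model: ModelDocument, path, format: str | None = None) -> None:
    """Write to COBRA JSON (deterministic byte layout) or SBML L3 + fbc."""
    path = str(path)
    fmt = format or ("sbml" if path.endswith((".xml", ".sbml")) else "json")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_json_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "sbml":
        import cobra

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(to_cobra(model), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def attach_annotations(model: ModelDocument, mapping: dict[str, str]) -> tuple[ModelDocument, list[str]]:
    """Attach protein-database accessions (e.g. UniProt ids) to genes.

    Keys not present among the model's genes are skipped and returned as
    warnings; the model is never mutated in place.
    """
    out = model.copy()
    unknown = []
    gene_set = set(model.genes)
    for gene, acc in mapping.items():
        if gene not in gene_set:
            unknown.append(gene)
            continue
        ann = dict(out.gene_annotations.get(gene, {}))
        ann["uniprot"] = acc
        out.gene_annotations[gene] = ann
    for g in unknown:
        warnings.warn(f"annotation mapping for unknown gene {g!r} ignored", stacklevel=2)
    return out, unknown
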