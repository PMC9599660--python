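"""Synthetic toy fixtures with analytic ground truth.

The generator emits every input the pipeline consumes — a small
mass-balanced metabolic model, UniProt-like protein records, a kinetics
table and a gene-abundance table — at a scale where the expected behavior
is known in closed form.  The model's topology mirrors the canonical
respiration/fermentation architecture behind overflow metabolism:

* a glucose exchange and transporter feeding a branch point;
* a respiration-like pathway — high biomass yield ``y1`` but high enzyme
  cost ``a1`` (g enzyme per unit flux), catalyzed by a heterotetrameric
  complex (GPR ``g1 and g2``);
* a fermentation-like pathway — lower yield ``y2 < y1``, cheaper enzymes
  ``a2 < a1``, secreting an acetate-like byproduct, catalyzed by an
  isozyme pair (GPR ``g3 or g4``, deliberately >=80% sequence-identical to
  exercise the and/or screen);
* an optional lysine-like product pathway (homodimeric enzyme);
* one reversible transport reaction, so both splitting steps fire.

With only the two branch reactions enzyme-constrained, the optimal-growth
problem reduces to a two-variable LP whose solution is written down in
:func:`overflow_switch_oracle`; the ground-truth record carries the
parameters so tests never re-derive expectations from the code under
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EcModelKitError
from .ec_core import ECModel, build_ec_model
from .enzyme_params import (
    AbundanceRecord,
    KineticEntry,
    MatchPolicy,
    build_enzyme_table,
    compute_f,
)
from .gem_io import MetaboliteRecord, ModelDocument, ReactionRecord, validate_model
from .gpr_curation import ProteinRecord, parse_subunit_count
from .model_expansion import SplitMap, expand_model

ORGANISM = "Corynebacterium glutamicum"

EC_RESP = "1.1.1.1"
EC_RESP_CLASS_SIBLING = "1.1.1.2"  # same class, carries the class-maximum kcat
EC_FERM = "2.3.1.8"
EC_PRODUCT = "4.1.1.20"

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ToyGemSpec:
    """Study conditions for one toy fixture; all rates are per-seed jittered
    around the defaults unless pinned explicitly."""

    seed: int = 0
    y1: float | None = None  # respiration biomass yield, gDCW/mmol glucose
    y2: float | None = None  # fermentation biomass yield
    u_star: float | None = None  # overflow onset, mmol/gDCW/h
    f: float = 0.46  # enzyme mass fraction of total protein
    ptotal: float = 0.56  # g protein / gDCW
    sigma: float = 0.5
    uptake_bound: float = 10.0
    include_product_pathway: bool = True
    include_complexes: bool = True
    include_isozymes: bool = True
    undervalue_resp_kcat: bool = False  # calibration fixture: kcat 10x too small


@dataclass
class GroundTruth:
    """Everything a test needs to predict the fixture's behavior."""

    y1: float
    y2: float
    a1: float  # g enzyme per unit respiration flux
    a2: float  # g enzyme per unit fermentation flux
    a_product: float
    pool: float
    u_star: float
    f: float
    ptotal: float
    sigma: float
    uptake_bound: float
    monomer_mws: dict[str, float]
    subunit_counts: dict[str, int]
    kcat_per_s: dict[str, float]  # per EC, the in-table "true" value
    organism: str = ORGANISM
    biomass_id: str = "BIOMASS"
    glucose_exchange: str = "EX_glc__D_e"
    oxygen_exchange: str = "EX_o2_e"
    byproduct_exchange: str = "EX_ac_e"
    product_exchange: str = "EX_lys__L_e"
    decoy_pair: tuple[str, str] = ("g3", "g4")
    decoy_identity: float = 0.0
    undervalue_factor: float = 1.0
    calibration_uptake: float = 0.0
    calibration_target: float = 0.0


def _resolve(spec: ToyGemSpec) -> GroundTruth:
    rng = np.random.default_rng(spec.seed)
    y1 = spec.y1 if spec.y1 is not None else 0.10 * rng.uniform(0.9, 1.1)
    y2 = spec.y2 if spec.y2 is not None else 0.05 * rng.uniform(0.9, 1.1)
    if not (y1 > y2 > 0):
        raise EcModelKitError(f"need y1 > y2 > 0, got {y1}, {y2}")
    u_star = spec.u_star if spec.u_star is not None else 4.5 * rng.uniform(0.9, 1.1)
    pool = spec.ptotal * spec.f
    a1 = pool / u_star
    # a2 below a1 * y2/y1 guarantees the fermentation route is the more
    # enzyme-efficient one (y2/a2 > y1/a1), which is what makes overflow pay.
    a2 = a1 * (y2 / y1) * rng.uniform(0.3, 0.6)
    if not (a1 > a2 > 0):
        raise EcModelKitError(f"need a1 > a2 > 0, got {a1}, {a2}")
    a_product = a1 * 0.5

    monomer_mws = {
        "g1": 30.26, "g2": 41.76,  # heterotetramer alpha2-beta2 -> 144.04 kDa
        "g3": 35.0, "g4": 35.0,
        "g5": 52.6,                # homodimer -> 105.2 kDa
        "g6": 28.0, "gt1": 45.0,
        "x1": 50.0, "x2": 60.0,    # measured but outside the model
    }
    subunit_counts = {"g1": 2, "g2": 2, "g3": 1, "g4": 1, "g5": 2, "g6": 1, "gt1": 1}
    mw_resp = 2 * monomer_mws["g1"] + 2 * monomer_mws["g2"] if spec.include_complexes else monomer_mws["g1"]
    mw_ferm = monomer_mws["g3"]
    mw_prod = 2 * monomer_mws["g5"]
    kcat = {
        EC_RESP: mw_resp / (spec.sigma * a1) / 3600.0,
        EC_FERM: mw_ferm / (spec.sigma * a2) / 3600.0,
        EC_PRODUCT: mw_prod / (spec.sigma * a_product) / 3600.0,
    }
    u_cal = 0.8 * u_star
    return GroundTruth(
        y1=y1, y2=y2, a1=a1, a2=a2, a_product=a_product, pool=pool,
        u_star=u_star, f=spec.f, ptotal=spec.ptotal, sigma=spec.sigma,
        uptake_bound=spec.uptake_bound,
        monomer_mws=monomer_mws, subunit_counts=subunit_counts, kcat_per_s=kcat,
        undervalue_factor=10.0 if spec.undervalue_resp_kcat else 1.0,
        calibration_uptake=u_cal,
        calibration_target=y1 * u_cal,
    )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def make_toy_gem(spec: ToyGemSpec = ToyGemSpec()) -> tuple[ModelDocument, GroundTruth]:
    truth = _resolve(spec)
    y1, y2 = truth.y1, truth.y2
    mets = [
        MetaboliteRecord("glc__D_e", "D-glucose (extracellular)", "e", "C6H12O6"),
        MetaboliteRecord("glc__D_c", "D-glucose", "c", "C6H12O6"),
        MetaboliteRecord("o2_e", "oxygen (extracellular)", "e", "O2"),
        MetaboliteRecord("o2_c", "oxygen", "c", "O2"),
        MetaboliteRecord("ac_c", "acetate", "c"),
        MetaboliteRecord("ac_e", "acetate (extracellular)", "e"),
        MetaboliteRecord("bm_c", "biomass precursor", "c"),
    ]
    resp_gpr = "g1 and g2" if spec.include_complexes else "g1"
    ferm_gpr = "g3 or g4" if spec.include_isozymes else "g3"
    rxns = [
        ReactionRecord("EX_glc__D_e", {"glc__D_e": -1.0}, -spec.uptake_bound, 0.0,
                       name="glucose exchange"),
        ReactionRecord("EX_o2_e", {"o2_e": -1.0}, -1000.0, 0.0, name="oxygen exchange"),
        ReactionRecord("EX_ac_e", {"ac_e": -1.0}, 0.0, 1000.0, name="acetate exchange"),
        ReactionRecord("GLCt", {"glc__D_e": -1.0, "glc__D_c": 1.0}, 0.0, 1000.0,
                       gpr_text="gt1", ec_numbers=("9.9.9.9",), name="glucose transport"),
        ReactionRecord("O2t", {"o2_e": -1.0, "o2_c": 1.0}, 0.0, 1000.0, name="oxygen transport"),
        ReactionRecord("RESP", {"glc__D_c": -1.0, "o2_c": -2.0, "bm_c": y1}, 0.0, 1000.0,
                       gpr_text=resp_gpr, ec_numbers=(EC_RESP,), name="respiratory pathway"),
        ReactionRecord("FERM", {"glc__D_c": -1.0, "bm_c": y2, "ac_c": 1.0}, 0.0, 1000.0,
                       gpr_text=ferm_gpr, ec_numbers=(EC_FERM,), name="fermentative pathway"),
        ReactionRecord("ACt", {"ac_c": -1.0, "ac_e": 1.0}, -1000.0, 1000.0,
                       gpr_text="g6", name="acetate transport (reversible)"),
        ReactionRecord("BIOMASS", {"bm_c": -1.0}, 0.0, 1000.0, name="biomass drain"),
    ]
    genes = ["g1", "g2", "g3", "g4", "g6", "gt1"]
    if spec.include_product_pathway:
        mets += [
            MetaboliteRecord("lys__L_c", "L-lysine", "c"),
            MetaboliteRecord("lys__L_e", "L-lysine (extracellular)", "e"),
        ]
        rxns += [
            ReactionRecord("LYSS", {"glc__D_c": -1.0, "lys__L_c": 1.0}, 0.0, 1000.0,
                           gpr_text="g5", ec_numbers=(EC_PRODUCT,), name="lysine pathway"),
            ReactionRecord("LYSt", {"lys__L_c": -1.0, "lys__L_e": 1.0}, 0.0, 1000.0,
                           name="lysine transport"),
            ReactionRecord("EX_lys__L_e", {"lys__L_e": -1.0}, 0.0, 1000.0,
                           name="lysine exchange"),
        ]
        genes.append("g5")
    model = ModelDocument(
        metabolites=mets, reactions=rxns, genes=sorted(genes),
        objective={"BIOMASS": 1.0}, id=f"toy_gem_seed{spec.seed}",
    )
    validate_model(model)
    return model, truth


# ---------------------------------------------------------------------------
# protein records
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _mutate(seq: str, n_sites: int, rng: np.random.Generator) -> str:
    out = list(seq)
    sites = rng.choice(len(seq), size=n_sites, replace=False)
    for s in sites:
        choices = [a for a in _AA if a != out[s]]
        out[s] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def make_protein_records(spec: ToyGemSpec = ToyGemSpec()) -> tuple[list[ProteinRecord], GroundTruth]:
    """Protein records with known interaction text and a >=80%-identical decoy pair."""
    truth = _resolve(spec)
    rng = np.random.default_rng(spec.seed + 1)
    seq = {g: _random_sequence(rng) for g in ("g1", "g2", "g3", "g5", "g6", "gt1", "x1", "x2")}
    n_mut = 9  # 9/60 mutated -> 85% identity, above the 80% design floor
    seq["g4"] = _mutate(seq["g3"], n_mut, rng)
    truth.decoy_identity = 100.0 * (60 - n_mut) / 60
    text = {
        "g1": "Tetramer of two alpha and two beta chains",
        "g2": "Tetramer of two alpha and two beta chains",
        "g3": "Monomer",
        "g4": "Monomer",
        "g5": "Homodimer",
        "g6": "Monomer",
        "gt1": "Forms oligomeric assemblies of unstated composition",  # unparseable on purpose
        "x1": "Monomer",
        "x2": "Monomer",
    }
    names = {
        "g1": "Branch oxidoreductase alpha subunit",
        "g2": "Branch oxidoreductase beta subunit",
        "g3": "Acyltransferase 1",
        "g4": "Acyltransferase 2",
        "g5": "Decarboxylase",
        "g6": "Acetate permease",
        "gt1": "Glucose permease",
        "x1": "Ribosomal protein L1",  # abundant but outside the model
        "x2": "Elongation factor Tu",
    }
    records = [
        ProteinRecord(
            accession=f"P{10000 + i}",
            gene_id=g,
            protein_name=names[g],
            monomer_mw=truth.monomer_mws[g],
            sequence=seq[g],
            interaction_text=text[g],
        )
        for i, g in enumerate(sorted(text))
    ]
    return records, truth


# ---------------------------------------------------------------------------
# kinetics and abundance tables
# ---------------------------------------------------------------------------


def make_kinetics_table(spec: ToyGemSpec = ToyGemSpec()) -> tuple[list[KineticEntry], GroundTruth]:
    """Kinetics entries per model EC, plus decoys at other organisms/levels.

    When ``spec.undervalue_resp_kcat`` is set, the organism-level entry for
    the respiration EC is 10x too small while the true maximum sits on a
    same-class sibling EC — the calibration loop must find and apply it.
    """
    truth = _resolve(spec)
    table = [
        KineticEntry(EC_RESP, truth.kcat_per_s[EC_RESP] / truth.undervalue_factor,
                     substrate="glucose", organism=ORGANISM, source="brenda"),
        KineticEntry(EC_FERM, truth.kcat_per_s[EC_FERM],
                     substrate="glucose", organism=ORGANISM, source="brenda"),
        KineticEntry(EC_FERM, truth.kcat_per_s[EC_FERM] * 0.2,
                     substrate="other", organism="Escherichia coli", source="sabio-rk"),
        # same-class sibling holding the class maximum for the respiration EC
        KineticEntry(EC_RESP_CLASS_SIBLING, truth.kcat_per_s[EC_RESP],
                     substrate="ethanol", organism="Escherichia coli", source="brenda"),
    ]
    if spec.include_product_pathway:
        table.append(
            KineticEntry(EC_PRODUCT, truth.kcat_per_s[EC_PRODUCT],
                         substrate="lysine", organism=ORGANISM, source="sabio-rk")
        )
    return table, truth


def make_abundance_records(spec: ToyGemSpec = ToyGemSpec()) -> tuple[list[AbundanceRecord], GroundTruth]:
    """Abundances whose mass split over model vs non-model genes gives exactly f."""
    truth = _resolve(spec)
    model_genes = ["g1", "g2", "g3", "g4", "g6", "gt1"] + (
        ["g5"] if spec.include_product_pathway else []
    )
    records = [AbundanceRecord(g, 1.0 / truth.monomer_mws[g]) for g in sorted(model_genes)]
    model_mass = float(len(model_genes))
    outside_mass = model_mass * (1.0 - truth.f) / truth.f
    records.append(AbundanceRecord("x1", 0.5 * outside_mass / truth.monomer_mws["x1"]))
    records.append(AbundanceRecord("x2", 0.5 * outside_mass / truth.monomer_mws["x2"]))
    return records, truth


# ---------------------------------------------------------------------------
# analytic overflow oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverflowPrediction:
    growth: float
    byproduct: float
    consumed: float
    enzyme_usage: float


def overflow_switch_oracle(
    y1: float, y2: float, a1: float, a2: float, pool: float
) -> tuple[float, "callable"]:
    """Closed-form solution of the two-pathway pool-allocation LP.

    maximize ``y1 u1 + y2 u2`` subject to ``u1 + u2 <= u`` and
    ``a1 u1 + a2 u2 <= pool`` with ``y1 > y2``, ``a1 > a2`` and
    ``y2/a2 > y1/a1``.  Below ``u* = pool/a1`` the high-yield path alone is
    optimal; between ``u*`` and ``pool/a2`` both constraints bind and the
    optimum mixes the paths with positive byproduct; beyond ``pool/a2``
    the substrate cannot all be consumed.  Returns ``(u_star, predict)``
    where ``predict(u)`` yields an :class:`OverflowPrediction`.
    """
    if not (y1 > y2 > 0 and a1 > a2 > 0):
        raise EcModelKitError("oracle requires y1 > y2 > 0 and a1 > a2 > 0")
    if not (y2 / a2 > y1 / a1):
        raise EcModelKitError("fermentation must be the more enzyme-efficient path")
    u_star = pool / a1
    u_sat = pool / a2

    def predict(u: float) -> OverflowPrediction:
        if u <= u_star:
            return OverflowPrediction(growth=y1 * u, byproduct=0.0, consumed=u,
                                      enzyme_usage=a1 * u)
        if u <= u_sat:
            u1 = (pool - a2 * u) / (a1 - a2)
            u2 = u - u1
            return OverflowPrediction(
                growth=y1 * u1 + y2 * u2, byproduct=u2, consumed=u, enzyme_usage=pool
            )
        return OverflowPrediction(
            growth=y2 * u_sat, byproduct=u_sat, consumed=u_sat, enzyme_usage=pool
        )

    return u_star, predict


# ---------------------------------------------------------------------------
# end-to-end fixture assembly
# ---------------------------------------------------------------------------


@dataclass
class ToyPipelineResult:
    base_model: ModelDocument
    split_model: ModelDocument
    split_map: SplitMap
    ec_model: ECModel
    truth: GroundTruth
    proteins: list[ProteinRecord]
    kinetics: list[KineticEntry]
    abundances: list[AbundanceRecord]
    unconstrained: list[tuple[str, str]]
    f_computed: float


def build_toy_pipeline(spec: ToyGemSpec = ToyGemSpec()) -> ToyPipelineResult:
    """Run the full construction pipeline on one fixture.

    make model -> split reversible and isozymes -> parse protein records
    into subunit compositions -> match kcats (organism-aware) -> compute f
    from the abundance table -> assemble the pool-constrained model.
    """
    model, truth = make_toy_gem(spec)
    split_model, split_map = expand_model(model)
    proteins, _ = make_protein_records(spec)
    kinetics, _ = make_kinetics_table(spec)
    abundances, _ = make_abundance_records(spec)
    compositions = {p.gene_id: parse_subunit_count(p.interaction_text) for p in proteins}
    monomer_mws = {p.gene_id: p.monomer_mw for p in proteins}
    enzymes, unconstrained = build_enzyme_table(
        split_model, compositions, monomer_mws, kinetics,
        sigma_default=truth.sigma, policy=MatchPolicy(organism=truth.organism),
    )
    f_val = compute_f(abundances, truth.monomer_mws, set(model.genes))
    ec = build_ec_model(split_model, enzymes, f=f_val, ptotal=truth.ptotal)
    return ToyPipelineResult(
        base_model=model, split_model=split_model, split_map=split_map,
        ec_model=ec, truth=truth, proteins=proteins, kinetics=kinetics,
        abundances=abundances, unconstrained=unconstrained, f_computed=f_val,
    )


def write_fixture_set(spec: ToyGemSpec, out_dir) -> dict[str, str]:
    """Write model JSON, proteins/kinetics/abundance TSVs and a ground-truth JSON."""
    import json
    import os

    from .enzyme_params import write_abundance_tsv, write_kinetics_tsv
    from .gem_io import write_model
    from .gpr_curation import write_protein_tsv

    os.makedirs(out_dir, exist_ok=True)
    model, truth = make_toy_gem(spec)
    proteins, _ = make_protein_records(spec)
    kinetics, _ = make_kinetics_table(spec)
    abundances, _ = make_abundance_records(spec)
    paths = {
        "model": os.path.join(out_dir, "model.json"),
        "proteins": os.path.join(out_dir, "proteins.tsv"),
        "kinetics": os.path.join(out_dir, "kinetics.tsv"),
        "abundance": os.path.join(out_dir, "abundance.tsv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_model(model, paths["model"])
    write_protein_tsv(proteins, paths["proteins"])
    write_kinetics_tsv(kinetics, paths["kinetics"])
    write_abundance_tsv(abundances, paths["abundance"])
    gt = {
        "y1": truth.y1, "y2": truth.y2, "a1": truth.a1, "a2": truth.a2,
        "pool": truth.pool, "u_star": truth.u_star, "f": truth.f,
        "ptotal": truth.ptotal, "sigma": truth.sigma,
        "kcat_per_s": truth.kcat_per_s, "organism": truth.organism,
        "calibration_uptake": truth.calibration_uptake,
        "calibration_target": truth.calibration_target,
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
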