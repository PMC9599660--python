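"""Enzyme parameterization: complex weights, kcat matching, the f fraction.

Units are locked across the toolkit: fluxes in mmol/gDCW/h, molecular
weights in kDa (= g/mmol), turnover numbers stored internally in 1/h.
With those choices ``v * MW / (sigma * kcat)`` is grams of enzyme per gram
dry cell weight, directly comparable to the proteome pool bound
``Ptotal * f`` (g protein/gDCW).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import EcModelKitError
from .gem_io import ModelDocument
from .gpr_curation import SubunitComposition, parse_gpr

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class KineticEntry:
    """One turnover-number measurement from a local kinetics table."""

    ec: str
    kcat_per_s: float
    substrate: str = ""
    organism: str = ""
    source: str = ""

    def __post_init__(self):
        if self.kcat_per_s <= 0:
            raise EcModelKitError(f"kcat must be positive, got {self.kcat_per_s}")
        if not _EC_RE.match(self.ec):
            raise EcModelKitError(f"malformed EC number {self.ec!r}")


@dataclass(frozen=True)
class AbundanceRecord:
    gene_id: str
    abundance: float  # relative units (transcript or protein abundance)

    def __post_init__(self):
        if self.abundance < 0:
            raise EcModelKitError(f"negative abundance for {self.gene_id}")


@dataclass
class EnzymeEntry:
    """Kinetic/mass parameters for one fully split, single-enzyme reaction."""

    reaction_id: str
    genes: dict[str, int]  # gene -> subunit copy number Nj
    mw_kda: float
    kcat_per_h: float
    sigma: float = 0.5
    kcat_source: str = ""
    flags: tuple[str, ...] = ()

    @property
    def pool_coefficient(self) -> float:
        """MW / (sigma * kcat): grams of enzyme needed per unit flux."""
        return self.mw_kda / (self.sigma * self.kcat_per_h)


def complex_mw(monomer_mws: dict[str, float], counts: dict[str, int]) -> float:
    """Complex molecular weight: sum over subunits j of Nj * MWj (kDa)."""
    total = 0.0
    for gene, n in counts.items():
        if gene not in monomer_mws:
            raise EcModelKitError(f"no monomer MW for gene {gene!r}")
        if n != int(n) or n < 1:
            raise EcModelKitError(f"subunit count for {gene!r} must be a positive integer, got {n}")
        total += int(n) * monomer_mws[gene]
    return total


def kcat_to_per_hour(kcat_per_s: float) -> float:
    if kcat_per_s <= 0:
        raise EcModelKitError(f"kcat must be positive, got {kcat_per_s}")
    return kcat_per_s * 3600.0


# ---------------------------------------------------------------------------
# kcat matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchPolicy:
    """How to search and aggregate a kinetics table.

    Levels, in priority order: (1) exact EC and organism, (2) exact EC any
    organism, (3) EC with the last field wildcarded (enzyme class).  Within
    the first non-empty level, entries are aggregated by ``aggregate``
    ("max" or "median").
    """

    organism: str = ""
    aggregate: str = "max"
    max_level: int = 3


def _ec_fields(ec: str) -> list[str]:
    return ec.split(".")


def _ec_matches(query: str, entry: str) -> bool:
    """Does a table entry's EC satisfy a query EC (query may hold '-' wildcards)?"""
    qf, ef = _ec_fields(query), _ec_fields(entry)
    if len(qf) != 4 or len(ef) != 4:
        return False
    return all(q == "-" or q == e for q, e in zip(qf, ef))


def _class_ec(ec: str) -> str:
    f = _ec_fields(ec)
    return ".".join(f[:3] + ["-"])


def _aggregate(values: list[float], how: str) -> float:
    import statistics

    if how == "max":
        return max(values)
    if how == "median":
        return statistics.median(values)
    raise EcModelKitError(f"unknown aggregate policy {how!r}")


def match_kcat(
    ec_list: list[str],
    table: list[KineticEntry],
    policy: MatchPolicy = MatchPolicy(),
) -> tuple[float, str] | None:
    """Find a turnover number for a reaction's EC annotations.

    Returns ``(kcat_per_s, provenance)`` from the highest-priority
    non-empty match level, or ``None`` when nothing matches at any level —
    the caller leaves such reactions unconstrained and logs them.
    """
    if not ec_list:
        return None
    levels: list[tuple[str, list[KineticEntry]]] = []
    l1 = [e for e in table if any(_ec_matches(q, e.ec) for q in ec_list)
          and policy.organism and e.organism == policy.organism]
    levels.append(("exact-ec+organism", l1))
    l2 = [e for e in table if any(_ec_matches(q, e.ec) for q in ec_list)]
    levels.append(("exact-ec", l2))
    class_queries = {_class_ec(q) for q in ec_list}
    l3 = [e for e in table if any(_ec_matches(q, e.ec) for q in class_queries)]
    levels.append(("ec-class", l3))
    for level_idx, (name, entries) in enumerate(levels, start=1):
        if level_idx > policy.max_level:
            break
        if entries:
            value = _aggregate([e.kcat_per_s for e in entries], policy.aggregate)
            srcs = sorted({e.source for e in entries if e.source})
            prov = f"level{level_idx}:{name}:{policy.aggregate} of {len(entries)} entries"
            if srcs:
                prov += f" [{';'.join(srcs)}]"
            return value, prov
    return None


def class_max_kcat(ec_list: list[str], table: list[KineticEntry]) -> float | None:
    """Highest kcat (1/s) available for the enzyme class (last EC field wildcarded)."""
    res = match_kcat(
        [_class_ec(q) for q in ec_list], table, MatchPolicy(aggregate="max")
    )
    return res[0] if res else None


# ---------------------------------------------------------------------------
# enzyme mass fraction f
# ---------------------------------------------------------------------------


def compute_f(
    abundances: list[AbundanceRecord],
    monomer_mws: dict[str, float],
    model_genes: set[str],
) -> float:
    """Mass fraction of measured protein attributable to model genes.

    ``f = sum_{i in model} A_i MW_i / sum_{j measured} A_j MW_j`` — the
    fraction of the cell's protein mass that the model's enzymes can
    account for, used to scale the total proteome pool.
    """
    num = 0.0
    den = 0.0
    for rec in abundances:
        if rec.gene_id not in monomer_mws:
            raise EcModelKitError(f"no monomer MW for measured gene {rec.gene_id!r}")
        mass = rec.abundance * monomer_mws[rec.gene_id]
        den += mass
        if rec.gene_id in model_genes:
            num += mass
    if den == 0:
        raise EcModelKitError("total measured protein mass is zero")
    return num / den


# ---------------------------------------------------------------------------
# enzyme table assembly
# ---------------------------------------------------------------------------


def subunit_counts_for_complex(
    genes: tuple[str, ...],
    compositions: dict[str, SubunitComposition],
) -> tuple[dict[str, int], tuple[str, ...]]:
    """Per-gene copy numbers Nj for one complex, from per-protein compositions.

    For a single-gene enzyme the gene's own total is its copy number
    (Homodimer -> 2).  For a multi-gene complex whose members report the
    same total T divisible by the gene count m, each gene gets T/m (the
    heterotetramer of two alpha and two beta chains gives each of its two
    genes N=2).  Anything else falls back to one copy per gene with a
    ``stoichiometry unknown`` flag — surfaced, not guessed.
    """
    flags: list[str] = []
    if len(genes) == 1:
        comp = compositions.get(genes[0])
        if comp is None:
            return {genes[0]: 1}, ("composition missing",)
        if comp.defaulted:
            flags.append("composition defaulted")
        return {genes[0]: comp.total}, tuple(flags)
    totals = []
    for g in genes:
        comp = compositions.get(g)
        totals.append(comp.total if comp is not None and not comp.defaulted else None)
    known = {t for t in totals if t is not None}
    if len(known) == 1:
        t = known.pop()
        if t % len(genes) == 0 and t >= len(genes):
            n = t // len(genes)
            if None in totals:
                flags.append("composition partially defaulted")
            return {g: n for g in genes}, tuple(flags)
    return {g: 1 for g in genes}, ("stoichiometry unknown",)


def build_enzyme_table(
    model_split: ModelDocument,
    compositions: dict[str, SubunitComposition],
    monomer_mws: dict[str, float],
    kinetics: list[KineticEntry],
    sigma_default: float = 0.5,
    policy: MatchPolicy = MatchPolicy(),
) -> tuple[list[EnzymeEntry], list[tuple[str, str]]]:
    """One :class:`EnzymeEntry` per catalyzed, kcat-matched split reaction.

    Returns the table plus an "unconstrained" report of
    ``(reaction_id, reason)`` for reactions that stay outside the pool
    constraint (no GPR, no EC annotation, or no kcat match).
    """
    entries: list[EnzymeEntry] = []
    unconstrained: list[tuple[str, str]] = []
    for r in model_split.reactions:
        if r.is_exchange:
            continue
        expr = parse_gpr(r.gpr_text)
        if len(expr) == 0:
            unconstrained.append((r.id, "no GPR"))
            continue
        if len(expr) > 1:
            raise EcModelKitError(f"reaction {r.id} still has {len(expr)} enzymes; split isozymes first")
        if not r.ec_numbers:
            unconstrained.append((r.id, "no EC annotation"))
            continue
        matched = match_kcat(list(r.ec_numbers), kinetics, policy)
        if matched is None:
            unconstrained.append((r.id, "no kcat match"))
            continue
        kcat_s, prov = matched
        genes = expr.enzymes[0]
        counts, flags = subunit_counts_for_complex(genes, compositions)
        try:
            mw = complex_mw(monomer_mws, counts)
        except EcModelKitError as exc:
            unconstrained.append((r.id, str(exc)))
            continue
        entries.append(
            EnzymeEntry(
                reaction_id=r.id,
                genes=counts,
                mw_kda=mw,
                kcat_per_h=kcat_to_per_hour(kcat_s),
                sigma=sigma_default,
                kcat_source=prov,
                flags=flags,
            )
        )
    return entries, unconstrained


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_kinetics_tsv(path) -> list[KineticEntry]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        KineticEntry(
            ec=row.ec,
            substrate=row.substrate,
            organism=row.organism,
            kcat_per_s=float(row.kcat_per_s),
            source=row.source,
        )
        for row in df.itertuples()
    ]


def write_kinetics_tsv(table: list[KineticEntry], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"ec": e.ec, "substrate": e.substrate, "organism": e.organism,
             "kcat_per_s": e.kcat_per_s, "source": e.source}
            for e in table
        ]
    ).to_csv(path, sep="\t", index=False)


def read_abundance_tsv(path) -> list[AbundanceRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [AbundanceRecord(gene_id=str(r.gene_id), abundance=float(r.abundance)) for r in df.itertuples()]


def write_abundance_tsv(records: list[AbundanceRecord], path) -> None:
    import pandas as pd

    pd.DataFrame([{"gene_id": a.gene_id, "abundance": a.abundance} for a in records]).to_csv(
        path, sep="\t", index=False
    )


def write_enzyme_tsv(entries: list[EnzymeEntry], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "reaction_id": e.reaction_id,
                "genes": ";".join(f"{g}:{n}" for g, n in sorted(e.genes.items())),
                "mw_kda": round(e.mw_kda, 6),
                "kcat_per_h": round(e.kcat_per_h, 6),
                "sigma": e.sigma,
                "provenance": e.kcat_source,
                "flags": ";".join(e.flags),
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)


def read_enzyme_tsv(path) -> list[EnzymeEntry]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples():
        genes = {}
        for part in row.genes.split(";"):
            if part:
                g, _, n = part.partition(":")
                genes[g] = int(n or 1)
        out.append(
            EnzymeEntry(
                reaction_id=row.reaction_id,
                genes=genes,
                mw_kda=float(row.mw_kda),
                kcat_per_h=float(row.kcat_per_h),
                sigma=float(row.sigma),
                kcat_source=row.provenance,
                flags=tuple(f for f in row.flags.split(";") if f),
            )
        )
    return out
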