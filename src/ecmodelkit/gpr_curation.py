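"""GPR rule parsing and curation.

A gene-protein-reaction (GPR) rule is a boolean expression over gene ids in
which ``and`` encodes a multi-subunit enzyme complex and ``or`` encodes
isozymes.  Published models frequently get this wrong in two ways that
matter for enzyme-constrained modeling:

* an ``and`` pair that is really a pair of isozymes (the two proteins are
  homologous — they catalyze the same reaction independently) inflates the
  complex molecular weight;
* the copy number of each subunit in a true complex (e.g. a heterotetramer
  of two alpha and two beta chains) is absent from the rule, so the complex
  weight computed from monomer weights is wrong.

This module provides: DNF normalization of GPR text, a term lexicon to
recognize complex-forming subunits from protein descriptions, a small
grammar over UniProt-style "Interaction" text that converts multiplicity
words (Homodimer, Heterotrimer, "Tetramer of two alpha and two beta
chains") into subunit counts, a global-alignment percent-identity screen
for suspect ``and`` pairs, and an explicit, logged edit step.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .errors import EcModelKitError, GprParseError
from .gem_io import ModelDocument, ReactionRecord

# ---------------------------------------------------------------------------
# GPR parsing -> disjunctive normal form
# ---------------------------------------------------------------------------

#: A complex is a sorted tuple of distinct gene ids.
Complex = tuple[str, ...]


@dataclass(frozen=True)
class GprExpression:
    """Disjunctive normal form of a GPR: each element is one candidate enzyme."""

    enzymes: tuple[Complex, ...]

    def __len__(self) -> int:
        return len(self.enzymes)

    def genes(self) -> set[str]:
        return {g for cx in self.enzymes for g in cx}

    def to_text(self) -> str:
        parts = [" and ".join(cx) if len(cx) > 1 else cx[0] for cx in self.enzymes]
        if len(parts) == 1:
            return parts[0]
        return " or ".join(f"({p})" if " " in p else p for p in parts)


_TOKEN_RE = re.compile(r"\(|\)|\S+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    out = []
    for m in re.finditer(r"[()]|[^\s()]+", text):
        out.append((m.group(0), m.start()))
    return out


def parse_gpr(text: str) -> GprExpression:
    """Parse GPR text into DNF with sorted gene ids and deduplicated complexes.

    Operators are case-insensitive; an empty string yields an empty
    expression (no catalyst).  Raises :class:`GprParseError` on unbalanced
    parentheses or dangling operators, with the offending position.
    """
    tokens = _tokenize(text)
    if not tokens:
        return GprExpression(())
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "or":
                pos += 1
                terms.append(parse_and())
            else:
                break
        # union of disjuncts
        return [cx for t in terms for cx in t]

    def parse_and():
        nonlocal pos
        factors = [parse_atom()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "and":
                pos += 1
                factors.append(parse_atom())
            else:
                break
        # cartesian product: (A or B) and (C or D) -> AC, AD, BC, BD
        out = []
        for combo in itertools.product(*factors):
            out.append(frozenset().union(*combo))
        return out

    def parse_atom():
        nonlocal pos
        tok, at = peek()
        if tok is None:
            raise GprParseError("unexpected end of GPR expression", at)
        if tok == "(":
            pos += 1
            inner = parse_or()
            tok2, at2 = peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parentheses", at2)
            pos += 1
            return inner
        if tok == ")":
            raise GprParseError("unbalanced parentheses", at)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"dangling operator {tok!r}", at)
        pos += 1
        return [frozenset([tok])]

    disjuncts = parse_or()
    tok, at = peek()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok!r}", at)
    seen: dict[Complex, None] = {}
    for d in disjuncts:
        seen.setdefault(tuple(sorted(d)), None)
    return GprExpression(tuple(sorted(seen)))


# ---------------------------------------------------------------------------
# protein records
# ---------------------------------------------------------------------------

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    gene_id: str
    protein_name: str
    monomer_mw: float  # kDa
    sequence: str
    interaction_text: str = ""

    def __post_init__(self):
        if self.monomer_mw <= 0:
            raise EcModelKitError(f"{self.accession}: monomer MW must be positive")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise EcModelKitError(f"{self.accession}: invalid residues {sorted(bad)}")


# ---------------------------------------------------------------------------
# complex-term detection
# ---------------------------------------------------------------------------

#: Terms in protein names / descriptions that indicate the protein is one
#: part of a multi-protein complex.  User-extensible.
DEFAULT_COMPLEX_LEXICON = (
    "subunit",
    "chain",
    "component",
    "binding protein",
    "assembly factor",
    "large subunit",
    "small subunit",
    "alpha subunit",
    "beta subunit",
)


def detect_complex_terms(
    name_or_description: str, lexicon=DEFAULT_COMPLEX_LEXICON
) -> tuple[bool, list[str]]:
    """Return whether any complex-indicating term occurs, and which ones.

    Matching is case-insensitive and word-boundary aware, so ``chain`` does
    not fire on "long-chain" only by substring accident at word interiors.
    """
    if not lexicon:
        raise EcModelKitError("empty lexicon")
    matched = []
    for term in lexicon:
        if re.search(rf"\b{re.escape(term)}\b", name_or_description, re.IGNORECASE):
            matched.append(term)
    return bool(matched), matched


# ---------------------------------------------------------------------------
# subunit-count grammar
# ---------------------------------------------------------------------------

#: Multiplicity words -> integers: Greek/Latin stems and spelled-out numerals.
DEFAULT_WORD_TABLE: dict[str, int] = {
    "mono": 1, "di": 2, "tri": 3, "tetra": 4, "penta": 5, "hexa": 6,
    "hepta": 7, "octa": 8, "nona": 9, "deca": 10, "undeca": 11, "dodeca": 12,
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
}


@dataclass(frozen=True)
class SubunitComposition:
    counts: dict[str, int]
    total: int
    defaulted: bool = False
    labels_known: bool = True

    def __post_init__(self):
        if self.total < 1:
            raise EcModelKitError("subunit total must be >= 1")
        if self.counts and sum(self.counts.values()) != self.total:
            raise EcModelKitError("subunit counts do not sum to total")


def _stem_value(stem: str, table: dict[str, int]) -> int | None:
    return table.get(stem.lower())


def parse_subunit_count(
    interaction_text: str, word_table: dict[str, int] | None = None
) -> SubunitComposition:
    """Translate UniProt-style oligomeric-state text into subunit counts.

    Recognized forms (case-insensitive, first match in the text wins):

    * ``Homo<k>mer`` (e.g. "Homodimer") -> total *k*, one subunit species;
    * ``Hetero<k>mer`` (e.g. "Heterotrimer") -> total *k*, species unknown;
    * ``<K>mer of <n1> <label1> and <n2> <label2> chains/subunits``
      (e.g. "Tetramer of two alpha and two beta chains") -> labelled counts;
    * bare ``<k>mer`` ("Dimer") -> total *k*, species unknown;
    * ``Monomer`` -> total 1.

    Anything else defaults to a monomer with ``defaulted=True`` — the flag
    is part of the contract so downstream weight calculations can report
    which enzymes carry assumed rather than parsed stoichiometry.
    """
    table = DEFAULT_WORD_TABLE if word_table is None else word_table
    text = interaction_text or ""

    # "<K>mer of <n1> <label1> ... and <n2> <label2> [chains|subunits]"
    m = re.search(
        r"(?:homo|hetero)?([a-z]+?)mer\s+of\s+([^.;]+)", text, re.IGNORECASE
    )
    if m:
        clause = m.group(2)
        parts = re.split(r",\s*|\s+and\s+", clause.strip())
        counts: dict[str, int] = {}
        ok = True
        for part in parts:
            pm = re.match(
                r"(?:(\d+)|([a-z]+))\s+([\w'-]+)(?:\s+(?:chains?|subunits?))?\s*$",
                part.strip(),
                re.IGNORECASE,
            )
            if not pm:
                ok = False
                break
            n = int(pm.group(1)) if pm.group(1) else _stem_value(pm.group(2), table)
            if n is None:
                ok = False
                break
            label = pm.group(3).lower()
            counts[label] = counts.get(label, 0) + n
        if ok and counts:
            stem_total = _stem_value(m.group(1), table)
            total = sum(counts.values())
            # the spelled-out clause is authoritative; the <K>mer stem is a
            # cross-check only (ignored when inconsistent, e.g. odd phrasing)
            if stem_total is not None and stem_total != total:
                pass
            return SubunitComposition(counts=counts, total=total)

    m = re.search(r"\bhomo([a-z]+?)mer(?:ic)?\b", text, re.IGNORECASE)
    if m:
        k = _stem_value(m.group(1), table)
        if k:
            return SubunitComposition(counts={"subunit": k}, total=k)

    m = re.search(r"\bhetero([a-z]+?)mer(?:ic)?\b", text, re.IGNORECASE)
    if m:
        k = _stem_value(m.group(1), table)
        if k:
            return SubunitComposition(counts={}, total=k, labels_known=False)

    if re.search(r"\bmonomer(?:ic)?\b", text, re.IGNORECASE):
        return SubunitComposition(counts={"subunit": 1}, total=1)

    m = re.search(r"\b([a-z]+?)mer(?:ic)?\b", text, re.IGNORECASE)
    if m:
        k = _stem_value(m.group(1), table)
        if k:
            return SubunitComposition(counts={}, total=k, labels_known=False)

    return SubunitComposition(counts={"subunit": 1}, total=1, defaulted=True)


# ---------------------------------------------------------------------------
# sequence-identity screen
# ---------------------------------------------------------------------------


def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity in [0, 100].

    Needleman-Wunsch with BLOSUM62 scoring and affine gaps (open 10,
    extend 0.5); identity = identical columns / alignment columns x 100.
    Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise EcModelKitError("pairwise_identity requires two non-empty sequences")
    a, b = seq_a.upper(), seq_b.upper()
    if a == b:
        return 100.0
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


@dataclass(frozen=True)
class ScreenResult:
    reaction_id: str
    gene_pair: tuple[str, str]
    identity: float | None
    verdict: str  # "suspect: convert and->or (manual check advised)" | "keep" | "unscreened"


SUSPECT = "suspect: convert and->or (manual check advised)"


def screen_and_relationships(
    model: ModelDocument,
    proteins: list[ProteinRecord],
    threshold: float = 20.0,
) -> list[ScreenResult]:
    """Flag ``and`` gene pairs whose proteins are mutually similar.

    Two proteins joined by ``and`` should be different subunits of one
    complex; a pairwise identity strictly greater than *threshold* percent
    suggests they are homologs — i.e. isozymes wrongly written as a
    complex.  Pairs lacking a sequence are reported as ``unscreened``
    rather than silently dropped.  Results are sorted by identity
    descending (unscreened last), then by reaction id.
    """
    seq_by_gene = {p.gene_id: p.sequence for p in proteins}
    results: list[ScreenResult] = []
    for r in model.reactions:
        expr = parse_gpr(r.gpr_text)
        for cx in expr.enzymes:
            if len(cx) < 2:
                continue
            for ga, gb in itertools.combinations(cx, 2):
                sa, sb = seq_by_gene.get(ga), seq_by_gene.get(gb)
                if not sa or not sb:
                    results.append(ScreenResult(r.id, (ga, gb), None, "unscreened"))
                    continue
                ident = pairwise_identity(sa, sb)
                verdict = SUSPECT if ident > threshold else "keep"
                results.append(ScreenResult(r.id, (ga, gb), ident, verdict))
    results.sort(key=lambda s: (-(s.identity if s.identity is not None else -1.0), s.reaction_id))
    return results


# ---------------------------------------------------------------------------
# explicit, logged GPR edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GprEdit:
    reaction_id: str
    old_gpr: str
    new_gpr: str


def apply_gpr_corrections(
    model: ModelDocument, edits: list[tuple[str, str]]
) -> tuple[ModelDocument, list[GprEdit]]:
    """Apply explicit GPR replacements; returns the new model and an edit log.

    Every new rule is parsed before any edit is applied, so a malformed
    edit leaves the model untouched.
    """
    rxn_ids = model.reaction_ids()
    for rid, new_text in edits:
        if rid not in rxn_ids:
            raise EcModelKitError(f"GPR edit targets unknown reaction {rid!r}")
        parse_gpr(new_text)  # raises GprParseError on malformed input
    out = model.copy()
    log: list[GprEdit] = []
    by_id = {r.id: r for r in out.reactions}
    for rid, new_text in edits:
        old = by_id[rid]
        log.append(GprEdit(rid, old.gpr_text, new_text))
        new_genes = parse_gpr(new_text).genes() - set(out.genes)
        if new_genes:
            out.genes = out.genes + sorted(new_genes)
        by_id[rid] = ReactionRecord(
            id=old.id, name=old.name, stoichiometry=old.stoichiometry,
            lower_bound=old.lower_bound, upper_bound=old.upper_bound,
            gpr_text=new_text, ec_numbers=old.ec_numbers, annotations=old.annotations,
        )
    out.reactions = [by_id[r.id] for r in out.reactions]
    return out, log


# ---------------------------------------------------------------------------
# protein-record I/O
# ---------------------------------------------------------------------------

PROTEIN_TSV_COLUMNS = ("accession", "gene_id", "protein_name", "monomer_mw_kda", "interaction_text", "sequence")


def read_protein_tsv(path) -> list[ProteinRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(PROTEIN_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise EcModelKitError(f"protein TSV missing columns: {sorted(missing)}")
    return [
        ProteinRecord(
            accession=row.accession,
            gene_id=row.gene_id,
            protein_name=row.protein_name,
            monomer_mw=float(row.monomer_mw_kda),
            sequence=row.sequence,
            interaction_text=row.interaction_text,
        )
        for row in df.itertuples()
    ]


def write_protein_tsv(records: list[ProteinRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "accession": p.accession,
                "gene_id": p.gene_id,
                "protein_name": p.protein_name,
                "monomer_mw_kda": p.monomer_mw,
                "interaction_text": p.interaction_text,
                "sequence": p.sequence,
            }
            for p in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_protein_flatfile(path) -> list[ProteinRecord]:
    """Minimal SwissProt-like flat-text reader.

    Understands ``ID`` (accession), ``GN`` (gene id), ``DE`` (protein
    name), ``CC   -!- SUBUNIT:`` (interaction text, possibly continued on
    following ``CC`` lines), ``MW`` (monomer kDa) and ``SQ`` + sequence
    lines terminated by ``//``.
    """
    records: list[ProteinRecord] = []
    cur: dict = {}
    in_seq = False
    in_subunit = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("//"):
                if cur:
                    records.append(
                        ProteinRecord(
                            accession=cur.get("id", ""),
                            gene_id=cur.get("gn", ""),
                            protein_name=cur.get("de", ""),
                            monomer_mw=float(cur.get("mw", 0) or 0),
                            sequence=cur.get("seq", ""),
                            interaction_text=cur.get("subunit", "").strip(),
                        )
                    )
                cur, in_seq, in_subunit = {}, False, False
                continue
            if in_seq:
                cur["seq"] = cur.get("seq", "") + "".join(line.split())
                continue
            tag, _, rest = line.partition("   ")
            rest = rest.strip()
            if tag == "ID":
                cur["id"] = rest.split()[0]
            elif tag == "GN":
                cur["gn"] = rest.rstrip(";").replace("Name=", "").strip()
            elif tag == "DE":
                cur["de"] = (cur.get("de", "") + " " + rest).strip()
            elif tag == "MW":
                cur["mw"] = rest
            elif tag == "CC":
                if rest.startswith("-!- SUBUNIT:"):
                    in_subunit = True
                    cur["subunit"] = rest[len("-!- SUBUNIT:"):].strip()
                elif rest.startswith("-!-"):
                    in_subunit = False
                elif in_subunit:
                    cur["subunit"] = cur.get("subunit", "") + " " + rest
            elif tag == "SQ":
                in_seq = True
    return records
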