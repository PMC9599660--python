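import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmodelkit import (
    GprParseError,
    MetaboliteRecord,
    ModelDocument,
    ProteinRecord,
    ReactionRecord,
    apply_gpr_corrections,
    detect_complex_terms,
    pairwise_identity,
    parse_gpr,
    parse_subunit_count,
    screen_and_relationships,
)
from ecmodelkit.errors import EcModelKitError
from ecmodelkit.gpr_curation import SUSPECT


# ---------------------------------------------------------------------------
# parse_gpr
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Cgl2565 and Cgl2566", (("Cgl2565", "Cgl2566"),)),
        ("a or b", (("a",), ("b",))),
        ("a and (b or c)", (("a", "b"), ("a", "c"))),
        ("a AND b OR c", (("a", "b"), ("c",))),
        ("(a or b) and (c or d)", (("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"))),
        ("", ()),
    ],
)
def test_parse_gpr_dnf(text, expected):
    assert parse_gpr(text).enzymes == expected


@pytest.mark.parametrize("text", ["a and", "(a or b", "a or or b", "a b)", "and a"])
def test_parse_gpr_rejects_malformed(text):
    with pytest.raises(GprParseError):
        parse_gpr(text)


def _random_tree(rng, genes):
    """Random and/or tree over distinct genes; returns (text, expansion_count)."""
    if len(genes) == 1:
        return genes[0], 1
    k = rng.randrange(1, len(genes))
    left, right = genes[:k], genes[k:]
    lt, lc = _random_tree(rng, left)
    rt, rc = _random_tree(rng, right)
    if rng.random() < 0.5:
        return f"({lt}) or ({rt})", lc + rc  # disjunct counts add
    return f"({lt}) and ({rt})", lc * rc  # cartesian product


def test_dnf_size_matches_product_sum_oracle():
    rng = random.Random(42)
    for trial in range(50):
        n = rng.randrange(1, 7)
        genes = [f"g{trial}_{i}" for i in range(n)]
        text, count = _random_tree(rng, genes)
        assert len(parse_gpr(text)) == count


def test_dnf_is_boolean_equivalent_by_truth_table():
    rng = random.Random(7)
    for trial in range(30):
        genes = [f"x{i}" for i in range(rng.randrange(1, 6))]
        text, _ = _random_tree(rng, genes)
        expr = parse_gpr(text)
        py = text.replace("and", " and ").replace("or", " or ")
        for values in itertools.product([False, True], repeat=len(genes)):
            env = dict(zip(genes, values))
            direct = eval(py, {}, env)
            via_dnf = any(all(env[g] for g in cx) for cx in expr.enzymes)
            assert direct == via_dnf


# ---------------------------------------------------------------------------
# complex-term detection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "name,hit,term",
    [
        ("Anthranilate synthase component 1", True, "component"),
        ("Citrate synthase", False, None),
        ("NADH dehydrogenase subunit B", True, "subunit"),
        ("ATP-binding protein of ABC transporter", True, "binding protein"),
        ("Chaperonin assembly factor", True, "assembly factor"),
        ("polypeptide CHAIN elongation", True, "chain"),
    ],
)
def test_detect_complex_terms(name, hit, term):
    found, matched = detect_complex_terms(name)
    assert found is hit
    if term:
        assert term in matched


# ---------------------------------------------------------------------------
# subunit-count grammar
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,total,counts,defaulted",
    [
        ("Homodimer", 2, {"subunit": 2}, False),
        ("", 1, {"subunit": 1}, True),
        ("Tetramer of two alpha and two beta chains", 4, {"alpha": 2, "beta": 2}, False),
        ("Heterotrimer", 3, {}, False),
        ("Homotetramer; binds DNA", 4, {"subunit": 4}, False),
        ("Monomer", 1, {"subunit": 1}, False),
        ("Hexamer of three alpha and three beta subunits", 6, {"alpha": 3, "beta": 3}, False),
        ("Homodecamer", 10, {"subunit": 10}, False),
        ("Dimer", 2, {}, False),
        ("Interacts with RpoB", 1, {"subunit": 1}, True),
        ("Trimer of 2 large and 1 small subunits", 3, {"large": 2, "small": 1}, False),
    ],
)
def test_parse_subunit_count(text, total, counts, defaulted):
    comp = parse_subunit_count(text)
    assert comp.total == total
    assert comp.counts == counts
    assert comp.defaulted is defaulted


@settings(max_examples=200, deadline=None)
@given(st.text(max_size=40))
def test_subunit_total_at_least_one_and_flag_consistent(text):
    comp = parse_subunit_count(text)
    assert comp.total >= 1
    if comp.defaulted:
        assert comp.total == 1


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------


def test_identity_of_identical_sequences():
    assert pairwise_identity("MKTAYIAKQR", "MKTAYIAKQR") == 100.0


def test_identity_of_disjoint_sequences():
    assert pairwise_identity("AAAA", "CCCC") == 0.0


def test_identity_matches_gapless_oracle():
    # equal-length 10-mers, 3 mismatches; the worst BLOSUM62 mismatch
    # (-4) beats opening a gap (-10 - 0.5), so the optimal global
    # alignment is gapless and identity is exactly matches/length
    a = "MKTAYIAKQR"
    b = "MKTGYIGKQW"  # mismatches at positions 3, 6, 9
    assert pairwise_identity(a, b) == pytest.approx(70.0)


def test_identity_with_forced_terminal_gap():
    # b extends a by 3 residues: alignment has 10 matched + 3 gap columns
    a = "MKTAYIAKQR"
    b = a + "GGG"
    assert pairwise_identity(a, b) == pytest.approx(100.0 * 10 / 13)


def test_identity_symmetric_and_bounded():
    rng = random.Random(3)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(10):
        a = "".join(rng.choice(aas) for _ in range(rng.randrange(5, 30)))
        b = "".join(rng.choice(aas) for _ in range(rng.randrange(5, 30)))
        ab, ba = pairwise_identity(a, b), pairwise_identity(b, a)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 100.0


def test_identity_rejects_empty():
    with pytest.raises(EcModelKitError):
        pairwise_identity("", "ACD")


# ---------------------------------------------------------------------------
# and-relationship screen
# ---------------------------------------------------------------------------


def _screen_model(gpr="a and b"):
    return ModelDocument(
        metabolites=[MetaboliteRecord("m_c", "m", "c"), MetaboliteRecord("n_c", "n", "c")],
        reactions=[ReactionRecord("MCITL2", {"m_c": -1.0, "n_c": 1.0}, 0.0, 10.0, gpr_text=gpr)],
        genes=["a", "b"],
        objective={},
    )


def _prot(gene, seq):
    return ProteinRecord(accession=gene.upper(), gene_id=gene, protein_name=gene,
                         monomer_mw=30.0, sequence=seq, interaction_text="")


def test_screen_flags_similar_and_pair():
    # 81% identical pair (near-identical sequences), well above threshold
    a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    b = a[:6] + "GWPCHN" + a[12:]
    ident = pairwise_identity(a, b)
    assert ident > 20
    results = screen_and_relationships(_screen_model(), [_prot("a", a), _prot("b", b)])
    assert len(results) == 1
    assert results[0].verdict == SUSPECT
    assert results[0].identity == pytest.approx(ident)


def test_screen_keeps_dissimilar_pair():
    results = screen_and_relationships(
        _screen_model(), [_prot("a", "AAAAAAAAAA"), _prot("b", "CCCCCCCCCC")]
    )
    assert results[0].verdict == "keep"


def test_screen_threshold_is_strict_greater_than():
    a, b = "AAAAA", "AACCC"  # gapless optimum: 2/5 = 40% identity
    ident = pairwise_identity(a, b)
    results = screen_and_relationships(
        _screen_model(), [_prot("a", a), _prot("b", b)], threshold=ident
    )
    assert results[0].verdict == "keep"
    results = screen_and_relationships(
        _screen_model(), [_prot("a", a), _prot("b", b)], threshold=ident - 1e-9
    )
    assert results[0].verdict == SUSPECT


def test_screen_reports_missing_sequence_as_unscreened():
    results = screen_and_relationships(_screen_model(), [_prot("a", "AAAA")])
    assert results[0].verdict == "unscreened"


def test_screen_monotone_in_threshold():
    rng = random.Random(11)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    prots = [_prot(g, "".join(rng.choice(aas) for _ in range(20))) for g in ("a", "b")]
    suspects = []
    for thr in (0.0, 10.0, 50.0, 99.0):
        res = screen_and_relationships(_screen_model(), prots, threshold=thr)
        suspects.append(sum(1 for r in res if r.verdict == SUSPECT))
    assert suspects == sorted(suspects, reverse=True)


# ---------------------------------------------------------------------------
# explicit corrections
# ---------------------------------------------------------------------------


def test_apply_gpr_corrections_and_to_or():
    model = _screen_model("a and b")
    out, log = apply_gpr_corrections(model, [("MCITL2", "a or b")])
    assert len(parse_gpr(out.get_reaction("MCITL2").gpr_text)) == 2
    assert log[0].old_gpr == "a and b" and log[0].new_gpr == "a or b"
    assert model.get_reaction("MCITL2").gpr_text == "a and b"  # input untouched


def test_apply_gpr_corrections_empty_and_errors():
    model = _screen_model()
    out, log = apply_gpr_corrections(model, [])
    assert out.get_reaction("MCITL2").gpr_text == model.get_reaction("MCITL2").gpr_text
    assert log == []
    with pytest.raises(EcModelKitError, match="GHOST"):
        apply_gpr_corrections(model, [("GHOST", "a")])
    with pytest.raises(GprParseError):
        apply_gpr_corrections(model, [("MCITL2", "a and (b")])
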