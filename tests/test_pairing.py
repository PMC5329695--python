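"""Pseudoknot pair classification, state extraction and artifact prediction."""

import itertools

import pytest

from primer16s import (
    PairClass,
    PairedSiteRegistry,
    TemplateRecord,
    ValidationError,
    audit_primer,
    build_coordinate_map,
    classify_pair,
    composition_profile,
    predict_amplicon,
    template_pair_state,
)
from primer16s.pairing import pair_geometry


# ---------------------------------------------------------------- rule table

@pytest.mark.parametrize("b19, b916, expected", [
    ("A", "T", PairClass.NATIVE_FUNCTIONAL),      # gamma-like 19A-916U
    ("A", "U", PairClass.NATIVE_FUNCTIONAL),      # RNA alphabet accepted
    ("C", "G", PairClass.NATIVE_FUNCTIONAL),      # beta-like 19C-916G
    ("A", "G", PairClass.NONNATIVE_FUNCTIONAL),   # primer-creatable, tolerated
    ("C", "T", PairClass.NONNATIVE_DEFECTIVE),    # primer-creatable, defective
    ("C", "U", PairClass.NONNATIVE_DEFECTIVE),
    ("G", "T", PairClass.UNKNOWN),                # never assayed
    ("T", "A", PairClass.UNKNOWN),                # orientation matters
    (None, "T", PairClass.ABSENT),
    ("A", None, PairClass.ABSENT),
    ("-", "G", PairClass.ABSENT),
])
def test_classify_pair_rule_table(b19, b916, expected):
    assert classify_pair(b19, b916) is expected


def test_rule_table_is_total_and_exactly_four_known_combinations():
    """Only the four experimentally tested combinations leave 'unknown'."""
    known = 0
    for a, b in itertools.product("ACGT", repeat=2):
        cls = classify_pair(a, b)          # total: never raises on concrete bases
        assert cls is classify_pair(a, b)  # deterministic
        if cls not in (PairClass.UNKNOWN, PairClass.ABSENT):
            known += 1
    assert known == 4


def test_ambiguous_bases_rejected_with_guidance():
    with pytest.raises(ValidationError, match="expand"):
        classify_pair("R", "T")


def test_pair_geometry_annotation():
    assert pair_geometry("A", "T") == "watson_crick"
    assert pair_geometry("G", "C") == "watson_crick"
    assert pair_geometry("G", "T") == "wobble"
    assert pair_geometry("A", "G") == "mispair"
    assert pair_geometry(None, "G") == "absent"


def test_registry_invariants():
    reg = PairedSiteRegistry()
    assert reg.partner_of(19) == 916 and reg.partner_of(916) == 19
    assert reg.partner_of(1527) is None
    assert reg.all_positions == {17, 18, 19, 916, 917, 918, 1527}
    with pytest.raises(ValidationError):
        PairedSiteRegistry(pairs=((19, 916), (19, 918)))
    with pytest.raises(ValidationError):
        PairedSiteRegistry(pairs=((916, 19),))


# ---------------------------------------------------------------- pair state

def test_reference_template_is_native_gamma_like(reference):
    cm = build_coordinate_map(reference, reference)
    states = template_pair_state(reference, cm)
    focus = next(s for s in states if s.pair == (19, 916))
    assert (focus.base_a, focus.base_b) == ("A", "T")
    assert focus.pair_class is PairClass.NATIVE_FUNCTIONAL
    # h2 companions are annotated but never functionality-classified
    for s in states:
        if s.pair != (19, 916):
            assert s.pair_class is None
            assert s.geometry == "watson_crick"


def test_beta_like_template_is_native_functional(reference):
    beta = reference[:18] + "C" + reference[19:915] + "G" + reference[916:]
    cm = build_coordinate_map(beta, reference)
    focus = next(s for s in template_pair_state(beta, cm) if s.pair == (19, 916))
    assert (focus.base_a, focus.base_b) == ("C", "G")
    assert focus.pair_class is PairClass.NATIVE_FUNCTIONAL


def test_truncated_template_reports_absent(reference):
    cm = build_coordinate_map(reference[:800], reference)
    focus = next(s for s in template_pair_state(reference[:800], cm)
                 if s.pair == (19, 916))
    assert focus.base_b is None
    assert focus.pair_class is PairClass.ABSENT


# ---------------------------------------------------------------- prediction

def _map(seq, reference):
    return build_coordinate_map(seq, reference)


def test_variant_primer_on_beta_template_creates_functional_artifact(
        reference, primers):
    """8-27 primer with 19A over a 19C/916G template fixes the non-native
    A-G pair into the amplicon."""
    beta = reference[:18] + "C" + reference[19:915] + "G" + reference[916:]
    t = TemplateRecord(id="beta", sequence=beta)
    pred = predict_amplicon(t, primers["Bac8f(A)"], primers["UN1542r"],
                            _map(beta, reference))
    assert pred.amplifiable
    assert [(s.ecoli_pos, s.template_base, s.imposed_base)
            for s in pred.substitutions] == [(19, "C", "A")]
    assert pred.risk_flag == "artifact_functional"


def test_variant_primer_on_gamma_template_creates_defective_artifact(
        reference, primers):
    t = TemplateRecord(id="gamma", sequence=reference)
    pred = predict_amplicon(t, primers["Bac8f(C)"], primers["UN1542r"],
                            _map(reference, reference))
    assert [(s.ecoli_pos, s.template_base, s.imposed_base)
            for s in pred.substitutions] == [(19, "A", "C")]
    assert pred.risk_flag == "artifact_defective"
    focus_after = next(s for s in pred.pair_states_after if s.pair == (19, 916))
    assert focus_after.pair_class is PairClass.NONNATIVE_DEFECTIVE


def test_safe_primer_pair_never_alters_any_pair_state(mixed_corpus, primers):
    """Headline property: the 1-18 / 1528-1542 primer set leaves every
    pseudoknot pair state of every synthetic template unchanged."""
    records, _, maps = mixed_corpus
    n_checked = 0
    for r in records:
        if not maps[r.id].anchorable:
            continue
        pred = predict_amplicon(r, primers["Bac1f"], primers["UN1542r"],
                                maps[r.id])
        if not pred.amplifiable:
            continue
        n_checked += 1
        assert pred.risk_flag == "none"
        for before, after in zip(pred.pair_states_before, pred.pair_states_after):
            assert (before.base_a, before.base_b, before.pair_class) == \
                   (after.base_a, after.base_b, after.pair_class)
        assert all(s.ecoli_pos not in (19, 916, 1527)
                   for s in pred.substitutions)
    assert n_checked > 20


def test_prediction_is_idempotent(reference, primers):
    """Re-amplifying a predicted amplicon introduces no further changes."""
    beta = reference[:18] + "C" + reference[19:915] + "G" + reference[916:]
    t = TemplateRecord(id="b", sequence=beta)
    pred = predict_amplicon(t, primers["Bac8f(A)"], primers["UN1542r"],
                            _map(beta, reference))
    amplicon = TemplateRecord(id="amp", sequence=pred.amplicon_sequence)
    pred2 = predict_amplicon(amplicon, primers["Bac8f(A)"], primers["UN1542r"],
                             _map(amplicon.sequence, reference))
    assert pred2.amplifiable
    assert pred2.substitutions == []
    assert pred2.risk_flag == "none"


def test_unanchorable_template_not_amplifiable(reference, primers):
    t = TemplateRecord(id="junk", sequence="ACGT" * 100)
    pred = predict_amplicon(t, primers["Bac1f"], primers["UN1542r"],
                            _map(t.sequence, reference))
    assert not pred.amplifiable


def test_degenerate_positions_adopt_template_base(reference, primers):
    """A degenerate primer position compatible with the template imposes
    nothing; an incompatible one imposes the smallest expansion member."""
    from primer16s import Primer
    p = Primer("degen", "AAATTGAAGAGTTTGATN", "forward", (1, 18))
    t = TemplateRecord(id="r", sequence=reference)
    pred = predict_amplicon(t, p, primers["UN1542r"], _map(reference, reference))
    assert pred.substitutions == []

    # template carries G at position 4 where the primer has Y = {C, T}
    mut = reference[:3] + "G" + reference[4:]
    py = Primer("y4", "AAAYTGAAGAGTTTGATC", "forward", (1, 18))
    pred2 = predict_amplicon(TemplateRecord(id="m", sequence=mut), py,
                             primers["UN1542r"], _map(mut, reference))
    subs = [s for s in pred2.substitutions if s.ecoli_pos == 4]
    assert len(subs) == 1
    assert subs[0].imposed_base == "C" and subs[0].ambiguous


# ---------------------------------------------------------------- audits

def test_audit_verdicts_on_mixed_collection(clean_corpus, primers):
    records, _, maps = clean_corpus
    registry = PairedSiteRegistry()
    prof5 = composition_profile(records, maps, (1, 30))
    prof3 = composition_profile(records, maps, (1520, 1542))

    unsafe = audit_primer(primers["Bac8f(A)"], registry, prof5)
    assert not unsafe.safe and unsafe.offending_positions == [19]

    safe = audit_primer(primers["Bac1f"], registry, prof5)
    assert safe.safe and safe.verdict == "safe"

    lone = audit_primer(primers["UN1541r(U)"], registry, prof3)
    assert not lone.safe and lone.offending_positions == [1527]

    assert audit_primer(primers["UN1542r"], registry, prof3).safe
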