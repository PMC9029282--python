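"""Allele harmonization: orientation cases, palindromes, invariances."""

import dataclasses

import pytest

from mrkit.estimators import wald_ratio
from mrkit.harmonization import (
    ABSENT,
    AMBIGUOUS,
    MISMATCH,
    HarmonizedPair,
    harmonize,
)
from mrkit.instrument_selection import InstrumentSet
from conftest import make_record, make_table


def run_one(exp_kw, out_kw, policy="infer_by_eaf", band=0.08):
    exposure = make_table([make_record("rs1", **exp_kw)], role="exposure")
    outcome = make_table([make_record("rs1", **out_kw)], role="outcome")
    return harmonize(
        InstrumentSet(["rs1"]), exposure, outcome, palindromic_policy=policy,
        eaf_ambiguity_band=band,
    )


@pytest.mark.parametrize(
    "out_alleles, out_beta, expected_action, expected_Gamma",
    [
        (("A", "G"), 0.05, "none", 0.05),
        (("G", "A"), 0.05, "sign_flip", -0.05),
        (("T", "C"), 0.05, "strand_flip", 0.05),  # reverse complement of A/G
        (("C", "T"), 0.05, "strand_flip_and_sign_flip", -0.05),
    ],
)
def test_orientation_cases(out_alleles, out_beta, expected_action, expected_Gamma):
    report = run_one(
        dict(effect_allele="A", other_allele="G", beta=0.1),
        dict(effect_allele=out_alleles[0], other_allele=out_alleles[1], beta=out_beta),
    )
    assert not report.removed
    (pair,) = report.kept
    assert pair.action == expected_action
    assert pair.Gamma_hat == pytest.approx(expected_Gamma)
    assert pair.gamma_hat == pytest.approx(0.1)


def test_irreconcilable_alleles_removed():
    report = run_one(
        dict(effect_allele="A", other_allele="G"),
        dict(effect_allele="A", other_allele="C"),
    )
    assert report.removed == [("rs1", MISMATCH)]


def test_variant_absent_from_outcome_removed():
    exposure = make_table([make_record("rs1"), make_record("rs2")], role="exposure")
    outcome = make_table([make_record("rs1")], role="outcome")
    report = harmonize(InstrumentSet(["rs1", "rs2"]), exposure, outcome)
    assert report.kept_ids == ["rs1"]
    assert report.removed == [("rs2", ABSENT)]


def test_palindromic_dropped_under_drop_policy():
    report = run_one(
        dict(effect_allele="A", other_allele="T", eaf=0.1),
        dict(effect_allele="A", other_allele="T", eaf=0.1),
        policy="drop",
    )
    assert report.removed == [("rs1", AMBIGUOUS)]


def test_palindromic_opposite_minor_allele_sign_flips():
    report = run_one(
        dict(effect_allele="A", other_allele="T", eaf=0.10, beta=0.1),
        dict(effect_allele="A", other_allele="T", eaf=0.88, beta=0.05),
        band=0.08,
    )
    (pair,) = report.kept
    assert pair.action == "sign_flip" and pair.palindromic
    assert pair.Gamma_hat == pytest.approx(-0.05)
    assert pair.eaf_outcome == pytest.approx(0.12)


def test_palindromic_inference_matches_physical_enumeration():
    """Exhaustive check of the 2x2 label/strand cases against physical truth.

    The physical situation: the exposure's effect allele has frequency 0.1
    and the true outcome effect on it is +0.05.  The outcome GWAS may have
    labelled either allele as effect allele, and may have genotyped either
    strand (invisible for an A/T pair).  Whatever the labelling, the
    harmonized outcome effect must recover +0.05.
    """
    truth_effect, truth_eaf = 0.05, 0.1
    for reported_ea, reported_oa in [("A", "T"), ("T", "A")]:
        for strand_flipped in (False, True):
            # what the outcome GWAS reports for its chosen label
            physical_allele = reported_ea if not strand_flipped else {"A": "T", "T": "A"}[reported_ea]
            if physical_allele == "A":  # the exposure's effect allele
                out_beta, out_eaf = truth_effect, truth_eaf
            else:
                out_beta, out_eaf = -truth_effect, 1 - truth_eaf
            report = run_one(
                dict(effect_allele="A", other_allele="T", eaf=truth_eaf, beta=0.1),
                dict(effect_allele=reported_ea, other_allele=reported_oa,
                     eaf=out_eaf, beta=out_beta),
            )
            (pair,) = report.kept
            assert pair.Gamma_hat == pytest.approx(truth_effect), (
                reported_ea, strand_flipped,
            )


def test_palindromic_ambiguous_eaf_band_removed():
    for eaf_exp, eaf_out in [(0.45, 0.1), (0.1, 0.55), (0.5, 0.5)]:
        report = run_one(
            dict(effect_allele="C", other_allele="G", eaf=eaf_exp),
            dict(effect_allele="C", other_allele="G", eaf=eaf_out),
            band=0.08,
        )
        assert report.removed == [("rs1", AMBIGUOUS)]


def test_palindromic_missing_eaf_removed_conservatively():
    report = run_one(
        dict(effect_allele="A", other_allele="T", eaf=None),
        dict(effect_allele="A", other_allele="T", eaf=0.1),
    )
    assert report.removed == [("rs1", AMBIGUOUS)]


def test_harmonization_is_idempotent():
    """Re-harmonizing tables already on a common effect allele changes nothing."""
    exposure = make_table(
        [make_record("rs1", effect_allele="A", other_allele="G", beta=0.1, eaf=0.2)],
        role="exposure",
    )
    outcome_raw = make_table(
        [make_record("rs1", effect_allele="G", other_allele="A", beta=0.05, eaf=0.7)],
        role="outcome",
    )
    first = harmonize(InstrumentSet(["rs1"]), exposure, outcome_raw)
    (pair,) = first.kept
    # rebuild an outcome table expressing the harmonized effect
    outcome_aligned = make_table(
        [
            make_record(
                "rs1",
                effect_allele="A",
                other_allele="G",
                beta=pair.Gamma_hat,
                eaf=pair.eaf_outcome,
            )
        ],
        role="outcome",
    )
    second = harmonize(InstrumentSet(["rs1"]), exposure, outcome_aligned)
    (pair2,) = second.kept
    assert pair2.action == "none"
    assert pair2.Gamma_hat == pair.Gamma_hat
    assert pair2.eaf_outcome == pair.eaf_outcome


def test_sign_flip_is_an_involution():
    rec = make_record("rs1", effect_allele="A", other_allele="G", beta=0.3, eaf=0.2)
    back = rec.flipped().flipped()
    assert back.beta == rec.beta
    assert back.effect_allele == rec.effect_allele and back.other_allele == rec.other_allele
    assert back.eaf == pytest.approx(rec.eaf)


def test_wald_ratio_invariant_to_effect_allele_choice():
    """Flipping the exposure's effect allele flips both effects; the ratio survives."""
    exposure = make_table(
        [make_record("rs1", effect_allele="A", other_allele="G", beta=0.1, eaf=0.2)],
        role="exposure",
    )
    outcome = make_table(
        [make_record("rs1", effect_allele="A", other_allele="G", beta=0.05, eaf=0.25)],
        role="outcome",
    )
    flipped_exposure = make_table([exposure.get("rs1").flipped()], role="exposure")
    (p1,) = harmonize(InstrumentSet(["rs1"]), exposure, outcome).kept
    (p2,) = harmonize(InstrumentSet(["rs1"]), flipped_exposure, outcome).kept
    assert p2.gamma_hat == -p1.gamma_hat and p2.Gamma_hat == -p1.Gamma_hat
    assert wald_ratio(p1).beta_hat == pytest.approx(wald_ratio(p2).beta_hat)
    assert wald_ratio(p1).se == pytest.approx(wald_ratio(p2).se)


def test_report_partitions_the_instrument_set():
    exposure = make_table(
        [
            make_record("rs1", effect_allele="A", other_allele="G"),
            make_record("rs2", effect_allele="A", other_allele="T", eaf=0.5),
            make_record("rs3", effect_allele="C", other_allele="A"),
        ],
        role="exposure",
    )
    outcome = make_table(
        [
            make_record("rs1", effect_allele="A", other_allele="G"),
            make_record("rs2", effect_allele="A", other_allele="T", eaf=0.5),
        ],
        role="outcome",
    )
    report = harmonize(InstrumentSet(["rs1", "rs2", "rs3"]), exposure, outcome)
    kept = set(report.kept_ids)
    removed = {vid for vid, _ in report.removed}
    assert kept | removed == {"rs1", "rs2", "rs3"} and not (kept & removed)


def test_empty_instrument_set_and_bad_policy_are_errors():
    table = make_table([make_record("rs1")])
    with pytest.raises(ValueError, match="empty"):
        harmonize(InstrumentSet([]), table, table)
    with pytest.raises(ValueError, match="policy"):
        harmonize(InstrumentSet(["rs1"]), table, table, palindromic_policy="keep")


def test_pair_rejects_nonpositive_se():
    with pytest.raises(ValueError):
        HarmonizedPair("rs1", 0.1, 0.0, 0.05, 0.01)
    pair = HarmonizedPair("rs1", -0.1, 0.01, 0.05, 0.02)
    flipped = pair.oriented_positive()
    assert flipped.gamma_hat == 0.1 and flipped.Gamma_hat == -0.05
    assert dataclasses.replace(flipped) == flipped.oriented_positive()
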