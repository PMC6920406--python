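"""Reading, validation and harmonization of summary-statistic tables."""

import itertools

import numpy as np
import pytest

from mrkit.summary_data import (
    DROPPED_ACTIONS,
    SnpAssociation,
    SummaryDataError,
    complement_allele,
    harmonize,
    is_palindromic,
    mean_f_statistic,
    read_summary_table,
    write_summary_table,
)
from conftest import build_instruments


def snp(rsid, ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3, p=1e-9):
    return SnpAssociation(rsid, ea, oa, beta, se, eaf, p)


# ---------------------------------------------------------------- reading


def test_read_summary_table_roundtrips_valid_rows(tmp_path):
    path = tmp_path / "sumstats.tsv"
    path.write_text(
        "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\n"
        "rs1\ta\tg\t0.25\t0.021\t0.002\t1e-10\n"
        "rs2\tT\tC\t0.6\t-0.015\t0.003\t2e-8\n"
        "rs3\tG\tC\t0.48\t0.018\t0.0025\tNA\n"
    )
    records = read_summary_table(path)
    assert len(records) == 3
    assert records[0] == SnpAssociation("rs1", "A", "G", 0.021, 0.002, 0.25, 1e-10)
    assert records[1].beta == -0.015
    assert records[2].pvalue is None and records[2].palindromic


def test_read_summary_table_write_read_identity(tmp_path):
    records = [snp("rs1"), snp("rs2", "T", "C", -0.02, 0.005, 0.7, 0.04)]
    path = tmp_path / "out.tsv"
    write_summary_table(records, path)
    assert read_summary_table(path) == records


def test_read_rejects_nonpositive_se_naming_offender(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\n"
        "rs1\tA\tG\t0.2\t0.02\t0.002\t1e-9\n"
        "rsBAD\tA\tG\t0.2\t0.02\t0\t1e-9\n"
    )
    with pytest.raises(SummaryDataError, match="rsBAD"):
        read_summary_table(path)


def test_read_rejects_duplicate_rsids(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text(
        "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\n"
        "rs1\tA\tG\t0.2\t0.02\t0.002\t1e-9\n"
        "rs1\tT\tC\t0.3\t0.01\t0.002\t1e-9\n"
    )
    with pytest.raises(SummaryDataError, match="rs1"):
        read_summary_table(path)


def test_read_with_custom_column_map_and_csv(tmp_path):
    path = tmp_path / "sumstats.csv"
    path.write_text("marker,a1,a2,freq,b,stderr,p\nrs9,C,T,0.1,0.05,0.01,0.001\n")
    records = read_summary_table(
        path,
        column_map={
            "rsid": "marker",
            "effect_allele": "a1",
            "other_allele": "a2",
            "eaf": "freq",
            "beta": "b",
            "se": "stderr",
            "pvalue": "p",
        },
    )
    assert records == [SnpAssociation("rs9", "C", "T", 0.05, 0.01, 0.1, 0.001)]


# ------------------------------------------------------------ palindromes


@pytest.mark.parametrize(
    "a1,a2,expected",
    [("A", "T", True), ("T", "A", True), ("G", "C", True), ("C", "G", True),
     ("A", "G", False), ("A", "C", False), ("T", "G", False), ("T", "C", False)],
)
def test_is_palindromic(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


def test_is_palindromic_rejects_invalid_symbol():
    with pytest.raises(SummaryDataError):
        is_palindromic("A", "N")


# ----------------------------------------------------------- harmonization


def test_harmonize_identical_labels_kept_as_is():
    exp = [snp("rs1", "A", "G", 0.02, 0.002, 0.3)]
    out = [snp("rs1", "A", "G", 0.05, 0.01, 0.31)]
    inst = harmonize(exp, out)
    rec = inst.instruments[0]
    assert rec.action == "kept_as_is"
    assert rec.beta_exposure == 0.02 and rec.beta_outcome == 0.05


def test_harmonize_all_label_configurations_against_relabelling_oracle():
    """Enumerate exposure-sign x outcome-label x outcome-strand configurations.

    Ground truth: the effect of the exposure-increasing allele is +0.02 on
    the exposure and +0.05 on the outcome (EAF 0.3).  Every relabelling of
    the same underlying association must harmonize back to those values.
    """
    for exp_flip, out_swap, out_comp in itertools.product([False, True], repeat=3):
        ea, oa, bx, fx = "A", "G", 0.02, 0.3
        if exp_flip:  # exposure reported for the other allele
            ea, oa, bx, fx = oa, ea, -bx, 1 - fx
        oea, ooa, by, fy = "A", "G", 0.05, 0.3
        if out_swap:
            oea, ooa, by, fy = ooa, oea, -by, 1 - fy
        if out_comp:
            oea, ooa = complement_allele(oea), complement_allele(ooa)
        inst = harmonize(
            [snp("rs1", ea, oa, bx, 0.002, fx)],
            [snp("rs1", oea, ooa, by, 0.01, fy)],
        )
        rec = inst.instruments[0]
        assert rec.action not in DROPPED_ACTIONS
        assert rec.beta_exposure == pytest.approx(0.02)
        assert rec.beta_outcome == pytest.approx(0.05)
        assert rec.eaf_exposure == pytest.approx(0.3)
        assert rec.eaf_outcome == pytest.approx(0.3)
        assert rec.effect_allele == "A" and rec.other_allele == "G"


def test_harmonize_is_idempotent():
    exp = [snp("rs1", "A", "G", -0.02, 0.002, 0.7), snp("rs2", "T", "C", 0.01, 0.001, 0.2)]
    out = [snp("rs1", "G", "A", 0.05, 0.01, 0.72), snp("rs2", "A", "G", 0.03, 0.01, 0.81)]
    once = harmonize(exp, out)
    exp2 = [
        SnpAssociation(r.rsid, r.effect_allele, r.other_allele, r.beta_exposure,
                       r.se_exposure, r.eaf_exposure, r.pvalue_exposure)
        for r in once.instruments
    ]
    out2 = [
        SnpAssociation(r.rsid, r.effect_allele, r.other_allele, r.beta_outcome,
                       r.se_outcome, r.eaf_outcome, r.pvalue_outcome)
        for r in once.instruments
    ]
    twice = harmonize(exp2, out2)
    # the action trail may differ (everything is aligned the second time);
    # the instrument content must not
    cols = [c for c in once.to_frame().columns if c != "action"]
    assert twice.to_frame()[cols].equals(once.to_frame()[cols])
    assert all(r.action == "kept_as_is" for r in twice.instruments)


def test_allele_relabelling_equivariance():
    """Swapping alleles + negating beta in an input leaves the result unchanged."""
    exp = [snp("rs1", "A", "G", 0.02, 0.002, 0.3)]
    out = [snp("rs1", "A", "G", 0.05, 0.01, 0.31)]
    relabelled_exp = [snp("rs1", "G", "A", -0.02, 0.002, 0.7)]
    relabelled_out = [snp("rs1", "G", "A", -0.05, 0.01, 0.69)]
    base = harmonize(exp, out).to_frame()
    for e, o in [(relabelled_exp, out), (exp, relabelled_out),
                 (relabelled_exp, relabelled_out)]:
        frame = harmonize(e, o).to_frame()
        assert np.allclose(
            frame[["beta_exposure", "beta_outcome"]],
            base[["beta_exposure", "beta_outcome"]],
        )
        assert (frame["effect_allele"] == base["effect_allele"]).all()


def test_wald_ratio_unchanged_by_sign_flip_harmonization():
    """Sign flips cancel in the ratio when both betas flip together."""
    from mrkit.estimators import wald_ratio

    exp = [snp("rs1", "A", "G", 0.02, 0.002, 0.3)]
    out = [snp("rs1", "A", "G", 0.05, 0.01, 0.3)]
    flipped_exp = [snp("rs1", "G", "A", -0.02, 0.002, 0.7)]
    flipped_out = [snp("rs1", "G", "A", -0.05, 0.01, 0.7)]
    r1 = wald_ratio(harmonize(exp, out).instruments[0])
    r2 = wald_ratio(harmonize(flipped_exp, flipped_out).instruments[0])
    assert r1.theta == pytest.approx(r2.theta) and r1.se_theta == pytest.approx(r2.se_theta)


def test_record_count_conservation():
    exp = [snp(f"rs{i}") for i in range(6)]
    out = [snp(f"rs{i}", beta=0.05) for i in range(4)] + [snp("rsX")]
    inst = harmonize(exp, out)
    assert len(inst.records) == len(exp)
    counts = inst.dropped_counts()
    assert counts["dropped_missing"] == 2
    assert len(inst) + inst.n_dropped == len(exp)
    # within the rsid intersection everything is either kept or dropped-for-cause
    assert len(inst) + counts["dropped_ambiguous"] + counts["dropped_irreconcilable"] == 4


def test_harmonize_empty_intersection_is_fatal():
    with pytest.raises(SummaryDataError):
        harmonize([snp("rs1")], [snp("rs2")])


def test_irreconcilable_alleles_flagged_not_fatal():
    inst = harmonize(
        [snp("rs1", "A", "G"), snp("rs2", "A", "G")],
        [snp("rs1", "A", "C"), snp("rs2", "A", "G")],
    )
    actions = {r.rsid: r.action for r in inst.records}
    assert actions["rs1"] == "dropped_irreconcilable"
    assert actions["rs2"] == "kept_as_is"


@pytest.mark.parametrize(
    "policy,expect_kept",
    [("retain_same_strand", True), ("drop_above_threshold", False)],
)
def test_high_maf_palindromic_policies(policy, expect_kept):
    exp = [snp("rs1", "A", "T", 0.02, 0.002, 0.48), snp("rs2", "A", "G", 0.02, 0.002, 0.3)]
    out = [snp("rs1", "A", "T", 0.05, 0.01, 0.49), snp("rs2", "A", "G", 0.05, 0.01, 0.3)]
    inst = harmonize(exp, out, palindromic_maf_threshold=0.45, palindromic_policy=policy)
    actions = {r.rsid: r.action for r in inst.records}
    if expect_kept:
        assert actions["rs1"] == "kept_as_is" and inst.n_palindromic_retained == 1
    else:
        assert actions["rs1"] == "dropped_ambiguous"


def test_infer_by_frequency_palindromic_resolution():
    # low-MAF palindromic: outcome EAF 0.85 for the T allele on the other
    # strand reads as 0.15 for A; frequency concordance detects the flip
    exp = [snp("rs1", "A", "T", 0.02, 0.002, eaf=0.15)]
    out_same = [snp("rs1", "A", "T", 0.05, 0.01, eaf=0.14)]
    out_flipped = [snp("rs1", "A", "T", -0.05, 0.01, eaf=0.86)]
    for out, expected_beta in [(out_same, 0.05), (out_flipped, 0.05)]:
        inst = harmonize(exp, out, palindromic_policy="infer_by_frequency")
        assert inst.instruments[0].beta_outcome == pytest.approx(expected_beta)
    # high MAF: ambiguous under frequency inference
    exp_hi = [snp("rs1", "A", "T", 0.02, 0.002, eaf=0.49)]
    out_hi = [snp("rs1", "A", "T", 0.05, 0.01, eaf=0.5)]
    inst = harmonize(exp_hi, out_hi, palindromic_policy="infer_by_frequency")
    assert inst.records[0].action == "dropped_ambiguous"
    # missing EAF: cannot resolve, fail safe
    exp_na = [SnpAssociation("rs1", "A", "T", 0.02, 0.002, None, None)]
    inst = harmonize(exp_na, out_hi, palindromic_policy="infer_by_frequency")
    assert inst.records[0].action == "dropped_ambiguous"


def test_study_like_fixture_retains_high_maf_palindromic_snps(study_like_instruments):
    palin = [r for r in study_like_instruments if r.palindromic]
    assert len(palin) == 10
    assert all(min(r.eaf_exposure, 1 - r.eaf_exposure) > 0.40 for r in palin)


# ------------------------------------------------------------- F-statistic


def test_mean_f_statistic_examples():
    single = build_instruments([0.01], [0.0], [0.01], [0.01])
    assert mean_f_statistic(single) == pytest.approx(1.0)
    two = build_instruments([0.2, 0.4], [0.0, 0.0], [0.1, 0.1], [0.1, 0.1])
    assert mean_f_statistic(two) == pytest.approx(10.0)  # mean of 4 and 16


def test_mean_f_statistic_empty_set_errors():
    from mrkit.summary_data import InstrumentSet

    with pytest.raises(SummaryDataError):
        mean_f_statistic(InstrumentSet([]))
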