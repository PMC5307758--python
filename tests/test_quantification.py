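"""Triplicate aggregation, QC flagging and the 40-ΔΔCq transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerconcord.panel import GENE_PANEL, REF_GENES, TARGET_GENES
from markerconcord.quantification import (
    CalibratorProfile,
    CqTableError,
    QcRules,
    aggregate_triplicates,
    apply_qc,
    normalize_expression,
    quantify,
)

from conftest import make_cq_frame


def triplicate_frame(values, gene="MKI67"):
    rows = [("S1", "R1", gene, i + 1, v) for i, v in enumerate(values)]
    return make_cq_frame(rows)


@pytest.mark.parametrize(
    "values, expected_median, expected_n",
    [
        ((20.0, 20.0, 20.0), 20.0, 3),     # constant triple
        ((20.1, 20.3, 35.0), 20.3, 3),     # middle order statistic beats the outlier
        ((21.0, 20.0, None), 20.5, 2),     # two detected -> their mean
        ((22.5, None, None), 22.5, 1),     # single detected, flagged via n_used
        ((None, None, None), None, 0),     # gene-level missing
    ],
)
def test_triplicate_median_rules(values, expected_median, expected_n):
    out = aggregate_triplicates(triplicate_frame(values))
    row = out.iloc[0]
    if expected_median is None:
        assert np.isnan(row["median_cq"])
    else:
        assert row["median_cq"] == pytest.approx(expected_median)
    assert row["n_replicates_used"] == expected_n


def test_duplicate_well_keys_rejected():
    df = make_cq_frame(
        [("S1", "R1", "MKI67", 1, 20.0), ("S1", "R1", "MKI67", 1, 21.0)]
    )
    with pytest.raises(CqTableError, match="duplicate"):
        aggregate_triplicates(df)


def test_unknown_gene_rejected():
    df = make_cq_frame([("S1", "R1", "GAPDH", 1, 20.0)])
    with pytest.raises(CqTableError, match="GAPDH"):
        aggregate_triplicates(df)


def full_sample_medians(ref=25.0, target=28.0, spread=0.0, drop=()):
    rows = []
    for g in GENE_PANEL:
        if g in drop:
            continue
        base = ref if g in REF_GENES else target
        rows += [("S1", "R1", g, i + 1, base + spread * (i == 2)) for i in range(3)]
    return aggregate_triplicates(make_cq_frame(rows))


class TestQc:
    def test_missing_reference_gene(self):
        med = full_sample_medians(drop=("B2M",))
        qc = apply_qc(med, QcRules())
        assert qc.iloc[0]["qc_status"] == "invalid(reference gene missing)"

    def test_low_rna_yield(self):
        med = full_sample_medians(ref=33.0)
        qc = apply_qc(med, QcRules(max_ref_mean_cq=32.0))
        assert qc.iloc[0]["qc_status"] == "invalid(low RNA yield)"

    def test_excess_replicate_spread(self):
        med = full_sample_medians(spread=2.0)
        qc = apply_qc(med, QcRules(max_replicate_spread=1.0))
        assert qc.iloc[0]["qc_status"] == "invalid(replicate spread)"

    def test_all_present_zero_spread_valid(self):
        med = full_sample_medians()
        qc = apply_qc(med, QcRules())
        assert qc.iloc[0]["qc_status"] == "valid"

    def test_insufficient_replicates(self):
        rows = []
        for g in GENE_PANEL:
            n = 1 if g == "PGR" else 3
            rows += [("S1", "R1", g, i + 1, 26.0) for i in range(n)]
        med = aggregate_triplicates(make_cq_frame(rows))
        qc = apply_qc(med, QcRules(min_valid_replicates=2))
        assert qc.iloc[0]["qc_status"] == "invalid(insufficient replicates: PGR)"


CAL = CalibratorProfile(
    run_id="R1",
    cq_target={"ESR1": 25.0, "PGR": 27.0, "MKI67": 27.0, "ERBB2": 26.0},
    mean_cq_ref=20.0,
)


def test_sample_equal_to_calibrator_gives_40():
    medians = {"B2M": 20.0, "CALM2": 20.0, **CAL.cq_target}
    prof = normalize_expression(medians, CAL, "S1")
    assert prof.values == pytest.approx({g: 40.0 for g in TARGET_GENES})


def test_hand_evaluated_formula():
    # (25 - 20) - (27 - 20) = -2  ->  40 - (-2) = 42
    medians = {"B2M": 20.0, "CALM2": 20.0, "MKI67": 25.0}
    prof = normalize_expression(medians, CAL, "S1")
    assert prof.values["MKI67"] == pytest.approx(42.0)


def test_shift_invariance_example():
    medians = {"B2M": 21.0, "CALM2": 19.0, "MKI67": 26.0, "ESR1": 24.0}
    base = normalize_expression(medians, CAL, "S1").values
    shifted = normalize_expression(
        {g: v + 3.0 for g, v in medians.items()}, CAL, "S1"
    ).values
    assert shifted == pytest.approx(base)


finite_cq = st.floats(min_value=5.0, max_value=39.0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    b2m=finite_cq, calm2=finite_cq, target=finite_cq,
    cal_t=finite_cq, cal_ref=finite_cq,
    shift=st.floats(min_value=-5, max_value=5),
)
def test_shift_invariance_property(b2m, calm2, target, cal_t, cal_ref, shift):
    cal = CalibratorProfile("R1", {g: cal_t for g in TARGET_GENES}, cal_ref)
    meds = {"B2M": b2m, "CALM2": calm2, "MKI67": target}
    base = normalize_expression(meds, cal).values["MKI67"]
    moved = normalize_expression(
        {g: v + shift for g, v in meds.items()}, cal
    ).values["MKI67"]
    assert moved == pytest.approx(base, abs=1e-9)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    b2m=finite_cq, calm2=finite_cq, target=finite_cq,
    cal_t=finite_cq, cal_ref=finite_cq,
    offset=st.floats(min_value=-3, max_value=3),
)
def test_run_offset_cancellation(b2m, calm2, target, cal_t, cal_ref, offset):
    """A gene offset applied to sample and calibrator wells alike cancels."""
    cal = CalibratorProfile("R1", {g: cal_t for g in TARGET_GENES}, cal_ref)
    base = normalize_expression({"B2M": b2m, "CALM2": calm2, "MKI67": target}, cal)
    cal_off = CalibratorProfile(
        "R1", {g: cal_t + offset for g in TARGET_GENES}, cal_ref
    )
    moved = normalize_expression(
        {"B2M": b2m, "CALM2": calm2, "MKI67": target + offset}, cal_off
    )
    assert moved.values["MKI67"] == pytest.approx(base.values["MKI67"], abs=1e-9)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(b2m=finite_cq, calm2=finite_cq, target=finite_cq,
       delta=st.floats(min_value=0, max_value=5))
def test_monotonicity_in_target_cq(b2m, calm2, target, delta):
    """Lowering the target median Cq by delta raises 40-ΔΔCq by exactly delta."""
    meds = {"B2M": b2m, "CALM2": calm2, "MKI67": target}
    base = normalize_expression(meds, CAL).values["MKI67"]
    lowered = normalize_expression({**meds, "MKI67": target - delta}, CAL).values["MKI67"]
    assert lowered - base == pytest.approx(delta, abs=1e-9)


def test_missing_calibrator_run_is_hard_error(small_cq):
    broken = small_cq[small_cq["sample_id"] != "CALIBRATOR"].copy()
    with pytest.raises(CqTableError, match="calibrator"):
        quantify(broken)


def test_quantify_reports_every_sample_once(small_cq):
    expr = quantify(small_cq)
    ids = [s for s in small_cq["sample_id"].unique() if s != "CALIBRATOR"]
    assert sorted(expr["sample_id"]) == sorted(ids)
    assert not expr["sample_id"].duplicated().any()
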