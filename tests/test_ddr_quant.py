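"""Geometric MFIs, fold-induction kinetics and survival proportions."""

import numpy as np
import pandas as pd
import pytest

from ddrcyto.ddr_quant import (AnalyzedSample, fold_induction_table,
                               geometric_mfi, stratified_kinetics,
                               survival_proportions)
from ddrcyto.errors import MissingReferenceError
from ddrcyto.fcs_io import AcquisitionMetadata, ChannelDescriptor, EventFrame
from ddrcyto.gating import Membership
from ddrcyto.synthetic_data import expected_fold, expected_frequency, \
    population_leaves
from ddrcyto.gating import default_gating_spec


def test_geometric_mfi_closed_forms():
    assert geometric_mfi([2, 8], min_events=1) == pytest.approx(4.0)
    assert geometric_mfi([1, 10, 100], min_events=1) == pytest.approx(10.0)
    assert geometric_mfi([0, 2, 8], min_events=1) == pytest.approx(4.0)


def test_geometric_mfi_min_events_contract():
    assert np.isnan(geometric_mfi(np.arange(1, 11), min_events=30))
    assert np.isnan(geometric_mfi(np.zeros(100), min_events=1))
    assert np.isfinite(geometric_mfi(np.arange(1, 31), min_events=30))


def _sample(donor, condition, t, ddr_values, members=None, phases=None):
    chans = [ChannelDescriptor("Sm147Di", marker="gH2AX", role="intranuclear_ddr")]
    n = len(ddr_values)
    frame = EventFrame(np.asarray(ddr_values, float).reshape(-1, 1), chans,
                       meta=AcquisitionMetadata(donor, condition, t))
    mem = Membership(pd.DataFrame({
        "CD45+": np.ones(n, bool),
        "pop": np.ones(n, bool) if members is None else np.asarray(members)}))
    return AnalyzedSample(frame=frame, membership=mem, phases=phases)


def test_fold_induction_against_untreated_reference():
    s0 = _sample("d1", "untreated", 0.0, [10.0] * 40)
    s1 = _sample("d1", "IR_2Gy", 1.0, [20.0] * 40)
    table = fold_induction_table([s0, s1], min_events=30)
    pop = table[table.population == "pop"].set_index("timepoint_h")
    assert pop.loc[0.0, "fold_induction"] == 1.0
    assert pop.loc[1.0, "fold_induction"] == pytest.approx(2.0)


def test_low_count_rows_are_flagged_missing():
    s0 = _sample("d1", "untreated", 0.0, [10.0] * 40)
    s1 = _sample("d1", "IR_2Gy", 1.0, [20.0] * 10)  # below min_events
    table = fold_induction_table([s0, s1], min_events=30)
    row = table[(table.population == "pop") & (table.timepoint_h == 1.0)].iloc[0]
    assert np.isnan(row.fold_induction)
    assert bool(row.low_n)


def test_missing_untreated_reference_raises():
    s1 = _sample("d1", "IR_2Gy", 1.0, [20.0] * 40)
    with pytest.raises(MissingReferenceError):
        fold_induction_table([s1])


def test_scale_equivariance_of_geo_mfi_and_folds(rng):
    base = rng.gamma(2.0, 20.0, 200) + 1.0
    s0 = _sample("d1", "untreated", 0.0, base)
    s1 = _sample("d1", "IR_2Gy", 1.0, base * 3.0)
    t1 = fold_induction_table([s0, s1], min_events=30)
    s0c = _sample("d1", "untreated", 0.0, base * 7.0)
    s1c = _sample("d1", "IR_2Gy", 1.0, base * 21.0)
    t2 = fold_induction_table([s0c, s1c], min_events=30)
    m1 = t1[t1.population == "pop"].sort_values("timepoint_h")
    m2 = t2[t2.population == "pop"].sort_values("timepoint_h")
    assert np.allclose(m2.geo_mfi, 7.0 * m1.geo_mfi)
    assert np.allclose(m2.fold_induction, m1.fold_induction)


def test_survival_proportions_basic_and_absent_population():
    members = [True] * 80 + [False] * 20
    s = _sample("d1", "untreated", 0.0, [10.0] * 100, members=members)
    surv = survival_proportions([s])
    assert surv[surv.population == "pop"].pct_of_viable_cd45.iloc[0] == 80.0
    s2 = _sample("d1", "untreated", 0.0, [10.0] * 50, members=[False] * 50)
    surv2 = survival_proportions([s2])
    assert surv2[surv2.population == "pop"].pct_of_viable_cd45.iloc[0] == 0.0


def test_stratified_folds_match_unstratified_when_equal(rng):
    phases0 = np.array(["G0", "G1"] * 100, dtype=object)
    base = rng.gamma(4.0, 10.0, 200) + 1.0
    s0 = _sample("d1", "untreated", 0.0, base, phases=phases0)
    s1 = _sample("d1", "IR_2Gy", 1.0, base * 2.5, phases=phases0)
    table = stratified_kinetics([s0, s1], min_events=20)
    pop = table[(table.population == "pop") & (table.timepoint_h == 1.0)]
    folds = pop.set_index("stratum")["fold_induction"]
    assert folds["ki67+"] == pytest.approx(folds["ki67-"], rel=0.10)
    t0 = table[(table.population == "pop") & (table.timepoint_h == 0.0)]
    assert (t0.fold_induction == 1.0).all()


def test_stratified_small_stratum_flagged():
    phases = np.array(["G0"] * 95 + ["G1"] * 5, dtype=object)
    s0 = _sample("d1", "untreated", 0.0, [10.0] * 100, phases=phases)
    s1 = _sample("d1", "IR_2Gy", 1.0, [20.0] * 100, phases=phases)
    table = stratified_kinetics([s0, s1], min_events=30)
    kp = table[(table.population == "pop") & (table.stratum == "ki67+")]
    assert kp.low_n.all()
    assert kp.fold_induction.isna().all()


# -- against generator ground truth -----------------------------------------

def test_fold_recovery_on_small_experiment(small_config, analyzed_samples):
    kin = fold_induction_table(analyzed_samples)
    leaves = population_leaves(small_config, default_gating_spec())
    for pop in ("CD3+ T", "CD19+CD20+ B"):
        for marker, t in (("gH2AX", 1.0), ("p-CHK2", 1.0), ("p53", 8.0)):
            est = kin[(kin.population == pop) & (kin.marker == marker)
                      & (kin.timepoint_h == t)].fold_induction.mean()
            tru = expected_fold(small_config, leaves[pop], marker, t)
            assert est == pytest.approx(tru, rel=0.20)


def test_b_cell_composition_decline_matches_closed_form(small_config,
                                                        analyzed_samples):
    surv = survival_proportions(analyzed_samples)
    leaves = population_leaves(small_config, default_gating_spec())
    b24 = surv[(surv.population == "CD19+CD20+ B")
               & (surv.timepoint_h == 24.0)].pct_of_viable_cd45.mean()
    expected = expected_frequency(small_config, leaves["CD19+CD20+ B"], 24.0)
    assert b24 == pytest.approx(expected, abs=1.2)
    b0 = surv[(surv.population == "CD19+CD20+ B")
              & (surv.timepoint_h == 0.0)].pct_of_viable_cd45.mean()
    assert b0 > b24
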