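"""The synthetic experiment generator: curves, defaults, determinism."""

import numpy as np
import pytest

from ddrcyto.errors import ConfigError
from ddrcyto.synthetic_data import (ResponseCurve, SimulationConfig,
                                    SubsetProfile, default_config_at,
                                    default_config_healthy, default_panel,
                                    expected_frequency, fold_at,
                                    population_leaves, simulate_experiment)
from ddrcyto.gating import default_gating_spec


def test_fold_at_closed_forms():
    c = ResponseCurve(3.0, 1.0)
    assert fold_at(c, 0.0) == 1.0
    assert fold_at(c, 1.0) == pytest.approx(4.0)
    assert fold_at(c, 24.0) == pytest.approx(1.0 + 3 * 24 * np.exp(-23), abs=1e-12)
    assert fold_at(c, 24.0) == pytest.approx(1.0, abs=1e-6)  # back to baseline


def test_fold_at_peaks_at_tp():
    c = ResponseCurve(2.0, 6.0)
    ts = np.linspace(0, 48, 2000)
    vals = [fold_at(c, t) for t in ts]
    assert ts[int(np.argmax(vals))] == pytest.approx(6.0, abs=0.1)
    assert max(vals) == pytest.approx(3.0, abs=1e-3)


def test_invalid_curve_parameters():
    with pytest.raises(ConfigError):
        ResponseCurve(1.0, 0.0)
    with pytest.raises(ConfigError):
        fold_at(ResponseCurve(1.0, 1.0), -1.0)


def test_panel_covers_all_roles():
    panel = default_panel()
    roles = {}
    for c in panel:
        roles.setdefault(c.role, []).append(c)
    assert len(roles["surface"]) == 20
    assert len(roles["intranuclear_ddr"]) == 4
    assert len(roles["barcode"]) == 6
    assert len(roles["dna"]) == 2
    assert len(roles["viability"]) == 1
    assert len(roles["cellcycle"]) == 2


def test_healthy_defaults_encode_response_ordering():
    cfg = default_config_healthy()
    by_name = {s.name: s for s in cfg.subsets}

    def amp(subset, marker):
        return by_name[subset].curve("IR_2Gy", marker).amplitude

    # gH2AX: NK > T > B
    assert amp("NK dim CD16+ CD57-", "gH2AX") > amp("CD4 CM", "gH2AX") \
        > amp("B naive", "gH2AX")
    # p-CHK2 dominated by B cells
    assert amp("B naive", "p-CHK2") > 3 * amp("CD4 naive", "p-CHK2")
    assert amp("B naive", "p-CHK2") > 3 * amp("NK dim CD16+ CD57-", "p-CHK2")
    # naive T: lower gH2AX, higher p-ATM and p53 than memory
    assert amp("CD4 naive", "gH2AX") < amp("CD4 CM", "gH2AX")
    assert amp("CD4 naive", "p-ATM") > amp("CD4 EM", "p-ATM")
    assert amp("CD4 naive", "p53") > amp("CD4 EM", "p53")
    # p53 peaks at 8 h, the early markers at 1 h after IR
    for s in cfg.subsets:
        assert s.curve("IR_2Gy", "p53").peak_time == 8.0
        assert s.curve("IR_2Gy", "gH2AX").peak_time == 1.0
    # survival multipliers: 1 at t=0 by contract, B declining at 24 h
    for s in cfg.subsets:
        assert s.survival_at("IR_2Gy", 0.0) == 1.0
    assert by_name["B naive"].survival_at("IR_2Gy", 24.0) < 0.6
    assert by_name["NK dim CD16+ CD57-"].survival_at("IR_2Gy", 24.0) == 1.0


def test_uvc_defaults_shift_early_peak():
    cfg = default_config_healthy(condition="UVC_100mJ")
    s = cfg.subsets[0]
    assert s.curve("UVC_100mJ", "gH2AX").peak_time == 6.0
    assert s.curve("UVC_100mJ", "p53").peak_time == 8.0


def test_at_config_abrogates_response():
    healthy = default_config_healthy()
    at = default_config_at()
    h = {s.name: s for s in healthy.subsets}
    for s in at.subsets:
        for marker in ("p-CHK2", "p-ATM", "p53"):
            assert s.curve("IR_2Gy", marker).amplitude <= \
                0.1 * h[s.name].curve("IR_2Gy", marker).amplitude + 1e-12
        # every true fold stays within the abrogation band
        for marker in ("gH2AX", "p-CHK2", "p-ATM", "p53"):
            for t in (1.0, 4.0, 8.0, 24.0):
                assert 0.8 <= fold_at(s.curve("IR_2Gy", marker), t) <= 1.2
    assert at.cohort == "AT"
    b_at = {s.name: s for s in at.subsets}["B naive"]
    assert b_at.survival_at("IR_2Gy", 24.0) < h["B naive"].survival_at("IR_2Gy", 24.0)


def test_simulation_is_seed_deterministic():
    cfg = default_config_healthy(n_donors=1, events_per_timepoint=400, seed=5)
    a = simulate_experiment(cfg)[0]
    b = simulate_experiment(cfg)[0]
    assert np.array_equal(a.frame.values, b.frame.values)
    assert a.truth.equals(b.truth)
    cfg2 = default_config_healthy(n_donors=1, events_per_timepoint=400, seed=6)
    c = simulate_experiment(cfg2)[0]
    assert not np.array_equal(a.frame.values, c.frame.values)


def test_event_counts_and_truth_alignment(small_config, small_donors):
    d = small_donors[0]
    n_tp = small_config.events_per_timepoint
    n_singlets = len(small_config.timepoints) * n_tp
    n_doub = int(round(small_config.doublet_fraction * n_singlets))
    assert d.frame.n_events == n_singlets + n_doub
    assert len(d.truth) == d.frame.n_events
    per_tp = d.truth[~d.truth.doublet].groupby("timepoint_h").size()
    assert (per_tp == n_tp).all()


def test_sidecar_folds_reach_configured_peak(small_config, small_donors):
    d = small_donors[0]
    tf = d.truth_folds
    at_zero = tf[tf.timepoint_h == 0.0]
    assert (at_zero.true_fold == 1.0).all()
    # peak fold equals 1 + A x donor factor; donor factors are mean-1 with
    # 15% CV, so the cohort-level mean peak is close to 1 + A
    peak = tf[(tf.population == "NK dim CD16+ CD57-") & (tf.marker == "gH2AX")
              & (tf.timepoint_h == 1.0)].true_fold
    assert peak.iloc[0] == pytest.approx(4.0, rel=0.5)


def test_overfull_frequencies_rejected():
    subsets = [SubsetProfile(name=f"s{i}", frequency=0.4, markers={"CD45": "pos"})
               for i in range(3)]
    with pytest.raises(ConfigError):
        SimulationConfig(subsets=subsets, timepoints=(0.0, 1.0))


def test_expected_frequency_renormalises_survival(small_config):
    spec = default_gating_spec()
    leaves = population_leaves(small_config, spec)
    b0 = expected_frequency(small_config, leaves["CD19+CD20+ B"], 0.0)
    b24 = expected_frequency(small_config, leaves["CD19+CD20+ B"], 24.0)
    assert b0 == pytest.approx(8.1, abs=0.3)
    assert b24 == pytest.approx(4.5, abs=0.4)
    nk24 = expected_frequency(small_config, leaves["CD56dim CD16+ NK"], 24.0)
    nk0 = expected_frequency(small_config, leaves["CD56dim CD16+ NK"], 0.0)
    assert nk24 > nk0  # renormalisation, not NK death
    assert nk24 - nk0 < 0.4


def test_population_leaves_mapping(small_config):
    spec = default_gating_spec()
    leaves = population_leaves(small_config, spec)
    assert set(leaves["CD3+ T"]) == {"CD4 naive", "CD4 CM", "CD4 EM",
                                     "CD8 naive", "CD8 CM", "CD8 EM"}
    assert leaves["CD56dim CD16+ NK"] == ["NK dim CD16+ CD57-",
                                          "NK dim CD16+ CD57+"]
    assert "unclassified" in leaves["CD45+"]
    assert "B naive" in leaves["naive B"]
    assert "B plasmablast unswitched" not in leaves["CD19+CD20+ B"]
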