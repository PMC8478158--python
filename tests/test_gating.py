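"""Threshold estimation, hierarchical population assignment, cell cycle."""

import numpy as np
import pytest

from ddrcyto.errors import EstimationError, GatingSpecError
from ddrcyto.fcs_io import ChannelDescriptor, EventFrame
from ddrcyto.gating import (MarkerPredicate, PopulationDef,
                            ThresholdSet, assign_populations,
                            classify_cell_cycle, default_gating_spec,
                            estimate_thresholds, gating_spec_from_yaml,
                            gating_spec_to_yaml, spec_markers,
                            _effective_predicates)
from ddrcyto.synthetic_data import population_leaves


def _marker_frame(data: dict):
    chans = [ChannelDescriptor(f"{m}Di", marker=m) for m in data]
    vals = np.column_stack([np.asarray(v, dtype=float) for v in data.values()])
    return EventFrame(vals, chans, transformed=True)


# -- threshold estimation ----------------------------------------------------

def test_valley_threshold_between_separated_modes(rng):
    x = np.concatenate([rng.normal(0.5, 0.3, 5000), rng.normal(4.0, 0.5, 5000)])
    f = _marker_frame({"CD3": x})
    thr = estimate_thresholds(f, ["CD3"])
    assert 1.5 < thr.t1["CD3"] < 3.0
    # independent oracle: brute-force minimum of a fine histogram density
    hist, edges = np.histogram(x, bins=400)
    centers = 0.5 * (edges[:-1] + edges[1:])
    inner = (centers > 1.0) & (centers < 3.5)
    oracle = centers[inner][np.argmin(np.convolve(hist, np.ones(9) / 9,
                                                  "same")[inner])]
    assert abs(thr.t1["CD3"] - oracle) < 0.75


def test_unimodal_channel_falls_back_to_quantile(rng):
    x = np.abs(rng.normal(0.0, 0.3, 3000))
    f = _marker_frame({"CD38": x})
    thr = estimate_thresholds(f, ["CD38"])
    assert thr.t1["CD38"] >= np.quantile(x, 0.95) - 1e-9


def test_always_positive_marker_gated_below_its_mode(rng):
    x = rng.normal(4.0, 0.5, 5000)  # CD45 on lymphocytes: all positive
    f = _marker_frame({"CD45": x})
    thr = estimate_thresholds(f, ["CD45"])
    assert thr.t1["CD45"] < 3.5
    assert (x >= thr.t1["CD45"]).mean() > 0.95


def test_thresholds_invariant_to_event_order(rng):
    x = np.concatenate([rng.normal(0.3, 0.2, 2000), rng.normal(4.0, 0.6, 500)])
    f1 = _marker_frame({"CD19": x})
    f2 = _marker_frame({"CD19": x[rng.permutation(x.size)]})
    a = estimate_thresholds(f1, ["CD19"])
    b = estimate_thresholds(f2, ["CD19"])
    assert a.t1["CD19"] == b.t1["CD19"]


def test_threshold_estimation_errors(rng):
    with pytest.raises(EstimationError):
        estimate_thresholds(_marker_frame({"CD3": np.ones(50)}), ["CD3"])
    f = _marker_frame({"CD3": np.ones(500)})
    with pytest.raises(EstimationError):
        estimate_thresholds(f, ["CD3"])


def test_two_level_marker_gets_ordered_thresholds(rng):
    x = np.concatenate([rng.normal(0.2, 0.2, 9000),
                        rng.normal(3.2, 0.4, 700), rng.normal(6.9, 0.4, 300)])
    thr = estimate_thresholds(_marker_frame({"CD56": x}), ["CD56"])
    assert thr.t1["CD56"] < thr.t2["CD56"]
    assert 1.0 < thr.t1["CD56"] < 2.8
    assert 3.5 < thr.t2["CD56"] < 6.0


def test_threshold_csv_roundtrip(tmp_path):
    thr = ThresholdSet(t1={"CD3": 1.5, "CD56": 1.2}, t2={"CD56": 4.0},
                       provenance="estimated")
    thr.to_csv(tmp_path / "thr.csv")
    back = ThresholdSet.from_csv(tmp_path / "thr.csv")
    assert back.t1 == thr.t1
    assert back.t2 == thr.t2
    assert back.provenance == "estimated"


# -- population assignment ---------------------------------------------------

def _uniform_thresholds(markers, t1=1.0, t2=3.0):
    return ThresholdSet(t1={m: t1 for m in markers}, t2={m: t2 for m in markers})


def test_naive_cd4_membership_chain():
    spec = default_gating_spec()
    markers = spec_markers(spec)
    data = {m: [0.1] for m in markers}
    for m in ("CD45", "CD3", "CD4", "CD45RA", "CCR7"):
        data[m] = [2.0]
    mem = assign_populations(_marker_frame(data), spec, _uniform_thresholds(markers))
    row = mem.matrix.iloc[0]
    assert row[["CD45+", "CD3+ T", "CD3+CD4+", "naive CD4"]].all()
    assert not row["CM CD4"] and not row["CD3+CD8+"] and not row["CD19+CD20+ B"]


def test_dim_nk_membership():
    spec = default_gating_spec()
    markers = spec_markers(spec)
    data = {m: [0.1] for m in markers}
    data["CD45"] = [2.0]
    data["CD56"] = [2.0]  # within [t1, t2) = dim
    data["CD16"] = [2.0]
    mem = assign_populations(_marker_frame(data), spec, _uniform_thresholds(markers))
    row = mem.matrix.iloc[0]
    assert row["CD56dim CD16+ NK"]
    assert not row["CD56bright CD16+ NK"]
    assert row["CD57- CD56dim CD16+ NK"] and not row["CD57+ CD56dim CD16+ NK"]


def test_transitional_b_needs_double_bright():
    spec = default_gating_spec()
    markers = spec_markers(spec)
    data = {m: [0.1, 0.1] for m in markers}
    for m in ("CD45", "CD19", "CD20"):
        data[m] = [2.0, 2.0]
    data["IgM"] = [4.0, 2.0]  # event 0: IgM++; event 1: IgM+ only
    data["CD38"] = [4.0, 4.0]
    mem = assign_populations(_marker_frame(data), spec, _uniform_thresholds(markers))
    assert mem.matrix.loc[0, "transitional B"]
    assert not mem.matrix.loc[1, "transitional B"]
    assert mem.matrix.loc[0, "CD19+CD20+ B"]


def test_missing_t2_is_spec_error():
    spec = [PopulationDef("x", [MarkerPredicate("CD56", "bright")])]
    f = _marker_frame({"CD56": [1.0]})
    with pytest.raises(GatingSpecError):
        assign_populations(f, spec, ThresholdSet(t1={"CD56": 1.0}))


def test_default_spec_structure():
    spec = default_gating_spec()
    assert len(spec) >= 25
    names = {p.name for p in spec}
    assert len(names) == len(spec)
    effective = _effective_predicates(spec)
    by_name = {p.name: p for p in spec}
    for p in spec:
        if p.parent:
            child = {(q.marker, q.level) for q in effective[p.name]}
            parent = {(q.marker, q.level) for q in effective[p.parent]}
            assert parent <= child


def test_spec_yaml_roundtrip():
    spec = default_gating_spec()
    text = gating_spec_to_yaml(spec)
    back = gating_spec_from_yaml(text)
    assert [(p.name, p.parent, p.predicates) for p in back] == \
        [(p.name, p.parent, p.predicates) for p in spec]


def test_hierarchy_consistency_on_simulated_data(analyzed_samples):
    spec = default_gating_spec()
    by_name = {p.name: p for p in spec}
    for s in analyzed_samples:
        m = s.membership.matrix
        for p in spec:
            if p.parent:
                assert not (m[p.name] & ~m[p.parent]).any()


def test_cd4_siblings_nearly_partition_cd4(analyzed_samples):
    # the generator emits only naive/CM/EM CD4 states
    for s in analyzed_samples:
        m = s.membership.matrix
        cd4 = int(m["CD3+CD4+"].sum())
        if cd4 == 0:
            continue
        covered = int((m["naive CD4"] | m["CM CD4"] | m["EM CD4"]).sum())
        assert covered / cd4 >= 0.95


def test_frequency_recovery_on_small_simulation(small_config, small_donors,
                                                analyzed_samples):
    spec = default_gating_spec()
    leaves = population_leaves(small_config, spec)
    donor = small_donors[0]
    live = donor.truth[donor.truth.live & ~donor.truth.doublet]
    donor_samples = [s for s in analyzed_samples
                     if s.frame.meta.donor_id == donor.donor_id]
    pooled = np.vstack([s.membership.matrix.to_numpy() for s in donor_samples])
    cols = donor_samples[0].membership.populations
    denom = pooled[:, cols.index("CD45+")].sum()
    for pop in ("CD3+ T", "CD3+CD4+", "naive CD4", "CD56dim CD16+ NK",
                "CD19+CD20+ B", "naive B"):
        est = 100.0 * pooled[:, cols.index(pop)].sum() / denom
        tru = 100.0 * live.subset.isin(leaves[pop]).mean()
        assert est == pytest.approx(tru, abs=1.5)


# -- cell cycle --------------------------------------------------------------

def test_cell_cycle_predicate_table():
    f = _marker_frame({"ki67": [2.0, 2.0, 0.1, 0.1],
                       "IdU": [2.0, 0.1, 0.1, 2.0]})
    thr = ThresholdSet(t1={"ki67": 1.0, "IdU": 1.0})
    phases = classify_cell_cycle(f, thr)
    assert phases.tolist() == ["S", "G1", "G0", "KI67NEG_IDUPOS"]


def test_cell_cycle_partitions_all_events(analyzed_samples):
    s = analyzed_samples[0]
    counts = {p: int((s.phases == p).sum())
              for p in ("G0", "G1", "S", "KI67NEG_IDUPOS")}
    assert sum(counts.values()) == s.frame.n_events
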