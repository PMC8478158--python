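"""Ground-truth benchmarks: run the full pipeline on synthetic experiments
and score every stage against the generator's closed-form truth.

These are the package's verification workloads: fold-induction recovery,
qualitative response orderings, AT/control discrimination, debarcoding and
gating accuracy, type-I error control of the Tukey comparisons, and
survival-composition detection.  Each function takes an integer seed (all
randomness flows from it) and returns plain dictionaries of metrics, so the
same entry points serve the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ddr_quant import DDR_MARKERS, fold_induction_table, survival_proportions
from .debarcode import UNASSIGNED, debarcode
from .gating import default_gating_spec
from .pipeline import _survival_comparisons, analyze_donor
from .preprocess import arcsinh_transform
from .stats import two_way_anova_tukey
from .synthetic_data import (SimulationConfig, default_config_at,
                             default_config_healthy, expected_fold,
                             fold_at, population_leaves, simulate_experiment)

TOP_POPULATIONS = ("CD3+ T", "CD56dim CD16+ NK", "CD19+CD20+ B")


def _seeds(seed: int, n: int) -> list[int]:
    """n child seeds below 2**31 derived from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_experiment(config: SimulationConfig):
    """Simulate and push every donor through the full analysis chain."""
    donors = simulate_experiment(config)
    samples = []
    for d in donors:
        samples += analyze_donor(d.frame, d.scheme, d.manifest)
    return donors, samples


def fold_recovery(seed: int, n_donors: int = 26, events_per_timepoint: int = 4000,
                  min_frequency: float = 0.02) -> dict:
    """Cohort-mean fold-induction recovery against configured truth.

    Returns the worst relative error over all (population, marker, post-
    damage time point) cells for populations at or above ``min_frequency``
    of viable CD45+, plus the survival-composition readouts.
    """
    cfg = default_config_healthy(n_donors=n_donors,
                                 events_per_timepoint=events_per_timepoint,
                                 seed=seed)
    donors, samples = run_experiment(cfg)
    kinetics = fold_induction_table(samples)
    survival = survival_proportions(samples)
    spec = default_gating_spec()
    leaves = population_leaves(cfg, spec)
    base_freq = {p: sum(s.frequency for s in cfg.subsets if s.name in leaves[p])
                 for p in leaves}

    worst = 0.0
    worst_cell = None
    n_cells = 0
    for pop, pop_leaves in leaves.items():
        if base_freq[pop] < min_frequency:
            continue
        sub = kinetics[kinetics.population == pop]
        for marker in DDR_MARKERS:
            for t in [tp for tp in cfg.timepoints if tp > 0]:
                est = sub[(sub.marker == marker)
                          & (sub.timepoint_h == t)].fold_induction.mean()
                tru = expected_fold(cfg, pop_leaves, marker, t)
                rel = abs(est / tru - 1.0)
                n_cells += 1
                if rel > worst:
                    worst, worst_cell = rel, (pop, marker, t)

    comp = survival.groupby(["population", "timepoint_h"])["pct_of_viable_cd45"].mean()
    return {
        "max_abs_rel_error": float(worst),
        "worst_cell": worst_cell,
        "n_cells": n_cells,
        "n_events": n_donors * len(cfg.timepoints) * events_per_timepoint,
        "t_pct_baseline": float(comp[("CD3+ T", 0.0)]),
        "nk_pct_baseline": float(comp[("CD56dim CD16+ NK", 0.0)]
                                 + comp[("CD56bright CD16- NK", 0.0)]
                                 + comp[("CD56bright CD16+ NK", 0.0)]),
        "b_pct_baseline": float(comp[("CD19+CD20+ B", 0.0)]),
        "b_pct_24h": float(comp[("CD19+CD20+ B", 24.0)]),
        "t_pct_24h": float(comp[("CD3+ T", 24.0)]),
        "nk_pct_24h": float(comp[("CD56dim CD16+ NK", 24.0)]
                            + comp[("CD56bright CD16- NK", 24.0)]
                            + comp[("CD56bright CD16+ NK", 24.0)]),
    }


def ordering_rates(seed: int, n_seeds: int = 20, n_donors: int = 5,
                   events_per_timepoint: int = 2000) -> dict:
    """Fraction of seeds reproducing the qualitative 1 h response orderings:
    gH2AX NK > T > B and p-CHK2 B > T."""
    ok_gh2ax = ok_pchk2 = 0
    for s in _seeds(seed, n_seeds):
        cfg = default_config_healthy(n_donors=n_donors,
                                     events_per_timepoint=events_per_timepoint,
                                     timepoints=(0.0, 1.0), seed=s)
        _, samples = run_experiment(cfg)
        kin = fold_induction_table(samples)
        m = kin[kin.timepoint_h == 1.0].groupby(
            ["population", "marker"])["fold_induction"].mean()
        g = m.xs("gH2AX", level="marker")
        c = m.xs("p-CHK2", level="marker")
        ok_gh2ax += bool(g["CD56dim CD16+ NK"] > g["CD3+ T"] > g["CD19+CD20+ B"])
        ok_pchk2 += bool(c["CD19+CD20+ B"] > c["CD3+ T"])
    return {"gh2ax_nk_t_b": ok_gh2ax / n_seeds, "pchk2_b_t": ok_pchk2 / n_seeds,
            "n_seeds": n_seeds}


def at_discrimination(seed: int, n_seeds: int = 20, n_control: int = 10,
                      n_at: int = 3, events_per_timepoint: int = 20000) -> dict:
    """AT vs control separation on the p-CHK2 fold at 1 h in B cells, and the
    abrogation band of all AT fold estimates (four top-level populations,
    all four markers)."""
    separated = 0
    at_min, at_max = np.inf, -np.inf
    min_gap = np.inf
    pops = ("CD45+",) + TOP_POPULATIONS
    for s in _seeds(seed, n_seeds):
        ctrl_cfg = default_config_healthy(
            n_donors=n_control, events_per_timepoint=events_per_timepoint,
            timepoints=(0.0, 1.0), seed=s)
        at_cfg = default_config_at(
            n_donors=n_at, events_per_timepoint=events_per_timepoint,
            timepoints=(0.0, 1.0), seed=s + 1)
        _, ctrl_samples = run_experiment(ctrl_cfg)
        _, at_samples = run_experiment(at_cfg)
        kin_c = fold_induction_table(ctrl_samples)
        kin_a = fold_induction_table(at_samples)
        sel = lambda k: k[(k.population == "CD19+CD20+ B")
                          & (k.marker == "p-CHK2") & (k.timepoint_h == 1.0)]
        ctrl_folds = sel(kin_c).fold_induction
        at_folds = sel(kin_a).fold_induction
        gap = float(ctrl_folds.min() - at_folds.max())
        min_gap = min(min_gap, gap)
        separated += bool(gap > 0)
        band = kin_a[kin_a.population.isin(pops)
                     & (kin_a.timepoint_h == 1.0)].fold_induction
        at_min = min(at_min, float(band.min()))
        at_max = max(at_max, float(band.max()))
    return {"separated_fraction": separated / n_seeds, "min_gap": min_gap,
            "at_fold_min": at_min, "at_fold_max": at_max, "n_seeds": n_seeds}


def at_abrogation_band(seed: int, events_per_timepoint: int = 20000) -> dict:
    """Estimated AT folds across all time points and markers (one cohort)."""
    cfg = default_config_at(n_donors=3, events_per_timepoint=events_per_timepoint,
                            seed=seed)
    _, samples = run_experiment(cfg)
    kin = fold_induction_table(samples)
    band = kin[kin.population.isin(("CD45+",) + TOP_POPULATIONS)
               & (kin.timepoint_h > 0)].fold_induction
    return {"fold_min": float(band.min()), "fold_max": float(band.max()),
            "n": int(band.size)}


def debarcode_accuracy(seed: int, events_per_timepoint: int = 2500) -> dict:
    """Assignment accuracy on true singlets and rejection of cross-sample
    barcode doublets, at the default separation cutoff."""
    cfg = default_config_healthy(n_donors=1,
                                 events_per_timepoint=events_per_timepoint,
                                 seed=seed)
    d = simulate_experiment(cfg)[0]
    res = debarcode(arcsinh_transform(d.frame), d.scheme)
    singlet = ~d.truth["doublet"].to_numpy()
    truth_labels = d.truth["sample_label"].to_numpy()
    accuracy = float((res.assignment[singlet] == truth_labels[singlet]).mean())
    cross = (d.truth["doublet"] & (d.truth["sample_label"] == "DOUBLET")).to_numpy()
    rejection = float((res.assignment[cross] == UNASSIGNED).mean())
    return {"singlet_accuracy": accuracy, "doublet_rejection": rejection,
            "n_singlets": int(singlet.sum()), "n_doublets": int(cross.sum())}


def gating_recovery(seed: int, events_per_timepoint: int = 10000) -> dict:
    """Population-frequency recovery (percentage points of viable CD45+, vs
    the sidecar truth) and the hierarchy-consistency invariant, on one donor
    of 5 x events_per_timepoint events."""
    cfg = default_config_healthy(n_donors=1,
                                 events_per_timepoint=events_per_timepoint,
                                 seed=seed)
    donors, samples = run_experiment(cfg)
    d = donors[0]
    spec = default_gating_spec()
    leaves = population_leaves(cfg, spec)
    live = d.truth[d.truth.live & ~d.truth.doublet]

    mats = [s.membership.matrix for s in samples]
    pooled = pd.concat(mats, ignore_index=True)
    denom = int(pooled["CD45+"].sum())
    worst = 0.0
    worst_pop = None
    for pop in pooled.columns:
        est = 100.0 * pooled[pop].sum() / denom
        tru = 100.0 * live.subset.isin(leaves[pop]).mean()
        if abs(est - tru) > worst:
            worst, worst_pop = abs(est - tru), pop

    hierarchy_ok = True
    by_name = {p.name: p for p in spec}
    for m in mats:
        for p in spec:
            if p.parent and (m[p.name] & ~m[p.parent]).any():
                hierarchy_ok = False
    return {"max_freq_error_pp": float(worst), "worst_population": worst_pop,
            "hierarchy_consistent": hierarchy_ok,
            "n_events": len(cfg.timepoints) * events_per_timepoint}


def tukey_null_type1(seed: int, n_reps: int = 200, n_donors: int = 26,
                     noise_cv: float = 0.10) -> dict:
    """Type-I error of the Tukey-adjusted population comparisons under a null
    in which every population shares the same response curve (per-donor
    folds jittered by lognormal measurement noise)."""
    from .synthetic_data import ResponseCurve

    curve = ResponseCurve(2.0, 1.0)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    significant = total = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rows = []
        for _d in range(n_donors):
            for pop in TOP_POPULATIONS:
                for t in (1.0, 4.0, 8.0, 24.0):
                    rows.append({
                        "population": pop, "timepoint_h": t,
                        "fold_induction": fold_at(curve, t)
                        * float(np.exp(rng.normal(0.0, sigma)))})
        for r in two_way_anova_tukey(pd.DataFrame(rows)):
            total += 1
            significant += bool(r.p_adjusted <= 0.05)
    return {"type1_rate": significant / total, "n_comparisons": total}


def survival_detection(seed: int, n_seeds: int = 10, n_donors: int = 8,
                       events_per_timepoint: int = 2500) -> dict:
    """Detection of the B-cell composition decline at 24 h (Šídák-adjusted
    paired comparisons) and non-detection of the stable NK composition."""
    b_sig = nk_ns = 0
    for s in _seeds(seed, n_seeds):
        cfg = default_config_healthy(n_donors=n_donors,
                                     events_per_timepoint=events_per_timepoint,
                                     seed=s)
        _, samples = run_experiment(cfg)
        surv = survival_proportions(samples)
        st = _survival_comparisons(surv, TOP_POPULATIONS).set_index("population")
        b_sig += bool(st.loc["CD19+CD20+ B", "p_adjusted"] <= 0.05)
        nk_ns += bool(st.loc["CD56dim CD16+ NK", "p_adjusted"] > 0.05)
    return {"b_decline_detected": b_sig / n_seeds,
            "nk_stable_ns": nk_ns / n_seeds, "n_seeds": n_seeds}
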