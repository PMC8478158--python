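"""Per-population DDR quantification: geometric MFIs, fold-induction
kinetics, survival proportions, and cell-cycle stratified variants.

Geometric MFIs are computed on the raw (untransformed) intensity scale over
strictly positive values, matching the convention of mainstream cytometry
analysis software.  Fold induction is per-donor: each (donor, population,
marker) trace is normalised to the same donor's untreated (time-0) sample,
which was barcoded, pooled and stained in the same tube and is therefore
the natural within-donor reference.  Cells with fewer than ``min_events``
positive events yield a missing (NaN) value with a flag rather than an
unstable estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingReferenceError, ValidationError
from .fcs_io import EventFrame
from .gating import Membership

DDR_MARKERS = ("gH2AX", "p-ATM", "p-CHK2", "p53")

DEFAULT_MIN_EVENTS = 30

KINETICS_COLUMNS = [
    "donor", "cohort", "condition", "population", "marker", "timepoint_h",
    "n_events", "n_positive", "geo_mfi", "fold_induction", "low_n",
]


@dataclass
class AnalyzedSample:
    """One debarcoded, gated sample ready for quantification."""

    frame: EventFrame
    membership: Membership
    phases: np.ndarray | None = None  # per-event cell-cycle phase

    def __post_init__(self) -> None:
        if self.frame.meta is None:
            raise ValidationError("analyzed sample needs acquisition metadata")
        if len(self.membership.matrix) != self.frame.n_events:
            raise ValidationError("membership matrix does not match event count")
        if self.phases is not None and len(self.phases) != self.frame.n_events:
            raise ValidationError("phase vector does not match event count")


def geometric_mfi(values: np.ndarray, min_events: int = DEFAULT_MIN_EVENTS) -> float:
    """Geometric mean of the strictly positive raw intensities.

    Zeros (ion-count dropout) are excluded; if fewer than ``min_events``
    positive values remain the estimate is considered unreliable and NaN is
    returned (callers flag the row).
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[v > 0]
    if v.size < min_events:
        return float("nan")
    return float(np.exp(np.mean(np.log(v))))


def _marker_names(sample: AnalyzedSample, markers) -> list[str]:
    if markers is not None:
        return list(markers)
    ddr = [c.marker for c in sample.frame.channels_with_role("intranuclear_ddr")]
    return ddr or list(DDR_MARKERS)


def _mfi_rows(samples, markers, min_events, stratum_of=None):
    """Long table of geometric MFIs per (sample, population, marker[, stratum])."""
    rows = []
    for s in samples:
        meta = s.frame.meta
        strata = ([(None, np.ones(s.frame.n_events, dtype=bool))] if stratum_of is None
                  else stratum_of(s))
        for pop in s.membership.populations:
            member = s.membership.matrix[pop].to_numpy()
            for stratum, smask in strata:
                mask = member & smask
                n = int(mask.sum())
                for m in _marker_names(s, markers):
                    raw = s.frame.raw_marker(m)[mask]
                    n_pos = int(np.sum(raw > 0))
                    mfi = geometric_mfi(raw, min_events=min_events)
                    row = {
                        "donor": meta.donor_id, "cohort": meta.cohort,
                        "condition": meta.condition, "population": pop,
                        "marker": m, "timepoint_h": float(meta.timepoint_h),
                        "n_events": n, "n_positive": n_pos, "geo_mfi": mfi,
                        "low_n": not np.isfinite(mfi),
                    }
                    if stratum is not None:
                        row["stratum"] = stratum
                    rows.append(row)
    return pd.DataFrame(rows)


def _add_fold(table: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
    """fold_induction = geo_mfi(t) / geo_mfi(untreated) within each group."""
    ref = table[table["condition"] == "untreated"].set_index(group_keys)["geo_mfi"]
    if ref.index.has_duplicates:
        raise ValidationError("multiple untreated reference rows for the same group")
    donors = set(table["donor"])
    ref_donors = set(table.loc[table["condition"] == "untreated", "donor"])
    missing = sorted(donors - ref_donors)
    if missing:
        raise MissingReferenceError(
            f"no untreated reference sample for donor(s): {', '.join(missing)}")
    idx = pd.MultiIndex.from_frame(table[group_keys])
    denom = ref.reindex(idx).to_numpy()
    table = table.copy()
    table["fold_induction"] = table["geo_mfi"].to_numpy() / denom
    # self-normalisation: the untreated row is exactly 1 unless its MFI is missing
    t0 = table["condition"] == "untreated"
    table.loc[t0 & np.isfinite(table["geo_mfi"]), "fold_induction"] = 1.0
    table["low_n"] = table["low_n"] | ~np.isfinite(table["fold_induction"])
    return table


def fold_induction_table(
    samples: list[AnalyzedSample],
    markers: list[str] | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> pd.DataFrame:
    """Tidy kinetics table: one row per (donor, population, marker, time point).

    Requires an untreated (t=0) sample per donor; missing MFIs propagate as
    NaN folds with the ``low_n`` flag set.
    """
    table = _mfi_rows(samples, markers, min_events)
    table = _add_fold(table, ["donor", "population", "marker"])
    return table[KINETICS_COLUMNS].sort_values(
        ["donor", "population", "marker", "timepoint_h"]).reset_index(drop=True)


def stratified_kinetics(
    samples: list[AnalyzedSample],
    markers: list[str] | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
    by_phase: bool = False,
) -> pd.DataFrame:
    """Fold-induction kinetics computed within ki67+ / ki67- strata.

    ki67+ comprises cycling cells (G1 and S phases); ki67- the quiescent G0
    pool plus the ki67-IdU+ arrest class.  With ``by_phase`` the strata are
    the four phases themselves.  Normalisation is within-stratum: each
    stratum has its own untreated reference.
    """
    def stratum_of(s: AnalyzedSample):
        if s.phases is None:
            raise ValidationError("stratified kinetics needs cell-cycle phases")
        ph = np.asarray(s.phases, dtype=object)
        if by_phase:
            return [(p, ph == p) for p in ("G0", "G1", "S", "KI67NEG_IDUPOS")]
        pos = (ph == "G1") | (ph == "S")
        return [("ki67+", pos), ("ki67-", ~pos)]

    table = _mfi_rows(samples, markers, min_events, stratum_of=stratum_of)
    table = _add_fold(table, ["donor", "population", "marker", "stratum"])
    cols = KINETICS_COLUMNS[:5] + ["stratum"] + KINETICS_COLUMNS[5:]
    return table[cols].sort_values(
        ["donor", "population", "marker", "stratum", "timepoint_h"]).reset_index(drop=True)


def survival_proportions(
    samples: list[AnalyzedSample],
    denominator: str = "CD45+",
) -> pd.DataFrame:
    """Population sizes as percentages of the viable CD45+ pool per time point.

    The viability gate must already have been applied upstream; this is a
    composition readout (shifts in relative abundance), not an absolute
    death rate.
    """
    rows = []
    for s in samples:
        meta = s.frame.meta
        denom = int(s.membership.matrix[denominator].sum())
        for pop in s.membership.populations:
            n = int(s.membership.matrix[pop].sum())
            pct = 100.0 * n / denom if denom > 0 else float("nan")
            rows.append({
                "donor": meta.donor_id, "cohort": meta.cohort,
                "condition": meta.condition, "population": pop,
                "timepoint_h": float(meta.timepoint_h),
                "n_events": n, "pct_of_viable_cd45": pct,
                "flag_zero_denominator": denom == 0,
            })
    return pd.DataFrame(rows).sort_values(
        ["donor", "population", "timepoint_h"]).reset_index(drop=True)
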