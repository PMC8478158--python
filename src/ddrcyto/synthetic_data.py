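"""Ground-truth synthetic mass-cytometry experiments.

The generator emits, per virtual donor, one pooled barcoded event file with
exactly the structure the analysis pipeline expects to disentangle:

* five time points (untreated plus 1/4/8/24 h after damage), each tagged
  with a 3-of-6 palladium barcode key and pooled into one frame;
* ~20 surface channels with subset-specific zero-inflated lognormal
  expression driving the full hierarchical gating tree;
* four intranuclear DDR channels whose raw intensities are scaled by a
  pulse-shaped fold-induction curve specific to subset, marker and damage
  type (gamma-like pulse: fold(t) = 1 + A * (t/tp) * exp(1 - t/tp), which
  is 1 at t=0, peaks at exactly 1+A at t=tp and decays back to baseline);
* ki67/IdU cell-cycle structure, an iridium DNA signal for singlet
  discrimination, and a cisplatin viability channel;
* injected artifacts: dead cells (cisplatin-high) and doublets (channel-
  wise sums of two events, detectable both on DNA content and by their
  >= 4 high barcode channels);
* survival decay: per-subset multipliers thin out subsets over time (B
  cells die by 24 h), shifting the viable composition.

Every event's true time point, subset, phase and artifact status is
recorded in a sidecar table, and every true fold value is available in
closed form, so each pipeline stage can be scored against ground truth.
A single seed determines the whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .debarcode import BarcodeScheme, PD_CHANNELS, all_keys, save_code_book
from .errors import ConfigError
from .fcs_io import (AcquisitionMetadata, ChannelDescriptor, EventFrame,
                     save_panel, write_fcs)

DDR_MARKERS = ("gH2AX", "p-ATM", "p-CHK2", "p53")
TIMEPOINTS = (0.0, 1.0, 4.0, 8.0, 24.0)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def default_panel() -> list[ChannelDescriptor]:
    """The acquisition panel: 20 surface markers, 4 DDR markers, ki67/IdU,
    6 Pd barcode channels, cisplatin viability and Ir191/Ir193 DNA."""
    surface = [
        ("Sm154Di", "154Sm", "CD45"), ("Er170Di", "170Er", "CD3"),
        ("Yb174Di", "174Yb", "CD4"), ("Er168Di", "168Er", "CD8"),
        ("Tm169Di", "169Tm", "CD45RA"), ("Dy164Di", "164Dy", "CD45RO"),
        ("Tb159Di", "159Tb", "CCR7"), ("Nd144Di", "144Nd", "CD69"),
        ("Yb176Di", "176Yb", "CD56"), ("Ho165Di", "165Ho", "CD16"),
        ("Dy163Di", "163Dy", "CD57"), ("Nd142Di", "142Nd", "CD19"),
        ("Yb171Di", "171Yb", "CD20"), ("Nd146Di", "146Nd", "IgD"),
        ("Yb172Di", "172Yb", "IgM"), ("Gd160Di", "160Gd", "IgGk"),
        ("Eu151Di", "151Eu", "IgGl"), ("Gd158Di", "158Gd", "CD27"),
        ("Er167Di", "167Er", "CD38"), ("Sm152Di", "152Sm", "CD21"),
    ]
    ddr = [("Sm147Di", "147Sm", "gH2AX"), ("Pr141Di", "141Pr", "p-ATM"),
           ("Dy161Di", "161Dy", "p-CHK2"), ("Nd150Di", "150Nd", "p53")]
    cc = [("Dy162Di", "162Dy", "ki67"), ("I127Di", "127I", "IdU")]
    chans = [ChannelDescriptor(cid, metal, marker, "surface")
             for cid, metal, marker in surface]
    chans += [ChannelDescriptor(cid, metal, marker, "intranuclear_ddr")
              for cid, metal, marker in ddr]
    chans += [ChannelDescriptor(cid, metal, marker, "cellcycle")
              for cid, metal, marker in cc]
    chans += [ChannelDescriptor(cid, f"{cid[2:5]}Pd", f"BC_{cid[:5]}", "barcode")
              for cid in PD_CHANNELS]
    chans.append(ChannelDescriptor("Pt195Di", "195Pt", "cisplatin", "viability"))
    chans.append(ChannelDescriptor("Ir191Di", "191Ir", "DNA1", "dna"))
    chans.append(ChannelDescriptor("Ir193Di", "193Ir", "DNA2", "dna"))
    return chans


# ---------------------------------------------------------------------------
# response curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseCurve:
    """Pulse-shaped fold induction: amplitude A (peak fold excess) and peak
    time tp in hours; fold(0)=1 and fold(tp)=1+A exactly."""

    amplitude: float = 0.0
    peak_time: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_time <= 0:
            raise ConfigError("response curve peak_time must be > 0")
        if self.amplitude < 0:
            raise ConfigError("response curve amplitude must be >= 0")


def fold_at(curve: ResponseCurve, t: float) -> float:
    """Evaluate the pulse: 1 + A * (t/tp) * exp(1 - t/tp)."""
    if t < 0:
        raise ConfigError("time must be >= 0")
    r = t / curve.peak_time
    return 1.0 + curve.amplitude * r * float(np.exp(1.0 - r))


# ---------------------------------------------------------------------------
# expression levels and subset profiles
# ---------------------------------------------------------------------------

#: raw-scale expression models per level token:
#: (lognormal median, lognormal CV, zero fraction) -- "neg" uses a
#: half-normal background instead of a lognormal component.
LEVEL_TABLE: dict[str, tuple[float, float, float]] = {
    "neg": (0.0, 0.0, 0.55),
    "pos": (150.0, 0.8, 0.002),
    "dim": (60.0, 0.5, 0.002),
    "bright": (2500.0, 0.5, 0.002),
    "very_high": (2500.0, 0.5, 0.002),
}
NEG_BACKGROUND_SIGMA = 1.5  # half-normal scale of the negative background

#: DDR baselines: shared raw-scale lognormal medians so that composite
#: populations have closed-form expected folds (weighted geometric means)
DDR_BASELINE = {"gH2AX": 20.0, "p-ATM": 15.0, "p-CHK2": 12.0, "p53": 18.0}
DDR_CV = 0.8
DDR_ZERO_FRAC = 0.03


@dataclass
class SubsetProfile:
    """Ground truth for one leaf subset of viable CD45+ lymphocytes."""

    name: str
    frequency: float
    markers: dict[str, str]  # marker -> level token; unlisted markers are neg
    responses: dict[str, dict[str, ResponseCurve]] = field(default_factory=dict)
    # condition -> timepoint -> survival multiplier in (0, 1]
    survival: dict[str, dict[float, float]] = field(default_factory=dict)
    cellcycle: tuple[float, float, float] = (0.92, 0.07, 0.01)  # G0, G1, S

    def __post_init__(self) -> None:
        if not 0 <= self.frequency <= 1:
            raise ConfigError(f"subset frequency out of range for {self.name!r}")
        if abs(sum(self.cellcycle) - 1.0) > 1e-9:
            raise ConfigError(f"cell-cycle fractions must sum to 1 for {self.name!r}")
        for cond, tbl in self.survival.items():
            if tbl.get(0.0, 1.0) != 1.0:
                raise ConfigError("survival multiplier at t=0 must be 1")
            for s in tbl.values():
                if not 0 < s <= 1:
                    raise ConfigError("survival multipliers must lie in (0, 1]")

    def survival_at(self, condition: str, t: float) -> float:
        return self.survival.get(condition, {}).get(t, 1.0)

    def curve(self, condition: str, marker: str) -> ResponseCurve:
        return self.responses.get(condition, {}).get(marker, ResponseCurve(0.0, 1.0))


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic experiment; seed-deterministic."""

    subsets: list[SubsetProfile]
    n_donors: int = 26
    cohort: str = "control"
    condition: str = "IR_2Gy"
    timepoints: tuple[float, ...] = TIMEPOINTS
    events_per_timepoint: int = 20000
    dead_fraction: float = 0.10
    doublet_fraction: float = 0.02
    barcode_noise_cv: float = 0.3
    composition_jitter_cv: float = 0.10  # per-sample handling variability
    donor_amplitude_cv: float = 0.15  # donor-to-donor DDR variability
    ki67neg_idupos_frac: float = 0.005
    key_assignment: dict[float, str] = field(default_factory=dict)
    separation_cutoff: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(s.frequency for s in self.subsets)
        if total > 1.0 + 1e-9:
            raise ConfigError(f"leaf subset frequencies sum to {total:.3f} > 1")
        if not set(self.timepoints) <= set(TIMEPOINTS):
            raise ConfigError("time points must be a subset of {0, 1, 4, 8, 24}")
        if not self.key_assignment:
            self.key_assignment = dict(
                zip(self.timepoints, balanced_key_labels(len(self.timepoints))))

    def scheme_for(self, donor_id: str) -> tuple[BarcodeScheme, dict[str, AcquisitionMetadata]]:
        """Per-donor code book (one key per pooled time point) and manifest."""
        keys, manifest = {}, {}
        key_bits = {f"BC{i + 1:02d}": bits for i, bits in enumerate(all_keys())}
        for t in self.timepoints:
            label = f"{donor_id}_t{t:g}"
            keys[label] = key_bits[self.key_assignment[t]]
            manifest[label] = AcquisitionMetadata(
                donor_id=donor_id,
                condition="untreated" if t == 0 else self.condition,
                timepoint_h=t, cohort=self.cohort)
        return BarcodeScheme(keys=keys, separation_cutoff=self.separation_cutoff), manifest


#: balanced key subsets: every Pd channel is high in some pooled samples and
#: low in others, so the robust per-channel rescaling is well conditioned
#: (key bit patterns: BC01={0,1,2} BC04={0,1,5} BC06={0,2,4} BC08={0,3,4}
#:  BC15={1,3,5} BC19={2,4,5} BC20={3,4,5})
_BALANCED_KEY_SETS = {
    2: ("BC01", "BC20"),
    3: ("BC01", "BC20", "BC06"),
    4: ("BC01", "BC20", "BC06", "BC15"),
    5: ("BC01", "BC08", "BC15", "BC19", "BC04"),
}


def balanced_key_labels(n: int) -> tuple[str, ...]:
    if n not in _BALANCED_KEY_SETS:
        raise ConfigError(f"no balanced default key set for {n} pooled samples; "
                          "provide key_assignment explicitly")
    return _BALANCED_KEY_SETS[n]


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def _t_cell_curves(naive: bool, cm: bool, condition: str) -> dict[str, ResponseCurve]:
    tp_early = 1.0 if condition == "IR_2Gy" else 6.0
    if naive:
        g, atm, chk2, p53 = 1.2, 1.8, 1.1, 1.5
    elif cm:
        g, atm, chk2, p53 = 1.9, 1.3, 0.95, 1.0
    else:  # effector memory
        g, atm, chk2, p53 = 1.6, 1.0, 0.9, 0.8
    if condition == "UVC_100mJ":
        p53 *= 0.6
    return {
        "gH2AX": ResponseCurve(g, tp_early),
        "p-ATM": ResponseCurve(atm, tp_early),
        "p-CHK2": ResponseCurve(chk2, tp_early),
        "p53": ResponseCurve(p53, 8.0),
    }


def _nk_curves(bright: bool, cd16: bool, condition: str) -> dict[str, ResponseCurve]:
    tp_early = 1.0 if condition == "IR_2Gy" else 6.0
    g = 3.0 if not bright else (2.8 if cd16 else 3.2 if condition == "UVC_100mJ" else 2.8)
    atm = 2.0 if cd16 or not bright else 1.4
    chk2 = 1.0
    p53 = 0.6 if not bright else 0.9
    return {
        "gH2AX": ResponseCurve(g, tp_early),
        "p-ATM": ResponseCurve(atm, tp_early),
        "p-CHK2": ResponseCurve(chk2, tp_early),
        "p53": ResponseCurve(p53, 8.0),
    }


def _b_cell_curves(naive: bool, condition: str) -> dict[str, ResponseCurve]:
    tp_early = 1.0 if condition == "IR_2Gy" else 6.0
    g = 0.45 if naive else 0.7
    return {
        "gH2AX": ResponseCurve(g, tp_early),
        "p-ATM": ResponseCurve(1.4, tp_early),
        "p-CHK2": ResponseCurve(4.0, tp_early),
        "p53": ResponseCurve(1.0, 8.0),
    }


#: viable-composition survival decay under damage; B cells die by 24 h.
#: s24 = 0.535 reproduces a B-cell composition drop from ~8.1% to ~4.5%.
_B_SURVIVAL = {1.0: 1.0, 4.0: 0.95, 8.0: 0.85, 24.0: 0.535}

_T = {"CD45": "pos", "CD3": "pos"}
_B = {"CD45": "pos", "CD19": "pos", "CD20": "pos", "CD21": "pos"}
_NK = {"CD45": "pos"}


def _healthy_subsets(condition: str) -> list[SubsetProfile]:
    cc_t = (0.92, 0.07, 0.01)
    cc_nk = (0.85, 0.10, 0.05)
    cc_b = (0.95, 0.045, 0.005)
    surv = {condition: dict(_B_SURVIVAL)}

    def t_sub(name, freq, extra, naive=False, cm=False):
        return SubsetProfile(
            name=name, frequency=freq, markers={**_T, **extra},
            responses={condition: _t_cell_curves(naive, cm, condition)},
            cellcycle=cc_t)

    def nk_sub(name, freq, extra, bright, cd16):
        return SubsetProfile(
            name=name, frequency=freq, markers={**_NK, **extra},
            responses={condition: _nk_curves(bright, cd16, condition)},
            cellcycle=cc_nk)

    def b_sub(name, freq, extra, naive=False):
        return SubsetProfile(
            name=name, frequency=freq, markers={**_B, **extra},
            responses={condition: _b_cell_curves(naive, condition)},
            survival=surv, cellcycle=cc_b)

    # baseline composition anchored to reported means: T 75.5%, NK 7.0%,
    # B 8.1% of viable CD45+, remainder unclassified
    subsets = [
        t_sub("CD4 naive", 0.755 * 0.376,
              {"CD4": "pos", "CD45RA": "pos", "CCR7": "pos"}, naive=True),
        t_sub("CD4 CM", 0.755 * 0.105,
              {"CD4": "pos", "CD45RO": "pos", "CCR7": "pos"}, cm=True),
        t_sub("CD4 EM", 0.755 * 0.070, {"CD4": "pos", "CD45RO": "pos"}),
        t_sub("CD8 naive", 0.755 * 0.360,
              {"CD8": "pos", "CD45RA": "pos", "CCR7": "pos"}, naive=True),
        t_sub("CD8 CM", 0.755 * 0.050,
              {"CD8": "pos", "CD45RO": "pos", "CCR7": "pos"}, cm=True),
        t_sub("CD8 EM", 0.755 * 0.039, {"CD8": "pos", "CD45RO": "pos"}),
        nk_sub("NK bright CD16-", 0.07 * 0.15, {"CD56": "bright"},
               bright=True, cd16=False),
        nk_sub("NK bright CD16+ CD57-", 0.07 * 0.05,
               {"CD56": "bright", "CD16": "pos"}, bright=True, cd16=True),
        nk_sub("NK bright CD16+ CD57+", 0.07 * 0.05,
               {"CD56": "bright", "CD16": "pos", "CD57": "pos"}, bright=True, cd16=True),
        nk_sub("NK dim CD16+ CD57-", 0.07 * 0.375,
               {"CD56": "dim", "CD16": "pos"}, bright=False, cd16=True),
        nk_sub("NK dim CD16+ CD57+", 0.07 * 0.375,
               {"CD56": "dim", "CD16": "pos", "CD57": "pos"}, bright=False, cd16=True),
        b_sub("B naive", 0.081 * 0.523, {"IgD": "pos", "IgM": "pos"}, naive=True),
        b_sub("B MZ-like", 0.081 * 0.200,
              {"CD27": "pos", "IgM": "pos", "IgD": "pos"}),
        b_sub("B IgM-only", 0.081 * 0.141, {"CD27": "pos", "IgM": "pos"}),
        b_sub("B switched IgGk", 0.081 * 0.050, {"CD27": "pos", "IgGk": "pos"}),
        b_sub("B switched IgGl", 0.081 * 0.025, {"CD27": "pos", "IgGl": "pos"}),
        b_sub("B atypical", 0.081 * 0.020,
              {"CD45": "pos", "CD19": "pos", "CD20": "pos"}),
        b_sub("B transitional", 0.081 * 0.015,
              {"IgM": "very_high", "CD38": "very_high", "IgD": "pos"}, naive=True),
        b_sub("B plasmablast unswitched", 0.081 * 0.015,
              {"CD45": "pos", "CD19": "pos", "CD27": "pos", "CD38": "pos",
               "IgM": "pos"}),
        b_sub("B plasmablast switched", 0.081 * 0.011,
              {"CD45": "pos", "CD19": "pos", "CD27": "pos", "CD38": "pos"}),
        SubsetProfile(
            name="unclassified", frequency=1.0 - 0.755 - 0.07 - 0.081,
            markers={"CD45": "pos"},
            responses={condition: _t_cell_curves(False, False, condition)},
            cellcycle=cc_t),
    ]
    # atypical B / plasmablasts: CD21 and CD20 must not inherit from _B
    fixups = {"B atypical": {"CD21": "neg"}, "B plasmablast unswitched": {"CD20": "neg", "CD21": "neg"},
              "B plasmablast switched": {"CD20": "neg", "CD21": "neg"}}
    for s in subsets:
        if s.name in fixups:
            s.markers = {**s.markers, **fixups[s.name]}
            s.markers = {m: l for m, l in s.markers.items() if l != "neg"}
    return subsets


def default_config_healthy(
    n_donors: int = 26,
    events_per_timepoint: int = 20000,
    condition: str = "IR_2Gy",
    timepoints: tuple[float, ...] = TIMEPOINTS,
    seed: int = 0,
) -> SimulationConfig:
    """Default healthy-donor study: encodes the qualitative response ordering
    (gH2AX: NK > T > B; p-CHK2: B >> T, NK; p53 peaking at 8 h; early markers
    peaking at 1 h after IR and ~6 h after UVC; naive T with lower gH2AX but
    higher p-ATM/p53 than memory; B-cell survival loss by 24 h)."""
    return SimulationConfig(
        subsets=_healthy_subsets(condition), n_donors=n_donors, cohort="control",
        condition=condition, timepoints=timepoints,
        events_per_timepoint=events_per_timepoint, seed=seed)


#: residual partial gH2AX activation in AT (absolute amplitude, fold <= ~1.2)
_AT_PARTIAL_GH2AX = 0.15
_AT_SCALE = 0.02
_AT_PARTIAL_SUBSETS = ("CD4 EM", "CD8 EM", "NK bright CD16-",
                       "NK bright CD16+ CD57-", "NK bright CD16+ CD57+")


def default_config_at(
    n_donors: int = 3,
    events_per_timepoint: int = 20000,
    condition: str = "IR_2Gy",
    timepoints: tuple[float, ...] = TIMEPOINTS,
    seed: int = 0,
) -> SimulationConfig:
    """ATM-deficient (ataxia telangiectasia) cohort: the healthy configuration
    with all DDR amplitudes scaled to near zero.  A small residual gH2AX
    response is retained in effector-memory T cells and CD56bright NK cells
    (other kinases partially compensate for H2AX phosphorylation), kept small
    enough that every true fold stays within ~[0.8, 1.2].  B-cell survival at
    24 h is below the healthy cohort's."""
    cfg = default_config_healthy(n_donors=n_donors,
                                 events_per_timepoint=events_per_timepoint,
                                 condition=condition, timepoints=timepoints, seed=seed)
    subsets = []
    for s in cfg.subsets:
        responses = {}
        for cond, curves in s.responses.items():
            scaled = {}
            for marker, c in curves.items():
                amp = c.amplitude * _AT_SCALE
                if marker == "gH2AX" and s.name in _AT_PARTIAL_SUBSETS:
                    amp = _AT_PARTIAL_GH2AX
                scaled[marker] = ResponseCurve(amp, c.peak_time)
            responses[cond] = scaled
        survival = {cond: dict(tbl) for cond, tbl in s.survival.items()}
        if s.name.startswith("B ") and survival:
            survival[condition][24.0] = 0.30
        subsets.append(replace(s, responses=responses, survival=survival))
    return replace(cfg, subsets=subsets, cohort="AT", n_donors=n_donors)


# ---------------------------------------------------------------------------
# closed-form expected values
# ---------------------------------------------------------------------------

def population_leaves(config: SimulationConfig, population_spec) -> dict[str, list[str]]:
    """Map each gating-spec population to the leaf subsets that satisfy it.

    Evaluated symbolically from the level tokens: a leaf's marker at level
    ``neg``/absent satisfies neg and low predicates; ``pos`` satisfies pos;
    ``dim`` satisfies pos and dim; ``bright``/``very_high`` satisfy pos,
    bright and very_high.
    """
    from .gating import _effective_predicates  # local import to avoid cycle

    satisfied_by = {
        "neg": {"neg", "low"}, "pos": {"pos"}, "dim": {"pos", "dim"},
        "bright": {"pos", "bright", "very_high"},
        "very_high": {"pos", "bright", "very_high"},
    }
    effective = _effective_predicates(population_spec)
    out: dict[str, list[str]] = {}
    for pop, preds in effective.items():
        leaves = []
        for s in config.subsets:
            ok = True
            for p in preds:
                token = s.markers.get(p.marker, "neg")
                if p.level not in satisfied_by[token]:
                    ok = False
                    break
            if ok:
                leaves.append(s.name)
        out[pop] = leaves
    return out


def expected_fold(config: SimulationConfig, leaves: list[str], marker: str,
                  t: float) -> float:
    """Closed-form expected fold induction of a (possibly composite)
    population: the frequency-weighted geometric mean of its leaf folds
    (exact because all leaves share the marker's baseline median)."""
    profiles = [s for s in config.subsets if s.name in leaves]
    if not profiles:
        return float("nan")
    w = np.array([s.frequency * s.survival_at(config.condition, t) for s in profiles])
    w = w / w.sum()
    logf = np.array([np.log(fold_at(s.curve(config.condition, marker), t))
                     for s in profiles])
    return float(np.exp(np.sum(w * logf)))


def expected_frequency(config: SimulationConfig, leaves: list[str], t: float) -> float:
    """Expected % of viable CD45+ at time t, after survival renormalisation."""
    weights = {s.name: s.frequency * s.survival_at(config.condition, t)
               for s in config.subsets}
    total = sum(weights.values())
    return 100.0 * sum(weights[l] for l in leaves if l in weights) / total


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

def _lognormal(rng, median: float, cv: float, n: int) -> np.ndarray:
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return median * np.exp(rng.normal(0.0, sigma, size=n))


def _marker_column(rng, level: str, n: int) -> np.ndarray:
    if level == "neg":
        x = np.abs(rng.normal(0.0, NEG_BACKGROUND_SIGMA, size=n))
        x[rng.random(n) < LEVEL_TABLE["neg"][2]] = 0.0
        return x
    median, cv, zero = LEVEL_TABLE[level]
    x = _lognormal(rng, median, cv, n)
    x[rng.random(n) < zero] = 0.0
    return x


#: raw-scale models for the structural channels
_IR191_MEDIAN, _IR_SIGMA = 500.0, 0.12   # lognormal of DNA content
_IR193_RATIO = 1.6                        # natural Ir193/Ir191 abundance ratio
_CIS_LIVE = (2.0, 0.7)                    # (median, cv) for live cells
_CIS_DEAD = (80.0, 0.5)
_BC_HIGH = (200.0,)                       # median of a set barcode channel
_BC_LOW_SIGMA = 2.0                       # half-normal background of unset channels
_KI67_POS = (150.0, 0.8)
_IDU_POS = (150.0, 0.8)


@dataclass
class DonorSample:
    """One virtual donor's pooled barcoded acquisition plus ground truth."""

    donor_id: str
    cohort: str
    frame: EventFrame  # pooled, raw scale, untransformed
    truth: pd.DataFrame  # per-event: sample_label, timepoint_h, subset, phase, live, doublet
    scheme: BarcodeScheme
    manifest: dict[str, AcquisitionMetadata]
    truth_folds: pd.DataFrame  # donor, population(leaf), marker, timepoint_h, true_fold


def _simulate_donor(config: SimulationConfig, donor_id: str,
                    rng: np.random.Generator) -> DonorSample:
    panel = default_panel()
    markers = [c.marker for c in panel]
    col = {m: i for i, m in enumerate(markers)}
    pd_cols = [next(i for i, c in enumerate(panel) if c.channel_id == ch)
               for ch in PD_CHANNELS]
    scheme, manifest = config.scheme_for(donor_id)
    key_of_t = {manifest[label].timepoint_h: scheme.keys[label] for label in scheme.keys}
    label_of_t = {manifest[label].timepoint_h: label for label in scheme.keys}

    # donor-level multiplicative DDR variability, mean-1 lognormal
    sig_d = float(np.sqrt(np.log1p(config.donor_amplitude_cv ** 2)))
    donor_amp = {
        (s.name, m): float(np.exp(rng.normal(-0.5 * sig_d ** 2, sig_d)))
        for s in config.subsets for m in DDR_MARKERS
    }

    blocks, truths, fold_rows = [], [], []
    for t in config.timepoints:
        n = config.events_per_timepoint
        # composition: configured frequency x survival x per-sample jitter
        weights = np.array([
            s.frequency * s.survival_at(config.condition, t) for s in config.subsets])
        if config.composition_jitter_cv > 0:
            sig_j = float(np.sqrt(np.log1p(config.composition_jitter_cv ** 2)))
            weights = weights * np.exp(rng.normal(-0.5 * sig_j ** 2, sig_j,
                                                  size=weights.size))
        probs = weights / weights.sum()
        counts = rng.multinomial(n, probs)

        mat = np.zeros((n, len(panel)))
        subset_lab = np.empty(n, dtype=object)
        phase_lab = np.empty(n, dtype=object)
        start = 0
        for s, k in zip(config.subsets, counts):
            if k == 0:
                continue
            sl = slice(start, start + k)
            start += k
            subset_lab[sl] = s.name
            for m in markers:
                if m in ("DNA1", "DNA2", "cisplatin", "ki67", "IdU") or m.startswith("BC_"):
                    continue
                if m in DDR_MARKERS:
                    continue
                level = s.markers.get(m, "neg")
                mat[sl, col[m]] = _marker_column(rng, level, k)
            # DDR channels: baseline lognormal scaled by the true fold
            for m in DDR_MARKERS:
                fold = fold_at(s.curve(config.condition, m), t)
                fold = 1.0 + (fold - 1.0) * donor_amp[(s.name, m)]
                x = _lognormal(rng, DDR_BASELINE[m] * fold, DDR_CV, k)
                x[rng.random(k) < DDR_ZERO_FRAC] = 0.0
                mat[sl, col[m]] = x
                fold_rows.append({
                    "donor": donor_id, "population": s.name, "marker": m,
                    "timepoint_h": t, "true_fold": fold,
                })
            # cell cycle
            g0, g1, sph = s.cellcycle
            u = rng.random(k)
            ph = np.where(u < g0, "G0", np.where(u < g0 + g1, "G1", "S"))
            arrest = rng.random(k) < config.ki67neg_idupos_frac
            ph = np.where(arrest & (ph == "G0"), "KI67NEG_IDUPOS", ph)
            phase_lab[sl] = ph
            ki67_pos = (ph == "G1") | (ph == "S")
            idu_pos = (ph == "S") | (ph == "KI67NEG_IDUPOS")
            mat[sl, col["ki67"]] = np.where(
                ki67_pos, _lognormal(rng, *_KI67_POS, k),
                np.abs(rng.normal(0, NEG_BACKGROUND_SIGMA, k)))
            mat[sl, col["IdU"]] = np.where(
                idu_pos, _lognormal(rng, *_IDU_POS, k),
                np.abs(rng.normal(0, NEG_BACKGROUND_SIGMA, k)))

        # DNA channels: the two iridium isotopes read the same intercalator
        # signal, so per-cell DNA content dominates and the channels are
        # nearly perfectly correlated
        dna = _IR191_MEDIAN * np.exp(rng.normal(0.0, _IR_SIGMA, n))
        mat[:, col["DNA1"]] = dna
        mat[:, col["DNA2"]] = dna * _IR193_RATIO * np.exp(rng.normal(0, 0.005, n))

        # viability: a configured fraction of events are dead (cisplatin-high)
        dead = rng.random(n) < config.dead_fraction
        cis = _lognormal(rng, *_CIS_LIVE, n)
        cis[dead] = _lognormal(rng, *_CIS_DEAD, int(dead.sum()))
        mat[:, col["cisplatin"]] = cis

        # barcode: 3 of 6 Pd channels high with multiplicative noise
        bits = key_of_t[t]
        for j, pc in enumerate(pd_cols):
            if j in bits:
                mat[:, pc] = _lognormal(rng, _BC_HIGH[0], config.barcode_noise_cv, n)
            else:
                mat[:, pc] = np.abs(rng.normal(0.0, _BC_LOW_SIGMA, n))

        blocks.append(mat)
        truths.append(pd.DataFrame({
            "sample_label": label_of_t[t], "timepoint_h": t,
            "subset": subset_lab, "phase": phase_lab,
            "live": ~dead, "doublet": False,
        }))

    pool = np.vstack(blocks)
    truth = pd.concat(truths, ignore_index=True)

    # doublets: channel-wise sums of two random events (possibly from
    # different time points), so DNA content and barcode pattern both betray them
    n_total = pool.shape[0]
    n_doub = int(round(config.doublet_fraction * n_total))
    if n_doub:
        i = rng.integers(0, n_total, size=n_doub)
        j = rng.integers(0, n_total, size=n_doub)
        doublet_mat = pool[i] + pool[j]
        same_label = truth["sample_label"].to_numpy()[i] == truth["sample_label"].to_numpy()[j]
        doub_truth = pd.DataFrame({
            "sample_label": np.where(same_label, truth["sample_label"].to_numpy()[i], "DOUBLET"),
            "timepoint_h": np.where(same_label, truth["timepoint_h"].to_numpy()[i], np.nan),
            "subset": "doublet", "phase": "G0",
            "live": truth["live"].to_numpy()[i] & truth["live"].to_numpy()[j],
            "doublet": True,
        })
        pool = np.vstack([pool, doublet_mat])
        truth = pd.concat([truth, doub_truth], ignore_index=True)

    order = rng.permutation(pool.shape[0])
    pool = pool[order]
    truth = truth.iloc[order].reset_index(drop=True)

    frame = EventFrame(pool, panel)
    return DonorSample(
        donor_id=donor_id, cohort=config.cohort, frame=frame, truth=truth,
        scheme=scheme, manifest=manifest,
        truth_folds=pd.DataFrame(fold_rows))


def simulate_experiment(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> list[DonorSample]:
    """Simulate the full experiment: one pooled barcoded sample per donor.

    With ``out_dir`` the pooled FCS files, code books, manifest, panel and
    ground-truth sidecars are also written to disk.  The configured seed
    fully determines the output.
    """
    master = np.random.SeedSequence(config.seed)
    donor_seeds = master.spawn(config.n_donors)
    prefix = "AT" if config.cohort == "AT" else "D"
    donors = [
        _simulate_donor(config, f"{prefix}{i + 1:02d}", np.random.default_rng(ss))
        for i, ss in enumerate(donor_seeds)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_panel(default_panel(), out / "panel.csv")
        manifest_rows = []
        for d in donors:
            write_fcs(d.frame, out / f"{d.donor_id}_pooled.fcs")
            save_code_book(d.scheme, out / f"{d.donor_id}_codebook.csv")
            d.truth.to_csv(out / f"{d.donor_id}_truth_events.csv", index=False)
            d.truth_folds.to_csv(out / f"{d.donor_id}_truth_folds.csv", index=False)
            for label, meta in d.manifest.items():
                manifest_rows.append({
                    "sample_label": label, "donor": meta.donor_id,
                    "condition": meta.condition, "timepoint_h": meta.timepoint_h,
                    "cohort": meta.cohort})
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    return donors
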