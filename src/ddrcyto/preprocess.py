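"""Event-level preprocessing: arcsinh transform, singlet and viability gates.

Mass-cytometry ion counts are heavy-tailed and zero-inflated; the standard
variance-stabilising transform is x -> asinh(x / cofactor) with cofactor 5.
Nucleated single cells are identified on the iridium DNA intercalator
channels (Ir191/Ir193): doublets carry roughly twice the DNA signal and
fall above the singlet band.  Dead/permeable cells take up the cisplatin
viability stain strongly and are removed as cisplatin-high.

Both gates are plain per-event filters, so they commute and are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._density import kde_grid, density_peaks, main_mode, valley_between
from .errors import EstimationError, PanelError, StateError, ValidationError
from .fcs_io import EventFrame

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransformSpec:
    """arcsinh cofactor; 5 is the mass-cytometry community default."""

    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ValidationError("arcsinh cofactor must be positive")


@dataclass
class PreprocessThresholds:
    """Transformed-scale bounds for the DNA (singlet) and viability gates.

    ``dna_low``/``dna_high`` bound the first iridium channel (Ir191); the
    second channel (Ir193) sits higher by the isotope-abundance offset, so
    its band is the same width shifted by ``dna_offset2`` (estimated as the
    mode difference between the two channels).
    """

    dna_low: float
    dna_high: float
    viability_max: float = np.inf
    dna_offset2: float = 0.0
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if not self.dna_low < self.dna_high:
            raise ValidationError("dna_low must be < dna_high")


def arcsinh_transform(
    frame: EventFrame,
    spec: TransformSpec | None = None,
    roles: set[str] | None = None,
) -> EventFrame:
    """Apply x -> asinh(x/cofactor) to the channels of the selected roles.

    By default every channel (barcode channels included) is transformed with
    the same cofactor.  The raw matrix is retained on the returned frame for
    raw-scale statistics (geometric MFIs).  Transforming twice is an error.
    """
    if frame.transformed:
        raise StateError("frame is already arcsinh-transformed")
    spec = spec or TransformSpec()
    out = frame.values.copy()
    cols = [
        i for i, c in enumerate(frame.channels)
        if roles is None or c.role in roles
    ]
    out[:, cols] = np.arcsinh(out[:, cols] / spec.cofactor)
    return EventFrame(out, frame.channels, meta=frame.meta, transformed=True,
                      raw=frame.values.copy())


def _dna_channels(frame: EventFrame) -> list[int]:
    chans = frame.channels_with_role("dna")
    if len(chans) < 2:
        raise PanelError("singlet gating needs two DNA (iridium) channels")
    return [frame.channel_index(c.channel_id) for c in chans[:2]]


def _viability_channel(frame: EventFrame) -> int:
    chans = frame.channels_with_role("viability")
    if not chans:
        raise PanelError("viability gating needs a cisplatin channel")
    return frame.channel_index(chans[0].channel_id)


def estimate_preprocess_thresholds(
    frame: EventFrame, k_mad: float = 3.0
) -> PreprocessThresholds:
    """Per-file default gates, mirroring the manual strategy.

    Singlet band: main Ir191 density mode +/- k*MAD (k=3), applied jointly to
    both iridium channels.  Viability bound: the density valley between the
    cisplatin-low (live) and cisplatin-high (dead) modes; if the channel is
    unimodal (no dead cells) the bound is mode + 6*MAD, i.e. effectively open.
    """
    if not frame.transformed:
        raise StateError("estimate thresholds on the transformed frame")
    if frame.n_events < 200:
        raise EstimationError("need >= 200 events to estimate preprocessing gates")
    i1, i2 = _dna_channels(frame)
    ir = frame.values[:, i1]
    mode = main_mode(ir)
    mad = float(np.median(np.abs(ir - np.median(ir))))
    if mad <= 0:
        raise EstimationError("degenerate DNA channel (zero MAD)")
    dna_low, dna_high = mode - k_mad * mad, mode + k_mad * mad
    dna_offset2 = main_mode(frame.values[:, i2]) - mode

    cis = frame.values[:, _viability_channel(frame)]
    grid, dens = kde_grid(cis)
    locs, heights = density_peaks(grid, dens)
    if locs.size >= 2:
        top2 = locs[np.argsort(heights)[-2:]]
        viability_max = valley_between(grid, dens, float(top2.min()), float(top2.max()))
    else:
        cmad = float(np.median(np.abs(cis - np.median(cis)))) or float(np.std(cis))
        viability_max = float(locs[0]) + 6.0 * cmad
    return PreprocessThresholds(dna_low=dna_low, dna_high=dna_high,
                                viability_max=viability_max,
                                dna_offset2=dna_offset2, provenance="estimated")


def gate_singlets(frame: EventFrame, thr: PreprocessThresholds) -> EventFrame:
    """Retain events with both iridium channels inside [dna_low, dna_high]."""
    if not frame.transformed:
        raise StateError("singlet gating operates on the transformed frame")
    i1, i2 = _dna_channels(frame)
    v = frame.values
    lo2, hi2 = thr.dna_low + thr.dna_offset2, thr.dna_high + thr.dna_offset2
    mask = (
        (v[:, i1] >= thr.dna_low) & (v[:, i1] <= thr.dna_high)
        & (v[:, i2] >= lo2) & (v[:, i2] <= hi2)
    )
    out = frame.select(mask)
    log.info("singlet gate: %d -> %d events", frame.n_events, out.n_events)
    return out


def gate_viable(frame: EventFrame, thr: PreprocessThresholds) -> EventFrame:
    """Retain cisplatin-low (live) events."""
    if not frame.transformed:
        raise StateError("viability gating operates on the transformed frame")
    j = _viability_channel(frame)
    mask = frame.values[:, j] <= thr.viability_max
    out = frame.select(mask)
    if out.n_events == 0 and frame.n_events > 0:
        log.warning("viability gate removed every event (all-dead sample?)")
    log.info("viability gate: %d -> %d events", frame.n_events, out.n_events)
    return out


@dataclass
class FilterAudit:
    """Events in/out per filter stage, for the run report and CSV audit log."""

    rows: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.rows.append({"stage": stage, "events_in": n_in, "events_out": n_out, **extra})
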