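"""Palladium barcode deconvolution (20-key, 3-of-6 scheme).

Each pooled sample carries a combinatorial barcode: exactly 3 of the 6
palladium isotopes (Pd102/104/105/106/108/110) are high, giving C(6,3)=20
distinct keys.  Deconvolution is single-cell separation debarcoding: the 6
transformed Pd intensities are rescaled per channel to [0, 1] by a robust
(1st-99th percentile) range, sorted, and the event is assigned to the key
whose set bits are the top-3 channels, provided the separation (3rd-highest
minus 4th-highest rescaled value) clears a cutoff.  Doublets of two
differently-keyed cells have >= 4 high channels, hence near-zero separation,
and are rejected as UNASSIGNED.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ManifestError, PanelError, ValidationError
from .fcs_io import AcquisitionMetadata, EventFrame

log = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

#: the six palladium barcode channels, by increasing mass
PD_CHANNELS = ("Pd102Di", "Pd104Di", "Pd105Di", "Pd106Di", "Pd108Di", "Pd110Di")


def all_keys() -> list[tuple[int, ...]]:
    """The 20 possible 3-of-6 bit patterns, lexicographically ordered."""
    return list(itertools.combinations(range(6), 3))


@dataclass
class BarcodeScheme:
    """Code book mapping sample labels to 3-of-6 Pd bit patterns."""

    keys: dict[str, tuple[int, ...]]
    pd_channels: tuple[str, ...] = PD_CHANNELS
    separation_cutoff: float = 0.3

    def __post_init__(self) -> None:
        if len(self.pd_channels) != 6:
            raise ValidationError("a 3-of-6 scheme needs exactly 6 Pd channels")
        if not 0.0 <= self.separation_cutoff <= 1.0:
            raise ValidationError("separation_cutoff must lie in [0, 1]")
        patterns = []
        for label, bits in self.keys.items():
            bits = tuple(sorted(int(b) for b in bits))
            if len(bits) != 3 or len(set(bits)) != 3 or not all(0 <= b < 6 for b in bits):
                raise ValidationError(f"key for {label!r} must set exactly 3 of 6 bits")
            self.keys[label] = bits
            patterns.append(bits)
        if len(set(patterns)) != len(patterns):
            raise ValidationError("barcode keys must be distinct")
        if len(patterns) > 20:
            raise ValidationError("a 3-of-6 scheme admits at most 20 keys")


def full_scheme(separation_cutoff: float = 0.3) -> BarcodeScheme:
    """The complete 20-key code book with vendor-style labels BC01..BC20."""
    return BarcodeScheme(
        keys={f"BC{i + 1:02d}": bits for i, bits in enumerate(all_keys())},
        separation_cutoff=separation_cutoff,
    )


def load_code_book(path: str | Path, separation_cutoff: float = 0.3) -> BarcodeScheme:
    """Code book CSV: sample_label plus 6 binary columns (one per Pd channel)."""
    keys: dict[str, tuple[int, ...]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["sample_label"]
            bits = tuple(i for i, ch in enumerate(PD_CHANNELS) if int(row[ch]))
            keys[label] = bits
    return BarcodeScheme(keys=keys, separation_cutoff=separation_cutoff)


def save_code_book(scheme: BarcodeScheme, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_label", *scheme.pd_channels])
        for label, bits in scheme.keys.items():
            w.writerow([label, *[1 if i in bits else 0 for i in range(6)]])


@dataclass
class DebarcodeResult:
    assignment: np.ndarray  # per-event sample label or UNASSIGNED
    separation: np.ndarray  # per-event separation in [0, 1]
    yield_table: pd.DataFrame  # sample_label, n_events (UNASSIGNED row included)

    def __post_init__(self) -> None:
        if int(self.yield_table["n_events"].sum()) != self.assignment.size:
            raise ValidationError("yield table counts must sum to the total event count")


def debarcode(frame: EventFrame, scheme: BarcodeScheme) -> DebarcodeResult:
    """Assign each event to a barcode key by top-3 separation.

    Operates on the transformed Pd intensities; the per-channel robust range
    used for rescaling is computed on the pooled file itself.
    """
    if not frame.transformed:
        raise ValidationError("debarcode operates on arcsinh-transformed intensities")
    try:
        cols = [frame.channel_index(c) for c in scheme.pd_channels]
    except PanelError as e:
        raise PanelError(f"barcode channel missing: {e}") from None
    pd_mat = frame.values[:, cols]

    lo = np.percentile(pd_mat, 1, axis=0)
    hi = np.percentile(pd_mat, 99, axis=0)
    span = hi - lo
    bad = span <= 1e-9
    if np.any(bad):
        names = [scheme.pd_channels[i] for i in np.where(bad)[0]]
        raise ConfigError(f"degenerate (constant) barcode channel(s): {', '.join(names)}")
    scaled = np.clip((pd_mat - lo) / span, 0.0, 1.0)

    order = np.argsort(scaled, axis=1)  # ascending
    srt = np.take_along_axis(scaled, order, axis=1)
    separation = srt[:, 3] - srt[:, 2]  # 3rd-highest minus 4th-highest

    top3 = np.sort(order[:, 3:], axis=1)
    # encode 3-bit patterns as integers for vectorised lookup
    code = top3[:, 0] * 36 + top3[:, 1] * 6 + top3[:, 2]
    lut = np.full(6 * 36 + 36 + 6, -1, dtype=np.int64)
    labels = list(scheme.keys)
    for idx, label in enumerate(labels):
        b = scheme.keys[label]
        lut[b[0] * 36 + b[1] * 6 + b[2]] = idx
    key_idx = lut[code]

    assigned = (separation >= scheme.separation_cutoff) & (key_idx >= 0)
    assignment = np.full(frame.n_events, UNASSIGNED, dtype=object)
    assignment[assigned] = np.array(labels, dtype=object)[key_idx[assigned]]

    counts = [{"sample_label": lab, "n_events": int(np.sum(assignment == lab))}
              for lab in labels]
    counts.append({"sample_label": UNASSIGNED,
                   "n_events": int(np.sum(assignment == UNASSIGNED))})
    yield_table = pd.DataFrame(counts)
    log.info("debarcoded %d events: %d assigned, %d unassigned",
             frame.n_events, int(assigned.sum()), int((~assigned).sum()))
    return DebarcodeResult(assignment=assignment, separation=separation,
                           yield_table=yield_table)


def split_by_sample(
    frame: EventFrame,
    result: DebarcodeResult,
    manifest: dict[str, AcquisitionMetadata],
) -> dict[str, EventFrame]:
    """One EventFrame per assigned label, with acquisition metadata attached.

    UNASSIGNED events are dropped (they stay counted in the yield table).
    """
    out: dict[str, EventFrame] = {}
    present = [l for l in pd.unique(result.assignment) if l != UNASSIGNED]
    missing = sorted(set(present) - set(manifest))
    if missing:
        raise ManifestError(f"labels missing from manifest: {', '.join(missing)}")
    for label in present:
        sub = frame.select(result.assignment == label)
        out[label] = sub.with_meta(manifest[label])
    if not out:
        log.warning("no events assigned to any barcode key")
    return out
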