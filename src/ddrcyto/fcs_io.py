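"""FCS event-file I/O and the in-memory event container.

The pipeline consumes FCS 3.0/3.1 list-mode files as produced by a Helios
mass cytometer (``$DATATYPE`` F or I, ``$MODE`` L) and always writes FCS 3.1
with float32 data.  Channel identity is carried by the ``$PnN`` short name;
``$PnS`` holds the biological marker label and is used for display only.
Acquisition metadata (donor, condition, time point, cohort) travels in
custom TEXT keywords so that debarcoded per-sample files remain
self-describing.

Only the first dataset of a multi-dataset file is read (a warning is
emitted); the pipeline operates on debarcoded single-sample files.
"""

from __future__ import annotations

import csv
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import FcsFormatError, PanelError, TruncationError, ValidationError

ROLES = ("surface", "intranuclear_ddr", "cellcycle", "barcode", "viability", "dna", "other")

CONDITIONS = ("untreated", "IR_2Gy", "UVC_100mJ")

#: custom TEXT keywords used to round-trip acquisition metadata
_META_KEYWORDS = {
    "donor_id": "DDRDONOR",
    "condition": "DDRCONDITION",
    "timepoint_h": "DDRTIMEPOINT",
    "cohort": "DDRCOHORT",
    "il2": "DDRIL2",
}


@dataclass(frozen=True)
class ChannelDescriptor:
    """One acquisition channel: detector name, metal tag, marker, role."""

    channel_id: str
    metal: str = ""
    marker: str = ""
    role: str = "other"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown channel role {self.role!r} for {self.channel_id}")


@dataclass
class AcquisitionMetadata:
    """Provenance of one debarcoded sample."""

    donor_id: str
    condition: str = "untreated"
    timepoint_h: float = 0.0
    cohort: str = "control"
    il2: bool = True

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        # the untreated sample is, by definition, the time-0 reference
        if (self.timepoint_h == 0) != (self.condition == "untreated"):
            raise ValidationError(
                f"timepoint {self.timepoint_h} h inconsistent with condition "
                f"{self.condition!r}: t=0 iff untreated"
            )


class EventFrame:
    """Events x channels intensity matrix with channel + acquisition metadata.

    ``values`` holds the working-scale intensities (raw ion counts until
    :func:`ddrcyto.preprocess.arcsinh_transform` is applied, arcsinh scale
    afterwards).  When a transform is applied the raw matrix is retained in
    ``raw`` because geometric MFIs are computed on the raw scale.
    """

    def __init__(
        self,
        values: np.ndarray,
        channels: Sequence[ChannelDescriptor],
        meta: AcquisitionMetadata | None = None,
        transformed: bool = False,
        raw: np.ndarray | None = None,
    ) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValidationError("intensity matrix must be 2-D (events x channels)")
        if values.shape[1] != len(channels):
            raise ValidationError(
                f"matrix has {values.shape[1]} columns but {len(channels)} channel descriptors"
            )
        ids = [c.channel_id for c in channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("channel_id values must be unique within a panel")
        if not transformed and values.size and np.nanmin(values) < 0:
            raise ValidationError("raw intensities must be non-negative")
        self.values = values
        self.channels = list(channels)
        self.meta = meta
        self.transformed = transformed
        self.raw = None if raw is None else np.asarray(raw, dtype=np.float64)
        self._col = {c.channel_id.lower(): i for i, c in enumerate(self.channels)}
        self._marker_col: dict[str, int] = {}
        for i, c in enumerate(self.channels):
            key = c.marker.lower() if c.marker else c.channel_id.lower()
            self._marker_col.setdefault(key, i)

    # -- basic introspection -------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def channel_index(self, channel_id: str) -> int:
        try:
            return self._col[channel_id.lower()]
        except KeyError:
            raise PanelError(f"channel {channel_id!r} not in panel") from None

    def marker_index(self, marker: str) -> int:
        """Column index by marker name (case-insensitive), falling back to channel_id."""
        key = marker.lower()
        if key in self._marker_col:
            return self._marker_col[key]
        if key in self._col:
            return self._col[key]
        raise PanelError(f"marker {marker!r} not in panel")

    def marker(self, marker: str) -> np.ndarray:
        """Working-scale intensities for a marker."""
        return self.values[:, self.marker_index(marker)]

    def raw_marker(self, marker: str) -> np.ndarray:
        """Raw-scale intensities for a marker (pre-transform values)."""
        mat = self.raw if (self.transformed and self.raw is not None) else self.values
        return mat[:, self.marker_index(marker)]

    def channels_with_role(self, role: str) -> list[ChannelDescriptor]:
        return [c for c in self.channels if c.role == role]

    # -- derived frames ------------------------------------------------------

    def select(self, mask: np.ndarray) -> "EventFrame":
        """Row subset preserving order, channel metadata and raw values."""
        mask = np.asarray(mask)
        return EventFrame(
            self.values[mask],
            self.channels,
            meta=self.meta,
            transformed=self.transformed,
            raw=None if self.raw is None else self.raw[mask],
        )

    def with_meta(self, meta: AcquisitionMetadata) -> "EventFrame":
        return EventFrame(self.values, self.channels, meta=meta,
                          transformed=self.transformed, raw=self.raw)

    def copy(self) -> "EventFrame":
        return EventFrame(self.values.copy(), list(self.channels), meta=self.meta,
                          transformed=self.transformed,
                          raw=None if self.raw is None else self.raw.copy())


# ---------------------------------------------------------------------------
# panel files
# ---------------------------------------------------------------------------

def load_panel(path: str | Path) -> list[ChannelDescriptor]:
    """Load a panel description (channel_id, metal, marker, role) from CSV or YAML."""
    path = Path(path)
    rows: Iterable[dict]
    if path.suffix.lower() in (".yaml", ".yml"):
        rows = yaml.safe_load(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    return [
        ChannelDescriptor(
            channel_id=r["channel_id"],
            metal=r.get("metal", "") or "",
            marker=r.get("marker", "") or "",
            role=r.get("role", "other") or "other",
        )
        for r in rows
    ]


def save_panel(channels: Sequence[ChannelDescriptor], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel_id", "metal", "marker", "role"])
        for c in channels:
            w.writerow([c.channel_id, c.metal, c.marker, c.role])


@dataclass
class PanelReport:
    passed: bool
    missing_roles: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def validate_panel(frame: EventFrame, required_roles: Iterable[str]) -> PanelReport:
    """Report whether every required role maps to at least one channel."""
    present = {c.role for c in frame.channels}
    missing = sorted(set(required_roles) - present)
    msgs = [f"no channel with role {r!r}" for r in missing]
    return PanelReport(passed=not missing, missing_roles=missing, messages=msgs)


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading delimiter; a trailing delimiter is required but we are lenient
    parts = body.strip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    kw = {}
    for k, v in zip(parts[::2], parts[1::2]):
        kw[k.strip().upper()] = v
    return kw


def _required(kw: dict[str, str], key: str) -> str:
    if key not in kw:
        raise FcsFormatError(f"missing required TEXT keyword {key}")
    return kw[key]


def read_fcs(path: str | Path, panel: Sequence[ChannelDescriptor] | None = None) -> EventFrame:
    """Read an FCS 3.0/3.1 file into an :class:`EventFrame`.

    When a panel is given, channels are matched case-insensitively by
    ``$PnN`` against ``channel_id``; unmatched channels are retained with
    role ``other``.
    """
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise FcsFormatError("file shorter than the 58-byte FCS header")
    version = data[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"unsupported FCS version {version!r}")

    def _offset(a: int, b: int, name: str) -> int:
        try:
            return int(data[a:b].decode("latin-1").strip() or 0)
        except ValueError:
            raise FcsFormatError(f"non-numeric header offset for {name}") from None

    text_begin = _offset(10, 18, "TEXT begin")
    text_end = _offset(18, 26, "TEXT end")
    data_begin = _offset(26, 34, "DATA begin")
    data_end = _offset(34, 42, "DATA end")
    if text_begin <= 0 or text_end < text_begin:
        raise FcsFormatError("invalid TEXT segment offsets in header")
    kw = _parse_text_segment(data[text_begin:text_end + 1])

    if int(kw.get("$NEXTDATA", "0") or 0) != 0:
        warnings.warn("multi-dataset FCS file: reading only the first dataset", stacklevel=2)

    if data_begin == 0 or data_end == 0:
        data_begin = int(_required(kw, "$BEGINDATA"))
        data_end = int(_required(kw, "$ENDDATA"))

    datatype = _required(kw, "$DATATYPE").upper()
    if datatype not in ("F", "I"):
        raise FcsFormatError(f"unsupported $DATATYPE {datatype!r} (only F and I)")
    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsFormatError(f"unsupported $MODE {mode!r} (only list mode L)")
    byteord = _required(kw, "$BYTEORD")
    little = byteord.startswith("1")
    n_par = int(_required(kw, "$PAR"))
    n_tot = int(_required(kw, "$TOT"))

    bits = [int(_required(kw, f"$P{i}B")) for i in range(1, n_par + 1)]
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    labels = [kw.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    ranges = [int(float(kw.get(f"$P{i}R", "0") or 0)) for i in range(1, n_par + 1)]

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsFormatError("$DATATYPE F requires $PnB=32 for every parameter")
        itemsize = 4
        dtype = np.dtype("<f4" if little else ">f4")
        expected = n_tot * n_par * itemsize
        seg = data[data_begin:data_begin + expected]
        if len(seg) < expected:
            raise TruncationError(
                f"DATA segment holds {len(seg)} bytes but $TOT={n_tot} events "
                f"x {n_par} parameters need {expected}"
            )
        mat = np.frombuffer(seg, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)
    else:  # I
        if any(b not in (8, 16, 32) for b in bits):
            raise FcsFormatError("$DATATYPE I supports only 8/16/32-bit parameters ($PnB)")
        row_bytes = sum(b // 8 for b in bits)
        expected = n_tot * row_bytes
        seg = data[data_begin:data_begin + expected]
        if len(seg) < expected:
            raise TruncationError(
                f"DATA segment holds {len(seg)} bytes but needs {expected}"
            )
        if len(set(bits)) == 1:
            w = bits[0] // 8
            dtype = np.dtype(("<" if little else ">") + {1: "u1", 2: "u2", 4: "u4"}[w])
            mat = np.frombuffer(seg, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)
        else:  # mixed widths: slow path
            mat = np.empty((n_tot, n_par), dtype=np.float64)
            fmt = ("<" if little else ">") + "".join({8: "B", 16: "H", 32: "I"}[b] for b in bits)
            rec = struct.Struct(fmt)
            for i in range(n_tot):
                mat[i] = rec.unpack_from(seg, i * row_bytes)
        # mask each parameter to its $PnR range (next power of two - 1)
        for j, r in enumerate(ranges):
            if r > 0:
                mask = (1 << int(np.ceil(np.log2(r)))) - 1 if r > 1 else 1
                mat[:, j] = np.asarray(mat[:, j], dtype=np.int64) & mask

    # channel descriptors: match against panel if given
    by_id = {c.channel_id.lower(): c for c in (panel or [])}
    chans = []
    for nm, lb in zip(names, labels):
        c = by_id.get(nm.lower())
        if c is None:
            c = ChannelDescriptor(channel_id=nm, marker=lb, role="other")
        chans.append(c)

    meta = None
    if _META_KEYWORDS["donor_id"] in kw:
        meta = AcquisitionMetadata(
            donor_id=kw[_META_KEYWORDS["donor_id"]],
            condition=kw.get(_META_KEYWORDS["condition"], "untreated"),
            timepoint_h=float(kw.get(_META_KEYWORDS["timepoint_h"], "0")),
            cohort=kw.get(_META_KEYWORDS["cohort"], "control"),
            il2=kw.get(_META_KEYWORDS["il2"], "1") == "1",
        )
    transformed = kw.get("DDRTRANSFORMED", "0") == "1"
    return EventFrame(mat, chans, meta=meta, transformed=transformed)


# ---------------------------------------------------------------------------
# FCS writing
# ---------------------------------------------------------------------------

def write_fcs(frame: EventFrame, path: str | Path) -> None:
    """Write an :class:`EventFrame` as FCS 3.1 ($DATATYPE F, little-endian).

    ``$PnN`` carries ``channel_id`` and ``$PnS`` the marker label, so
    ``read_fcs(write_fcs(f))`` reproduces the frame to float32 precision.
    """
    vals = frame.values
    if vals.size and not np.all(np.isfinite(vals)):
        raise ValidationError("cannot write non-finite intensities to FCS")
    n_tot, n_par = vals.shape
    payload = vals.astype("<f4").tobytes()

    delim = "/"
    kw: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i, c in enumerate(frame.channels, start=1):
        rng = 262144  # nominal range; informative only for float data
        if vals.size:
            m = float(np.max(np.abs(vals[:, i - 1]))) if n_tot else 0.0
            rng = max(int(np.ceil(m)) + 1, 1)
        kw += [
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}N", c.channel_id),
            (f"$P{i}S", c.marker or c.channel_id),
            (f"$P{i}R", str(rng)),
        ]
    if frame.meta is not None:
        m = frame.meta
        kw += [
            (_META_KEYWORDS["donor_id"], m.donor_id),
            (_META_KEYWORDS["condition"], m.condition),
            (_META_KEYWORDS["timepoint_h"], repr(float(m.timepoint_h))),
            (_META_KEYWORDS["cohort"], m.cohort),
            (_META_KEYWORDS["il2"], "1" if m.il2 else "0"),
        ]
    kw.append(("DDRTRANSFORMED", "1" if frame.transformed else "0"))

    # assemble with placeholder data offsets, then patch
    def render(pairs: list[tuple[str, str]]) -> str:
        out = delim
        for k, v in pairs:
            v = v if v != "" else " "
            if delim in k or delim in v:
                raise ValidationError(f"TEXT value for {k} contains the delimiter {delim!r}")
            out += f"{k}{delim}{v}{delim}"
        return out

    text_begin = 58
    # iterate because $BEGINDATA/$ENDDATA lengths feed back into the offsets
    begin_data, end_data = 0, 0
    for _ in range(4):
        pairs = kw + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        text = render(pairs)
        text_end = text_begin + len(text) - 1
        nb = text_end + 1
        ne = nb + len(payload) - 1 if payload else nb
        if (nb, ne) == (begin_data, end_data):
            break
        begin_data, end_data = nb, ne
    text = render(kw + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))])
    text_end = text_begin + len(text) - 1

    def fmt(off: int) -> bytes:
        s = str(off)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry the truth
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_begin) + fmt(text_end)
    header += fmt(begin_data if begin_data <= 99999999 else 0)
    header += fmt(end_data if end_data <= 99999999 else 0)
    header += fmt(0) + fmt(0)  # no ANALYSIS segment
    blob = header + text.encode("latin-1") + payload
    Path(path).write_bytes(blob)
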