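"""Declarative hierarchical immunophenotyping and cell-cycle classification.

Populations are defined as conjunctions of per-marker level predicates
(neg/pos/dim/bright/very_high/low) arranged in a tree: a child population
inherits all of its parent's predicates and adds its own, so membership of
a child always implies membership of the parent.  Memberships are reported
as a boolean events x populations matrix, not exclusive labels, because the
population set overlaps by construction (an event can be CD3+, CD3+CD4+
and naive CD4 at once).

Level semantics on the transformed scale, given per-marker thresholds t1
(< t2 where defined):

    neg:        x <  t1
    pos:        x >= t1
    dim:        t1 <= x < t2
    bright:     x >= t2    ("high" and "bright" are synonyms; "++" likewise)
    very_high:  x >= t2
    low:        x <  t1    (CD21low / CD38low: low is not distinguished
                            from negative)

Cell-cycle phases partition events by ki67 and IdU: ki67+IdU+ = S,
ki67+IdU- = G1, ki67-IdU- = G0; ki67-IdU+ cells (a transient
replication-arrest state seen after UVC) are reported as their own class
rather than merged into S.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from ._density import kde_grid, density_peaks, valley_between
from .errors import EstimationError, GatingSpecError, PanelError, ValidationError
from .fcs_io import EventFrame

LEVELS = ("neg", "pos", "dim", "bright", "very_high", "low")
#: levels whose predicate needs the upper threshold t2
TWO_THRESHOLD_LEVELS = ("dim", "bright", "very_high")

PHASES = ("G0", "G1", "S", "KI67NEG_IDUPOS")


@dataclass(frozen=True)
class MarkerPredicate:
    marker: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown predicate level {self.level!r}")


@dataclass
class PopulationDef:
    name: str
    predicates: list[MarkerPredicate]
    parent: str | None = None

    def __post_init__(self) -> None:
        if not self.predicates:
            raise ValidationError(f"population {self.name!r} has no predicates")


@dataclass
class ThresholdSet:
    """Per-marker thresholds on the transformed scale."""

    t1: dict[str, float]
    t2: dict[str, float] = field(default_factory=dict)
    provenance: str = "manual"

    def __post_init__(self) -> None:
        for m, hi in self.t2.items():
            lo = self.t1.get(m)
            if lo is not None and not lo < hi:
                raise ValidationError(f"t1 < t2 violated for marker {m!r}")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["marker", "t1", "t2", "provenance"])
            for m in sorted(self.t1):
                w.writerow([m, repr(self.t1[m]),
                            repr(self.t2[m]) if m in self.t2 else "", self.provenance])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThresholdSet":
        t1, t2, prov = {}, {}, "manual"
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                t1[row["marker"]] = float(row["t1"])
                if row.get("t2"):
                    t2[row["marker"]] = float(row["t2"])
                prov = row.get("provenance", prov) or prov
        return cls(t1=t1, t2=t2, provenance=prov)


class Membership:
    """Boolean events x populations matrix with hierarchy helpers."""

    def __init__(self, matrix: pd.DataFrame):
        self.matrix = matrix

    @property
    def populations(self) -> list[str]:
        return list(self.matrix.columns)

    def counts(self) -> pd.Series:
        return self.matrix.sum(axis=0).astype(int)

    def frequencies(self, denominator: str = "CD45+") -> pd.Series:
        """Population frequencies as a percentage of a reference population."""
        denom = int(self.matrix[denominator].sum())
        if denom == 0:
            return self.matrix.sum() * np.nan
        return 100.0 * self.matrix.sum(axis=0) / denom


# ---------------------------------------------------------------------------
# threshold estimation
# ---------------------------------------------------------------------------

def _valley_t1(values: np.ndarray, q: float) -> tuple[float, float | None, str]:
    """(t1, uppermost mode or None, method) for one marker."""
    grid, dens = kde_grid(values)
    locs, heights = density_peaks(grid, dens)
    if locs.size >= 2:
        top2 = locs[np.argsort(heights)[-2:]]
        t1 = valley_between(grid, dens, float(top2.min()), float(top2.max()))
        upper = float(locs.max())
        return t1, upper if upper > t1 else None, "valley"
    return float(np.quantile(values, q)), None, "quantile"


def estimate_thresholds(
    frame: EventFrame,
    markers: Sequence[str],
    method: str = "valley",
    q: float = 0.95,
    two_level_markers: Iterable[str] = ("CD56", "IgM", "CD38"),
    always_positive: Iterable[str] = ("CD45",),
) -> ThresholdSet:
    """Estimate per-marker gate thresholds from the transformed distribution.

    ``valley``: t1 is the deepest KDE minimum between the two largest modes;
    unimodal channels fall back to the q-quantile.  Markers in
    ``always_positive`` are expressed by every analysed event (CD45 on
    lymphocytes), so their unimodal distribution is the positive one and t1
    is placed at mode - 3*MAD instead.  For markers that need an upper
    threshold, t2 is the midpoint between t1 and the uppermost density mode
    (or, if no mode lies above t1, the midpoint to the 99.9th percentile).
    """
    if not frame.transformed:
        raise EstimationError("estimate thresholds on the transformed frame")
    if frame.n_events < 200:
        raise EstimationError("need >= 200 events to estimate gate thresholds")
    if method not in ("valley", "quantile"):
        raise ValidationError(f"unknown threshold method {method!r}")
    two_level = set(two_level_markers)
    positive = {m.lower() for m in always_positive}

    t1_map: dict[str, float] = {}
    t2_map: dict[str, float] = {}
    for m in markers:
        x = frame.marker(m)
        if np.ptp(x) <= 0:
            raise EstimationError(f"constant channel for marker {m!r}")
        if method == "quantile":
            t1, upper = float(np.quantile(x, q)), None
        elif m.lower() in positive:
            grid, dens = kde_grid(x)
            mode = float(grid[int(np.argmax(dens))])
            mad = float(np.median(np.abs(x - np.median(x)))) or float(np.std(x))
            t1, upper = mode - 3.0 * mad, None
        else:
            t1, upper, _ = _valley_t1(x, q)
        t1_map[m] = t1
        if m in two_level:
            if upper is None:
                upper = float(np.quantile(x, 0.999))
            t2 = 0.5 * (t1 + upper)
            if t2 <= t1:  # degenerate channel top: nudge above t1
                t2 = t1 + 1e-6
            t2_map[m] = t2
    return ThresholdSet(t1=t1_map, t2=t2_map, provenance="estimated")


# ---------------------------------------------------------------------------
# population assignment
# ---------------------------------------------------------------------------

def _effective_predicates(spec: Sequence[PopulationDef]) -> dict[str, list[MarkerPredicate]]:
    by_name = {p.name: p for p in spec}
    cache: dict[str, list[MarkerPredicate]] = {}

    def resolve(name: str, seen: tuple[str, ...] = ()) -> list[MarkerPredicate]:
        if name in cache:
            return cache[name]
        if name in seen:
            raise GatingSpecError(f"population hierarchy cycle through {name!r}")
        p = by_name.get(name)
        if p is None:
            raise GatingSpecError(f"unknown parent population {name!r}")
        preds = list(p.predicates)
        if p.parent is not None:
            preds = resolve(p.parent, seen + (name,)) + preds
        cache[name] = preds
        return preds

    return {p.name: resolve(p.name) for p in spec}


def _predicate_mask(x: np.ndarray, level: str, t1: float, t2: float | None,
                    marker: str) -> np.ndarray:
    if level in ("pos",):
        return x >= t1
    if level in ("neg", "low"):
        return x < t1
    if t2 is None:
        raise GatingSpecError(f"level {level!r} on {marker!r} needs an upper threshold t2")
    if level == "dim":
        return (x >= t1) & (x < t2)
    return x >= t2  # bright / very_high


def assign_populations(
    frame: EventFrame, spec: Sequence[PopulationDef], thr: ThresholdSet
) -> Membership:
    """Evaluate the gating tree; overlapping memberships are expected."""
    effective = _effective_predicates(spec)
    # validate marker/threshold availability up front
    for name, preds in effective.items():
        for p in preds:
            frame.marker_index(p.marker)
            if p.marker not in thr.t1:
                raise GatingSpecError(f"no threshold t1 for marker {p.marker!r} "
                                      f"(population {name!r})")
            if p.level in TWO_THRESHOLD_LEVELS and p.marker not in thr.t2:
                raise GatingSpecError(f"level {p.level!r} on {p.marker!r} needs t2 "
                                      f"(population {name!r})")
    cols = {}
    for pop in spec:
        mask = np.ones(frame.n_events, dtype=bool)
        for p in effective[pop.name]:
            x = frame.marker(p.marker)
            mask &= _predicate_mask(x, p.level, thr.t1[p.marker],
                                    thr.t2.get(p.marker), p.marker)
        cols[pop.name] = mask
    return Membership(pd.DataFrame(cols))


def classify_cell_cycle(frame: EventFrame, thr: ThresholdSet) -> np.ndarray:
    """Four-way ki67/IdU partition: S, G1, G0 and the ki67-IdU+ arrest class."""
    for m in ("ki67", "IdU"):
        if m not in thr.t1:
            raise PanelError(f"cell-cycle classification needs a threshold for {m!r}")
    ki67 = frame.marker("ki67") >= thr.t1["ki67"]
    idu = frame.marker("IdU") >= thr.t1["IdU"]
    phase = np.empty(frame.n_events, dtype=object)
    phase[ki67 & idu] = "S"
    phase[ki67 & ~idu] = "G1"
    phase[~ki67 & ~idu] = "G0"
    phase[~ki67 & idu] = "KI67NEG_IDUPOS"
    return phase


# ---------------------------------------------------------------------------
# the default population tree
# ---------------------------------------------------------------------------

def _pop(name: str, parent: str | None, *preds: tuple[str, str]) -> PopulationDef:
    return PopulationDef(name=name,
                         predicates=[MarkerPredicate(m, lvl) for m, lvl in preds],
                         parent=parent)


def default_gating_spec() -> list[PopulationDef]:
    """The full lymphocyte population tree used throughout the analysis.

    T cells split by CD4/CD8 and naive/central-memory/effector-memory
    (CD45RA/CD45RO x CCR7); NK cells by CD56 intensity and CD16, with CD57
    stratification of the CD16+ subsets; B cells by CD27/IgD/IgM isotype
    state, plus plasmablasts (CD19+CD20-) and the CD21low CD38low
    compartment.  "memory B" keeps its literal CD19+CD20+CD27+ definition
    and therefore excludes plasmablasts only through the CD20+ requirement
    of its parent gate.
    """
    specs = [
        _pop("CD45+", None, ("CD45", "pos")),
        _pop("CD3+ T", "CD45+", ("CD3", "pos")),
        _pop("CD3+CD4+", "CD3+ T", ("CD4", "pos")),
        _pop("naive CD4", "CD3+CD4+", ("CD45RA", "pos"), ("CCR7", "pos")),
        _pop("CM CD4", "CD3+CD4+", ("CD45RO", "pos"), ("CCR7", "pos")),
        _pop("EM CD4", "CD3+CD4+", ("CD45RO", "pos"), ("CCR7", "neg")),
        _pop("CD3+CD8+", "CD3+ T", ("CD8", "pos")),
        _pop("naive CD8", "CD3+CD8+", ("CD45RA", "pos"), ("CCR7", "pos")),
        _pop("CM CD8", "CD3+CD8+", ("CD45RO", "pos"), ("CCR7", "pos")),
        _pop("EM CD8", "CD3+CD8+", ("CD45RO", "pos"), ("CCR7", "neg")),
        _pop("CD56bright CD16- NK", "CD45+",
             ("CD3", "neg"), ("CD56", "bright"), ("CD16", "neg")),
        _pop("CD56bright CD16+ NK", "CD45+",
             ("CD3", "neg"), ("CD56", "bright"), ("CD16", "pos")),
        _pop("CD56dim CD16+ NK", "CD45+",
             ("CD3", "neg"), ("CD56", "dim"), ("CD16", "pos")),
        _pop("CD57+ CD56bright CD16+ NK", "CD56bright CD16+ NK", ("CD57", "pos")),
        _pop("CD57- CD56bright CD16+ NK", "CD56bright CD16+ NK", ("CD57", "neg")),
        _pop("CD57+ CD56dim CD16+ NK", "CD56dim CD16+ NK", ("CD57", "pos")),
        _pop("CD57- CD56dim CD16+ NK", "CD56dim CD16+ NK", ("CD57", "neg")),
        _pop("CD19+CD20+ B", "CD45+", ("CD3", "neg"), ("CD19", "pos"), ("CD20", "pos")),
        _pop("naive B", "CD19+CD20+ B", ("CD27", "neg"), ("IgD", "pos")),
        _pop("memory B", "CD19+CD20+ B", ("CD27", "pos")),
        _pop("unswitched memory B", "memory B", ("IgM", "pos")),
        _pop("class-switched memory B IgGk", "memory B",
             ("IgM", "neg"), ("IgGk", "pos")),
        _pop("class-switched memory B IgGl", "memory B",
             ("IgM", "neg"), ("IgGl", "pos")),
        _pop("MZ-like B", "memory B", ("IgM", "pos"), ("IgD", "pos")),
        _pop("transitional B", "CD19+CD20+ B", ("IgM", "very_high"), ("CD38", "very_high")),
        _pop("IgM-only B", "memory B", ("IgM", "pos"), ("IgD", "neg")),
        _pop("atypical memory B", "CD19+CD20+ B",
             ("CD27", "neg"), ("IgM", "neg"), ("IgD", "neg")),
        _pop("unswitched plasmablast", "CD45+",
             ("CD3", "neg"), ("CD19", "pos"), ("CD20", "neg"),
             ("CD27", "pos"), ("CD38", "pos"), ("IgM", "pos")),
        _pop("class-switched plasmablast", "CD45+",
             ("CD3", "neg"), ("CD19", "pos"), ("CD20", "neg"),
             ("CD27", "pos"), ("CD38", "pos"), ("IgM", "neg")),
        _pop("CD21low CD38low B", "CD19+CD20+ B", ("CD21", "low"), ("CD38", "low")),
    ]
    return specs


def spec_markers(spec: Sequence[PopulationDef]) -> list[str]:
    """All marker names referenced by a gating spec, in first-use order."""
    seen: dict[str, None] = {}
    for preds in _effective_predicates(spec).values():
        for p in preds:
            seen.setdefault(p.marker)
    return list(seen)


# ---------------------------------------------------------------------------
# YAML (de)serialisation of gating specs
# ---------------------------------------------------------------------------

def gating_spec_to_yaml(spec: Sequence[PopulationDef], path: str | Path | None = None) -> str:
    doc = [
        {
            "name": p.name,
            "parent": p.parent,
            "predicates": [{"marker": q.marker, "level": q.level} for q in p.predicates],
        }
        for p in spec
    ]
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def gating_spec_from_yaml(source: str | Path) -> list[PopulationDef]:
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    return [
        PopulationDef(
            name=d["name"],
            parent=d.get("parent"),
            predicates=[MarkerPredicate(q["marker"], q["level"]) for q in d["predicates"]],
        )
        for d in doc
    ]
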