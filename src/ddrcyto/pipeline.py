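"""End-to-end orchestration: read -> preprocess -> debarcode -> gate ->
quantify -> stats, with audit trails and deterministic outputs.

The pipeline operates on directories of pooled barcoded FCS files (one per
donor) plus a manifest, a panel and per-donor code books — the layout the
synthetic generator emits and the layout a debarcoding-ready real
experiment takes.  Gating thresholds are estimated per donor on the pooled
cleaned events of all time points (all time points of a donor were stained
in one tube, so one threshold set per donor keeps time points comparable)
and then applied to every time point.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ddr_quant import (AnalyzedSample, fold_induction_table,
                        stratified_kinetics, survival_proportions)
from .debarcode import UNASSIGNED, debarcode, load_code_book, split_by_sample
from .errors import ConfigError, DataError, ManifestError, ValidationError
from .fcs_io import AcquisitionMetadata, load_panel, read_fcs
from .gating import (assign_populations, classify_cell_cycle,
                     default_gating_spec, estimate_thresholds,
                     gating_spec_from_yaml, spec_markers)
from .preprocess import (FilterAudit, TransformSpec,
                         arcsinh_transform, estimate_preprocess_thresholds,
                         gate_singlets, gate_viable)
from .stats import sidak_pairs, star_code, students_t, \
    two_way_anova_tukey

log = logging.getLogger(__name__)

#: populations compared in the headline kinetics statistics
DEFAULT_STATS_POPULATIONS = ("CD3+ T", "CD56dim CD16+ NK", "CD19+CD20+ B")


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    manifest: Path | None = None  # default: <input_dir>/manifest.csv
    panel: Path | None = None  # default: <input_dir>/panel.csv
    gating_spec: Path | None = None  # default: built-in population tree
    cofactor: float = 5.0
    separation_cutoff: float = 0.3
    min_events: int = 30
    dna_band_mads: float = 3.0
    preprocess_overrides: dict = field(default_factory=dict)
    stats_populations: tuple[str, ...] = DEFAULT_STATS_POPULATIONS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"pipeline config {path} is not a mapping")
        kwargs = {}
        for key in ("input_dir", "output_dir", "manifest", "panel", "gating_spec"):
            if doc.get(key) is not None:
                kwargs[key] = Path(doc[key])
        for key in ("cofactor", "separation_cutoff", "min_events",
                    "dna_band_mads", "seed", "preprocess_overrides"):
            if key in doc:
                kwargs[key] = doc[key]
        if "stats_populations" in doc:
            kwargs["stats_populations"] = tuple(doc["stats_populations"])
        missing = {"input_dir", "output_dir"} - set(kwargs)
        if missing:
            raise ConfigError(f"pipeline config missing keys: {sorted(missing)}")
        return cls(**kwargs)


def load_manifest(path: str | Path) -> dict[str, AcquisitionMetadata]:
    """Manifest CSV/YAML: sample_label, donor, condition, timepoint_h, cohort."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        rows = yaml.safe_load(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    out = {}
    for r in rows:
        out[r["sample_label"]] = AcquisitionMetadata(
            donor_id=r["donor"], condition=r["condition"],
            timepoint_h=float(r["timepoint_h"]),
            cohort=r.get("cohort", "control") or "control",
            il2=str(r.get("il2", "1")) in ("1", "True", "true"))
    return out


def analyze_donor(
    pooled_frame,
    scheme,
    manifest: dict[str, AcquisitionMetadata],
    gating_spec=None,
    cofactor: float = 5.0,
    dna_band_mads: float = 3.0,
    preprocess_overrides: dict | None = None,
    audit: FilterAudit | None = None,
) -> list[AnalyzedSample]:
    """Run one pooled donor acquisition through cleaning, debarcoding and gating.

    Returns one :class:`AnalyzedSample` per recovered time point.  This is
    the library entry point the CLI wraps; synthetic benchmarks call it
    directly on in-memory frames.
    """
    spec = gating_spec if gating_spec is not None else default_gating_spec()
    audit = audit if audit is not None else FilterAudit()

    frame = arcsinh_transform(pooled_frame, TransformSpec(cofactor=cofactor))
    thr = estimate_preprocess_thresholds(frame, k_mad=dna_band_mads)
    for key, val in (preprocess_overrides or {}).items():
        setattr(thr, key, float(val))
    n0 = frame.n_events
    frame = gate_singlets(frame, thr)
    audit.record("singlets", n0, frame.n_events)
    n1 = frame.n_events
    frame = gate_viable(frame, thr)
    audit.record("viability", n1, frame.n_events)

    result = debarcode(frame, scheme)
    audit.record("debarcode", frame.n_events,
                 int((result.assignment != UNASSIGNED).sum()))
    per_sample = split_by_sample(frame, result, manifest)

    # thresholds estimated once per donor on the pooled cleaned events
    markers = spec_markers(spec) + ["ki67", "IdU"]
    thr_gates = estimate_thresholds(frame, markers)

    samples = []
    for label in sorted(per_sample, key=lambda l: manifest[l].timepoint_h):
        sub = per_sample[label]
        membership = assign_populations(sub, spec, thr_gates)
        phases = classify_cell_cycle(sub, thr_gates)
        samples.append(AnalyzedSample(frame=sub, membership=membership, phases=phases))
    return samples


def _survival_comparisons(survival: pd.DataFrame, populations,
                          t_late: float = 24.0) -> pd.DataFrame:
    """Paired t-tests of per-donor composition, untreated vs t_late, with a
    Šídák adjustment across the compared populations."""
    rows = []
    for pop in populations:
        sub = survival[survival["population"] == pop]
        piv = sub.pivot_table(index="donor", columns="timepoint_h",
                              values="pct_of_viable_cd45")
        if 0.0 not in piv.columns or t_late not in piv.columns:
            continue
        piv = piv.dropna(subset=[0.0, t_late])
        if len(piv) < 2:
            continue
        res = students_t(piv[0.0].to_numpy(), piv[t_late].to_numpy(), paired=True)
        rows.append({"population": pop, "comparison": f"0h vs {t_late:g}h",
                     "statistic": res.statistic, "df": res.df, "p_raw": res.p_raw})
    if not rows:
        return pd.DataFrame(columns=["population", "comparison", "statistic",
                                     "df", "p_raw", "p_adjusted", "stars"])
    df = pd.DataFrame(rows)
    df["p_adjusted"] = sidak_pairs(df["p_raw"].to_numpy())
    df["stars"] = [star_code(p) for p in df["p_adjusted"]]
    return df


@dataclass
class RunReport:
    stages: list[dict]
    warnings: list[str]
    files: list[str]
    config: dict
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis over a directory of pooled donor files.

    Emits kinetics, stratified-kinetics, survival, comparison, threshold and
    yield CSVs plus a JSON run report; deterministic given config + seed.
    """
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    if not in_dir.is_dir():
        raise DataError(f"input directory {in_dir} does not exist")
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = load_manifest(config.manifest or in_dir / "manifest.csv")
    panel = load_panel(config.panel or in_dir / "panel.csv")
    spec = (gating_spec_from_yaml(Path(config.gating_spec))
            if config.gating_spec else default_gating_spec())

    donors = sorted({m.donor_id for m in manifest.values()})
    audit = FilterAudit()
    all_samples: list[AnalyzedSample] = []
    yield_tables = []
    for donor in donors:
        fcs = in_dir / f"{donor}_pooled.fcs"
        if not fcs.exists():
            raise ManifestError(f"missing pooled FCS file for donor {donor}: {fcs}")
        code_book = in_dir / f"{donor}_codebook.csv"
        if not code_book.exists():
            raise ManifestError(f"missing code book for donor {donor}: {code_book}")
        frame = read_fcs(fcs, panel=panel)
        scheme = load_code_book(code_book, separation_cutoff=config.separation_cutoff)
        donor_manifest = {l: m for l, m in manifest.items() if m.donor_id == donor}
        missing = set(scheme.keys) - set(donor_manifest)
        if missing:
            raise ManifestError(
                f"code book labels missing from manifest for donor {donor}: "
                f"{sorted(missing)}")
        donor_audit = FilterAudit()
        samples = analyze_donor(
            frame, scheme, donor_manifest, gating_spec=spec,
            cofactor=config.cofactor, dna_band_mads=config.dna_band_mads,
            preprocess_overrides=config.preprocess_overrides, audit=donor_audit)
        for row in donor_audit.rows:
            audit.record(row["stage"], row["events_in"], row["events_out"], donor=donor)
        all_samples.extend(samples)

    kinetics = fold_induction_table(all_samples, min_events=config.min_events)
    stratified = stratified_kinetics(all_samples, min_events=config.min_events)
    survival = survival_proportions(all_samples)

    comparisons = []
    for marker in sorted(kinetics["marker"].unique()):
        sub = kinetics[
            kinetics["marker"].eq(marker)
            & kinetics["population"].isin(config.stats_populations)
            & kinetics["timepoint_h"].gt(0)
        ]
        sub = sub[np.isfinite(sub["fold_induction"])]
        if sub["population"].nunique() < 2 or len(sub) < 4:
            log.warning("too few finite folds to compare populations for %s", marker)
            continue
        try:
            results = two_way_anova_tukey(sub)
        except ValidationError as exc:
            log.warning("skipping comparisons for %s: %s", marker, exc)
            continue
        for r in results:
            d = vars(r)
            d["marker"] = marker
            comparisons.append(d)
    comparisons = pd.DataFrame(comparisons)
    surv_stats = _survival_comparisons(survival, config.stats_populations)

    # estimated thresholds per donor for the audit trail
    files = []
    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        files.append(str(path))

    emit(kinetics, "kinetics.csv")
    emit(stratified, "kinetics_stratified.csv")
    emit(survival, "survival.csv")
    emit(comparisons, "comparisons_kinetics.csv")
    emit(surv_stats, "comparisons_survival.csv")
    emit(pd.DataFrame(audit.rows), "filter_audit.csv")

    report = RunReport(
        stages=audit.rows, warnings=[], files=files,
        config={
            "input_dir": str(in_dir), "output_dir": str(out_dir),
            "cofactor": config.cofactor,
            "separation_cutoff": config.separation_cutoff,
            "min_events": config.min_events,
            "dna_band_mads": config.dna_band_mads,
            "stats_populations": list(config.stats_populations),
            "seed": config.seed,
        })
    report.to_json(out_dir / "run_report.json")
    return report
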