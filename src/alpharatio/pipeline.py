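"""End-to-end orchestration: simulate → preprocess → features → compare.

Reproduces the analysis shape of a sensor- and region-level resting-state
case-control spectral study on synthetic cohorts: per-subject Welch spectra
and seven spectral features, whole-head averages, permutation group contrasts
with FDR control, post hoc correlations with pain/depression covariates, and
a lateralization index over homologous region pairs.  Every number in a
report is regenerable from the configuration and its seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohortsim import (
    CohortSpec,
    GroupTemplate,
    Recording,
    control_template,
    draw_subject_specs,
    patient_template,
    simulate_regions,
    simulate_subject,
)
from .exceptions import InvalidArgumentError, PipelineError
from .groupstats import (
    FeatureMatrix,
    GroupContrast,
    PermTestResult,
    lateralization_table,
    pearson_correlation,
)
from .preprocess import PreprocessConfig, preprocess_recording
from .spectral import (
    BandScheme,
    FEATURE_NAMES,
    WelchConfig,
    extract_features,
    filter_regions,
    sensor_average,
    welch_psd,
)

__all__ = [
    "StatsConfig",
    "AnalysisConfig",
    "AnalysisReport",
    "subject_features",
    "run_sensor_analysis",
    "run_region_analysis",
    "compare_psd_bins",
]


@dataclass
class StatsConfig:
    n_permutations: int = 10000
    level: float = 0.05
    seed: int = 0
    fdr_family: str = "joint"


@dataclass
class AnalysisConfig:
    """Aggregated configuration for a full analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    bands: BandScheme = field(default_factory=BandScheme)
    stats: StatsConfig = field(default_factory=StatsConfig)
    input_dir: str | None = None  # when set, recordings are loaded instead of simulated

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return enc(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @staticmethod
    def _template_from_dict(sub: dict, builder) -> GroupTemplate:
        from .cohortsim import AperiodicSpec, ArtifactConfig

        sub = dict(sub)
        if "covariates" in sub:
            sub["covariates"] = {k: tuple(v) for k, v in sub["covariates"].items()}
        if isinstance(sub.get("aperiodic"), dict):
            sub["aperiodic"] = AperiodicSpec(**sub["aperiodic"])
        if isinstance(sub.get("artifacts"), dict):
            sub["artifacts"] = ArtifactConfig(**sub["artifacts"])
        if "peak_options" in sub:
            sub["peak_options"] = tuple(tuple(o) for o in sub["peak_options"])
        return builder(**sub)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        cohort_d = dict(d.get("cohort", {}))
        for key, builder in (("control", control_template), ("patient", patient_template)):
            if key in cohort_d and isinstance(cohort_d[key], dict):
                cohort_d[key] = cls._template_from_dict(cohort_d[key], builder)
        cohort = CohortSpec(**cohort_d)
        pp_d = dict(d.get("preprocess", {}))
        if "bandpass" in pp_d:
            pp_d["bandpass"] = tuple(pp_d["bandpass"])
        if "ssp" in pp_d:
            from .preprocess import SSPConfig

            pp_d["ssp"] = {
                k: (SSPConfig(**v) if isinstance(v, dict) else v) for k, v in pp_d["ssp"].items()
            }
        return cls(
            cohort=cohort,
            preprocess=PreprocessConfig(**pp_d),
            welch=WelchConfig(**d.get("welch", {})),
            bands=BandScheme(**{
                **d.get("bands", {}),
                **(
                    {"bands": {k: tuple(v) for k, v in d["bands"]["bands"].items()}}
                    if "bands" in d.get("bands", {})
                    else {}
                ),
            }),
            stats=StatsConfig(**d.get("stats", {})),
            input_dir=d.get("input_dir"),
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


@dataclass
class AnalysisReport:
    """Everything one analysis level produces, with full provenance."""

    level: str  # "sensor" or "region"
    test: PermTestResult
    subject_averages: pd.DataFrame  # subject_id, group, one column per feature
    group_summary: pd.DataFrame  # feature x group mean/sd of subject averages
    correlations: pd.DataFrame
    psd_group_mean: pd.DataFrame  # frequency, per-group mean and SEM of mean PSD
    li_table: pd.DataFrame | None
    provenance: dict

    def write(self, out_dir) -> None:
        """Export the report as CSV/JSON files (created only on success)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prefix = self.level
        self.test.to_frame().to_csv(out / f"{prefix}_test.csv", index=False)
        self.subject_averages.to_csv(out / f"{prefix}_subject_averages.csv", index=False)
        self.group_summary.to_csv(out / f"{prefix}_group_summary.csv")
        self.correlations.to_csv(out / f"{prefix}_correlations.csv", index=False)
        self.psd_group_mean.to_csv(out / f"{prefix}_psd_group_mean.csv", index=False)
        if self.li_table is not None:
            self.li_table.to_csv(out / f"{prefix}_lateralization.csv", index=False)
        with open(out / f"{prefix}_provenance.json", "w") as f:
            json.dump(self.provenance, f, indent=2, default=str)


# ---------------------------------------------------------------------------
# Stage helpers


def subject_features(signals, cfg: AnalysisConfig):
    """Welch PSD + feature extraction for one subject's cleaned segments."""
    psd = welch_psd(signals, cfg.welch)
    return psd, extract_features(psd, cfg.bands)


def _group_summary(subject_averages: pd.DataFrame) -> pd.DataFrame:
    feats = [c for c in subject_averages.columns if c in FEATURE_NAMES]
    return subject_averages.groupby("group")[feats].agg(["mean", "std"]).T


def _correlation_table(subject_averages: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Post hoc Pearson correlations of the subject-average alpha power ratio
    against the covariates available in the subject table (uncorrected)."""
    merged = subject_averages.merge(table, on=["subject_id", "group"], how="left")
    rows = []
    plans = [
        ("patient", "pain_vas"),
        ("patient", "pain_duration"),
        ("patient", "depression_score"),
        ("control", "depression_score"),
    ]
    for group, cov in plans:
        if cov not in merged.columns:
            continue
        sub = merged[merged["group"] == group]
        x = sub["alpha_power_ratio"].to_numpy(dtype=float)
        y = sub[cov].to_numpy(dtype=float)
        try:
            res = pearson_correlation(x, y)
        except Exception:
            continue
        rows.append({"group": group, "covariate": cov, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows, columns=["group", "covariate", "r", "p", "n"])


def _psd_group_mean(psds, table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean ± SEM of each subject's signal-average PSD."""
    freqs = psds[0].freqs
    per_subject = np.vstack([p.power.mean(axis=0) for p in psds])
    out = {"frequency_hz": freqs}
    for group in sorted(table["group"].unique()):
        mask = (table["group"] == group).to_numpy()
        vals = per_subject[mask]
        out[f"{group}_mean"] = vals.mean(axis=0)
        out[f"{group}_sem"] = vals.std(axis=0, ddof=1) / np.sqrt(mask.sum())
    return pd.DataFrame(out)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# Analyses


def run_sensor_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Full sensor-level chain on a simulated (or loaded) cohort."""
    with _stage("simulate"):
        if cfg.input_dir:
            from .io import load_cohort

            recordings, table = load_cohort(cfg.input_dir)
        else:
            specs, table = draw_subject_specs(cfg.cohort)
            recordings = [
                simulate_subject(
                    s,
                    duration=cfg.cohort.duration,
                    sampling_rate=cfg.cohort.sampling_rate,
                    n_channels=cfg.cohort.n_channels,
                )
                for s in specs
            ]

    with _stage("preprocess"):
        cleaned, pp_logs = [], []
        for rec in recordings:
            segments, log = preprocess_recording(rec, cfg.preprocess)
            if not segments:
                raise InvalidArgumentError("no usable segments after preprocessing")
            cleaned.append(segments)
            pp_logs.append(log)

    with _stage("features"):
        psds, features, averages = [], [], []
        for segs, (_, row) in zip(cleaned, table.iterrows()):
            psd, feats = subject_features(segs, cfg)
            psds.append(psd)
            features.append(feats)
            avg = sensor_average(feats)
            averages.append({"subject_id": row["subject_id"], "group": row["group"], **avg.to_dict()})
        subject_averages = pd.DataFrame(averages)

    with _stage("compare"):
        fm = FeatureMatrix.from_features(features, table)
        model = GroupContrast(
            fm,
            n_permutations=cfg.stats.n_permutations,
            level=cfg.stats.level,
            fdr_family=cfg.stats.fdr_family,
        )
        test = model.fit(seed=cfg.stats.seed)

    with _stage("report"):
        provenance = {
            "level": "sensor",
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "package_version": __version__,
            "stats_seed": cfg.stats.seed,
            "master_seed": cfg.cohort.master_seed,
            "preprocess_logs": pp_logs,
        }
        return AnalysisReport(
            level="sensor",
            test=test,
            subject_averages=subject_averages,
            group_summary=_group_summary(subject_averages),
            correlations=_correlation_table(subject_averages, table),
            psd_group_mean=_psd_group_mean(psds, table),
            li_table=None,
            provenance=provenance,
        )


def run_region_analysis(cfg: AnalysisConfig, region_meta: pd.DataFrame | None = None) -> AnalysisReport:
    """Region-level chain: simulated region time series, region filtering,
    per-region features, group contrast, and lateralization indices."""
    with _stage("simulate"):
        specs, table = draw_subject_specs(cfg.cohort)
        region_sets = [
            simulate_regions(
                s,
                n_regions=cfg.cohort.n_regions,
                duration=cfg.cohort.duration,
                sampling_rate=cfg.cohort.sampling_rate,
                region_meta=region_meta,
            )
            for s in specs
        ]

    with _stage("filter_regions"):
        meta = region_sets[0].region_meta
        kept = filter_regions(meta)
        if len(kept) < 2:
            raise InvalidArgumentError(
                f"fewer than 2 regions remain after the >20-grid-point filter ({len(kept)})"
            )
        keep_idx = meta.index[meta["name"].isin(kept["name"])].to_numpy()
        region_sets = [
            dataclasses.replace(r, data=r.data[keep_idx], region_meta=kept.copy())
            for r in region_sets
        ]

    with _stage("features"):
        psds, features, averages = [], [], []
        for rts, (_, row) in zip(region_sets, table.iterrows()):
            psd, feats = subject_features(rts, cfg)
            psds.append(psd)
            features.append(feats)
            avg = sensor_average(feats)
            averages.append({"subject_id": row["subject_id"], "group": row["group"], **avg.to_dict()})
        subject_averages = pd.DataFrame(averages)

    with _stage("compare"):
        fm = FeatureMatrix.from_features(features, table)
        model = GroupContrast(
            fm,
            n_permutations=cfg.stats.n_permutations,
            level=cfg.stats.level,
            fdr_family=cfg.stats.fdr_family,
        )
        test = model.fit(seed=cfg.stats.seed)
        li = lateralization_table(fm)

    with _stage("report"):
        provenance = {
            "level": "region",
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "package_version": __version__,
            "stats_seed": cfg.stats.seed,
            "master_seed": cfg.cohort.master_seed,
            "n_regions_kept": len(kept),
        }
        return AnalysisReport(
            level="region",
            test=test,
            subject_averages=subject_averages,
            group_summary=_group_summary(subject_averages),
            correlations=_correlation_table(subject_averages, table),
            psd_group_mean=_psd_group_mean(psds, table),
            li_table=li,
            provenance=provenance,
        )


def compare_psd_bins(
    psds: Sequence, table: pd.DataFrame, n_permutations: int = 10000, seed: int = 0,
    level: float = 0.05,
) -> PermTestResult:
    """Optional analysis mode: group test across all frequency bins of the
    subject-average PSD (FDR over bins)."""
    freqs = psds[0].freqs
    values = np.stack([p.power.mean(axis=0)[None, :].T for p in psds])  # subjects x bins x 1
    fm = FeatureMatrix(
        values=values,
        feature_names=["psd"],
        subject_table=table.reset_index(drop=True),
        signal_meta=pd.DataFrame({"name": [f"{f:.2f}Hz" for f in freqs]}),
    )
    return GroupContrast(fm, n_permutations=n_permutations, level=level).fit(seed=seed)
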