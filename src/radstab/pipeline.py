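"""End-to-end orchestration: simulate -> fit -> extract -> stability -> staging.

`run_cohort_analysis` performs the whole analysis in memory from a single
`RunConfig` (fast path used by tests and the acceptance script);
`run_pipeline` additionally persists every intermediate artifact (NIfTI
volumes, CSV tables, JSON reports, Markdown summary) under an output
directory. Everything is reproducible from (config, master_seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import io as rio
from .features import (
    DiscretizationConfig,
    RoiMask,
    extract_features,
    feature_frame,
    select_2d_slice,
)
from .fitting import FitOptions, fit_map_set
from .quality import cnr, compare_quality, measure_roi_stats, snr
from .stability import stability_table, summarize
from .staging import staging_screen
from .synthetic import (
    DEFAULT_SIGMA,
    AfProfile,
    HeterogeneityModel,
    default_phantom_spec,
    make_cohort,
    reference_tissue_mask,
)

__all__ = ["RunConfig", "CohortAnalysis", "run_cohort_analysis", "run_pipeline",
           "perturb_mask"]


@dataclass(frozen=True)
class RunConfig:
    """Single configuration object driving the full pipeline."""

    master_seed: int = 0
    n_low: int = 12
    n_high: int = 28
    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing: tuple[float, float, float] = (3.0, 2.8, 4.4)
    lesion_radii: tuple[float, float, float] = (9.0, 9.0, 4.5)
    signal_model: str = "combined"
    heterogeneity_amplitude: float = 0.12
    stage_amp_multiplier: float = 1.6
    stage_radius_multiplier: float = 1.3
    sigma: float = DEFAULT_SIGMA
    af_profiles: dict = field(
        default_factory=lambda: {
            "S1": {"af": 1, "tr_ms": 4700.0, "t1_ms": 1500.0, "sigma_scale": 1.0},
            "S2": {"af": 2, "tr_ms": 2500.0, "t1_ms": 1500.0, "sigma_scale": 1.1},
            "S3": {"af": 3, "tr_ms": 2000.0, "t1_ms": 1500.0, "sigma_scale": 1.3},
        }
    )
    r2_threshold: float = 0.8
    refine_full_nlls: bool = True
    discretization_method: str = "fixed_bin_count"
    n_bins: int = 32
    stable_rule: str = "both"
    analysis_sequence: str = "S2"
    quality_jitter: int = 1

    def __post_init__(self):
        if self.analysis_sequence not in self.af_profiles:
            raise ValueError("analysis_sequence must name one of the AF profiles")
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("cohort sizes must be >= 1")

    # -- derived sub-configs ------------------------------------------------
    def phantom_spec(self):
        return default_phantom_spec(
            grid_shape=tuple(self.grid_shape),
            voxel_spacing=tuple(self.voxel_spacing),
            lesion_radii=tuple(self.lesion_radii),
            signal_model=self.signal_model,
            heterogeneity=HeterogeneityModel(amplitude=self.heterogeneity_amplitude),
            stage_amp_multiplier=self.stage_amp_multiplier,
            lesion_center=tuple(float(n) / 2 for n in self.grid_shape),
        )

    def af(self) -> dict[str, AfProfile]:
        return {k: AfProfile(**v) for k, v in self.af_profiles.items()}

    def fit_options(self) -> FitOptions:
        return FitOptions(r2_threshold=self.r2_threshold,
                          refine_full_nlls=self.refine_full_nlls)

    def discretization(self) -> DiscretizationConfig:
        return DiscretizationConfig(method=self.discretization_method,
                                    n_bins=self.n_bins)

    # -- (de)serialization --------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "voxel_spacing", "lesion_radii"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def perturb_mask(mask: np.ndarray, seed: int = 0) -> np.ndarray:
    """Second-reader delineation emulation: 1-voxel in-plane morphology.

    Randomly (seeded) erodes or dilates the mask by one voxel in-plane,
    standing in for the inter-observer difference between two radiologists.
    Falls back to the original mask if the perturbation empties it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    struct = np.zeros((3, 3, 1), dtype=bool)
    struct[1, :, 0] = True
    struct[:, 1, 0] = True
    if rng.random() < 0.5:
        out = ndimage.binary_erosion(mask, structure=struct)
    else:
        out = ndimage.binary_dilation(mask, structure=struct)
    return out if out.any() else mask.copy()


@dataclass
class CohortAnalysis:
    """All in-memory results of one cohort run."""

    config: RunConfig
    metadata: pd.DataFrame
    quality: pd.DataFrame
    quality_stats: dict
    features: pd.DataFrame
    features_rater_b: pd.DataFrame
    stability: pd.DataFrame
    summaries: dict
    staging: pd.DataFrame
    fit_reports: list

    @property
    def labels(self) -> pd.DataFrame:
        return self.metadata.drop_duplicates("subject_id")[["subject_id", "stage"]]


def _sub_seed(*keys) -> int:
    ss = np.random.SeedSequence([int(k) for k in keys])
    return int(np.random.default_rng(ss).integers(0, 2**31 - 1))


def run_cohort_analysis(config: RunConfig, cohort=None,
                        include_staging: bool = True,
                        artifact_sink=None) -> CohortAnalysis:
    """Run the full analysis for one seeded cohort.

    ``artifact_sink(subject_id, stage, truth, series_by_label, map_sets)`` is
    invoked per subject when persistence is wanted (see :func:`run_pipeline`).
    ``include_staging=False`` skips the second-reader extraction and staging
    screen (used by multi-seed stability studies).
    """
    spec = config.phantom_spec()
    af = config.af()
    if cohort is None:
        cohort = make_cohort(
            config.n_low, config.n_high, base_spec=spec, af_profiles=af,
            seed=config.master_seed, sigma=config.sigma,
            stage_radius_multiplier=config.stage_radius_multiplier,
        )
    fit_opts = config.fit_options()
    disc = config.discretization()
    voxel_volume = float(np.prod(config.voxel_spacing))

    quality_rows = []
    vectors = []
    vectors_b = []
    fit_reports = []
    for s_idx, (subject_id, stage, truth, series_by_label) in enumerate(cohort):
        lesion = truth.lesion_mask
        roi3 = RoiMask(mask=lesion, mode="3D")
        roi2 = select_2d_slice(lesion)
        muscle3 = reference_tissue_mask(truth)
        muscle2 = np.zeros_like(muscle3)
        muscle2[:, :, roi2.slice_index] = muscle3[:, :, roi2.slice_index]
        if not muscle2.any():  # reference tissue absent on the tumor slice
            muscle2 = muscle3

        map_sets = {}
        for q_idx, (label, series) in enumerate(sorted(series_by_label.items())):
            b800 = series.volumes[..., series.scheme.indices_of([800.0])[0]]
            jseed = _sub_seed(config.master_seed, 900, s_idx, q_idx)
            tumor_stats = measure_roi_stats(
                b800, roi2.mask, jitter=config.quality_jitter, seed=jseed,
                label="tumor")
            muscle_stats = measure_roi_stats(
                b800, muscle2, jitter=config.quality_jitter, seed=jseed + 1,
                label="muscle")
            quality_rows.append({
                "subject_id": subject_id, "stage": stage, "sequence": label,
                "snr": snr(tumor_stats), "cnr": cnr(tumor_stats, muscle_stats),
            })

            map_set = fit_map_set(series, fit_opts, mask=lesion)
            map_sets[label] = map_set
            fit_reports.append(map_set.report)
            for roi in (roi2, roi3):
                fvs = extract_features(
                    map_set, roi, disc, subject_id=subject_id, sequence=label,
                    voxel_volume=voxel_volume)
                vectors.extend(fvs.values())

        if include_staging:
            # second-reader emulation on the analysis sequence only
            pseed = _sub_seed(config.master_seed, 901, s_idx)
            mask_b = perturb_mask(lesion, seed=pseed)
            ms = map_sets[config.analysis_sequence]
            for roi_b in (select_2d_slice(mask_b), RoiMask(mask=mask_b, mode="3D")):
                fvs = extract_features(
                    ms, roi_b, disc, subject_id=subject_id,
                    sequence=config.analysis_sequence, voxel_volume=voxel_volume)
                vectors_b.extend(fvs.values())

        if artifact_sink is not None:
            artifact_sink(subject_id, stage, truth, series_by_label, map_sets)

    quality = pd.DataFrame(quality_rows)
    quality_stats = {
        metric: compare_quality(quality, metric=metric) for metric in ("snr", "cnr")
    }
    features = feature_frame(vectors)
    features_b = feature_frame(vectors_b)

    stability = stability_table(features, stable_rule=config.stable_rule)
    summaries = summarize(stability)

    seq = config.analysis_sequence
    if include_staging:
        staging = staging_screen(
            features[features["sequence"] == seq],
            stability,
            features_b[features_b["sequence"] == seq],
            cohort.metadata.drop_duplicates("subject_id")[["subject_id", "stage"]],
        )
    else:
        staging = pd.DataFrame()
    return CohortAnalysis(
        config=config,
        metadata=cohort.metadata,
        quality=quality,
        quality_stats=quality_stats,
        features=features,
        features_rater_b=features_b,
        stability=stability,
        summaries=summaries,
        staging=staging,
        fit_reports=fit_reports,
    )


def _summary_markdown(result: CohortAnalysis) -> str:
    c = result.config
    lines = [
        "# Cohort analysis summary",
        "",
        f"Subjects: {c.n_low} low-stage + {c.n_high} high-stage "
        f"(master seed {c.master_seed})",
        "",
        "## Image quality (b = 800 volume)",
    ]
    for metric in ("snr", "cnr"):
        st = result.quality_stats[metric]
        mean = result.quality.groupby("sequence")[metric].mean()
        lines.append(
            f"- {metric.upper()}: "
            + ", ".join(f"{s} = {mean[s]:.2f}" for s in ("S1", "S2", "S3"))
            + f"; Friedman p = {st['friedman_p']:.3g}; adjusted pairwise p: "
            + ", ".join(
                f"{a}-{b} = {v['p_adjusted']:.3g}"
                for (a, b), v in st["pairwise"].items()
            )
        )
    lines += ["", "## Stable features (CCC > 0.9 and COV <= 0.1)"]
    sp = result.summaries["stable_proportions"]
    for _, row in sp.iterrows():
        lines.append(
            f"- {row['map']} ({row['roi_mode']}): "
            f"{100 * row['stable_proportion']:.1f}% of {row['n_features']}"
        )
    n_sel = int(result.staging["selected"].sum()) if len(result.staging) else 0
    lines += [
        "",
        "## Staging screen",
        f"- Analysis sequence: {c.analysis_sequence}",
        f"- Stable features screened: {len(result.staging)}",
        f"- Selected (p < 0.05, ICC > 0.75): {n_sel}",
        "- Note: no multiple-testing correction is applied to the per-feature "
        "p-values.",
    ]
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, out_dir, persist_volumes: bool = True) -> CohortAnalysis:
    """Execute all stages and persist every intermediate under ``out_dir``.

    Artifacts: per-subject DWI series/masks/maps (NIfTI + TSV b-tables, when
    ``persist_volumes``), quality/feature/stability/staging CSVs, JSON stats
    reports and a Markdown summary.
    """
    out = Path(out_dir)
    spacing = tuple(config.voxel_spacing)
    for sub in ("cohort", "maps", "features", "quality", "stability", "staging"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    def sink(subject_id, stage, truth, series_by_label, map_sets):
        if not persist_volumes:
            return
        sdir = out / "cohort" / subject_id
        sdir.mkdir(exist_ok=True)
        rio.write_mask(sdir / "lesion_mask.nii.gz", truth.lesion_mask, spacing)
        for name, fld in truth.param_fields.items():
            rio.write_volume(sdir / f"truth_{name}.nii.gz", fld, spacing)
        for label, series in series_by_label.items():
            rio.write_series(sdir / label, series, spacing)
        mdir = out / "maps" / subject_id
        mdir.mkdir(exist_ok=True)
        for label, ms in map_sets.items():
            rio.write_map_set(mdir / label, ms, spacing)

    result = run_cohort_analysis(config, artifact_sink=sink)

    metadata = result.metadata.copy()
    metadata["path"] = [
        str(Path("cohort") / row.subject_id / f"{row.sequence}_dwi.nii.gz")
        for row in metadata.itertuples()
    ]
    metadata.to_csv(out / "cohort" / "metadata.csv", index=False)
    result.quality.to_csv(out / "quality" / "quality.csv", index=False)

    def _stats_jsonable(stats):
        return {
            m: {
                **{k: v for k, v in st.items() if k != "pairwise"},
                "pairwise": {f"{a}-{b}": v for (a, b), v in st["pairwise"].items()},
            }
            for m, st in stats.items()
        }

    (out / "quality" / "quality_stats.json").write_text(
        json.dumps(_stats_jsonable(result.quality_stats), indent=1)
    )
    from .features import FAMILY_COUNTS, feature_manifest

    (out / "features" / "manifest.json").write_text(json.dumps({
        "n_features_per_map": 93,
        "family_counts": FAMILY_COUNTS,
        "feature_ids": list(feature_manifest()),
    }, indent=1))
    result.features.to_csv(out / "features" / "features.csv", index=False)
    result.features_rater_b.to_csv(
        out / "features" / "features_rater_b.csv", index=False
    )
    result.stability.to_csv(out / "stability" / "records.csv", index=False)
    for name, df in result.summaries.items():
        df.to_csv(out / "stability" / f"{name}.csv", index=False)
    result.staging.to_csv(out / "staging" / "records.csv", index=False)
    with open(out / "fit_reports.json", "w") as fh:
        json.dump(result.fit_reports, fh, indent=1)
    (out / "summary.md").write_text(_summary_markdown(result))
    return result
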