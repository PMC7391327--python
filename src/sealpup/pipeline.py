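"""End-to-end orchestration: census in, survival statistics and MPMs out.

The pipeline chains every stage of the analysis — read/correct the census,
weighted aggregation and trend tests, hierarchical variance partitioning,
leave-one-site-out sensitivity, bootstrap sample-size curves, matrix-model
construction and stochastic projection — and emits a machine-readable
summary plus tidy tables. Every stochastic stage consumes a substream
derived from the one root seed, so a fixed seed reproduces the whole run
byte-for-byte and any single stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import aggregate, data, mpm, projection, resampling, synthetic, varpart

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = (
    "aggregate",
    "partition",
    "sensitivity",
    "samplesize",
    "mpm",
    "project",
)


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the config-file schema."""

    input_path: str | None = None          # census CSV; None -> synthetic
    delimiter: str = ","
    correct: bool = True                   # apply the count correction
    synthetic: synthetic.SyntheticConfig | None = None
    weight_field: str = "n_pups"
    k_extreme: int = 10                    # worst/best group size
    min_overlap: int = 5                   # years shared for a Pearson pair
    n_min: int = 5
    n_max: int = 50
    boot_reps: int = 1000
    tolerance: float = 0.10
    threshold: float = 0.80
    structure: str = "age_structured_6plus"
    demography: mpm.DemographyParams = field(default_factory=mpm.DemographyParams)
    proj_years: int = 20
    proj_reps: int = 1000
    growth_horizon: int = 1000
    growth_burn_in: int = 50
    growth_reps: int = 100
    seed: int = 0
    outdir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            areas = tuple(
                synthetic.AreaSpec(**a) if isinstance(a, dict) else a
                for a in syn.pop("areas", ())
            )
            if areas:
                d["synthetic"] = synthetic.SyntheticConfig(areas=areas, **syn)
            else:
                d["synthetic"] = synthetic.pembrokeshire_design(**syn)
        if "demography" in d and isinstance(d["demography"], dict):
            d["demography"] = mpm.DemographyParams(**d["demography"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(d)


def _sub_seed(root: int, key: int) -> int:
    """Deterministic 31-bit substream seed for stage ``key``."""
    return int(np.random.SeedSequence(root, spawn_key=(key,)).generate_state(1)[0] % (2**31))


def _load_dataset(config: PipelineConfig) -> data.SurvivalDataset:
    if config.input_path is not None:
        return data.read_census_table(
            config.input_path, delimiter=config.delimiter, correct=config.correct
        )
    syn = config.synthetic or synthetic.pembrokeshire_design(
        seed=_sub_seed(config.seed, 0)
    )
    return synthetic.generate(syn)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the requested stages and return the summary dictionary.

    If ``config.outdir`` is set, tidy per-stage tables and a
    ``summary.json`` are written there. Stages not requested are absent
    from the summary.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    dataset = _load_dataset(config)
    if not dataset.records:
        raise ValueError("no census records to analyse")
    summary: dict[str, Any] = {
        "seed": config.seed,
        "n_records": len(dataset),
        "n_sites": len(dataset.sites),
        "n_areas": len(dataset.areas),
    }
    if outdir:
        data.write_census_table(dataset, outdir / "census_corrected.csv")

    overall = aggregate.overall_mean_survival(dataset, config.weight_field)
    s_late = mpm.estimate_late_survival(config.demography.s01_ref, overall)
    params = dataclasses.replace(config.demography, s_late=s_late)
    summary["overall_mean_survival"] = overall
    summary["s_late"] = s_late

    if "aggregate" in config.stages:
        series = aggregate.area_year_series(dataset, config.weight_field)
        summary["area_mean_survival"] = {
            a: aggregate.overall_mean_survival(dataset.for_area(a), config.weight_field)
            for a in dataset.areas
        }
        trends = {}
        for a in dataset.areas:
            pts = [s for s in series if s.area_id == a]
            if len(pts) >= 3:
                fit = aggregate.trend_test(pts)
                trends[a] = {
                    "slope": fit.slope, "F": fit.F, "df1": fit.df1,
                    "df2": fit.df2, "p_value": fit.p_value, "r2": fit.r2,
                }
        summary["trend"] = trends
        corr = aggregate.pairwise_site_correlations(dataset, config.min_overlap)
        summary["correlations"] = {
            "mean_r": corr.mean_r, "sem_r": corr.sem_r, "mean_p": corr.mean_p,
            "n_pairs": corr.n_pairs,
        }
        if outdir:
            aggregate.series_frame(series).to_csv(
                outdir / "area_year_series.csv", index=False
            )

    if "partition" in config.stages:
        part = varpart.hierarchical_partition(dataset)
        summary["variance_partition"] = {
            "percent": dict(sorted(part.percent.items())),
            "independent": dict(sorted(part.independent.items())),
            "r2_full": part.r2_full,
        }

    if "sensitivity" in config.stages:
        subset = data.subset_years_all_areas(dataset)
        sens = resampling.loo_site_sensitivity(subset, config.weight_field)
        deltas = [s.delta for s in sens]
        models = resampling.sensitivity_models(sens)
        summary["sensitivity"] = {
            "n_sites": len(sens),
            "min_delta": min(deltas),
            "max_delta": max(deltas),
            "models": {
                name: {"F": m.F, "df1": m.df1, "df2": m.df2, "p_value": m.p_value}
                for name, m in sorted(models.items())
            },
        }
        if outdir:
            import pandas as pd

            pd.DataFrame(
                {
                    "site": [s.site_id for s in sens],
                    "area": [s.area_id for s in sens],
                    "delta": deltas,
                    "mean_pups": [s.mean_pups for s in sens],
                }
            ).to_csv(outdir / "site_sensitivity.csv", index=False)

    if "samplesize" in config.stages:
        n_range = range(config.n_min, config.n_max + 1)
        scopes = [("pooled", dataset)] + [
            (a, dataset.for_area(a)) for a in dataset.areas
        ]
        boot_seed = _sub_seed(config.seed, 1)
        curves = []
        req = {}
        for key, (scope, ds) in enumerate(scopes):
            curve = resampling.sample_size_curve(
                ds, n_range=n_range, reps=config.boot_reps,
                tolerance=config.tolerance, seed=boot_seed,
                scope=scope, scope_key=key,
            )
            curves.append(curve)
            req[scope] = resampling.required_n(curve, config.threshold)
        summary["required_n"] = req
        if outdir:
            import pandas as pd

            rows = [
                {"scope": c.scope, "n": n, "proportion": p}
                for c in curves
                for n, p in zip(c.n_values, c.proportion_within)
            ]
            pd.DataFrame(rows).to_csv(outdir / "sample_size_curves.csv", index=False)

    sets = None
    if "mpm" in config.stages or "project" in config.stages:
        sets = mpm.build_matrix_sets(
            dataset, params, config.structure, config.k_extreme, config.weight_field
        )

    if "mpm" in config.stages:
        lam_sites = {m.label: mpm.growth_rate(m) for m in sets["per_site"].matrices}
        summary["lambda_areas"] = {
            m.label: mpm.growth_rate(m) for m in sets["per_area"].matrices
        }
        summary["lambda_sites"] = {
            "min": min(lam_sites.values()),
            "max": max(lam_sites.values()),
        }
        summary["lambda_extremes"] = {
            m.label: mpm.growth_rate(m) for m in sets["worst_best_pooled"].matrices
        }
        if outdir:
            import pandas as pd

            pd.DataFrame(
                {"site": list(lam_sites), "lambda": list(lam_sites.values())}
            ).to_csv(outdir / "lambda_per_site.csv", index=False)
            _export_matrix_sets(sets, outdir / "matrices")

    if "project" in config.stages:
        n0 = projection.default_initial_vector(config.structure)
        proj_seed = _sub_seed(config.seed, 2)
        log_ls = {}
        for idx, which in enumerate(("worst_site_years", "best_site_years")):
            res = projection.stochastic_project(
                sets[which], n0, years=config.proj_years, reps=config.proj_reps,
                seed=proj_seed + idx, compute_growth=False,
            )
            log_ls[which] = projection.stochastic_growth_rate(
                sets[which], n0, horizon=config.growth_horizon,
                burn_in=config.growth_burn_in, reps=config.growth_reps,
                seed=proj_seed + idx,
            )
            if outdir:
                import pandas as pd

                q = np.percentile(res.total_size, [2.5, 50, 97.5], axis=0)
                pd.DataFrame(
                    {
                        "year": np.arange(config.proj_years + 1),
                        "median": q[1],
                        "lo2.5": q[0],
                        "hi97.5": q[2],
                    }
                ).to_csv(outdir / f"projection_{which}.csv", index=False)
        summary["log_lambda_s"] = {
            "worst": log_ls["worst_site_years"],
            "best": log_ls["best_site_years"],
        }

    if outdir:
        (outdir / "summary.json").write_text(summary_json(summary))
    return summary


def summary_json(summary: dict[str, Any]) -> str:
    """Canonical JSON serialisation (sorted keys; byte-stable given a seed)."""
    return json.dumps(summary, sort_keys=True, indent=2) + "\n"


def _export_matrix_sets(sets: dict[str, mpm.MatrixSet], root: Path) -> None:
    """Write each matrix as delimited text with a metadata header comment."""
    manifest = {}
    for name, mset in sets.items():
        d = root / name
        d.mkdir(parents=True, exist_ok=True)
        files = []
        for i, m in enumerate(mset.matrices):
            fname = f"{i:03d}_{m.label.replace(':', '_').replace('/', '_')}.csv"
            header = f"# label={m.label} s_e={m.s_e:.6f} structure={m.structure}\n"
            body = "\n".join(",".join(f"{v:.10g}" for v in row) for row in m.matrix)
            (d / fname).write_text(header + body + "\n")
            files.append(fname)
        manifest[name] = files
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
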