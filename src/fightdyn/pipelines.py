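"""End-to-end pipeline comparison.

Thirteen analysis pipelines are compared on one capture dataset: the
summary-metrics route (z-scored fight metrics -> PCA) and twelve DTW routes
({raw, high-pass, first-derivative} x {X, Y, Z, XYZ} -> dissimilarity matrix
-> PCoA).  Every pipeline then goes through Ward clustering with
gap-statistic k selection and the Bayesian physiology linkage, and is scored
by K-fold IC (ranking criterion; lower is better), Bayesian R^2 and the
cumulative variance of the three retained dimensions (reported, never used
for ranking).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dtw import pairwise_dissimilarity
from .errors import FightDynError
from .io import CaptureDataset, get_logger, write_matrix
from .linkage import (
    bayes_r2,
    build_design,
    envfit_vectors,
    fit_linkage,
    kfold_ic,
    marginal_effects,
)
from .metrics import BURST_THRESHOLD, metrics_matrix
from .ordination import gap_statistic, pca, pcoa, ward_cluster

logger = get_logger()


@dataclass(frozen=True)
class PipelineSpec:
    """One of the 13 analysis routes."""

    name: str
    ordination: str  # "pca" | "pcoa"
    variant: Optional[str] = None  # None for the summary pipeline
    channels: Optional[str] = None
    include_duration: bool = False


_VARIANT_PREFIX = {"raw": "raw", "highpass": "hp", "derivative": "d1"}


def pipeline_specs() -> list[PipelineSpec]:
    """The 13 enumerable pipelines; fight duration enters only the summary one."""
    specs = [PipelineSpec(name="summary", ordination="pca", include_duration=True)]
    for variant, prefix in _VARIANT_PREFIX.items():
        for channels in ("X", "Y", "Z", "XYZ"):
            specs.append(
                PipelineSpec(
                    name=f"{prefix}_{channels}",
                    ordination="pcoa",
                    variant=variant,
                    channels=channels,
                )
            )
    return specs


@dataclass
class RunConfig:
    """Effort and threshold settings for a comparison run.

    The default is the reduced-effort mode (fast, suitable for tests and
    exploratory runs); :meth:`paper` returns the full-effort settings
    (4 chains-worth of draws, 3000 warm-up steps, 100 gap bootstraps, 999
    permutations).
    """

    burst_threshold: float = BURST_THRESHOLD
    min_run: int = 1
    kmax: int = 6
    folds: int = 10
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    gap_B: int = 50
    permutations: int = 199
    normalized_dtw: bool = False
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def paper(cls, **overrides) -> "RunConfig":
        cfg = cls(chains=4, warmup=3000, draws=1000, gap_B=100, permutations=999)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class ComparisonRow:
    """One pipeline's scorecard."""

    method: str
    cumulative_variance_pct: float = float("nan")
    kfold_ic: float = float("nan")
    bayes_r2: float = float("nan")
    significant_dims: str = ""
    significant_covariates: str = ""
    chosen_k: Optional[int] = None
    failed: bool = field(default=False, repr=False)


def _sub_seed(master: int, name: str, salt: str) -> int:
    """Deterministic per-pipeline sub-seed; adding pipelines shifts nothing."""
    return (int(master) ^ zlib.crc32(f"{name}/{salt}".encode())) % (2**31 - 1)


def run_pipeline(
    dataset: CaptureDataset, spec: PipelineSpec, config: Optional[RunConfig] = None
) -> ComparisonRow:
    """Run one pipeline end to end; artifacts land under config.outdir if set."""
    config = config or RunConfig()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if spec.ordination == "pca":
        mm = metrics_matrix(dataset, config.burst_threshold, config.min_run)
        ordn = pca(mm)
        if outdir:
            mm.to_csv(outdir / "metrics_zscored.csv")
    else:
        dm = pairwise_dissimilarity(
            dataset, spec.variant, spec.channels, normalized=config.normalized_dtw
        )
        ordn = pcoa(dm)
        if outdir:
            write_matrix(dm, outdir / f"dissimilarity_{spec.name}.csv")

    n = len(ordn.ids)
    k_max = max(1, min(config.kmax, n - 1))
    profile = gap_statistic(
        ordn.scores, k_max, B=config.gap_B, seed=_sub_seed(config.seed, spec.name, "gap")
    )
    clusters = ward_cluster(ordn.scores, profile.chosen_k)

    design = build_design(dataset, ordn, include_duration=spec.include_duration)
    fit = fit_linkage(
        design,
        chains=config.chains,
        warmup=config.warmup,
        draws=config.draws,
        seed=_sub_seed(config.seed, spec.name, "fit"),
    )
    ic, fold_assignment = kfold_ic(
        design,
        folds=min(config.folds, design.n),
        seed=_sub_seed(config.seed, spec.name, "kfold"),
        chains=config.chains,
        warmup=config.warmup,
        draws=config.draws,
    )
    r2 = bayes_r2(fit)
    variables = {
        "blood_ph": np.array([dataset.records[f].blood_ph for f in ordn.ids]),
        "lactate": np.array([dataset.records[f].lactate for f in ordn.ids]),
    }
    vectors = envfit_vectors(
        ordn,
        variables,
        permutations=config.permutations,
        seed=_sub_seed(config.seed, spec.name, "envfit"),
    )

    if outdir:
        scores = ordn.scores_frame()
        for i, v in enumerate(ordn.variance_explained):
            scores.attrs[f"variance_Dim{i + 1}"] = float(v)
        scores.to_csv(outdir / f"ordination_scores_{spec.name}.csv")
        pd.DataFrame(
            {
                "k": profile.k_values,
                "log_w": profile.log_w,
                "gap": profile.gap,
                "se": profile.se,
            }
        ).to_csv(outdir / f"gap_profile_{spec.name}.csv", index=False)
        pd.DataFrame(
            {"fish_id": clusters.ids, "cluster": clusters.labels_at_k}
        ).to_csv(outdir / f"clusters_{spec.name}.csv", index=False)
        model_summary = {
            "pipeline": spec.name,
            "coefficients": fit.summary.reset_index().to_dict(orient="records"),
            "residual_correlation": dict(
                zip(("median", "ci_2.5", "ci_97.5"), fit.rho_summary)
            ),
            "kfold_ic": ic,
            "fold_assignment": fold_assignment.tolist(),
            "bayes_r2": r2,
            "significant_dims": fit.significant_dims,
            "significant_covariates": fit.significant_covariates,
            "envfit": {
                name: {
                    "direction": vf.direction.tolist(),
                    "r2": vf.r2,
                    "p_value": vf.p_value,
                }
                for name, vf in vectors.items()
            },
            "chosen_k": profile.chosen_k,
            "notes": {
                "response_normalization": "rank-based inverse normal, offset 0.5",
                "dtw_distance": "normalized" if config.normalized_dtw else "unnormalized",
                "pcoa_negative_eigenvalues": "dropped, no correction",
                "bayes_r2_aggregation": "mean of the two responses' posterior medians",
            },
        }
        with open(outdir / f"model_summary_{spec.name}.json", "w") as fh:
            json.dump(model_summary, fh, indent=2)
        credible = {s.split(":")[0] for s in fit.significant_dims + fit.significant_covariates}
        for predictor in sorted(credible):
            marginal_effects(fit, predictor).to_csv(
                outdir / f"marginal_effects_{spec.name}_{predictor}.csv", index=False
            )

    dims = sorted({s.split(":")[0] for s in fit.significant_dims})
    covs = sorted({s.split(":")[0] for s in fit.significant_covariates})
    return ComparisonRow(
        method=spec.name,
        cumulative_variance_pct=100.0 * ordn.cumulative_variance_dim1_3,
        kfold_ic=float(ic),
        bayes_r2=r2["mean"],
        significant_dims=",".join(dims) or "None",
        significant_covariates=",".join(covs) or "None",
        chosen_k=profile.chosen_k,
    )


def compare_all(
    dataset: CaptureDataset, config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Run all 13 pipelines and return the comparison table.

    Rows are sorted ascending by K-fold IC (the ranking criterion); a failed
    pipeline keeps its row, marked with NaN scores, and never disturbs the
    others.  Raises only if every pipeline fails.
    """
    config = config or RunConfig()
    rows = []
    for spec in pipeline_specs():
        try:
            rows.append(run_pipeline(dataset, spec, config))
        except FightDynError as exc:
            logger.warning("pipeline %s failed: %s", spec.name, exc)
            rows.append(ComparisonRow(method=spec.name, failed=True))
    if all(r.failed for r in rows):
        raise FightDynError("all pipelines failed")
    table = pd.DataFrame(
        [
            {
                "method": r.method,
                "cumulative_variance_pct": r.cumulative_variance_pct,
                "kfold_ic": r.kfold_ic,
                "bayes_r2": r.bayes_r2,
                "significant_dims": r.significant_dims if not r.failed else "failed",
                "significant_covariates": r.significant_covariates if not r.failed else "failed",
                "chosen_k": r.chosen_k,
            }
            for r in rows
        ]
    )
    table = table.sort_values(
        "kfold_ic", ascending=True, na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    if config.outdir:
        table.to_csv(Path(config.outdir) / "comparison_table.csv", index=False)
    return table
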