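"""Bayesian linkage of fight signatures to post-capture physiology.

The model is a bivariate Gaussian regression with identity links:

    y_i = (pH_i, lactate_i) = beta_o + beta_dim D_i + beta_cov X_i + eps_i

where the responses are rank-normalized blood pH and plasma lactate, D_i are
the three retained ordination scores, X_i the covariates (species indicator,
z-scored body mass and water temperature, plus z-scored fight duration for
the summary-metrics pipeline only) and eps_i is bivariate normal with
estimated residual SDs and residual correlation rho.  Priors are weakly
informative on the standardized scale: coefficients N(0, 5), residual SDs
half-Student-t(3, 0, 2.5), rho uniform on (-1, 1).

The posterior is sampled with an affine-invariant ensemble sampler (emcee);
walkers play the role of chains for split-R-hat / effective-sample-size
diagnostics.  Out-of-sample performance is scored by a 10-fold
cross-validation information criterion (-2 x held-out expected log predictive
density; lower is better) and in-sample fit by Bayesian R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import emcee
import numpy as np
import pandas as pd

from .errors import (
    CollinearityError,
    ConvergenceWarning,
    DegenerateColumnError,
    FitError,
    ParameterError,
    SizeError,
    ValidationError,
)
from .io import CaptureDataset
from .metrics import metrics_table
from .ordination import OrdinationResult
from .preprocess import NormalizationMap, normalize_response, zscore

RESPONSES = ("blood_ph", "lactate")
CORRELOGRAM_VARIABLES = [
    "n_bursts",
    "fight_duration",
    "mean_actvsum",
    "total_effort",
    "water_temp",
    "fork_length",
    "lactate",
    "blood_ph",
]


@dataclass
class LinkageDesign:
    """Complete-case design: normalized responses and standardized predictors."""

    ids: list[str]
    Y: np.ndarray  # n x 2, columns (blood_ph, lactate), rank-normalized
    X: np.ndarray  # n x p predictors, no intercept column
    predictor_names: list[str]
    response_names: tuple[str, str]
    maps: dict[str, NormalizationMap]
    include_duration: bool

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "LinkageDesign":
        return LinkageDesign(
            ids=[self.ids[i] for i in rows],
            Y=self.Y[rows],
            X=self.X[rows],
            predictor_names=self.predictor_names,
            response_names=self.response_names,
            maps=self.maps,
            include_duration=self.include_duration,
        )


@dataclass
class LinkageFit:
    """Posterior summaries and diagnostics for one pipeline's linkage model."""

    design: LinkageDesign
    summary: pd.DataFrame  # per-parameter mean/median/sd/ci/rhat/ess_ratio
    beta_draws: np.ndarray  # S x (p+1) x 2
    sigma_draws: np.ndarray  # S x 2
    rho_draws: np.ndarray  # S
    significant_dims: list[str] = field(default_factory=list)
    significant_covariates: list[str] = field(default_factory=list)
    convergence_ok: bool = True
    seed: Optional[int] = None

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    @property
    def rho_summary(self) -> tuple[float, float, float]:
        lo, hi = np.percentile(self.rho_draws, [2.5, 97.5])
        return float(np.median(self.rho_draws)), float(lo), float(hi)


@dataclass
class VectorFit:
    """One variable fitted onto the ordination: direction, r2, permutation p."""

    variable: str
    direction: np.ndarray
    r2: float
    p_value: float


def build_design(
    dataset: CaptureDataset,
    ordination: OrdinationResult,
    include_duration: bool = False,
) -> LinkageDesign:
    """Assemble responses and predictors for the linkage model.

    Responses are rank-normalized; continuous covariates z-scored; species is
    a 0/1 indicator with chinook as reference.  The fight-duration covariate
    is present only for the summary-metrics pipeline.
    """
    ids = list(ordination.ids)
    missing = [fid for fid in ids if fid not in dataset.records]
    if missing:
        raise ValidationError(f"no record for fish: {missing}")
    recs = [dataset.records[fid] for fid in ids]
    incomplete = [
        r.fish_id
        for r in recs
        if r.blood_ph is None
        or r.lactate is None
        or r.body_mass is None
        or r.water_temp is None
        or (include_duration and r.fight_duration is None)
    ]
    if incomplete:
        raise ValidationError(f"incomplete physiology/covariates for fish: {incomplete}")

    ph_z, ph_map = normalize_response([r.blood_ph for r in recs])
    lac_z, lac_map = normalize_response([r.lactate for r in recs])
    Y = np.column_stack([ph_z, lac_z])

    k = ordination.scores.shape[1]
    cols = [ordination.scores[:, i] for i in range(k)]
    names = [f"Dim{i + 1}" for i in range(k)]
    cols.append(np.array([1.0 if r.species == "coho" else 0.0 for r in recs]))
    names.append("species_coho")
    cols.append(zscore([r.body_mass for r in recs]))
    names.append("body_mass")
    cols.append(zscore([r.water_temp for r in recs]))
    names.append("water_temp")
    if include_duration:
        cols.append(zscore([r.fight_duration for r in recs]))
        names.append("fight_duration")
    X = np.column_stack(cols)

    full = np.column_stack([np.ones(len(ids)), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise CollinearityError(
            f"design matrix rank deficient; columns: {['intercept'] + names}"
        )
    return LinkageDesign(
        ids=ids,
        Y=Y,
        X=X,
        predictor_names=names,
        response_names=RESPONSES,
        maps={"blood_ph": ph_map, "lactate": lac_map},
        include_duration=include_duration,
    )


# --- posterior ---------------------------------------------------------------

_COEF_SD = 5.0  # prior SD of intercepts and coefficients
_SIGMA_DF = 3.0  # half-Student-t prior on residual SDs
_SIGMA_SCALE = 2.5


def _log_posterior(theta: np.ndarray, Xf: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized log posterior over walkers; theta is (W, ndim).

    Parameterization: vec(B) row-major ((p+1) x 2), then log sigma_1,
    log sigma_2, atanh(rho); Jacobians for the transformed scales included.
    """
    W = theta.shape[0]
    n, q = Xf.shape
    # hard support bounds so runaway walkers return -inf instead of NaN
    ok = (
        np.all(np.abs(theta[:, : 2 * q]) < 1e6, axis=1)
        & np.all(np.abs(theta[:, 2 * q : 2 * q + 2]) < 15, axis=1)
        & (np.abs(theta[:, 2 * q + 2]) < 15)
    )
    theta = np.where(ok[:, None], theta, 0.0)
    B = theta[:, : 2 * q].reshape(W, q, 2)
    ls = theta[:, 2 * q : 2 * q + 2]
    zr = theta[:, 2 * q + 2]
    s = np.exp(ls)
    rho = np.tanh(zr)
    one_m_r2 = 1.0 - rho**2

    mu = np.einsum("ij,wjk->wik", Xf, B)
    E = Y[None, :, :] - mu
    e1, e2 = E[:, :, 0], E[:, :, 1]
    quad = (
        (e1 / s[:, None, 0]) ** 2
        - 2 * rho[:, None] * e1 * e2 / (s[:, None, 0] * s[:, None, 1])
        + (e2 / s[:, None, 1]) ** 2
    ).sum(axis=1) / one_m_r2
    loglik = (
        -n * np.log(2 * np.pi)
        - n * (ls[:, 0] + ls[:, 1] + 0.5 * np.log(one_m_r2))
        - 0.5 * quad
    )
    lp = -0.5 * np.sum(B**2, axis=(1, 2)) / _COEF_SD**2
    # half-t on sigma, plus log-sigma Jacobian
    lp += np.sum(
        -(_SIGMA_DF + 1) / 2 * np.log1p((s / _SIGMA_SCALE) ** 2 / _SIGMA_DF) + ls,
        axis=1,
    )
    # uniform rho, with d rho / d z = 1 - rho^2 Jacobian
    lp += np.log(one_m_r2)
    return np.where(ok, loglik + lp, -np.inf)


def fit_linkage(
    design: LinkageDesign,
    chains: int = 4,
    warmup: int = 3000,
    draws: int = 1000,
    seed: Optional[int] = None,
) -> LinkageFit:
    """Sample the bivariate Gaussian regression posterior.

    ``warmup`` ensemble steps are discarded and ``draws`` steps retained; the
    ensemble uses at least 2 x ndim + 2 walkers (and at least ``chains``),
    each walker acting as a chain for split-R-hat and effective-sample-size
    diagnostics.  An R-hat above 1.05 attaches a non-fatal convergence
    warning.  Fully reproducible under a fixed seed.
    """
    n, p = design.n, design.p
    q = p + 1
    Xf = np.column_stack([np.ones(n), design.X])
    Y = design.Y
    ndim = 2 * q + 3
    nwalkers = max(2 * ndim + 2, chains)
    nwalkers += nwalkers % 2

    rng = np.random.default_rng(seed)
    # initialize near the least-squares solution for fast burn-in
    B0, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    resid = Y - Xf @ B0
    s0 = np.maximum(resid.std(axis=0, ddof=min(q, n - 1)), 0.05)
    r0 = 0.0
    if n > q + 2:
        c = np.corrcoef(resid.T)[0, 1]
        if np.isfinite(c):
            r0 = np.clip(c, -0.9, 0.9)
    center = np.concatenate([B0.ravel(), np.log(s0), [np.arctanh(r0)]])
    p0 = center[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))

    # differential-evolution moves mix far better than the stretch move in
    # this ~20-dimensional posterior
    sampler = emcee.EnsembleSampler(
        nwalkers,
        ndim,
        _log_posterior,
        args=(Xf, Y),
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    try:
        sampler.run_mcmc(p0, warmup + draws, progress=False, skip_initial_state_check=True)
    except Exception as exc:  # pragma: no cover - sampler failure is exceptional
        raise FitError(f"posterior sampling failed: {exc}") from exc

    chain = sampler.get_chain(discard=warmup)  # (draws, nwalkers, ndim)
    flat = chain.reshape(-1, ndim)
    S = flat.shape[0]
    B = flat[:, : 2 * q].reshape(S, q, 2)
    sigma = np.exp(flat[:, 2 * q : 2 * q + 2])
    rho = np.tanh(flat[:, 2 * q + 2])

    names = ["intercept"] + design.predictor_names
    rows = []
    nat = np.concatenate(
        [flat[:, : 2 * q], sigma, np.tanh(flat[:, 2 * q + 2])[:, None]], axis=1
    )
    nat_names = (
        [f"{nm}:{rs}" for nm in names for rs in design.response_names]
        + ["sigma_blood_ph", "sigma_lactate"]
        + ["residual_cor"]
    )
    per_chain = np.swapaxes(chain, 0, 1)  # (nwalkers, draws, ndim)
    for idx, pname in enumerate(nat_names):
        if idx < 2 * q:
            samples = per_chain[:, :, idx]
        elif idx < 2 * q + 2:
            samples = np.exp(per_chain[:, :, idx])
        else:
            samples = np.tanh(per_chain[:, :, 2 * q + 2])
        col = samples.reshape(-1)
        lo, hi = np.percentile(col, [2.5, 97.5])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(samples))  # (chain, draw) = (walker, step)
            ess = float(az.ess(samples))
        rows.append(
            {
                "parameter": pname,
                "mean": float(col.mean()),
                "median": float(np.median(col)),
                "sd": float(col.std(ddof=1)),
                "ci_2.5": float(lo),
                "ci_97.5": float(hi),
                "rhat": rhat,
                "ess_ratio": ess / col.size,
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")

    fit = LinkageFit(
        design=design,
        summary=summary,
        beta_draws=B,
        sigma_draws=sigma,
        rho_draws=rho,
        seed=seed,
    )
    for pname in summary.index:
        base = pname.split(":")[0]
        lo, hi = summary.loc[pname, "ci_2.5"], summary.loc[pname, "ci_97.5"]
        if lo > 0 or hi < 0:
            if base.startswith("Dim"):
                fit.significant_dims.append(pname)
            elif base in ("species_coho", "body_mass", "water_temp", "fight_duration"):
                fit.significant_covariates.append(pname)
    max_rhat = float(summary["rhat"].max())
    if max_rhat > 1.05:
        fit.convergence_ok = False
        warnings.warn(
            f"max split R-hat {max_rhat:.3f} > 1.05; treat posterior with caution",
            ConvergenceWarning,
        )
    return fit


def kfold_ic(
    design: LinkageDesign,
    folds: int = 10,
    seed: Optional[int] = None,
    chains: int = 4,
    warmup: int = 3000,
    draws: int = 1000,
    max_density_draws: int = 1000,
) -> tuple[float, np.ndarray]:
    """K-fold cross-validation information criterion.

    Rows are partitioned into ``folds`` balanced folds (sizes differ by at
    most 1) under the seed; each fold is scored by the log pointwise
    predictive density of its held-out rows under the model refit on the
    remaining rows.  Returns (-2 x sum lppd, fold assignment).
    """
    n = design.n
    if n < folds:
        raise ParameterError(
            f"n = {n} < folds = {folds}; reduce the number of folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % folds
    lppd = 0.0
    for f in range(folds):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fit = fit_linkage(
            design.subset(train), chains=chains, warmup=warmup, draws=draws, seed=sub_seed
        )
        S = fit.n_draws
        keep = np.linspace(0, S - 1, min(S, max_density_draws)).astype(int)
        Xf = np.column_stack([np.ones(len(test)), design.X[test]])
        Yt = design.Y[test]
        mu = np.einsum("ij,sjk->sik", Xf, fit.beta_draws[keep])  # (S', m, 2)
        E = Yt[None] - mu
        s = fit.sigma_draws[keep]
        r = fit.rho_draws[keep]
        one_m_r2 = 1.0 - r**2
        e1, e2 = E[:, :, 0], E[:, :, 1]
        quad = (
            (e1 / s[:, None, 0]) ** 2
            - 2 * r[:, None] * e1 * e2 / (s[:, None, 0] * s[:, None, 1])
            + (e2 / s[:, None, 1]) ** 2
        ) / one_m_r2[:, None]
        logp = (
            -np.log(2 * np.pi)
            - np.log(s[:, None, 0])
            - np.log(s[:, None, 1])
            - 0.5 * np.log(one_m_r2)[:, None]
            - 0.5 * quad
        )  # (S', m)
        m = logp.shape[0]
        lppd += float(
            np.sum(np.logaddexp.reduce(logp, axis=0) - np.log(m))
        )
    return -2.0 * lppd, assignment


def bayes_r2(fit: LinkageFit) -> dict[str, float]:
    """Bayesian R^2: per-draw Var(fit)/(Var(fit) + sigma^2), medianized.

    Returns per-response posterior medians and their mean as the model-level
    value (key ``"mean"``).
    """
    Xf = np.column_stack([np.ones(fit.design.n), fit.design.X])
    mu = np.einsum("ij,sjk->sik", Xf, fit.beta_draws)  # (S, n, 2)
    var_fit = mu.var(axis=1, ddof=1)  # (S, 2)
    r2 = var_fit / (var_fit + fit.sigma_draws**2)
    out = {
        resp: float(np.median(r2[:, i])) for i, resp in enumerate(fit.design.response_names)
    }
    out["mean"] = float(np.mean([out[r] for r in fit.design.response_names]))
    return out


def envfit_vectors(
    ordination: OrdinationResult,
    variables: dict[str, np.ndarray],
    permutations: int = 999,
    seed: Optional[int] = None,
) -> dict[str, VectorFit]:
    """Fit external variables as vectors onto the ordination scores.

    Each variable is regressed (with intercept) on the retained score matrix;
    r2 is the squared multiple correlation and the direction the normalized
    coefficient vector.  Significance comes from permuting the variable
    across fish: p = (1 + #{r2* >= r2}) / (1 + permutations).
    """
    scores = ordination.scores
    n = scores.shape[0]
    if n < 3:
        raise SizeError("envfit needs >= 3 fish")
    rng = np.random.default_rng(seed)
    Xf = np.column_stack([np.ones(n), scores])
    pinv = np.linalg.pinv(Xf)
    results: dict[str, VectorFit] = {}
    for name, v in variables.items():
        v = np.asarray(v, dtype=float)
        if np.all(v == v[0]):
            raise DegenerateColumnError(f"variable {name!r} is constant")

        def r_squared(y: np.ndarray) -> float:
            coef = pinv @ y
            resid = y - Xf @ coef
            sst = float(np.sum((y - y.mean()) ** 2))
            return 1.0 - float(np.sum(resid**2)) / sst, coef

        r2, coef = r_squared(v)
        exceed = 0
        for _ in range(permutations):
            r2_star, _ = r_squared(rng.permutation(v))
            if r2_star >= r2:
                exceed += 1
        direction = coef[1:]
        norm = np.linalg.norm(direction)
        if norm > 0:
            direction = direction / norm
        results[name] = VectorFit(
            variable=name,
            direction=direction,
            r2=max(0.0, min(1.0, r2)),
            p_value=(1 + exceed) / (1 + permutations),
        )
    return results


def marginal_effects(
    fit: LinkageFit,
    predictor: str,
    grid_size: int = 50,
) -> pd.DataFrame:
    """Predicted response curves over one predictor, others held at their mean.

    The indicator covariate is held at the reference level (chinook).  Per-draw
    predictions are back-transformed to the original physiology scale through
    the stored inverse normalization; the curve reports the median and the
    2.5/97.5 percentile band for both responses.
    """
    design = fit.design
    if predictor not in design.predictor_names:
        raise ParameterError(
            f"unknown predictor {predictor!r}; have {design.predictor_names}"
        )
    j = design.predictor_names.index(predictor)
    grid = np.linspace(design.X[:, j].min(), design.X[:, j].max(), grid_size)
    base = design.X.mean(axis=0)
    if "species_coho" in design.predictor_names:
        base[design.predictor_names.index("species_coho")] = 0.0
    Xg = np.tile(base, (grid_size, 1))
    Xg[:, j] = grid
    Xf = np.column_stack([np.ones(grid_size), Xg])
    mu = np.einsum("ij,sjk->sik", Xf, fit.beta_draws)  # (S, grid, 2)
    frames = []
    for i, resp in enumerate(design.response_names):
        back = design.maps[resp].inverse(mu[:, :, i].ravel()).reshape(mu.shape[0], grid_size)
        med = np.median(back, axis=0)
        lo, hi = np.percentile(back, [2.5, 97.5], axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "predictor": predictor,
                    "value": grid,
                    "response": resp,
                    "median": med,
                    "ci_2.5": lo,
                    "ci_97.5": hi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def correlogram(dataset: CaptureDataset) -> pd.DataFrame:
    """Pearson correlation matrix of the eight fight/physiology variables."""
    mt = metrics_table(dataset)
    rows = {}
    for fid in dataset.fish_ids:
        rec = dataset.records[fid]
        rows[fid] = {
            "n_bursts": mt.loc[fid, "n_bursts"],
            "fight_duration": mt.loc[fid, "fight_duration"],
            "mean_actvsum": mt.loc[fid, "mean_actvsum"],
            "total_effort": mt.loc[fid, "total_effort"],
            "water_temp": rec.water_temp,
            "fork_length": rec.fork_length,
            "lactate": rec.lactate,
            "blood_ph": rec.blood_ph,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[CORRELOGRAM_VARIABLES]
    if df.isna().any().any():
        bad = sorted(df.index[df.isna().any(axis=1)])
        raise ValidationError(f"incomplete cases for correlogram: {bad}")
    if (df.std(ddof=1) == 0).any():
        const = list(df.columns[df.std(ddof=1) == 0])
        raise DegenerateColumnError(f"constant variable(s) in correlogram: {const}")
    return df.corr(method="pearson")
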