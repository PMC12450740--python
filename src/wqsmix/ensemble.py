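"""Ensemble estimation of mixture weights and the weighted quantile sum index.

The WQS model regresses the outcome on a single index ``Σ_i w_i q_i`` of
quantile-scored components, with weights constrained to the unit simplex
(``w_i >= 0``, ``Σ w_i = 1``) and the index slope sign-constrained to a
declared direction of association. In the stratified interaction form the
weights are stratum-specific (``2c`` parameters for two strata) and the
model carries a reference slope ``b1`` plus an interaction ``b12``, so the
second stratum's slope is ``b2 = b1 + b12``.

Weights are estimated in the training split only, averaged over an ensemble
of fits — bootstrap resamples of the observations, or random subsets of the
components when parameters outnumber observations — to stabilize estimation
under complex correlation among components.

Numerics: weights are parameterized through a softmax map onto the simplex
and the slopes through per-stratum sign-bounded parameters ``(b1, b2)``
(which linearizes the coupled constraint ``b1 + b12`` on the second
stratum's slope); the penalized least-squares objective is minimized by
L-BFGS-B with an analytic gradient. Training fits assume independence
across rows; intra-subject correlation is handled downstream in the
holdout mixed model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .dataset import MixtureDataset, ValidationError
from .quantiles import QuantiledMixture

logger = logging.getLogger(__name__)

_SIMPLEX_TOL = 1e-8


class EnsembleError(RuntimeError):
    """Ensemble could not produce valid averaged weights."""


@dataclass
class WQSFit:
    """Result of one constrained WQS fit.

    ``weights`` has one row per stratum (a single row when unstratified);
    ``slopes`` holds the per-stratum index slopes ``(b1,)`` or ``(b1, b2)``.
    """

    weights: np.ndarray          # (n_strata, c), each row on the simplex
    slopes: np.ndarray           # (n_strata,) index slope per stratum
    intercept: float
    stratum_effect: float | None
    covariate_coefs: np.ndarray
    converged: bool
    objective: float
    n_iter: int

    @property
    def b1(self) -> float:
        return float(self.slopes[0])

    @property
    def b12(self) -> float | None:
        if len(self.slopes) < 2:
            return None
        return float(self.slopes[1] - self.slopes[0])


@dataclass
class WeightSet:
    """Averaged ensemble weights with provenance.

    Attributes
    ----------
    weights
        ``(n_strata, c)`` nonnegative matrix; each stratum row sums to 1.
    direction
        Declared direction of the index-outcome association.
    selection_counts
        How many converged ensemble fits included each (stratum, component).
    per_fit_weights
        Per-fit ``(n_strata, c)`` weight matrices (NaN where a component was
        not sampled in a random-subset fit).
    per_fit_betas
        Per-fit slope vectors.
    """

    weights: np.ndarray
    direction: str
    component_names: list[str]
    selection_counts: np.ndarray
    per_fit_weights: list[np.ndarray] = field(default_factory=list, repr=False)
    per_fit_betas: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if np.any(self.weights < -_SIMPLEX_TOL):
            raise ValueError("negative weight in WeightSet")
        sums = self.weights.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _SIMPLEX_TOL):
            raise ValueError(f"stratum weights must sum to 1, got {sums}")

    @property
    def n_strata(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclass
class WQSFitConfig:
    """Settings for ensemble weight estimation.

    Parameters
    ----------
    nq
        Quantile bins used for scoring (deciles by default).
    direction
        ``"positive"`` or ``"negative"`` association of index and outcome.
    b
        Number of ensemble replicates (bootstrap samples or random subsets).
    ensemble_kind
        ``"bootstrap"`` or ``"random_subset"``.
    subset_size
        Components per random subset; ``None`` selects
        ``floor(n_strata * sqrt(c))`` automatically.
    stratified
        Estimate stratum-specific weights and slopes.
    resample_unit
        Bootstrap resampling unit: ``"subject"`` (cluster bootstrap,
        default — rows within a subject are correlated) or ``"row"``.
    solver_opts
        Options forwarded to the L-BFGS-B solver.
    """

    nq: int = 10
    direction: str = "positive"
    b: int = 100
    ensemble_kind: str = "bootstrap"
    subset_size: int | None = None
    stratified: bool = False
    resample_unit: str = "subject"
    solver_opts: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValidationError(f"b must be >= 1, got {self.b}")
        if self.direction not in ("positive", "negative"):
            raise ValidationError(f"direction must be positive/negative, got {self.direction}")
        if self.ensemble_kind not in ("bootstrap", "random_subset"):
            raise ValidationError(f"unknown ensemble_kind {self.ensemble_kind!r}")
        if self.resample_unit not in ("subject", "row"):
            raise ValidationError(f"unknown resample_unit {self.resample_unit!r}")


def auto_subset_size(n_components: int, n_strata: int = 1) -> int:
    """Default random-subset size: ``floor(n_strata * sqrt(c))``.

    For 30 components and 2 strata this gives 10.
    """
    return int(math.floor(n_strata * math.sqrt(n_components)))


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = theta - theta.max()
    e = np.exp(z)
    return e / e.sum()


def fit_wqs_single(
    quantiles: QuantiledMixture | np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    stratum: np.ndarray | None = None,
    direction: str = "positive",
    solver_opts: dict | None = None,
) -> WQSFit:
    """One constrained nonlinear least-squares WQS fit on training rows.

    Model::

        y = b0 + b1*WQS + [b12*WQS*I(s=2) + g*I(s=2)] + covariates + e

    with ``WQS`` built from stratum-specific simplex weights and the slope(s)
    sign-constrained to ``direction``. Internally the slopes are parameterized
    as per-stratum ``(b1, b2)``, both bounded by the direction.

    Parameters
    ----------
    quantiles
        Quantile scores for the training rows (matrix or QuantiledMixture).
    stratum
        Per-row 0/1 indicator (0 = reference); ``None`` for unstratified fits.

    Raises
    ------
    ValidationError
        Constant outcome, or fewer than 3 rows in a stratum.
    """
    Q = quantiles.scores if isinstance(quantiles, QuantiledMixture) else np.asarray(quantiles)
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    y = np.asarray(outcome, dtype=float)
    n, c = Q.shape
    if np.ptp(y) == 0:
        raise ValidationError("outcome is constant; degenerate design")

    S = 1 if stratum is None else 2
    if stratum is None:
        masks = [np.ones(n, dtype=bool)]
    else:
        stratum = np.asarray(stratum).astype(int)
        masks = [stratum == 0, stratum == 1]
    for s, m in enumerate(masks):
        if m.sum() < 3:
            raise ValidationError(f"stratum {s} has {int(m.sum())} rows; at least 3 required")

    cols = [np.ones(n)]
    if stratum is not None:
        cols.append(masks[1].astype(float))
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    p = X.shape[1]

    sign = 1.0 if direction == "positive" else -1.0
    # ftol drives termination in practice; gtol is loose because zero weights
    # push softmax logits toward -inf where the gradient decays slowly
    opts = {"maxiter": 1000, "ftol": 1e-8, "gtol": 1e-5}
    opts.update(solver_opts or {})

    Qs = [Q[m] for m in masks]

    def unpack(params):
        theta = params[: S * c].reshape(S, c)
        beta = params[S * c : S * c + p]
        slopes = params[S * c + p :]
        return theta, beta, slopes

    def model_parts(params):
        theta, beta, slopes = unpack(params)
        W = np.vstack([_softmax(theta[s]) for s in range(S)])
        yhat = X @ beta
        idx = np.zeros(n)
        for s in range(S):
            idx_s = Qs[s] @ W[s]
            yhat[masks[s]] += slopes[s] * idx_s
            idx[masks[s]] = idx_s
        return W, beta, slopes, yhat, idx

    def objective(params):
        W, beta, slopes, yhat, idx = model_parts(params)
        r = y - yhat
        f = float(r @ r)
        grad = np.empty_like(params)
        for s in range(S):
            g_w = -2.0 * slopes[s] * (Qs[s].T @ r[masks[s]])
            w = W[s]
            grad[s * c : (s + 1) * c] = w * (g_w - (w @ g_w))
        grad[S * c : S * c + p] = -2.0 * (X.T @ r)
        for s in range(S):
            grad[S * c + p + s] = -2.0 * float(idx[masks[s]] @ r[masks[s]])
        return f, grad

    # initialize: uniform weights; linear coefficients from OLS with those weights
    theta0 = np.zeros(S * c)
    W0 = np.full((S, c), 1.0 / c)
    idx_cols = np.zeros((n, S))
    for s in range(S):
        idx_cols[masks[s], s] = Qs[s] @ W0[s]
    D = np.column_stack([X, idx_cols])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    beta0 = coef[:p]
    slopes0 = np.clip(sign * coef[p:], 1e-6, None) * sign

    x0 = np.concatenate([theta0, beta0, slopes0])
    bounds = [(None, None)] * (S * c + p)
    bounds += [(0.0, None) if sign > 0 else (None, 0.0)] * S

    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds, options=opts)
    W, beta, slopes, yhat, _ = model_parts(res.x)
    # renormalize defensively (softmax already lands on the simplex)
    W = np.clip(W, 0.0, None)
    W /= W.sum(axis=1, keepdims=True)

    return WQSFit(
        weights=W,
        slopes=np.asarray(slopes, dtype=float),
        intercept=float(beta[0]),
        stratum_effect=float(beta[1]) if stratum is not None else None,
        covariate_coefs=np.asarray(beta[(2 if stratum is not None else 1):], dtype=float),
        converged=bool(res.success),
        objective=float(res.fun),
        n_iter=int(res.nit),
    )


def _training_arrays(data: MixtureDataset, quantiles: QuantiledMixture, stratified: bool):
    y = data.outcome
    cov = data.covariates
    strat = data.stratum_indicator() if stratified else None
    if stratified and strat is None:
        raise ValidationError("stratified fit requested but dataset has no stratum column")
    return quantiles.scores.astype(float), y, cov, strat


def _average_weights(per_fit: list[np.ndarray], S: int, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean of per-fit weights where sampled, renormalized to the simplex."""
    stack = np.stack(per_fit)  # (n_fits, S, c)
    counts = np.sum(~np.isnan(stack), axis=0).astype(int)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mean = np.where(counts > 0, mean, 0.0)
    sums = mean.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise EnsembleError("averaged weights degenerate (all zero in a stratum)")
    return mean / sums, counts


def bootstrap_ensemble(
    data: MixtureDataset,
    quantiles: QuantiledMixture,
    config: WQSFitConfig,
    rng: np.random.Generator | None = None,
) -> WeightSet:
    """Estimate weights by averaging ``b`` bootstrap-resampled fits.

    Resampling is with replacement at the subject level by default (cluster
    bootstrap), so the intra-subject dependence structure is respected even
    though each fit itself assumes independence.
    """
    if config.ensemble_kind != "bootstrap":
        raise ValidationError("config.ensemble_kind must be 'bootstrap'")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    Q, y, cov, strat = _training_arrays(data, quantiles, config.stratified)
    n, c = Q.shape
    S = 2 if config.stratified else 1

    subj = data.subject_ids
    uniq = data.subjects
    per_w, per_b = [], []
    n_failed = 0
    for _ in range(config.b):
        if config.resample_unit == "subject":
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            rows = np.concatenate([np.flatnonzero(subj == s) for s in chosen])
        else:
            rows = rng.integers(0, n, size=n)
        try:
            fit = fit_wqs_single(
                Q[rows], y[rows],
                covariates=None if cov is None else cov[rows],
                stratum=None if strat is None else strat[rows],
                direction=config.direction,
                solver_opts=config.solver_opts,
            )
        except ValidationError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            logger.debug("bootstrap fit did not converge; excluded")
            continue
        per_w.append(fit.weights)
        per_b.append(fit.slopes)
    if n_failed > 0.2 * config.b:
        raise EnsembleError(
            f"{n_failed}/{config.b} bootstrap fits failed to converge; "
            "consider more data or fewer components"
        )
    weights, counts = _average_weights(per_w, S, c)
    return WeightSet(
        weights=weights,
        direction=config.direction,
        component_names=list(quantiles.component_names),
        selection_counts=counts,
        per_fit_weights=per_w,
        per_fit_betas=per_b,
    )


def random_subset_ensemble(
    data: MixtureDataset,
    quantiles: QuantiledMixture,
    config: WQSFitConfig,
    rng: np.random.Generator | None = None,
) -> WeightSet:
    """Estimate weights by averaging fits on random component subsets.

    Used when parameters outnumber observations (e.g. 60 stratified weights
    from 42 rows). Each replicate samples ``subset_size`` *original*
    components — not stratum-expanded parameters — and, in stratified mode,
    estimates weights for the sampled components in both strata, so every
    stratum is represented in every replicate. A component's final weight is
    the mean over replicates in which it was sampled, renormalized per
    stratum.

    Raises
    ------
    EnsembleError
        If a component was never included in a converged fit (the number of
        replicates was inadequate to cover all components).
    """
    if config.ensemble_kind != "random_subset":
        raise ValidationError("config.ensemble_kind must be 'random_subset'")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    Q, y, cov, strat = _training_arrays(data, quantiles, config.stratified)
    n, c = Q.shape
    S = 2 if config.stratified else 1
    size = config.subset_size if config.subset_size is not None else auto_subset_size(c, S)
    size = min(size, c - 1) if c > 1 else 1
    if config.subset_size is not None and config.subset_size >= c and c > 1:
        raise ValidationError(f"subset_size must be < n_components ({c})")

    per_w, per_b = [], []
    n_failed = 0
    for _ in range(config.b):
        subset = np.sort(rng.choice(c, size=size, replace=False))
        try:
            fit = fit_wqs_single(
                Q[:, subset], y,
                covariates=cov,
                stratum=strat,
                direction=config.direction,
                solver_opts=config.solver_opts,
            )
        except ValidationError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        full = np.full((S, c), np.nan)
        full[:, subset] = fit.weights
        per_w.append(full)
        per_b.append(fit.slopes)
    if n_failed > 0.2 * config.b:
        raise EnsembleError(
            f"{n_failed}/{config.b} random-subset fits failed to converge; "
            "consider more data or fewer components"
        )
    weights, counts = _average_weights(per_w, S, c)
    never = np.flatnonzero((counts == 0).any(axis=0))
    if never.size:
        names = [quantiles.component_names[j] for j in never]
        raise EnsembleError(
            f"components never sampled in a converged fit: {names}; "
            "increase the number of random subsets (b)"
        )
    return WeightSet(
        weights=weights,
        direction=config.direction,
        component_names=list(quantiles.component_names),
        selection_counts=counts,
        per_fit_weights=per_w,
        per_fit_betas=per_b,
    )


def compute_wqs_index(
    quantiles: QuantiledMixture,
    weights: WeightSet,
    stratum: np.ndarray | None = None,
) -> np.ndarray:
    """Per-row weighted index ``Σ_i w_{s(r),i} q_{r,i}``.

    Rows use their stratum's weight vector; with a single weight row the
    stratum argument is ignored. The index lies in ``[0, nq - 1]``.
    """
    if list(weights.component_names) != list(quantiles.component_names):
        raise ValidationError("component order of weights does not match quantiles")
    Q = quantiles.scores.astype(float)
    if weights.n_strata == 1 or stratum is None:
        if weights.n_strata > 1 and stratum is None:
            raise ValidationError("stratified weights require a per-row stratum")
        return Q @ weights.weights[0]
    stratum = np.asarray(stratum).astype(int)
    if stratum.max() >= weights.n_strata or stratum.min() < 0:
        raise ValidationError("row stratum not present in WeightSet")
    out = np.empty(Q.shape[0])
    for s in range(weights.n_strata):
        m = stratum == s
        out[m] = Q[m] @ weights.weights[s]
    return out
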