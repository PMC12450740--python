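"""Synthetic repeated-measures mixture data with known ground truth.

The generator emulates the structure of a small repeated-measures exposure
study: ``n_subjects`` each observed on ``n_occasions`` occasions, ``c``
correlated exposure components, an optional two-level stratifying factor
with stratum-specific sparse true weights, a linear mixture effect on a
continuous outcome, a subject-level covariate, a subject random intercept
and Gaussian residual noise.

Exposures are drawn from a Gaussian copula (multivariate normal with a
block or first-order autoregressive correlation target) and mapped to
lognormal marginals by default, since environmental concentrations are
right-skewed; quantile scoring downstream is invariant to that monotone
map. The true mixture effect acts on the quantile-score scale — the
outcome's fixed-effect surface is ``b0 + b_s * Σ_i w_{s,i} q_i + ...`` with
``b_1 = b1`` in the reference stratum and ``b_2 = b1 + b12`` in the other —
matching the model form the analysis estimates, which makes parameter
recovery well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import MixtureDataset, ValidationError
from .quantiles import quantile_score_dataset


def sparse_weights(c: int, active: tuple[int, ...], values: tuple[float, ...] = (0.5, 0.3, 0.2)) -> np.ndarray:
    """Simplex weight vector with mass only on ``active`` component indices."""
    if len(active) != len(values):
        raise ValidationError("active indices and values must have equal length")
    w = np.zeros(c)
    w[list(active)] = values
    s = w.sum()
    if s <= 0:
        raise ValidationError("weights must have positive mass")
    return w / s


@dataclass
class SimulationSpec:
    """Generating parameters for a synthetic repeated-measures mixture study.

    Defaults mirror a small pilot-style design — 14 subjects on 3 occasions
    with 30 components and two equal strata — with a moderate positive
    mixture effect (``b1 = 0.5``, interaction ``b12 = 0.3``) carried by 3
    active components per stratum (disjoint supports between strata), an
    intra-subject correlation of 0.6 (``s_b^2 = 0.6``, ``s_e^2 = 0.4``) and
    a small positive covariate (age) effect.
    """

    n_subjects: int = 14
    n_occasions: int = 3
    n_components: int = 30
    corr_structure: str = "ar1"       # "ar1" or "block"
    corr_param: float = 0.5           # rho of AR(1) or within-block correlation
    block_size: int = 5               # used by "block"
    marginal: str = "lognormal"       # "lognormal" or "gaussian"
    stratified: bool = True
    stratum_prop: float = 0.5         # share of subjects in the reference stratum
    true_weights: np.ndarray | None = None   # (n_strata, c); None -> sparse defaults
    n_active: int = 3
    beta0: float = 0.0
    true_b1: float = 0.5
    true_b12: float = 0.3
    stratum_effect: float = 0.2
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.05})
    sigma_b2: float = 0.6
    sigma_e2: float = 0.4
    nq: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_occasions < 1:
            raise ValidationError("n_occasions must be >= 1")
        if self.sigma_b2 < 0 or self.sigma_e2 < 0:
            raise ValidationError("variances must be nonnegative")
        if not 0 < self.stratum_prop < 1 and self.stratified:
            raise ValidationError("stratum_prop must be in (0, 1)")

    @property
    def n_strata(self) -> int:
        return 2 if self.stratified else 1

    def resolved_weights(self) -> np.ndarray:
        """True weight matrix, filling in sparse defaults when unset.

        Default truth: ``n_active`` components carry weights proportional to
        (0.5, 0.3, 0.2, ...); strata use disjoint supports (components
        0..k-1 vs k..2k-1) so stratum-specific weight recovery is testable.
        """
        if self.true_weights is not None:
            W = np.atleast_2d(np.asarray(self.true_weights, dtype=float))
            if W.shape != (self.n_strata, self.n_components):
                raise ValidationError(
                    f"true_weights must be ({self.n_strata}, {self.n_components})"
                )
            if np.any(W < 0) or not np.allclose(W.sum(axis=1), 1.0, atol=1e-8):
                raise ValidationError("true weight vectors must lie on the simplex")
            return W
        k = self.n_active
        if self.n_strata * k > self.n_components:
            raise ValidationError("not enough components for disjoint active sets")
        base = np.array([0.5, 0.3, 0.2, 0.15, 0.1][:k] + [0.1] * max(0, k - 5))
        rows = []
        for s in range(self.n_strata):
            rows.append(sparse_weights(self.n_components, tuple(range(s * k, (s + 1) * k)), tuple(base)))
        return np.vstack(rows)

    def correlation_matrix(self) -> np.ndarray:
        c, rho = self.n_components, self.corr_param
        if self.corr_structure == "ar1":
            if not -1 < rho < 1:
                raise ValidationError(f"AR(1) parameter must be in (-1, 1), got {rho}")
            idx = np.arange(c)
            return rho ** np.abs(idx[:, None] - idx[None, :])
        if self.corr_structure == "block":
            R = np.eye(c)
            for start in range(0, c, self.block_size):
                stop = min(start + self.block_size, c)
                R[start:stop, start:stop] = rho
            np.fill_diagonal(R, 1.0)
            eig = np.linalg.eigvalsh(R)
            if eig.min() <= 1e-10:
                bad = f"block starting at component {start}"
                raise ValidationError(
                    f"requested block correlation is not positive definite ({bad}, rho={rho})"
                )
            return R
        raise ValidationError(f"unknown corr_structure {self.corr_structure!r}")


def generate(spec: SimulationSpec, rng: np.random.Generator | None = None) -> tuple[MixtureDataset, dict]:
    """Draw one dataset from the spec; returns ``(dataset, truth_record)``.

    The truth record stores every generating parameter plus the realized
    per-subject random intercepts, so recovery experiments can score any
    stage of the pipeline against the truth.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_sub, n_occ, c = spec.n_subjects, spec.n_occasions, spec.n_components
    n = n_sub * n_occ

    R = spec.correlation_matrix()
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 0:
        raise ValidationError("correlation matrix not positive definite")
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, c)) @ L.T
    if spec.marginal == "lognormal":
        X = np.exp(Z)
    elif spec.marginal == "gaussian":
        X = Z
    else:
        raise ValidationError(f"unknown marginal {spec.marginal!r}")

    subjects = np.repeat([f"S{i + 1:03d}" for i in range(n_sub)], n_occ)
    occasions = np.tile([f"R{t + 1:02d}" for t in range(n_occ)], n_sub)

    if spec.stratified:
        n_ref = int(round(spec.stratum_prop * n_sub))
        n_ref = min(max(n_ref, 1), n_sub - 1)
        subj_strat = np.array([0] * n_ref + [1] * (n_sub - n_ref))
        rng.shuffle(subj_strat)
        stratum_rows = np.repeat(subj_strat, n_occ)
        stratum_labels = np.where(stratum_rows == 0, "A", "B")
    else:
        subj_strat = np.zeros(n_sub, dtype=int)
        stratum_rows = np.zeros(n, dtype=int)
        stratum_labels = None

    age_subj = rng.standard_normal(n_sub)
    age = np.repeat(age_subj, n_occ)

    comp_names = [f"x{j + 1:02d}" for j in range(c)]
    df = pd.DataFrame(X, columns=comp_names)
    df.insert(0, "subject", subjects)
    df.insert(1, "occasion", occasions)
    df["age"] = age
    if stratum_labels is not None:
        df["stratum"] = stratum_labels
    df["y"] = 0.0  # placeholder; outcome needs quantile scores

    ds = MixtureDataset(
        data=df,
        subject_col="subject",
        occasion_col="occasion",
        outcome_col="y",
        component_cols=comp_names,
        covariate_cols=["age"],
        stratum_col="stratum" if stratum_labels is not None else None,
    )
    qm = quantile_score_dataset(ds, spec.nq)

    W = spec.resolved_weights()
    slopes = np.array([spec.true_b1, spec.true_b1 + spec.true_b12])[: spec.n_strata]
    index = np.einsum("rc,rc->r", qm.scores.astype(float), W[stratum_rows])
    u = rng.normal(0.0, np.sqrt(spec.sigma_b2), size=n_sub)
    eps = rng.normal(0.0, np.sqrt(spec.sigma_e2), size=n)
    y = (
        spec.beta0
        + slopes[stratum_rows] * index
        + spec.stratum_effect * (stratum_rows == 1)
        + spec.covariate_effects.get("age", 0.0) * age
        + u[np.repeat(np.arange(n_sub), n_occ)]
        + eps
    )
    df["y"] = y

    truth = {
        "spec": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(spec).items()},
        "true_weights": W.tolist(),
        "true_slopes": slopes.tolist(),
        "true_icc": spec.sigma_b2 / (spec.sigma_b2 + spec.sigma_e2)
        if (spec.sigma_b2 + spec.sigma_e2) > 0
        else float("nan"),
        "active_components": [
            [comp_names[j] for j in np.flatnonzero(W[s] > 0)] for s in range(W.shape[0])
        ],
        "random_intercepts": u.tolist(),
    }
    # re-validate with the filled outcome
    ds = MixtureDataset(
        data=df,
        subject_col="subject",
        occasion_col="occasion",
        outcome_col="y",
        component_cols=comp_names,
        covariate_cols=["age"],
        stratum_col="stratum" if stratum_labels is not None else None,
    )
    return ds, truth


def write_dataset(ds: MixtureDataset, truth: dict, csv_path: str, truth_path: str | None = None) -> None:
    """Write the dataset as CSV with an optional sidecar JSON truth record."""
    import json

    ds.data.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)


def recovery_experiment(
    spec: SimulationSpec,
    config,
    n_replicates: int = 10,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline on fresh draws and score recovery against truth.

    Returns a report with per-replicate median slope estimates, bias, the
    hit rate of true active components among the top weights, and recovered
    intra-subject correlation.

    ``config`` is an :class:`~wqsmix.pipeline.AnalysisConfig`.
    """
    from .pipeline import run_analysis
    from .mixed_inference import TERM_WQS, TERM_INTERACTION, significance_report

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    W_true = spec.resolved_weights()
    active = [np.flatnonzero(W_true[s] > 0) for s in range(W_true.shape[0])]

    b1s, b12s, b2s, iccs, hits, sig_b1 = [], [], [], [], [], []
    errors = []
    for i, child in enumerate(children):
        rep_rng = np.random.default_rng(child)
        try:
            ds, truth = generate(spec, rng=rep_rng)
            result = run_analysis(ds, config, seed=int(rep_rng.integers(2**31 - 1)))
        except Exception as exc:  # propagate with replicate index
            errors.append((i, str(exc)))
            raise RuntimeError(f"replicate {i} failed: {exc}") from exc
        coef = result.summary.coefficients
        b1s.append(coef.loc[TERM_WQS, "median"])
        if TERM_INTERACTION in coef.index:
            b12s.append(coef.loc[TERM_INTERACTION, "median"])
            b2s.append(coef.loc["wqs_stratum2", "median"])
        iccs.append(float(np.nanmedian(_offdiag(result.summary.median_corr.to_numpy()))))
        avg = result.summary.average_weights
        hit = True
        for s in range(W_true.shape[0]):
            sub = avg[avg["stratum"] == s].set_index("component")["mean_weight"]
            top = set(sub.nlargest(len(active[s])).index)
            truth_names = {f"x{j + 1:02d}" for j in active[s]}
            hit = hit and top == truth_names
        hits.append(hit)
        flags = significance_report(result.summary)
        sig_b1.append(bool(flags.loc[TERM_WQS, "significant"]))

    report = {
        "n_replicates": n_replicates,
        "true_b1": spec.true_b1,
        "true_b12": spec.true_b12,
        "true_icc": spec.sigma_b2 / (spec.sigma_b2 + spec.sigma_e2),
        "b1_medians": b1s,
        "b12_medians": b12s,
        "b2_medians": b2s,
        "icc_estimates": iccs,
        "b1_bias": float(np.mean(b1s) - spec.true_b1) if b1s else float("nan"),
        "weight_hit_rate": float(np.mean(hits)) if hits else float("nan"),
        "b1_significance_rate": float(np.mean(sig_b1)) if sig_b1 else float("nan"),
    }
    return report


def _offdiag(M: np.ndarray) -> np.ndarray:
    mask = ~np.eye(M.shape[0], dtype=bool)
    return M[mask]
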