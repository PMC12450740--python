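"""Random-intercept mixed-model inference in the holdout splits.

Each holdout fit conditions on the weights estimated in that split's own
training half: the weighted index is treated as a fixed covariate in

    y_rt = b0 + b1*WQS + b12*WQS*I(s=2) + g*I(s=2) + covariates
           + u_subject + e_rt,   u ~ N(0, s_b^2),  e ~ N(0, s_e^2)

fitted by restricted maximum likelihood. The second stratum's index slope
``b2 = b1 + b12`` is derived within each fit before any cross-holdout
summarization (medians of ``b1`` and ``b12`` do not in general sum to the
median of ``b2``). Across repeated holdouts the coefficients are summarized
by their median and 2.5/97.5 percentiles, and the intra-subject correlation
of the outcome by the entrywise median of per-holdout occasion-by-occasion
correlation matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .dataset import MixtureDataset, ValidationError
from .ensemble import WeightSet

logger = logging.getLogger(__name__)

# canonical fixed-effect term names used in summaries
TERM_INTERCEPT = "intercept"
TERM_WQS = "wqs"            # b1: index slope, reference stratum
TERM_STRATUM = "stratum"    # main effect of the second stratum level
TERM_INTERACTION = "wqs_x_stratum"  # b12
TERM_WQS_STRATUM2 = "wqs_stratum2"  # b2 = b1 + b12, derived per fit


@dataclass
class HoldoutFit:
    """One holdout's REML random-intercept fit, conditioned on training weights."""

    params: pd.Series                 # fixed-effect estimates by term name
    b2: float | None                  # b1 + b12 (None when unstratified)
    sigma_b2: float                   # random-intercept variance
    sigma_e2: float                   # residual variance
    corr_matrix: pd.DataFrame         # occasions x occasions empirical correlations
    model_icc: float                  # model-implied compound-symmetry correlation
    converged: bool
    n_rows: int
    n_subjects: int
    marginal_residuals: np.ndarray = field(repr=False, default=None)

    @property
    def b1(self) -> float:
        return float(self.params[TERM_WQS])

    @property
    def b12(self) -> float | None:
        if TERM_INTERACTION not in self.params.index:
            return None
        return float(self.params[TERM_INTERACTION])


@dataclass
class HoldoutSummary:
    """Percentile summaries of coefficients and correlations across holdouts."""

    coefficients: pd.DataFrame        # index = term, cols = median, p2.5, p97.5
    median_corr: pd.DataFrame         # entrywise median correlation matrix
    median_model_icc: float
    average_weights: pd.DataFrame     # component, stratum, mean_weight, mean_selection
    rh: int
    n_nonconverged: int

    def __post_init__(self) -> None:
        lo, med, hi = (self.coefficients[c] for c in ("p2.5", "median", "p97.5"))
        if not ((lo <= med + 1e-12) & (med <= hi + 1e-12)).all():
            raise ValueError("percentile summaries must be monotone per coefficient")


def compound_symmetry_icc(sigma_b2: float, sigma_e2: float) -> float:
    """Model-implied intra-subject correlation ``s_b^2 / (s_b^2 + s_e^2)``."""
    tot = sigma_b2 + sigma_e2
    if tot <= 0:
        return float("nan")
    return sigma_b2 / tot


def intra_subject_correlation(
    residuals: np.ndarray,
    subject_ids: np.ndarray,
    occasions: np.ndarray,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Empirical occasion-by-occasion correlation of marginal residuals.

    Residuals (outcome minus fixed-effect prediction) are reshaped to a
    subjects x occasions table and Pearson correlations computed pairwise,
    so subjects with missing occasions still contribute to the pairs they
    have. Pairs supported by fewer than ``min_pairs`` subjects are reported
    as missing.
    """
    tab = pd.DataFrame({"subject": subject_ids, "occasion": occasions, "resid": residuals})
    wide = tab.pivot(index="subject", columns="occasion", values="resid")
    corr = wide.corr(method="pearson", min_periods=min_pairs)
    n_pairs = wide.notna().astype(int).T @ wide.notna().astype(int)
    if (n_pairs.to_numpy() < min_pairs).any():
        warnings.warn(
            "some occasion pairs have fewer than "
            f"{min_pairs} contributing subjects; entries set to missing",
            UserWarning,
            stacklevel=2,
        )
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def _aliased_terms(X: pd.DataFrame) -> list[str]:
    """Names of columns that are linearly dependent on earlier columns."""
    A = X.to_numpy(dtype=float)
    aliased = []
    kept: list[int] = []
    for j in range(A.shape[1]):
        trial = A[:, kept + [j]]
        if np.linalg.matrix_rank(trial) <= len(kept):
            aliased.append(X.columns[j])
        else:
            kept.append(j)
    return aliased


def fit_mixed_holdout(
    data: MixtureDataset,
    wqs_index: np.ndarray,
    stratified: bool = True,
) -> HoldoutFit:
    """REML random-intercept fit of the holdout outcome on the weighted index.

    Parameters
    ----------
    data
        The holdout rows (long format). The subject column defines the
        random-intercept grouping.
    wqs_index
        Per-row index values computed from this holdout's own training
        weights.
    stratified
        Include the stratum main effect and index-by-stratum interaction.

    Notes
    -----
    With fewer than 2 subjects observed on 2+ occasions the random-intercept
    variance is unidentifiable; a warning is issued and the fit proceeds
    (fixed effects then coincide with ordinary least squares).
    """
    y = data.outcome
    n = len(y)
    wqs_index = np.asarray(wqs_index, dtype=float)
    if wqs_index.shape[0] != n:
        raise ValidationError("wqs_index length does not match holdout rows")

    X = pd.DataFrame({TERM_INTERCEPT: np.ones(n), TERM_WQS: wqs_index})
    if stratified:
        strat = data.stratum_indicator()
        if strat is None:
            raise ValidationError("stratified fit requested but dataset has no stratum column")
        X[TERM_STRATUM] = strat.astype(float)
        X[TERM_INTERACTION] = wqs_index * strat
    for cname in data.covariate_cols:
        X[cname] = data.data[cname].to_numpy(dtype=float)

    aliased = _aliased_terms(X)
    if aliased:
        raise ValidationError(f"singular fixed-effect design; aliased terms: {aliased}")

    groups = data.subject_ids
    occ_per_subject = pd.Series(groups).groupby(groups).size()
    if (occ_per_subject >= 2).sum() < 2:
        warnings.warn(
            "fewer than 2 subjects with repeated occasions; random-intercept "
            "variance is unidentifiable (fixed effects reduce to OLS)",
            UserWarning,
            stacklevel=2,
        )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    # a boundary estimate (sigma_b^2 -> 0) is a valid REML solution and is
    # not flagged; only genuine optimizer failures are
    converged = not any(
        issubclass(w.category, ConvergenceWarning)
        and "failed to converge" in str(w.message).lower()
        for w in caught
    )
    if not converged:
        logger.debug(
            "mixed model convergence flagged: %s",
            "; ".join(str(w.message) for w in caught),
        )

    params = pd.Series(res.fe_params, index=X.columns)
    sigma_b2 = float(np.asarray(res.cov_re)[0, 0])
    sigma_e2 = float(res.scale)
    b2 = None
    if stratified:
        b2 = float(params[TERM_WQS] + params[TERM_INTERACTION])

    resid = y - X.to_numpy() @ params.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        corr = intra_subject_correlation(resid, groups, data.occasions)

    return HoldoutFit(
        params=params,
        b2=b2,
        sigma_b2=sigma_b2,
        sigma_e2=sigma_e2,
        corr_matrix=corr,
        model_icc=compound_symmetry_icc(sigma_b2, sigma_e2),
        converged=converged,
        n_rows=n,
        n_subjects=data.n_subjects,
        marginal_residuals=resid,
    )


def summarize_holdouts(
    fits: list[HoldoutFit],
    weight_sets: list[WeightSet] | None = None,
    include_nonconverged: bool = False,
) -> HoldoutSummary:
    """Median and 2.5/97.5 percentile of every coefficient across holdouts.

    Percentiles use linear interpolation between order statistics. The
    correlation matrix is summarized entrywise by the median; averaged
    weights are the per-component mean across the holdouts' weight sets.
    """
    if not fits:
        raise ValidationError("no holdout fits to summarize")
    used = fits if include_nonconverged else [f for f in fits if f.converged]
    n_bad = len(fits) - len([f for f in fits if f.converged])
    if not used:
        raise ValidationError("zero converged holdout fits")

    terms = list(used[0].params.index)
    rows = {}
    for t in terms:
        vals = np.array([f.params[t] for f in used])
        rows[t] = _pctl_row(vals)
    if used[0].b2 is not None:
        rows[TERM_WQS_STRATUM2] = _pctl_row(np.array([f.b2 for f in used]))
    coef = pd.DataFrame(rows, index=["median", "p2.5", "p97.5"]).T

    corr_stack = [f.corr_matrix for f in used]
    occ = corr_stack[0].index
    med_corr = pd.DataFrame(
        np.nanmedian(np.stack([c.reindex(index=occ, columns=occ).to_numpy() for c in corr_stack]), axis=0),
        index=occ,
        columns=occ,
    )
    med_icc = float(np.median([f.model_icc for f in used]))

    avg_w = pd.DataFrame()
    if weight_sets:
        stack = np.stack([ws.weights for ws in weight_sets])  # (rh, S, c)
        mean_w = stack.mean(axis=0)
        sel = np.stack([ws.selection_counts for ws in weight_sets]).mean(axis=0)
        names = weight_sets[0].component_names
        recs = []
        for s in range(mean_w.shape[0]):
            for j, name in enumerate(names):
                recs.append(
                    {
                        "component": name,
                        "stratum": s,
                        "mean_weight": mean_w[s, j],
                        "mean_selection_count": sel[s, j],
                    }
                )
        avg_w = pd.DataFrame(recs)

    return HoldoutSummary(
        coefficients=coef,
        median_corr=med_corr,
        median_model_icc=med_icc,
        average_weights=avg_w,
        rh=len(fits),
        n_nonconverged=n_bad,
    )


def _pctl_row(vals: np.ndarray) -> list[float]:
    return [
        float(np.percentile(vals, 50)),
        float(np.percentile(vals, 2.5)),
        float(np.percentile(vals, 97.5)),
    ]


def significance_report(summary: HoldoutSummary) -> pd.DataFrame:
    """Flag coefficients whose 2.5-97.5 percentile interval excludes zero.

    ``borderline`` is a heuristic label: the interval endpoint nearest zero
    lies within 10% of the median's magnitude. Percentile intervals across
    repeated holdouts are not exact confidence intervals; the flags are
    descriptive.
    """
    coef = summary.coefficients
    lo, hi, med = coef["p2.5"], coef["p97.5"], coef["median"]
    significant = (lo > 0) | (hi < 0)
    nearest = np.minimum(np.abs(lo), np.abs(hi))
    borderline = (~significant) & (nearest <= 0.10 * np.abs(med))
    return pd.DataFrame(
        {
            "median": med,
            "p2.5": lo,
            "p97.5": hi,
            "significant": significant,
            "sign": np.sign(med).astype(int),
            "borderline_heuristic": borderline,
        }
    )
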