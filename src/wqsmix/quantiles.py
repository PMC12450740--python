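"""Quantile scoring of mixture component concentrations.

Each component is ranked into ``nq`` quantile bins (deciles by default),
replacing the raw concentration by an integer score in ``0..nq-1``. Scoring
puts all components on a common ordinal scale so that a weighted sum of
scores is interpretable as a mixture index.

Convention: cut points are the empirical sample quantiles at ``k/nq``
(``k = 1..nq-1``) under the linear-interpolation definition, and a value's
score is the number of cut points strictly below it. Tied raw values
therefore always receive the same score regardless of row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import MixtureDataset, ValidationError


class QuantileWarning(UserWarning):
    """Degenerate quantile binning (ties collapse bins, constant columns)."""


@dataclass
class QuantiledMixture:
    """Integer quantile scores for every component column.

    Attributes
    ----------
    scores
        Integer matrix, rows = subject-occasions, columns = components,
        entries in ``{0, ..., nq - 1}``.
    nq
        Number of quantile bins.
    component_names
        Ordered component labels matching the score columns.
    cut_points
        ``(n_components, nq - 1)`` thresholds on the raw scale,
        non-decreasing within each component.
    """

    scores: np.ndarray
    nq: int
    component_names: list[str]
    cut_points: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim == 1:
            self.scores = self.scores[:, None]
        if self.scores.shape[1] != len(self.component_names):
            raise ValueError("score columns must match component_names")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > self.nq - 1):
            raise ValueError(f"scores must lie in 0..{self.nq - 1}")
        if np.any(np.diff(np.atleast_2d(self.cut_points), axis=1) < 0):
            raise ValueError("cut_points must be non-decreasing within each component")

    @property
    def n_rows(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def subset(self, row_indices: np.ndarray) -> "QuantiledMixture":
        return QuantiledMixture(
            scores=self.scores[np.asarray(row_indices)],
            nq=self.nq,
            component_names=list(self.component_names),
            cut_points=self.cut_points,
        )


def quantile_score(values, nq: int, name: str = "component") -> tuple[np.ndarray, np.ndarray]:
    """Rank a numeric vector into ``nq`` quantile bins.

    Returns ``(scores, cut_points)`` where ``scores[j]`` counts the cut
    points strictly below ``values[j]``.

    Raises
    ------
    ValidationError
        If ``nq < 2``, the vector is shorter than ``nq``, or contains
        non-finite entries.

    Warns
    -----
    QuantileWarning
        When ties leave fewer than ``nq`` occupied bins (including the
        all-constant case, which scores every row 0).
    """
    values = np.asarray(values, dtype=float)
    if nq < 2:
        raise ValidationError(f"nq must be >= 2, got {nq}")
    if values.ndim != 1:
        raise ValidationError("values must be a 1-d vector")
    if not np.isfinite(values).all():
        raise ValidationError(f"non-finite values in {name!r}")
    if values.size and np.all(values == values[0]):
        warnings.warn(
            f"{name!r} is constant; all scores set to 0", QuantileWarning, stacklevel=2
        )
        return (
            np.zeros(values.size, dtype=np.int64),
            np.full(nq - 1, values[0] if values.size else np.nan),
        )
    if values.size < nq:
        raise ValidationError(
            f"{name!r} has {values.size} values, fewer than nq={nq} bins"
        )

    probs = np.arange(1, nq) / nq
    cut_points = np.quantile(values, probs)  # linear interpolation
    # score = number of cut points strictly less than the value
    scores = np.searchsorted(cut_points, values, side="left").astype(np.int64)

    n_occupied = len(np.unique(scores))
    if n_occupied < nq:
        warnings.warn(
            f"{name!r}: ties collapse {nq} bins to {n_occupied} occupied bins",
            QuantileWarning,
            stacklevel=2,
        )
    return scores, cut_points


def quantile_score_dataset(data: MixtureDataset, nq: int) -> QuantiledMixture:
    """Apply :func:`quantile_score` to every component column of a dataset.

    Scoring is done on the full dataset before any train/holdout split, so
    holdout rows are scored on the same scale as training rows.
    """
    X = data.components
    n, c = X.shape
    scores = np.empty((n, c), dtype=np.int64)
    cuts = np.empty((c, nq - 1), dtype=float)
    for j, cname in enumerate(data.component_cols):
        scores[:, j], cuts[j] = quantile_score(X[:, j], nq, name=cname)
    return QuantiledMixture(
        scores=scores, nq=nq, component_names=list(data.component_cols), cut_points=cuts
    )
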