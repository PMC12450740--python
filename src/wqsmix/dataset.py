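"""Validated long-format container for repeated-measures mixture data.

A :class:`MixtureDataset` wraps a pandas DataFrame in long format — one row
per subject-occasion — together with the column roles the analysis needs:
subject identifier, occasion label, continuous outcome, mixture component
concentrations, optional covariates and an optional two-level stratifying
factor (e.g. sex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when input data violate the long-format contract."""


@dataclass
class MixtureDataset:
    """Long-format repeated-measures mixture dataset.

    Parameters
    ----------
    data
        One row per subject-occasion. All role columns must be present.
    subject_col, occasion_col, outcome_col
        Names of the subject ID, occasion label and continuous outcome columns.
    component_cols
        Ordered names of the mixture component concentration columns.
    covariate_cols
        Names of numeric covariate columns (may be empty).
    stratum_col
        Optional name of a two-level stratifying factor.
    """

    data: pd.DataFrame
    subject_col: str
    occasion_col: str
    outcome_col: str
    component_cols: list[str]
    covariate_cols: list[str] = field(default_factory=list)
    stratum_col: str | None = None

    def __post_init__(self) -> None:
        self._validate()

    # -- properties -------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_components(self) -> int:
        return len(self.component_cols)

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject IDs in order of first appearance."""
        return self.data[self.subject_col].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[self.outcome_col].to_numpy(dtype=float)

    @property
    def components(self) -> np.ndarray:
        """Raw concentration matrix, rows = subject-occasions."""
        return self.data[self.component_cols].to_numpy(dtype=float)

    @property
    def covariates(self) -> np.ndarray | None:
        if not self.covariate_cols:
            return None
        return self.data[self.covariate_cols].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data[self.subject_col].to_numpy()

    @property
    def occasions(self) -> np.ndarray:
        return self.data[self.occasion_col].to_numpy()

    @property
    def stratum_levels(self) -> list | None:
        if self.stratum_col is None:
            return None
        return sorted(self.data[self.stratum_col].unique())

    def stratum_indicator(self) -> np.ndarray | None:
        """Per-row 0/1 indicator: 0 = reference (first sorted level), 1 = other."""
        if self.stratum_col is None:
            return None
        levels = self.stratum_levels
        return (self.data[self.stratum_col] == levels[1]).to_numpy().astype(int)

    def subset(self, row_indices: np.ndarray) -> "MixtureDataset":
        """Row subset (positional indices), preserving roles."""
        return MixtureDataset(
            data=self.data.iloc[np.asarray(row_indices)].reset_index(drop=True),
            subject_col=self.subject_col,
            occasion_col=self.occasion_col,
            outcome_col=self.outcome_col,
            component_cols=list(self.component_cols),
            covariate_cols=list(self.covariate_cols),
            stratum_col=self.stratum_col,
        )

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        roles = (
            [self.subject_col, self.occasion_col, self.outcome_col]
            + list(self.component_cols)
            + list(self.covariate_cols)
            + ([self.stratum_col] if self.stratum_col else [])
        )
        missing = [c for c in roles if c not in self.data.columns]
        if missing:
            raise ValidationError(f"columns not found in data: {missing}")
        seen: set[str] = set()
        for c in roles:
            if c in seen:
                raise ValidationError(f"column {c!r} assigned to more than one role")
            seen.add(c)
        if not self.component_cols:
            raise ValidationError("at least one component column is required")

        for c in list(self.component_cols) + [self.outcome_col] + list(self.covariate_cols):
            col = pd.to_numeric(self.data[c], errors="coerce")
            if col.isna().any():
                n_bad = int(col.isna().sum())
                raise ValidationError(
                    f"column {c!r} has {n_bad} missing or non-numeric entries; "
                    "complete numeric data are required"
                )
            if not np.isfinite(col.to_numpy(dtype=float)).all():
                raise ValidationError(f"column {c!r} contains non-finite values")

        dup = self.data.duplicated(subset=[self.subject_col, self.occasion_col])
        if dup.any():
            pairs = self.data.loc[dup, [self.subject_col, self.occasion_col]]
            raise ValidationError(
                f"duplicated (subject, occasion) pairs: {pairs.values.tolist()[:5]}"
            )

        if self.stratum_col is not None:
            levels = self.data[self.stratum_col].unique()
            if len(levels) != 2:
                raise ValidationError(
                    f"stratum column {self.stratum_col!r} must have exactly 2 levels, "
                    f"found {len(levels)}"
                )
            # stratum must be constant within subject
            nlev = self.data.groupby(self.subject_col)[self.stratum_col].nunique()
            if (nlev > 1).any():
                bad = nlev[nlev > 1].index.tolist()
                raise ValidationError(f"stratum varies within subject(s): {bad[:5]}")


def load_dataset(
    path: str,
    subject_col: str,
    occasion_col: str,
    outcome_col: str,
    component_cols: list[str],
    covariate_cols: list[str] | None = None,
    stratum_col: str | None = None,
    drop_incomplete: bool = True,
    sep: str = ",",
) -> MixtureDataset:
    """Read a delimited long-format file and validate it.

    Rows with missing outcome, component or covariate values are dropped
    (with a logged count) when ``drop_incomplete`` is set; otherwise they
    raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep=sep)
    required = (
        [subject_col, occasion_col, outcome_col]
        + list(component_cols)
        + list(covariate_cols or [])
    )
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"file {path} is missing columns: {missing_cols}")
    if drop_incomplete:
        numeric_cols = [outcome_col] + list(component_cols) + list(covariate_cols or [])
        for c in numeric_cols:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        complete = df[numeric_cols].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.warning("dropped %d incomplete rows from %s", n_dropped, path)
        df = df.loc[complete].reset_index(drop=True)
    return MixtureDataset(
        data=df,
        subject_col=subject_col,
        occasion_col=occasion_col,
        outcome_col=outcome_col,
        component_cols=list(component_cols),
        covariate_cols=list(covariate_cols or []),
        stratum_col=stratum_col,
    )


def percent_change(pre: pd.Series | np.ndarray, post: pd.Series | np.ndarray) -> np.ndarray:
    """Percent change (post - pre) / pre, the usual pre/post outcome transform."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre == 0):
        raise ValidationError("pre-measure contains zeros; percent change undefined")
    return (post - pre) / pre
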