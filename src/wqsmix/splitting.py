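"""Repeated train/holdout partitions for weight estimation and inference.

The analysis estimates index weights in a training fraction (typically 40%)
and tests the index slope in the complementary holdout (60%), repeating the
random split many times and summarizing holdout estimates by median and
2.5/97.5 percentiles.

Two contracts distinguish this from a generic splitter:

* the split unit defaults to the *subject*, so all repeated measures of one
  subject fall on the same side — otherwise the subject random intercept
  leaks information between training and holdout;
* when a stratifying factor is given, per-stratum proportions on the train
  side match the full data within rounding (largest-remainder allocation),
  so small strata are never absent from either side by chance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import MixtureDataset, ValidationError


@dataclass
class SplitPlan:
    """Indices for ``rh`` repeated train/holdout splits.

    ``splits`` holds ``(train_row_indices, holdout_row_indices)`` pairs of
    0-based positional row indices into the dataset the plan was built from.
    """

    rh: int
    train_fraction: float
    splits: list[tuple[np.ndarray, np.ndarray]]
    subject_ids: np.ndarray
    seed: int | None = None
    group_subjects: bool = True
    stratum_col: str | None = field(default=None)

    def __len__(self) -> int:
        return self.rh

    def __iter__(self):
        return iter(self.splits)

    def to_json(self, path: str) -> None:
        """Serialize the plan; row indices are 0-based positions."""
        payload = {
            "format": "wqsmix split plan; row indices are 0-based positions",
            "rh": self.rh,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "group_subjects": self.group_subjects,
            "stratum_col": self.stratum_col,
            "subject_ids": [str(s) for s in self.subject_ids],
            "splits": [
                {"train": np.asarray(tr).tolist(), "holdout": np.asarray(ho).tolist()}
                for tr, ho in self.splits
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        splits = [
            (np.asarray(s["train"], dtype=int), np.asarray(s["holdout"], dtype=int))
            for s in payload["splits"]
        ]
        return cls(
            rh=payload["rh"],
            train_fraction=payload["train_fraction"],
            splits=splits,
            subject_ids=np.asarray(payload["subject_ids"]),
            seed=payload.get("seed"),
            group_subjects=payload.get("group_subjects", True),
            stratum_col=payload.get("stratum_col"),
        )


def _largest_remainder(counts: np.ndarray, fraction: float) -> np.ndarray:
    """Allocate floor + largest-remainder so totals round to fraction * sum."""
    exact = counts * fraction
    base = np.floor(exact).astype(int)
    target = int(round(counts.sum() * fraction))
    remainder = exact - base
    short = target - base.sum()
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(remainder, kind="stable")
        take = order[: -short]
        base[take] = np.maximum(base[take] - 1, 0)
    return base


def split_once(
    data: MixtureDataset,
    train_fraction: float = 0.4,
    stratum: str | None = None,
    group_subjects: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/holdout partition of the dataset rows.

    Parameters
    ----------
    train_fraction
        Proportion of units (subjects when ``group_subjects``, else rows)
        placed in the training set; the rest form the holdout.
    stratum
        Optional stratifying column; per-stratum proportions are preserved
        within rounding.
    group_subjects
        Keep all rows of a subject on the same side (default). A row-level
        mode is available for single-occasion data.

    Returns
    -------
    (train_indices, holdout_indices)
        Sorted 0-based positional row indices partitioning the dataset.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng() if rng is None else rng

    df = data.data
    if group_subjects:
        unit_ids = data.subjects
        unit_of_row = df[data.subject_col].to_numpy()
    else:
        unit_ids = np.arange(len(df))
        unit_of_row = unit_ids

    if stratum is not None:
        if stratum not in df.columns:
            raise ValidationError(f"stratum column {stratum!r} not in data")
        if group_subjects:
            unit_stratum = (
                df.drop_duplicates(data.subject_col)
                .set_index(data.subject_col)[stratum]
                .loc[unit_ids]
                .to_numpy()
            )
        else:
            unit_stratum = df[stratum].to_numpy()
        levels, level_idx = np.unique(unit_stratum, return_inverse=True)
        counts = np.bincount(level_idx)
        if group_subjects and np.any(counts < 2):
            lvl = levels[np.argmin(counts)]
            raise ValidationError(
                f"stratum level {lvl!r} has fewer than 2 subjects; "
                "collect more data or use a row-level split"
            )
        n_train_per = _largest_remainder(counts.astype(float), train_fraction)
        if np.any(n_train_per == 0) or np.any(n_train_per == counts):
            bad = levels[(n_train_per == 0) | (n_train_per == counts)][0]
            raise ValidationError(
                f"stratum level {bad!r} would be absent from one side after "
                "proportional allocation; use more data or a row-level split"
            )
        train_units = []
        for k in range(len(levels)):
            members = unit_ids[level_idx == k]
            chosen = rng.choice(members, size=n_train_per[k], replace=False)
            train_units.append(chosen)
        train_units = np.concatenate(train_units)
    else:
        n_train = int(round(len(unit_ids) * train_fraction))
        n_train = min(max(n_train, 1), len(unit_ids) - 1)
        train_units = rng.choice(unit_ids, size=n_train, replace=False)

    in_train = np.isin(unit_of_row, train_units)
    train_idx = np.flatnonzero(in_train)
    holdout_idx = np.flatnonzero(~in_train)
    return train_idx, holdout_idx


def repeated_splits(
    data: MixtureDataset,
    rh: int = 30,
    train_fraction: float = 0.4,
    stratum: str | None = None,
    group_subjects: bool = True,
    seed: int | None = None,
) -> SplitPlan:
    """Build ``rh`` independent train/holdout splits (the repeated holdouts).

    A master seed spawns one child RNG per split, so plans are reproducible
    and individual splits are independent streams.
    """
    if rh < 1:
        raise ValidationError(f"rh must be >= 1, got {rh}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(rh)
    splits = [
        split_once(
            data,
            train_fraction=train_fraction,
            stratum=stratum,
            group_subjects=group_subjects,
            rng=np.random.default_rng(child),
        )
        for child in children
    ]
    return SplitPlan(
        rh=rh,
        train_fraction=train_fraction,
        splits=splits,
        subject_ids=data.subject_ids,
        seed=seed,
        group_subjects=group_subjects,
        stratum_col=stratum,
    )
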