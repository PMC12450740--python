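"""End-to-end orchestration: score, split, estimate weights, infer, summarize.

The sequence per repeated holdout:

1. quantile-score the full dataset (scores are computed once, before
   splitting, so holdout rows share the training scale);
2. randomly split subjects into training (default 40%) and holdout (60%),
   preserving stratum proportions;
3. estimate simplex weights in the training rows with the configured
   ensemble (bootstrap resamples or random component subsets);
4. build the weighted index on the holdout rows from that split's own
   training weights and fit the random-intercept mixed model there.

Holdout coefficients, intra-subject correlation matrices and weights are
then summarized across the ``rh`` repeats by medians and 2.5/97.5
percentiles.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MixtureDataset, ValidationError, load_dataset
from .ensemble import (
    WQSFitConfig,
    WeightSet,
    bootstrap_ensemble,
    compute_wqs_index,
    random_subset_ensemble,
)
from .mixed_inference import (
    HoldoutFit,
    HoldoutSummary,
    fit_mixed_holdout,
    significance_report,
    summarize_holdouts,
)
from .quantiles import quantile_score_dataset
from .splitting import SplitPlan, repeated_splits

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Settings for a full repeated-holdout WQS mixed-effects analysis.

    Defaults are the method's reference profile: deciles, a 40/60
    training/holdout split, 30 repeated holdouts, and either 100 bootstrap
    samples or 200 random subsets of automatic size.
    """

    nq: int = 10
    direction: str = "positive"
    ensemble_kind: str = "random_subset"
    b: int = 200
    subset_size: int | None = None
    rh: int = 30
    train_fraction: float = 0.4
    group_subjects: bool = True
    resample_unit: str = "subject"
    stratified: bool | None = None      # None -> stratified iff dataset has a stratum
    grand_average: bool = False         # sensitivity mode: one pooled weight vector
    solver_opts: dict = field(default_factory=dict)

    def fit_config(self, stratified: bool, seed: int | None = None) -> WQSFitConfig:
        return WQSFitConfig(
            nq=self.nq,
            direction=self.direction,
            b=self.b,
            ensemble_kind=self.ensemble_kind,
            subset_size=self.subset_size,
            stratified=stratified,
            resample_unit=self.resample_unit,
            solver_opts=dict(self.solver_opts),
            seed=seed,
        )


@dataclass
class AnalysisResult:
    """Everything a repeated-holdout analysis produced."""

    split_plan: SplitPlan
    weight_sets: list[WeightSet]
    holdout_fits: list[HoldoutFit]
    summary: HoldoutSummary
    config: AnalysisConfig
    seed: int | None


def run_analysis(
    data: MixtureDataset,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> AnalysisResult:
    """Run the full repeated-holdout WQS mixed-effects analysis in memory."""
    config = config or AnalysisConfig()
    stratified = (
        config.stratified
        if config.stratified is not None
        else data.stratum_col is not None
    )
    if stratified and data.stratum_col is None:
        raise ValidationError("config requests stratified analysis but data has no stratum")

    qm = quantile_score_dataset(data, config.nq)

    ss = np.random.SeedSequence(seed)
    split_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
    plan = repeated_splits(
        data,
        rh=config.rh,
        train_fraction=config.train_fraction,
        stratum=data.stratum_col if stratified else None,
        group_subjects=config.group_subjects,
        seed=split_seed,
    )
    ens_children = ss.spawn(config.rh)

    ensemble_fn = (
        bootstrap_ensemble if config.ensemble_kind == "bootstrap" else random_subset_ensemble
    )
    weight_sets: list[WeightSet] = []
    for (train_idx, _), child in zip(plan, ens_children):
        train_data = data.subset(train_idx)
        train_qm = qm.subset(train_idx)
        ws = ensemble_fn(
            train_data,
            train_qm,
            config.fit_config(stratified),
            rng=np.random.default_rng(child),
        )
        weight_sets.append(ws)

    if config.grand_average:
        grand = np.mean(np.stack([ws.weights for ws in weight_sets]), axis=0)
        grand /= grand.sum(axis=1, keepdims=True)
        pooled = WeightSet(
            weights=grand,
            direction=config.direction,
            component_names=weight_sets[0].component_names,
            selection_counts=np.sum(
                np.stack([ws.selection_counts for ws in weight_sets]), axis=0
            ),
        )
        index_weights = [pooled] * config.rh
    else:
        index_weights = weight_sets

    fits: list[HoldoutFit] = []
    for (train_idx, holdout_idx), ws in zip(plan, index_weights):
        holdout_data = data.subset(holdout_idx)
        holdout_qm = qm.subset(holdout_idx)
        strat_rows = holdout_data.stratum_indicator() if stratified else None
        index = compute_wqs_index(holdout_qm, ws, stratum=strat_rows)
        fits.append(fit_mixed_holdout(holdout_data, index, stratified=stratified))

    summary = summarize_holdouts(fits, weight_sets)
    return AnalysisResult(
        split_plan=plan,
        weight_sets=weight_sets,
        holdout_fits=fits,
        summary=summary,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# File-based configuration and result bundles (the CLI surface)
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative configuration for a file-to-file pipeline run."""

    input_path: str
    output_dir: str
    subject_col: str
    occasion_col: str
    outcome_col: str
    component_cols: list[str]
    covariate_cols: list[str] = field(default_factory=list)
    stratum_col: str | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int | None = None
    sep: str = ","

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        analysis = AnalysisConfig(**raw.pop("analysis", {}))
        return cls(analysis=analysis, **raw)


def validate_dataset(path: str, config: RunConfig) -> MixtureDataset:
    """Load and validate the configured input file."""
    return load_dataset(
        path,
        subject_col=config.subject_col,
        occasion_col=config.occasion_col,
        outcome_col=config.outcome_col,
        component_cols=config.component_cols,
        covariate_cols=config.covariate_cols,
        stratum_col=config.stratum_col,
        sep=config.sep,
    )


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-to-file pipeline: read input, run the analysis, write the bundle.

    Writes to ``config.output_dir``: the split plan (JSON), per-holdout and
    averaged weight tables (CSV), the coefficient summary in a
    median/2.5%/97.5% layout (CSV + JSON), the median intra-subject
    correlation matrix (CSV), significance flags (CSV) and a machine-
    readable run log with the seed and library versions (JSON).
    """
    data = validate_dataset(config.input_path, config)
    result = run_analysis(data, config.analysis, seed=config.seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    result.split_plan.to_json(str(out / "split_plan.json"))

    per_fit_rows = []
    for h, ws in enumerate(result.weight_sets):
        for s in range(ws.n_strata):
            for j, name in enumerate(ws.component_names):
                per_fit_rows.append(
                    {
                        "holdout": h,
                        "stratum": s,
                        "component": name,
                        "weight": ws.weights[s, j],
                        "selection_count": int(ws.selection_counts[s, j]),
                    }
                )
    pd.DataFrame(per_fit_rows).to_csv(out / "holdout_weights.csv", index=False)
    result.summary.average_weights.to_csv(out / "average_weights.csv", index=False)

    coef = result.summary.coefficients
    coef.to_csv(out / "summary_coefficients.csv", index_label="coefficient")
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "coefficients": coef.to_dict(orient="index"),
                "median_model_icc": result.summary.median_model_icc,
                "median_correlation": result.summary.median_corr.to_dict(),
                "rh": result.summary.rh,
                "n_nonconverged": result.summary.n_nonconverged,
            },
            fh,
            indent=2,
        )
    result.summary.median_corr.to_csv(out / "median_correlation.csv")
    significance_report(result.summary).to_csv(out / "significance.csv", index_label="coefficient")

    fit_rows = []
    for h, f in enumerate(result.holdout_fits):
        row = {"holdout": h, "converged": f.converged, "sigma_b2": f.sigma_b2,
               "sigma_e2": f.sigma_e2, "model_icc": f.model_icc, "b2": f.b2}
        row.update({f"coef_{k}": v for k, v in f.params.items()})
        fit_rows.append(row)
    pd.DataFrame(fit_rows).to_csv(out / "holdout_fits.csv", index=False)

    import statsmodels

    log = {
        "seed": config.seed,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "analysis"},
            "analysis": asdict(config.analysis),
        },
        "n_rows": data.n_rows,
        "n_subjects": data.n_subjects,
        "n_components": data.n_components,
        "n_nonconverged_holdouts": result.summary.n_nonconverged,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return result
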