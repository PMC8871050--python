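"""Run configuration and cohort demographic summaries.

`summarize_cohort` produces the standard case-control demographics table:
pooled-variance two-sample t-tests for continuous covariates and Pearson
chi-square tests (no continuity correction) for binary ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = ["RunConfig", "summarize_cohort"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a mass-analysis run."""

    cohort_csv: str = ""
    group_column: str = "diagnosis"
    group_order: list[str] | None = None
    confounds: list[str] = field(default_factory=lambda: ["age", "sex", "tiv"])
    modalities: list[str] | None = None
    standardize: bool = True
    correction: str = "benjamini_hochberg"
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "massmva_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def validate_against(self, cohort: pd.DataFrame) -> None:
        missing = [c for c in [self.group_column, *self.confounds] if c not in cohort.columns]
        if missing:
            raise ValueError(f"config references absent cohort columns: {missing}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def summarize_cohort(
    cohort: pd.DataFrame,
    group_column: str = "diagnosis",
    continuous: tuple[str, ...] = ("age", "tiv"),
    binary: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Per-group descriptive statistics with between-group tests.

    Continuous covariates: mean ± SD per group and the pooled-variance
    two-sided t-test p-value.  Binary covariates: per-group counts of the
    two levels and the Pearson chi-square p-value (no continuity
    correction).
    """
    levels = list(pd.unique(cohort[group_column]))
    if len(levels) < 2:
        raise ValueError(f"need two groups in {group_column!r}, found {levels}")
    if len(levels) > 2:
        raise ValueError(f"more than two groups in {group_column!r}: {levels}")
    g1 = cohort[cohort[group_column] == levels[0]]
    g2 = cohort[cohort[group_column] == levels[1]]

    rows = []
    for c in continuous:
        x, y = g1[c].to_numpy(float), g2[c].to_numpy(float)
        if np.var(x, ddof=1) + np.var(y, ddof=1) == 0 and x.mean() == y.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        rows.append(
            {
                "covariate": c,
                "test": "t",
                f"{levels[0]} (n={len(g1)})": f"{x.mean():.1f} ± {x.std(ddof=1):.1f}",
                f"{levels[1]} (n={len(g2)})": f"{y.mean():.1f} ± {y.std(ddof=1):.1f}",
                "p": p,
                "mean_1": x.mean(),
                "sd_1": x.std(ddof=1),
                "mean_2": y.mean(),
                "sd_2": y.std(ddof=1),
            }
        )
    for c in binary:
        tab = pd.crosstab(cohort[group_column], cohort[c])
        if tab.shape[1] < 2 or (tab.to_numpy() == tab.to_numpy()[0]).all():
            p = 1.0
        else:
            p = float(stats.chi2_contingency(tab.to_numpy(), correction=False)[1])
        counts1 = "/".join(str(int(v)) for v in tab.loc[levels[0]])
        counts2 = "/".join(str(int(v)) for v in tab.loc[levels[1]])
        rows.append(
            {
                "covariate": c,
                "test": "chi2",
                f"{levels[0]} (n={len(g1)})": counts1,
                f"{levels[1]} (n={len(g2)})": counts2,
                "p": p,
                "mean_1": np.nan,
                "sd_1": np.nan,
                "mean_2": np.nan,
                "sd_2": np.nan,
            }
        )
    return pd.DataFrame(rows)
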