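"""Preregistered analysis: the cue-predictivity statistics and the
test-round linear probability regression.

The pipeline operates on the canonical long-format choice dataset (one row
per participant x round). For each condition it subsets to the 12 test
rounds and fits, by ordinary least squares, the linear probability model

    chose_cue_option ~ 1 + historical_predictivity

with standard errors that are heteroskedasticity-robust and clustered on
the participant. The slope is the estimated cue weight: the change in the
probability of choosing the cue-indicated option per unit change in the
share of previously experienced rounds where the cue marked the superior
option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .environment import Condition, Trial

__all__ = [
    "RegressionFit",
    "cue_predictive",
    "historical_predictivity",
    "preregistered_regression",
    "fit_all_conditions",
    "marginal_effect",
    "binned_choice_rates",
    "chance_benchmark",
    "results_table",
    "format_results_table",
]


@dataclass(slots=True)
class RegressionFit:
    """Fitted linear probability model for one condition.

    Coefficients are on the probability scale: the intercept is the
    estimated probability of choosing the cue option at historical
    predictivity zero, and the slope is the change in that probability per
    unit historical predictivity.
    """

    condition: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    n_obs: int
    n_clusters: int

    @property
    def t_slope(self) -> float:
        return self.slope / self.se_slope

    @property
    def t_intercept(self) -> float:
        return self.intercept / self.se_intercept


def cue_predictive(trial: Trial) -> int:
    """Dummy that is 1 iff the cue-indicated option is the superior option
    (the option with a decoy / the default / the indicator-shape option)."""
    return int(trial.cue_position == trial.superior_position)


def historical_predictivity(flags: Sequence[int], r: int) -> float:
    """Share of cue-predictive rounds among rounds 1..r-1.

    ``flags`` must cover at least the first r-1 rounds (practice included).
    Undefined at r = 1 (no history): raises ``ValueError``; the regression
    never evaluates it there because test rounds start after the three
    practice rounds.
    """
    if r < 2:
        raise ValueError("historical predictivity is undefined before round 2")
    if len(flags) < r - 1:
        raise ValueError(f"need flags for rounds 1..{r - 1}, got {len(flags)}")
    return float(np.mean(np.asarray(flags[: r - 1], dtype=float)))


def _validate_columns(data: pd.DataFrame, needed: Iterable[str]) -> None:
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")


def preregistered_regression(
    data: pd.DataFrame, condition: str | Condition
) -> RegressionFit:
    """OLS of test-round cue choice on historical predictivity, with
    participant-clustered robust standard errors.

    The data is subset to the test rounds of ``condition``. Requires at
    least two participants (clusters) and nonzero variance in historical
    predictivity; otherwise the design is singular and a ``ValueError`` is
    raised. Standard errors use the cluster sandwich estimator with the
    standard finite-sample correction.
    """
    condition = Condition(condition).value
    _validate_columns(
        data,
        [
            "condition",
            "round_kind",
            "participant_id",
            "chose_cue_option",
            "historical_predictivity",
        ],
    )
    sub = data[
        (data["condition"] == condition) & (data["round_kind"] == "test")
    ].copy()
    if sub["historical_predictivity"].isna().any():
        raise ValueError("test-round records with undefined history")
    n_clusters = sub["participant_id"].nunique()
    if n_clusters < 2:
        raise ValueError("need test rounds from at least 2 participants")
    x = sub["historical_predictivity"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("historical predictivity has zero variance")
    y = sub["chose_cue_option"].to_numpy(dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(
        cov_type="cluster",
        cov_kwds={"groups": sub["participant_id"].to_numpy()},
    )
    return RegressionFit(
        condition=condition,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        se_intercept=float(fit.bse[0]),
        se_slope=float(fit.bse[1]),
        n_obs=int(fit.nobs),
        n_clusters=int(n_clusters),
    )


def fit_all_conditions(data: pd.DataFrame) -> dict[str, RegressionFit]:
    """Fit the preregistered regression separately for every condition
    present in the dataset."""
    present = set(data["condition"])
    return {
        cond.value: preregistered_regression(data, cond)
        for cond in Condition
        if cond.value in present
    }


def marginal_effect(fit: RegressionFit, delta: float = 0.10) -> float:
    """Estimated change in choice probability, in percentage points, for a
    ``delta`` change in historical predictivity (slope x delta x 100)."""
    return fit.slope * delta * 100.0


def binned_choice_rates(
    data: pd.DataFrame, condition: str | Condition
) -> pd.DataFrame:
    """Local averages of cue choice by historical predictivity rounded to
    two decimals — the binning used for scatter displays of a binary
    outcome. Returns columns (historical_predictivity, mean_chose_cue, n);
    empty conditions yield an empty table."""
    condition = Condition(condition).value
    _validate_columns(
        data,
        ["condition", "round_kind", "chose_cue_option", "historical_predictivity"],
    )
    sub = data[
        (data["condition"] == condition) & (data["round_kind"] == "test")
    ]
    if sub.empty:
        return pd.DataFrame(
            columns=["historical_predictivity", "mean_chose_cue", "n"]
        )
    binned = (
        sub.assign(
            historical_predictivity=sub["historical_predictivity"].round(2)
        )
        .groupby("historical_predictivity", as_index=False)
        .agg(
            mean_chose_cue=("chose_cue_option", "mean"),
            n=("chose_cue_option", "size"),
        )
        .sort_values("historical_predictivity", ignore_index=True)
    )
    return binned


def chance_benchmark(
    condition: str | Condition, chooser_assumption: str = "uniform_over_3"
) -> float:
    """Expected test-round probability of choosing the cue option under a
    cue-blind chooser.

    ``uniform_over_3``: the chooser picks uniformly among the three
    options, so the cue is chosen with probability 1/3 in every condition.
    ``dominance_respecting``: the chooser never picks the dominated decoy
    and is otherwise uniform; in decoy test rounds the cue option is one of
    the two non-decoy options (superior or second-best, equally likely), so
    it is chosen with probability 1/2. The default and rule conditions have
    no dominated option, leaving the benchmark at 1/3.
    """
    condition = Condition(condition)
    if chooser_assumption == "uniform_over_3":
        return 1.0 / 3.0
    if chooser_assumption == "dominance_respecting":
        return 0.5 if condition is Condition.DECOY else 1.0 / 3.0
    raise ValueError(f"unknown chooser assumption {chooser_assumption!r}")


def results_table(fits: dict[str, RegressionFit] | Sequence[RegressionFit]) -> pd.DataFrame:
    """Arrange fitted models as a coefficient table, one row per condition."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    return pd.DataFrame(
        [
            {
                "condition": f.condition,
                "intercept": f.intercept,
                "se_intercept": f.se_intercept,
                "slope": f.slope,
                "se_slope": f.se_slope,
                "t_slope": f.t_slope,
                "n_obs": f.n_obs,
                "n_clusters": f.n_clusters,
            }
            for f in fits
        ]
    )


def format_results_table(
    fits: dict[str, RegressionFit] | Sequence[RegressionFit]
) -> str:
    """Plain-text coefficient table (SEs in parentheses, clustered on
    participant)."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    lines = [
        "Linear probability model: P(chose cue option) ~ historical predictivity",
        "Test rounds only; SEs in parentheses, robust, clustered on participant.",
        "",
        f"{'':24s}" + "".join(f"{f.condition:>12s}" for f in fits),
        f"{'Constant':24s}"
        + "".join(f"{f.intercept:12.3f}" for f in fits),
        f"{'':24s}"
        + "".join(f"{'(' + format(f.se_intercept, '.3f') + ')':>12s}" for f in fits),
        f"{'Historical predictivity':24s}"
        + "".join(f"{f.slope:12.3f}" for f in fits),
        f"{'':24s}"
        + "".join(f"{'(' + format(f.se_slope, '.3f') + ')':>12s}" for f in fits),
        f"{'Observations':24s}" + "".join(f"{f.n_obs:12d}" for f in fits),
        f"{'Participants':24s}" + "".join(f"{f.n_clusters:12d}" for f in fits),
    ]
    return "\n".join(lines)
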