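"""Ganglionic-length tipping-point analysis of megacolon penetrance.

The phenotype axis is the ganglionic fraction: the percentage of colon
length (from the cecum) that contains myenteric ganglia.  Obstruction is
deterministic below a threshold fraction (~80% in the modelled strain).
Males average a ganglionic fraction near that tipping point; females
average beyond it, which turns a small quantitative shift into a strong
male bias of a binary phenotype.

Operations: the empirical critical region (extremes of the affected and
non-affected groups), per-sex penetrance and means, a closed-form Gaussian
penetrance prediction, and Welch's two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import Cohort

__all__ = [
    "CriticalRegion",
    "PenetranceTable",
    "critical_region",
    "penetrance_by_sex",
    "mean_ganglionic_by_sex",
    "predict_penetrance",
    "welch_t",
    "logistic_threshold_fit",
]


@dataclass(frozen=True)
class CriticalRegion:
    """Empirical interval bracketing the obstruction threshold.

    ``lower`` is the shortest ganglionic fraction among non-affected
    animals, ``upper`` the longest among megacolon-affected animals; the
    groups overlap when ``upper >= lower``.
    """

    lower: float
    upper: float
    overlap: bool


@dataclass(frozen=True)
class PenetranceTable:
    n_male: int
    n_female: int
    affected_male: int
    affected_female: int

    @property
    def penetrance_male(self) -> float:
        return self.affected_male / self.n_male if self.n_male else float("nan")

    @property
    def penetrance_female(self) -> float:
        return self.affected_female / self.n_female if self.n_female else float("nan")

    @property
    def male_female_ratio(self) -> float:
        """Male:female ratio among affected animals (nan when no affected
        females)."""
        if self.affected_female == 0:
            return float("nan")
        return self.affected_male / self.affected_female


def _animals(cohort) -> pd.DataFrame:
    return cohort.animals if isinstance(cohort, Cohort) else pd.DataFrame(cohort)


def critical_region(cohort) -> CriticalRegion:
    """Critical region for developing megacolon: delimited by the longest
    ganglionic zone found in an affected case and the shortest observed in a
    non-affected individual."""
    df = _animals(cohort)
    affected = df[df["megacolon"].astype(bool)]
    healthy = df[~df["megacolon"].astype(bool)]
    if affected.empty:
        raise ValueError("one-sided region: no megacolon-affected animals")
    if healthy.empty:
        raise ValueError("one-sided region: no non-affected animals")
    lower = float(healthy["ganglionic_fraction"].min())
    upper = float(affected["ganglionic_fraction"].max())
    return CriticalRegion(lower=lower, upper=upper, overlap=upper >= lower)


def penetrance_by_sex(cohort) -> PenetranceTable:
    df = _animals(cohort)
    if df.empty:
        raise ValueError("empty cohort")
    m = df[df["sex"] == "M"]
    f = df[df["sex"] == "F"]
    return PenetranceTable(
        n_male=len(m),
        n_female=len(f),
        affected_male=int(m["megacolon"].sum()),
        affected_female=int(f["megacolon"].sum()),
    )


def mean_ganglionic_by_sex(cohort) -> pd.DataFrame:
    """Per-sex arithmetic mean, sd (ddof=1) and n of the ganglionic
    fraction."""
    df = _animals(cohort)
    if df.empty:
        raise ValueError("empty cohort")
    out = (
        df.groupby("sex")["ganglionic_fraction"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
    )
    return out


def predict_penetrance(mu: float, sigma: float, threshold: float) -> float:
    """Predicted megacolon penetrance under the tipping-point model.

    With ganglionic fractions ~ Normal(mu, sigma) and deterministic
    obstruction below ``threshold``, penetrance is the Gaussian lower-tail
    probability Phi((threshold - mu)/sigma); sigma = 0 degenerates to a step
    function.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return float(mu < threshold)
    return float(stats.norm.cdf((threshold - mu) / sigma))


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns (t, df, two-sided p).  When both groups have zero variance and
    equal means the test is vacuous and p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def logistic_threshold_fit(cohort) -> dict[str, float]:
    """Optional extra: logistic regression of megacolon on ganglionic
    fraction; returns the 50%-penetrance fraction and slope.

    This smooth alternative to the two-extremes critical region is not part
    of the primary analysis and is provided for exploration only.
    """
    import statsmodels.api as sm

    df = _animals(cohort)
    x = sm.add_constant(df["ganglionic_fraction"].to_numpy(float))
    y = df["megacolon"].astype(float).to_numpy()
    fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    return {"midpoint": float(-b0 / b1), "slope": float(b1)}
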