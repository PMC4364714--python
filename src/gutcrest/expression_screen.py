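"""Negative-binomial differential-expression screen and candidate ranking.

The screen takes a genes x samples count matrix from a two-group design
(two replicates per condition in the reference experiment), normalises
library depth by median-of-ratios size factors, and tests every gene with
two independent negative-binomial schemes:

* scheme A ("exact"): a conditional NB exact test on the group sums, with a
  moderated common + tagwise dispersion estimate;
* scheme B ("lrt"): an NB likelihood-ratio test with per-gene
  method-of-moments dispersions shrunk toward a fitted mean-dispersion
  trend.

Both p-value sets are Benjamini-Hochberg adjusted and a gene is called
differentially expressed only by consensus: displayed fold change at least
``min_fold`` in magnitude AND both adjusted p-values below ``alpha``
(defaults 2-fold and 0.001).  Fold changes below 1 are displayed with the
negative-reciprocal convention (0.25 -> -4.0).

Downstream prioritisation: the sex-chromosome screen (X-linked
downregulated / Y-linked upregulated genes), distance ranking of
upregulated genes on the insertion chromosome, and a two-sided
hypergeometric term-enrichment test with BH correction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NBDifferentialExpression",
    "median_ratio_normalize",
    "nb_de_test",
    "consensus_filter",
    "sex_linked_screen",
    "rank_insertion_candidates",
    "hypergeom_enrichment",
    "display_fold",
    "internal_fold",
]

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_FOLD = 2.0


def display_fold(fold: float | np.ndarray):
    """Signed display convention: ratios below one are shown as the
    negative reciprocal (0.25 -> -4.0); ratios >= 1 are shown as-is."""
    fold = np.asarray(fold, dtype=float)
    out = np.where(fold >= 1.0, fold, -1.0 / fold)
    return float(out) if out.ndim == 0 else out


def internal_fold(displayed: float | np.ndarray):
    """Inverse of :func:`display_fold`."""
    displayed = np.asarray(displayed, dtype=float)
    out = np.where(displayed >= 0, displayed, -1.0 / displayed)
    return float(out) if out.ndim == 0 else out


def median_ratio_normalize(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, factor_j is the median over genes (nonzero in every
    sample) of count_gj / geometric-mean_g.  Identical columns get equal
    factors and the normalised means are invariant to a global rescale of
    the counts.
    """
    c = counts.to_numpy(dtype=float)
    allpos = (c > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logc = np.log(c[allpos])
    log_gm = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_gm, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersion machinery
# ---------------------------------------------------------------------------


def _mom_dispersion(y: np.ndarray, group_idx: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments NB dispersion from normalised counts.

    Returns (overall normalised mean, phi_g) with pooled within-group
    variance; phi clipped to [0, 10].
    """
    m = y.mean(axis=1)
    ss = np.zeros(y.shape[0])
    df = 0
    for idx in group_idx:
        sub = y[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    v = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (v - m) / m**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return m, np.clip(phi, 0.0, 10.0)


def _fit_trend(m: np.ndarray, phi: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of the mean-dispersion trend phi(m) = a/m + b over
    informative genes; both coefficients clipped non-negative."""
    ok = (m >= 1) & np.isfinite(phi)
    if ok.sum() < 10:
        return 0.0, float(np.median(phi[ok])) if ok.any() else 0.0
    X = np.column_stack([1.0 / m[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, phi[ok], rcond=None)
    a, b = float(max(coef[0], 0.0)), float(max(coef[1], 1e-6))
    return a, b


# ---------------------------------------------------------------------------
# Scheme A: conditional NB exact test
# ---------------------------------------------------------------------------


def _exact_test(
    sa: np.ndarray, sb: np.ndarray, na: int, nb: int, phi: np.ndarray
) -> np.ndarray:
    """Conditional NB exact test on integer group sums.

    Under the null both groups share a per-sample mean mu = (sa+sb)/(na+nb);
    the group sums are NB with sizes na/phi and nb/phi.  Conditional on the
    total, the p-value is the summed probability of all splits no more
    likely than the observed one.  The support is evaluated on a +/-20-sd
    window around the conditional mean (negligible mass outside),
    renormalised within the window.
    """
    sa = np.asarray(sa, dtype=np.int64)
    sb = np.asarray(sb, dtype=np.int64)
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-8)
    T = sa + sb
    n = na + nb
    mu = T / n
    ra, rb = na / phi, nb / phi
    mu_a, mu_b = na * mu, nb * mu
    pa = ra / (ra + np.maximum(mu_a, 1e-12))
    pb = rb / (rb + np.maximum(mu_b, 1e-12))

    var_b = mu_b + phi / nb * mu_b**2
    half = np.ceil(20.0 * np.sqrt(var_b) + 20.0).astype(np.int64)
    center = np.rint(mu_b).astype(np.int64)
    lo = np.maximum(np.minimum(center - half, sb - 5), 0)
    hi = np.minimum(np.maximum(center + half, sb + 5), T)
    lens = hi - lo + 1

    offsets = np.concatenate([[0], np.cumsum(lens)])
    total = int(offsets[-1])
    gene = np.repeat(np.arange(len(T)), lens)
    ks = np.arange(total) - np.repeat(offsets[:-1], lens) + np.repeat(lo, lens)

    la = stats.nbinom.logpmf(np.repeat(T, lens) - ks, np.repeat(ra, lens), np.repeat(pa, lens))
    lb = stats.nbinom.logpmf(ks, np.repeat(rb, lens), np.repeat(pb, lens))
    logp = la + lb
    seg_max = np.maximum.reduceat(logp, offsets[:-1])
    w = np.exp(logp - seg_max[gene])
    denom = np.add.reduceat(w, offsets[:-1])

    l_obs = stats.nbinom.logpmf(T - sb, ra, pa) + stats.nbinom.logpmf(sb, rb, pb)
    keep = logp <= (l_obs[gene] + 1e-8)
    numer = np.add.reduceat(np.where(keep, w, 0.0), offsets[:-1])
    p = numer / denom
    # degenerate: total of zero -> single outcome -> p = 1
    p = np.where(T == 0, 1.0, p)
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Scheme B: NB likelihood-ratio test with trended dispersion
# ---------------------------------------------------------------------------


def _nb_loglik(c: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood, counts c and means mu of equal shape,
    size r per row."""
    r = r[:, None]
    mu = np.maximum(mu, 1e-12)
    ll = (
        gammaln(c + r)
        - gammaln(r)
        - gammaln(c + 1)
        + r * np.log(r / (r + mu))
        + c * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _fit_q(c: np.ndarray, f: np.ndarray, r: np.ndarray, iters: int = 30) -> np.ndarray:
    """Per-gene NB MLE of the common normalised abundance q with fixed
    dispersion, means mu_j = f_j * q.  Newton iteration on the score; the
    moment estimate sum(c)/sum(f) is the starting point (and the exact MLE
    in the Poisson limit or for equal size factors)."""
    q = np.maximum(c.sum(axis=1) / f.sum(), 1e-8)
    for _ in range(iters):
        fq = f[None, :] * q[:, None]
        denom = r[:, None] + fq
        score = (c / np.maximum(q[:, None], 1e-12) - (c + r[:, None]) * f[None, :] / denom).sum(axis=1)
        hess = (
            -c / np.maximum(q[:, None] ** 2, 1e-24)
            + (c + r[:, None]) * (f[None, :] ** 2) / denom**2
        ).sum(axis=1)
        step = np.where(hess != 0, score / hess, 0.0)
        q_new = np.clip(q - step, 1e-8, None)
        if np.max(np.abs(q_new - q) / np.maximum(q, 1.0)) < 1e-10:
            q = q_new
            break
        q = q_new
    return q


def _lrt_test(
    counts: np.ndarray, f: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    phi = np.maximum(phi, 1e-8)
    r = 1.0 / phi
    q0 = _fit_q(counts, f, r)
    qa = _fit_q(counts[:, idx_a], f[idx_a], r)
    qb = _fit_q(counts[:, idx_b], f[idx_b], r)
    ll0 = _nb_loglik(counts, f[None, :] * q0[:, None], r)
    lla = _nb_loglik(counts[:, idx_a], f[None, idx_a] * qa[:, None], r)
    llb = _nb_loglik(counts[:, idx_b], f[None, idx_b] * qb[:, None], r)
    dev = np.maximum(2.0 * (lla + llb - ll0), 0.0)
    return stats.chi2.sf(dev, df=1)


# ---------------------------------------------------------------------------
# The estimator and its functional wrapper
# ---------------------------------------------------------------------------


class NBDifferentialExpression(BaseEstimator):
    """Two-scheme NB differential-expression screen with a consensus rule.

    Parameters
    ----------
    alpha : adjusted-p threshold applied to *both* schemes (default 0.001).
    min_fold : minimum displayed fold-change magnitude (default 2).
    prior_df_exact : prior degrees of freedom shrinking tagwise dispersions
        toward the common value in scheme A.
    prior_df_lrt : prior degrees of freedom shrinking per-gene dispersions
        toward the mean-dispersion trend in scheme B.
    control : group label treated as the denominator of fold changes; by
        default the first label in sorted order.

    Fitted attributes: ``size_factors_``, ``common_dispersion_``,
    ``trend_coef_``, ``results_`` (per-gene table), ``de_`` (consensus
    subset) and ``tallies_``.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        min_fold: float = DEFAULT_MIN_FOLD,
        prior_df_exact: float = 20.0,
        prior_df_lrt: float = 8.0,
        control: str | None = None,
    ):
        self.alpha = alpha
        self.min_fold = min_fold
        self.prior_df_exact = prior_df_exact
        self.prior_df_lrt = prior_df_lrt
        self.control = control

    def fit(self, X, y, *, annotation: pd.DataFrame | None = None):
        """Fit the screen.

        X : (n_samples, n_genes) count matrix (DataFrame or array).
        y : per-sample group labels, exactly two levels, >= 2 samples each.
        annotation : optional per-gene frame with chromosome/start/end,
            merged into ``results_``.
        """
        if isinstance(X, pd.DataFrame):
            counts = X.T.copy()  # genes x samples
        else:
            X = np.asarray(X)
            counts = pd.DataFrame(
                X.T, index=[f"gene{i:04d}" for i in range(X.shape[1])]
            )
        y = pd.Series(list(y), index=counts.columns)
        levels = sorted(y.unique())
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        control = self.control if self.control is not None else levels[0]
        if control not in levels:
            raise ValueError(f"control level {control!r} not among {levels}")
        treat = [l for l in levels if l != control][0]
        idx_a = np.flatnonzero((y == control).to_numpy())
        idx_b = np.flatnonzero((y == treat).to_numpy())
        if len(idx_a) < 2 or len(idx_b) < 2:
            raise ValueError("each group needs >= 2 samples")

        c = counts.to_numpy(dtype=float)
        all_zero = c.sum(axis=1) == 0
        self.size_factors_ = median_ratio_normalize(counts)
        f = self.size_factors_.to_numpy()
        yn = c / f[None, :]

        tested = ~all_zero
        ct = c[tested]
        yt = yn[tested]

        m, phi_g = _mom_dispersion(yt, [idx_a, idx_b])
        informative = m >= 1
        common = float(phi_g[informative].mean()) if informative.any() else 0.0
        df_g = len(idx_a) + len(idx_b) - 2
        phi_exact = (self.prior_df_exact * common + df_g * phi_g) / (
            self.prior_df_exact + df_g
        )
        a_tr, b_tr = _fit_trend(m, phi_g)
        phi_trend = a_tr / np.maximum(m, 0.5) + b_tr
        phi_lrt = (self.prior_df_lrt * phi_trend + df_g * phi_g) / (
            self.prior_df_lrt + df_g
        )
        self.common_dispersion_ = common
        self.trend_coef_ = (a_tr, b_tr)

        # scheme A on equalised pseudo-counts
        pseudo = np.rint(yt).astype(np.int64)
        p_exact = _exact_test(
            pseudo[:, idx_a].sum(axis=1),
            pseudo[:, idx_b].sum(axis=1),
            len(idx_a),
            len(idx_b),
            phi_exact,
        )
        # scheme B on raw counts with size-factor offsets
        p_lrt = _lrt_test(ct, f, idx_a, idx_b, phi_lrt)

        mean_a = yt[:, idx_a].mean(axis=1)
        mean_b = yt[:, idx_b].mean(axis=1)
        fold = (mean_b + 0.5) / (mean_a + 0.5)

        res = pd.DataFrame(index=counts.index)
        res["all_zero"] = all_zero
        for col in (
            "mean_control",
            "mean_mutant",
            "fold",
            "fold_display",
            "p_exact",
            "p_lrt",
            "padj_exact",
            "padj_lrt",
        ):
            res[col] = np.nan
        res.loc[tested, "mean_control"] = mean_a
        res.loc[tested, "mean_mutant"] = mean_b
        res.loc[tested, "fold"] = fold
        res.loc[tested, "fold_display"] = display_fold(fold)
        res.loc[tested, "p_exact"] = p_exact
        res.loc[tested, "p_lrt"] = p_lrt
        res.loc[tested, "padj_exact"] = multipletests(p_exact, method="fdr_bh")[1]
        res.loc[tested, "padj_lrt"] = multipletests(p_lrt, method="fdr_bh")[1]
        if annotation is not None:
            res = res.join(annotation, how="left")
        res.index.name = "gene"
        self.results_ = res
        self.groups_ = (control, treat)
        self.de_, self.tallies_ = consensus_filter(
            res, min_fold=self.min_fold, alpha=self.alpha
        )
        return self


def nb_de_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    annotation: pd.DataFrame | None = None,
    control: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> pd.DataFrame:
    """Run the two-scheme NB screen on a genes x samples count matrix and
    return the per-gene results table (see :class:`NBDifferentialExpression`)."""
    est = NBDifferentialExpression(alpha=alpha, min_fold=min_fold, control=control)
    est.fit(counts.T, list(groups), annotation=annotation)
    return est.results_


def consensus_filter(
    records: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep genes with displayed |fold| >= min_fold and *both* adjusted
    p-values below alpha; returns (subset, tallies)."""
    r = records
    ok = (
        r["fold_display"].abs() >= min_fold
    ) & (r["padj_exact"] < alpha) & (r["padj_lrt"] < alpha)
    if "all_zero" in r:
        ok &= ~r["all_zero"].astype(bool)
    sub = r[ok.fillna(False)]
    up = int((sub["fold_display"] > 0).sum())
    down = int((sub["fold_display"] < 0).sum())
    return sub, {"up": up, "down": down, "total": up + down}


def sex_linked_screen(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a DE set into X-linked downregulated and Y-linked
    upregulated genes, each sorted by chromosomal position."""
    if "chromosome" not in records:
        raise ValueError("records need a 'chromosome' column")
    x_down = records[
        (records["chromosome"].astype(str) == "X") & (records["fold_display"] < 0)
    ].sort_values("start")
    y_up = records[
        (records["chromosome"].astype(str) == "Y") & (records["fold_display"] > 0)
    ].sort_values("start")
    return x_down, y_up


def rank_insertion_candidates(
    records: pd.DataFrame,
    insertion_position: int,
    chromosome: str = "10",
    min_fold: float = 4.0,
) -> pd.DataFrame:
    """Rank upregulated genes on the insertion chromosome by distance to the
    insertion position.

    Distance is the nearest gene-boundary distance, zero when the gene spans
    the position; downregulated genes are never ranked (the screened
    mechanism is relief of repression).
    """
    r = records[
        (records["chromosome"].astype(str) == str(chromosome))
        & (records["fold_display"] >= min_fold)
    ].copy()
    if r.empty:
        return r.assign(distance=pd.Series(dtype=float))
    start = r["start"].to_numpy(float)
    end = r["end"].to_numpy(float)
    pos = float(insertion_position)
    dist = np.where(
        (start <= pos) & (pos <= end),
        0.0,
        np.minimum(np.abs(start - pos), np.abs(end - pos)),
    )
    r["distance"] = dist
    return r.sort_values("distance")


def hypergeom_enrichment(
    selected: Sequence[str],
    universe: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    alpha: float = 0.01,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Two-sided hypergeometric term enrichment with BH correction.

    For each term, tests whether its overlap with ``selected`` is larger
    (enrichment) or smaller (depletion) than expected from the universe;
    p is twice the smaller tail, capped at 1.  A term passes when its fold
    enrichment is at least ``min_fold`` away from 1 in either direction and
    its BH-adjusted p is below ``alpha``.
    """
    sel = set(selected)
    uni = set(universe)
    if not sel:
        raise ValueError("empty gene set")
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(uni), len(sel)
    rows = []
    for term, genes in term_map.items():
        members = set(genes) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & sel)
        p_enr = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_dep = float(stats.hypergeom.cdf(k, N, K, n))
        p = min(1.0, 2.0 * min(p_enr, p_dep))
        fold = (k / n) / (K / N)
        rows.append((term, k, n, K, N, fold, p))
    out = pd.DataFrame(
        rows,
        columns=["term", "hits", "set_size", "universe_hits", "universe_size", "fold", "p"],
    )
    if out.empty:
        out["padj"] = []
        out["passes"] = []
        return out
    out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["passes"] = (
        ((out["fold"] >= min_fold) | (out["fold"] <= 1.0 / min_fold))
        & (out["padj"] < alpha)
    )
    return out.sort_values("padj").reset_index(drop=True)
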