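"""Per-probe variability statistics and group dispersion summaries.

The central statistic is the within-group sample standard deviation of each
probe's normalized log-ratio.  Variance heterogeneity between groups is
assessed per probe with Bartlett's chi-square test (pairwise or across all
three groups); the genome-wide shift in variability is summarized by an
unequal-variance (Welch) t-test on the SD distributions, a p-value frequency
histogram, and the dispersion of principal-component scores per group.
Technical-artifact diagnostics correlate the per-group SD with the
reference-pool SD across arrays and with probe GC content (Pearson r): no
correlation indicates the inter-sample variation is biological rather than a
probe-intrinsic hybridization artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .preprocess import SignalMatrix

logger = logging.getLogger(__name__)

PAIRWISE_COMPARISONS = (("control", "F1"), ("F1", "F6"))


@dataclass
class PcaSummary:
    scores: pd.DataFrame                 # arrays x components
    explained_variance_ratio: np.ndarray
    group_component_sd: pd.DataFrame     # groups x components
    group_volume: pd.Series              # product of component SDs per group


def group_sd(sm: SignalMatrix, min_n: int = 3) -> pd.DataFrame:
    """Within-group sample SD (denominator n-1) per probe.

    A probe is marked missing (NaN) for a group when fewer than ``min_n`` of
    that group's arrays retain it — below that the SD is not meaningful.
    """
    out = {}
    for grp in pd.unique(sm.groups):
        vals = sm.values[sm.arrays_of(grp)]
        n = vals.notna().sum(axis=1)
        sd = vals.std(axis=1, ddof=1)
        sd[n < min_n] = np.nan
        out[grp] = sd
    return pd.DataFrame(out, index=sm.values.index)


def bartlett_per_probe(sm: SignalMatrix, groups=None) -> pd.DataFrame:
    """Bartlett's test of equal variances, vectorized across probes.

    ``groups`` selects which treatment groups enter the test (default: all in
    the design).  Probes where any group has fewer than 2 values or zero
    variance are flagged (NaN statistic and p).  Returns a DataFrame with
    columns ``statistic``, ``pvalue``, ``df``.
    """
    if groups is None:
        groups = list(pd.unique(sm.groups))
    if len(groups) < 2:
        raise ValueError("Bartlett's test needs at least 2 groups")
    k = len(groups)
    ns, variances = [], []
    for grp in groups:
        vals = sm.values[sm.arrays_of(grp)].to_numpy(dtype=float)
        n = np.isfinite(vals).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            var = np.nanvar(vals, axis=1, ddof=1)
        ns.append(n)
        variances.append(var)
    ns = np.vstack(ns)           # k x probes
    variances = np.vstack(variances)
    N = ns.sum(axis=0)
    valid = (ns >= 2).all(axis=0) & (variances > 0).all(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((ns - 1) * variances).sum(axis=0) / (N - k)
        T = (N - k) * np.log(sp2) - ((ns - 1) * np.log(variances)).sum(axis=0)
        C = 1.0 + (1.0 / (3.0 * (k - 1))) * (
            (1.0 / (ns - 1)).sum(axis=0) - 1.0 / (N - k))
        T = T / C
    T = np.where(valid, T, np.nan)
    p = np.where(valid, stats.chi2.sf(np.where(valid, T, 0.0), k - 1), np.nan)
    return pd.DataFrame({"statistic": T, "pvalue": p, "df": k - 1},
                        index=sm.values.index)


def pvalue_histogram(pvalues, n_bins: int = 20) -> pd.DataFrame:
    """Counts of p-values over equal-width bins on [0, 1].

    An accumulation of probes in the lowest bin, relative to the uniform
    expectation ``n / n_bins``, quantifies an excess of probes with higher
    variance in one group than the other.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "uniform_expected": p.size / n_bins,
    })


def sd_distribution_test(sd_a, sd_b):
    """Welch unequal-variance t-test comparing two SD distributions.

    Returns ``(t, p, summary)`` where the summary holds box-plot quantiles
    (10th/25th/50th/75th/90th percentiles) and means for both inputs.
    """
    a = np.asarray(sd_a, dtype=float)
    b = np.asarray(sd_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each input needs at least 2 finite values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate inputs: both samples constant")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    qs = [10, 25, 50, 75, 90]
    summary = pd.DataFrame(
        {"a": np.append(np.percentile(a, qs), a.mean()),
         "b": np.append(np.percentile(b, qs), b.mean())},
        index=[f"p{q}" for q in qs] + ["mean"])
    return float(t), float(p), summary


def pca_dispersion(sm: SignalMatrix, n_components: int = 3) -> PcaSummary:
    """Principal components of arrays over probe space and per-group spread.

    Probes with any missing value are excluded; probe-wise mean-centering,
    no scaling (log-ratios share a scale).  The per-group SD of the scores on
    the first components measures each group's dispersion; their product is
    an ellipsoid-volume proxy.
    """
    vals = sm.values.dropna(axis=0, how="any")
    if vals.shape[0] <= vals.shape[1]:
        raise ValueError("need more complete probes than arrays for PCA")
    X = vals.to_numpy(dtype=float).T          # arrays x probes
    X = X - X.mean(axis=0, keepdims=True)     # probe-wise centering
    k = min(n_components, X.shape[0] - 1)
    if not np.any(X):
        # all arrays identical: zero scores, zero dispersion
        scores = np.zeros((X.shape[0], k))
        evr = np.zeros(k)
    else:
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
    comp_cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=vals.columns, columns=comp_cols)
    grp_sd = scores_df.groupby(sm.groups).std(ddof=1)
    return PcaSummary(
        scores=scores_df,
        explained_variance_ratio=evr,
        group_component_sd=grp_sd,
        group_volume=grp_sd.prod(axis=1),
    )


def reference_pool_sd(reference_signals: pd.DataFrame) -> pd.Series:
    """Intrinsic probe variability: SD of the reference-pool channel across
    all arrays (the same pooled sample is hybridized on every array, so this
    spread is purely technical)."""
    return reference_signals.std(axis=1, ddof=1)


def technical_diagnostics(sd_table: pd.DataFrame, ref_sd: pd.Series,
                          gc: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each group's probe SD with the reference-pool
    SD and with probe GC content.

    Near-zero correlations indicate that inter-sample variation is not driven
    by probe-intrinsic technical variability or base composition.  Rows with
    any missing value are excluded pairwise; a zero-variance vector yields a
    missing r.
    """
    rows = []
    for grp in sd_table.columns:
        for name, other in [("reference_pool_sd", ref_sd), ("gc", gc)]:
            x = sd_table[grp]
            aligned = pd.concat([x, other.reindex(x.index)], axis=1).dropna()
            if len(aligned) < 3 or aligned.iloc[:, 0].std() == 0 \
                    or aligned.iloc[:, 1].std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(aligned.iloc[:, 0], aligned.iloc[:, 1])
            rows.append({"group": grp, "diagnostic": name, "r": r,
                         "pvalue": p, "n": len(aligned)})
    return pd.DataFrame(rows)


def variability_table(sm: SignalMatrix, reference_signals: pd.DataFrame,
                      annotation: pd.DataFrame, min_n: int = 3,
                      comparisons=PAIRWISE_COMPARISONS) -> pd.DataFrame:
    """Assemble the per-probe variability table: per-group SDs, pairwise
    Bartlett statistics/p-values, reference-pool SD and GC content."""
    table = group_sd(sm, min_n=min_n)
    table.columns = [f"sd_{g}" for g in table.columns]
    for a, b in comparisons:
        bt = bartlett_per_probe(sm, groups=[a, b])
        table[f"bartlett_T_{a}_vs_{b}"] = bt["statistic"]
        table[f"bartlett_p_{a}_vs_{b}"] = bt["pvalue"]
    table["reference_pool_sd"] = reference_pool_sd(reference_signals).reindex(table.index)
    table["gc"] = annotation["gc"].reindex(table.index)
    return table
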