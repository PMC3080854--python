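"""Quality control and normalization of raw two-color array signals.

Raw probe log-ratios pass through two steps before variance analysis:

1. low-signal filtering — features whose raw mean intensity lies within
   ``k`` standard deviations of the array background (default k = 2.6) are
   removed, per array;
2. LOESS normalization — the intensity-dependent dye-bias trend is removed by
   local regression of the log-ratio on log10 mean intensity, then each array
   is median-scaled to zero.  Both test and reference samples underwent the
   same enrichment, so normalized signals are expected to center around 0.

A Shapiro–Wilk helper is provided to confirm that normalized probe signals
are approximately normally distributed, which the downstream variance tests
assume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)


@dataclass
class SignalMatrix:
    """Probe x array log2 Cy3/Cy5 ratios with the array -> group design."""

    values: pd.DataFrame
    design: pd.DataFrame  # columns: array_id, group
    provenance: str = "raw"  # raw | filtered | normalized

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.design["array_id"])
        if missing:
            raise ValueError(f"arrays missing from design: {sorted(missing)}")

    @property
    def groups(self) -> pd.Series:
        return self.design.set_index("array_id")["group"].loc[self.values.columns]

    def arrays_of(self, group: str) -> list[str]:
        cols = [a for a in self.values.columns if self.groups[a] == group]
        if not cols:
            raise KeyError(f"no arrays in group {group!r}")
        return cols


def read_signal_matrix(signals_path, design_path, provenance="raw") -> SignalMatrix:
    values = pd.read_csv(signals_path, sep="\t", index_col="probe_id")
    design = pd.read_csv(design_path, sep="\t")
    return SignalMatrix(values=values, design=design, provenance=provenance)


def write_signal_matrix(sm: SignalMatrix, path) -> None:
    sm.values.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def filter_low_signal(signals: pd.DataFrame, intensity: pd.DataFrame,
                      background_mean: float, background_sd: float,
                      k: float = 2.6, per_array: bool = True):
    """Remove features whose raw intensity is within ``k`` SD of background.

    A feature (probe, array) with intensity <= background_mean + k * background_sd
    is set to missing; probes left with no retained value on any array are
    dropped.  With ``per_array=False`` a probe is removed on all arrays when
    its mean intensity across arrays falls inside the band.

    Returns ``(filtered signals, report)`` where the report lists removed
    feature counts per array and the removed probe ids.
    """
    if not np.isfinite(background_mean) or not np.isfinite(background_sd):
        raise ValueError("background parameters must be finite")
    if background_sd <= 0:
        raise ValueError("background_sd must be > 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    threshold = background_mean + k * background_sd
    intensity = intensity.reindex(index=signals.index, columns=signals.columns)
    if per_array:
        low = intensity.to_numpy() <= threshold
    else:
        low = np.broadcast_to(
            (intensity.mean(axis=1).to_numpy() <= threshold)[:, None],
            signals.shape).copy()
    low |= ~np.isfinite(intensity.to_numpy())
    out = signals.mask(pd.DataFrame(low, index=signals.index,
                                    columns=signals.columns))
    dropped_rows = out.index[out.isna().all(axis=1)]
    out = out.drop(index=dropped_rows)
    report = {
        "threshold": threshold,
        "removed_per_array": pd.Series(low.sum(axis=0), index=signals.columns),
        "removed_features": [
            (signals.index[i], signals.columns[j])
            for i, j in zip(*np.nonzero(low))
        ],
        "dropped_probes": list(dropped_rows),
    }
    logger.info("low-signal filter: threshold=%.3f, %d features removed, "
                "%d probes dropped entirely", threshold, int(low.sum()),
                len(dropped_rows))
    return out, report


# ---------------------------------------------------------------------------
# LOESS normalization
# ---------------------------------------------------------------------------

def loess_normalize(signals: pd.DataFrame, intensity: pd.DataFrame,
                    span: float = 0.3) -> pd.DataFrame:
    """Remove the intensity-dependent trend per array, then median-center.

    The trend is estimated by locally weighted regression (LOWESS) of the
    log-ratio on log10 mean intensity with the given span, evaluated at the
    observed covariate values, and subtracted; the per-array median is then
    subtracted so every array has median exactly 0.  Missing values are
    ignored during fitting and preserved in the output.
    """
    if signals.shape[0] < 20:
        raise ValueError("need at least 20 features per array for normalization")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    intensity = intensity.reindex(index=signals.index, columns=signals.columns)
    out = signals.copy()
    for col in signals.columns:
        y = signals[col].to_numpy(dtype=float)
        x = np.log10(np.clip(intensity[col].to_numpy(dtype=float), 1.0, None))
        ok = np.isfinite(y) & np.isfinite(x)
        resid = y.copy()
        if ok.sum() >= 20 and np.ptp(x[ok]) > 0:
            delta = 0.01 * np.ptp(x[ok])
            fitted = lowess(y[ok], x[ok], frac=span, delta=delta,
                            return_sorted=False)
            resid[ok] = y[ok] - fitted
        else:
            warnings.warn(f"array {col}: degenerate intensity covariate; "
                          "skipping trend removal, median-centering only")
        med = np.nanmedian(resid)
        out[col] = resid - med
    return out


def normalize_signal_matrix(sm: SignalMatrix, intensity: pd.DataFrame,
                            background_mean: float, background_sd: float,
                            k: float = 2.6, span: float = 0.3):
    """filter_low_signal + loess_normalize, preserving the design."""
    filtered, report = filter_low_signal(sm.values, intensity,
                                         background_mean, background_sd, k=k)
    normalized = loess_normalize(filtered, intensity.loc[filtered.index], span=span)
    return SignalMatrix(values=normalized, design=sm.design,
                        provenance="normalized"), report


def shapiro_normality(x):
    """Shapiro–Wilk test of normality; returns (W, p)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)
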