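"""Distribution comparison and replicate aggregation for per-cell counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute difference between the two empirical CDFs;
    the p-value is the asymptotic two-sided one (sample sizes in the
    intended use are hundreds of cells).  At the conventional 5% level,
    p >= 0.05 means the two count distributions are indistinguishable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _spread(values: np.ndarray, kind: str, axis: int = 0) -> np.ndarray:
    n = values.shape[axis]
    if n < 2:
        return np.zeros_like(values.mean(axis=axis))
    sd = values.std(axis=axis, ddof=1)
    if kind == "sd":
        return sd
    if kind == "sem":
        return sd / np.sqrt(n)
    raise ValueError("spread must be 'sd' or 'sem'")


@dataclass(eq=False)
class ReplicateSummary:
    """Per-count proportions averaged over replicates.

    ``proportions[r, k]`` is the fraction of cells in replicate r with
    count k (counts above ``max_count`` pooled into the last bin).
    """

    bins: np.ndarray
    proportions: np.ndarray
    mean_proportion: np.ndarray
    spread_proportion: np.ndarray
    mean_count: float
    count_spread: float
    n_replicates: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.bins,
                "mean_proportion": self.mean_proportion,
                "spread": self.spread_proportion,
            }
        )


def aggregate_replicates(
    replicates: list, max_count: int, spread: str = "sd"
) -> ReplicateSummary:
    """Average per-count proportions over independent replicates.

    For each replicate the proportion of cells with count 0..max_count is
    computed (counts beyond the last bin are pooled into it); the summary
    is the mean proportion per bin with its spread across replicates
    ('sd', the default, or 'sem'), plus the mean per-cell count and its
    spread the same way.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    arrs = []
    for rep in replicates:
        arr = np.asarray(rep)
        if arr.size == 0:
            raise ValueError("empty replicate")
        if (arr < 0).any():
            raise ValueError("counts must be >= 0")
        arrs.append(arr)
    bins = np.arange(max_count + 1)
    props = np.zeros((len(arrs), max_count + 1))
    for i, arr in enumerate(arrs):
        pooled = np.minimum(arr, max_count)
        props[i] = np.bincount(pooled.astype(int), minlength=max_count + 1) / arr.size
    rep_means = np.array([a.mean() for a in arrs])
    return ReplicateSummary(
        bins=bins,
        proportions=props,
        mean_proportion=props.mean(axis=0),
        spread_proportion=_spread(props, spread),
        mean_count=float(rep_means.mean()),
        count_spread=float(_spread(rep_means, spread)),
        n_replicates=len(arrs),
    )


def dose_response(conditions: dict, spread: str = "sd") -> pd.DataFrame:
    """Summarise per-cell mean intensities per induction condition.

    ``conditions`` maps a condition label (e.g. inducer concentration) to
    the per-cell mean-intensity-per-area values measured under it.  The
    returned table preserves the input order: condition, mean, spread, n.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    rows = []
    for label, values in conditions.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"condition {label!r} has no values")
        rows.append(
            {
                "condition": label,
                "mean": float(arr.mean()),
                "spread": float(_spread(arr, spread)),
                "n": int(arr.size),
            }
        )
    return pd.DataFrame(rows, columns=["condition", "mean", "spread", "n"])
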