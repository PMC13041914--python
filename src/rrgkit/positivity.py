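"""Nuclear marker positivity from per-nucleus intensity tables.

The module starts where segmentation ends: a table of per-nucleus median
channel intensities with organoid (or tile/slice) identifiers.  Thresholds are
derived from the intensity histogram (Otsu by default, first-valley or manual
as alternatives), nuclei are classified positive when their median intensity
strictly exceeds the threshold, and positivity is aggregated per organoid with
a global conditional co-expression summary P(ERalpha+ | PR+).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PositivityResult",
    "threshold_from_histogram",
    "classify_and_aggregate",
    "summarize_over_organoids",
]


def _otsu_exact(x: np.ndarray) -> float:
    """Otsu's threshold computed on the sorted sample (no histogram binning).

    Between-class variance is evaluated at every split between consecutive
    distinct values; the threshold is the midpoint of the pair straddling the
    best split, which places it centrally in the empty gap between
    well-separated classes instead of at a bin edge.
    """
    xs = np.sort(x)
    n = xs.size
    csum = np.cumsum(xs)
    total = csum[-1]
    k = np.arange(1, n)  # class 0 = xs[:k]
    w0 = k / n
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    between = w0 * (1 - w0) * (mu0 - mu1) ** 2
    valid = xs[1:] > xs[:-1]  # cannot split inside a tie group
    between[~valid] = -np.inf
    best = int(np.argmax(between))
    return float(0.5 * (xs[best] + xs[best + 1]))


@dataclass
class PositivityResult:
    """Per-organoid positivity fractions plus global co-expression."""

    per_organoid: pd.DataFrame  # index organoid_id; n_nuclei, pct_<ch>, pct_double
    p_er_given_pr: float
    thresholds: dict[str, float]
    channels: tuple[str, str]


def threshold_from_histogram(
    intensities,
    method: str = "otsu",
    manual: float | None = None,
    bins: int = 256,
) -> float:
    """Derive a positivity threshold from the intensity histogram.

    ``otsu`` maximises between-class variance over all splits of the sorted
    sample on the log1p intensity scale, where fluorescence background and
    positive components are close to Gaussian (raw-scale Otsu is biased into
    the skewed positive class); the threshold is returned on the raw scale.
    ``first_valley`` returns the first local minimum after the dominant
    low-intensity (background) peak of a ``bins``-bin histogram; ``manual``
    passes ``manual`` through -- the histogram-then-visual-refinement
    workflow's escape hatch.
    """
    x = np.asarray(intensities, dtype=float)
    if method == "manual":
        if manual is None:
            raise ValueError("manual method requires a threshold value")
        return float(manual)
    if x.size and np.all(x == x[0]):
        raise ValueError("constant intensities: no separable classes")
    if x.size < 50:
        warnings.warn(f"only {x.size} nuclei; histogram threshold may be unstable", stacklevel=2)
    if method == "otsu":
        if (x < 0).any():
            raise ValueError("intensities must be nonnegative")
        return float(np.expm1(_otsu_exact(np.log1p(x))))
    if method == "first_valley":
        counts, edges = np.histogram(x, bins=bins)
        win = max(3, bins // 32) | 1  # odd smoothing window
        smooth = np.convolve(counts, np.ones(win) / win, mode="same")
        peak = int(np.argmax(smooth))
        height = smooth[peak]
        candidates = [
            i for i in range(peak + 1, bins - 1)
            if smooth[i] <= smooth[i - 1] and smooth[i] < smooth[i + 1]
        ]
        # a valley should dip well below the background peak; fall back to the
        # first raw local minimum only if no such dip exists
        deep = [i for i in candidates if smooth[i] <= 0.5 * height]
        pick = deep[0] if deep else (candidates[0] if candidates else None)
        if pick is None:
            raise ValueError("no valley found after the dominant peak")
        # the valley may be a flat stretch (empty bins); take its midpoint
        end = pick
        while end + 1 < bins - 1 and smooth[end + 1] <= smooth[pick] + 1e-12:
            end += 1
        return float(0.5 * (edges[pick] + edges[end + 1]))
    raise ValueError(f"unknown method {method!r}")


def classify_and_aggregate(
    table: pd.DataFrame,
    thresholds: dict[str, float],
    channels: tuple[str, str] = ("ER", "PR"),
) -> PositivityResult:
    """Classify nuclei (strictly above threshold = positive) and aggregate.

    Returns per-organoid nucleus counts, single-marker and double-positive
    percentages, and the global conditional co-expression P(ch1+ | ch2+)
    (ERalpha given PR by default).  Organoids appear in the table only if they
    contributed nuclei, so the zero-nucleus case cannot arise from grouping;
    an entirely empty table is an error.
    """
    if table.empty:
        raise ValueError("empty intensity table")
    for ch in channels:
        if ch not in thresholds:
            raise ValueError(f"no threshold supplied for channel {ch!r}")
        if ch not in table.columns:
            raise KeyError(f"channel column {ch!r} missing from table")
    ch1, ch2 = channels
    df = table.copy()
    for ch in channels:
        df[f"_{ch}_pos"] = df[ch] > thresholds[ch]
    df["_double"] = df[f"_{ch1}_pos"] & df[f"_{ch2}_pos"]

    grouped = df.groupby("organoid_id", observed=True)
    per = pd.DataFrame(
        {
            "n_nuclei": grouped.size(),
            f"pct_{ch1}": 100.0 * grouped[f"_{ch1}_pos"].mean(),
            f"pct_{ch2}": 100.0 * grouped[f"_{ch2}_pos"].mean(),
            "pct_double": 100.0 * grouped["_double"].mean(),
        }
    )
    n_ch2 = int(df[f"_{ch2}_pos"].sum())
    p_cond = float(df.loc[df[f"_{ch2}_pos"], f"_{ch1}_pos"].mean()) if n_ch2 else float("nan")
    return PositivityResult(
        per_organoid=per,
        p_er_given_pr=p_cond,
        thresholds={ch: float(thresholds[ch]) for ch in channels},
        channels=channels,
    )


def summarize_over_organoids(result: PositivityResult) -> pd.DataFrame:
    """Median and range of the per-organoid percentages (one point per organoid)."""
    per = result.per_organoid
    cols = [c for c in per.columns if c.startswith("pct_")]
    return pd.DataFrame(
        {
            "median": per[cols].median(),
            "min": per[cols].min(),
            "max": per[cols].max(),
            "n_organoids": len(per),
        }
    )
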