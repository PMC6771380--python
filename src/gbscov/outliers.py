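"""Robust outlier calling on denoised coverage profiles and stretch assembly.

Windows whose denoised log2 ratio deviates strongly from the sample's own
genome-wide distribution are flagged with a robust z-score based on the
median and the MAD (median absolute deviation, scaled by 1.4826 for
consistency with the normal standard deviation):

    z_i = (p_i - median(p)) / (1.4826 * median(|p - median(p)|))

A window is an outlier when |z_i| exceeds the normal quantile for the
chosen probability (99.99% by default, threshold ~3.719).  Consecutive
outlier windows are then assembled into stretches: a stretch may bridge a
single non-outlier window but never two in a row, must start and end on
outlier windows, and must contain a minimum number of outlier windows
(3 by default; 30 for the conservative "long stretch" screen used on
large, lower-coverage collections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .profiles import DenoisedProfile
from .windows import GenomeWindows

MAD_SCALE = 1.4826  # normal-consistency factor
DEFAULT_PROB = 0.9999
DEFAULT_MIN_OUTLIERS = 3
LONG_MIN_OUTLIERS = 30


@dataclass
class OutlierCalls:
    """Per-window robust z-scores and outlier flags for one sample."""

    sample_id: str
    z: np.ndarray
    flag: np.ndarray  # bool per window
    threshold: float
    sidedness: str
    mad_zero: bool = False


@dataclass(frozen=True)
class OutlierStretch:
    """A called segment of consecutive outlier windows on one chromosome.

    Window indices are global grid indices, inclusive on both ends;
    bp coordinates are 0-based half-open.  ``n_outliers`` counts flagged
    windows only (bridged gap windows are not counted).
    """

    chrom: str
    start_window: int
    end_window: int
    start_bp: int
    end_bp: int
    n_outliers: int
    direction: str  # 'increased' | 'decreased'
    mean_p: float

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_windows(self) -> int:
        return self.end_window - self.start_window + 1


def call_outliers(
    profile: DenoisedProfile,
    prob: float = DEFAULT_PROB,
    sidedness: str = "two_sided",
) -> OutlierCalls:
    """Flag outlier windows with a MAD-based robust z-score.

    The median and MAD are computed over the sample's genome-wide
    denoised profile.  ``sidedness='two_sided'`` flags |z| above the
    normal quantile; 'upper' flags only positive deviations.  When the
    MAD is zero (degenerate, e.g. constant profile) no window is flagged
    and a warning is emitted.
    """
    p = np.asarray(profile.p, dtype=np.float64)
    if p.size < 2:
        raise ValueError("profile must contain at least 2 windows")
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    if sidedness not in ("two_sided", "upper"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    med = np.median(p)
    mad = MAD_SCALE * np.median(np.abs(p - med))
    threshold = float(norm.ppf(prob))
    if mad == 0:
        warnings.warn(
            f"sample {profile.sample_id!r}: MAD of the denoised profile is zero; "
            "no outliers can be called",
            stacklevel=2,
        )
        z = np.zeros_like(p)
        flag = np.zeros(p.size, dtype=bool)
        return OutlierCalls(profile.sample_id, z, flag, threshold, sidedness,
                            mad_zero=True)
    z = (p - med) / mad
    if sidedness == "two_sided":
        flag = np.abs(z) > threshold
    else:
        flag = z > threshold
    return OutlierCalls(profile.sample_id, z, flag, threshold, sidedness)


def _grouped_runs(flag_idx: np.ndarray) -> list[tuple[int, int, int]]:
    """Group flagged indices into gap-tolerant runs.

    Two flagged windows belong to the same run iff at most one unflagged
    window separates them (index difference <= 2).  Returns
    (first, last, n_flagged) per run.
    """
    runs: list[tuple[int, int, int]] = []
    if flag_idx.size == 0:
        return runs
    start = prev = int(flag_idx[0])
    n = 1
    for i in flag_idx[1:]:
        i = int(i)
        if i - prev <= 2:
            n += 1
        else:
            runs.append((start, prev, n))
            start, n = i, 1
        prev = i
    runs.append((start, prev, n))
    return runs


def find_stretches(
    calls: OutlierCalls,
    windows: GenomeWindows,
    min_outliers: int = DEFAULT_MIN_OUTLIERS,
    profile: DenoisedProfile | None = None,
) -> list[OutlierStretch]:
    """Assemble flagged windows into maximal gap-tolerant stretches.

    Stretches are per-chromosome runs of flagged windows in which a
    single unflagged window may be bridged but two consecutive unflagged
    windows always terminate the run; runs start and end on flagged
    windows and need at least ``min_outliers`` flagged windows.

    When ``profile`` is given, the direction (increased/decreased
    coverage) and the mean denoised value over the stretch are filled in;
    otherwise direction is derived from the z-scores.
    """
    if min_outliers < 1:
        raise ValueError("min_outliers must be >= 1")
    if calls.flag.size != windows.n_windows:
        raise ValueError("calls do not match the window grid")
    values = profile.p if profile is not None else calls.z
    stretches: list[OutlierStretch] = []
    for name, _ in windows.chromosomes:
        sl = windows.chrom_slice(name)
        offset = sl.start
        flag_idx = np.flatnonzero(calls.flag[sl])
        for first, last, n_flagged in _grouped_runs(flag_idx):
            if n_flagged < min_outliers:
                continue
            lo, hi = offset + first, offset + last
            mean_p = float(np.mean(values[lo:hi + 1]))
            stretches.append(OutlierStretch(
                chrom=name,
                start_window=lo,
                end_window=hi,
                start_bp=int(windows.starts[lo]),
                end_bp=int(windows.ends[hi]),
                n_outliers=n_flagged,
                direction="increased" if mean_p > 0 else "decreased",
                mean_p=mean_p,
            ))
    return stretches


def longest_stretch(
    stretches: Sequence[OutlierStretch],
    windows: GenomeWindows | None = None,
) -> OutlierStretch | None:
    """The stretch with the most outlier windows.

    Ties break by larger bp span, then by chromosome order on the grid
    (falling back to name order), then by lowest start coordinate.
    """
    if not stretches:
        return None
    if windows is not None:
        order = {name: i for i, name in enumerate(windows.chrom_names)}
        chrom_rank = lambda s: order.get(s.chrom, len(order))  # noqa: E731
    else:
        chrom_rank = lambda s: s.chrom  # noqa: E731
    return min(
        stretches,
        key=lambda s: (-s.n_outliers, -s.span_bp, chrom_rank(s), s.start_bp),
    )


def classify_direction(stretch: OutlierStretch, profile: DenoisedProfile) -> str:
    """'increased' if the mean denoised value over the stretch is positive,
    'decreased' otherwise (an exact zero mean counts as decreased)."""
    mean_p = float(np.mean(profile.p[stretch.start_window:stretch.end_window + 1]))
    return "increased" if mean_p > 0 else "decreased"


def overlap_fraction(
    stretch_region: tuple[str, int, int],
    annotated: tuple[str, int, int],
) -> tuple[float, float]:
    """Overlap of a detected region with an annotated one.

    Returns ``(fraction_of_annotated, jaccard)`` where the first is
    intersection length over the annotated region's length and the second
    is intersection over union.  Intervals are half-open; regions on
    different chromosomes do not overlap.
    """
    s_chrom, s_lo, s_hi = stretch_region
    a_chrom, a_lo, a_hi = annotated
    if a_hi <= a_lo:
        raise ValueError("annotated interval has zero or negative length")
    if s_hi < s_lo:
        raise ValueError("stretch interval has negative length")
    if s_chrom != a_chrom:
        return 0.0, 0.0
    inter = max(0, min(s_hi, a_hi) - max(s_lo, a_lo))
    union = (s_hi - s_lo) + (a_hi - a_lo) - inter
    return inter / (a_hi - a_lo), (inter / union if union > 0 else 0.0)


@dataclass
class FrequencySummary:
    """How often each window is flagged across a collection."""

    n_samples: int
    n_flagged: np.ndarray  # int per window
    fraction: np.ndarray  # in [0, 1]
    threshold_fraction: float
    robust_windows: np.ndarray  # indices with fraction >= threshold


def frequency_summary(
    calls_collection: Sequence[OutlierCalls],
    threshold_fraction: float,
) -> FrequencySummary:
    """Per-window outlier frequency over a collection of samples.

    The robust set contains windows flagged in at least
    ``threshold_fraction`` of the samples (inclusive boundary — a window
    flagged in exactly 3% of genotypes is in the 3% set).
    """
    if not calls_collection:
        raise ValueError("no outlier calls supplied")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    n_windows = calls_collection[0].flag.size
    for c in calls_collection:
        if c.flag.size != n_windows:
            raise ValueError("inconsistent window grids across samples")
    n_flagged = np.sum([c.flag for c in calls_collection], axis=0).astype(np.int64)
    n_samples = len(calls_collection)
    fraction = n_flagged / n_samples
    # nudge for float division: 3/100 must land in the 0.03 set
    robust = np.flatnonzero(fraction >= threshold_fraction - 1e-12)
    return FrequencySummary(n_samples, n_flagged, fraction,
                            threshold_fraction, robust)
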