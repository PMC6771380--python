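"""Normalization, reference profiles, log2 coverage ratios, and denoising.

Raw window counts depend on library size and on the strong positional
trend of GBS coverage (telomere-high, centromere-low), so each sample is
first scaled to counts per million read starts (c), then compared window
by window against a reference profile r — either a known ancestor's
normalized counts or the per-window median over the collection:

    d_i = log2((c_i + eps) / (r_i + eps)),    eps = 1e6 / N

where N is the genome-wide window count, so eps is the expected number of
reads per window and dampens the noise of poorly covered windows.  The
log ratio is finally smoothed with a centered rolling mean of width 5,
applied per chromosome, yielding the denoised profile p that downstream
outlier calling operates on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .windows import GenomeWindows, WindowCountVector

DEFAULT_SMOOTH_K = 5


@dataclass
class NormalizedCounts:
    """Per-window counts scaled to a per-million-read-starts basis."""

    sample_id: str
    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.float64)
        if (self.c < 0).any():
            raise ValueError("normalized counts must be non-negative")


@dataclass
class ReferenceProfile:
    """Expected normalized count per window.

    mode 'ancestor' copies one sample's normalized counts; mode 'median'
    takes the per-window median over all supplied samples.
    """

    r: np.ndarray
    mode: str
    source: tuple[str, ...]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)


@dataclass
class LogRatioProfile:
    sample_id: str
    d: np.ndarray


@dataclass
class DenoisedProfile:
    sample_id: str
    p: np.ndarray


def normalize(counts: WindowCountVector) -> NormalizedCounts:
    """Scale raw window counts to counts per million passing reads."""
    if counts.total_passing <= 0:
        raise ValueError(f"sample {counts.sample_id!r} has no passing reads")
    c = counts.counts.astype(np.float64) / counts.total_passing * 1e6
    return NormalizedCounts(counts.sample_id, c)


def build_reference(
    samples: Sequence[NormalizedCounts],
    mode: str = "median",
    ancestor_id: str | None = None,
    leave_one_out: str | None = None,
) -> ReferenceProfile:
    """Build the reference profile r.

    Parameters
    ----------
    mode
        'ancestor': r is the named sample's normalized counts verbatim.
        'median': r_i is the per-window median over all samples; with an
        even number of samples this is the mean of the two central order
        statistics.
    leave_one_out
        When set (median mode only), that sample is excluded from the
        median — off by default, i.e. the query sample contributes to its
        own reference, matching a median over *all* samples.
    """
    if not samples:
        raise ValueError("no samples supplied")
    if mode == "ancestor":
        if ancestor_id is None:
            raise ValueError("ancestor mode requires ancestor_id")
        for s in samples:
            if s.sample_id == ancestor_id:
                return ReferenceProfile(s.c.copy(), "ancestor", (ancestor_id,))
        raise ValueError(f"ancestor {ancestor_id!r} not among supplied samples")
    if mode == "median":
        pool = [s for s in samples if s.sample_id != leave_one_out]
        if not pool:
            raise ValueError("leave-one-out removed every sample")
        mat = np.vstack([s.c for s in pool])
        r = np.median(mat, axis=0)
        return ReferenceProfile(r, "median", tuple(s.sample_id for s in pool))
    raise ValueError(f"unknown reference mode {mode!r}")


def log_ratio(
    sample: NormalizedCounts,
    ref: ReferenceProfile,
    epsilon: float,
) -> LogRatioProfile:
    """d_i = log2((c_i + eps) / (r_i + eps)); finite for eps > 0."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if sample.c.shape != ref.r.shape:
        raise ValueError(
            f"length mismatch: sample has {sample.c.size} windows, "
            f"reference has {ref.r.size}"
        )
    d = np.log2((sample.c + epsilon) / (ref.r + epsilon))
    return LogRatioProfile(sample.sample_id, d)


def _rolling_mean_truncated(x: np.ndarray, k: int) -> np.ndarray:
    """Centered rolling mean with a shrinking window at the edges."""
    half = k // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def denoise(
    profile: LogRatioProfile,
    windows: GenomeWindows,
    k: int = DEFAULT_SMOOTH_K,
) -> DenoisedProfile:
    """Smooth d with a centered width-k rolling mean, per chromosome.

    Smoothing never crosses chromosome boundaries.  At chromosome ends
    the window is truncated to the available values, so output length
    equals input length.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"smoothing width must be a positive odd integer, got {k}")
    if profile.d.size != windows.n_windows:
        raise ValueError("profile length does not match window grid")
    p = np.empty_like(profile.d)
    for name, _ in windows.chromosomes:
        sl = windows.chrom_slice(name)
        p[sl] = _rolling_mean_truncated(profile.d[sl], k)
    return DenoisedProfile(profile.sample_id, p)
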