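"""Genomic window grid, alignment read filters, and per-window read-start counting.

GBS (genotyping-by-sequencing) reads start at restriction-enzyme cut sites,
so the number of read *starts* in a fixed genomic window is a direct proxy
for how well that region is represented in the sample's library.  This
module builds the non-overlapping window grid over a genome, applies the
alignment-quality filter, and counts filtered read starts per window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 500_000
DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_ALIGNED = 30
DEFAULT_MIN_READS = 100_000

#: CIGAR operation codes that consume the query but are clipped away.
_CLIP_OPS = frozenset("SH")
_CIGAR_QUERY_OPS = frozenset("MIS=X")


@dataclass(frozen=True)
class GenomeWindows:
    """A fixed grid of non-overlapping windows covering a genome.

    Every base pair of every chromosome belongs to exactly one window;
    the last window of a chromosome may be shorter than ``window_size``.
    ``epsilon`` is the expected number of reads per window for a library
    normalized to one million read starts, ``1e6 / N``; it is used as the
    pseudocount that keeps the log2 coverage ratio finite.
    """

    chromosomes: tuple[tuple[str, int], ...]
    window_size: int
    starts: np.ndarray  # per-window start, 0-based
    ends: np.ndarray  # per-window end, half-open
    chrom_index: np.ndarray  # per-window index into `chromosomes`
    chrom_offsets: dict[str, tuple[int, int]]  # chrom -> (first window, n windows)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def epsilon(self) -> float:
        return 1e6 / self.n_windows

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def window_of(self, chrom: str, pos: int) -> int:
        """Global index of the window containing 0-based position ``pos``."""
        first, n = self.chrom_offsets[chrom]
        idx = pos // self.window_size
        if idx >= n or pos < 0:
            raise ValueError(
                f"position {pos} outside chromosome {chrom!r}"
            )
        return first + idx

    def chrom_slice(self, chrom: str) -> slice:
        first, n = self.chrom_offsets[chrom]
        return slice(first, first + n)

    def window_region(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a window, 0-based half-open."""
        name = self.chromosomes[self.chrom_index[index]][0]
        return name, int(self.starts[index]), int(self.ends[index])


def build_windows(
    chrom_lengths: Sequence[tuple[str, int]] | dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> GenomeWindows:
    """Divide each chromosome into non-overlapping windows of equal size.

    Parameters
    ----------
    chrom_lengths
        Ordered ``(name, length)`` pairs or a mapping (insertion-ordered).
    window_size
        Window width in bp; the default of 500 kb matches the grid used
        for barley and wheat GBS screening.
    """
    if isinstance(chrom_lengths, dict):
        chrom_lengths = list(chrom_lengths.items())
    if not chrom_lengths:
        raise ValueError("chromosome list is empty")
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")

    starts: list[int] = []
    ends: list[int] = []
    chrom_idx: list[int] = []
    offsets: dict[str, tuple[int, int]] = {}
    chroms: list[tuple[str, int]] = []
    for ci, (name, length) in enumerate(chrom_lengths):
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if name in offsets:
            raise ValueError(f"duplicate chromosome name {name!r}")
        n = -(-length // window_size)  # ceil division
        offsets[name] = (len(starts), n)
        chroms.append((name, length))
        for w in range(n):
            starts.append(w * window_size)
            ends.append(min((w + 1) * window_size, length))
            chrom_idx.append(ci)

    return GenomeWindows(
        chromosomes=tuple(chroms),
        window_size=window_size,
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        chrom_index=np.asarray(chrom_idx, dtype=np.int32),
        chrom_offsets=offsets,
    )


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Alignment-quality filter applied before counting.

    A read is counted only if it is mapped, is the primary alignment
    (neither secondary nor supplementary), has mapping quality of at
    least ``min_mapq`` (PHRED), and retains at least ``min_aligned_bases``
    non-clipped query bases (read length minus soft- and hard-clipped
    bases) — the "not overclipped" rule.  With ``count_both_mates`` both
    mates of a pair are counted independently whenever each passes.
    """

    min_mapq: int = DEFAULT_MIN_MAPQ
    min_aligned_bases: int = DEFAULT_MIN_ALIGNED
    count_both_mates: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.min_aligned_bases < 0:
            raise ValueError("min_aligned_bases must be >= 0")


def _nonclipped_query_length(read: pysam.AlignedSegment) -> int:
    """Query bases that survive clipping: read length minus soft+hard clips."""
    cigar = read.cigartuples
    if not cigar:
        raise ValueError("missing CIGAR")
    total = 0
    for op, length in cigar:
        # ops consuming the query: M(0), I(1), S(4), =(7), X(8); H(5) is
        # part of the original read but clipped away, like S.
        if op in (0, 1, 7, 8):
            total += length
    return total


def passes_filter(read: pysam.AlignedSegment, policy: ReadFilterPolicy) -> bool:
    """True iff an alignment record passes the counting filter."""
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if not policy.count_both_mates and read.is_paired and read.is_read2:
        return False
    if read.mapping_quality < policy.min_mapq:
        return False
    try:
        aligned = _nonclipped_query_length(read)
    except ValueError:
        warnings.warn(
            f"read {read.query_name!r} has no parseable CIGAR; treated as failing",
            stacklevel=2,
        )
        return False
    return aligned >= policy.min_aligned_bases


@dataclass
class WindowCountVector:
    """Per-sample raw read-start counts on a window grid.

    ``total_passing`` is the genome-wide number of reads that passed the
    filter; by construction it equals ``counts.sum()``.
    """

    sample_id: str
    counts: np.ndarray  # int64, aligned to GenomeWindows order
    total_passing: int
    skipped_unknown_chrom: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("window counts must be non-negative")
        if int(self.counts.sum()) != self.total_passing:
            raise ValueError(
                "sum of window counts "
                f"({int(self.counts.sum())}) != total_passing ({self.total_passing})"
            )


def count_reads(
    records: Iterable[pysam.AlignedSegment],
    windows: GenomeWindows,
    policy: ReadFilterPolicy | None = None,
    sample_id: str = "sample",
    on_unknown_chrom: str = "skip",
) -> WindowCountVector:
    """Count filtered read starts per window.

    Each passing record increments the window containing its leftmost
    aligned reference position (strand-independent).  Records on
    chromosomes absent from the grid are skipped and tallied by default,
    or raise when ``on_unknown_chrom='error'``.
    """
    if policy is None:
        policy = ReadFilterPolicy()
    if on_unknown_chrom not in ("skip", "error"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'error'")
    counts = np.zeros(windows.n_windows, dtype=np.int64)
    total = 0
    skipped = 0
    for read in records:
        if not passes_filter(read, policy):
            continue
        chrom = read.reference_name
        if chrom not in windows.chrom_offsets:
            if on_unknown_chrom == "error":
                raise ValueError(f"read on unknown chromosome {chrom!r}")
            skipped += 1
            continue
        counts[windows.window_of(chrom, read.reference_start)] += 1
        total += 1
    if skipped:
        logger.info("%s: skipped %d passing reads on unknown chromosomes",
                    sample_id, skipped)
    return WindowCountVector(sample_id, counts, total, skipped_unknown_chrom=skipped)


def count_reads_from_file(
    path: str,
    windows: GenomeWindows,
    policy: ReadFilterPolicy | None = None,
    sample_id: str | None = None,
) -> WindowCountVector:
    """Count read starts from a SAM/BAM/CRAM file."""
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return count_reads(fh, windows, policy, sample_id=sample_id)


def qc_samples(
    samples: Sequence[WindowCountVector],
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[list[WindowCountVector], list[WindowCountVector]]:
    """Split samples into (kept, discarded) by total passing reads.

    Samples with strictly fewer than ``min_reads`` passing reads are
    discarded; input order is preserved in both lists.
    """
    kept = [s for s in samples if s.total_passing >= min_reads]
    discarded = [s for s in samples if s.total_passing < min_reads]
    return kept, discarded


def read_fai(path: str) -> list[tuple[str, int]]:
    """Chromosome names and lengths from a FAI-style text file.

    Only the first two tab-separated columns (name, length) are used, so
    a plain two-column table works as well as a full ``.fai`` index.
    """
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed FAI line: {line!r}")
            out.append((fields[0], int(fields[1])))
    if not out:
        raise ValueError(f"no chromosomes found in {path}")
    return out
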