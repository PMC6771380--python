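"""Presence/absence analysis of GBS read-start loci in a genomic region.

GBS fragments begin at restriction-enzyme cut sites, so within a region of
interest every distinct alignment start position is a candidate locus.
Comparing which samples carry reads at which loci (e.g. recurrent parent,
wild donor, and introgression-line offspring) separates sequence-level
differences from methylation-level ones: a locus present in the donor but
absent in the offspring, with no sequence change expected, points at a
methylation shift silencing the restriction site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .windows import ReadFilterPolicy, passes_filter

DEFAULT_MIN_COMBINED = 10


@dataclass
class LocusTable:
    """Read-start loci in a region with per-sample start counts.

    Loci are distinct leftmost aligned reference positions (0-based,
    strand-ignored) that carry at least one passing read in any sample and
    whose combined count over all samples meets ``min_combined``.
    """

    region: tuple[str, int, int]
    sample_ids: tuple[str, ...]
    positions: np.ndarray  # sorted locus positions
    counts: np.ndarray  # shape (n_loci, n_samples)
    min_combined: int

    @property
    def n_loci(self) -> int:
        return len(self.positions)

    def presence(self) -> np.ndarray:
        """Boolean presence matrix: a sample has a locus iff count >= 1."""
        return self.counts >= 1


def _start_positions_from_alignments(
    records: Iterable[pysam.AlignedSegment],
    region: tuple[str, int, int],
    policy: ReadFilterPolicy,
) -> Counter:
    chrom, lo, hi = region
    tally: Counter = Counter()
    for read in records:
        if not passes_filter(read, policy):
            continue
        if read.reference_name != chrom:
            continue
        pos = read.reference_start
        if lo <= pos < hi:
            tally[pos] += 1
    return tally


def build_locus_table(
    samples: Sequence[tuple[str, object]],
    region: tuple[str, int, int],
    min_combined: int = DEFAULT_MIN_COMBINED,
    policy: ReadFilterPolicy | None = None,
) -> LocusTable:
    """Tabulate read-start loci in ``region`` across samples.

    Parameters
    ----------
    samples
        ``(sample_id, source)`` pairs where source is either an iterable
        of alignment records (filtered with ``policy``) or a mapping
        ``{position: count}`` of pre-computed passing read starts.
    region
        ``(chrom, start, end)``, 0-based half-open.
    min_combined
        Loci whose summed count over all samples is below this are
        dropped (default 10, the combined-coverage floor).
    """
    chrom, lo, hi = region
    if hi <= lo:
        raise ValueError("region must have positive length")
    if not samples:
        raise ValueError("at least one sample required")
    if policy is None:
        policy = ReadFilterPolicy()

    per_sample: list[Counter] = []
    for _sid, source in samples:
        if isinstance(source, Mapping):
            tally = Counter({
                int(pos): int(n) for pos, n in source.items()
                if lo <= int(pos) < hi and int(n) > 0
            })
        else:
            tally = _start_positions_from_alignments(source, region, policy)
        per_sample.append(tally)

    combined: Counter = Counter()
    for tally in per_sample:
        combined.update(tally)
    positions = np.array(
        sorted(pos for pos, n in combined.items() if n >= min_combined),
        dtype=np.int64,
    )
    counts = np.zeros((len(positions), len(samples)), dtype=np.int64)
    pos_index = {int(p): i for i, p in enumerate(positions)}
    for j, tally in enumerate(per_sample):
        for pos, n in tally.items():
            i = pos_index.get(pos)
            if i is not None:
                counts[i, j] = n
    return LocusTable(
        region=region,
        sample_ids=tuple(sid for sid, _ in samples),
        positions=positions,
        counts=counts,
        min_combined=min_combined,
    )


def presence_partition(
    table: LocusTable,
    sample_subsets: Sequence[str] | None = None,
) -> dict[tuple[str, ...], int]:
    """Partition loci by which samples carry them (Venn-diagram counts).

    Each locus is assigned to exactly one membership pattern — the tuple
    of sample ids with at least one read at that locus — so the counts
    over all non-empty patterns sum to the retained locus total.  Loci
    with no read in any of the selected samples are grouped under the
    empty pattern ``()``.
    """
    ids = tuple(sample_subsets) if sample_subsets is not None else table.sample_ids
    col = {sid: j for j, sid in enumerate(table.sample_ids)}
    missing = [sid for sid in ids if sid not in col]
    if missing:
        raise ValueError(f"unknown sample ids: {missing}")
    presence = table.presence()
    patterns: dict[tuple[str, ...], int] = {}
    for i in range(table.n_loci):
        pattern = tuple(sid for sid in ids if presence[i, col[sid]])
        patterns[pattern] = patterns.get(pattern, 0) + 1
    return patterns
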