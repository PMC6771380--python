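"""Shared fixtures: a tiny two-chromosome grid and a hand-placed
alignment fixture with known expected window counts."""

from __future__ import annotations

import numpy as np
import pytest

from gbscov import build_windows, write_alignment_fixture

# tiny genome: chrA 1.2 Mb (3 windows at 500 kb), chrB 0.6 Mb (2 windows)
TINY_CHROMS = [("chrA", 1_200_000), ("chrB", 600_000)]

# (qname, flag, chrom, 0-based pos, mapq, cigar) — coordinate-sorted
# within chromosome; the comment states why each read passes or fails.
FIXTURE_READS = [
    ("r_pass_start", 0, "chrA", 0, 60, "100M"),        # pass -> win 0
    ("r_secondary", 256, "chrA", 10_000, 60, "100M"),  # fail: secondary
    ("r_lowmapq", 0, "chrA", 20_000, 19, "100M"),      # fail: MAPQ 19
    ("r_mapq20", 0, "chrA", 30_000, 20, "100M"),       # pass -> win 0
    ("r_overclip", 0, "chrA", 40_000, 60, "80S20M"),   # fail: 20 kept bases
    ("r_suppl", 2048, "chrA", 50_000, 60, "30M70H"),   # fail: supplementary
    ("r_unmapped", 4, "chrA", 60_000, 0, "100M"),      # fail: unmapped
    ("r_last_in_w0", 0, "chrA", 499_999, 60, "100M"),  # pass -> win 0
    ("r_boundary", 0, "chrA", 500_000, 60, "100M"),    # pass -> win 1
    ("r_reverse", 16, "chrA", 700_000, 60, "100M"),    # pass -> win 1
    ("r_clip_ok", 0, "chrA", 1_100_000, 60, "70S30M"), # pass -> win 2 (30 kept)
    ("r_chrB", 0, "chrB", 0, 60, "100M"),              # pass -> win 3
    ("r_chrB_last", 0, "chrB", 550_000, 60, "50M"),    # pass -> win 4 (short window)
]

# hand-computed expectation for the default filter policy
EXPECTED_COUNTS = np.array([3, 2, 1, 1, 1], dtype=np.int64)
EXPECTED_TOTAL = 8


@pytest.fixture
def tiny_windows():
    return build_windows(TINY_CHROMS, 500_000)


@pytest.fixture
def fixture_sam(tmp_path):
    path = tmp_path / "tiny.sam"
    write_alignment_fixture(str(path), TINY_CHROMS, FIXTURE_READS)
    return str(path)


@pytest.fixture
def fixture_bam(tmp_path):
    path = tmp_path / "tiny.bam"
    write_alignment_fixture(str(path), TINY_CHROMS, FIXTURE_READS)
    return str(path)
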