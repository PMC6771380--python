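"""Readers and writers for window-count tables, profiles, stretches and
frequency summaries.

Machine outputs use 0-based half-open coordinates throughout: count and
profile tables are headered TSV, stretch calls are headerless BED6.
Human-readable reports render coordinates in Mb.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .outliers import FrequencySummary, OutlierCalls, OutlierStretch
from .profiles import DenoisedProfile, LogRatioProfile, NormalizedCounts, ReferenceProfile
from .windows import GenomeWindows, WindowCountVector


def _grid_frame(windows: GenomeWindows) -> pd.DataFrame:
    names = np.array(windows.chrom_names)
    return pd.DataFrame({
        "chrom": names[windows.chrom_index],
        "start": windows.starts,
        "end": windows.ends,
    })


def write_counts_tsv(path: str, counts: WindowCountVector,
                     windows: GenomeWindows) -> None:
    """Counts TSV: two comment lines (sample id, total passing) then a
    headered table chrom/start/end/count."""
    df = _grid_frame(windows)
    df["count"] = counts.counts
    with open(path, "w") as fh:
        fh.write(f"# sample_id={counts.sample_id}\n")
        fh.write(f"# total_passing={counts.total_passing}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str) -> tuple[WindowCountVector, pd.DataFrame]:
    """Read back a counts TSV; returns the vector and the window table."""
    sample_id = None
    total = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "sample_id":
                sample_id = val
            elif key.strip() == "total_passing":
                total = int(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    if sample_id is None or total is None:
        raise ValueError(f"{path}: missing sample_id/total_passing header")
    vec = WindowCountVector(sample_id, df["count"].to_numpy(np.int64), total)
    return vec, df


def write_profile_tsv(
    path: str,
    windows: GenomeWindows,
    normalized: NormalizedCounts,
    reference: ReferenceProfile,
    ratio: LogRatioProfile,
    denoised: DenoisedProfile,
) -> None:
    df = _grid_frame(windows)
    df["c"] = normalized.c
    df["r"] = reference.r
    df["d"] = ratio.d
    df["p"] = denoised.p
    with open(path, "w") as fh:
        fh.write(f"# sample_id={normalized.sample_id}\n")
        fh.write(f"# reference_mode={reference.mode}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_stretches_bed(path: str, stretches: Sequence[OutlierStretch],
                        sample_id: str) -> None:
    """BED6: chrom, start, end, name=sample:direction, score=n_outliers, '.'"""
    with open(path, "w") as fh:
        for s in stretches:
            fh.write(
                f"{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                f"{sample_id}:{s.direction}\t{s.n_outliers}\t.\n"
            )


def write_stretches_tsv(path: str, rows: Sequence[dict]) -> None:
    cols = ["sample_id", "chrom", "start", "end", "n_outliers",
            "direction", "mean_p"]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_frequency_tsv(path: str, summary: FrequencySummary,
                        windows: GenomeWindows) -> None:
    df = _grid_frame(windows)
    df["n_flagged"] = summary.n_flagged
    df["fraction"] = summary.fraction
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_calls_tsv(path: str, calls: OutlierCalls,
                    windows: GenomeWindows) -> None:
    df = _grid_frame(windows)
    df["z"] = calls.z
    df["outlier"] = calls.flag.astype(int)
    with open(path, "w") as fh:
        fh.write(f"# sample_id={calls.sample_id}\n")
        fh.write(f"# threshold={calls.threshold!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def format_region_mb(chrom: str, start_bp: int, end_bp: int) -> str:
    """Human-readable region like 'chr4H:631.5-647M'."""
    def mb(x: int) -> str:
        v = x / 1e6
        return f"{v:g}"
    return f"{chrom}:{mb(start_bp)}-{mb(end_bp)}M"


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
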