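"""End-to-end orchestration: counts -> QC -> profiles -> outliers -> reports.

``run_pipeline`` sequences the whole coverage screen on a set of
per-sample window counts and writes the standard artifacts (profile
tables, outlier calls, stretch BED/TSV, a per-sample longest-stretch
report, a frequency summary, and a config echo for provenance).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from . import io as gio
from .outliers import (
    DEFAULT_MIN_OUTLIERS,
    DEFAULT_PROB,
    LONG_MIN_OUTLIERS,
    OutlierCalls,
    OutlierStretch,
    call_outliers,
    find_stretches,
    frequency_summary,
    longest_stretch,
)
from .profiles import (
    DenoisedProfile,
    build_reference,
    denoise,
    log_ratio,
    normalize,
)
from .windows import (
    DEFAULT_MIN_READS,
    GenomeWindows,
    WindowCountVector,
    qc_samples,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All tunables of one pipeline run; echoed into the output directory."""

    window_size: int = 500_000
    min_mapq: int = 20
    min_aligned_bases: int = 30
    reference_mode: str = "median"  # or 'ancestor'
    ancestor_id: str | None = None
    prob: float = DEFAULT_PROB
    sidedness: str = "two_sided"
    smooth_k: int = 5
    min_outliers: int = DEFAULT_MIN_OUTLIERS
    long_min_outliers: int = LONG_MIN_OUTLIERS
    min_reads: int = DEFAULT_MIN_READS
    frequency_threshold: float = 0.03
    out_dir: str | None = None
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


@dataclass
class SampleResult:
    sample_id: str
    total_passing: int
    calls: OutlierCalls
    profile: DenoisedProfile
    stretches: list[OutlierStretch]
    long_stretches: list[OutlierStretch]
    longest: OutlierStretch | None


@dataclass
class PipelineResult:
    windows: GenomeWindows
    config: RunConfig
    samples: list[SampleResult]
    discarded: list[str]
    frequency: object | None

    def long_stretch_table(self) -> list[dict]:
        """Per-sample rows for samples carrying at least one long stretch,
        reporting the largest stretch and its direction (Low/High style)."""
        rows = []
        for s in self.samples:
            if not s.long_stretches:
                continue
            top = longest_stretch(s.long_stretches, self.windows)
            rows.append({
                "sample_id": s.sample_id,
                "total_passing": s.total_passing,
                "region": gio.format_region_mb(top.chrom, top.start_bp, top.end_bp),
                "chrom": top.chrom,
                "start": top.start_bp,
                "end": top.end_bp,
                "n_outliers": top.n_outliers,
                "type": "High" if top.direction == "increased" else "Low",
            })
        return rows


def run_pipeline(
    counts: Sequence[WindowCountVector],
    windows: GenomeWindows,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full coverage screen on pre-computed window counts.

    Stages: discard samples below the read-total floor; normalize to
    counts per million; build the reference (collection median or a named
    ancestor); per sample compute the log2 ratio with the expected-reads
    pseudocount, smooth per chromosome, call MAD outliers, and assemble
    gap-tolerant stretches at both the standard and the long-stretch
    minimum; finally summarize outlier frequency across the collection.
    """
    if config is None:
        config = RunConfig(window_size=windows.window_size)
    if not counts:
        raise ValueError("no samples supplied")

    kept, dropped = qc_samples(counts, config.min_reads)
    logger.info("QC: kept %d samples, discarded %d (< %d passing reads)",
                len(kept), len(dropped), config.min_reads)
    if not kept:
        raise ValueError("all samples were discarded by the read-total filter")

    normalized = [normalize(c) for c in kept]
    reference = build_reference(
        normalized, mode=config.reference_mode, ancestor_id=config.ancestor_id
    )
    eps = windows.epsilon

    results: list[SampleResult] = []
    all_calls: list[OutlierCalls] = []
    for vec, norm_c in zip(kept, normalized):
        d = log_ratio(norm_c, reference, eps)
        p = denoise(d, windows, k=config.smooth_k)
        calls = call_outliers(p, prob=config.prob, sidedness=config.sidedness)
        stretches = find_stretches(calls, windows, config.min_outliers, profile=p)
        long_stretches = [
            s for s in stretches if s.n_outliers >= config.long_min_outliers
        ]
        results.append(SampleResult(
            sample_id=vec.sample_id,
            total_passing=vec.total_passing,
            calls=calls,
            profile=p,
            stretches=stretches,
            long_stretches=long_stretches,
            longest=longest_stretch(stretches, windows),
        ))
        all_calls.append(calls)

    freq = frequency_summary(all_calls, config.frequency_threshold)
    result = PipelineResult(
        windows=windows,
        config=config,
        samples=results,
        discarded=[c.sample_id for c in dropped],
        frequency=freq,
    )
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str) -> None:
    """Write stretch BED/TSV, frequency summary, long-stretch table,
    discarded-sample log, and the config echo."""
    gio.ensure_dir(out_dir)
    windows = result.windows
    stretch_rows = []
    with open(f"{out_dir}/stretches.bed", "w") as bed:
        for s in result.samples:
            for st in s.stretches:
                bed.write(
                    f"{st.chrom}\t{st.start_bp}\t{st.end_bp}\t"
                    f"{s.sample_id}:{st.direction}\t{st.n_outliers}\t.\n"
                )
                stretch_rows.append({
                    "sample_id": s.sample_id, "chrom": st.chrom,
                    "start": st.start_bp, "end": st.end_bp,
                    "n_outliers": st.n_outliers, "direction": st.direction,
                    "mean_p": st.mean_p,
                })
    gio.write_stretches_tsv(f"{out_dir}/stretches.tsv", stretch_rows)
    gio.write_frequency_tsv(f"{out_dir}/frequency.tsv", result.frequency, windows)

    import pandas as pd
    table = result.long_stretch_table()
    pd.DataFrame(
        table,
        columns=["sample_id", "total_passing", "region", "chrom", "start",
                 "end", "n_outliers", "type"],
    ).to_csv(f"{out_dir}/long_stretches.tsv", sep="\t", index=False)

    with open(f"{out_dir}/discarded.txt", "w") as fh:
        for sid in result.discarded:
            fh.write(sid + "\n")
    with open(f"{out_dir}/config.yaml", "w") as fh:
        fh.write(f"# gbscov {__version__}\n")
        fh.write(result.config.to_yaml())
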