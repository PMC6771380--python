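"""Synthetic GBS-like window counts with known ground-truth events.

The generator emulates the features of real GBS coverage data that the
detection method must tolerate: a strong positional trend (coverage high
near telomeres, low near centromeres), library-size variation between
samples, Poisson (optionally negative-binomial) counting noise, and
regional coverage events — deletions, duplications, introgressions and
methylation shifts — planted as ground truth so detection can be scored.

It produces per-window counts directly rather than simulating reads;
a separate helper writes tiny SAM/BAM fixtures with hand-placed reads to
exercise the alignment-parsing path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam
import yaml

from .windows import GenomeWindows, WindowCountVector, build_windows

EVENT_KINDS = ("deletion", "duplication", "introgression", "methylation_shift")

# Scaled-down seven-chromosome genome used as the default simulation
# grid: 7 x 100 Mb at 500 kb windows = 1,400 windows.
DEFAULT_CHROMOSOMES = tuple((f"chr{i}H", 100_000_000) for i in range(1, 8))


@dataclass(frozen=True)
class ModificationEvent:
    """A ground-truth regional coverage change.

    ``factor`` multiplies the expected coverage of the covered region:
    0 for a deletion, >1 (e.g. 1.5-2.0) for a duplication, and a
    fractional value (e.g. 0.1-0.5) for an introgression, where reads
    from the donor segment align poorly against the crop reference.  For
    ``methylation_shift`` the factor is instead a per-window dropout
    probability: each covered window keeps a Beta-distributed fraction of
    its weight with mean ``1 - factor``, mimicking methylation silencing
    a varying subset of restriction sites per window.
    """

    chrom: str
    start: int
    end: int
    kind: str
    factor: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.factor < 0:
            raise ValueError("factor must be non-negative")
        if self.kind == "methylation_shift" and not 0 <= self.factor <= 1:
            raise ValueError("methylation_shift factor is a probability")
        if self.end <= self.start:
            raise ValueError("event interval must have positive length")

    @property
    def region(self) -> tuple[str, int, int]:
        return self.chrom, self.start, self.end


@dataclass
class SimulationSpec:
    """Study conditions for a simulated GBS collection.

    Defaults emulate a barley-like screen at desk scale: a seven-
    chromosome genome of 100 Mb chromosomes on the standard 500 kb grid,
    30 samples, and library sizes around 500,000 passing reads (the
    typical per-sample read total of a genebank GBS run), varying
    log-normally between samples with a coefficient of variation of 0.3.
    ``contrast`` sets the telomere/centromere coverage ratio of the
    baseline (0 = flat); the default 1.5 gives roughly a four-fold ratio,
    comparable to the positional trend of real GBS profiles.
    """

    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    window_size: int = 500_000
    n_samples: int = 30
    library_size_mean: float = 500_000.0
    library_size_cv: float = 0.3
    dispersion: float | None = None  # None -> Poisson; else NB size parameter
    contrast: float = 1.5
    centromere_frac: float = 0.5
    events: dict[str, list[ModificationEvent]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if not 0 < self.centromere_frac < 1:
            raise ValueError("centromere_frac must be in (0, 1)")
        if self.contrast < 0:
            raise ValueError("contrast must be non-negative")

    def windows(self) -> GenomeWindows:
        return build_windows(list(self.chromosomes), self.window_size)

    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        events = {
            sid: [ModificationEvent(**ev) for ev in evs]
            for sid, evs in raw.pop("events", {}).items()
        }
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple(
                (c["name"], int(c["length"])) for c in raw["chromosomes"]
            )
        return cls(events=events, **raw)

    def to_yaml(self) -> str:
        data = {
            "chromosomes": [
                {"name": n, "length": l} for n, l in self.chromosomes
            ],
            "window_size": self.window_size,
            "n_samples": self.n_samples,
            "library_size_mean": self.library_size_mean,
            "library_size_cv": self.library_size_cv,
            "dispersion": self.dispersion,
            "contrast": self.contrast,
            "centromere_frac": self.centromere_frac,
            "seed": self.seed,
            "events": {
                sid: [
                    {"chrom": e.chrom, "start": e.start, "end": e.end,
                     "kind": e.kind, "factor": e.factor}
                    for e in evs
                ]
                for sid, evs in self.events.items()
            },
        }
        return yaml.safe_dump(data, sort_keys=False)


def baseline_landscape(
    spec: SimulationSpec,
    windows: GenomeWindows | None = None,
) -> np.ndarray:
    """Expected relative weight per window, normalized to sum 1.

    Within each chromosome the weight is minimal at the configured
    centromere and maximal at the chromosome ends: the weight of a window
    at normalized centromere distance u in [0, 1] is exp(contrast * u^2),
    a smooth bowl whose depth is set by ``contrast`` (0 gives a flat
    landscape).
    """
    if windows is None:
        windows = spec.windows()
    weights = np.empty(windows.n_windows, dtype=np.float64)
    for name, length in windows.chromosomes:
        sl = windows.chrom_slice(name)
        mid = (windows.starts[sl] + windows.ends[sl]) / 2.0
        cen = spec.centromere_frac * length
        max_dist = max(cen, length - cen)
        u = np.abs(mid - cen) / max_dist
        weights[sl] = np.exp(spec.contrast * u ** 2)
    return weights / weights.sum()


def apply_events(
    weights: np.ndarray,
    events: Sequence[ModificationEvent],
    windows: GenomeWindows,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Scale baseline weights by ground-truth events.

    Windows fully inside an event region are multiplied by its factor;
    windows partially covered are scaled on the covered fraction only.
    Overlapping events of different kinds are rejected.  Methylation
    shifts draw a per-window Beta-distributed retention factor and
    therefore require ``rng``.
    """
    out = np.asarray(weights, dtype=np.float64).copy()
    claimed: dict[int, str] = {}
    for ev in events:
        if ev.chrom not in windows.chrom_offsets:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        chrom_len = dict(windows.chromosomes)[ev.chrom]
        if ev.end > chrom_len:
            raise ValueError(
                f"event {ev.chrom}:{ev.start}-{ev.end} exceeds chromosome length"
            )
        sl = windows.chrom_slice(ev.chrom)
        for gi in range(sl.start, sl.stop):
            w_lo, w_hi = int(windows.starts[gi]), int(windows.ends[gi])
            overlap = min(w_hi, ev.end) - max(w_lo, ev.start)
            if overlap <= 0:
                continue
            prior = claimed.get(gi)
            if prior is not None and prior != ev.kind:
                raise ValueError(
                    f"overlapping events of different kinds ({prior!r} vs "
                    f"{ev.kind!r}) in window {gi}"
                )
            claimed[gi] = ev.kind
            covered = overlap / (w_hi - w_lo)
            if ev.kind == "methylation_shift":
                if rng is None:
                    raise ValueError("methylation_shift events need an rng")
                mean_keep = 1.0 - ev.factor
                conc = 10.0
                keep = rng.beta(mean_keep * conc + 1e-9,
                                (1.0 - mean_keep) * conc + 1e-9)
                factor = keep
            else:
                factor = ev.factor
            # partially covered windows: covered fraction scales by the
            # factor, the remainder keeps its baseline weight
            out[gi] = out[gi] * (covered * factor + (1.0 - covered))
    return out


def draw_counts(
    weights: np.ndarray,
    library_size: float,
    rng: np.random.Generator,
    sample_id: str = "sim",
    dispersion: float | None = None,
) -> WindowCountVector:
    """Draw per-window counts with mean library_size * weight.

    Poisson by default; with ``dispersion`` set, negative-binomial with
    that size parameter (smaller = more overdispersed).
    """
    mu = np.asarray(weights, dtype=np.float64) * library_size
    if (mu < 0).any():
        raise ValueError("weights must be non-negative")
    if dispersion is None:
        counts = rng.poisson(mu)
    else:
        # NB via Gamma-Poisson mixture; mu=0 windows stay 0
        lam = np.where(
            mu > 0,
            rng.gamma(dispersion, np.where(mu > 0, mu, 1.0) / dispersion),
            0.0,
        )
        counts = rng.poisson(lam)
    counts = counts.astype(np.int64)
    return WindowCountVector(sample_id, counts, int(counts.sum()))


def simulate_collection(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeWindows, list[WindowCountVector], dict[str, list[ModificationEvent]]]:
    """Simulate a whole collection under ``spec``.

    Returns the window grid, one count vector per sample, and the
    ground-truth event map (sample id -> events).  With a fixed seed the
    output is reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    windows = spec.windows()
    base = baseline_landscape(spec, windows)
    sigma = np.sqrt(np.log1p(spec.library_size_cv ** 2))
    samples: list[WindowCountVector] = []
    for sid in spec.sample_ids():
        events = spec.events.get(sid, [])
        weights = apply_events(base, events, windows, rng) if events else base
        lib = spec.library_size_mean * rng.lognormal(-sigma ** 2 / 2, sigma)
        samples.append(
            draw_counts(weights, lib, rng, sample_id=sid,
                        dispersion=spec.dispersion)
        )
    return windows, samples, dict(spec.events)


# ---------------------------------------------------------------------------
# Tiny alignment fixtures for the SAM/BAM counting path


def write_alignment_fixture(
    path: str,
    chrom_lengths: Sequence[tuple[str, int]],
    reads: Sequence[tuple[str, int, str, int, int, str]],
) -> None:
    """Write a small SAM or BAM file with hand-placed reads.

    ``reads`` holds ``(qname, flag, chrom, pos0, mapq, cigar)`` tuples
    (positions 0-based).  The output format follows the file extension
    (.sam or .bam); records are written coordinate-sorted per the input
    order, with dummy sequence matching the CIGAR query length.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths],
    }
    mode = "wb" if str(path).endswith(".bam") else "w"
    tid = {name: i for i, (name, _) in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for qname, flag, chrom, pos, mapq, cigar in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = tid[chrom]
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = cigar
            # hard clips are not part of the stored sequence
            stored = sum(
                l for op, l in (a.cigartuples or []) if op in (0, 1, 4, 7, 8)
            )
            a.query_sequence = "A" * stored
            a.query_qualities = pysam.qualitystring_to_array("I" * stored)
            out.write(a)
    if mode == "wb":
        pysam.index(str(path))
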