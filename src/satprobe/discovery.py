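"""Sliding-window discovery of satellite-dense, interspersed-repeat-free regions.

The selection criterion is the one used to pick FISH probe targets: a window
qualifies when its base coverage by tandem satellite annotation is high and
its coverage by interspersed (transposon-derived, hence non-chromosome-
specific) annotation is at or below a ceiling — zero by default.  Qualifying
windows that overlap or abut are merged, fractions are recomputed over the
merged span, and short regions are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from satprobe.io import RepeatInterval

logger = logging.getLogger(__name__)

DEFAULT_SATELLITE_CLASSES = frozenset({"Satellite"})
DEFAULT_INTERSPERSED_CLASSES = frozenset({"SINE", "LINE", "LTR", "DNA", "Retroposon"})


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the window scan.

    Simple_repeat and Low_complexity annotations count as neither satellite
    nor interspersed unless explicitly added to one of the class sets.
    """

    window: int = 10_000
    step: int = 1_000
    min_satellite_fraction: float = 0.8
    max_interspersed_fraction: float = 0.0
    satellite_classes: frozenset[str] = DEFAULT_SATELLITE_CLASSES
    interspersed_classes: frozenset[str] = DEFAULT_INTERSPERSED_CLASSES
    min_region_length: int = 20_000
    require_single_family: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError(f"need 0 < step <= window, got step={self.step}, window={self.window}")
        for name in ("min_satellite_fraction", "max_interspersed_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        sat = frozenset(self.satellite_classes)
        inter = frozenset(self.interspersed_classes)
        if sat & inter:
            raise ValueError(f"satellite and interspersed class sets overlap: {sorted(sat & inter)}")
        object.__setattr__(self, "satellite_classes", sat)
        object.__setattr__(self, "interspersed_classes", inter)
        if self.min_region_length < 0:
            raise ValueError("min_region_length must be >= 0")


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of qualifying windows, 0-based half-open."""

    chrom: str
    start: int
    end: int
    satellite_fraction: float
    interspersed_fraction: float
    dominant_rep_name: str = ""
    n_windows: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) half-open spans; abutting spans are joined."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _class_coverage(
    intervals: Sequence[RepeatInterval], classes: frozenset[str], start: int, end: int
) -> int:
    """Bases of [start, end) covered by the union of intervals in the class set."""
    clipped = [
        (max(iv.start, start), min(iv.end, end))
        for iv in intervals
        if iv.rep_class in classes and iv.start < end and iv.end > start
    ]
    return sum(e - s for s, e in _merge_spans(clipped))


def window_composition(
    intervals: Sequence[RepeatInterval],
    chrom: str,
    start: int,
    end: int,
    config: ScanConfig | None = None,
) -> tuple[float, float]:
    """Return (satellite_fraction, interspersed_fraction) of window [start, end).

    Fractions are union-of-overlaps base coverage by each class set, clipped to
    the window; overlapping same-class annotations are not double-counted.
    """
    if end <= start:
        raise ValueError(f"window end must exceed start, got [{start}, {end})")
    config = config or ScanConfig()
    on_chrom = [iv for iv in intervals if iv.chrom == chrom]
    width = end - start
    sat = _class_coverage(on_chrom, config.satellite_classes, start, end)
    inter = _class_coverage(on_chrom, config.interspersed_classes, start, end)
    return sat / width, inter / width


def _dominant_rep_name(
    intervals: Sequence[RepeatInterval], config: ScanConfig, start: int, end: int
) -> str:
    coverage: dict[str, int] = {}
    for iv in intervals:
        if iv.rep_class in config.satellite_classes and iv.start < end and iv.end > start:
            coverage[iv.rep_name] = coverage.get(iv.rep_name, 0) + min(iv.end, end) - max(iv.start, start)
    if not coverage:
        return ""
    # max coverage; lexicographic tiebreak for determinism
    return min(coverage, key=lambda name: (-coverage[name], name))


def scan_candidate_regions(
    intervals: Sequence[RepeatInterval],
    chrom_length: int,
    config: ScanConfig | None = None,
    chrom: str | None = None,
) -> list[CandidateRegion]:
    """Scan one chromosome's annotation for candidate probe-target regions.

    Slides a window of ``config.window`` bp by ``config.step``; windows passing
    both composition thresholds are merged (overlap or exact abutment), merged
    spans shorter than ``config.min_region_length`` or failing the recomputed
    thresholds are dropped.  Output is sorted and non-overlapping.

    ``chrom`` defaults to the single chromosome named by the intervals; it must
    be given for an empty annotation.
    """
    config = config or ScanConfig()
    chroms = {iv.chrom for iv in intervals}
    if chrom is None:
        if len(chroms) > 1:
            raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
        chrom = next(iter(chroms), "chrN")
    elif chroms - {chrom}:
        raise ValueError(f"intervals on {sorted(chroms - {chrom})} do not belong to {chrom}")

    if config.window > chrom_length:
        logger.warning(
            "window (%d bp) exceeds chromosome length (%d bp); no scan performed",
            config.window, chrom_length,
        )
        return []

    on_chrom = sorted(
        (iv for iv in intervals if iv.chrom == chrom), key=lambda iv: (iv.start, iv.end)
    )

    qualifying: list[tuple[int, int]] = []
    for ws in range(0, chrom_length - config.window + 1, config.step):
        we = ws + config.window
        sat, inter = window_composition(on_chrom, chrom, ws, we, config)
        if sat >= config.min_satellite_fraction and inter <= config.max_interspersed_fraction:
            qualifying.append((ws, we))

    regions: list[CandidateRegion] = []
    window_counts = _window_counts_per_merge(qualifying)
    for (rs, re_), n_win in window_counts:
        if re_ - rs < config.min_region_length:
            continue
        sat, inter = window_composition(on_chrom, chrom, rs, re_, config)
        if sat < config.min_satellite_fraction or inter > config.max_interspersed_fraction:
            continue
        if config.require_single_family:
            names = {
                iv.rep_name
                for iv in on_chrom
                if iv.rep_class in config.satellite_classes and iv.start < re_ and iv.end > rs
            }
            if len(names) > 1:
                continue
        regions.append(
            CandidateRegion(
                chrom=chrom, start=rs, end=re_,
                satellite_fraction=sat, interspersed_fraction=inter,
                dominant_rep_name=_dominant_rep_name(on_chrom, config, rs, re_),
                n_windows=n_win,
            )
        )
    return regions


def _window_counts_per_merge(
    qualifying: Sequence[tuple[int, int]],
) -> list[tuple[tuple[int, int], int]]:
    """Merge qualifying windows, tracking how many windows each merge absorbed."""
    out: list[tuple[tuple[int, int], int]] = []
    for s, e in sorted(qualifying):
        if out and s <= out[-1][0][1]:
            (ms, me), n = out[-1]
            out[-1] = ((ms, max(me, e)), n + 1)
        else:
            out.append(((s, e), 1))
    return out


def rank_regions(regions: Sequence[CandidateRegion]) -> list[CandidateRegion]:
    """Stable sort: satellite fraction desc, length desc, start asc."""
    return sorted(regions, key=lambda r: (-r.satellite_fraction, -(r.end - r.start), r.start))


def write_region_bed(regions: Iterable[CandidateRegion], path) -> None:
    """BED4 export; name column carries the dominant satellite repeat name."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.dominant_rep_name or '.'}\n")


def write_region_report(regions: Iterable[CandidateRegion], path) -> None:
    """TSV report with composition fractions (machine-readable, no separators)."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tlength\tsatellite_fraction\tinterspersed_fraction\t"
            "dominant_rep_name\tn_windows\n"
        )
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.length}\t"
                f"{r.satellite_fraction:.6f}\t{r.interspersed_fraction:.6f}\t"
                f"{r.dominant_rep_name or '.'}\t{r.n_windows}\n"
            )
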