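"""BAC clone selection against a candidate region and clone-table consistency checks.

Clone tables are 1-based inclusive (the convention under which every mapped
row of the packaged reference table satisfies ``insert = end - start + 1``);
candidate regions are internal 0-based half-open.  Conversion happens inside
the operations, never in the data model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from satprobe.discovery import CandidateRegion
from satprobe.io import BacClone, zero_based

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionPolicy:
    """How clones are matched to a region.

    ``contained`` (default) keeps only clones lying wholly inside the region —
    the strictest reading of choosing clones "within" a target.  ``overlap``
    keeps clones whose mapped span overlaps the region by at least
    ``min_overlap_fraction`` of the span.  Multi-mapping clones are never
    selected as unique probes; with ``allow_multimapping`` they are surfaced
    separately as dispersed-target probe candidates.
    """

    mode: str = "contained"
    min_overlap_fraction: float = 0.5
    allow_multimapping: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("contained", "overlap"):
            raise ValueError(f"mode must be 'contained' or 'overlap', got {self.mode!r}")
        if not (0.0 <= self.min_overlap_fraction <= 1.0):
            raise ValueError("min_overlap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CloneConsistencyReport:
    """Mapped span vs. reported insert size for one clone.

    ``consistent`` is None (not applicable) for multi-mapping clones, which
    have no single mapped span.
    """

    name: str
    span_bp: int | None
    reported_insert: int
    delta: int | None
    consistent: bool | None


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def clone_span_bp(start: int, end: int) -> int:
    """Span of a 1-based inclusive clone placement: ``end - start + 1``."""
    if start > end:
        raise ValueError(f"start ({start}) exceeds end ({end})")
    return end - start + 1


def select_clones(
    clones: Sequence[BacClone],
    region: CandidateRegion,
    policy: SelectionPolicy | None = None,
) -> list[BacClone]:
    """Select clones suitable as unique probes for ``region``.

    Returns mapped clones passing the policy, in input order.  Multi-mapping
    clones are never returned; retrieve them with :func:`dispersed_candidates`
    when ``policy.allow_multimapping`` is set.
    """
    policy = policy or SelectionPolicy()
    region_chrom = _norm_chrom(region.chrom)
    mapped = [c for c in clones if not c.is_multi_mapping]
    if not any(_norm_chrom(c.chrom) == region_chrom for c in mapped):
        logger.warning("region chromosome %r absent from clone table; empty selection", region.chrom)
        return []

    selected: list[BacClone] = []
    for clone in mapped:
        if _norm_chrom(clone.chrom) != region_chrom:
            continue
        cs, ce = zero_based(clone.start, clone.end)  # type: ignore[arg-type]
        if policy.mode == "contained":
            if region.start <= cs and ce <= region.end:
                selected.append(clone)
        else:
            span = ce - cs
            overlap = min(ce, region.end) - max(cs, region.start)
            if span > 0 and overlap / span >= policy.min_overlap_fraction:
                selected.append(clone)
    return selected


def dispersed_candidates(clones: Sequence[BacClone]) -> list[BacClone]:
    """Multi-mapping clones — candidates for dispersed-target (repeat-binding) probes."""
    return [c for c in clones if c.is_multi_mapping]


def check_clone_consistency(
    clones: Sequence[BacClone], tolerance: int = 0
) -> list[CloneConsistencyReport]:
    """Compare each mapped clone's span with its reported insert size.

    Multi-mapping clones get a not-applicable report (span and delta absent,
    ``consistent`` None).
    """
    reports: list[CloneConsistencyReport] = []
    for clone in clones:
        if clone.is_multi_mapping:
            reports.append(
                CloneConsistencyReport(
                    name=clone.name, span_bp=None, reported_insert=clone.insert_size,
                    delta=None, consistent=None,
                )
            )
            continue
        span = clone_span_bp(clone.start, clone.end)  # type: ignore[arg-type]
        delta = span - clone.insert_size
        reports.append(
            CloneConsistencyReport(
                name=clone.name, span_bp=span, reported_insert=clone.insert_size,
                delta=delta, consistent=abs(delta) <= tolerance,
            )
        )
    return reports


def write_consistency_report(reports: Sequence[CloneConsistencyReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("clone\tspan_bp\treported_insert\tdelta\tconsistent\n")
        for r in reports:
            span = "NA" if r.span_bp is None else str(r.span_bp)
            delta = "NA" if r.delta is None else str(r.delta)
            cons = "NA" if r.consistent is None else str(r.consistent).lower()
            fh.write(f"{r.name}\t{span}\t{r.reported_insert}\t{delta}\t{cons}\n")
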