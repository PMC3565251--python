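"""Deterministic k-mer surrogate for an interactive BLASTn specificity screen.

A candidate probe is decomposed into overlapping k-mers (canonicalized to the
lexicographic minimum of each k-mer and its reverse complement), and every
chromosome is scanned for occurrences.  Overlapping occurrences are all
counted — tandem satellite targets owe their signal strength to copy number,
and collapsing overlaps would understate it.

The mapping between BLAST sensitivity settings and a k-mer length is
heuristic, not an equivalence: smaller ``k`` roughly plays the role of a more
permissive word size / E-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from satprobe.io import SequenceRecord
from satprobe.primers import reverse_complement

CHROMOSOME_SPECIFIC = "chromosome_specific"
DISPERSED = "dispersed"
OFF_TARGET_RISK = "off_target_risk"
NO_HITS = "no_hits"


@dataclass(frozen=True)
class SpecificityConfig:
    k: int = 16
    max_mismatch: int = 0
    count_both_strands: bool = True
    pseudocount: int = 0

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError(f"k must be >= 4, got {self.k}")
        if self.max_mismatch != 0:
            raise ValueError("only max_mismatch=0 is supported")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass(frozen=True)
class SpecificityReport:
    """Where a probe's k-mers land across a genome.

    ``target_fraction`` is hits(target)/total_hits and is None when the probe
    produced no hits anywhere (the ``no_hits`` flag).
    """

    probe_id: str
    per_chrom_hits: Mapping[str, int]
    target_chrom: str
    total_hits: int
    target_fraction: float | None

    @property
    def no_hits(self) -> bool:
        return self.total_hits == 0


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def probe_kmers(probe: str, config: SpecificityConfig | None = None) -> set[str]:
    """All overlapping k-mers of the probe; k-mers containing N are skipped.

    Canonicalized (min of k-mer and reverse complement) when
    ``count_both_strands``.
    """
    config = config or SpecificityConfig()
    probe = probe.upper()
    if len(probe) < config.k:
        raise ValueError(f"probe ({len(probe)} nt) shorter than k ({config.k})")
    kmers: set[str] = set()
    for i in range(len(probe) - config.k + 1):
        kmer = probe[i : i + config.k]
        if "N" in kmer:
            continue
        kmers.add(_canonical(kmer) if config.count_both_strands else kmer)
    return kmers


def genome_hit_profile(
    probe: str,
    genome: Sequence[SequenceRecord],
    config: SpecificityConfig | None = None,
    target_chrom: str | None = None,
    probe_id: str = "probe",
) -> SpecificityReport:
    """Count occurrences of the probe's k-mers on every chromosome.

    Every overlapping position is tested; when ``count_both_strands``, the
    chromosome window is canonicalized before lookup, so hits on either strand
    count.  ``target_chrom`` defaults to the chromosome with the most hits.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    config = config or SpecificityConfig()
    kmers = probe_kmers(probe, config)
    k = config.k
    per_chrom: dict[str, int] = {}
    for chrom in genome:
        seq = chrom.sequence
        count = config.pseudocount
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            if config.count_both_strands:
                window = _canonical(window)
            if window in kmers:
                count += 1
        per_chrom[chrom.id] = count
    total = sum(per_chrom.values())
    if target_chrom is None:
        target_chrom = max(per_chrom, key=lambda c: (per_chrom[c], c))
    fraction = per_chrom.get(target_chrom, 0) / total if total > 0 else None
    return SpecificityReport(
        probe_id=probe_id, per_chrom_hits=per_chrom, target_chrom=target_chrom,
        total_hits=total, target_fraction=fraction,
    )


def classify_probe(
    report: SpecificityReport,
    min_target_fraction: float = 0.95,
    min_target_hits: int = 10,
) -> str:
    """Classify a profiled probe.

    ``chromosome_specific``: target fraction and target hit count both clear
    their thresholds.  ``dispersed``: at least two chromosomes each carry
    strictly more than ``min_target_hits``.  Otherwise ``off_target_risk``;
    ``no_hits`` when the probe matched nothing.
    """
    if report.no_hits:
        return NO_HITS
    target_hits = report.per_chrom_hits.get(report.target_chrom, 0)
    if report.target_fraction is not None and (
        report.target_fraction >= min_target_fraction and target_hits >= min_target_hits
    ):
        return CHROMOSOME_SPECIFIC
    strong = sum(1 for h in report.per_chrom_hits.values() if h > min_target_hits)
    if strong >= 2:
        return DISPERSED
    return OFF_TARGET_RISK


def write_specificity_report(report: SpecificityReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\thits\tis_target\n")
        for chrom in sorted(report.per_chrom_hits):
            fh.write(
                f"{report.probe_id}\t{chrom}\t{report.per_chrom_hits[chrom]}\t"
                f"{str(chrom == report.target_chrom).lower()}\n"
            )
        frac = "NA" if report.target_fraction is None else f"{report.target_fraction:.6f}"
        fh.write(f"{report.probe_id}\tTOTAL\t{report.total_hits}\t{frac}\n")
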