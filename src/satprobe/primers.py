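"""Repeat-targeting primer scoring and in-silico PCR.

Primers meant to distinguish one tandem-repeat family from a closely related
satellite family must anneal where the template diverges from the satellite
consensus motif.  "Minimal homology" is operationalized as the exact
occurrence count of the motif (and, by default, its reverse complement)
within the primer footprint, plus the fraction of primer bases covered by
those occurrences.

In-silico PCR uses a Hamming-distance site model: no indels, uniform
mismatch weighting, no 3'-end special-casing.  ``N`` never matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from satprobe.io import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Published forward/reverse primer pair amplifying a 248 bp product from the
#: Y-heterochromatin pentanucleotide repeat monomer, and the 27-nt genome
#: screening query drawn from the same monomer.
Y_REPEAT_PRIMER_FWD = "GAACCGTACGATTCCATTCCTTTTGAA"
Y_REPEAT_PRIMER_REV = "TTCCATTCCATTCCATTCCTTTCCTTT"
Y_REPEAT_QUERY_27NT = "ATTCCGTACGATTCCATTCCTTTTGAA"

#: Human satellite III consensus pentamer that specific primers must avoid.
SATELLITE_III_CONSENSUS = "TTCCA"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusMotif:
    """The satellite consensus motif primers should avoid."""

    motif: str = SATELLITE_III_CONSENSUS
    both_strands: bool = True

    def __post_init__(self) -> None:
        motif = self.motif.upper()
        if len(motif) < 2 or set(motif) - set("ACGT"):
            raise ValueError(f"motif must be >= 2 bp over ACGT, got {self.motif!r}")
        object.__setattr__(self, "motif", motif)


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    template_start: int
    strand: str
    length: int
    consensus_match_count: int
    consensus_coverage: float
    gc_fraction: float
    tm_wallace: float


@dataclass(frozen=True)
class BindingSite:
    """Primer footprint on the template, 1-based inclusive; strand is where the primer anneals."""

    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    length: int
    fwd_site: BindingSite
    rev_site: BindingSite


def _hamming(a: str, b: str) -> int:
    """Mismatch count; N mismatches everything."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def _motif_hits(primer: str, motif: ConsensusMotif, max_mismatch: int = 0) -> list[int]:
    """Offsets in primer where the motif (either strand if configured) occurs."""
    patterns = {motif.motif}
    if motif.both_strands:
        patterns.add(reverse_complement(motif.motif))
    m = len(motif.motif)
    hits = []
    for i in range(len(primer) - m + 1):
        window = primer[i : i + m]
        if any(_hamming(window, p) <= max_mismatch for p in patterns):
            hits.append(i)
    return hits


def consensus_homology(
    primer: str, motif: ConsensusMotif | None = None, max_mismatch: int = 0
) -> tuple[int, float]:
    """Score a primer against the consensus motif.

    Returns ``(match_count, coverage)``: the number of offsets at which the
    motif (or its reverse complement when ``both_strands``) occurs exactly
    (or within ``max_mismatch`` substitutions), and the fraction of primer
    bases lying under at least one occurrence.
    """
    motif = motif or ConsensusMotif()
    primer = primer.upper()
    if len(primer) < len(motif.motif):
        raise ValueError(
            f"primer ({len(primer)} nt) shorter than motif ({len(motif.motif)} nt)"
        )
    hits = _motif_hits(primer, motif, max_mismatch)
    covered: set[int] = set()
    m = len(motif.motif)
    for h in hits:
        covered.update(range(h, h + m))
    return len(hits), len(covered) / len(primer)


def gc_fraction(primer: str) -> float:
    """G+C fraction of the primer. ``N`` is not allowed."""
    primer = primer.upper()
    if not primer:
        raise ValueError("empty primer")
    if "N" in primer:
        raise ValueError("primer contains N")
    return (primer.count("G") + primer.count("C")) / len(primer)


def tm_wallace(primer: str) -> float:
    """Wallace-rule melting temperature: ``2*(A+T) + 4*(G+C)`` degrees C."""
    primer = primer.upper()
    if not primer:
        raise ValueError("empty primer")
    if "N" in primer:
        raise ValueError("primer contains N (Tm undefined)")
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PrimerConstraints:
    gc_min: float = 0.0
    gc_max: float = 1.0
    tm_min: float = float("-inf")
    tm_max: float = float("inf")


def enumerate_primers(
    monomer: SequenceRecord,
    length_range: Iterable[int],
    motif: ConsensusMotif | None = None,
    constraints: PrimerConstraints | None = None,
    motif_max_mismatch: int = 0,
) -> list[PrimerCandidate]:
    """Exhaustively score every substring primer of each requested length.

    Both strands are enumerated (``template_start`` is always the 0-based
    footprint start on the forward strand).  Candidates containing ``N`` are
    skipped.  Ranking is deterministic: ascending consensus coverage, then
    ascending match count, then smallest |GC - 0.5|, then template_start,
    strand ('+' first), length.
    """
    lengths = sorted(set(length_range))
    if not lengths:
        raise ValueError("empty length_range")
    if monomer.length < max(lengths):
        raise ValueError(
            f"monomer ({monomer.length} bp) shorter than max primer length ({max(lengths)})"
        )
    motif = motif or ConsensusMotif()
    constraints = constraints or PrimerConstraints()

    candidates: list[PrimerCandidate] = []
    seq = monomer.sequence
    for L in lengths:
        for i in range(monomer.length - L + 1):
            fwd = seq[i : i + L]
            if "N" in fwd:
                continue
            for strand, primer in (("+", fwd), ("-", reverse_complement(fwd))):
                gc = gc_fraction(primer)
                tm = tm_wallace(primer)
                if not (constraints.gc_min <= gc <= constraints.gc_max):
                    continue
                if not (constraints.tm_min <= tm <= constraints.tm_max):
                    continue
                count, cov = consensus_homology(primer, motif, motif_max_mismatch)
                candidates.append(
                    PrimerCandidate(
                        sequence=primer, template_start=i, strand=strand, length=L,
                        consensus_match_count=count, consensus_coverage=cov,
                        gc_fraction=gc, tm_wallace=tm,
                    )
                )
    candidates.sort(
        key=lambda c: (
            c.consensus_coverage,
            c.consensus_match_count,
            abs(c.gc_fraction - 0.5),
            c.template_start,
            c.strand,
            c.length,
        )
    )
    return candidates


def _find_sites(template: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(0-based start, mismatches) of every pattern occurrence, Hamming model."""
    n, m = len(template), len(pattern)
    sites = []
    if max_mismatch == 0:
        # exact search via str.find, skipping N-containing matches implicitly
        start = template.find(pattern)
        while start != -1:
            sites.append((start, 0))
            start = template.find(pattern, start + 1)
        # N never matches, and exact find can't match through N unless pattern
        # itself has N — reject that case up front in insilico_pcr.
        return sites
    for i in range(n - m + 1):
        d = _hamming(template[i : i + m], pattern)
        if d <= max_mismatch:
            sites.append((i, d))
    return sites


def insilico_pcr(
    template: SequenceRecord,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
    max_product: int = 5_000,
) -> list[AmpliconPrediction]:
    """Predict PCR products of a primer pair on a linear template.

    The forward primer is matched on the + strand; the reverse primer binds
    the - strand, i.e. its reverse complement is matched on the template.
    Every forward/reverse site pair whose product (forward 5' end through
    reverse 5' end, 1-based inclusive) is at most ``max_product`` bp long is
    reported, ordered by product start then length.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    if not template.sequence:
        raise ValueError("template must be non-empty")
    if "N" in fwd or "N" in rev:
        raise ValueError("primers must not contain N")

    seq = template.sequence
    fwd_sites = _find_sites(seq, fwd, max_mismatch)
    rev_sites = _find_sites(seq, reverse_complement(rev), max_mismatch)

    products: list[AmpliconPrediction] = []
    for fs, fmm in fwd_sites:
        start1 = fs + 1  # forward 5' end, 1-based
        for rs, rmm in rev_sites:
            end1 = rs + len(rev)  # reverse 5' end, 1-based
            length = end1 - start1 + 1
            if start1 > end1 or length > max_product:
                continue
            # both footprints must lie within the product
            if fs + len(fwd) > end1 or rs + 1 < start1:
                continue
            products.append(
                AmpliconPrediction(
                    template_id=template.id, start=start1, end=end1, length=length,
                    fwd_site=BindingSite(start=start1, end=fs + len(fwd), strand="+", mismatches=fmm),
                    rev_site=BindingSite(start=rs + 1, end=end1, strand="-", mismatches=rmm),
                )
            )
    products.sort(key=lambda p: (p.start, p.length))
    return products


def write_primer_table(candidates: Sequence[PrimerCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sequence\ttemplate_start\tstrand\tlength\tconsensus_match_count\t"
            "consensus_coverage\tgc_fraction\ttm_wallace\n"
        )
        for c in candidates:
            fh.write(
                f"{c.sequence}\t{c.template_start}\t{c.strand}\t{c.length}\t"
                f"{c.consensus_match_count}\t{c.consensus_coverage:.6f}\t"
                f"{c.gc_fraction:.6f}\t{c.tm_wallace:.1f}\n"
            )


def write_amplicon_table(products: Sequence[AmpliconPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "template\tstart\tend\tlength\tfwd_start\tfwd_end\tfwd_mismatches\t"
            "rev_start\trev_end\trev_mismatches\n"
        )
        for p in products:
            fh.write(
                f"{p.template_id}\t{p.start}\t{p.end}\t{p.length}\t"
                f"{p.fwd_site.start}\t{p.fwd_site.end}\t{p.fwd_site.mismatches}\t"
                f"{p.rev_site.start}\t{p.rev_site.end}\t{p.rev_site.mismatches}\n"
            )
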