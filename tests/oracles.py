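"""Naive brute-force reference implementations, kept deliberately independent
of the package's interval/string arithmetic: everything here works per-base or
per-position with plain Python loops."""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_coverage_fraction(intervals, classes, chrom, start, end):
    """Per-base membership test over the window."""
    covered = 0
    for pos in range(start, end):
        for iv in intervals:
            if iv.chrom == chrom and iv.rep_class in classes and iv.start <= pos < iv.end:
                covered += 1
                break
    return covered / (end - start)


def naive_window_scan(intervals, chrom, chrom_length, config):
    """Label every base, test every window, merge qualifying windows, filter.

    Returns a list of (start, end) spans.
    """
    sat = [False] * chrom_length
    inter = [False] * chrom_length
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        target = None
        if iv.rep_class in config.satellite_classes:
            target = sat
        elif iv.rep_class in config.interspersed_classes:
            target = inter
        if target is not None:
            for pos in range(max(0, iv.start), min(chrom_length, iv.end)):
                target[pos] = True

    if config.window > chrom_length:
        return []
    qualifying = []
    for ws in range(0, chrom_length - config.window + 1, config.step):
        we = ws + config.window
        satf = sum(sat[ws:we]) / config.window
        interf = sum(inter[ws:we]) / config.window
        if satf >= config.min_satellite_fraction and interf <= config.max_interspersed_fraction:
            qualifying.append((ws, we))

    merged = []
    for s, e in qualifying:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    spans = []
    for s, e in merged:
        if e - s < config.min_region_length:
            continue
        satf = sum(sat[s:e]) / (e - s)
        interf = sum(inter[s:e]) / (e - s)
        if satf >= config.min_satellite_fraction and interf <= config.max_interspersed_fraction:
            spans.append((s, e))
    return spans


def naive_motif_scan(primer, motif, both_strands=True):
    """(count, coverage) by checking every offset against the motif strings."""
    patterns = [motif]
    if both_strands:
        patterns.append(revcomp(motif))
    m = len(motif)
    hits = [i for i in range(len(primer) - m + 1) if primer[i : i + m] in patterns]
    covered = set()
    for h in hits:
        covered.update(range(h, h + m))
    return len(hits), len(covered) / len(primer)


def naive_pcr(template_seq, fwd, rev, max_mismatch=0, max_product=5000):
    """All (start1, end1, length) products by exhaustive site pairing."""

    def mism(a, b):
        return sum(1 for x, y in zip(a, b) if x != y or "N" in (x, y))

    rc_rev = revcomp(rev)
    fwd_sites = [
        i for i in range(len(template_seq) - len(fwd) + 1)
        if mism(template_seq[i : i + len(fwd)], fwd) <= max_mismatch
    ]
    rev_sites = [
        j for j in range(len(template_seq) - len(rev) + 1)
        if mism(template_seq[j : j + len(rev)], rc_rev) <= max_mismatch
    ]
    products = []
    for i in fwd_sites:
        for j in rev_sites:
            start1, end1 = i + 1, j + len(rev)
            length = end1 - start1 + 1
            if start1 <= end1 and length <= max_product:
                if i + len(fwd) <= end1 and j + 1 >= start1:
                    products.append((start1, end1, length))
    products.sort(key=lambda p: (p[0], p[2]))
    return products


def naive_kmer_counts(probe, genome, k, both_strands=True):
    """Slide every probe k-mer over every chromosome; count all occurrences
    (either orientation when both_strands)."""
    probe_kmers = set()
    for i in range(len(probe) - k + 1):
        kmer = probe[i : i + k]
        if "N" not in kmer:
            probe_kmers.add(kmer)
            if both_strands:
                probe_kmers.add(revcomp(kmer))
    counts = {}
    for rec in genome:
        seq = rec.sequence
        n = 0
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" not in window and window in probe_kmers:
                n += 1
        counts[rec.id] = n
    return counts
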