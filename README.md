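# satprobe

Toolkit for designing chromosome-specific tandem-repeat FISH probe targets
from public sequence annotation:

1. **Scan** a chromosome's repeat annotation (RepeatMasker `.out` or BED) for
   regions densely covered by tandem satellite DNA and free of interspersed
   (SINE/LINE/LTR/DNA) repeats, which are not chromosome-specific.
2. **Select** BAC clones contained in (or overlapping) a candidate region from
   a clone placement table, and cross-check each clone's mapped span against
   its reported insert size. A six-clone reference table ships with the
   package (`satprobe/data/table1_clones.tsv`).
3. **Design primers** targeting a repeat monomer while avoiding the human
   satellite III consensus motif `TTCCA` (exact-occurrence count + footprint
   coverage), with Wallace-rule Tm and GC filters.
4. **In-silico PCR**: predict amplicons of a primer pair on a template
   (Hamming mismatch model, no indels).
5. **Specificity screen**: a deterministic k-mer surrogate for an interactive
   BLASTn screen — profile where a probe's canonical k-mers hit across a
   genome and classify it as chromosome-specific / dispersed / off-target
   risk.
6. **Simulate** deterministic toy genomes with planted satellite arrays,
   interspersed elements, clone placements and primer sites, plus a JSON
   truth manifest, so the whole pipeline is testable offline.

Coordinates are 0-based half-open internally; clone tables and amplicon
reports use the 1-based inclusive convention of the source material.

## CLI

All stages are subcommands of a single entry point:

```sh
satprobe scan --annotation repeats.out --chrom-length 200000 \
    --out-bed regions.bed --out-report regions.tsv
satprobe select --region-bed regions.bed --clones clones.tsv \
    --out-selected selected.tsv --out-consistency consistency.tsv
satprobe primers --monomer monomer.fa --min-len 20 --max-len 27 --out primers.tsv
satprobe ispcr --template monomer.fa \
    --fwd GAACCGTACGATTCCATTCCTTTTGAA --rev TTCCATTCCATTCCATTCCTTTCCTTT \
    --out amplicons.tsv
satprobe specificity --probe probe.fa --genome genome.fa --target chrA \
    -k 16 --out specificity.tsv
satprobe simulate --config fixture.yaml --outdir sim/
```

`satprobe <subcommand> --help` documents every flag; scan thresholds
(window, step, satellite/interspersed fractions, minimum region length) are
all configurable.

## Layout

```
src/satprobe/
  io.py           FASTA / BED / RepeatMasker .out / clone-table parsing
  discovery.py    sliding-window candidate-region scan
  clones.py       clone selection + consistency checks
  primers.py      consensus-motif scoring, primer enumeration, in-silico PCR
  specificity.py  k-mer cross-chromosome hit profiling
  fixtures.py     deterministic synthetic genomes with truth manifests
  cli.py          click command group
tests/            pytest suite (unit, property/hypothesis, acceptance)
```
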