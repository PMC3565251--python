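"""Deterministic synthetic genomes with planted truth for end-to-end testing.

A :class:`FixtureSpec` plants tandem satellite arrays, interspersed-repeat
annotations, clone placements and primer sites on seeded-random background
chromosomes, and :func:`generate_fixture` realizes it together with a
machine-readable truth manifest holding the expected downstream answers
(candidate regions, selected clones, amplicons).  The same seed and spec
always produce byte-identical artifacts.

The divergence model is i.i.d. substitution only — no indels — so planted
coordinates stay exact.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from satprobe.discovery import ScanConfig
from satprobe.io import (
    BacClone,
    RepeatInterval,
    SequenceRecord,
    write_clone_table,
    write_fasta,
    write_repeatmasker_out,
)
from satprobe.primers import (
    Y_REPEAT_PRIMER_FWD,
    Y_REPEAT_PRIMER_REV,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))

#: Pentamer pool for satellite-consensus-like monomers (weighted toward the
#: exact consensus; the variants each differ by one substitution).
_CONSENSUS_PENTAMERS = ("TTCCA", "TTCCA", "TTCCA", "TTCCT", "TTCCG", "TTCAA", "CTCCA")

#: 40 bp consensus-free island (contains neither TTCCA nor TGGAA on either strand).
_DIVERGENT_ISLAND = "GACGTCAGCTAGCTGACGTCAGCTAGCTGACGTCAGCTAG"

DYZ1_MONOMER_LENGTH = 3564
#: 0-based plant offsets reproducing the published amplicon geometry:
#: forward primer 5' end at 1-based position 2965, product end at 3212.
_FWD_PLANT_OFFSET = 2964
_REV_PLANT_OFFSET = 3212 - len(Y_REPEAT_PRIMER_REV)  # = 3185
_ISLAND_OFFSET = 1200


class FixtureSpecError(ValueError):
    """Raised when planted features collide or fall outside their chromosome."""


@dataclass(frozen=True)
class PlantedArray:
    chrom: str
    start: int  # 0-based
    monomer: str
    copies: int
    divergence: float = 0.0
    name: str = "SAT_SIM"

    @property
    def end(self) -> int:
        return self.start + len(self.monomer) * self.copies


@dataclass(frozen=True)
class InterspersedElement:
    chrom: str
    start: int  # 0-based
    length: int
    rep_class: str  # combined "class/family" accepted, e.g. "SINE/Alu"
    name: str = "IR_SIM"

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class ClonePlacement:
    name: str
    chrom: str
    start: int  # 1-based inclusive (clone-table convention)
    end: int


@dataclass(frozen=True)
class PrimerPlant:
    """Plant a primer binding site: '+' writes the primer itself at ``position``,
    '-' writes its reverse complement (the primer then anneals to the - strand)."""

    template: str
    sequence: str
    position: int  # 0-based
    strand: str = "+"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    chromosomes: tuple[tuple[str, int], ...]
    planted_arrays: tuple[PlantedArray, ...] = ()
    interspersed_elements: tuple[InterspersedElement, ...] = ()
    clone_placements: tuple[ClonePlacement, ...] = ()
    primer_plants: tuple[PrimerPlant, ...] = ()
    primer_pairs: tuple[tuple[str, str, str], ...] = ()  # (template, fwd, rev)


@dataclass
class Fixture:
    genome: list[SequenceRecord]
    annotation: list[RepeatInterval]
    clones: list[BacClone]
    manifest: dict


def _validate(spec: FixtureSpec) -> None:
    lengths = dict(spec.chromosomes)
    features: list[tuple[str, int, int, str]] = []
    for a in spec.planted_arrays:
        features.append((a.chrom, a.start, a.end, f"array {a.name}"))
    for e in spec.interspersed_elements:
        features.append((e.chrom, e.start, e.end, f"element {e.name}"))
    for p in spec.primer_plants:
        features.append((p.template, p.position, p.position + len(p.sequence), f"primer@{p.position}"))
    for chrom, start, end, label in features:
        if chrom not in lengths:
            raise FixtureSpecError(f"{label}: unknown chromosome {chrom!r}")
        if start < 0 or end > lengths[chrom]:
            raise FixtureSpecError(
                f"{label}: [{start}, {end}) outside {chrom} (length {lengths[chrom]})"
            )
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, label in features:
        by_chrom.setdefault(chrom, []).append((start, end, label))
    for chrom, feats in by_chrom.items():
        feats.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(feats, feats[1:]):
            if s2 < e1:
                raise FixtureSpecError(f"{chrom}: {l1} [{s1},{e1}) overlaps {l2} [{s2},{e2})")
    for c in spec.clone_placements:
        if c.chrom not in lengths:
            raise FixtureSpecError(f"clone {c.name}: unknown chromosome {c.chrom!r}")
        if not (1 <= c.start <= c.end <= lengths[c.chrom]):
            raise FixtureSpecError(f"clone {c.name}: bad placement {c.start}..{c.end}")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _diverge(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, list[int]]:
    """Apply i.i.d. substitutions at the given per-base rate; substituted bases
    always change (new base drawn from the other three)."""
    if rate <= 0:
        return seq, []
    hit = rng.random(len(seq)) < rate
    positions = np.flatnonzero(hit)
    out = seq.copy()
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return out, positions.tolist()


def _expected_regions_naive(
    annotation: list[RepeatInterval], chrom_lengths: dict[str, int], config: ScanConfig
) -> list[dict]:
    """Per-base brute-force evaluation of the window criterion — an oracle
    independent of the scanner's interval arithmetic."""
    expected = []
    for chrom, length in chrom_lengths.items():
        if config.window > length:
            continue
        sat = np.zeros(length, dtype=bool)
        inter = np.zeros(length, dtype=bool)
        for iv in annotation:
            if iv.chrom != chrom:
                continue
            if iv.rep_class in config.satellite_classes:
                sat[iv.start : iv.end] = True
            elif iv.rep_class in config.interspersed_classes:
                inter[iv.start : iv.end] = True
        sat_c = np.concatenate([[0], np.cumsum(sat)])
        inter_c = np.concatenate([[0], np.cumsum(inter)])
        spans: list[list[int]] = []
        for ws in range(0, length - config.window + 1, config.step):
            we = ws + config.window
            satf = (sat_c[we] - sat_c[ws]) / config.window
            interf = (inter_c[we] - inter_c[ws]) / config.window
            if satf >= config.min_satellite_fraction and interf <= config.max_interspersed_fraction:
                if spans and ws <= spans[-1][1]:
                    spans[-1][1] = max(spans[-1][1], we)
                else:
                    spans.append([ws, we])
        for rs, re_ in spans:
            if re_ - rs < config.min_region_length:
                continue
            satf = (sat_c[re_] - sat_c[rs]) / (re_ - rs)
            interf = (inter_c[re_] - inter_c[rs]) / (re_ - rs)
            if satf >= config.min_satellite_fraction and interf <= config.max_interspersed_fraction:
                expected.append({"chrom": chrom, "start": int(rs), "end": int(re_)})
    return expected


def _expected_amplicons(spec: FixtureSpec) -> list[dict]:
    """Amplicon predictions derived purely from plant-position arithmetic."""
    out = []
    for template, fwd, rev in spec.primer_pairs:
        fwd_plants = [p for p in spec.primer_plants
                      if p.template == template and p.sequence == fwd and p.strand == "+"]
        rev_plants = [p for p in spec.primer_plants
                      if p.template == template and p.sequence == rev and p.strand == "-"]
        for fp in fwd_plants:
            for rp in rev_plants:
                start1 = fp.position + 1
                end1 = rp.position + len(rev)
                if start1 <= end1 and fp.position + len(fwd) <= end1:
                    out.append({
                        "template": template, "start": start1, "end": end1,
                        "length": end1 - start1 + 1, "fwd": fwd, "rev": rev,
                    })
    out.sort(key=lambda a: (a["template"], a["start"], a["length"]))
    return out


def generate_fixture(spec: FixtureSpec, scan_config: ScanConfig | None = None) -> Fixture:
    """Realize a fixture spec into sequences, annotation, clones and truth manifest."""
    _validate(spec)
    scan_config = scan_config or ScanConfig()
    rng = np.random.default_rng(spec.seed)
    chrom_lengths = dict(spec.chromosomes)

    arrays_by_chrom: dict[str, list[PlantedArray]] = {}
    for a in spec.planted_arrays:
        arrays_by_chrom.setdefault(a.chrom, []).append(a)

    genome: list[SequenceRecord] = []
    annotation: list[RepeatInterval] = []
    manifest_arrays: list[dict] = []

    for name, length in spec.chromosomes:
        seq = _random_sequence(rng, length)
        for a in arrays_by_chrom.get(name, []):
            monomer = np.array(list(a.monomer.upper()))
            tandem = np.tile(monomer, a.copies)
            tandem, sub_positions = _diverge(rng, tandem, a.divergence)
            seq[a.start : a.end] = tandem
            annotation.append(
                RepeatInterval(
                    chrom=name, start=a.start, end=a.end, strand="+",
                    rep_name=a.name, rep_class="Satellite", rep_family="satellite",
                )
            )
            manifest_arrays.append({
                "chrom": name, "start": a.start, "end": a.end,
                "monomer_length": len(a.monomer), "copies": a.copies,
                "divergence": a.divergence,
                "n_substitutions": len(sub_positions),
                "substitution_positions": [a.start + p for p in sub_positions],
            })
        for e in spec.interspersed_elements:
            if e.chrom != name:
                continue
            cls, _, family = e.rep_class.partition("/")
            annotation.append(
                RepeatInterval(
                    chrom=name, start=e.start, end=e.end, strand="+",
                    rep_name=e.name, rep_class=cls, rep_family=family,
                )
            )
        for p in spec.primer_plants:
            if p.template != name:
                continue
            site = p.sequence.upper() if p.strand == "+" else reverse_complement(p.sequence)
            seq[p.position : p.position + len(site)] = np.array(list(site))
        genome.append(SequenceRecord(id=name, sequence="".join(seq)))

    annotation.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    clones = [
        BacClone(
            name=c.name, chrom=c.chrom, band="sim", start=c.start, end=c.end,
            insert_size=c.end - c.start + 1, end_accessions=(f"{c.name}.L", f"{c.name}.R"),
        )
        for c in spec.clone_placements
    ]

    expected_regions = _expected_regions_naive(annotation, chrom_lengths, scan_config)
    expected_clones = sorted(
        c.name
        for c in clones
        if any(
            r["chrom"] == c.chrom and r["start"] <= c.start - 1 and c.end <= r["end"]
            for r in expected_regions
        )
    )

    manifest = {
        "seed": spec.seed,
        "chromosomes": [{"name": n, "length": l} for n, l in spec.chromosomes],
        "arrays": manifest_arrays,
        "interspersed": [asdict(e) | {"end": e.end} for e in spec.interspersed_elements],
        "clones": [asdict(c) for c in spec.clone_placements],
        "primer_plants": [asdict(p) for p in spec.primer_plants],
        "expected": {
            "candidate_regions": expected_regions,
            "selected_clones": expected_clones,
            "amplicons": _expected_amplicons(spec),
        },
    }
    return Fixture(genome=genome, annotation=annotation, clones=clones, manifest=manifest)


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, RepeatMasker-dialect annotation, clone TSV and JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "annotation": outdir / "repeats.out",
        "clones": outdir / "clones.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(fixture.genome, paths["fasta"])
    write_repeatmasker_out(fixture.annotation, paths["annotation"])
    write_clone_table(fixture.clones, paths["clones"])
    paths["manifest"].write_text(json.dumps(fixture.manifest, indent=1, sort_keys=True) + "\n")
    return paths


def table1_fixture(dest: str | Path | None = None) -> Path:
    """Path to the packaged six-clone reference placement table (copied to
    ``dest`` when given)."""
    src = resources.files("satprobe").joinpath("data/table1_clones.tsv")
    with resources.as_file(src) as path:
        if dest is None:
            return Path(path)
        dest = Path(dest)
        shutil.copy(path, dest)
        return dest


def dyz1_like_monomer(seed: int = 0) -> SequenceRecord:
    """A 3,564 bp satellite-consensus-like monomer with planted primer geometry.

    The body is a tandem run of consensus-family pentamers; a 40 bp
    consensus-free island is planted for primer design to find, and the
    published forward/reverse primer sites are planted so that in-silico PCR
    yields a single product at 1-based positions 2965-3212 (248 bp).
    """
    rng = np.random.default_rng(seed)
    pentamers = [_CONSENSUS_PENTAMERS[i] for i in rng.integers(0, len(_CONSENSUS_PENTAMERS),
                                                              size=DYZ1_MONOMER_LENGTH // 5 + 1)]
    seq = list("".join(pentamers)[:DYZ1_MONOMER_LENGTH])
    seq[_ISLAND_OFFSET : _ISLAND_OFFSET + len(_DIVERGENT_ISLAND)] = _DIVERGENT_ISLAND
    seq[_FWD_PLANT_OFFSET : _FWD_PLANT_OFFSET + len(Y_REPEAT_PRIMER_FWD)] = Y_REPEAT_PRIMER_FWD
    rc_rev = reverse_complement(Y_REPEAT_PRIMER_REV)
    seq[_REV_PLANT_OFFSET : _REV_PLANT_OFFSET + len(rc_rev)] = rc_rev
    return SequenceRecord(id="satY_monomer_sim", sequence="".join(seq))
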