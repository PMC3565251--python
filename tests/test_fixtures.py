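from __future__ import annotations

import math

import pytest

from oracles import naive_motif_scan
from satprobe.clones import select_clones
from satprobe.discovery import ScanConfig, scan_candidate_regions
from satprobe.fixtures import (
    ClonePlacement,
    FixtureSpec,
    FixtureSpecError,
    InterspersedElement,
    PlantedArray,
    PrimerPlant,
    dyz1_like_monomer,
    generate_fixture,
    table1_fixture,
    write_fixture,
)
from satprobe.io import parse_clone_table, parse_repeatmasker_out, read_fasta
from satprobe.primers import (
    Y_REPEAT_PRIMER_FWD,
    Y_REPEAT_PRIMER_REV,
    consensus_homology,
    insilico_pcr,
)


class TestGenerateFixture:
    def test_zero_features(self):
        fixture = generate_fixture(FixtureSpec(seed=1, chromosomes=(("c", 1_000),)))
        assert fixture.annotation == []
        assert fixture.genome[0].length == 1_000

    def test_same_seed_byte_identical(self, tmp_path):
        spec = FixtureSpec(
            seed=5,
            chromosomes=(("c1", 30_000),),
            planted_arrays=(PlantedArray("c1", 2_000, "TTCCA", 4_000, divergence=0.05),),
            clone_placements=(ClonePlacement("CL", "c1", 3_001, 9_000),),
        )
        dirs = [tmp_path / "a", tmp_path / "b"]
        for d in dirs:
            write_fixture(generate_fixture(spec), d)
        for name in ("genome.fasta", "repeats.out", "clones.tsv", "manifest.json"):
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_different_seed_differs(self):
        specs = [FixtureSpec(seed=s, chromosomes=(("c", 2_000),)) for s in (1, 2)]
        a, b = (generate_fixture(s).genome[0].sequence for s in specs)
        assert a != b

    def test_divergence_zero_exact_copies(self):
        spec = FixtureSpec(
            seed=2, chromosomes=(("c", 1_000),),
            planted_arrays=(PlantedArray("c", 100, "TTCCA", 20, divergence=0.0),),
        )
        fixture = generate_fixture(spec)
        assert fixture.genome[0].sequence[100:200] == "TTCCA" * 20
        assert fixture.manifest["arrays"][0]["n_substitutions"] == 0

    def test_divergence_within_binomial_bound(self):
        n, rate = 50_000, 0.1
        spec = FixtureSpec(
            seed=3, chromosomes=(("c", n + 200),),
            planted_arrays=(PlantedArray("c", 100, "TTCCA", n // 5, divergence=rate),),
        )
        fixture = generate_fixture(spec)
        realized = fixture.genome[0].sequence[100 : 100 + n]
        mismatches = sum(a != b for a, b in zip(realized, "TTCCA" * (n // 5)))
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(mismatches - n * rate) <= 3 * sd
        assert mismatches == fixture.manifest["arrays"][0]["n_substitutions"]

    def test_overlapping_features_rejected(self):
        spec = FixtureSpec(
            seed=1, chromosomes=(("c", 10_000),),
            planted_arrays=(
                PlantedArray("c", 0, "TTCCA", 100, name="A1"),
                PlantedArray("c", 400, "TTCCA", 100, name="A2"),
            ),
        )
        with pytest.raises(FixtureSpecError, match="overlaps"):
            generate_fixture(spec)

    def test_feature_outside_chromosome_rejected(self):
        spec = FixtureSpec(
            seed=1, chromosomes=(("c", 100),),
            planted_arrays=(PlantedArray("c", 50, "TTCCA", 100),),
        )
        with pytest.raises(FixtureSpecError, match="outside"):
            generate_fixture(spec)

    def test_annotation_matches_manifest(self, tmp_path):
        spec = FixtureSpec(
            seed=9, chromosomes=(("c", 40_000),),
            planted_arrays=(PlantedArray("c", 5_000, "TTCCA", 4_000),),
            interspersed_elements=(InterspersedElement("c", 30_000, 300, "SINE/Alu"),),
        )
        fixture = generate_fixture(spec)
        paths = write_fixture(fixture, tmp_path)
        reread = parse_repeatmasker_out(paths["annotation"])
        emitted = {(iv.chrom, iv.start, iv.end, iv.rep_class) for iv in reread}
        truth = {(a["chrom"], a["start"], a["end"], "Satellite") for a in fixture.manifest["arrays"]}
        truth |= {(e["chrom"], e["start"], e["end"], e["rep_class"].split("/")[0])
                  for e in fixture.manifest["interspersed"]}
        assert emitted == truth


class TestTruthClosure:
    def test_scan_select_pcr_reproduce_manifest(self, tmp_path):
        monomer = dyz1_like_monomer(seed=1)
        config = ScanConfig()
        spec = FixtureSpec(
            seed=21,
            chromosomes=(("chrT", 150_000), ("chrU", 60_000)),
            planted_arrays=(PlantedArray("chrT", 40_000, monomer.sequence, 14,
                                         divergence=0.0, name="SATY_SIM"),),
            clone_placements=(
                ClonePlacement("CL_IN", "chrT", 45_001, 80_000),
                ClonePlacement("CL_ELSEWHERE", "chrU", 10_001, 30_000),
            ),
            primer_plants=(),
            primer_pairs=(),
        )
        fixture = generate_fixture(spec, scan_config=config)
        expected = fixture.manifest["expected"]

        chrT = [iv for iv in fixture.annotation if iv.chrom == "chrT"]
        regions = scan_candidate_regions(chrT, 150_000, config, chrom="chrT")
        assert [
            {"chrom": r.chrom, "start": r.start, "end": r.end} for r in regions
        ] == [r for r in expected["candidate_regions"] if r["chrom"] == "chrT"]

        clones = parse_clone_table(write_fixture(fixture, tmp_path)["clones"])
        selected = []
        for region in regions:
            selected += [c.name for c in select_clones(clones, region)]
        assert sorted(selected) == expected["selected_clones"]

        # each of the 14 tandem monomer copies carries the planted primer
        # sites: 14 within-copy products plus 13 cross-copy products
        chrT_seq = read_fasta(tmp_path / "genome.fasta")[0]
        amps = insilico_pcr(chrT_seq, Y_REPEAT_PRIMER_FWD, Y_REPEAT_PRIMER_REV)
        assert sorted(a.length for a in amps) == [248] * 14 + [248 + 3564] * 13

    def test_expected_amplicons_from_plant_arithmetic(self):
        spec = FixtureSpec(
            seed=4,
            chromosomes=(("t", 2_000),),
            primer_plants=(
                PrimerPlant("t", "GATTACAGATTACAGATTACA", 300, "+"),
                PrimerPlant("t", "CCGGTTAACCGGTTAACCGGT", 900, "-"),
            ),
            primer_pairs=(("t", "GATTACAGATTACAGATTACA", "CCGGTTAACCGGTTAACCGGT"),),
        )
        fixture = generate_fixture(spec)
        (expected,) = fixture.manifest["expected"]["amplicons"]
        assert (expected["start"], expected["end"]) == (301, 921)
        got = insilico_pcr(fixture.genome[0], "GATTACAGATTACAGATTACA",
                           "CCGGTTAACCGGTTAACCGGT")
        assert [(a.start, a.end, a.length) for a in got] == [
            (expected["start"], expected["end"], expected["length"])
        ]


class TestTable1Fixture:
    def test_six_rows(self, table1_path):
        body = table1_path.read_text().strip().splitlines()
        assert len(body) == 7  # header + six clone rows

    def test_multiple_coordinates_row(self, table1_path):
        row = next(l for l in table1_path.read_text().splitlines() if "RP11-242E13" in l)
        fields = row.split("\t")
        assert fields[3] == fields[4] == "multiple"

    def test_round_trips_through_parser(self, tmp_path, table1_path):
        clones = parse_clone_table(table1_fixture(tmp_path / "copy.tsv"))
        assert len(clones) == 6


class TestDyz1LikeMonomer:
    def test_length(self, monomer):
        assert monomer.length == 3564

    def test_planted_amplicon_geometry(self, monomer):
        (amp,) = insilico_pcr(monomer, Y_REPEAT_PRIMER_FWD, Y_REPEAT_PRIMER_REV)
        assert (amp.start, amp.end, amp.length) == (2965, 3212, 248)

    def test_island_scores_below_background(self, monomer):
        island = monomer.sequence[1200:1240]
        background = monomer.sequence[400:440]
        assert consensus_homology(island) < consensus_homology(background)
        assert consensus_homology(island) == naive_motif_scan(island, "TTCCA") == (0, 0.0)

    def test_deterministic(self):
        assert dyz1_like_monomer(7).sequence == dyz1_like_monomer(7).sequence
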