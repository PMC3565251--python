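from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from satprobe.discovery import ScanConfig
from satprobe.fixtures import (
    ClonePlacement,
    FixtureSpec,
    InterspersedElement,
    PlantedArray,
    dyz1_like_monomer,
    generate_fixture,
    table1_fixture,
)


@pytest.fixture(scope="session")
def table1_path() -> Path:
    return table1_fixture()


@pytest.fixture(scope="session")
def monomer():
    return dyz1_like_monomer(seed=0)


@pytest.fixture(scope="session")
def small_scan_config() -> ScanConfig:
    """Shrunk scan geometry so brute-force oracles stay fast."""
    return ScanConfig(window=2_000, step=250, min_region_length=4_000)


@pytest.fixture(scope="session")
def planted_fixture():
    """50 kb satellite array in 200 kb of unique background, one clone inside."""
    spec = FixtureSpec(
        seed=7,
        chromosomes=(("chrA", 200_000),),
        planted_arrays=(PlantedArray("chrA", 60_000, "TTCCA", 10_000),),
        clone_placements=(
            ClonePlacement("CL_IN", "chrA", 65_001, 95_000),
            ClonePlacement("CL_OUT", "chrA", 150_001, 180_000),
        ),
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def interrupted_fixture(small_scan_config):
    """Satellite array split by an interspersed Alu — tests the exclusion rule."""
    spec = FixtureSpec(
        seed=11,
        chromosomes=(("chrB", 60_000),),
        planted_arrays=(
            PlantedArray("chrB", 10_000, "TTCCA", 2_000, name="SAT_L"),  # 10-20 kb
            PlantedArray("chrB", 20_300, "TTCCA", 2_000, name="SAT_R"),  # 20.3-30.3 kb
        ),
        interspersed_elements=(InterspersedElement("chrB", 20_000, 300, "SINE/Alu"),),
    )
    return generate_fixture(spec, scan_config=small_scan_config)
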