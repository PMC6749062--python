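import numpy as np
import pytest

from lohqtl.genome import ChromosomeSpec, HetSNPMap
from lohqtl.synth import MapConfig, generate_map


def make_toy_map(markers_per_chrom: int = 12) -> HetSNPMap:
    """Small 4-chromosome map with MAT (chr3) and ACE2 (chr12) loci and
    evenly spaced markers; cheap enough for per-test construction."""
    chroms = [
        ChromosomeSpec(id=3, length=320_000, centromere_pos=114_000, special_loci={"MAT": 200_000}),
        ChromosomeSpec(id=5, length=570_000, centromere_pos=152_000),
        ChromosomeSpec(id=12, length=1_078_000, centromere_pos=151_000, special_loci={"ACE2": 520_000}),
        ChromosomeSpec(id=15, length=1_091_000, centromere_pos=327_000),
    ]
    chrom_ids, positions = [], []
    for c in chroms:
        step = c.length // (markers_per_chrom + 1)
        pos = [k * step for k in range(1, markers_per_chrom + 1)]
        # one marker exactly at each selectable locus, so its genotype
        # tracks the locus allele deterministically
        pos.extend(c.special_loci.values())
        for p in sorted(set(pos)):
            chrom_ids.append(c.id)
            positions.append(p)
    return HetSNPMap(chroms, np.array(chrom_ids), np.array(positions))


@pytest.fixture
def toy_map() -> HetSNPMap:
    return make_toy_map()


@pytest.fixture(scope="session")
def default_map() -> HetSNPMap:
    """The full study-scale synthetic map (~12,000 markers, 16 chromosomes)."""
    return generate_map(MapConfig(seed=20_19))


@pytest.fixture(scope="session")
def medium_map() -> HetSNPMap:
    """A decimated 16-chromosome map (~600 markers) for scan-heavy tests."""
    return generate_map(
        MapConfig(seed=7, target_marker_count=600, marker_counts={4: 15, 14: 40}, chr15_marker_share=0.12)
    )
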