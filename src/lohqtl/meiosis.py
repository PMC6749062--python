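"""Chromatid-resolution meiosis, tetrad formation, and inbred-cross design.

Each meiosis replicates the two homologs of every chromosome into four
chromatids, applies crossovers (Poisson-distributed counts allocated to
chromosomes in proportion to physical length, ~90 genome-wide per
meiosis, optionally at least one per chromosome), and deals the four
chromatids to four spores, one whole chromatid per spore per chromosome.
This makes 2:2 allele segregation at every marker a structural property,
not a statistical one (no gene conversion, no interference).  The deal
is an exchangeable random permutation per chromosome, which reproduces
the classic combinatorial heterozygosity accounting for intra-tetrad
(2/3 retained) and inter-tetrad (1/2 retained) matings.

Spores carry their MAT and ACE2 alleles, tracked exactly through the
crossover exchanges, which drives spore selection for the inter-tetrad
inbred collection: one MATalpha ACE2 spore and one MATa ace2-A7 spore per
tetrad, crossed in all pairwise inter-tetrad combinations (13 tetrads ->
C(13,2) = 78 inbred diploids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import (
    ACE2_ALLELE_OF,
    MAT_ALLELE_OF,
    M,
    ORIGIN_OF_ACE2,
    ORIGIN_OF_MAT,
    P,
    ConfigurationError,
    DiploidGenotype,
    HaplotypeVector,
    HetSNPMap,
    combine_parents,
)


@dataclass
class CrossoverModel:
    """Genome-wide crossover regime for one meiosis."""

    genome_mean_crossovers: float = 90.0
    obligate_chiasma: bool = True  # at least one crossover per chromosome

    def validate(self, n_chromosomes: int) -> None:
        if self.obligate_chiasma and self.genome_mean_crossovers < n_chromosomes:
            raise ConfigurationError(
                "mean crossover count below chromosome number with obligate chiasma"
            )


@dataclass
class Tetrad:
    """Four haploid spores from one meiosis."""

    spores: tuple[HaplotypeVector, HaplotypeVector, HaplotypeVector, HaplotypeVector]
    tetrad_id: str | None = None


def ancestral_haplotypes(hmap: HetSNPMap) -> tuple[HaplotypeVector, HaplotypeVector]:
    """The two unrecombined parental haplotypes of the fully heterozygous
    ancestor: all-M (MATa, ace2-A7) and all-P (MATalpha, ACE2)."""
    n = hmap.n_markers
    h_m = HaplotypeVector(
        origins=np.full(n, M, dtype=np.int8),
        mat_allele=MAT_ALLELE_OF[M],
        ace2_allele=ACE2_ALLELE_OF[M],
        spore_id="ancestor_M",
    )
    h_p = HaplotypeVector(
        origins=np.full(n, P, dtype=np.int8),
        mat_allele=MAT_ALLELE_OF[P],
        ace2_allele=ACE2_ALLELE_OF[P],
        spore_id="ancestor_P",
    )
    return h_m, h_p


def simulate_tetrad(
    hmap: HetSNPMap,
    model: CrossoverModel | None = None,
    rng: np.random.Generator | int | None = None,
    parents: tuple[HaplotypeVector, HaplotypeVector] | None = None,
    tetrad_id: str | None = None,
    forced_crossovers: dict[int, list[tuple[int, int, int]]] | None = None,
    stats: dict | None = None,
) -> Tetrad:
    """Simulate one meiosis of a diploid and return its tetrad.

    ``parents`` are the diploid's two constituent haplotypes (default: the
    pristine fully heterozygous ancestor).  ``forced_crossovers`` maps a
    chromosome id to an explicit list of ``(m_chromatid, p_chromatid,
    bp_position)`` exchanges (chromatid indices 0/1 within each homolog),
    overriding the random draw for that chromosome — used for exact,
    enumerable test scenarios.  If ``stats`` is a dict it receives the
    realized crossover counts (``n_crossovers`` total and per chromosome).
    """
    model = model or CrossoverModel()
    model.validate(len(hmap.chromosomes))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if parents is None:
        parents = ancestral_haplotypes(hmap)
    h1, h2 = parents
    if len(h1) != hmap.n_markers or len(h2) != hmap.n_markers:
        raise ValueError("parent haplotypes do not match the map")

    mat_chrom, mat_pos = hmap.special_locus("MAT")
    ace2_chrom, ace2_pos = hmap.special_locus("ACE2")
    parent_locus_origin = {
        "MAT": (ORIGIN_OF_MAT[h1.mat_allele], ORIGIN_OF_MAT[h2.mat_allele]),
        "ACE2": (ORIGIN_OF_ACE2[h1.ace2_allele], ORIGIN_OF_ACE2[h2.ace2_allele]),
    }
    locus_on_chrom: dict[int, list[tuple[str, int]]] = {}
    locus_on_chrom.setdefault(mat_chrom, []).append(("MAT", mat_pos))
    locus_on_chrom.setdefault(ace2_chrom, []).append(("ACE2", ace2_pos))

    n = hmap.n_markers
    spore_origins = [np.empty(n, dtype=np.int8) for _ in range(4)]
    spore_locus: list[dict[str, int]] = [{} for _ in range(4)]
    total_len = hmap.total_length
    co_per_chrom: dict[int, int] = {}

    for chrom in hmap.chromosomes:
        sl = hmap.chrom_slice(chrom.id)
        pos = hmap.positions[sl]
        # four chromatids: two sisters per homolog
        tids = [
            h1.origins[sl].copy(), h1.origins[sl].copy(),
            h2.origins[sl].copy(), h2.origins[sl].copy(),
        ]
        loci = locus_on_chrom.get(chrom.id, [])
        tid_locus = [
            {name: parent_locus_origin[name][0 if t < 2 else 1] for name, _ in loci}
            for t in range(4)
        ]

        if forced_crossovers is not None and chrom.id in forced_crossovers:
            events = [(i, 2 + j, x) for i, j, x in forced_crossovers[chrom.id]]
        else:
            lam = model.genome_mean_crossovers * chrom.length / total_len
            n_co = int(rng.poisson(lam))
            if model.obligate_chiasma:
                n_co = max(n_co, 1)
            events = [
                (int(rng.integers(0, 2)), 2 + int(rng.integers(0, 2)), int(rng.integers(1, chrom.length)))
                for _ in range(n_co)
            ]
        co_per_chrom[chrom.id] = len(events)

        for i, j, x in events:
            distal = pos > x
            tids[i][distal], tids[j][distal] = tids[j][distal].copy(), tids[i][distal].copy()
            for name, lpos in loci:
                if lpos > x:
                    tid_locus[i][name], tid_locus[j][name] = tid_locus[j][name], tid_locus[i][name]

        # Deal the four chromatids to the four spores by a uniform random
        # permutation, independently per chromosome.  Whole chromatids
        # travel together, so within-chromosome linkage is physical, and
        # 2:2 segregation at every marker is structural; across
        # chromosomes the deal is exchangeable, matching the classic
        # combinatorial heterozygosity accounting (a random sibling-spore
        # mating retains exactly 2/3 of heterozygosity at loci unlinked
        # to the mating-type selection).
        deal = rng.permutation(4)
        for spore_k, tid_k in enumerate(deal):
            spore_origins[spore_k][sl] = tids[tid_k]
            for name, _ in loci:
                spore_locus[spore_k][name] = tid_locus[tid_k][name]

    if stats is not None:
        stats["n_crossovers"] = sum(co_per_chrom.values())
        stats["crossovers_per_chromosome"] = co_per_chrom

    spores = tuple(
        HaplotypeVector(
            origins=spore_origins[k],
            mat_allele=MAT_ALLELE_OF[spore_locus[k]["MAT"]],
            ace2_allele=ACE2_ALLELE_OF[spore_locus[k]["ACE2"]],
            spore_id=f"{tetrad_id or 'tetrad'}_spore{k + 1}",
        )
        for k in range(4)
    )
    return Tetrad(spores=spores, tetrad_id=tetrad_id)


def sib_mate(
    tetrad: Tetrad,
    rng: np.random.Generator | int | None = None,
    strain_id: str | None = None,
    return_parents: bool = False,
):
    """Mate one random MATa spore with one random MATalpha spore of the
    same tetrad and return the resulting diploid genotype."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a_spores = [s for s in tetrad.spores if s.mat_allele == "a"]
    alpha_spores = [s for s in tetrad.spores if s.mat_allele == "alpha"]
    if not a_spores or not alpha_spores:
        raise ValueError("tetrad lacks one of the mating types")
    sa = a_spores[int(rng.integers(len(a_spores)))]
    sb = alpha_spores[int(rng.integers(len(alpha_spores)))]
    d = combine_parents(sa, sb, strain_id=strain_id)
    if return_parents:
        return d, (sa, sb)
    return d


def select_spores(
    tetrad: Tetrad, rng: np.random.Generator | int | None = None
) -> tuple[HaplotypeVector, HaplotypeVector] | None:
    """Pick the (MATalpha ACE2, MATa ace2-A7) spore pair, or ``None``.

    Returns ``None`` (REJECT) when no qualifying pair exists; for unlinked
    MAT/ACE2 this happens in ~1/6 of tetrads.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alpha_ok = [s for s in tetrad.spores if s.mat_allele == "alpha" and s.ace2_allele == "ACE2"]
    a_ok = [s for s in tetrad.spores if s.mat_allele == "a" and s.ace2_allele == "ace2-A7"]
    if not alpha_ok or not a_ok:
        return None
    return (
        alpha_ok[int(rng.integers(len(alpha_ok)))],
        a_ok[int(rng.integers(len(a_ok)))],
    )


def design_inbred_collection(
    selected: Sequence[tuple[HaplotypeVector, HaplotypeVector]],
    tetrad_ids: Sequence[str] | None = None,
) -> list[DiploidGenotype]:
    """Cross every unordered pair of tetrads {i, j}, i<j, mating the
    alpha-spore of i with the a-spore of j.  No intra-tetrad crosses.

    ``selected`` holds one (alpha, a) spore pair per tetrad; n tetrads
    yield n(n-1)/2 diploids (13 -> 78).
    """
    n = len(selected)
    if tetrad_ids is None:
        tetrad_ids = [f"T{k + 1:02d}" for k in range(n)]
    if len(set(tetrad_ids)) != n:
        raise ValueError("duplicate tetrad ids")
    diploids = []
    for i in range(n):
        for j in range(i + 1, n):
            alpha_i = selected[i][0]
            a_j = selected[j][1]
            d = combine_parents(alpha_i, a_j, strain_id=f"{tetrad_ids[i]}x{tetrad_ids[j]}")
            diploids.append(d)
    return diploids


@dataclass
class CollectionResult:
    """A simulated inter-tetrad inbred collection."""

    pairs: list[tuple[HaplotypeVector, HaplotypeVector]]
    diploids: list[DiploidGenotype]
    tetrads: list[Tetrad] = field(default_factory=list)
    n_rejected: int = 0


def simulate_collection(
    hmap: HetSNPMap,
    n_tetrads: int = 13,
    model: CrossoverModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> CollectionResult:
    """Simulate tetrads from the fully heterozygous ancestor, keep the
    first ``n_tetrads`` whose spore selection succeeds, and build the
    inter-tetrad inbred collection."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pairs: list[tuple[HaplotypeVector, HaplotypeVector]] = []
    kept: list[Tetrad] = []
    n_rejected = 0
    k = 0
    while len(pairs) < n_tetrads:
        k += 1
        t = simulate_tetrad(hmap, model=model, rng=rng, tetrad_id=f"T{k:02d}")
        pair = select_spores(t, rng)
        if pair is None:
            n_rejected += 1
            continue
        pairs.append(pair)
        kept.append(t)
    ids = [t.tetrad_id for t in kept]
    diploids = design_inbred_collection(pairs, tetrad_ids=ids)
    return CollectionResult(pairs=pairs, diploids=diploids, tetrads=kept, n_rejected=n_rejected)
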