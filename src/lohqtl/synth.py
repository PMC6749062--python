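"""Synthetic phased HetSNP maps and phenotype-generating models.

Emulates the marker landscape of a partially heterozygous hybrid yeast
genome: ~12,000 HetSNPs over 16 chromosomes, with only ~60% of the genome
lying in high-density heterozygous blocks (the rest already eroded to
homozygosity, hence marker-free).  Three chromosomes get distinctive
profiles mirroring the chromosomes used for targeted uniparental disomy:

* chromosome 4 — large but marker-poor, one central cluster of HetSNPs;
* chromosome 14 — mid-size, ~700 HetSNPs and one long homozygous segment;
* chromosome 15 — large, >1,400 HetSNPs (~12% of the genome total)
  scattered over its whole length.

Phenotypes follow a standard quantitative-genetics liability model: each
planted QTL contributes ``a*x + d*z`` with the additive code ``x`` equal
to -1/0/+1 for PP/MP/MM and the dominance indicator ``z`` equal to 1 for
heterozygotes, plus Gaussian residual noise.  The heat trait is an
ordinal 0-5 colony-size score obtained by thresholding the liability; the
competition trait maps linearly to a bounded per-generation selection
coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import (
    MM,
    MP,
    PP,
    ChromosomeSpec,
    ConfigurationError,
    DiploidGenotype,
    HetSNPMap,
    filter_linked_markers,
)

# Approximate S. cerevisiae chromosome lengths (bp) and centromere
# positions, chr1..chr16; total ~12.07 Mb.
DEFAULT_CHROM_LENGTHS = (
    230_218, 813_184, 316_620, 1_531_933, 576_874, 270_161, 1_090_940,
    562_643, 439_888, 745_751, 666_816, 1_078_177, 924_431, 784_333,
    1_091_291, 948_066,
)
DEFAULT_CENTROMERES = (
    151_465, 238_207, 114_385, 449_711, 151_987, 148_510, 496_920,
    105_586, 355_629, 436_307, 440_129, 150_828, 268_031, 628_758,
    326_584, 555_957,
)

SE_MEDIAN_FACTOR = math.sqrt(math.pi / 2)  # 1.2533...

# Liability cutpoints for the six heat-score bins (scores 0..5).  Chosen
# so that ~40% of a standard-normal (null) population lands in score 3,
# mirroring the share of strains that matched the parent's score.
DEFAULT_HEAT_CUTPOINTS = (-2.0, -1.2, -0.525, 0.525, 1.2)


@dataclass
class MapConfig:
    """Configuration of the synthetic HetSNP map generator."""

    n_chromosomes: int = 16
    chrom_lengths: Sequence[int] = DEFAULT_CHROM_LENGTHS
    centromeres: Sequence[int] = DEFAULT_CENTROMERES
    target_het_genome_fraction: float = 0.60
    target_marker_count: int = 12_023
    mat_pos: int = 200_000  # on chromosome 3
    ace2_pos: int = 520_000  # on chromosome 12
    # per-chromosome profile overrides: chrom id -> profile name
    profiles: dict[int, str] = field(
        default_factory=lambda: {4: "central_cluster", 14: "long_hom_segment", 15: "scattered_dense"}
    )
    # marker-count overrides for the profiled chromosomes
    marker_counts: dict[int, int] = field(default_factory=lambda: {4: 150, 14: 700})
    chr15_marker_share: float = 0.12  # fraction of all markers on chromosome 15
    block_length_mean: float = 40_000.0  # lognormal mean block length (bp)
    block_length_sigma: float = 0.6  # lognormal sigma (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_het_genome_fraction <= 1):
            raise ConfigurationError("het fraction must be in (0, 1]")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigurationError("chromosome lengths must be positive")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigurationError("chrom_lengths length != n_chromosomes")


@dataclass(frozen=True)
class QTL:
    """One planted QTL: marker index, additive effect, dominance deviation."""

    marker_index: int
    additive: float
    dominance: float
    trait: str  # "heat" | "competition"


@dataclass
class QTLTruth:
    """The planted genetic architecture, for truth-vs-called evaluation."""

    qtls: list[QTL] = field(default_factory=list)

    def for_trait(self, trait: str) -> list[QTL]:
        return [q for q in self.qtls if q.trait == trait]


@dataclass
class PhenotypeConfig:
    """Residual noise, replicate structure and trait link functions."""

    residual_sd: dict[str, float] = field(default_factory=lambda: {"heat": 1.0, "competition": 1.0})
    heat_cutpoints: Sequence[float] = DEFAULT_HEAT_CUTPOINTS
    replicates: int = 3
    s_per_latent: float = 0.01  # competition latent -> selection coefficient
    s_bound: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        cp = list(self.heat_cutpoints)
        if len(cp) != 5 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ConfigurationError("heat cutpoints must be 5 strictly increasing values (6 bins)")


def _block_layout(
    length: int,
    het_fraction: float,
    rng: np.random.Generator,
    block_mean: float,
    sigma: float,
) -> list[tuple[int, int]]:
    """Alternating heterozygous-block / homozygous-gap layout.

    Block and gap lengths are lognormal with means tuned so the expected
    block coverage equals ``het_fraction``.
    """
    if het_fraction >= 1.0:
        return [(1, length)]
    gap_mean = block_mean * (1 - het_fraction) / het_fraction
    mu_b = math.log(block_mean) - sigma**2 / 2
    mu_g = math.log(gap_mean) - sigma**2 / 2
    blocks: list[tuple[int, int]] = []
    pos = 1
    # unbiased start: begin in a block with probability het_fraction
    in_block = rng.random() < het_fraction
    while pos <= length:
        draw = rng.lognormal(mu_b if in_block else mu_g, sigma)
        seg = max(1, int(round(draw)))
        end = min(length, pos + seg - 1)
        if in_block:
            blocks.append((pos, end))
        pos = end + 1
        in_block = not in_block
    return blocks


def _chr_layout(cfg: MapConfig, chrom_id: int, length: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    f = cfg.target_het_genome_fraction
    profile = cfg.profiles.get(chrom_id, "scattered")
    if profile == "central_cluster":
        # one heterozygous block centred on the chromosome midpoint
        span = int(round(f * length))
        start = max(1, (length - span) // 2)
        return [(start, min(length, start + span - 1))]
    if profile == "long_hom_segment":
        # one long marker-free segment in the right arm; blocks elsewhere
        seg_len = int(round(0.30 * length))
        seg_start = int(round(0.55 * length))
        seg_end = min(length, seg_start + seg_len - 1)
        # raise block density outside the segment to keep coverage ~f
        f_out = min(0.95, f * length / (length - seg_len))
        out: list[tuple[int, int]] = []
        for b0, b1 in _block_layout(length, f_out, rng, cfg.block_length_mean, cfg.block_length_sigma):
            if b1 < seg_start or b0 > seg_end:
                out.append((b0, b1))
            else:
                if b0 < seg_start:
                    out.append((b0, seg_start - 1))
                if b1 > seg_end:
                    out.append((seg_end + 1, b1))
        return out
    if profile == "scattered_dense":
        # full-length scatter; slightly denser blocks
        return _block_layout(length, min(0.95, f + 0.1), rng, cfg.block_length_mean, cfg.block_length_sigma)
    return _block_layout(length, f, rng, cfg.block_length_mean, cfg.block_length_sigma)


def _sample_positions(blocks: list[tuple[int, int]], count: int, rng: np.random.Generator) -> np.ndarray:
    lengths = np.array([b1 - b0 + 1 for b0, b1 in blocks], dtype=np.int64)
    capacity = int(lengths.sum())
    if count > capacity:
        raise ConfigurationError(f"requested {count} markers but blocks hold only {capacity} bp")
    chosen: set[int] = set()
    weights = lengths / lengths.sum()
    while len(chosen) < count:
        need = count - len(chosen)
        picks = rng.choice(len(blocks), size=max(need * 2, 16), p=weights)
        offs = rng.random(picks.size)
        for k, u in zip(picks, offs):
            b0, b1 = blocks[k]
            pos = b0 + int(u * (b1 - b0 + 1))
            chosen.add(pos)
            if len(chosen) >= count:
                break
    return np.sort(np.fromiter(chosen, dtype=np.int64))


def generate_map(cfg: MapConfig | None = None) -> HetSNPMap:
    """Generate a synthetic phased HetSNP map.

    Markers are placed only inside heterozygous blocks; block coverage
    approximates ``target_het_genome_fraction`` of the genome.  The same
    seed always yields the same map (PCG64 generator).
    """
    cfg = cfg or MapConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_chromosomes
    lengths = list(cfg.chrom_lengths)
    total_len = sum(lengths)

    counts = dict(cfg.marker_counts)
    if 15 <= n:
        counts.setdefault(15, int(round(cfg.chr15_marker_share * cfg.target_marker_count)))
    fixed = {c: v for c, v in counts.items() if c <= n}
    remaining = cfg.target_marker_count - sum(fixed.values())
    free = [c for c in range(1, n + 1) if c not in fixed]
    free_len = sum(lengths[c - 1] for c in free)
    for c in free:
        fixed[c] = int(round(remaining * lengths[c - 1] / free_len))

    chromosomes: list[ChromosomeSpec] = []
    chrom_ids: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    layout: dict[int, list[tuple[int, int]]] = {}
    covered = 0
    for c in range(1, n + 1):
        special = {}
        if c == 3:
            special["MAT"] = cfg.mat_pos
        if c == 12:
            special["ACE2"] = cfg.ace2_pos
        spec = ChromosomeSpec(
            id=c, length=lengths[c - 1], centromere_pos=cfg.centromeres[c - 1], special_loci=special
        )
        chromosomes.append(spec)
        blocks = _chr_layout(cfg, c, spec.length, rng)
        layout[c] = blocks
        covered += sum(b1 - b0 + 1 for b0, b1 in blocks)
        pos = _sample_positions(blocks, fixed[c], rng)
        chrom_ids.append(np.full(pos.size, c, dtype=np.int64))
        positions.append(pos)

    hmap = HetSNPMap(chromosomes, np.concatenate(chrom_ids), np.concatenate(positions))
    # realized heterozygous-block layout, kept for coverage accounting
    hmap.blocks = layout  # type: ignore[attr-defined]
    hmap.block_fraction = covered / hmap.total_length  # type: ignore[attr-defined]
    return hmap


def plant_qtls(
    hmap: HetSNPMap,
    n_per_trait: dict[str, int],
    effect_sizes: dict[str, tuple[float, float]],
    seed: int | np.random.Generator = 0,
) -> QTLTruth:
    """Plant mutually unlinked QTLs (distinct chromosomes when possible).

    ``effect_sizes[trait] = (a, d)``; each planted QTL is assigned that
    additive effect and dominance deviation, with the sign fixed so M is
    the increasing allele.  Markers inside the MAT/ACE2 exclusion windows
    are never chosen.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = filter_linked_markers(hmap)
    truth = QTLTruth()
    for trait, n_q in n_per_trait.items():
        if n_q == 0:
            continue
        a, d = effect_sizes[trait]
        chroms_avail = sorted(set(int(c) for c in hmap.chrom_ids[eligible]))
        if n_q > len(chroms_avail):
            raise ConfigurationError(
                f"cannot place {n_q} unlinked QTLs on {len(chroms_avail)} chromosomes"
            )
        chosen_chroms = rng.choice(chroms_avail, size=n_q, replace=False)
        for c in chosen_chroms:
            cand = eligible[hmap.chrom_ids[eligible] == c]
            idx = int(rng.choice(cand))
            truth.qtls.append(QTL(marker_index=idx, additive=a, dominance=d, trait=trait))
    return truth


def additive_code(codes: np.ndarray) -> np.ndarray:
    """Genotype codes -> additive predictor x: PP=-1, MP=0, MM=+1."""
    return (1 - codes.astype(np.int64)).astype(np.float64)


def dominance_code(codes: np.ndarray) -> np.ndarray:
    """Genotype codes -> dominance indicator z: MP=1, homozygotes=0."""
    return (codes == MP).astype(np.float64)


def phenotypes_from_genotypes(
    genotype_matrix: np.ndarray,
    truth: QTLTruth,
    cfg: PhenotypeConfig,
    trait: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent trait values for each strain under the planted architecture.

    ``genotype_matrix`` is (n_strains, n_markers) int8 codes.  The latent
    value is the sum of ``a*x + d*z`` over the trait's QTLs plus Gaussian
    noise with the trait's residual SD.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_strains = genotype_matrix.shape[0]
    latent = np.zeros(n_strains, dtype=np.float64)
    for q in truth.for_trait(trait):
        g = genotype_matrix[:, q.marker_index]
        latent += q.additive * additive_code(g) + q.dominance * dominance_code(g)
    sd = cfg.residual_sd.get(trait, 0.0)
    if sd > 0:
        latent = latent + rng.normal(0.0, sd, size=n_strains)
    return latent


def latent_to_selection(latent: np.ndarray, cfg: PhenotypeConfig) -> np.ndarray:
    """Map competition latent values to per-generation selection
    coefficients, identity link bounded inside (-s_bound, s_bound)."""
    b = cfg.s_bound
    return np.clip(latent * cfg.s_per_latent, -b + 1e-9, b - 1e-9)


def heat_score_from_liability(x: np.ndarray | float, cutpoints: Sequence[float] | None = None) -> np.ndarray:
    """Ordinal 0-5 heat-tolerance score: the liability's bin index."""
    cp = np.asarray(cutpoints if cutpoints is not None else DEFAULT_HEAT_CUTPOINTS, dtype=float)
    return np.searchsorted(cp, np.atleast_1d(np.asarray(x, dtype=float)), side="left").astype(np.int64)


def summarize_scores(replicate_scores: np.ndarray) -> tuple[float, float, float]:
    """Median score across replicates with its standard error.

    Returns ``(median, se_mean, se_median)`` where the SE of the median is
    1.253 (= sqrt(pi/2)) times the SE of the mean.
    """
    scores = np.asarray(replicate_scores, dtype=float)
    if scores.size < 1:
        raise ValueError("need at least one replicate")
    med = float(np.median(scores))
    if scores.size == 1:
        return med, 0.0, 0.0
    se_mean = float(np.std(scores, ddof=1) / math.sqrt(scores.size))
    return med, se_mean, SE_MEDIAN_FACTOR * se_mean
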