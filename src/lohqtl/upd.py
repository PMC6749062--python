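"""Targeted uniparental disomy (UPD) and the counter-selection screen.

Driving transcription through a centromere destabilises it and induces
loss of the marked homolog; the transient monosomic then endoduplicates
the remaining homolog, yielding a diploid homozygous for one whole
chromosome (UPD) while heterozygosity elsewhere is untouched.  Clones
surviving counter-selection for the centromere-adjacent cassette fall
into four mechanistic classes, distinguished by a three-marker genotyping
screen (left-arm distal, centromere-proximal, right-arm distal) followed
by a tetrad-viability test:

===================  =======================  =========
mechanism            three screen markers     viability
===================  =======================  =========
cassette point mut.  all heterozygous         4:0
interstitial LOH     proximal homozygous,     4:0
                     >=1 distal heterozygous
monosomy             all homozygous-looking   2:2
UPD                  all homozygous           4:0
===================  =======================  =========

PCR-RFLP genotyping cannot distinguish a hemizygous single allele from a
homozygous pair, so monosomics "look" homozygous; the tetrad test
resolves them (2 viable : 2 inviable spores).  The only class the screen
cannot separate from UPD is an LOH tract long enough to span all three
markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import (
    GENO_SYMBOL,
    HAP_SYMBOL,
    M,
    MM,
    MP,
    P,
    PP,
    ConfigurationError,
    DiploidGenotype,
    HetSNPMap,
)

MECHANISMS = ("amds_point_mutation", "interstitial_loh", "monosomy", "upd")

REJECT_MARKERS = "reject_markers"
REJECT_TETRAD = "reject_tetrad"
ACCEPT_UPD = "accept_upd"


@dataclass
class CounterSelectedClone:
    """One clone surviving cassette counter-selection."""

    mechanism: str
    chrom: int
    kept: str | None  # "M" | "P" | None
    marker_genotypes: tuple[str, str, str]  # symbols at (left distal, cen-proximal, right distal)
    tetrad_viability: str  # "4:0" | "2:2"
    tract: tuple[int, int] | None = None  # LOH tract (bp) where applicable


def apply_upd(
    parent: DiploidGenotype, hmap: HetSNPMap, chrom: int, keep: str
) -> DiploidGenotype:
    """Make every marker of ``chrom`` homozygous for the ``keep``
    haplotype; all other chromosomes are untouched.  Idempotent."""
    if keep not in ("M", "P"):
        raise ValueError("keep must be 'M' or 'P'")
    sl = hmap.chrom_slice(chrom)  # raises on invalid chromosome id
    codes = parent.codes.copy()
    codes[sl] = MM if keep == "M" else PP
    return DiploidGenotype(codes=codes, strain_id=f"{parent.strain_id or 'parent'}_UPD{chrom}{keep}{keep}")


def retained_het_fraction(parent: DiploidGenotype, derived: DiploidGenotype) -> float:
    """Fraction of the parent's heterozygous markers still heterozygous."""
    was_het = parent.codes == MP
    if not was_het.any():
        raise ValueError("parent has no heterozygous markers")
    return float(np.mean(derived.codes[was_het] == MP))


def screen_marker_indices(hmap: HetSNPMap, chrom: int) -> tuple[int, int, int]:
    """Global indices of the three screen markers on ``chrom``: left-arm
    distal (first), centromere-proximal (nearest the centromere), and
    right-arm distal (last)."""
    sl = hmap.chrom_slice(chrom)
    if sl.stop - sl.start < 3:
        raise ConfigurationError(f"chromosome {chrom} has fewer than 3 markers")
    cen = hmap.chromosome(chrom).centromere_pos
    return sl.start, hmap.nearest_marker(chrom, cen), sl.stop - 1


def _loh_tract(
    hmap: HetSNPMap, chrom: int, rng: np.random.Generator, mean_length: float
) -> tuple[int, int]:
    """An interstitial LOH tract anchored over the centromere-adjacent
    cassette site, truncated so it never spans both telomeres."""
    spec = hmap.chromosome(chrom)
    cen = spec.centromere_pos
    left = float(rng.exponential(mean_length / 2))
    right = float(rng.exponential(mean_length / 2))
    start = max(1, int(cen - left))
    end = min(spec.length, int(cen + right))
    if start == 1 and end == spec.length:
        # keep at least one telomere outside the tract
        if rng.integers(0, 2):
            start = 2
        else:
            end = spec.length - 1
    return start, end


def simulate_counterselected_clone(
    mechanism: str,
    parent: DiploidGenotype,
    hmap: HetSNPMap,
    chrom: int,
    rng: np.random.Generator | int | None = None,
    loh_mean_length: float = 150_000.0,
) -> CounterSelectedClone:
    """Simulate the screen-visible state of one counter-selected clone."""
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = screen_marker_indices(hmap, chrom)
    parent_sym = tuple(GENO_SYMBOL[int(parent.codes[i])] for i in idx)
    kept_code = int(rng.integers(0, 2))  # which haplotype survives, where applicable
    kept = HAP_SYMBOL[kept_code]
    hom_sym = "MM" if kept_code == M else "PP"

    if mechanism == "amds_point_mutation":
        return CounterSelectedClone(mechanism, chrom, None, parent_sym, "4:0")
    if mechanism == "interstitial_loh":
        start, end = _loh_tract(hmap, chrom, rng, loh_mean_length)
        syms = tuple(
            hom_sym if start <= hmap.positions[i] <= end and parent.codes[i] == MP else parent_sym[k]
            for k, i in enumerate(idx)
        )
        return CounterSelectedClone(mechanism, chrom, kept, syms, "4:0", tract=(start, end))
    if mechanism == "monosomy":
        # hemizygous alleles read as homozygous by PCR-RFLP
        return CounterSelectedClone(mechanism, chrom, kept, (hom_sym,) * 3, "2:2")
    # upd
    return CounterSelectedClone(mechanism, chrom, kept, (hom_sym,) * 3, "4:0")


def screen_clone(clone: CounterSelectedClone) -> str:
    """Two-step screening decision tree.

    Reject unless all three markers genotype as homozygous; then reject
    unless sporulation gives four viable spores per tetrad; accept the
    rest as UPD.
    """
    if any(s not in ("MM", "PP") for s in clone.marker_genotypes):
        return REJECT_MARKERS
    if clone.tetrad_viability != "4:0":
        return REJECT_TETRAD
    return ACCEPT_UPD
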