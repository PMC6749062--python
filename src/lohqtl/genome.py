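"""Phased HetSNP maps and genotype containers for a hybrid diploid genome.

A natural hybrid diploid carries two diverged haplotypes, labelled ``M``
(maternal) and ``P`` (paternal) by convention.  Every heterozygous SNP
(HetSNP) is a marker at which the two haplotypes differ; after meiosis and
mating, each marker of a derived diploid is heterozygous (``MP``) or
homozygous for one haplotype (``MM`` / ``PP``).

Coordinates are 1-based inclusive base pairs.  Genotype codes are small
integers chosen so that the diploid code is the sum of the two gamete
origin codes: ``M = 0``, ``P = 1``; ``MM = 0``, ``MP = 1``, ``PP = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# gamete origin codes
M = 0
P = 1
HAP_SYMBOL = {M: "M", P: "P"}
SYMBOL_HAP = {v: k for k, v in HAP_SYMBOL.items()}

# diploid genotype codes (= sum of the two gamete origins)
MM = 0
MP = 1
PP = 2
GENO_SYMBOL = {MM: "MM", MP: "MP", PP: "PP"}
SYMBOL_GENO = {v: k for k, v in GENO_SYMBOL.items()}

# Which haplotype carries which functional allele at the two selectable
# loci.  The assignment is arbitrary (phase labels are themselves
# arbitrary) and fixed here as a package convention.
MAT_ALLELE_OF = {M: "a", P: "alpha"}
ACE2_ALLELE_OF = {M: "ace2-A7", P: "ACE2"}
ORIGIN_OF_MAT = {v: k for k, v in MAT_ALLELE_OF.items()}
ORIGIN_OF_ACE2 = {v: k for k, v in ACE2_ALLELE_OF.items()}


class GenotypeTableError(ValueError):
    """Raised when a genotype table cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised when a map lacks a required special locus or is malformed."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical length, centromere, and named loci.

    ``special_loci`` maps locus name (e.g. ``"MAT"``, ``"ACE2"``) to its
    1-based bp position.
    """

    id: int
    length: int
    centromere_pos: int
    special_loci: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError(f"chromosome {self.id}: length must be positive")
        if not (0 < self.centromere_pos < self.length):
            raise ConfigurationError(
                f"chromosome {self.id}: centromere {self.centromere_pos} outside (0, {self.length})"
            )
        for name, pos in self.special_loci.items():
            if not (1 <= pos <= self.length):
                raise ConfigurationError(
                    f"chromosome {self.id}: locus {name} at {pos} outside [1, {self.length}]"
                )


class HetSNPMap:
    """A phased marker scaffold: chromosomes plus sorted marker positions.

    Parameters
    ----------
    chromosomes:
        Chromosome specs, one per chromosome, ids unique.
    chrom_ids, positions:
        Parallel arrays giving each marker's chromosome id and bp
        position, sorted by (chromosome, position) with positions unique
        per chromosome.
    marker_ids:
        Optional marker names; default ``"chr<k>:<pos>"``.
    """

    def __init__(
        self,
        chromosomes: Sequence[ChromosomeSpec],
        chrom_ids: np.ndarray,
        positions: np.ndarray,
        marker_ids: Sequence[str] | None = None,
    ) -> None:
        self.chromosomes = list(chromosomes)
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate chromosome ids")
        self._chrom_by_id = {c.id: c for c in self.chromosomes}
        self.chrom_ids = np.asarray(chrom_ids, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=np.int64)
        if self.chrom_ids.shape != self.positions.shape:
            raise ConfigurationError("chrom_ids and positions differ in length")

        order = {c.id: k for k, c in enumerate(self.chromosomes)}
        key = np.array([order[c] for c in self.chrom_ids])
        if np.any(np.diff(key) < 0) or np.any(
            (np.diff(key) == 0) & (np.diff(self.positions) <= 0)
        ):
            raise ConfigurationError("markers must be sorted by (chromosome, position), unique per chromosome")
        for c in self.chromosomes:
            sel = self.chrom_ids == c.id
            if np.any(self.positions[sel] > c.length) or np.any(self.positions[sel] < 1):
                raise ConfigurationError(f"chromosome {c.id}: marker outside [1, length]")

        if marker_ids is None:
            marker_ids = [f"chr{c}:{p}" for c, p in zip(self.chrom_ids, self.positions)]
        self.marker_ids = list(marker_ids)
        if len(self.marker_ids) != self.n_markers:
            raise ConfigurationError("marker_ids length mismatch")

        self._slices: dict[int, slice] = {}
        for c in self.chromosomes:
            idx = np.flatnonzero(self.chrom_ids == c.id)
            self._slices[c.id] = slice(int(idx[0]), int(idx[-1]) + 1) if idx.size else slice(0, 0)

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def chromosome(self, chrom_id: int) -> ChromosomeSpec:
        try:
            return self._chrom_by_id[chrom_id]
        except KeyError:
            raise ConfigurationError(f"no chromosome with id {chrom_id}") from None

    def chrom_slice(self, chrom_id: int) -> slice:
        self.chromosome(chrom_id)
        return self._slices[chrom_id]

    def special_locus(self, name: str) -> tuple[int, int]:
        """Return (chromosome id, position) of a named locus."""
        for c in self.chromosomes:
            if name in c.special_loci:
                return c.id, c.special_loci[name]
        raise ConfigurationError(f"map has no special locus named {name!r}")

    def nearest_marker(self, chrom_id: int, pos: int) -> int:
        """Global index of the marker on ``chrom_id`` closest to ``pos``."""
        sl = self.chrom_slice(chrom_id)
        if sl.stop == sl.start:
            raise ConfigurationError(f"chromosome {chrom_id} has no markers")
        pos_arr = self.positions[sl]
        k = int(np.argmin(np.abs(pos_arr - pos)))
        return sl.start + k

    def __repr__(self) -> str:  # pragma: no cover
        return f"HetSNPMap({len(self.chromosomes)} chromosomes, {self.n_markers} markers)"


@dataclass
class HaplotypeVector:
    """One gamete: per-marker haplotype origin plus its MAT and ACE2 alleles."""

    origins: np.ndarray  # int8, values in {M, P}
    mat_allele: str  # "a" | "alpha"
    ace2_allele: str  # "ACE2" | "ace2-A7"
    spore_id: str | None = None

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype=np.int8)
        if self.mat_allele not in ("a", "alpha"):
            raise ValueError(f"bad MAT allele {self.mat_allele!r}")
        if self.ace2_allele not in ("ACE2", "ace2-A7"):
            raise ValueError(f"bad ACE2 allele {self.ace2_allele!r}")

    def __len__(self) -> int:
        return int(self.origins.size)


@dataclass
class DiploidGenotype:
    """Per-marker genotype of one diploid strain, coded MM=0, MP=1, PP=2."""

    codes: np.ndarray  # int8
    strain_id: str | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def het_fraction(self) -> float:
        return float(np.mean(self.codes == MP))


@dataclass(frozen=True)
class AlleleCounts:
    """Sequencing read counts for the reference and alternative allele."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")


REF, ALT, NOCALL = "REF", "ALT", "NOCALL"


def call_haploid_allele(counts: AlleleCounts, threshold: float = 0.95) -> str:
    """Call a haploid allele from read counts.

    ALT is called only when the alternative-allele frequency strictly
    exceeds ``threshold``; REF only when no alternative read was seen at
    all; anything in between (or zero coverage) is NOCALL.
    """
    total = counts.ref_count + counts.alt_count
    if total < 1:
        return NOCALL
    if counts.alt_count / total > threshold:
        return ALT
    if counts.alt_count == 0:
        return REF
    return NOCALL


def combine_parents(
    h1: HaplotypeVector, h2: HaplotypeVector, strain_id: str | None = None
) -> DiploidGenotype:
    """Deduce a diploid genotype from its two haploid parents.

    A marker is heterozygous exactly when the parents carry different
    haplotype origins there; otherwise it is homozygous for the shared
    origin.  Symmetric in its arguments.
    """
    if len(h1) != len(h2):
        raise ValueError(f"parent haplotypes differ in length ({len(h1)} vs {len(h2)})")
    codes = (h1.origins.astype(np.int8) + h2.origins.astype(np.int8)).astype(np.int8)
    return DiploidGenotype(codes=codes, strain_id=strain_id)


def genotype_fractions(d: DiploidGenotype) -> tuple[float, float, float]:
    """Return (f_MP, f_MM, f_PP), the per-marker genotype class fractions."""
    n = len(d)
    if n == 0:
        raise ValueError("empty genotype")
    f_mm = float(np.mean(d.codes == MM))
    f_mp = float(np.mean(d.codes == MP))
    f_pp = float(np.mean(d.codes == PP))
    return f_mp, f_mm, f_pp


def filter_linked_markers(
    hmap: HetSNPMap, window_mat: int = 50_000, window_ace2: int = 75_000
) -> np.ndarray:
    """Indices of markers not genetically linked to MAT or ACE2.

    Removes markers within the closed interval ±``window_mat`` of MAT and
    ±``window_ace2`` of ACE2 (on their respective chromosomes); these loci
    are forced heterozygous by the spore-selection scheme and carry no
    mapping information.
    """
    mat_chrom, mat_pos = hmap.special_locus("MAT")
    ace2_chrom, ace2_pos = hmap.special_locus("ACE2")
    drop = np.zeros(hmap.n_markers, dtype=bool)
    for chrom, pos, w in ((mat_chrom, mat_pos, window_mat), (ace2_chrom, ace2_pos, window_ace2)):
        sel = (hmap.chrom_ids == chrom) & (np.abs(hmap.positions - pos) <= w)
        drop |= sel
    return np.flatnonzero(~drop)


# ---------------------------------------------------------------------------
# Genotype table I/O (tab-separated, lossless round trip)
# ---------------------------------------------------------------------------

_MAGIC = "#lohqtl-genotype-table\tv1"
_VALID_SYMBOLS = frozenset({"MM", "MP", "PP", "M", "P"})


def write_genotype_table(
    path: str | Path,
    hmap: HetSNPMap,
    genotypes: pd.DataFrame | None = None,
    provenance: str | None = None,
) -> None:
    """Write a map (and optionally per-strain genotype columns) as TSV.

    ``genotypes`` is a DataFrame of genotype symbols (``MM``/``MP``/``PP``
    for diploids, ``M``/``P`` for haploids), one row per marker in map
    order, one column per strain.  Chromosome metadata is stored in
    comment lines so the round trip is lossless.
    """
    path = Path(path)
    if genotypes is not None and len(genotypes) != hmap.n_markers:
        raise ValueError("genotype table row count does not match map")
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        if provenance:
            fh.write(f"#provenance\t{provenance}\n")
        for c in hmap.chromosomes:
            loci = "".join(f"\t{k}={v}" for k, v in sorted(c.special_loci.items()))
            fh.write(f"#chromosome\tid={c.id}\tlength={c.length}\tcentromere={c.centromere_pos}{loci}\n")
        strains = list(genotypes.columns) if genotypes is not None else []
        fh.write("\t".join(["chrom", "pos", "marker_id", *strains]) + "\n")
        cols = [hmap.chrom_ids.astype(str), hmap.positions.astype(str), np.array(hmap.marker_ids)]
        if genotypes is not None:
            for s in strains:
                cols.append(genotypes[s].to_numpy(dtype=str))
        block = np.column_stack(cols)
        fh.write("\n".join("\t".join(row) for row in block))
        fh.write("\n")


def read_genotype_table(path: str | Path) -> tuple[HetSNPMap, pd.DataFrame]:
    """Read a genotype TSV written by :func:`write_genotype_table`.

    Returns the map and a (possibly empty-columned) DataFrame of genotype
    symbols indexed like the map.  Raises :class:`GenotypeTableError`
    naming the offending row/cell on malformed input.
    """
    path = Path(path)
    chromosomes: list[ChromosomeSpec] = []
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split("\t")
                if parts[0] == "#chromosome":
                    kv = dict(p.split("=", 1) for p in parts[1:])
                    special = {
                        k: int(v)
                        for k, v in kv.items()
                        if k not in ("id", "length", "centromere")
                    }
                    chromosomes.append(
                        ChromosomeSpec(
                            id=int(kv["id"]),
                            length=int(kv["length"]),
                            centromere_pos=int(kv["centromere"]),
                            special_loci=special,
                        )
                    )
                continue
            if header is None:
                header = line.split("\t")
                if header[:3] != ["chrom", "pos", "marker_id"]:
                    raise GenotypeTableError(
                        f"{path}:{lineno}: expected header starting 'chrom pos marker_id'"
                    )
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise GenotypeTableError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            rows.append(fields)
    if header is None:
        raise GenotypeTableError(f"{path}: no header row found")
    if not chromosomes:
        raise GenotypeTableError(f"{path}: no #chromosome metadata lines found")

    strains = header[3:]
    chrom_ids = np.array([int(r[0]) for r in rows], dtype=np.int64)
    positions = np.array([int(r[1]) for r in rows], dtype=np.int64)
    marker_ids = [r[2] for r in rows]
    if len(set(marker_ids)) != len(marker_ids):
        seen: set[str] = set()
        for i, mid in enumerate(marker_ids):
            if mid in seen:
                raise GenotypeTableError(f"{path}: duplicate marker id {mid!r} at data row {i + 1}")
            seen.add(mid)
    try:
        hmap = HetSNPMap(chromosomes, chrom_ids, positions, marker_ids)
    except ConfigurationError as exc:
        raise GenotypeTableError(f"{path}: {exc}") from exc

    data: dict[str, list[str]] = {s: [] for s in strains}
    for i, r in enumerate(rows):
        for j, s in enumerate(strains):
            sym = r[3 + j]
            if sym not in _VALID_SYMBOLS:
                raise GenotypeTableError(
                    f"{path}: data row {i + 1} (marker {r[2]}), strain {s!r}: unknown genotype {sym!r}"
                )
            data[s].append(sym)
    table = pd.DataFrame(data, index=marker_ids, dtype=object)
    return hmap, table


def encode_diploids(table: pd.DataFrame) -> np.ndarray:
    """Symbol DataFrame -> (n_strains, n_markers) int8 code matrix."""
    mat = np.empty((table.shape[1], table.shape[0]), dtype=np.int8)
    for j, s in enumerate(table.columns):
        mat[j] = [SYMBOL_GENO[v] for v in table[s]]
    return mat


def diploids_to_table(diploids: Sequence[DiploidGenotype], hmap: HetSNPMap) -> pd.DataFrame:
    """Diploid genotypes -> symbol DataFrame keyed by marker id."""
    data = {}
    for k, d in enumerate(diploids):
        if len(d) != hmap.n_markers:
            raise ValueError(f"strain {d.strain_id}: genotype length does not match map")
        name = d.strain_id or f"strain_{k + 1}"
        data[name] = [GENO_SYMBOL[int(c)] for c in d.codes]
    return pd.DataFrame(data, index=hmap.marker_ids, dtype=object)
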