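"""Single-QTL genome scan with permutation thresholds, region calling,
inheritance-mode classification and variance-explained estimation.

With fully observed genotypes, Haley-Knott regression at a marker is the
least-squares fit of the phenotype on the additive code x (PP=-1, MP=0,
MM=+1) and the dominance indicator z (MP=1), which is equivalent to a
one-way fit of the three genotype-class means.  The marker LOD is the
regression likelihood-ratio statistic

    LOD = (n/2) * log10(RSS0 / RSS1)

where RSS0 comes from the intercept-only model.  Genome-wide significance
is controlled by phenotype permutations: each run shuffles the phenotype
``n_iterations`` times (genotypes fixed), records the maximum LOD across
scanned markers, and takes the (1-alpha) nearest-rank percentile of those
maxima; the final threshold is the median over ``n_runs`` independent
runs.

Regions are maximal runs of consecutive above-threshold markers on one
chromosome.  At each region peak, Tukey HSD pairwise comparisons of the
three genotype-class means classify inheritance as additive, dominant or
overdominant, and the percent variance explained (PVE) is 100 * R^2 of
the genotype-class model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genome import MM, MP, PP, ConfigurationError, HetSNPMap
from .synth import additive_code, dominance_code

ADDITIVE = "additive"
DOMINANT = "dominant"
OVERDOMINANT = "overdominant"


@dataclass
class PermutationSpec:
    """Permutation design for the genome-wide LOD threshold."""

    n_iterations: int = 10_000
    n_runs: int = 5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ConfigurationError("need at least 100 permutation iterations")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")


@dataclass
class ScanResult:
    """Per-marker LOD scan output."""

    lod: np.ndarray  # (n_markers,), NaN at flagged markers
    favored: np.ndarray  # object array of "M"/"P"/"" per marker
    scanned: np.ndarray  # bool mask; False where <2 genotype classes
    n_strains: int
    threshold: float | None = None

    def to_frame(self, hmap: HetSNPMap) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": hmap.chrom_ids,
                "pos": hmap.positions,
                "marker_id": hmap.marker_ids,
                "lod": self.lod,
                "favored_allele": self.favored,
                "scanned": self.scanned,
            }
        )


@dataclass
class Region:
    """One significant region: a maximal above-threshold marker run."""

    chrom: int
    start_index: int
    end_index: int
    peak_index: int
    peak_lod: float
    start_pos: int = 0
    end_pos: int = 0
    peak_pos: int = 0
    favored_allele: str = ""
    inheritance: str | None = None
    pve: float | None = None
    relative_pve: float | None = None


def _class_stats(G: np.ndarray, y: np.ndarray):
    """Per-marker class counts and phenotype sums for MM/MP/PP."""
    counts = np.stack([(G == c).sum(axis=0) for c in (MM, MP, PP)])
    sums = np.stack([y @ (G == c) for c in (MM, MP, PP)])
    return counts, sums


def hk_scan(G: np.ndarray, y: np.ndarray) -> ScanResult:
    """Genome scan: LOD and favored allele at every marker.

    ``G`` is an (n_strains, n_markers) int8 genotype-code matrix, ``y``
    the phenotype vector.  Markers with fewer than two genotype classes
    in the sample are flagged and not scored.  A constant phenotype gives
    LOD = 0 everywhere; a perfect fit (RSS1 = 0) is reported as +inf with
    a warning.
    """
    G = np.asarray(G)
    y = np.asarray(y, dtype=np.float64)
    n, m = G.shape
    if n < 4:
        raise ValueError("need at least 4 strains")
    if y.shape != (n,):
        raise ValueError("phenotype length does not match genotypes")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")

    counts, sums = _class_stats(G, y)
    scanned = (counts > 0).sum(axis=0) >= 2
    tss = float(np.sum((y - y.mean()) ** 2))
    yy = float(np.sum(y * y))

    with np.errstate(divide="ignore", invalid="ignore"):
        explained = np.where(counts > 0, sums**2 / np.where(counts > 0, counts, 1), 0.0)
        rss1 = yy - explained.sum(axis=0)
    rss1 = np.maximum(rss1, 0.0)

    lod = np.full(m, np.nan)
    if tss == 0.0:
        lod[scanned] = 0.0
    else:
        with np.errstate(divide="ignore"):
            vals = (n / 2.0) * np.log10(tss / rss1)
        perfect = scanned & (rss1 <= 1e-12 * tss)
        if perfect.any():
            warnings.warn(f"{int(perfect.sum())} marker(s) fit the phenotype exactly; LOD set to +inf")
            vals[perfect] = np.inf
        lod[scanned] = vals[scanned]

    favored = np.full(m, "", dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    both_hom = (counts[0] > 0) & (counts[2] > 0)
    favored[both_hom & (means[0] > means[2])] = "M"
    favored[both_hom & (means[2] > means[0])] = "P"
    only_mm = (counts[0] > 0) & (counts[2] == 0) & (counts[1] > 0)
    favored[only_mm & (means[0] > means[1])] = "M"
    favored[only_mm & (means[1] > means[0])] = "P"
    only_pp = (counts[2] > 0) & (counts[0] == 0) & (counts[1] > 0)
    favored[only_pp & (means[2] > means[1])] = "P"
    favored[only_pp & (means[1] > means[2])] = "M"
    favored[~scanned] = ""
    return ScanResult(lod=lod, favored=favored, scanned=scanned, n_strains=n)


def _max_lod_permuted(
    G: np.ndarray, y: np.ndarray, scanned: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Max LOD over scanned markers for each permuted phenotype column.

    ``perms`` is an (n_strains, n_perm) matrix of permuted phenotypes.
    The total sum of squares is permutation-invariant, so only the
    within-class sums change.
    """
    n = G.shape[0]
    yy = float(np.sum(y * y))
    tss = float(np.sum((y - y.mean()) ** 2))
    sel = np.flatnonzero(scanned)
    Gs = G[:, sel]
    explained = np.zeros((sel.size, perms.shape[1]))
    for c in (MM, MP, PP):
        ind = (Gs == c).astype(np.float64)  # (n, m_sel)
        counts = ind.sum(axis=0)  # (m_sel,)
        S = ind.T @ perms  # (m_sel, n_perm)
        nz = counts > 0
        explained[nz] += S[nz] ** 2 / counts[nz, None]
    rss1 = np.maximum(yy - explained, 1e-300)
    with np.errstate(divide="ignore"):
        lod = (n / 2.0) * np.log10(tss / rss1)
    return lod.max(axis=0)


def permutation_threshold(
    G: np.ndarray,
    y: np.ndarray,
    spec: PermutationSpec | None = None,
    rng: np.random.Generator | int | None = None,
    block_size: int = 256,
) -> tuple[float, list[float]]:
    """Genome-wide LOD threshold from phenotype permutations.

    Returns ``(threshold, per-run thresholds)``: per run the (1-alpha)
    nearest-rank percentile of the max-LOD null distribution; the final
    threshold is the median across runs.
    """
    spec = spec or PermutationSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    G = np.asarray(G)
    y = np.asarray(y, dtype=np.float64)
    scanned = hk_scan(G, y).scanned
    if not scanned.any():
        raise ValueError("no scannable markers")
    run_thresholds = []
    k = int(np.ceil((1 - spec.alpha) * spec.n_iterations))  # nearest-rank index
    for _ in range(spec.n_runs):
        maxima = np.empty(spec.n_iterations)
        done = 0
        while done < spec.n_iterations:
            b = min(block_size, spec.n_iterations - done)
            perms = np.empty((y.size, b))
            for j in range(b):
                perms[:, j] = rng.permutation(y)
            maxima[done : done + b] = _max_lod_permuted(G, y, scanned, perms)
            done += b
        maxima.sort()
        run_thresholds.append(float(maxima[k - 1]))
    return float(np.median(run_thresholds)), run_thresholds


def call_regions(
    scan: ScanResult, threshold: float, hmap: HetSNPMap, gap: int = 0
) -> list[Region]:
    """Maximal runs of consecutive scanned markers with LOD >= threshold.

    ``gap`` > 0 bridges up to that many consecutive sub-threshold scanned
    markers inside a region.  Peak ties break to the leftmost marker.
    """
    regions: list[Region] = []
    for chrom in hmap.chromosomes:
        sl = hmap.chrom_slice(chrom.id)
        idx = np.arange(sl.start, sl.stop)
        idx = idx[scan.scanned[idx]]
        if idx.size == 0:
            continue
        above = scan.lod[idx] >= threshold
        start = None
        below_run = 0
        last_above = -1
        for k, ok in enumerate(above):
            if ok:
                if start is None:
                    start = k
                last_above = k
                below_run = 0
            elif start is not None:
                below_run += 1
                if below_run > gap:
                    regions.append(_make_region(scan, hmap, chrom.id, idx[start : last_above + 1]))
                    start = None
                    below_run = 0
        if start is not None:
            regions.append(_make_region(scan, hmap, chrom.id, idx[start : last_above + 1]))
    return regions


def _make_region(scan: ScanResult, hmap: HetSNPMap, chrom: int, members: np.ndarray) -> Region:
    lods = scan.lod[members]
    peak_local = int(np.argmax(lods))  # argmax returns the leftmost maximum
    peak = int(members[peak_local])
    return Region(
        chrom=chrom,
        start_index=int(members[0]),
        end_index=int(members[-1]),
        peak_index=peak,
        peak_lod=float(lods[peak_local]),
        start_pos=int(hmap.positions[members[0]]),
        end_pos=int(hmap.positions[members[-1]]),
        peak_pos=int(hmap.positions[peak]),
        favored_allele=str(scan.favored[peak]),
    )


def classify_inheritance(y: np.ndarray, codes: np.ndarray, alpha: float = 0.05) -> str | None:
    """Inheritance mode at one marker from Tukey HSD pairwise tests.

    Overdominant: the heterozygote mean lies strictly outside the
    homozygote range and differs significantly from both homozygotes.
    Dominant: the heterozygote is indistinguishable from exactly one
    homozygote while the two homozygotes differ.  Additive otherwise
    (heterozygote intermediate).  Returns ``None`` when any genotype
    class has fewer than two strains.
    """
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes)
    groups = {c: y[codes == c] for c in (MM, MP, PP)}
    if any(v.size < 2 for v in groups.values()):
        return None
    labels = np.concatenate([np.full(groups[c].size, c) for c in (MM, MP, PP)])
    values = np.concatenate([groups[c] for c in (MM, MP, PP)])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    uniq = [int(g) for g in res.groupsunique]
    pairs = [
        (uniq[i], uniq[j])
        for i in range(len(uniq))
        for j in range(i + 1, len(uniq))
    ]  # statsmodels reports comparisons in this combination order
    sig = {pair: bool(rej) for pair, rej in zip(pairs, res.reject)}
    het_vs_mm = sig[(MM, MP)]
    het_vs_pp = sig[(MP, PP)]
    hom_vs_hom = sig[(MM, PP)]
    mean_mm, mean_mp, mean_pp = (groups[c].mean() for c in (MM, MP, PP))
    lo, hi = min(mean_mm, mean_pp), max(mean_mm, mean_pp)
    if not (lo <= mean_mp <= hi) and het_vs_mm and het_vs_pp:
        return OVERDOMINANT
    if hom_vs_hom and (het_vs_mm != het_vs_pp):
        return DOMINANT
    return ADDITIVE


def pve(y: np.ndarray, codes: np.ndarray) -> float:
    """Percent variance explained: 100 * R^2 of the genotype-class model."""
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes)
    classes = [c for c in (MM, MP, PP) if np.any(codes == c)]
    if y.size <= len(classes):
        raise ValueError("fewer strains than model parameters")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    rss = sum(float(np.sum((y[codes == c] - y[codes == c].mean()) ** 2)) for c in classes)
    return 100.0 * (1.0 - rss / tss)


def relative_pve(pves: list[float]) -> list[float]:
    """PVE values normalised to the locus with the highest PVE."""
    if not pves:
        return []
    top = max(pves)
    if top <= 0:
        return [0.0 for _ in pves]
    return [v / top for v in pves]


def _design(G_sel: np.ndarray, which: list[int]) -> np.ndarray:
    cols = [np.ones(G_sel.shape[0])]
    for j in which:
        cols.append(additive_code(G_sel[:, j]))
        cols.append(dominance_code(G_sel[:, j]))
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def multi_qtl_pve(
    G_sel: np.ndarray,
    y: np.ndarray,
    order: list[int] | None = None,
    alpha: float = 0.01,
) -> tuple[float, list[int]]:
    """Joint PVE of a multi-locus model built by forward selection.

    ``G_sel`` is (n_strains, n_candidate_loci) of genotype codes, columns
    typically the region peak markers ordered by single-locus LOD.  A
    candidate is retained when its partial F-test in the joint model has
    p < ``alpha``.  Returns (joint PVE, kept column indices).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if order is None:
        order = list(range(G_sel.shape[1]))
    tss = float(np.sum((y - y.mean()) ** 2))
    kept: list[int] = []
    for j in order:
        trial = kept + [j]
        X1 = _design(G_sel, trial)
        rss1, rank1 = _rss(X1, y)
        X0 = _design(G_sel, kept)
        rss0, rank0 = _rss(X0, y)
        df_num = rank1 - rank0
        df_den = n - rank1
        if df_num <= 0 or df_den <= 0:
            continue
        if rss1 <= 0:
            kept = trial
            continue
        f_stat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
        if stats.f.sf(f_stat, df_num, df_den) < alpha:
            kept = trial
    rss_final, _ = _rss(_design(G_sel, kept), y)
    if tss == 0:
        return 0.0, kept
    return 100.0 * (1.0 - rss_final / tss), kept


def scan_2d(
    G: np.ndarray,
    y: np.ndarray,
    hmap: HetSNPMap,
    decimation: int = 5,
) -> pd.DataFrame:
    """Pairwise epistasis scan over a decimated marker grid.

    For marker pairs on distinct chromosomes, the interaction LOD is
    ``(n/2) * log10(RSS_additive_pair / RSS_full_pair)`` where the full
    model adds all four product terms between the two loci's (x, z)
    predictors (i.e. fits all nine two-locus class means).
    """
    G = np.asarray(G)
    y = np.asarray(y, dtype=float)
    n = G.shape[0]
    grid = np.arange(0, G.shape[1], decimation)
    rows = []
    for a_i, i in enumerate(grid):
        for j in grid[a_i + 1 :]:
            if hmap.chrom_ids[i] == hmap.chrom_ids[j]:
                continue
            x1, z1 = additive_code(G[:, i]), dominance_code(G[:, i])
            x2, z2 = additive_code(G[:, j]), dominance_code(G[:, j])
            X_add = np.column_stack([np.ones(n), x1, z1, x2, z2])
            X_full = np.column_stack(
                [X_add, x1 * x2, x1 * z2, z1 * x2, z1 * z2]
            )
            rss_add, _ = _rss(X_add, y)
            rss_full, _ = _rss(X_full, y)
            if rss_full <= 0:
                lod_int = np.inf
            else:
                lod_int = (n / 2.0) * np.log10(max(rss_add, 1e-300) / rss_full)
            rows.append((int(i), int(j), float(lod_int)))
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "interaction_lod"])


def closed_form_single_marker_threshold(n: int, alpha: float = 0.05) -> float:
    """Analytic null threshold for a single fully informative marker.

    Under a Gaussian null the scan statistic at one three-class marker is
    an F(2, n-3) test; the (1-alpha) LOD quantile follows from
    R^2* = 2F*/(2F* + (n-3)) and LOD = (n/2) log10(1/(1-R^2*)).
    """
    f_crit = stats.f.isf(alpha, 2, n - 3)
    r2 = 2 * f_crit / (2 * f_crit + (n - 3))
    return (n / 2.0) * np.log10(1.0 / (1.0 - r2))
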