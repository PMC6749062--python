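"""End-to-end pipeline: map -> meiosis/inbreeding -> phenotypes -> scan.

A single global seed drives every stage through named substreams derived
with ``numpy.random.SeedSequence(seed).spawn()`` in a fixed order
(map, meiosis, qtl_truth, phenotype, competition, scan), so re-running
one stage never perturbs the randomness of the others and identical
config + seed gives byte-identical outputs.  Every output TSV carries a
provenance comment line (package version, seed, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .competition import CocultureConfig, simulate_coculture
from .genome import (
    DiploidGenotype,
    filter_linked_markers,
    genotype_fractions,
    diploids_to_table,
    write_genotype_table,
)
from .meiosis import CrossoverModel, simulate_collection
from .qtl import (
    PermutationSpec,
    call_regions,
    classify_inheritance,
    hk_scan,
    multi_qtl_pve,
    permutation_threshold,
    pve,
    relative_pve,
)
from .synth import (
    MapConfig,
    PhenotypeConfig,
    QTLTruth,
    generate_map,
    heat_score_from_liability,
    latent_to_selection,
    phenotypes_from_genotypes,
    plant_qtls,
    summarize_scores,
)

STREAM_NAMES = ("map", "meiosis", "qtl_truth", "phenotype", "competition", "scan")
TRAITS = ("heat", "competition")


@dataclass
class QTLPlanConfig:
    """How many QTLs to plant per trait and with what effects."""

    n_per_trait: dict[str, int] = field(default_factory=lambda: {"heat": 2, "competition": 2})
    additive_effect: dict[str, float] = field(
        default_factory=lambda: {"heat": 0.8165, "competition": 0.8165}
    )
    dominance_effect: dict[str, float] = field(
        default_factory=lambda: {"heat": 0.0, "competition": 0.0}
    )


@dataclass
class RunConfig:
    """All stage configs plus the global seed and output directory."""

    map: MapConfig = field(default_factory=MapConfig)
    crossover: CrossoverModel = field(default_factory=CrossoverModel)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    coculture: CocultureConfig = field(default_factory=CocultureConfig)
    permutation: PermutationSpec = field(default_factory=PermutationSpec)
    qtl_plan: QTLPlanConfig = field(default_factory=QTLPlanConfig)
    n_tetrads: int = 13
    mat_window: int = 50_000
    ace2_window: int = 75_000
    region_gap: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("map", "phenotype", "coculture"):
            for k, v in d[key].items():
                if isinstance(v, tuple):
                    d[key][k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        parts = {
            "map": MapConfig,
            "crossover": CrossoverModel,
            "phenotype": PhenotypeConfig,
            "coculture": CocultureConfig,
            "permutation": PermutationSpec,
            "qtl_plan": QTLPlanConfig,
        }
        kwargs = {}
        for name, klass in parts.items():
            if name in d:
                sub = dict(d.pop(name))
                if name == "map" and "profiles" in sub:
                    sub["profiles"] = {int(k): v for k, v in sub["profiles"].items()}
                if name == "map" and "marker_counts" in sub:
                    sub["marker_counts"] = {int(k): v for k, v in sub["marker_counts"].items()}
                kwargs[name] = klass(**sub)
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named per-stage generators split from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAM_NAMES, children)}


def _write_tsv(path: Path, df: pd.DataFrame, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write all artifacts into ``outdir``.

    Returns the machine-readable run summary (also written as
    ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(config.seed)
    provenance = f"lohqtl {__version__} seed={config.seed} config={config.config_hash()}"
    config.to_yaml(outdir / "config.yaml")
    summary: dict = {"version": __version__, "seed": config.seed, "config_hash": config.config_hash()}

    # stage 1: map
    map_cfg = dataclasses.replace(config.map, seed=int(rngs["map"].integers(2**31)))
    hmap = generate_map(map_cfg)
    summary["n_markers"] = hmap.n_markers
    summary["n_chromosomes"] = len(hmap.chromosomes)

    # stage 2: meiosis + inbred collection
    coll = simulate_collection(hmap, n_tetrads=config.n_tetrads, model=config.crossover, rng=rngs["meiosis"])
    diploids = coll.diploids
    fracs = np.array([genotype_fractions(d) for d in diploids])
    summary["n_strains"] = len(diploids)
    summary["n_tetrads"] = config.n_tetrads
    summary["tetrads_rejected"] = coll.n_rejected
    summary["mean_f_MP"] = round(float(fracs[:, 0].mean()), 6)
    summary["mean_f_MM"] = round(float(fracs[:, 1].mean()), 6)
    summary["mean_f_PP"] = round(float(fracs[:, 2].mean()), 6)
    table = diploids_to_table(diploids, hmap)
    write_genotype_table(outdir / "genotypes.tsv", hmap, table, provenance=provenance)
    G = np.stack([d.codes for d in diploids])

    # stage 3: planted QTL truth
    truth = plant_qtls(
        hmap,
        config.qtl_plan.n_per_trait,
        {t: (config.qtl_plan.additive_effect[t], config.qtl_plan.dominance_effect[t]) for t in TRAITS},
        seed=rngs["qtl_truth"],
    )
    truth_df = pd.DataFrame(
        [
            {
                "trait": q.trait,
                "marker_index": q.marker_index,
                "marker_id": hmap.marker_ids[q.marker_index],
                "chrom": int(hmap.chrom_ids[q.marker_index]),
                "pos": int(hmap.positions[q.marker_index]),
                "additive": q.additive,
                "dominance": q.dominance,
            }
            for q in truth.qtls
        ]
    )
    _write_tsv(outdir / "truth.tsv", truth_df, provenance)

    # stage 4: phenotypes
    pheno_rng = rngs["phenotype"]
    pcfg = config.phenotype
    heat_gen = phenotypes_from_genotypes(
        G, truth, dataclasses.replace(pcfg, residual_sd={"heat": 0.0}), "heat", rng=pheno_rng
    )
    heat_scores = np.empty((len(diploids), pcfg.replicates), dtype=np.int64)
    for r in range(pcfg.replicates):
        lat = heat_gen + pheno_rng.normal(0.0, pcfg.residual_sd["heat"], size=len(diploids))
        heat_scores[:, r] = heat_score_from_liability(lat, pcfg.heat_cutpoints)
    heat_summary = [summarize_scores(heat_scores[i]) for i in range(len(diploids))]
    heat_median = np.array([h[0] for h in heat_summary])
    heat_se_med = np.array([h[2] for h in heat_summary])

    comp_latent = phenotypes_from_genotypes(G, truth, pcfg, "competition", rng=pheno_rng)
    s_values = latent_to_selection(comp_latent, pcfg)

    # stage 5: co-culture competitions
    comp_rng = rngs["competition"]
    ccfg = config.coculture
    traj_rows = []
    comp_frac = {c: np.empty(len(diploids)) for c in ccfg.measured_cycles}
    for i, d in enumerate(diploids):
        traj = simulate_coculture(float(s_values[i]), ccfg, rng=comp_rng, strain_id=d.strain_id)
        for r in range(traj.observed.shape[0]):
            for k, c in enumerate(traj.cycles):
                traj_rows.append((d.strain_id, r + 1, int(c), float(traj.observed[r, k])))
        for k, c in enumerate(traj.cycles):
            comp_frac[int(c)][i] = traj.observed[:, k].mean()
    _write_tsv(
        outdir / "trajectories.tsv",
        pd.DataFrame(traj_rows, columns=["strain_id", "replicate", "cycle", "fraction"]),
        provenance,
    )
    pheno_df = pd.DataFrame(
        {
            "strain_id": [d.strain_id for d in diploids],
            "heat_median": heat_median,
            "heat_se_median": np.round(heat_se_med, 6),
            **{f"comp_fraction_c{c}": np.round(comp_frac[c], 6) for c in ccfg.measured_cycles},
        }
    )
    _write_tsv(outdir / "phenotypes.tsv", pheno_df, provenance)

    # stage 6: QTL scans (phenotype for competition = cycle-5 fraction)
    scan_rng = rngs["scan"]
    keep = filter_linked_markers(hmap, config.mat_window, config.ace2_window)
    summary["n_markers_after_filter"] = int(keep.size)
    phenotypes = {"heat": heat_median, "competition": comp_frac[5]}
    region_rows = []
    eval_rows = []
    for trait in TRAITS:
        y = phenotypes[trait]
        scan = hk_scan(G, y)
        excluded = np.ones(hmap.n_markers, dtype=bool)
        excluded[keep] = False
        scan.scanned[excluded] = False
        scan.lod[excluded] = np.nan
        thr, runs = permutation_threshold(G[:, keep], y, config.permutation, rng=scan_rng)
        scan.threshold = thr
        regions = call_regions(scan, thr, hmap, gap=config.region_gap)
        pves = []
        for reg in regions:
            codes = G[:, reg.peak_index]
            reg.inheritance = classify_inheritance(y, codes)
            reg.pve = pve(y, codes)
            pves.append(reg.pve)
        for reg, rel in zip(regions, relative_pve(pves)):
            reg.relative_pve = rel
        peaks = sorted(regions, key=lambda r: -r.peak_lod)
        joint_pve, kept_cols = (0.0, [])
        if peaks:
            G_peaks = G[:, [r.peak_index for r in peaks]]
            joint_pve, kept_cols = multi_qtl_pve(G_peaks, y)
        _write_tsv(outdir / f"scan_{trait}.tsv", scan.to_frame(hmap), provenance)
        for reg in regions:
            region_rows.append(
                {
                    "trait": trait,
                    "chrom": reg.chrom,
                    "start_pos": reg.start_pos,
                    "end_pos": reg.end_pos,
                    "peak_pos": reg.peak_pos,
                    "peak_lod": round(reg.peak_lod, 4),
                    "favored_allele": reg.favored_allele,
                    "inheritance": reg.inheritance or "unavailable",
                    "pve": round(reg.pve, 3),
                    "relative_pve": round(reg.relative_pve, 4),
                }
            )
        summary[f"{trait}_threshold"] = round(thr, 4)
        summary[f"{trait}_threshold_runs"] = [round(t, 4) for t in runs]
        summary[f"{trait}_n_regions"] = len(regions)
        summary[f"{trait}_joint_pve"] = round(joint_pve, 3)
        summary[f"{trait}_n_loci_in_joint_model"] = len(kept_cols)
        for q in truth.for_trait(trait):
            hit = None
            for reg in regions:
                if reg.start_index <= q.marker_index <= reg.end_index:
                    hit = reg
                    break
            eval_rows.append(
                {
                    "trait": trait,
                    "marker_id": hmap.marker_ids[q.marker_index],
                    "chrom": int(hmap.chrom_ids[q.marker_index]),
                    "pos": int(hmap.positions[q.marker_index]),
                    "recovered": hit is not None,
                    "distance_to_peak_bp": abs(int(hmap.positions[q.marker_index]) - hit.peak_pos)
                    if hit
                    else -1,
                }
            )
    _write_tsv(outdir / "regions.tsv", pd.DataFrame(region_rows, columns=[
        "trait", "chrom", "start_pos", "end_pos", "peak_pos", "peak_lod",
        "favored_allele", "inheritance", "pve", "relative_pve",
    ]), provenance)
    eval_df = pd.DataFrame(eval_rows, columns=[
        "trait", "marker_id", "chrom", "pos", "recovered", "distance_to_peak_bp",
    ])
    _write_tsv(outdir / "truth_eval.tsv", eval_df, provenance)
    summary["qtls_planted"] = len(truth.qtls)
    summary["qtls_recovered"] = int(eval_df["recovered"].sum()) if len(eval_df) else 0

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


REPORT_FILES = ("summary.json", "phenotypes.tsv", "regions.tsv", "truth_eval.tsv")


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    for name in REPORT_FILES:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing run artifact: {run_dir / name}")
    with open(run_dir / "summary.json") as fh:
        summary = json.load(fh)
    pheno = read_tsv(run_dir / "phenotypes.tsv")
    regions = read_tsv(run_dir / "regions.tsv")
    evaldf = read_tsv(run_dir / "truth_eval.tsv")

    lines = [
        f"lohqtl run report (seed {summary['seed']}, config {summary['config_hash']})",
        "",
        f"Map: {summary['n_markers']} markers on {summary['n_chromosomes']} chromosomes "
        f"({summary['n_markers_after_filter']} after MAT/ACE2 exclusion)",
        f"Collection: {summary['n_strains']} inbred diploids from {summary['n_tetrads']} tetrads "
        f"({summary['tetrads_rejected']} tetrads rejected during spore selection)",
        "Mean genotype fractions: "
        f"f_MP={summary['mean_f_MP']:.3f} f_MM={summary['mean_f_MM']:.3f} f_PP={summary['mean_f_PP']:.3f}",
        "",
        "Phenotype distributions:",
        f"  heat-score median range: {pheno['heat_median'].min():.1f}..{pheno['heat_median'].max():.1f}",
        f"  cycle-5 competition fraction range: "
        f"{pheno['comp_fraction_c5'].min():.3f}..{pheno['comp_fraction_c5'].max():.3f}",
        "",
    ]
    for trait in TRAITS:
        sub = regions[regions["trait"] == trait]
        lines.append(
            f"{trait}: threshold LOD {summary[f'{trait}_threshold']:.2f}, "
            f"{summary[f'{trait}_n_regions']} significant region(s), "
            f"joint PVE {summary[f'{trait}_joint_pve']:.1f}%"
        )
        for _, r in sub.iterrows():
            lines.append(
                f"  chr{int(r['chrom'])}:{int(r['start_pos'])}-{int(r['end_pos'])} "
                f"peak LOD {r['peak_lod']:.2f} allele {r['favored_allele']} "
                f"{r['inheritance']} PVE {r['pve']:.1f}%"
            )
    lines.append("")
    lines.append("Planted QTL recovery:")
    if len(evaldf) == 0:
        lines.append("  no QTLs planted (pure-noise phenotypes)")
    else:
        for _, r in evaldf.iterrows():
            status = "recovered" if bool(r["recovered"]) else "missed"
            extra = f", {int(r['distance_to_peak_bp'])} bp from peak" if bool(r["recovered"]) else ""
            lines.append(f"  {r['trait']} {r['marker_id']}: {status}{extra}")
    return "\n".join(lines) + "\n"
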