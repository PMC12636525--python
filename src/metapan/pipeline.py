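"""Stage orchestration: simulate -> partition -> recruit -> pnps ->
envcluster -> analyze.

Each stage reads and writes tab-delimited files in a single output
directory, so stages can be run individually (e.g. pointing the partition
stage at an externally produced cluster matrix) or end to end from a YAML
configuration. A run manifest recording the seed, thresholds and library
versions is written alongside the outputs; rerunning with the same
configuration reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import metadata as importlib_metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, codon, envcluster, io, pangenome, recruitment, simulate
from .errors import MetapanError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "partition", "recruit", "pnps", "envcluster", "analyze")

DEFAULT_THRESHOLDS = {
    "detection": 0.25,
    "min_coverage": 20,
    "departure": 0.05,
    "rare_prevalence": 0.15,
    "purifying_cutoff": 0.1,
    "translation_table": 11,
}


class StageError(MetapanError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sim_config(config: dict) -> simulate.SimConfig:
    fields = {f.name for f in dataclasses.fields(simulate.SimConfig)}
    overrides = dict(config.get("simulate") or {})
    unknown = set(overrides) - fields
    if unknown:
        raise MetapanError(f"unknown simulate options: {sorted(unknown)}")
    for key in ("genomes_per_genus", "habitat_of_genus"):
        if isinstance(overrides.get(key), list):
            overrides[key] = tuple(overrides[key])
    overrides.setdefault("seed", int(config.get("seed", 0)))
    return simulate.SimConfig(**overrides)


def _thresholds(config: dict) -> dict:
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(config.get("thresholds") or {})
    return thr


def stage_simulate(config: dict, out: Path) -> None:
    cfg = _sim_config(config)
    seed_note = [f"seed={cfg.seed}"]
    matrix, meta, pan_truth = simulate.gen_pangenome(cfg)
    io.write_cluster_matrix(matrix, out / "cluster_matrix.tsv", seed_note)
    io.write_metadata(meta, out / "genome_metadata.tsv", seed_note)
    truth_cat = pd.DataFrame(
        {
            "cluster_id": list(pan_truth.cluster_category),
            "category": list(pan_truth.cluster_category.values()),
            "habitat_tag": [pan_truth.habitat_tag[c] for c in pan_truth.cluster_category],
        }
    )
    io.write_table(truth_cat, out / "truth_categories.tsv", seed_note)

    profiles, cov_truth = simulate.gen_coverage(matrix, meta, cfg)
    io.write_coverage_tracks(profiles, out / "coverage_tracks.tsv", seed_note)
    io.write_gene_coords(profiles, out / "gene_coords.tsv", seed_note)
    io.write_table(
        cov_truth.abundance.reset_index(), out / "truth_abundance.tsv", seed_note
    )
    samples = pd.DataFrame(
        sorted(cov_truth.sample_habitat.items()), columns=["sample_id", "habitat"]
    )
    io.write_table(samples, out / "sample_habitats.tsv", seed_note)

    env, env_labels = simulate.gen_env(cfg)
    io.write_env_matrix(env, out / "env_matrix.tsv", seed_note)
    io.write_table(
        env_labels.rename_axis("sample_id").reset_index(),
        out / "truth_env_labels.tsv", seed_note,
    )

    _simulate_variants(cfg, matrix, meta, pan_truth, out, seed_note)


def _simulate_variants(cfg, matrix, meta, pan_truth, out: Path, seed_note) -> None:
    """Variant tables for one representative genome per non-rare genus.

    Habitat-specific (genus-specific) gene clusters are generated at the
    low end of the pN/pS spectrum; a slice of core clusters spans it, with
    most genes under strong purifying selection.
    """
    rng = np.random.default_rng([cfg.seed, 6])
    genus_of = meta.set_index("genome_id")["genus"]
    habitat_of = meta.set_index("genome_id")["habitat"]
    core = [c for c, cat in pan_truth.cluster_category.items() if cat == "core"][:10]
    targets: dict[str, float] = {}
    for c in core:
        if rng.random() < 0.8:
            targets[c] = float(rng.uniform(0.01, 0.09))
        else:
            targets[c] = float(rng.uniform(0.12, 0.4))
    spec_by_genus: dict[str, list[str]] = {}
    for c, cat in pan_truth.cluster_category.items():
        if cat == "genus_specific":
            genus = c.split("_spec_")[0].removeprefix("GC_")
            spec_by_genus.setdefault(genus, []).append(c)
            targets[c] = float(rng.uniform(0.005, 0.03))

    cds_map = {c: simulate.random_cds(cfg.gene_length_codons, rng) for c in targets}
    reps = []
    for genus in pd.unique(meta["genus"]):
        genomes = meta.loc[meta["genus"] == genus, "genome_id"]
        rep = sorted(genomes)[0]
        if habitat_of[rep] in simulate.HABITATS:
            reps.append(rep)

    tables, truth_rows = [], []
    for rep in reps:
        genus = genus_of[rep]
        habitat = habitat_of[rep]
        deep_samples = [f"S_{habitat}_{i + 1:02d}" for i in range(2)]
        genes = core + spec_by_genus.get(genus, [])
        for gene in genes:
            if matrix.loc[gene, rep] < 1:
                continue
            gene_cfg = dataclasses.replace(
                cfg, target_pn=targets[gene] * cfg.target_ps
            )
            for sample in deep_samples:
                table, t = simulate.gen_scvs(
                    cds_map[gene], gene_cfg, gene_id=gene, genome_id=rep,
                    sample_id=sample, rng=rng,
                )
                tables.append(table)
                truth_rows.append(
                    {"gene_id": gene, "genome_id": rep, "sample_id": sample,
                     "pnps_truth": t.pnps[gene]}
                )
    variants = pd.concat(tables, ignore_index=True)
    io.write_variant_table(variants, out / "variants.tsv", seed_note)
    io.write_fasta(cds_map, out / "cds.fasta")
    io.write_table(pd.DataFrame(truth_rows), out / "truth_pnps.tsv", seed_note)


def stage_partition(config: dict, out: Path) -> None:
    thr = _thresholds(config)
    matrix = io.read_cluster_matrix(out / "cluster_matrix.tsv")
    meta = io.read_metadata(out / "genome_metadata.tsv")
    categories = pangenome.habitat_specific(
        pangenome.classify_clusters(matrix, meta), meta
    )
    io.write_table(categories, out / "cluster_categories.tsv")
    counts = pangenome.category_counts(categories).rename_axis("category")
    io.write_table(counts.reset_index(name="n_clusters"), out / "category_counts.tsv")
    prevalence = pangenome.prevalence_classes(
        matrix, meta, rare_below=thr["rare_prevalence"]
    )
    io.write_table(prevalence, out / "prevalence_classes.tsv")
    groups = meta.set_index("genome_id")["genus"]
    enrichment = pangenome.functional_enrichment(matrix >= 1, groups)
    io.write_table(enrichment, out / "enrichment.tsv")


def stage_recruit(config: dict, out: Path) -> None:
    thr = _thresholds(config)
    matrix = io.read_cluster_matrix(out / "cluster_matrix.tsv")
    meta = io.read_metadata(out / "genome_metadata.tsv")
    profiles = io.read_coverage_tracks(
        out / "coverage_tracks.tsv", out / "gene_coords.tsv"
    )
    detections = recruitment.detection_table(profiles)
    io.write_table(detections, out / "detection.tsv")
    gene_cov = recruitment.gene_coverage_table(profiles)
    io.write_table(gene_cov, out / "gene_coverage.tsv")
    genome_cov = recruitment.genome_coverage_table(profiles)
    io.write_table(genome_cov, out / "genome_coverage.tsv")
    neighbor_map = (config.get("recruit") or {}).get("neighbor_map")
    sets = recruitment.scg_sets(matrix, meta, neighbor_map)
    genome_rel, genus_rel = recruitment.relative_abundance(
        gene_cov, sets, detections, meta, threshold=thr["detection"]
    )
    io.write_table(genome_rel.reset_index(), out / "abundance_genome.tsv")
    io.write_table(genus_rel.reset_index(), out / "abundance_genus.tsv")


def stage_pnps(config: dict, out: Path) -> None:
    thr = _thresholds(config)
    variants = io.read_variant_table(
        out / "variants.tsv", table_id=thr["translation_table"]
    )
    cds_map = io.read_fasta(out / "cds.fasta")
    table = codon.pnps_table(
        variants, cds_map,
        min_coverage=thr["min_coverage"],
        departure=thr["departure"],
        table_id=thr["translation_table"],
    )
    io.write_table(table, out / "pnps.tsv")


def stage_envcluster(config: dict, out: Path) -> None:
    opts = config.get("envcluster") or {}
    env = io.read_env_matrix(out / "env_matrix.tsv")
    scaled = envcluster.zscale(env)
    k, labels = envcluster.kmeans_select(
        scaled,
        k_max=int(opts.get("k_max", min(6, len(env) - 1))),
        runs=int(opts.get("runs", 10)),
        seed=int(config.get("seed", 0)),
    )
    out_labels = labels.rename_axis("sample_id").reset_index()
    out_labels.insert(0, "k_selected", k)
    io.write_table(out_labels, out / "env_clusters.tsv")
    scores, loadings, var_frac = envcluster.pca(scaled)
    io.write_table(scores.rename_axis("sample_id").reset_index(),
                   out / "env_pca_scores.tsv")
    io.write_table(loadings.rename_axis("parameter").reset_index(),
                   out / "env_pca_loadings.tsv")
    io.write_table(
        pd.DataFrame({"component": scores.columns, "variance_fraction": var_frac}),
        out / "env_pca_variance.tsv",
    )


def stage_analyze(config: dict, out: Path) -> None:
    thr = _thresholds(config)
    pnps = io.read_table(out / "pnps.tsv")
    categories = io.read_table(out / "cluster_categories.tsv")
    tags = dict(zip(categories["cluster_id"], categories["habitat_tag"]))
    ranked = analysis.rank_pnps(pnps, tags)
    io.write_table(ranked, out / "ranked_genes.tsv")
    summary = analysis.purifying_summary(pnps, cutoff=thr["purifying_cutoff"])
    io.write_table(summary.rename_axis("genome_id").reset_index(),
                   out / "purifying_summary.tsv")
    io.write_table(analysis.variance_components(pnps), out / "variance_components.tsv")
    gene_cov = io.read_table(out / "gene_coverage.tsv")
    genome_cov = io.read_table(out / "genome_coverage.tsv")
    habitat_genes = set(categories.loc[
        categories["habitat_tag"].isin(("coastal", "offshore")), "cluster_id"
    ])
    corr = analysis.gene_genome_cov_corr(
        gene_cov[gene_cov["gene_id"].isin(habitat_genes)], genome_cov
    )
    io.write_table(corr.rename_axis("gene_id").reset_index(),
                   out / "gene_genome_corr.tsv")
    if (config.get("analyze") or {}).get("rank_plot"):
        analysis.plot_rank_curves(ranked, out / "rank_plot.png")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "partition": stage_partition,
    "recruit": stage_recruit,
    "pnps": stage_pnps,
    "envcluster": stage_envcluster,
    "analyze": stage_analyze,
}


def run_pipeline(config: dict, out_dir, stages=None) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(stages or config.get("stages") or STAGES)
    unknown = [s for s in todo if s not in STAGES]
    if unknown:
        raise MetapanError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    todo = [s for s in STAGES if s in todo]
    for stage in todo:
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise StageError(stage, exc) from exc
    manifest = {
        "seed": int(config.get("seed", 0)),
        "stages": todo,
        "thresholds": _thresholds(config),
        "simulate": config.get("simulate") or {},
        "versions": _versions(),
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _versions() -> dict:
    out = {}
    for pkg in ("metapan", "numpy", "pandas", "scipy", "scikit-learn",
                "statsmodels", "biopython"):
        try:
            out[pkg] = importlib_metadata.version(pkg)
        except importlib_metadata.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
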