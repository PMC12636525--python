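"""Read-recruitment summaries: detection, trimmed coverage and abundance.

Works from per-nucleotide depth profiles of each genome in each metagenome
sample. Two robust statistics drive everything downstream:

* **detection** — breadth of coverage, the fraction of positions covered
  by at least one read; genomes below a detection threshold (default 0.25)
  in a sample are treated as absent there, which suppresses false
  positives from non-specific recruitment.
* **mean coverage Q2Q3** — the interquartile mean depth: positions whose
  depths fall in the lowest and highest quartiles are discarded before
  averaging, which damps hot spots of non-specific recruitment.

Relative abundance is estimated from single-copy core genes (SCGs) of each
genus — clusters in exactly one copy in every genome of the genus — so
highly recruiting accessory genes cannot bias genome-level coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

DETECTION_THRESHOLD = 0.25


@dataclass
class CoverageProfile:
    """Per-nucleotide depths of one genome in one sample.

    ``gene_map`` maps gene identifiers to 0-based half-open [start, stop)
    intervals on the genome.
    """

    genome_id: str
    sample_id: str
    depths: np.ndarray
    gene_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.size == 0:
            raise InputError(f"empty depth vector for {self.genome_id}/{self.sample_id}")
        for gene, (start, stop) in self.gene_map.items():
            if not (0 <= start < stop <= self.depths.size):
                raise InputError(
                    f"gene {gene} interval [{start},{stop}) outside genome "
                    f"{self.genome_id} of length {self.depths.size}"
                )


def detection(depths) -> float:
    """Fraction of positions covered by at least one read."""
    arr = np.asarray(depths)
    if arr.size == 0:
        raise InputError("detection of an empty depth vector is undefined")
    return float(np.count_nonzero(arr >= 1) / arr.size)


def q2q3_mean(depths) -> float:
    """Interquartile (Q2Q3) mean depth.

    Depths are sorted and floor(n/4) positions are dropped from each end
    before taking the arithmetic mean; with stable sorting of ties this is
    reproducible across platforms without quantile-interpolation
    ambiguity. Vectors shorter than 4 fall back to the plain mean with a
    warning.
    """
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise InputError("q2q3_mean of an empty depth vector is undefined")
    if arr.size < 4:
        logger.warning("q2q3_mean: vector of length %d, using plain mean", arr.size)
        return float(arr.mean())
    trim = arr.size // 4
    return float(np.sort(arr, kind="stable")[trim: arr.size - trim].mean())


def detection_table(profiles) -> pd.DataFrame:
    """Detection of every genome in every sample, one row per profile."""
    return pd.DataFrame(
        [
            {"genome_id": p.genome_id, "sample_id": p.sample_id,
             "detection": detection(p.depths)}
            for p in profiles
        ],
        columns=["genome_id", "sample_id", "detection"],
    )


def gene_coverage_table(profiles) -> pd.DataFrame:
    """Q2Q3 mean coverage of every gene in every profile."""
    rows = []
    for p in profiles:
        for gene, (start, stop) in p.gene_map.items():
            rows.append(
                {"gene_id": gene, "genome_id": p.genome_id,
                 "sample_id": p.sample_id,
                 "q2q3_mean": q2q3_mean(p.depths[start:stop])}
            )
    return pd.DataFrame(rows, columns=["gene_id", "genome_id", "sample_id", "q2q3_mean"])


def genome_coverage_table(profiles) -> pd.DataFrame:
    """Q2Q3 mean coverage of each whole genome in each sample."""
    return pd.DataFrame(
        [
            {"genome_id": p.genome_id, "sample_id": p.sample_id,
             "q2q3_mean": q2q3_mean(p.depths)}
            for p in profiles
        ],
        columns=["genome_id", "sample_id", "q2q3_mean"],
    )


def single_copy_core(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    genus: str,
    neighbor_map: dict[str, str] | None = None,
) -> set[str]:
    """Single-copy core gene clusters of a genus.

    Clusters present in exactly one copy in every genome of the genus. A
    genus represented by a single genome satisfies the core condition
    vacuously; when ``neighbor_map`` names a nearest-neighbor genus for
    it, the set is intersected with the neighbor's single-copy core so the
    estimate is not inflated by the genome's entire single-copy content.
    """
    genus_of = meta.set_index("genome_id")["genus"]
    genomes = [g for g in matrix.columns if genus_of.get(g) == genus]
    if not genomes:
        raise InputError(f"unknown genus {genus!r}")
    sub = matrix[genomes]
    own = set(sub.index[(sub == 1).all(axis=1)])
    if len(genomes) == 1 and neighbor_map and genus in neighbor_map:
        neighbor = neighbor_map[genus]
        own &= single_copy_core(matrix, meta, neighbor)
    return own


def scg_sets(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    neighbor_map: dict[str, str] | None = None,
) -> dict[str, set[str]]:
    """Single-copy core sets for every genus in the metadata."""
    return {
        genus: single_copy_core(matrix, meta, genus, neighbor_map)
        for genus in pd.unique(meta["genus"])
    }


def relative_abundance(
    gene_cov: pd.DataFrame,
    scg_sets: dict[str, set[str]],
    detections: pd.DataFrame,
    meta: pd.DataFrame,
    threshold: float = DETECTION_THRESHOLD,
    mode: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection-filtered relative abundance at genome and genus level.

    Per genome and sample the Q2Q3 coverages of the genus's single-copy
    core genes are averaged (``mode="mean"``; ``"sum"`` keeps the raw sum,
    which biases toward genera with more SCGs) and zeroed whenever the
    genome's detection falls below ``threshold``. Genome values are then
    normalized to sum to one within each sample (all-zero samples stay
    zero), and genus abundance is the sum over member genomes.

    Returns ``(genome_abundance, genus_abundance)`` as wide DataFrames
    (entities x samples).
    """
    if mode not in ("mean", "sum"):
        raise InputError(f"unknown normalization mode {mode!r}")
    genus_of = meta.set_index("genome_id")["genus"]
    genomes = sorted(set(gene_cov["genome_id"]) | set(detections["genome_id"]))
    samples = sorted(set(gene_cov["sample_id"]) | set(detections["sample_id"]))
    det = (
        detections.pivot(index="genome_id", columns="sample_id", values="detection")
        .reindex(index=genomes, columns=samples)
    )
    if det.isna().any().any():
        raise InputError("missing detection record for some genome/sample pair")

    raw = pd.DataFrame(0.0, index=genomes, columns=samples)
    cov = gene_cov.set_index(["genome_id", "gene_id", "sample_id"])["q2q3_mean"]
    for genome in genomes:
        genus = genus_of.get(genome)
        if genus is None:
            raise InputError(f"genome {genome} missing from metadata")
        scgs = scg_sets.get(genus)
        if not scgs:
            raise InputError(f"empty single-copy core set for genus {genus}")
        try:
            sub = cov.loc[genome].loc[sorted(scgs)]
        except KeyError as exc:
            raise InputError(
                f"missing SCG coverage for genome {genome}: {exc}"
            ) from None
        agg = sub.groupby("sample_id").mean() if mode == "mean" else sub.groupby("sample_id").sum()
        for sample in samples:
            if sample not in agg.index:
                raise InputError(f"missing SCG coverage for {genome} in {sample}")
            if det.loc[genome, sample] >= threshold:
                raw.loc[genome, sample] = float(agg[sample])

    totals = raw.sum(axis=0)
    genome_rel = raw.div(totals.where(totals > 0, other=np.inf), axis=1)
    genus_rel = genome_rel.groupby(genus_of.loc[genome_rel.index].to_numpy()).sum()
    genus_rel.index.name = "genus"
    genome_rel.index.name = "genome_id"
    return genome_rel, genus_rel
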