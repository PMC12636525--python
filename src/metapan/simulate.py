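"""Synthetic metapangenome data with recorded ground truth.

Generates every input the pipeline consumes — a genomes-by-gene-cluster
copy-number matrix with designed category structure, habitat-structured
per-nucleotide coverage profiles, single-codon-variant tables with a
designed pN/pS, and a two-cluster environmental parameter matrix — so the
full analysis is testable end to end without sequencing data.

The emulated study design: genera carry a habitat label (coastal,
offshore, or rare), metagenome samples come from two habitats, and a
genome recruits reads deeply in samples matching its genus's habitat and
only marginally elsewhere, so the detection threshold separates true from
spurious presence. Coverage noise is negative-binomial per position
(variance m + a*m^2 at mean m and dispersion a); dispersion 0 switches
every generator into a deterministic mode with constant depths and fixed
variant placement, which is what makes exact-equality round-trip tests
possible. Every generator is a pure function of its configuration,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codon import (
    codon_site_counts,
    nonsynonymous_neighbors,
    split_codons,
    synonymous_neighbors,
    translate_codon,
)
from .errors import ConfigError, InputError
from .recruitment import CoverageProfile

HABITATS = ("coastal", "offshore")

_ENV_PARAMS = (
    "chlorophyll_a", "silicate", "phosphate", "temperature", "salinity", "ph",
    "heterotrophic_bacteria", "prochlorococcus",
)
# Direction of the coastal shift for each parameter: coastal waters have
# elevated chlorophyll/silicate/phosphate and heterotroph counts, and
# depressed salinity/pH/Prochlorococcus relative to offshore.
_ENV_DIRECTION = (+1, +1, +1, +1, -1, -1, +1, -1)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated community and its observation process.

    Defaults describe a desk-scale community: six genera spanning both
    habitats plus one rarely-recruiting genus, three genomes per genus,
    a pangenome with core/genus-specific/multi-genus/singleton pools, six
    metagenome samples per habitat, deep matched recruitment (50x) against
    marginal mismatched recruitment (0.1x), and genes under strong
    purifying selection (target pN/pS = 0.1).
    """

    n_genera: int = 6
    genomes_per_genus: int | tuple[int, ...] = 3
    n_core: int = 40
    n_genus_specific_per_genus: int = 6
    n_multi_genus: int = 8
    n_singletons: int = 30
    habitat_of_genus: tuple[str, ...] | None = None
    n_samples_per_habitat: int = 6
    depth_match: float = 50.0
    depth_mismatch: float = 0.1
    depth_rare: float = 0.0
    depth_dispersion: float = 0.5
    depth_genome_sigma: float = 0.4
    gene_length_codons: int = 60
    target_pn: float = 0.01
    target_ps: float = 0.10
    scv_coverage: int = 100
    planted_alt_freq: float = 0.30
    env_separation: float = 8.0
    n_env_params: int = 6
    detection_threshold: float = 0.25
    seed: int = 0

    @property
    def deterministic(self) -> bool:
        return self.depth_dispersion == 0

    def genus_names(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genera)]

    def genus_sizes(self) -> list[int]:
        if isinstance(self.genomes_per_genus, int):
            return [self.genomes_per_genus] * self.n_genera
        sizes = list(self.genomes_per_genus)
        if len(sizes) != self.n_genera:
            raise ConfigError(
                f"genomes_per_genus has {len(sizes)} entries for "
                f"{self.n_genera} genera"
            )
        return sizes

    def habitats(self) -> list[str]:
        if self.habitat_of_genus is not None:
            habs = list(self.habitat_of_genus)
            if len(habs) != self.n_genera:
                raise ConfigError("habitat_of_genus must name every genus")
            bad = set(habs) - {"coastal", "offshore", "rare"}
            if bad:
                raise ConfigError(f"unknown habitat labels {sorted(bad)}")
            return habs
        # default: alternate coastal/offshore, last genus rare when n >= 5
        habs = [HABITATS[i % 2] for i in range(self.n_genera)]
        if self.n_genera >= 5:
            habs[-1] = "rare"
        return habs

    def validate(self) -> None:
        counts = {
            "n_genera": self.n_genera,
            "n_core": self.n_core,
            "n_genus_specific_per_genus": self.n_genus_specific_per_genus,
            "n_multi_genus": self.n_multi_genus,
            "n_singletons": self.n_singletons,
            "n_samples_per_habitat": self.n_samples_per_habitat,
            "gene_length_codons": self.gene_length_codons,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be non-negative, got {value}")
        if self.n_genera < 1:
            raise ConfigError("need at least one genus")
        if any(s < 1 for s in self.genus_sizes()):
            raise ConfigError("every genus needs at least one genome")
        if self.n_multi_genus > 0 and self.n_genera < 3:
            raise ConfigError(
                "multi-genus-specific clusters need at least 3 genera (a "
                "cluster core to all genera would be core, not multi-genus)"
            )
        habs = self.habitats()
        if self.n_samples_per_habitat > 0:
            for habitat in HABITATS:
                if habitat not in habs:
                    raise ConfigError(
                        f"habitat effects need at least one {habitat} genus"
                    )
        if not 0 <= self.target_pn <= 1:
            raise ConfigError("target_pn must lie in [0, 1]")
        if not 0 < self.target_ps <= 1:
            raise ConfigError("target_ps must lie in (0, 1]")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be non-negative")
        if not 0 < self.planted_alt_freq < 1:
            raise ConfigError("planted_alt_freq must lie in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators for round-trip tests."""

    cluster_category: dict[str, str] = field(default_factory=dict)
    habitat_tag: dict[str, str] = field(default_factory=dict)
    abundance: pd.DataFrame | None = None  # genomes x samples, rows sum to 1/col
    sample_habitat: dict[str, str] = field(default_factory=dict)
    pnps: dict[str, float] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Independent generator per (config seed, stream) pair."""
    return np.random.default_rng([config.seed, stream])


def gen_pangenome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Build a copy-number matrix realizing the configured category counts.

    Core clusters appear in every genome; genus-specific clusters in all
    genomes of one genus; multi-genus clusters in all genomes of a random
    proper subset of >= 2 genera; singletons in one random genome. A tenth
    of the core clusters get a second copy in one random genome so the
    single-copy core is a strict subset of the core.
    """
    config.validate()
    rng = _rng(config, 1)
    genera = config.genus_names()
    sizes = config.genus_sizes()
    habitats = dict(zip(genera, config.habitats()))
    genome_ids, genus_of = [], {}
    for genus, size in zip(genera, sizes):
        for i in range(size):
            gid = f"{genus}_g{i + 1}"
            genome_ids.append(gid)
            genus_of[gid] = genus

    truth = SimTruth()
    cluster_ids, columns = [], {g: [] for g in genome_ids}
    rows = []

    def add_cluster(cid: str, members: dict[str, int], category: str, tag: str):
        cluster_ids.append(cid)
        rows.append([members.get(g, 0) for g in genome_ids])
        truth.cluster_category[cid] = category
        truth.habitat_tag[cid] = tag

    for k in range(config.n_core):
        add_cluster(f"GC_core_{k + 1:04d}", {g: 1 for g in genome_ids}, "core", "none")
    if config.n_genus_specific_per_genus and len(genera) == 1:
        raise ConfigError("genus-specific clusters need at least 2 genera")
    for genus in genera:
        members = {g: 1 for g in genome_ids if genus_of[g] == genus}
        tag = habitats[genus] if habitats[genus] in HABITATS else "none"
        for k in range(config.n_genus_specific_per_genus):
            # a genus-specific cluster in a single-genome genus would be a
            # singleton; category truth follows the classifier's precedence
            category = "singleton" if len(members) == 1 else "genus_specific"
            add_cluster(f"GC_{genus}_spec_{k + 1:03d}", members, category,
                        tag if category == "genus_specific" else "none")
    for k in range(config.n_multi_genus):
        size = int(rng.integers(2, config.n_genera))  # proper subset, >= 2
        subset = sorted(rng.choice(genera, size=size, replace=False))
        members = {g: 1 for g in genome_ids if genus_of[g] in subset}
        habs = {habitats[g] for g in subset}
        tag = habs.pop() if len(habs) == 1 and habs & set(HABITATS) else "none"
        if tag not in HABITATS:
            tag = "none"
        add_cluster(f"GC_multi_{k + 1:03d}", members, "multi_genus_specific", tag)
    for k in range(config.n_singletons):
        host = str(rng.choice(genome_ids))
        add_cluster(f"GC_single_{k + 1:04d}", {host: 1}, "singleton", "none")

    matrix = pd.DataFrame(rows, index=cluster_ids, columns=genome_ids, dtype=int)
    matrix.index.name = "cluster_id"
    # extra copies on some core clusters (keeps categories, breaks single-copy)
    n_multicopy = config.n_core // 10
    if n_multicopy and len(genome_ids) > 1:
        dup_clusters = rng.choice(config.n_core, size=n_multicopy, replace=False)
        for ci in dup_clusters:
            gi = int(rng.integers(len(genome_ids)))
            matrix.iloc[int(ci), gi] = 2

    meta = pd.DataFrame(
        {
            "genome_id": genome_ids,
            "genus": [genus_of[g] for g in genome_ids],
            "habitat": [habitats[genus_of[g]] for g in genome_ids],
        }
    )
    return matrix, meta, truth


def _expected_detection(mean_depth: float, dispersion: float) -> float:
    """P(depth >= 1) per position under the coverage noise model."""
    if dispersion == 0:
        return 1.0 if mean_depth >= 1 else 0.0
    if mean_depth <= 0:
        return 0.0
    # NB(mean m, var m + a m^2): P(0) = (1 + a m)^(-1/a)
    return 1.0 - (1.0 + dispersion * mean_depth) ** (-1.0 / dispersion)


def gen_coverage(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    config: SimConfig,
) -> tuple[list[CoverageProfile], SimTruth]:
    """Simulate per-nucleotide depths of every genome in every sample.

    Each genome's length is the sum of its present clusters' gene lengths
    (one gene per present cluster, laid out contiguously). The mean depth
    in a sample is depth_match when the genome's genus matches the
    sample's habitat, depth_mismatch otherwise, and depth_rare for
    ``rare`` genera, times a per-genome lognormal abundance multiplier.
    Recorded truth abundances are expected relative depths after applying
    the detection rule to the expected breadth of coverage, which is what
    the recruitment stage can recover.
    """
    config.validate()
    rng = _rng(config, 2)
    genus_of = meta.set_index("genome_id")["genus"]
    habitat_of = meta.set_index("genome_id")["habitat"]
    gene_len = config.gene_length_codons * 3
    if gene_len == 0:
        raise InputError("zero-length genes give zero-length genomes")

    multipliers = {
        g: float(np.exp(rng.normal(0.0, config.depth_genome_sigma)))
        if config.depth_genome_sigma > 0 else 1.0
        for g in matrix.columns
    }

    samples = [
        (f"S_{habitat}_{i + 1:02d}", habitat)
        for habitat in HABITATS
        for i in range(config.n_samples_per_habitat)
    ]

    profiles: list[CoverageProfile] = []
    truth = SimTruth(sample_habitat=dict(samples))
    raw = pd.DataFrame(0.0, index=list(matrix.columns), columns=[s for s, _ in samples])
    disp = config.depth_dispersion
    for genome in matrix.columns:
        present = [c for c in matrix.index if matrix.loc[c, genome] >= 1]
        if not present:
            raise InputError(f"genome {genome} carries no gene clusters")
        gene_map = {
            c: (i * gene_len, (i + 1) * gene_len) for i, c in enumerate(present)
        }
        length = len(present) * gene_len
        for sample, habitat in samples:
            gh = habitat_of[genome]
            if gh == "rare":
                base = config.depth_rare
            elif gh == habitat:
                base = config.depth_match
            else:
                base = config.depth_mismatch
            m = base * multipliers[genome]
            if disp == 0:
                depths = np.full(length, float(m))
            elif m <= 0:
                depths = np.zeros(length, dtype=np.int64)
            else:
                depths = rng.negative_binomial(
                    n=1.0 / disp, p=1.0 / (1.0 + disp * m), size=length
                )
            profiles.append(
                CoverageProfile(genome, sample, depths, dict(gene_map))
            )
            if _expected_detection(m, disp) >= config.detection_threshold:
                raw.loc[genome, sample] = m
    totals = raw.sum(axis=0)
    truth.abundance = raw.div(totals.where(totals > 0, other=np.inf), axis=1)
    truth.abundance.index.name = "genome_id"
    return profiles, truth


STOPLESS_CODONS: tuple[str, ...] = tuple(
    sorted(
        c
        for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
        if translate_codon(c) is not None
    )
)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random coding sequence of sense codons (no internal stops)."""
    if n_codons < 1:
        raise ConfigError("a CDS needs at least one codon")
    return "".join(rng.choice(STOPLESS_CODONS, size=n_codons))


def gen_scvs(
    cds: str,
    config: SimConfig,
    *,
    gene_id: str = "gene_1",
    genome_id: str = "genome_1",
    sample_id: str = "sample_1",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Plant single-codon variants on a CDS at a designed pN/pS.

    The gene's synonymous (S) and nonsynonymous (N) site totals are
    computed by enumeration; round(target_ps * S) synonymous and
    round(target_pn * N) nonsynonymous variant codons are planted at
    distinct eligible sites (a site is eligible for a synonymous variant
    when the reference codon has a single-nucleotide synonymous neighbor;
    stop codons are never planted). The recorded truth is the realized

        pN/pS = (n_nonsyn / N) / (n_syn / S),

    which the codon-selection stage recovers exactly in deterministic
    mode. Every codon position gets a record at ``scv_coverage`` so
    coverage filtering is well defined; in stochastic mode the planted
    alternative's read count is binomial around ``planted_alt_freq``.
    """
    config.validate()
    if rng is None:
        rng = _rng(config, 3)
    codons = split_codons(cds)
    for i, c in enumerate(codons):
        if translate_codon(c) is None:
            raise InputError(f"internal stop codon at position {i + 1}")

    S = sum(codon_site_counts(c).syn for c in codons)
    N = sum(codon_site_counts(c).nonsyn for c in codons)
    n_syn = int(round(config.target_ps * S))
    n_nonsyn = int(round(config.target_pn * N))
    if config.target_ps > 0 and n_syn == 0:
        raise ConfigError(
            f"gene too short to host a synonymous variant at pS="
            f"{config.target_ps} (S={S:.2f} sites)"
        )

    eligible_syn = [i for i, c in enumerate(codons) if synonymous_neighbors(c)]
    if len(eligible_syn) < n_syn:
        raise ConfigError("gene too short to host the requested synonymous variants")
    if config.deterministic:
        syn_sites = eligible_syn[:n_syn]
    else:
        syn_sites = sorted(rng.choice(eligible_syn, size=n_syn, replace=False))
    taken = set(syn_sites)
    eligible_nonsyn = [
        i for i, c in enumerate(codons)
        if i not in taken and nonsynonymous_neighbors(c)
    ]
    if len(eligible_nonsyn) < n_nonsyn:
        raise ConfigError("gene too short to host the requested nonsynonymous variants")
    if config.deterministic:
        nonsyn_sites = eligible_nonsyn[:n_nonsyn]
    else:
        nonsyn_sites = sorted(rng.choice(eligible_nonsyn, size=n_nonsyn, replace=False))

    syn_set, nonsyn_set = set(syn_sites), set(nonsyn_sites)
    cov = config.scv_coverage
    records = []
    for i, ref in enumerate(codons):
        if i in syn_set:
            alts = synonymous_neighbors(ref)
        elif i in nonsyn_set:
            alts = nonsynonymous_neighbors(ref)
        else:
            alts = None
        if alts is None:
            counts = {ref: cov}
        else:
            alt = alts[0] if config.deterministic else str(rng.choice(alts))
            if config.deterministic:
                n_alt = int(round(config.planted_alt_freq * cov))
            else:
                n_alt = int(rng.binomial(cov, config.planted_alt_freq))
            counts = {ref: cov - n_alt}
            if n_alt > 0:
                counts[alt] = n_alt
        records.append(
            {
                "gene_id": gene_id,
                "genome_id": genome_id,
                "sample_id": sample_id,
                "codon_index": i + 1,
                "reference_codon": ref,
                "coverage": cov,
                "codon_counts": counts,
            }
        )
    ps = n_syn / S
    pn = n_nonsyn / N if N > 0 else 0.0
    truth = SimTruth(pnps={gene_id: pn / ps})
    return pd.DataFrame(records), truth


def gen_community_scvs(
    config: SimConfig,
    gene_targets: dict[str, float],
    *,
    genome_id: str = "genome_1",
    sample_id: str = "sample_1",
    gene_length_codons: int | None = None,
    stream: int = 4,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, float]]:
    """Generate variants for many genes, each with its own target pN/pS.

    ``gene_targets`` maps gene id -> target ratio; the synonymous rate is
    ``config.target_ps`` for every gene and the nonsynonymous rate is
    scaled to hit the target ratio. Returns (variant table, CDS map,
    realized truth ratios).
    """
    rng = _rng(config, stream)
    n_codons = gene_length_codons or config.gene_length_codons
    tables, cds_map, truth = [], {}, {}
    for gene, target in sorted(gene_targets.items()):
        cds = random_cds(n_codons, rng)
        cfg = replace(config, target_pn=target * config.target_ps)
        table, t = gen_scvs(
            cds, cfg, gene_id=gene, genome_id=genome_id, sample_id=sample_id, rng=rng
        )
        tables.append(table)
        cds_map[gene] = cds
        truth[gene] = t.pnps[gene]
    variants = pd.concat(tables, ignore_index=True)
    return variants, cds_map, truth


def purifying_targets(
    n_genes: int,
    frac_low: float,
    rng: np.random.Generator,
    low: tuple[float, float] = (0.01, 0.08),
    high: tuple[float, float] = (0.15, 0.4),
) -> dict[str, float]:
    """Target pN/pS per gene for a community under mostly strong selection.

    Exactly ``round(frac_low * n_genes)`` genes get a target drawn from
    ``low`` (strong purifying selection, below the conventional 0.1
    cutoff) and the rest from ``high``; the ranges leave a margin around
    0.1 so variant-count rounding cannot move a gene across the cutoff.
    """
    n_low = int(round(frac_low * n_genes))
    targets = {}
    for i in range(n_genes):
        lo, hi = (low if i < n_low else high)
        targets[f"gene_{i + 1:04d}"] = float(rng.uniform(lo, hi))
    return targets


def gen_pnps_table(
    n_genes: int = 40,
    n_genomes: int = 4,
    n_samples: int = 4,
    base: float = 0.06,
    gene_sd: float = 0.08,
    genome_sd: float = 0.005,
    sample_sd: float = 0.005,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic pN/pS records with additive gene/genome/sample effects.

    Intended for exercising the variance decomposition: with the default
    effect sizes gene-to-gene variation dominates, mirroring communities
    where selective pressure is a property of the gene rather than of the
    sample or the genome. Ratios are clipped at a small positive floor.
    """
    rng = np.random.default_rng(seed)
    gene_eff = rng.normal(0, gene_sd, n_genes)
    genome_eff = rng.normal(0, genome_sd, n_genomes)
    sample_eff = rng.normal(0, sample_sd, n_samples)
    rows = []
    for i in range(n_genes):
        for j in range(n_genomes):
            for k in range(n_samples):
                ratio = (
                    base + gene_eff[i] + genome_eff[j] + sample_eff[k]
                    + rng.normal(0, noise_sd)
                )
                rows.append(
                    {
                        "gene_id": f"gene_{i + 1:03d}",
                        "genome_id": f"genome_{j + 1:02d}",
                        "sample_id": f"sample_{k + 1:02d}",
                        "ratio": max(ratio, 1e-4),
                    }
                )
    return pd.DataFrame(rows)


def gen_env(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Two-habitat Gaussian environmental parameter matrix.

    Coastal samples have elevated chlorophyll/silicate-type parameters and
    depressed salinity/pH-type parameters, offshore the converse; cluster
    means sit ``env_separation`` within-cluster standard deviations apart
    on every parameter. Returns (matrix, habitat labels). With separation
    0 the clusters coincide and no recovery is guaranteed.
    """
    config.validate()
    if config.n_samples_per_habitat < 2:
        raise ConfigError("need at least 2 samples per habitat")
    rng = _rng(config, 5)
    n_params = config.n_env_params
    if not 1 <= n_params <= len(_ENV_PARAMS):
        raise ConfigError(f"n_env_params must lie in [1, {len(_ENV_PARAMS)}]")
    params = _ENV_PARAMS[:n_params]
    direction = np.asarray(_ENV_DIRECTION[:n_params], dtype=float)
    rows, labels, index = [], [], []
    for habitat in HABITATS:
        sign = +1.0 if habitat == "coastal" else -1.0
        mean = sign * direction * config.env_separation / 2.0
        for i in range(config.n_samples_per_habitat):
            rows.append(mean + rng.normal(0.0, 1.0, n_params))
            labels.append(habitat)
            index.append(f"S_{habitat}_{i + 1:02d}")
    matrix = pd.DataFrame(rows, index=index, columns=list(params))
    matrix.index.name = "sample_id"
    return matrix, pd.Series(labels, index=index, name="habitat")
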