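"""Downstream synthesis of per-gene selective pressures.

Takes the per-(gene, genome, sample) pN/pS records produced by
:mod:`metapan.codon` and summarizes them: gene rank curves per genome
(lowest pN/pS = strongest purifying selection first), the fraction of
genes under strong purifying selection, a sequential ANOVA decomposition
of pN/pS variance into gene, genome and sample components, and the
correlation of habitat-specific gene coverage with host-genome coverage
across samples. Undefined ratios (pS = 0 or insufficient coverage) are
excluded everywhere rather than imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

PURIFYING_CUTOFF = 0.1
_FACTOR_COLUMNS = {"gene": "gene_id", "genome": "genome_id", "sample": "sample_id"}


def _gene_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean defined ratio per (genome, gene), over samples passing filters."""
    defined = records.dropna(subset=["ratio"])
    return (
        defined.groupby(["genome_id", "gene_id"], as_index=False)["ratio"].mean()
    )


def rank_pnps(
    records: pd.DataFrame,
    habitat_tags: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank genes per genome from lowest to highest mean pN/pS.

    Rank 1 is the gene under the strongest purifying selection. Ties are
    broken by gene identifier so ranks are a permutation of 1..n. Habitat
    flags (coastal / offshore / none) are attached from ``habitat_tags``.
    """
    means = _gene_means(records)
    if means.empty:
        logger.warning("rank_pnps: no defined pN/pS ratios")
        return pd.DataFrame(
            columns=["genome_id", "gene_id", "mean_ratio", "rank", "habitat_flag"]
        )
    pieces = []
    for genome, group in means.groupby("genome_id", sort=True):
        ordered = group.sort_values(["ratio", "gene_id"]).reset_index(drop=True)
        ordered["rank"] = np.arange(1, len(ordered) + 1)
        pieces.append(ordered)
    out = pd.concat(pieces, ignore_index=True).rename(columns={"ratio": "mean_ratio"})
    tags = habitat_tags or {}
    out["habitat_flag"] = out["gene_id"].map(lambda g: tags.get(g, "none"))
    return out[["genome_id", "gene_id", "mean_ratio", "rank", "habitat_flag"]]


def purifying_summary(records: pd.DataFrame, cutoff: float = PURIFYING_CUTOFF) -> pd.Series:
    """Per-genome fraction of genes with mean pN/pS at or below ``cutoff``.

    Gene-level values are means over the samples where the gene passed the
    coverage filter; genomes without any defined ratio are omitted.
    """
    means = _gene_means(records)
    if means.empty:
        raise InputError("purifying_summary requires at least one defined ratio")
    frac = means.groupby("genome_id")["ratio"].apply(
        lambda r: float((r <= cutoff).mean())
    )
    frac.name = "fraction_le_cutoff"
    return frac


def variance_components(
    records: pd.DataFrame,
    factors: tuple[str, ...] = ("gene", "genome", "sample"),
) -> pd.DataFrame:
    """Sequential (Type I) ANOVA decomposition of pN/pS variance.

    Fits a main-effects linear model of the defined ratios on the ordered
    categorical factors and reports each factor's share of the total sum
    of squares; the residual closes the shares to 1. Factors with a single
    level carry no variance and are dropped with a warning. In a balanced
    complete design the decomposition is invariant to factor order;
    otherwise the order (default gene, genome, sample) matters and is the
    caller's modeling choice.
    """
    unknown = [f for f in factors if f not in _FACTOR_COLUMNS]
    if unknown:
        raise InputError(f"unknown factors {unknown}; expected subset of "
                         f"{sorted(_FACTOR_COLUMNS)}")
    data = records.dropna(subset=["ratio"]).copy()
    if data.empty:
        raise InputError("variance_components requires defined ratios")
    used = []
    for f in factors:
        col = _FACTOR_COLUMNS[f]
        if data[col].nunique() < 2:
            logger.warning("variance_components: factor %r has one level, dropped", f)
        else:
            used.append(f)
    total_ss = float(((data["ratio"] - data["ratio"].mean()) ** 2).sum())
    if total_ss == 0:
        raise InputError("ratios are constant; variance decomposition undefined")
    if not used:
        return pd.DataFrame(
            [{"factor": "residual", "fraction_of_ss": 1.0, "sum_sq": total_ss}]
        )
    formula = "ratio ~ " + " + ".join(f"C({_FACTOR_COLUMNS[f]})" for f in used)
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    rows = []
    for f in used:
        ss = float(table.loc[f"C({_FACTOR_COLUMNS[f]})", "sum_sq"])
        rows.append({"factor": f, "fraction_of_ss": ss / total_ss, "sum_sq": ss})
    resid_ss = float(table.loc["Residual", "sum_sq"])
    rows.append(
        {"factor": "residual", "fraction_of_ss": resid_ss / total_ss, "sum_sq": resid_ss}
    )
    return pd.DataFrame(rows, columns=["factor", "fraction_of_ss", "sum_sq"])


def gene_genome_cov_corr(
    gene_cov: pd.DataFrame,
    genome_cov: pd.DataFrame,
) -> pd.Series:
    """Pearson correlation of gene vs host-genome coverage across samples.

    ``gene_cov`` needs columns gene_id, genome_id, sample_id, q2q3_mean;
    ``genome_cov`` needs genome_id, sample_id, q2q3_mean. Genes with fewer
    than 3 paired samples or a constant vector on either side get NaN with
    a warning. Habitat-specific genes that track their genome's
    biogeography should correlate strongly.
    """
    merged = gene_cov.merge(
        genome_cov.rename(columns={"q2q3_mean": "genome_q2q3"}),
        on=["genome_id", "sample_id"],
        how="inner",
    )
    out = {}
    n_undefined = 0
    for gene, group in merged.groupby("gene_id", sort=True):
        x = group["q2q3_mean"].to_numpy(dtype=float)
        y = group["genome_q2q3"].to_numpy(dtype=float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[gene] = float("nan")
            n_undefined += 1
            continue
        out[gene] = float(stats.pearsonr(x, y).statistic)
    if n_undefined:
        logger.warning(
            "gene_genome_cov_corr: %d genes with undefined correlation", n_undefined
        )
    return pd.Series(out, name="pearson_r")


def plot_rank_curves(ranked: pd.DataFrame, path) -> None:
    """Render per-genome pN/pS rank curves, habitat-specific genes marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genomes = list(pd.unique(ranked["genome_id"]))
    fig, axes = plt.subplots(
        1, max(len(genomes), 1), figsize=(3 * max(len(genomes), 1), 3), squeeze=False
    )
    colors = {"coastal": "black", "offshore": "red", "none": "0.7"}
    for ax, genome in zip(axes[0], genomes):
        sub = ranked[ranked["genome_id"] == genome]
        ax.scatter(
            sub["rank"], sub["mean_ratio"],
            c=[colors.get(t, "0.7") for t in sub["habitat_flag"]], s=8,
        )
        ax.set_yscale("log")
        ax.set_title(genome, fontsize=8)
        ax.set_xlabel("gene rank")
    axes[0][0].set_ylabel("pN/pS")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
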