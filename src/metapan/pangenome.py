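"""Partitioning a pangenome into taxon- and habitat-specific gene pools.

Gene clusters are classified from a genomes-by-clusters copy-number matrix:

* **core** — present in every genome;
* **singleton** — present in exactly one genome;
* **genus_specific** — present in all genomes of exactly one genus and in
  no other genome;
* **multi_genus_specific** — present in all genomes of two or more genera
  and in no genome outside those genera;
* **accessory_other** — everything else.

Presence means copy number >= 1; higher copy numbers do not change the
category. Categories are mutually exclusive and exhaustive, with singleton
taking precedence (relevant for single-genome inputs where a singleton
would otherwise also be core).

Taxon-specific clusters whose host genera all share one habitat label are
additionally tagged as habitat-specific (coastal or offshore) pools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

CATEGORIES = (
    "core",
    "singleton",
    "genus_specific",
    "multi_genus_specific",
    "accessory_other",
)

#: Prevalence below which a gene is "rare" within a genus; prevalence 1 is
#: "core", anything in between (including the boundary itself) intermediate.
RARE_PREVALENCE = 0.15


def _check_meta(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Validate that metadata covers the matrix; return genome -> genus."""
    for col in ("genome_id", "genus"):
        if col not in meta.columns:
            raise InputError(f"metadata missing column {col!r}")
    if meta["genome_id"].duplicated().any():
        raise InputError("duplicate genome_id in metadata")
    genus_of = meta.set_index("genome_id")["genus"]
    missing = [g for g in matrix.columns if g not in genus_of.index]
    if missing:
        raise InputError(f"genomes missing from metadata: {missing}")
    return genus_of


def classify_clusters(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Assign every gene cluster to exactly one pangenome category.

    Parameters
    ----------
    matrix
        Copy numbers with clusters as rows (index) and genomes as columns.
    meta
        Genome metadata with columns ``genome_id``, ``genus`` (and
        optionally ``habitat``).

    Returns
    -------
    DataFrame with one row per cluster: ``cluster_id``, ``category``,
    ``genera`` (semicolon-joined host genera for taxon-specific
    categories, empty otherwise), ``n_genomes_present`` and
    ``involves_single_genome_genus`` (taxon-specific calls that rest on a
    genus with a single genome are flagged, as such counts overestimate
    true genus specificity).
    """
    genus_of = _check_meta(matrix, meta)
    presence = matrix.to_numpy() >= 1
    if presence.shape[0] and not presence.any(axis=1).all():
        empty = matrix.index[~presence.any(axis=1)].tolist()
        raise InputError(f"clusters with no presence in any genome: {empty}")
    genera = genus_of.loc[matrix.columns].to_numpy()
    genus_labels = pd.unique(genera)
    genus_cols = {g: np.flatnonzero(genera == g) for g in genus_labels}
    genus_sizes = {g: len(cols) for g, cols in genus_cols.items()}

    n_present = presence.sum(axis=1)
    n_genomes = presence.shape[1]

    rows = []
    for i, cluster in enumerate(matrix.index):
        pres = presence[i]
        touched = [g for g in genus_labels if pres[genus_cols[g]].any()]
        full = [g for g in touched if pres[genus_cols[g]].all()]
        if n_present[i] == 1:
            category, hosts = "singleton", ()
        elif n_present[i] == n_genomes:
            category, hosts = "core", ()
        elif touched == full:
            if len(full) == 1:
                category, hosts = "genus_specific", tuple(full)
            else:
                category, hosts = "multi_genus_specific", tuple(sorted(full))
        else:
            category, hosts = "accessory_other", ()
        rows.append(
            {
                "cluster_id": cluster,
                "category": category,
                "genera": ";".join(hosts),
                "n_genomes_present": int(n_present[i]),
                "involves_single_genome_genus": any(
                    genus_sizes[g] == 1 for g in hosts
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "category", "genera", "n_genomes_present",
            "involves_single_genome_genus",
        ],
    )


def category_counts(categories: pd.DataFrame) -> pd.Series:
    """Number of clusters per category (all categories reported, 0-filled)."""
    counts = categories["category"].value_counts()
    return counts.reindex(CATEGORIES, fill_value=0)


def habitat_specific(categories: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Tag taxon-specific clusters whose host genera share one habitat.

    A cluster is tagged ``coastal`` (``offshore``) iff it is genus-specific
    to a coastal (offshore) genus or multi-genus-specific to a set of
    genera that are all coastal (all offshore). Any set touching a genus
    with another habitat label (e.g. ``rare``) is tagged ``none``.
    """
    if "habitat" not in meta.columns:
        raise InputError("metadata missing column 'habitat'")
    habitat_of = meta.set_index("genus")["habitat"].groupby(level=0).first()

    def tag(row) -> str:
        if row["category"] not in ("genus_specific", "multi_genus_specific"):
            return "none"
        habitats = {habitat_of.get(g) for g in row["genera"].split(";") if g}
        if habitats == {"coastal"}:
            return "coastal"
        if habitats == {"offshore"}:
            return "offshore"
        return "none"

    out = categories.copy()
    out["habitat_tag"] = [tag(row) for _, row in out.iterrows()]
    return out


def prevalence_classes(matrix: pd.DataFrame, meta: pd.DataFrame,
                       rare_below: float = RARE_PREVALENCE) -> pd.DataFrame:
    """Per-genus prevalence class of every item a genus carries.

    For each (cluster, genus) pair with at least one carrier, prevalence is
    the fraction of the genus's genomes containing the item; the class is
    ``core`` at prevalence 1, ``rare`` below ``rare_below`` and
    ``intermediate`` otherwise (the boundary value itself is intermediate).
    """
    genus_of = _check_meta(matrix, meta)
    presence = matrix >= 1
    rows = []
    for genus, genomes in genus_of.groupby(genus_of):
        cols = [g for g in matrix.columns if g in set(genomes.index)]
        prev = presence[cols].mean(axis=1)
        for cluster, p in prev.items():
            if p == 0:
                continue
            if p == 1:
                cls = "core"
            elif p < rare_below:
                cls = "rare"
            else:
                cls = "intermediate"
            rows.append(
                {"cluster_id": cluster, "genus": genus,
                 "prevalence": float(p), "class": cls}
            )
    return pd.DataFrame(rows, columns=["cluster_id", "genus", "prevalence", "class"])


def functional_enrichment(presence: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Score differential presence of functions across genome groups.

    For each function (row of ``presence``, genomes as columns) with pooled
    presence fraction p-bar and per-group fractions p_g over N_g genomes,
    the Rao score statistic for equality of group proportions is

        score = sum_g N_g (p_g - p_bar)^2 / (p_bar (1 - p_bar))

    compared against a chi-square distribution with (groups - 1) degrees of
    freedom; q-values are Benjamini-Hochberg over all functions. The score
    is defined as 0 (p = 1) when the pooled fraction is 0 or 1.
    """
    groups = groups.loc[[g for g in presence.columns if g in groups.index]]
    if len(groups) != presence.shape[1]:
        missing = [g for g in presence.columns if g not in groups.index]
        raise InputError(f"genomes without group assignment: {missing}")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InputError("functional enrichment requires at least two groups")
    sizes = groups.value_counts()
    if (sizes == 0).any():
        raise InputError("every group needs at least one genome")
    df_chi = len(labels) - 1

    pres = (presence >= 1).astype(float)
    rows = []
    for function_id, row in pres.iterrows():
        p_bar = row.mean()
        fracs = {g: row[groups.index[groups == g]].mean() for g in labels}
        if p_bar in (0.0, 1.0):
            score, p = 0.0, 1.0
        else:
            score = sum(
                sizes[g] * (fracs[g] - p_bar) ** 2 for g in labels
            ) / (p_bar * (1 - p_bar))
            p = float(stats.chi2.sf(score, df_chi))
        rec = {"function_id": function_id, "score": float(score), "p_value": p}
        for g in labels:
            rec[f"frac_{g}"] = float(fracs[g])
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = []
    return out
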