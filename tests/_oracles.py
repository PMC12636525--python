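"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the category oracle
enumerates genus subsets directly, the coverage oracles use naive Python
loops and list slicing, and translation goes through Bio.Seq rather than
the package's codon-table cache.
"""

from itertools import combinations

import numpy as np
import pandas as pd
from Bio.Seq import Seq


def oracle_classify(present: pd.Series, genus_of: pd.Series) -> str:
    """Exhaustive subset-enumeration category call for one cluster."""
    carriers = frozenset(present.index[present])
    if len(carriers) == 1:
        return "singleton"
    if carriers == frozenset(present.index):
        return "core"
    genera = sorted(set(genus_of))
    for size in range(1, len(genera) + 1):
        for subset in combinations(genera, size):
            members = frozenset(g for g in present.index
                                if genus_of[g] in subset)
            if carriers == members:
                return "genus_specific" if size == 1 else "multi_genus_specific"
    return "accessory_other"


def random_cluster_matrix(rng: np.random.Generator, n_genomes: int = 8,
                          n_clusters: int = 40):
    """Random presence matrix + genus partition; every cluster non-empty."""
    genomes = [f"g{i + 1}" for i in range(n_genomes)]
    n_genera = int(rng.integers(2, 5))
    genus_of = pd.Series(
        [f"gen{rng.integers(n_genera) + 1}" for _ in genomes], index=genomes
    )
    # make sure each genus label is actually used
    for k in range(n_genera):
        genus_of.iloc[k % n_genomes] = f"gen{k + 1}"
    p = rng.uniform(0.15, 0.7)
    presence = rng.random((n_clusters, n_genomes)) < p
    for i in range(n_clusters):
        if not presence[i].any():
            presence[i, rng.integers(n_genomes)] = True
    matrix = pd.DataFrame(
        presence.astype(int),
        index=[f"c{i + 1}" for i in range(n_clusters)],
        columns=genomes,
    )
    meta = pd.DataFrame(
        {"genome_id": genomes, "genus": genus_of.values,
         "habitat": ["coastal"] * n_genomes}
    )
    return matrix, meta, genus_of


def naive_detection(depths) -> float:
    covered = sum(1 for d in depths if d >= 1)
    return covered / len(depths)


def naive_q2q3(depths) -> float:
    ordered = sorted(depths)
    trim = len(ordered) // 4
    kept = ordered[trim: len(ordered) - trim] if len(ordered) >= 4 else ordered
    return sum(kept) / len(kept)


def biopython_site_counts(codon: str, table_id: int = 11):
    """Synonymous/nonsynonymous site counts via Bio.Seq translation."""
    aa = str(Seq(codon).translate(table=table_id))
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            alt_aa = str(Seq(alt).translate(table=table_id))
            if alt_aa == aa and alt_aa != "*":
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0
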