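"""Per-gene pN/pS from single-codon variants.

The unit of observation is the codon: a single-codon variant (SCV) is a
codon position where reads support more than one codon state. For every
sense codon we count synonymous and nonsynonymous *sites* by enumerating
all nine single-nucleotide substitutions; a codon contributes syn/3
synonymous sites where syn is the number of substitutions that preserve
the amino acid. Observed variants are classified by comparing the amino
acid of the reference codon with that of the most abundant non-reference
codon. Then, per gene and sample,

    pN = (# nonsynonymous variant codons) / (nonsynonymous sites)
    pS = (# synonymous variant codons)    / (synonymous sites)

and pN/pS << 1 indicates purifying selection. Site totals only include
codons whose coverage passes the minimum-coverage filter, so pN and pS
are proportions over the same observable portion of the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import InputError

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: Default genetic code: bacterial/archaeal (translation table 11).
DEFAULT_TABLE = 11


@lru_cache(maxsize=None)
def _code(table_id: int) -> tuple[dict[str, str], frozenset[str]]:
    """Forward codon->amino-acid map and the stop-codon set for a table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


def translate_codon(codon: str, table_id: int = DEFAULT_TABLE) -> str | None:
    """Amino acid for a codon, ``None`` for a stop codon.

    Raises :class:`InputError` for codons with ambiguous bases.
    """
    codon = codon.upper()
    forward, stops = _code(table_id)
    if codon in stops:
        return None
    try:
        return forward[codon]
    except KeyError:
        raise InputError(f"ambiguous or malformed codon {codon!r}") from None


def is_sense(codon: str, table_id: int = DEFAULT_TABLE) -> bool:
    forward, _ = _code(table_id)
    return codon.upper() in forward


@dataclass(frozen=True)
class SiteCounts:
    """Synonymous and nonsynonymous site counts of a single codon.

    For any sense codon ``syn + nonsyn == 3`` because each of the three
    codon positions contributes one site, apportioned by the fraction of
    its three possible substitutions that are synonymous.
    """

    syn: float
    nonsyn: float


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = DEFAULT_TABLE) -> SiteCounts:
    """Count synonymous/nonsynonymous sites of a sense codon.

    Enumerates all nine single-nucleotide substitutions; a substitution is
    synonymous iff the amino acid is unchanged. Substitutions that create
    a stop codon count as nonsynonymous.
    """
    codon = codon.upper()
    aa = translate_codon(codon, table_id)
    if aa is None:
        raise InputError(f"stop codon {codon!r} has no site counts")
    forward, _ = _code(table_id)
    syn = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if forward.get(alt) == aa:
                syn += 1
    return SiteCounts(syn / 3.0, 3.0 - syn / 3.0)


def synonymous_neighbors(codon: str, table_id: int = DEFAULT_TABLE) -> list[str]:
    """Single-nucleotide neighbors encoding the same amino acid (sorted)."""
    aa = translate_codon(codon, table_id)
    forward, _ = _code(table_id)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if forward.get(alt) == aa:
                out.append(alt)
    return sorted(out)


def nonsynonymous_neighbors(codon: str, table_id: int = DEFAULT_TABLE) -> list[str]:
    """Single-nucleotide *sense* neighbors encoding a different amino acid."""
    aa = translate_codon(codon, table_id)
    forward, _ = _code(table_id)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            other = forward.get(alt)
            if other is not None and other != aa:
                out.append(alt)
    return sorted(out)


def classify_codon_change(ref: str, alt: str, table_id: int = DEFAULT_TABLE) -> str:
    """Classify a codon change as ``"synonymous"`` or ``"nonsynonymous"``.

    Classification is by amino-acid identity of the full codons, however
    many nucleotides differ; a change to a stop codon is nonsynonymous.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise InputError("reference and alternative codon are identical")
    ref_aa = translate_codon(ref, table_id)
    if ref_aa is None:
        raise InputError(f"reference codon {ref!r} is a stop codon")
    alt_aa = translate_codon(alt, table_id)  # None for stop -> nonsynonymous
    return "synonymous" if alt_aa == ref_aa else "nonsynonymous"


REQUIRED_VARIANT_COLUMNS = (
    "gene_id",
    "genome_id",
    "sample_id",
    "codon_index",
    "reference_codon",
    "coverage",
    "codon_counts",
)


def split_codons(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise InputError(f"coding sequence length {len(cds)} not divisible by 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def to_coding_strand(cds: str, variants: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Re-orient a minus-strand gene representation to coding orientation.

    A gene stored on the reverse strand has its CDS reverse-complemented and
    its codon records indexed from the other end, with every codon state
    reverse-complemented. Applying this twice is the identity, and pN/pS is
    invariant under a round trip because classification always happens on
    the coding strand.
    """
    n_codons = len(cds) // 3
    rc_cds = str(Seq(cds).reverse_complement())

    def rc(codon: str) -> str:
        return str(Seq(codon).reverse_complement())

    flipped = variants.copy()
    flipped["codon_index"] = n_codons + 1 - flipped["codon_index"].astype(int)
    flipped["reference_codon"] = flipped["reference_codon"].map(rc)
    flipped["codon_counts"] = flipped["codon_counts"].map(
        lambda counts: {rc(c): n for c, n in counts.items()}
    )
    return rc_cds, flipped


def _pick_variant_codon(counts: dict[str, int], ref: str, coverage: float,
                        departure: float) -> str | None:
    """Most abundant non-reference codon if its frequency passes departure.

    Ties are broken lexicographically so the result is reproducible.
    """
    nonref = {c.upper(): n for c, n in counts.items() if c.upper() != ref}
    if not nonref or coverage <= 0:
        return None
    best = min(nonref, key=lambda c: (-nonref[c], c))
    if nonref[best] / coverage >= departure:
        return best
    return None


def gene_pnps(
    variants: pd.DataFrame,
    cds: str,
    min_coverage: int = 20,
    departure: float = 0.05,
    table_id: int = DEFAULT_TABLE,
) -> pd.DataFrame:
    """Compute pN/pS for one gene, per (genome, sample) group of records.

    Parameters
    ----------
    variants
        Codon-level records for a single gene with columns
        ``gene_id, genome_id, sample_id, codon_index (1-based),
        reference_codon, coverage, codon_counts`` where ``codon_counts`` is
        a ``{codon: read count}`` mapping. Records are expected for every
        codon position the profiler observed, variable or not, so coverage
        filtering can act on the whole gene.
    cds
        Coding-strand sequence of the gene; reference codons are validated
        against it.
    min_coverage
        A codon participates (in site totals and as a potential variant)
        only when its coverage is at least this value.
    departure
        Minimum frequency of the most abundant non-reference codon for the
        position to count as a variant site.

    Returns
    -------
    One row per (gene, genome, sample) with variant counts, site counts,
    pn, ps and ratio. ``ratio`` is NaN (undefined) when ps == 0 or when no
    codon passes the coverage filter.
    """
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise InputError(f"variant table missing columns: {missing}")
    codons = split_codons(cds)
    n_skipped = 0
    rows = []
    for (gene, genome, sample), group in variants.groupby(
        ["gene_id", "genome_id", "sample_id"], sort=True
    ):
        syn_sites = nonsyn_sites = 0.0
        n_syn = n_nonsyn = 0
        any_covered = False
        for rec in group.itertuples(index=False):
            idx = int(rec.codon_index)
            if not 1 <= idx <= len(codons):
                raise InputError(
                    f"codon_index {idx} outside gene {gene} ({len(codons)} codons)"
                )
            ref = str(rec.reference_codon).upper()
            if not is_sense(ref, table_id):
                n_skipped += 1
                continue
            if ref != codons[idx - 1]:
                raise InputError(
                    f"reference codon {ref} at position {idx} of {gene} does not "
                    f"match CDS codon {codons[idx - 1]}"
                )
            cov = float(rec.coverage)
            if cov < min_coverage:
                continue
            any_covered = True
            sites = codon_site_counts(ref, table_id)
            syn_sites += sites.syn
            nonsyn_sites += sites.nonsyn
            alt = _pick_variant_codon(rec.codon_counts, ref, cov, departure)
            if alt is None:
                continue
            try:
                kind = classify_codon_change(ref, alt, table_id)
            except InputError:
                n_skipped += 1
                continue
            if kind == "synonymous":
                n_syn += 1
            else:
                n_nonsyn += 1
        if not any_covered:
            pn = ps = ratio = float("nan")
            syn_sites = nonsyn_sites = float("nan")
            n_syn = n_nonsyn = 0
        else:
            pn = n_nonsyn / nonsyn_sites if nonsyn_sites > 0 else float("nan")
            ps = n_syn / syn_sites if syn_sites > 0 else float("nan")
            ratio = pn / ps if ps and ps > 0 else float("nan")
        rows.append(
            {
                "gene_id": gene,
                "genome_id": genome,
                "sample_id": sample,
                "n_syn_variants": n_syn,
                "n_nonsyn_variants": n_nonsyn,
                "syn_sites": syn_sites,
                "nonsyn_sites": nonsyn_sites,
                "pn": pn,
                "ps": ps,
                "ratio": ratio,
            }
        )
    if n_skipped:
        logger.warning("gene_pnps: skipped %d records with non-sense codons", n_skipped)
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "genome_id", "sample_id", "n_syn_variants",
            "n_nonsyn_variants", "syn_sites", "nonsyn_sites", "pn", "ps", "ratio",
        ],
    )
    out.attrs["n_skipped"] = n_skipped
    return out


def pnps_table(
    variants: pd.DataFrame,
    cds_map: dict[str, str],
    min_coverage: int = 20,
    departure: float = 0.05,
    table_id: int = DEFAULT_TABLE,
) -> pd.DataFrame:
    """Apply :func:`gene_pnps` to every gene in a multi-gene variant table."""
    pieces = []
    for gene, group in variants.groupby("gene_id", sort=True):
        if gene not in cds_map:
            raise InputError(f"no CDS provided for gene {gene}")
        pieces.append(
            gene_pnps(group, cds_map[gene], min_coverage, departure, table_id)
        )
    if not pieces:
        return pd.DataFrame(
            columns=[
                "gene_id", "genome_id", "sample_id", "n_syn_variants",
                "n_nonsyn_variants", "syn_sites", "nonsyn_sites", "pn", "ps", "ratio",
            ]
        )
    return pd.concat(pieces, ignore_index=True)
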