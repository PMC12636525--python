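"""Readers and writers for every tabular dialect the pipeline touches.

All tables are UTF-8 tab-delimited with a single header row; lines
starting with ``#`` are metadata comments (the simulator records its seed
there) and are skipped on read. Identifiers are opaque strings. Coverage
tracks use a run-length-encoded, BED-graph-like 5-column layout
(genome, sample, 0-based start, half-open end, depth); gene coordinates a
4-column table; coding sequences plain FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import REQUIRED_VARIANT_COLUMNS, is_sense
from .errors import ParseError
from .recruitment import CoverageProfile

logger = logging.getLogger(__name__)


def write_table(df: pd.DataFrame, path, comments: list[str] | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- matrices

def write_cluster_matrix(matrix: pd.DataFrame, path, comments=None) -> None:
    write_table(matrix.rename_axis("cluster_id"), path, comments, index=True)


def read_cluster_matrix(path) -> pd.DataFrame:
    """Read a clusters-by-genomes copy-number matrix.

    Rejects duplicate cluster/genome identifiers, negative or non-integer
    copy numbers, and clusters with no presence in any genome.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = next(
            (line for line in fh if line.strip() and not line.startswith("#")), ""
        )
    raw_cols = header.rstrip("\n").split("\t")
    if len(set(raw_cols)) != len(raw_cols):
        raise ParseError(f"{path}: duplicate genome columns")
    df = read_table(path)
    if df.columns[0] != "cluster_id":
        raise ParseError(f"{path}: first column must be 'cluster_id'")
    if df["cluster_id"].duplicated().any():
        dup = df["cluster_id"][df["cluster_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate cluster ids {dup}")
    matrix = df.set_index("cluster_id")
    try:
        matrix = matrix.astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer copy numbers ({exc})") from exc
    if (matrix.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative copy numbers")
    empty = matrix.index[(matrix == 0).all(axis=1)].tolist()
    if empty:
        raise ParseError(f"{path}: clusters present in no genome: {empty}")
    return matrix


def write_metadata(meta: pd.DataFrame, path, comments=None) -> None:
    write_table(meta, path, comments)


def read_metadata(path) -> pd.DataFrame:
    meta = read_table(path)
    for col in ("genome_id", "genus", "habitat"):
        if col not in meta.columns:
            raise ParseError(f"{path}: metadata missing column {col!r}")
    if meta["genome_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate genome_id rows")
    return meta


# ---------------------------------------------------------------- variants

def _format_counts(counts: dict[str, int]) -> str:
    return ",".join(f"{c}:{n}" for c, n in sorted(counts.items()))


def _parse_counts(text: str) -> dict[str, int]:
    out = {}
    for item in str(text).split(","):
        if not item:
            continue
        codon, _, n = item.partition(":")
        out[codon.strip().upper()] = int(n)
    return out


def write_variant_table(variants: pd.DataFrame, path, comments=None) -> None:
    out = variants.copy()
    out["codon_counts"] = out["codon_counts"].map(_format_counts)
    write_table(out, path, comments)


def read_variant_table(path, table_id: int = 11) -> pd.DataFrame:
    """Read a codon-variant table, skipping rows with non-sense references.

    Skipped rows (stop or ambiguous reference codons) are counted in the
    returned frame's ``attrs["n_skipped"]`` and logged as one warning.
    """
    df = read_table(path)
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: variant table missing columns {missing}")
    df["reference_codon"] = df["reference_codon"].astype(str).str.upper()
    ok = df["reference_codon"].map(lambda c: is_sense(c, table_id))
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("%s: skipped %d rows with non-sense reference codons",
                       path, n_skipped)
    df = df[ok].reset_index(drop=True)
    df["codon_counts"] = df["codon_counts"].map(_parse_counts)
    df["codon_index"] = df["codon_index"].astype(int)
    df.attrs["n_skipped"] = n_skipped
    return df


# ---------------------------------------------------------------- coverage

def write_coverage_tracks(profiles, path, comments=None) -> None:
    """Run-length-encoded depth tracks, one row per constant-depth run."""
    rows = []
    for p in profiles:
        depths = np.asarray(p.depths)
        change = np.flatnonzero(np.diff(depths)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depths.size]))
        for s, e in zip(starts, ends):
            rows.append((p.genome_id, p.sample_id, int(s), int(e), float(depths[s])))
    df = pd.DataFrame(rows, columns=["genome_id", "sample_id", "start", "end", "depth"])
    write_table(df, path, comments)


def write_gene_coords(profiles, path, comments=None) -> None:
    """Gene coordinate table (genome-level, deduplicated across samples)."""
    seen, rows = set(), []
    for p in profiles:
        if p.genome_id in seen:
            continue
        seen.add(p.genome_id)
        for gene, (start, stop) in p.gene_map.items():
            rows.append((gene, p.genome_id, start, stop))
    df = pd.DataFrame(rows, columns=["gene_id", "genome_id", "start", "stop"])
    write_table(df, path, comments)


def read_coverage_tracks(tracks_path, coords_path, one_based: bool = False):
    """Rebuild :class:`CoverageProfile` objects from RLE tracks + coords.

    ``one_based=True`` accepts one-based inclusive gene coordinates and
    converts them to the 0-based half-open convention used internally.
    """
    tracks = read_table(tracks_path)
    coords = read_table(coords_path)
    offset = 1 if one_based else 0
    gene_maps: dict[str, dict[str, tuple[int, int]]] = {}
    for rec in coords.itertuples(index=False):
        start = int(rec.start) - offset
        stop = int(rec.stop)  # inclusive end == exclusive end - 1 + 1
        gene_maps.setdefault(rec.genome_id, {})[rec.gene_id] = (start, stop)
    profiles = []
    for (genome, sample), group in tracks.groupby(["genome_id", "sample_id"],
                                                  sort=True):
        group = group.sort_values("start")
        length = int(group["end"].max())
        depths = np.zeros(length, dtype=float)
        for rec in group.itertuples(index=False):
            depths[int(rec.start):int(rec.end)] = rec.depth
        if np.allclose(depths, np.round(depths)):
            depths = depths.astype(np.int64)
        profiles.append(
            CoverageProfile(genome, sample, depths, dict(gene_maps.get(genome, {})))
        )
    return profiles


# ---------------------------------------------------------------- sequences

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- env + config

def write_env_matrix(matrix: pd.DataFrame, path, comments=None) -> None:
    write_table(matrix.rename_axis("sample_id"), path, comments, index=True)


def read_env_matrix(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    df = df.set_index("sample_id")
    df = df.dropna(axis=0, how="any")
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise ParseError(f"{path}: need >= 2 complete samples and >= 1 parameter")
    return df


def read_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a YAML mapping")
    return cfg
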