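"""TSV plumbing: readers and writers for the three input tables and the
pipeline outputs.  All readers are gzip-transparent (pandas infers the
compression from the filename)."""

from __future__ import annotations


from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_counts",
    "read_entity_map",
    "read_lengths",
    "read_labels",
    "read_sg_dir",
    "write_sg_sets",
    "read_yaml_config",
]

# Header tokens accepted for the two-column gene->entity map; MSPminer-style
# exports ("gene ids and their corresponding MSP id") use varying spellings.
_GENE_TOKENS = {"gene_id", "gene", "geneid", "gene_name"}
_ENTITY_TOKENS = {"entity_id", "entity", "mspid", "msp_id", "msp", "cluster", "bin", "species"}
_LENGTH_TOKENS = {"length_bp", "length", "len", "gene_length"}
_LABEL_TOKENS = {"label", "taxonomy", "taxon", "annotation"}


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix.

    Expected layout: header row of sample ids, first column gene ids,
    integer cells.  Ragged rows and non-numeric or negative cells are
    validation errors naming the offender.
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"non-numeric count for gene {gene!r} in {path}")
    if (numeric < 0).any().any():
        gene = numeric.index[(numeric < 0).any(axis=1)][0]
        raise ValueError(f"negative count for gene {gene!r} in {path}")
    return numeric.astype(np.int64)


def _two_column(path, second_tokens, default_name: str) -> pd.Series:
    peek = _read_tsv(path, header=None, nrows=1, dtype=str)
    first_row = [str(v).strip().lower() for v in peek.iloc[0]]
    has_header = bool(set(first_row) & (_GENE_TOKENS | second_tokens))
    df = _read_tsv(path, header=0 if has_header else None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    series = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    series.index.name = "gene_id"
    series.name = default_name
    if series.index.duplicated().any():
        dup = series.index[series.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    return series


def read_entity_map(path) -> pd.Series:
    """gene_id -> entity_id map; header optional (MSPminer dialect accepted)."""
    return _two_column(path, _ENTITY_TOKENS, "entity_id").astype(str)


def read_lengths(path) -> pd.Series:
    """gene_id -> gene length in bp; lengths must be positive integers."""
    series = _two_column(path, _LENGTH_TOKENS, "length_bp")
    lengths = pd.to_numeric(series, errors="coerce")
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()][0]
        raise ValueError(f"non-numeric length for gene {bad!r} in {path}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r} in {path}")
    return lengths.astype(np.int64)


def read_labels(path) -> pd.Series:
    """gene_id -> taxonomy label (used for entity collapsing)."""
    return _two_column(path, _LABEL_TOKENS, "label").astype(str)


def write_sg_sets(sg_sets, out_dir) -> list[Path]:
    """Write one TSV per entity (entity_id, gene_id, rank, score, origin)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for entity_id in sorted(sg_sets):
        path = out_dir / f"{entity_id}_sg.tsv"
        sg_sets[entity_id].to_frame().to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_sg_dir(sg_dir) -> dict[str, pd.DataFrame]:
    """Read every ``*_sg.tsv`` written by :func:`write_sg_sets`."""
    sg_dir = Path(sg_dir)
    out = {}
    for path in sorted(sg_dir.glob("*_sg.tsv")):
        df = _read_tsv(path, dtype={"entity_id": str, "gene_id": str})
        if df.empty:
            continue
        out[str(df["entity_id"].iloc[0])] = df
    if not out:
        raise FileNotFoundError(f"no *_sg.tsv files found in {sg_dir}")
    return out


def read_yaml_config(path) -> dict:
    """Flat YAML config file -> dict (empty file -> empty dict)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return data
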