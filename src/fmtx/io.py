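"""Readers, writers and validation for the tabular formats shared by every stage.

Canonical on-disk format is UTF-8 TSV with ``#`` comment lines and the feature
identifier in the first column (features as rows, samples as columns, the common
amplicon-pipeline export layout).  BIOM 2.1 (HDF5) count tables are accepted
read-only as a convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")
TREATMENTS = ("control", "FMT")

#: canonical group labels derived from (genotype, treatment)
GROUPS = ("WT", "KO", "WT_FMT", "KO_FMT")


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed at all."""


def group_label(genotype: str, treatment: str) -> str:
    """Canonical group label, e.g. ('KO', 'FMT') -> 'KO_FMT'."""
    return genotype if treatment == "control" else f"{genotype}_FMT"


@dataclass
class CountTable:
    """Validated non-negative integer feature x sample matrix.

    ``data`` holds features as rows and samples as columns.  Validation
    enforces unique identifiers, integer non-negative entries, and drops
    all-zero samples with a logged warning (bowel-cleansed communities can
    legitimately be near-empty, so this is not an error).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric entries")
        if values.size:
            if np.any(values < 0):
                f, s = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at feature {df.index[f]!r}, sample {df.columns[s]!r}"
                )
            if not np.allclose(values, np.round(values)):
                f, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise ValidationError(
                    f"non-integer count at feature {df.index[f]!r}, sample {df.columns[s]!r}"
                )
        self.data = df.astype(np.int64)
        zero = self.data.columns[self.data.sum(axis=0) == 0]
        if len(zero):
            logger.warning("dropping %d all-zero sample(s): %s", len(zero), list(zero))
            self.data = self.data.drop(columns=zero)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)].copy())


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read and validate a feature x sample count table (TSV or BIOM 2.1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_tsv_matrix(path)
    elif format == "biom":
        df = _read_biom(path)
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    return CountTable(df)


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (malformed header?)")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_biom(path: Path) -> pd.DataFrame:
    """Minimal BIOM 2.1 (HDF5) reader: CSR 'observation' group layout."""
    import h5py

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() for x in fh["observation/ids"][:]]
        samp_ids = [x.decode() for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        data = grp["data"][:]
        indices = grp["indices"][:]
        indptr = grp["indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr), shape=(len(obs_ids), len(samp_ids)))
    return pd.DataFrame(mat.toarray(), index=obs_ids, columns=samp_ids)


def write_count_table(table: CountTable, path) -> None:
    path = Path(path)
    df = table.data.copy()
    df.index.name = "ID"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata: sample, genotype in {WT, KO}, treatment in
    {control, FMT}, optional pair_id.  Indexed by sample id."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in meta.columns}
    for required in ("sample", "genotype", "treatment"):
        if required not in cols:
            raise ValidationError(f"{path}: metadata misses column {required!r}")
    meta = meta.rename(columns={cols[k]: k for k in cols})
    meta = meta.set_index("sample")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id in metadata: {dup!r}")
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    bad = set(meta["genotype"]) - set(GENOTYPES)
    if bad:
        raise ValidationError(f"unknown genotype level(s): {sorted(bad)}")
    bad = set(meta["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"unknown treatment level(s): {sorted(bad)}")
    meta = meta.copy()
    meta["group"] = [
        group_label(g, t) for g, t in zip(meta["genotype"], meta["treatment"])
    ]
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")


def read_taxonomy(path) -> pd.DataFrame:
    """Read an ASV -> 7-rank lineage table; empty cells are unassigned ranks."""
    tax = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    tax = tax.fillna("")
    missing = [r for r in RANKS[:-1] if r not in tax.columns]
    if missing:
        raise ValidationError(f"taxonomy misses rank column(s): {missing}")
    for rank in tax.columns:
        if tax[rank].str.contains("\t").any():
            raise ValidationError(f"tab character inside rank {rank!r}")
    tax.index = tax.index.astype(str)
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    out = tax.copy()
    out.index.name = "ASV"
    out.to_csv(path, sep="\t")


def read_edge_table(path) -> pd.DataFrame:
    """Read a scored interaction edge list: gene_a, gene_b, score in [0, 1]."""
    edges = pd.read_csv(path, sep="\t", comment="#", dtype={"score": float})
    for required in ("gene_a", "gene_b", "score"):
        if required not in edges.columns:
            raise ValidationError(f"edge table misses column {required!r}")
    if ((edges["score"] < 0) | (edges["score"] > 1)).any():
        raise ValidationError("edge scores must lie in [0, 1]")
    return edges


def align_tables(counts: CountTable, meta: pd.DataFrame) -> tuple[CountTable, pd.DataFrame]:
    """Restrict a count table and metadata to their shared samples, same order.

    Dropped sample ids are logged.  An empty intersection is an error.
    """
    shared = [s for s in counts.sample_ids if s in meta.index]
    if not shared:
        raise ValidationError("count table and metadata share no sample ids")
    dropped = sorted(
        (set(counts.sample_ids) | set(meta.index)) - set(shared)
    )
    if dropped:
        logger.info("align_tables dropped %d sample(s): %s", len(dropped), dropped)
    return counts.subset_samples(shared), meta.loc[shared]


@dataclass
class RunRecord:
    """Parameters + seed provenance attached to every stage output."""

    stage: str
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stage": self.stage, "seed": self.seed, "params": self.params}
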