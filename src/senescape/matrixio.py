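"""Count-matrix, sample-metadata and gene-set I/O.

Matrices are plain pandas DataFrames (features x samples).  Two on-disk
dialects are supported: TSV with a header row, and MatrixMarket triplets
with sidecar one-name-per-line row/column files (for large sparse data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)


@dataclass
class SampleMeta:
    """Per-sample covariates: line (WT/control), timepoint (PDL or PDL.ctrl),
    replicate, optional batch and protein concentration (mg/mL).

    (line, timepoint, replicate) must be unique.
    """

    df: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.df
        for col in ("line", "timepoint", "replicate"):
            if col not in df.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        key = df[["line", "timepoint", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(line, timepoint, replicate) not unique")

    @classmethod
    def read(cls, path) -> "SampleMeta":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")

    def samples_for(self, line: str) -> pd.DataFrame:
        return self.df[self.df["line"] == line]


def read_matrix(path, format: str = "tsv") -> pd.DataFrame:
    """Read a feature x sample matrix.

    format 'tsv': first column feature ids, header row sample ids.
    format 'mtx': MatrixMarket file; row/column names are read from
    sidecar files ``<stem>.rownames.txt`` / ``<stem>.colnames.txt``.

    Duplicate feature ids and dimension mismatches are hard errors; missing
    values are disallowed.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        p = Path(path)
        m = scipy.io.mmread(p)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        stem = p.with_suffix("")  # strip .mtx
        rownames = _read_names(Path(str(stem) + ".rownames.txt"))
        colnames = _read_names(Path(str(stem) + ".colnames.txt"))
        if m.shape != (len(rownames), len(colnames)):
            raise ValueError(
                f"dimension mismatch: matrix {m.shape}, "
                f"{len(rownames)} row names, {len(colnames)} col names"
            )
        df = pd.DataFrame(m, index=rownames, columns=colnames)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r}")
    if df.isna().any().any():
        raise ValueError("missing values are not allowed in count matrices")
    logger.info("read_matrix: %s -> %d x %d", path, *df.shape)
    return df


def write_matrix(df: pd.DataFrame, path, format: str = "tsv") -> None:
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="feature_id")
    elif format == "mtx":
        p = Path(path)
        stem = p.with_suffix("")
        scipy.io.mmwrite(str(p), scipy.sparse.csr_matrix(df.to_numpy()))
        Path(str(stem) + ".rownames.txt").write_text(
            "\n".join(map(str, df.index)) + "\n"
        )
        Path(str(stem) + ".colnames.txt").write_text(
            "\n".join(map(str, df.columns)) + "\n"
        )
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def _read_names(path: Path) -> list[str]:
    return [l for l in path.read_text().splitlines() if l]


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name <tab> desc <tab> genes...) or a plain
    one-gene-per-line file (single set named after the file stem)."""
    p = Path(path)
    lines = [l.rstrip("\n") for l in p.read_text().splitlines() if l.strip()]
    if p.suffix.lower() == ".gmt" or (lines and "\t" in lines[0]):
        sets = {}
        for line in lines:
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = parts[2:]
        return sets
    return {p.stem: lines}


def read_motif_matrix(path) -> pd.DataFrame:
    """Read a binary peak x motif matrix.

    Accepts either a wide TSV (peak ids x motif ids, entries 0/1) or a
    two-column peak_id/motif_id pair list which is pivoted to binary.
    """
    head = pd.read_csv(path, sep="\t", nrows=1)
    if list(head.columns[:2]) == ["peak_id", "motif_id"] and head.shape[1] == 2:
        pairs = pd.read_csv(path, sep="\t", dtype=str)
        m = pd.crosstab(pairs["peak_id"], pairs["motif_id"]).clip(upper=1)
        m.index.name = None
        m.columns.name = None
        return m.astype(np.int8)
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("motif matrix entries must be 0/1")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate peak or motif ids in motif matrix")
    return df.astype(np.int8)
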