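"""Readers and writers for the pipeline's delimited-text interchange.

TSV is the canonical format (CSV accepted on read, chosen by extension).
Expression matrices have gene IDs in the first column and sample IDs in
the header; designs, annotations and truth tables are plain column
tables.  Images are 8-bit grayscale PNGs, label masks 16-bit PNGs.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_gene_list",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples abundance matrix from TSV/CSV."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric values in {path}")
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep=_sep(path), index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"sample_id", "animal_id", "genotype", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design {path} lacks columns: {sorted(missing)}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep=_sep(path), index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype=str).set_index("gene_id")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene IDs in annotation {path}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep=_sep(path), index_label="gene_id")


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:  # flatten RGB(A) that is actually grayscale
        img = img[..., 0]
    return img.astype(np.uint8)


def write_image(image: np.ndarray, path) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    return iio.imread(path).astype(np.uint16)


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), np.asarray(mask, dtype=np.uint16))
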