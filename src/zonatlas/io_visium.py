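"""Reading, writing and merging Space Ranger-style spatial expression bundles.

A bundle is a directory holding the standard 10x Visium triplet —
``matrix.mtx[.gz]`` (gene × spot counts, MatrixMarket coordinate format),
``features.tsv[.gz]`` (gene id, symbol, feature type) and
``barcodes.tsv[.gz]`` — plus a ``tissue_positions.csv`` with columns
(barcode, in_tissue, array_row, array_col, pxl_row_in_fullres,
pxl_col_in_fullres).  Gzipped and plain files are both accepted on read;
plain files are written so that fixtures stay human-readable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IncompatibleSamplesError, IntegrityError

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class SpotDataset:
    """Gene × spot count matrix with spot geometry and condition labels.

    ``counts`` is a CSR integer matrix of shape (n_genes, n_spots);
    ``positions`` is a DataFrame with one row per spot (same order as
    ``barcodes``) and the standard Space Ranger position columns.
    ``condition`` holds one label per spot (e.g. ctrl / fasted / refed);
    it is empty-string for datasets read straight from disk.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    positions: pd.DataFrame
    condition: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.condition is None:
            self.condition = np.full(len(self.barcodes), "", dtype=object)
        else:
            self.condition = np.asarray(self.condition, dtype=object)
        self.validate()

    # -- basic views ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_spots(self, mask_or_idx) -> "SpotDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpotDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
            barcodes=self.barcodes[idx],
            positions=self.positions.iloc[idx].reset_index(drop=True),
            condition=self.condition[idx],
        )

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise IntegrityError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise IntegrityError("barcodes are not unique")
        if len(self.gene_symbols) != len(self.gene_ids):
            raise IntegrityError("gene_symbols length does not match gene_ids")
        if len(self.positions) != len(self.barcodes):
            raise IntegrityError("positions table length does not match barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative counts")


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing file: {dir_path / stem}[.gz]")


def _find_positions(dir_path: Path) -> Path:
    for name in ("tissue_positions.csv", "tissue_positions_list.csv",
                 "tissue_positions.csv.gz", "tissue_positions_list.csv.gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing file: {dir_path / 'tissue_positions.csv'}")


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=[0, 1, 2], dtype=object)


def read_visium(dir_path) -> SpotDataset:
    """Read a Space Ranger-style bundle, keeping only ``in_tissue == 1`` spots.

    Gene order follows the features file.  Raises :class:`FormatError` for a
    missing file and :class:`IntegrityError` for inconsistent dimensions or
    duplicated barcodes.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    feat_path = _find(dir_path, "features.tsv")
    bc_path = _find(dir_path, "barcodes.tsv")
    pos_path = _find_positions(dir_path)

    try:
        counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    except Exception as exc:  # malformed matrix file
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    features = _read_tsv(feat_path)
    barcodes = _read_tsv(bc_path)[0].to_numpy(dtype=object)

    if counts.shape[0] != len(features):
        raise IntegrityError(
            f"matrix has {counts.shape[0]} rows but features.tsv lists "
            f"{len(features)} genes"
        )
    if counts.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix has {counts.shape[1]} columns but barcodes.tsv lists "
            f"{len(barcodes)} barcodes"
        )
    if len(set(barcodes)) != len(barcodes):
        raise IntegrityError(f"duplicated barcode in {bc_path}")

    # header auto-detection: Space Ranger >=2 writes a header line, older
    # tissue_positions_list.csv does not
    opener = gzip.open if pos_path.suffix == ".gz" else open
    with opener(pos_path, "rt") as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip() in ("barcode", '"barcode"')
    pos = pd.read_csv(
        pos_path,
        header=0 if has_header else None,
        names=POSITION_COLUMNS,
        dtype={
            "barcode": str,
            "in_tissue": np.int64,
            "array_row": np.int64,
            "array_col": np.int64,
            "pxl_row_in_fullres": np.float64,
            "pxl_col_in_fullres": np.float64,
        },
    )
    missing = set(barcodes) - set(pos["barcode"])
    if missing:
        raise IntegrityError(
            f"{len(missing)} barcodes absent from {pos_path.name} "
            f"(first: {sorted(missing)[0]})"
        )
    pos = pos.set_index("barcode").loc[barcodes].reset_index(drop=True)

    ds = SpotDataset(
        counts=counts,
        gene_ids=features[0].to_numpy(dtype=object),
        gene_symbols=features[1].to_numpy(dtype=object)
        if features.shape[1] > 1
        else features[0].to_numpy(dtype=object),
        barcodes=barcodes,
        positions=pos,
    )
    return ds.subset_spots(pos["in_tissue"].to_numpy() == 1)


def write_visium(ds: SpotDataset, dir_path) -> Path:
    """Write ``ds`` as a plain-text bundle; ``read_visium`` round-trips it."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    coo = sp.coo_matrix(ds.counts)
    scipy.io.mmwrite(
        str(dir_path / "matrix.mtx"),
        coo.astype(np.int64),
        field="integer",
        symmetry="general",
    )
    feat = pd.DataFrame(
        {
            0: ds.gene_ids,
            1: ds.gene_symbols,
            2: ["Gene Expression"] * ds.n_genes,
        }
    )
    feat.to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(ds.barcodes).to_csv(
        dir_path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pos = ds.positions.copy()
    pos["barcode"] = ds.barcodes
    # str() of a float is its shortest round-tripping representation, so the
    # positions survive a write/read cycle bit-exactly
    pos[POSITION_COLUMNS].to_csv(
        dir_path / "tissue_positions.csv", index=False, float_format=None
    )
    return dir_path


def merge_conditions(samples: Sequence[tuple[SpotDataset, str]]) -> SpotDataset:
    """Concatenate per-condition samples into one dataset.

    All samples must share an identical gene list and ordering.  Barcodes are
    suffixed with the sample's condition label so they stay unique, and the
    per-spot ``condition`` field is populated.
    """
    if not samples:
        raise IncompatibleSamplesError("no samples to merge")
    ref = samples[0][0]
    for ds, label in samples[1:]:
        if len(ds.gene_ids) != len(ref.gene_ids):
            raise IncompatibleSamplesError(
                f"gene list length differs: {len(ds.gene_ids)} vs "
                f"{len(ref.gene_ids)}"
            )
        neq = ds.gene_ids != ref.gene_ids
        if neq.any():
            i = int(np.flatnonzero(neq)[0])
            raise IncompatibleSamplesError(
                f"gene lists differ at position {i}: "
                f"{ds.gene_ids[i]!r} vs {ref.gene_ids[i]!r}"
            )
    counts = sp.hstack([ds.counts for ds, _ in samples], format="csr")
    barcodes = np.concatenate(
        [[f"{bc}-{label}" for bc in ds.barcodes] for ds, label in samples]
    )
    condition = np.concatenate(
        [np.full(ds.n_spots, label, dtype=object) for ds, label in samples]
    )
    positions = pd.concat(
        [ds.positions for ds, _ in samples], ignore_index=True
    )
    return SpotDataset(
        counts=counts,
        gene_ids=ref.gene_ids,
        gene_symbols=ref.gene_symbols,
        barcodes=barcodes,
        positions=positions,
        condition=condition,
    )


__all__ = [
    "SpotDataset",
    "read_visium",
    "write_visium",
    "merge_conditions",
    "POSITION_COLUMNS",
]
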