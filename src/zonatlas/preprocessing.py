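"""Per-spot QC, normalization, dimensionality reduction and clustering.

Normalization is log library-size scaling (``log1p(count * scale / total)``)
with per-gene standardization before PCA; clustering is Leiden modularity
community detection on a symmetrized k-NN graph in PC space.  Clusters whose
median hemoglobin UMI fraction exceeds a threshold are flagged as minor
(erythroid-contaminated); the portal–central axis is inferred on major
clusters only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .io_visium import SpotDataset

logger = logging.getLogger(__name__)

DEFAULT_MITO_PREFIX = "mt-"
DEFAULT_HEMOGLOBIN_GENES = ["Hba-a1", "Hba-a2", "Hbb-bs", "Hbb-bt"]


@dataclass
class QCMetrics:
    """Per-spot QC table: genes detected, total UMIs, mitochondrial and
    hemoglobin UMI fractions, and a removal flag for zero-UMI spots."""

    table: pd.DataFrame  # columns: n_genes_detected, total_umi,
    #                     mito_fraction, hemoglobin_fraction, flag_remove

    def __getitem__(self, col):
        return self.table[col]


@dataclass
class EmbeddingResult:
    """PCA scores, k-NN graph and community labels for one dataset.

    ``neighbor_graph`` stores Euclidean PC-space distances on the
    symmetrized k-NN edge set (no self-loops).  ``major_flag`` is one bool
    per cluster; it is all-True until :func:`flag_erythroid_clusters` runs.
    """

    pc_scores: np.ndarray
    neighbor_graph: sp.csr_matrix
    cluster_labels: np.ndarray
    major_flag: np.ndarray
    k_neighbors: int

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max()) + 1

    def major_spot_mask(self) -> np.ndarray:
        return self.major_flag[self.cluster_labels]


def compute_qc(
    ds: SpotDataset,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    hemoglobin_genes=None,
) -> QCMetrics:
    """Per-spot QC metrics.

    Mitochondrial fraction is the UMI share of genes whose symbol starts
    with ``mito_prefix`` (mouse convention ``mt-``); hemoglobin fraction is
    the UMI share of the listed globin genes.  Zero-UMI spots get fractions
    of 0 and are flagged for removal.
    """
    if hemoglobin_genes is None:
        hemoglobin_genes = DEFAULT_HEMOGLOBIN_GENES
    symbols = np.asarray(ds.gene_symbols, dtype=object)
    mito_mask = np.array([str(s).startswith(mito_prefix) for s in symbols])
    hb_mask = np.isin(symbols, np.asarray(hemoglobin_genes, dtype=object))
    if not mito_mask.any():
        logger.warning("no genes match mito prefix %r", mito_prefix)
    if not hb_mask.any():
        logger.warning("no genes match the hemoglobin gene list")

    counts = ds.counts
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel()
    hb = np.asarray(counts[hb_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        hb_frac = np.where(total > 0, hb / np.maximum(total, 1), 0.0)
    return QCMetrics(
        pd.DataFrame(
            {
                "barcode": ds.barcodes,
                "n_genes_detected": n_genes.astype(int),
                "total_umi": total.astype(int),
                "mito_fraction": mito_frac,
                "hemoglobin_fraction": hb_frac,
                "flag_remove": total == 0,
            }
        )
    )


def normalize_log(ds: SpotDataset, scale: float = 1e4) -> np.ndarray:
    """Log library-size normalization: ``log1p(count * scale / spot_total)``.

    Returns a dense gene × spot float matrix; all-zero spots map to all-zero
    columns.
    """
    counts = np.asarray(ds.counts.todense(), dtype=float)
    totals = counts.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(counts * (scale / safe))


def _standardize_genes(norm: np.ndarray) -> np.ndarray:
    mu = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (norm - mu) / sd


def select_hvg(norm: np.ndarray, n_top: int = 2000) -> np.ndarray:
    """Indices of the top genes by variance of the normalized matrix."""
    var = norm.var(axis=1)
    n_top = min(n_top, norm.shape[0])
    return np.sort(np.argsort(var)[::-1][:n_top])


def reduce_and_cluster(
    norm: np.ndarray,
    n_pcs: int = 30,
    k_neighbors: int = 15,
    resolution: float = 0.8,
    seed: int = 0,
    n_top_genes: int = 2000,
) -> EmbeddingResult:
    """PCA on standardized highly-variable genes, k-NN graph, Leiden clustering.

    The Leiden partition optimizes the Reichardt–Bornholdt configuration
    quality at the given resolution; labels are relabelled by decreasing
    cluster size so the output is deterministic under a fixed seed.
    """
    n_genes, n_spots = norm.shape
    if n_spots < k_neighbors + 1:
        raise ValidationError(
            f"need at least k_neighbors + 1 = {k_neighbors + 1} spots, got {n_spots}"
        )
    if k_neighbors < 2:
        raise ValidationError("k_neighbors must be >= 2")
    hvg = select_hvg(norm, n_top_genes)
    x = _standardize_genes(norm[hvg]).T  # spots x genes
    n_comp = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(x)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n_spots), k_neighbors)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    keep = rows != cols  # duplicate points can sneak self back in
    g = sp.csr_matrix((vals[keep], (rows[keep], cols[keep])), shape=(n_spots, n_spots))
    graph = g.maximum(g.T)  # symmetrize (union of directed k-NN edges)

    coo = sp.triu(graph, k=1).tocoo()
    igr = ig.Graph(n=n_spots, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        igr,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    labels = _relabel_by_size(labels)
    return EmbeddingResult(
        pc_scores=pcs,
        neighbor_graph=graph,
        cluster_labels=labels,
        major_flag=np.ones(int(labels.max()) + 1, dtype=bool),
        k_neighbors=k_neighbors,
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, sizes = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-sizes, kind="stable")]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[x] for x in labels])


def flag_erythroid_clusters(
    emb: EmbeddingResult, qc: QCMetrics, hb_threshold: float = 0.1
) -> EmbeddingResult:
    """Mark clusters with median hemoglobin fraction above ``hb_threshold``
    as minor (erythroid-contaminated); all other clusters stay major."""
    hb = qc["hemoglobin_fraction"].to_numpy()
    major = np.ones(emb.n_clusters, dtype=bool)
    for c in range(emb.n_clusters):
        members = emb.cluster_labels == c
        if members.any() and np.median(hb[members]) > hb_threshold:
            major[c] = False
    return replace(emb, major_flag=major)


__all__ = [
    "QCMetrics",
    "EmbeddingResult",
    "compute_qc",
    "normalize_log",
    "select_hvg",
    "reduce_and_cluster",
    "flag_erythroid_clusters",
    "DEFAULT_MITO_PREFIX",
    "DEFAULT_HEMOGLOBIN_GENES",
]
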