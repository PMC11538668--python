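"""Portal–central axis reconstruction by diffusion pseudotime.

The lobule coordinate is recovered from expression alone: a Gaussian
diffusion kernel with per-spot adaptive bandwidth is built on PC-space
distances, row-normalized into a Markov transition matrix, and its leading
non-trivial right eigenvectors (scaled by their eigenvalues) form the
diffusion components.  Pseudotime is the Euclidean distance to a root spot
in diffusion-component space, min–max rescaled to [0, 1] and oriented so
that t = 0 is periportal and t = 1 is pericentral using landmark marker
genes (Alb/Cyp2f2 portal, Glul/Lgr5 central by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .preprocessing import EmbeddingResult


@dataclass
class PseudotimeAxis:
    """Per-spot pseudotime on [0, 1] plus the diffusion embedding.

    Defined only on the spots it was computed on (major clusters); ``spots``
    holds their integer indices into the parent dataset and ``barcodes``
    their barcode strings.
    """

    t: np.ndarray
    spots: np.ndarray
    barcodes: np.ndarray
    root_spot: str
    orientation_applied: bool
    diffusion_components: np.ndarray


@dataclass
class BinnedProfile:
    """Bin-mean expression along pseudotime.

    ``table`` is long-format with one row per (gene, condition, bin):
    bin_lo, bin_hi, mean, se (sd/sqrt(n), sample sd) and n spots.  Empty
    bins carry NaN mean/se, never zero.
    """

    table: pd.DataFrame
    bin_edges: np.ndarray


# ---------------------------------------------------------------------------
# diffusion map
# ---------------------------------------------------------------------------

def _components_from_kernel(
    kernel: np.ndarray, n_dc: int, scaling: str = "dpt"
) -> np.ndarray:
    """Scaled non-trivial right eigenvectors of the row-normalized transition
    matrix of a symmetric non-negative kernel.

    Uses the symmetric conjugation D^{-1/2} K D^{-1/2} so a plain Hermitian
    eigensolver applies; signs are fixed deterministically.  With the
    default ``scaling="dpt"`` each component is weighted by
    ``lambda / (1 - lambda)`` — the diffusion-pseudotime metric, which sums
    the random walk over all path lengths and strongly damps the higher
    harmonics of a one-dimensional gradient; ``scaling="eigenvalue"``
    weights by ``lambda`` (the one-step diffusion map).
    """
    d = kernel.sum(axis=1)
    if (d <= 0).any():
        raise ValidationError("kernel has an all-zero row")
    dinv = 1.0 / np.sqrt(d)
    s = kernel * dinv[:, None] * dinv[None, :]
    s = (s + s.T) / 2
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1][: n_dc + 1]
    evals = evals[order]
    psi = evecs[:, order] * dinv[:, None]  # right eigenvectors of D^-1 K
    # drop the trivial constant eigenvector (eigenvalue 1)
    psi, evals = psi[:, 1:], evals[1:]
    psi = psi / np.linalg.norm(psi, axis=0)
    # deterministic sign: largest-magnitude entry positive
    flip = np.sign(psi[np.abs(psi).argmax(axis=0), np.arange(psi.shape[1])])
    flip[flip == 0] = 1.0
    if scaling == "dpt":
        weights = evals / np.maximum(1.0 - evals, 1e-9)
    elif scaling == "eigenvalue":
        weights = evals
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")
    return psi * flip * weights


def diffusion_map(
    emb: EmbeddingResult, n_dc: int = 10, kernel_width="auto", scaling: str = "dpt"
) -> np.ndarray:
    """Diffusion components of the spots in ``emb``.

    The kernel is ``exp(-d_ij^2 / (sigma_i sigma_j))`` on PC-space distances
    with the adaptive width ``sigma_i`` equal to the distance from spot i to
    its k-th nearest neighbor (k = the embedding's k_neighbors); passing a
    float ``kernel_width`` uses the fixed-width kernel
    ``exp(-d^2 / (2 w^2))`` instead.  Components are weighted by the
    diffusion-pseudotime metric ``lambda / (1 - lambda)`` by default (see
    :func:`_components_from_kernel`).  Raises if the k-NN graph is
    disconnected (increase ``k_neighbors``).
    """
    pcs = emb.pc_scores
    n = pcs.shape[0]
    if n < n_dc + 2:
        raise ValidationError(f"need at least n_dc + 2 = {n_dc + 2} spots")
    n_comp, _ = connected_components(emb.neighbor_graph, directed=False)
    if n_comp > 1:
        raise ValidationError(
            f"neighbor graph has {n_comp} connected components; "
            "increase k_neighbors"
        )
    d = cdist(pcs, pcs)
    if kernel_width == "auto":
        # per-spot bandwidth: distance to the k-th nearest *distinct*
        # neighbor.  Counting duplicate spots would drive the bandwidth to
        # zero and make the random walk nearly reducible (spurious
        # eigenvalues at 1 that swamp the diffusion metric).
        positive = d[d > 0]
        scale = np.median(positive) if positive.size else 1.0
        tol = 1e-6 * scale
        dsort = np.sort(d, axis=1)
        k = min(emb.k_neighbors, n - 1)
        kth = np.empty(n)
        for i in range(n):
            distinct = dsort[i][dsort[i] > tol]
            kth[i] = distinct[min(k - 1, len(distinct) - 1)] if distinct.size else scale
        kth = np.maximum(kth, max(1e-3 * scale, 1e-12))
        kernel = np.exp(-(d**2) / (kth[:, None] * kth[None, :]))
    else:
        w = float(kernel_width)
        if w <= 0:
            raise ValidationError("kernel_width must be positive")
        kernel = np.exp(-(d**2) / (2 * w**2))
    return _components_from_kernel(kernel, n_dc, scaling=scaling)


def pseudotime(
    dc: np.ndarray,
    cluster_labels: np.ndarray,
    root_cluster: int,
    spots: np.ndarray | None = None,
    barcodes: np.ndarray | None = None,
) -> PseudotimeAxis:
    """Distance-to-root pseudotime in diffusion-component space.

    The root spot is the medoid of ``root_cluster`` in diffusion space; the
    raw distances are min–max rescaled to [0, 1].
    """
    members = np.flatnonzero(cluster_labels == root_cluster)
    if len(members) == 0:
        raise ValidationError(f"root cluster {root_cluster} is empty")
    sub = dc[members]
    medoid = members[int(cdist(sub, sub).sum(axis=1).argmin())]
    t = np.linalg.norm(dc - dc[medoid], axis=1)
    rng_ = t.max() - t.min()
    t = (t - t.min()) / (rng_ if rng_ > 0 else 1.0)
    n = dc.shape[0]
    spots = np.arange(n) if spots is None else np.asarray(spots)
    barcodes = (
        spots.astype(str).astype(object) if barcodes is None
        else np.asarray(barcodes, dtype=object)
    )
    return PseudotimeAxis(
        t=t,
        spots=spots,
        barcodes=barcodes,
        root_spot=str(barcodes[int(np.flatnonzero(spots == medoid)[0])])
        if medoid in spots
        else str(barcodes[medoid]),
        orientation_applied=False,
        diffusion_components=dc,
    )


def default_root_cluster(
    norm: np.ndarray,
    gene_ids: np.ndarray,
    cluster_labels: np.ndarray,
    portal_markers,
) -> int:
    """Cluster with the highest mean portal-marker expression (root default)."""
    rows = np.flatnonzero(np.isin(np.asarray(gene_ids, dtype=object), portal_markers))
    if len(rows) == 0:
        raise ValidationError("no portal markers found in the gene list")
    score = norm[rows].mean(axis=0)
    clusters = np.unique(cluster_labels)
    means = [score[cluster_labels == c].mean() for c in clusters]
    return int(clusters[int(np.argmax(means))])


def orient_axis(
    axis: PseudotimeAxis,
    norm: np.ndarray,
    gene_ids: np.ndarray,
    portal_markers,
    central_markers,
) -> PseudotimeAxis:
    """Flip pseudotime if needed so t = 0 is periportal.

    If mean portal-marker expression correlates positively with t, t is
    replaced by 1 - t.  Idempotent; raises if either marker pole is absent
    from the gene list.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    p_rows = np.flatnonzero(np.isin(gene_ids, np.asarray(portal_markers, dtype=object)))
    c_rows = np.flatnonzero(np.isin(gene_ids, np.asarray(central_markers, dtype=object)))
    if len(p_rows) == 0 or len(c_rows) == 0:
        raise ValidationError(
            "orientation needs at least one portal and one central marker "
            "present in the gene list"
        )
    portal_mean = norm[np.ix_(p_rows, axis.spots)].mean(axis=0)
    corr = np.corrcoef(portal_mean, axis.t)[0, 1]
    t = 1.0 - axis.t if corr > 0 else axis.t
    return replace(axis, t=t, orientation_applied=True)


# ---------------------------------------------------------------------------
# binned profiles
# ---------------------------------------------------------------------------

def _bin_index(t: np.ndarray, n_bins: int) -> np.ndarray:
    return np.minimum((t * n_bins).astype(int), n_bins - 1)


def bin_mean_se(values: np.ndarray, t: np.ndarray, n_bins: int):
    """Per-bin mean, standard error (sample sd / sqrt(n)) and count for one
    row of values along t; empty bins are NaN."""
    idx = _bin_index(t, n_bins)
    mean = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = values[idx == b]
        n[b] = len(sel)
        if len(sel):
            mean[b] = sel.mean()
            se[b] = (sel.std(ddof=1) / np.sqrt(len(sel))) if len(sel) > 1 else 0.0
    return mean, se, n


def bin_profiles(
    norm: np.ndarray,
    gene_ids,
    axis: PseudotimeAxis,
    n_bins: int = 20,
    condition: np.ndarray | None = None,
) -> BinnedProfile:
    """Bin-mean expression profiles along pseudotime.

    ``norm`` is the gene × spot normalized matrix of the parent dataset;
    only the axis spots are used.  If ``condition`` (per parent spot) is
    given, profiles are computed per condition label.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    gene_ids = np.asarray(gene_ids, dtype=object)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    sub = norm[:, axis.spots]
    if condition is None:
        cond_labels = np.full(len(axis.spots), "all", dtype=object)
    else:
        cond_labels = np.asarray(condition, dtype=object)[axis.spots]
    frames = []
    n_genes = len(gene_ids)
    for cond in pd.unique(cond_labels):
        sel = cond_labels == cond
        t = axis.t[sel]
        mat = sub[:, sel]
        idx = _bin_index(t, n_bins)
        mean = np.full((n_genes, n_bins), np.nan)
        se = np.full((n_genes, n_bins), np.nan)
        n = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            in_bin = idx == b
            n[b] = int(in_bin.sum())
            if n[b]:
                block = mat[:, in_bin]
                mean[:, b] = block.mean(axis=1)
                se[:, b] = (
                    block.std(axis=1, ddof=1) / np.sqrt(n[b]) if n[b] > 1 else 0.0
                )
        frames.append(
            pd.DataFrame(
                {
                    "gene": np.repeat(gene_ids, n_bins),
                    "condition": cond,
                    "bin_lo": np.tile(edges[:-1], n_genes),
                    "bin_hi": np.tile(edges[1:], n_genes),
                    "mean": mean.ravel(),
                    "se": se.ravel(),
                    "n": np.tile(n, n_genes),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return BinnedProfile(table=table, bin_edges=edges)


__all__ = [
    "PseudotimeAxis",
    "BinnedProfile",
    "diffusion_map",
    "pseudotime",
    "default_root_cluster",
    "orient_axis",
    "bin_profiles",
    "bin_mean_se",
    "_components_from_kernel",
]
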