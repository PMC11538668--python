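"""Wilcoxon differential expression and per-spot ssGSEA pathway scoring.

Differential expression between spot groups uses the two-sided
Mann–Whitney/Wilcoxon rank-sum test (exact enumeration for small groups,
tie-corrected normal approximation otherwise) with Benjamini–Hochberg FDR
control; the average log2 fold change is computed with a pseudocount of 1
on the de-logged normalized scale, so it stays bounded at zero means.

ssGSEA scores quantify, per spot, how coordinately the members of a gene
set sit at the top (positive) or bottom (negative) of that spot's
expression ranking: the score is the integrated difference between the
rank-weighted in-set ECDF (weights rank^alpha) and the unweighted out-set
ECDF.  Gene sets are supplied in GMT format; the five MSigDB set names used
for the fasting study ship as named placeholders with empty member lists,
since MSigDB membership is licensed externally and not bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .axis_inference import BinnedProfile, PseudotimeAxis, bin_profiles
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: MSigDB set names used for pathway scoring in the fasting study;
#: member lists must be supplied by the user (e.g. via a GMT download)
DEFAULT_GENE_SETS: dict[str, list[str]] = {
    "HALLMARK_KRAS_SIGNALING_UP": [],
    "HALLMARK_MTORC1_SIGNALING": [],
    "BIOCARTA_PGC1A_PATHWAY": [],
    "MEBARKI_HCC_PROGENITOR_WNT_UP_CTNNB1_DEPENDENT": [],
    "KEGG_PPAR_SIGNALING_PATHWAY": [],
}


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    Columns: gene, avg_log2fc, p_value, fdr, direction (up/down), passes
    (|log2FC| above the fold-change threshold and FDR below the cutoff).
    """

    table: pd.DataFrame
    lfc_threshold: float
    fdr_threshold: float


@dataclass
class EnrichmentScore:
    """Per-spot enrichment scores: sets × spots DataFrame plus the gene-set
    registry used; sets with too little overlap are all-NaN rows."""

    scores: pd.DataFrame
    gene_sets: dict


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_de(
    norm: np.ndarray,
    gene_ids,
    group_a: np.ndarray,
    group_b: np.ndarray,
    lfc_threshold: float = 0.25,
    fdr_threshold: float = 0.05,
) -> DEResult:
    """Rank-sum differential expression of group A versus group B.

    ``group_a``/``group_b`` are disjoint spot index arrays (>= 3 spots
    each).  The exact null distribution is enumerated when both groups have
    at most 10 spots; otherwise the tie-corrected normal approximation is
    used.  avg_log2fc is ``log2((mean_a + 1) / (mean_b + 1))`` of de-logged
    normalized expression.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("both groups need at least 3 spots")
    if np.intersect1d(group_a, group_b).size:
        raise ValidationError("groups overlap")
    a = norm[:, group_a]
    b = norm[:, group_b]
    method = "exact" if max(a.shape[1], b.shape[1]) <= 10 else "asymptotic"
    res = mannwhitneyu(a, b, axis=1, alternative="two-sided", method=method)
    p = np.atleast_1d(res.pvalue)

    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    fdr = bh_fdr(p)
    table = pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=object),
            "avg_log2fc": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(lfc >= 0, "up", "down"),
            "passes": (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold),
        }
    )
    return DEResult(table=table, lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_one(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment score of one spot for one set (vector implementation).

    Genes are ordered by decreasing expression (average ranks for ties
    define the weights); the score integrates the running difference
    between the weighted in-set ECDF and the unweighted out-set ECDF.
    """
    n = len(expr)
    desc_rank = n + 1 - rankdata(expr)  # average ranks, 1 = highest
    order = np.argsort(-expr, kind="stable")
    in_ordered = in_set[order]
    w = np.where(in_ordered, np.abs(desc_rank[order]) ** alpha, 0.0)
    w_sum = w.sum()
    m = int(in_set.sum())
    p_in = np.cumsum(w) / w_sum
    p_out = np.cumsum(~in_ordered) / (n - m)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    norm: np.ndarray,
    gene_ids,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
    min_overlap: int = 5,
    normalize: bool = False,
) -> EnrichmentScore:
    """Per-spot single-sample GSEA scores for each gene set.

    Sets sharing fewer than ``min_overlap`` genes with the matrix are
    skipped (all-NaN row, logged).  ``normalize=True`` min–max rescales each
    set's scores across spots (off by default).
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_genes, n_spots = norm.shape
    masks = {}
    for name, members in gene_sets.items():
        mask = np.isin(gene_ids, np.asarray(list(members), dtype=object))
        overlap = int(mask.sum())
        if overlap < min_overlap or overlap == n_genes:
            logger.warning(
                "gene set %s skipped (overlap %d)", name, overlap
            )
            masks[name] = None
        else:
            masks[name] = mask

    out = np.full((len(gene_sets), n_spots), np.nan)
    for si in range(n_spots):
        expr = norm[:, si]
        for gi, (name, mask) in enumerate(masks.items()):
            if mask is not None:
                out[gi, si] = _ssgsea_one(expr, mask, alpha)
    scores = pd.DataFrame(out, index=list(gene_sets))
    if normalize:
        lo = scores.min(axis=1)
        span = scores.max(axis=1) - lo
        scores = scores.sub(lo, axis=0).div(span.replace(0, 1.0), axis=0)
    return EnrichmentScore(scores=scores, gene_sets=dict(gene_sets))


def pathway_axis_profile(
    scores: EnrichmentScore,
    axis: PseudotimeAxis,
    n_bins: int = 20,
    condition: np.ndarray | None = None,
) -> BinnedProfile:
    """Bin-mean pathway scores along the oriented axis (same binning
    contract as expression profiles)."""
    if not axis.orientation_applied:
        raise ValidationError("axis must be oriented")
    return bin_profiles(
        scores.scores.to_numpy(),
        np.asarray(scores.scores.index, dtype=object),
        axis,
        n_bins=n_bins,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# GMT gene-set files
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated
    (name, description, member genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    lines = [
        "\t".join([name, name] + list(members))
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = [
    "DEResult",
    "EnrichmentScore",
    "DEFAULT_GENE_SETS",
    "bh_fdr",
    "wilcoxon_de",
    "ssgsea_scores",
    "pathway_axis_profile",
    "read_gmt",
    "write_gmt",
]
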