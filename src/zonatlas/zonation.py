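"""Five-way zonation-pattern classification along the lobule axis.

For each sufficiently detected gene, three nonlinear models are fitted by
least squares to its expression profile along pseudotime t (oriented
0 = periportal, 1 = pericentral):

* ``poly2``      a + b t + c t^2            (gradual gradients)
* ``gauss``      h exp(-(t-mu)^2 / 2 sigma^2)   (localized maxima)
* ``inv_gauss``  C - h exp(-(t-mu)^2 / 2 sigma^2)  (interior trough)

Zonation strength is the normalized range of the selected model,
(max - min) / max of the fitted curve over the observed axis; genes below
the 0.1 cutoff are non-zonated, the rest are labeled periportal,
pericentral, midzonal or bipolar from the fitted curve's geometry.  Fits
default to 20-bin mean profiles, which stabilizes the least squares on
overdispersed counts; a raw-spot mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .axis_inference import PseudotimeAxis, bin_mean_se
from .errors import ValidationError
from .io_visium import SpotDataset
from .preprocessing import normalize_log

logger = logging.getLogger(__name__)

LABELS = ["periportal", "pericentral", "midzonal", "bipolar", "non_zonated"]

GRID_POINTS = 512
_EPS_MAX = 1e-8

#: parameter bounds preventing degenerate peak fits
SIGMA_BOUNDS = (0.02, 10.0)
MU_BOUNDS = (-0.5, 1.5)


@dataclass
class ZonationModelFit:
    """One fitted model family with its diagnostics.

    Extrema are evaluated on a 512-point grid over the observed t range so
    boundary-clipped and interior extrema are treated uniformly across
    families.  ``argmax_rel``/``argmin_rel`` are the extremum locations
    rescaled to [0, 1] relative to the observed t range.
    """

    family: str
    params: dict
    rss: float
    n_points: int
    fitted_min: float
    fitted_max: float
    normalized_range: float
    converged: bool
    argmax_rel: float = np.nan
    argmin_rel: float = np.nan
    endpoint_values: tuple = (np.nan, np.nan)

    @property
    def n_params(self) -> int:
        return len(self.params)


def filter_genes(
    ds: SpotDataset,
    min_count: int = 10,
    min_spots: int = 200,
    spot_mask: np.ndarray | None = None,
) -> list[str]:
    """Genes detected with over ``min_count`` counts in at least
    ``min_spots`` spots (strict > on the count, >= on the spot number)."""
    if min_count < 0 or min_spots < 0:
        raise ValidationError("thresholds must be >= 0")
    counts = ds.counts if spot_mask is None else ds.counts[:, np.asarray(spot_mask)]
    n_qualifying = np.asarray((counts > min_count).sum(axis=1)).ravel()
    keep = n_qualifying >= min_spots
    return [g for g, k in zip(ds.gene_ids, keep) if k]


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _poly2(t, a, b, c):
    return a + b * t + c * t**2


def _gauss(t, h, mu, sigma):
    return h * np.exp(-((t - mu) ** 2) / (2 * sigma**2))


def _inv_gauss(t, C, h, mu, sigma):
    return C - h * np.exp(-((t - mu) ** 2) / (2 * sigma**2))


def _fit_one(func, t, y, p0, bounds, names) -> ZonationModelFit:
    family = {"_poly2": "poly2", "_gauss": "gauss", "_inv_gauss": "inv_gauss"}[
        func.__name__
    ]
    try:
        popt, _ = curve_fit(
            func,
            t,
            y,
            p0=p0,
            bounds=bounds if bounds is not None else (-np.inf, np.inf),
            maxfev=20000,
            method="trf" if bounds is not None else "lm",
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError) as exc:
        logger.debug("%s fit failed: %s", family, exc)
        popt, converged = np.full(len(p0), np.nan), False

    params = dict(zip(names, popt))
    if not converged:
        return ZonationModelFit(
            family=family, params=params, rss=np.inf, n_points=len(t),
            fitted_min=np.nan, fitted_max=np.nan, normalized_range=np.nan,
            converged=False,
        )
    resid = y - func(t, *popt)
    rss = float(resid @ resid)
    grid = np.linspace(t.min(), t.max(), GRID_POINTS)
    curve = func(grid, *popt)
    span = t.max() - t.min()
    rel = (grid - t.min()) / (span if span > 0 else 1.0)
    fmax, fmin = float(curve.max()), float(curve.min())
    return ZonationModelFit(
        family=family,
        params=params,
        rss=rss,
        n_points=len(t),
        fitted_min=fmin,
        fitted_max=fmax,
        normalized_range=_normalized_range(fmin, fmax),
        converged=True,
        argmax_rel=float(rel[int(curve.argmax())]),
        argmin_rel=float(rel[int(curve.argmin())]),
        endpoint_values=(float(curve[0]), float(curve[-1])),
    )


def _fit_poly2(t: np.ndarray, y: np.ndarray) -> ZonationModelFit:
    # the quadratic model is linear in its coefficients, so the iterative
    # refinement converges to the unique least-squares solution; solve it
    # directly for numerical exactness on noiseless input
    design = np.column_stack([np.ones_like(t), t, t**2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    grid = np.linspace(t.min(), t.max(), GRID_POINTS)
    curve = coef[0] + coef[1] * grid + coef[2] * grid**2
    span = t.max() - t.min()
    rel = (grid - t.min()) / (span if span > 0 else 1.0)
    fmax, fmin = float(curve.max()), float(curve.min())
    return ZonationModelFit(
        family="poly2",
        params={"a": float(coef[0]), "b": float(coef[1]), "c": float(coef[2])},
        rss=rss,
        n_points=len(t),
        fitted_min=fmin,
        fitted_max=fmax,
        normalized_range=_normalized_range(fmin, fmax),
        converged=True,
        argmax_rel=float(rel[int(curve.argmax())]),
        argmin_rel=float(rel[int(curve.argmin())]),
        endpoint_values=(float(curve[0]), float(curve[-1])),
    )


def fit_models(expr: np.ndarray, t: np.ndarray) -> dict[str, ZonationModelFit]:
    """Least-squares fits of the three zonation model families.

    Starting values: poly2 all parameters at unity; gauss peak height one,
    mean at the average pseudotime, sd one; inv_gauss constant at the
    maximum observed expression (height max - min, mean at the average
    pseudotime, sd one).  A failed optimization is recorded with
    ``converged=False``, never raised.
    """
    expr = np.asarray(expr, dtype=float)
    t = np.asarray(t, dtype=float)
    ok = np.isfinite(expr) & np.isfinite(t)
    expr, t = expr[ok], t[ok]
    if len(t) < 8:
        raise ValidationError("need at least 8 points to fit")
    if np.ptp(t) == 0:
        raise ValidationError("t values are all identical")

    tbar = float(t.mean())
    ymax, ymin = float(expr.max()), float(expr.min())
    if ymax == ymin:
        # exactly constant input: the least-squares polynomial is the
        # constant itself; solve in closed form so the normalized range is
        # exactly zero rather than iteration noise
        const_fit = ZonationModelFit(
            family="poly2", params={"a": ymax, "b": 0.0, "c": 0.0}, rss=0.0,
            n_points=len(t), fitted_min=ymax, fitted_max=ymax,
            normalized_range=_normalized_range(ymax, ymax), converged=True,
            argmax_rel=0.0, argmin_rel=0.0, endpoint_values=(ymax, ymax),
        )
        failed = ZonationModelFit(
            family="gauss", params={}, rss=np.inf, n_points=len(t),
            fitted_min=np.nan, fitted_max=np.nan, normalized_range=np.nan,
            converged=False,
        )
        from dataclasses import replace as _replace

        return {
            "poly2": const_fit,
            "gauss": failed,
            "inv_gauss": _replace(failed, family="inv_gauss"),
        }
    peak_bounds = (
        [0.0, MU_BOUNDS[0], SIGMA_BOUNDS[0]],
        [np.inf, MU_BOUNDS[1], SIGMA_BOUNDS[1]],
    )
    trough_bounds = (
        [0.0, 0.0, MU_BOUNDS[0], SIGMA_BOUNDS[0]],
        [np.inf, np.inf, MU_BOUNDS[1], SIGMA_BOUNDS[1]],
    )
    return {
        "poly2": _fit_poly2(t, expr),
        "gauss": _fit_one(
            _gauss, t, expr, [1.0, tbar, 1.0], peak_bounds, ("h", "mu", "sigma")
        ),
        "inv_gauss": _fit_one(
            _inv_gauss,
            t,
            expr,
            [ymax, max(ymax - ymin, 1e-6), tbar, 1.0],
            trough_bounds,
            ("C", "h", "mu", "sigma"),
        ),
    }


def _normalized_range(fmin: float, fmax: float, eps: float = _EPS_MAX) -> float:
    if not np.isfinite(fmax) or fmax <= eps:
        return 0.0
    return (fmax - fmin) / fmax


def normalized_range(fit: ZonationModelFit) -> float:
    """(max - min) / max of the fitted curve; 0 for a (near-)zero maximum,
    which forces the non-zonated label."""
    if not fit.converged:
        raise ValidationError("normalized_range requires a converged fit")
    return _normalized_range(fit.fitted_min, fit.fitted_max)


def select_model(fits: dict[str, ZonationModelFit]) -> ZonationModelFit | None:
    """Minimum-AIC model among converged fits (AIC = n log(rss/n) + 2k);
    ties break in the order poly2, gauss, inv_gauss.  None if no fit
    converged."""
    best, best_aic = None, np.inf
    for family in ("poly2", "gauss", "inv_gauss"):
        fit = fits.get(family)
        if fit is None or not fit.converged:
            continue
        aic = fit.n_points * np.log(max(fit.rss, 1e-300) / fit.n_points) + 2 * fit.n_params
        if aic < best_aic:
            best, best_aic = fit, aic
    return best


def classify_gene(
    best: ZonationModelFit | None,
    threshold: float = 0.1,
    pole_boundaries: tuple[float, float] = (0.25, 0.75),
) -> str:
    """Zonation label from the selected fit.

    Normalized range below ``threshold`` is non-zonated.  Otherwise, with t
    oriented periportal-to-pericentral: an inv_gauss fit whose trough is
    interior and whose endpoints both clear the trough by
    ``threshold * fitted_max`` is bipolar; all remaining cases use the
    fitted argmax location m — m <= 0.25 periportal, m >= 0.75 pericentral,
    interior midzonal.
    """
    if best is None:
        return "non_zonated"
    if _normalized_range(best.fitted_min, best.fitted_max) < threshold:
        return "non_zonated"
    lo, hi = pole_boundaries
    if best.family == "inv_gauss":
        interior = 0.0 < best.argmin_rel < 1.0
        clears = (
            min(best.endpoint_values) >= best.fitted_min + threshold * best.fitted_max
        )
        if interior and clears:
            return "bipolar"
    m = best.argmax_rel
    if m <= lo:
        return "periportal"
    if m >= hi:
        return "pericentral"
    return "midzonal"


# ---------------------------------------------------------------------------
# batch classification and transitions
# ---------------------------------------------------------------------------

def classify_all(
    ds: SpotDataset,
    axis: PseudotimeAxis,
    gene_list=None,
    norm: np.ndarray | None = None,
    n_bins: int = 20,
    threshold: float = 0.1,
    min_count: int = 10,
    min_spots: int = 200,
    pole_boundaries: tuple[float, float] = (0.25, 0.75),
    use_bins: bool = True,
) -> pd.DataFrame:
    """Classify every eligible gene per condition.

    The detection filter (> ``min_count`` counts in >= ``min_spots`` axis
    spots) is applied per condition, so a gene may be labeled in one
    condition and missing in another.  Expression profiles are ``n_bins``
    bin means of log-normalized expression along the oriented axis (raw
    spots when ``use_bins`` is False).  Returns one row per (gene,
    condition) with label, selected family, normalized range, rss and
    parameters; per-gene fit warnings are aggregated, never raised.
    """
    if not axis.orientation_applied:
        raise ValidationError("axis must be oriented before classification")
    if norm is None:
        norm = normalize_log(ds)
    conditions = pd.unique(ds.condition[axis.spots])
    rows = []
    failed: list[tuple[str, str]] = []
    for cond in conditions:
        in_cond = ds.condition[axis.spots] == cond
        spot_idx = axis.spots[in_cond]
        t = axis.t[in_cond]
        mask = np.zeros(ds.n_spots, dtype=bool)
        mask[spot_idx] = True
        genes = set(filter_genes(ds, min_count, min_spots, spot_mask=mask))
        if gene_list is not None:
            genes &= set(gene_list)
        gene_idx = {g: i for i, g in enumerate(ds.gene_ids)}
        for gene in sorted(genes, key=lambda g: gene_idx[g]):
            y_spots = norm[gene_idx[gene], spot_idx]
            if use_bins:
                mean, _, nb = bin_mean_se(y_spots, t, n_bins)
                keep = nb > 0
                y, tt = mean[keep], (np.linspace(0, 1, n_bins + 1)[:-1]
                                     + 0.5 / n_bins)[keep]
            else:
                y, tt = y_spots, t
            try:
                fits = fit_models(y, tt)
            except ValidationError as exc:
                failed.append((gene, str(exc)))
                continue
            best = select_model(fits)
            if best is None:
                failed.append((gene, "no model converged"))
            label = classify_gene(best, threshold, pole_boundaries)
            row = {
                "gene": gene,
                "condition": cond,
                "label": label,
                "family": best.family if best is not None else "",
                "normalized_range": best.normalized_range if best else np.nan,
                "rss": best.rss if best else np.nan,
            }
            if best is not None:
                row.update({f"param_{k}": v for k, v in best.params.items()})
            rows.append(row)
    if failed:
        head = ", ".join(g for g, _ in failed[:10])
        logger.warning(
            "%d genes could not be fitted (first: %s)", len(failed), head
        )
    return pd.DataFrame(rows)


@dataclass
class TransitionTable:
    """Cross-tabulation of zonation labels between two conditions.

    ``matrix`` is a 5x5 integer DataFrame (rows = condition A labels,
    columns = condition B); ``genes`` maps each (label_a, label_b) cell to
    the gene list it counts.  Marginals conserve the per-condition label
    counts on the shared gene set exactly.
    """

    matrix: pd.DataFrame
    genes: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return int(self.matrix.to_numpy().sum())


def transition_table(labels_a: pd.Series, labels_b: pd.Series) -> TransitionTable:
    """Tabulate label transitions over the genes shared by two label tables
    (index = gene, value = label)."""
    shared = labels_a.index.intersection(labels_b.index)
    if len(shared) == 0:
        raise ValidationError("label tables share no genes")
    a = labels_a.loc[shared]
    b = labels_b.loc[shared]
    matrix = pd.DataFrame(0, index=LABELS, columns=LABELS, dtype=int)
    genes: dict = {}
    for g in shared:
        la, lb = a[g], b[g]
        matrix.loc[la, lb] += 1
        genes.setdefault((la, lb), []).append(g)
    return TransitionTable(matrix=matrix, genes=genes)


def labels_as_series(table: pd.DataFrame, condition: str) -> pd.Series:
    """Extract one condition's labels from a classify_all table as a
    gene-indexed Series."""
    sub = table[table["condition"] == condition]
    return pd.Series(sub["label"].to_numpy(), index=sub["gene"].to_numpy())


__all__ = [
    "LABELS",
    "ZonationModelFit",
    "TransitionTable",
    "filter_genes",
    "fit_models",
    "normalized_range",
    "select_model",
    "classify_gene",
    "classify_all",
    "transition_table",
    "labels_as_series",
]
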