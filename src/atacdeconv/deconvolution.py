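"""Constrained weighted least-squares deconvolution with an uncharacterized fraction.

Each bulk sample's TPM-like accessibility b over the marker peaks is modelled
as b ~ R p, where R holds the reference cell types' median accessibility and
p >= 0 with sum(p) <= 1.  The deficit 1 - sum(p) estimates the fraction of
uncharacterized cells (chiefly malignant), valid because marker peaks are
selected to be closed in cell types outside the reference.  Features are
weighted by the inverse of their mean reference variability (IQR), and the
convex quadratic program is solved exactly by an active-set method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import (
    CountsMatrix,
    ReferenceProfile,
    aggregate_matched_counts,
    tpm_like,
)
from .intervals import ChainAlignment, liftover_with_index, match_features

__all__ = [
    "MrnaFactors",
    "FeatureWeights",
    "DeconvolutionResult",
    "feature_weights",
    "epic_fit_sample",
    "estimate_uncharacterized",
    "mrna_renormalize",
    "deconvolve",
]

UNCHARACTERIZED = "uncharacterized"


@dataclass
class MrnaFactors:
    """Per-cell-type signal-per-cell factors; all 1 for ATAC (DNA-level signal)."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        for ct, m in self.factors.items():
            if m <= 0:
                raise ValueError(f"mRNA factor for {ct!r} must be positive")

    @classmethod
    def ones(cls, cell_types: list[str]) -> "MrnaFactors":
        return cls({ct: 1.0 for ct in cell_types})


@dataclass
class FeatureWeights:
    """Per-marker-peak fit weights, inverse to mean reference variability."""

    weights: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("weights must be finite and non-negative")
        if not (w > 0).any():
            raise ValueError("weights must not be all zero")
        self.weights = w


@dataclass
class DeconvolutionResult:
    """Per-sample cell-type fractions plus fit diagnostics.

    ``fractions`` is samples x (cell types + 'uncharacterized'); every row is
    on the simplex.  ``residuals`` holds the weighted residual norm of each
    fit, ``converged`` the solver flags, and ``marker_report`` the per-cell-type
    counts of markers retained after feature matching.
    """

    fractions: pd.DataFrame
    residuals: pd.Series
    converged: pd.Series
    n_matched_features: int
    marker_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.fractions.to_numpy()
        if (vals < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def feature_weights(profile: ReferenceProfile, marker_ids: list[str]) -> FeatureWeights:
    """w_j = 1 / (vbar_j + eps) with vbar the cross-cell-type mean IQR and
    eps = 1e-2 x median positive vbar (1 if every vbar is zero)."""
    index = {pid: i for i, pid in enumerate(profile.peaks.ids)}
    missing = [m for m in marker_ids if m not in index]
    if missing:
        raise ValueError(f"marker id(s) not in profile peaks: {missing[:5]}")
    rows = [index[m] for m in marker_ids]
    vbar = profile.v[rows, :].mean(axis=1)
    positive = vbar[vbar > 0]
    eps = 1e-2 * float(np.median(positive)) if positive.size else 1.0
    return FeatureWeights(1.0 / (vbar + eps), eps)


# ---------------------------------------------------------------------------
# Quadratic program: min ||W^(1/2)(R p - b)||^2  s.t.  p >= 0, sum(p) <= 1
# ---------------------------------------------------------------------------

def _solve_sum_constrained(Q: np.ndarray, c: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Active-set solver for min 1/2 p'Qp - c'p s.t. p >= 0, sum(p) = 1."""
    n = Q.shape[0]
    free = list(range(n))
    ones = np.ones(n)
    for _ in range(max_iter):
        while True:
            nf = len(free)
            K = np.zeros((nf + 1, nf + 1))
            K[:nf, :nf] = Q[np.ix_(free, free)]
            K[:nf, nf] = 1.0
            K[nf, :nf] = 1.0
            rhs = np.concatenate([c[free], [1.0]])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            x_f, lam = sol[:nf], sol[nf]
            if (x_f >= -1e-12).all() or nf == 1:
                break
            free.pop(int(np.argmin(x_f)))
        p = np.zeros(n)
        p[free] = np.maximum(x_f, 0.0)
        grad = Q @ p - c
        bound = [i for i in range(n) if i not in free]
        if not bound:
            return p
        mu = grad[np.array(bound)] - lam
        j = int(np.argmin(mu))
        if mu[j] >= -1e-10:
            return p
        free.append(bound[j])
        free.sort()
    return p


def epic_fit_sample(
    b: np.ndarray, R: np.ndarray, w: FeatureWeights
) -> tuple[np.ndarray, float, bool]:
    """Fit one sample's cell-type proportions.

    Solves argmin sum_j w_j (b_j - sum_i R_ji p_i)^2 subject to p >= 0 and
    sum(p) <= 1, as a convex QP: the unconstrained-sum nonnegative solution is
    taken when already feasible (it is then globally optimal), otherwise the
    sum constraint binds and an equality-constrained active-set solve applies.
    Returns (p, weighted residual norm, uniqueness flag); rank-deficient R is
    handled with a tiny ridge and flagged non-unique.
    """
    b = np.asarray(b, float)
    R = np.asarray(R, float)
    if R.shape[0] < R.shape[1]:
        raise ValueError("need at least as many marker peaks as cell types")
    sw = np.sqrt(w.weights)
    Aw = R * sw[:, None]
    bw = b * sw
    Q = Aw.T @ Aw
    c = Aw.T @ bw
    unique = True
    if np.linalg.matrix_rank(R) < R.shape[1]:
        unique = False
        warnings.warn("reference matrix is rank-deficient; solution may be non-unique",
                      stacklevel=2)
        Q = Q + (1e-10 * np.trace(Q)) * np.eye(Q.shape[0])
    from scipy.optimize import nnls

    if unique:
        p, _ = nnls(Aw, bw)
    else:
        p, _ = nnls(np.vstack([Aw, math.sqrt(1e-10 * np.trace(Q)) * np.eye(R.shape[1])]),
                    np.concatenate([bw, np.zeros(R.shape[1])]))
    if p.sum() > 1.0 + 1e-12:
        p = _solve_sum_constrained(Q, c)
    p = np.clip(p, 0.0, None)
    resid = float(np.linalg.norm(Aw @ p - bw))
    return p, resid, unique


def estimate_uncharacterized(p: np.ndarray) -> float:
    """Uncharacterized fraction: the clamped deficit 1 - sum(p)."""
    return max(0.0, 1.0 - float(np.sum(p)))


def mrna_renormalize(
    p: np.ndarray,
    p_u: float,
    cell_types: list[str],
    factors: MrnaFactors | None = None,
) -> np.ndarray:
    """Divide each fraction by its per-cell signal factor and renormalize to 1.

    The uncharacterized factor is fixed at 1; with all factors 1 (the ATAC
    default) this is the identity up to the sum-to-1 normalization.
    """
    if factors is None:
        factors = MrnaFactors.ones(cell_types)
    m = np.array([factors.factors.get(ct, 1.0) for ct in cell_types] + [1.0])
    full = np.concatenate([p, [p_u]]) / m
    total = full.sum()
    if total <= 0:
        # degenerate all-zero fit: report everything as uncharacterized
        out = np.zeros(len(cell_types) + 1)
        out[-1] = 1.0
        return out
    return full / total


# ---------------------------------------------------------------------------
# End-to-end deconvolution
# ---------------------------------------------------------------------------

def deconvolve(
    bulk: CountsMatrix,
    profile: ReferenceProfile,
    chains: list[ChainAlignment] | None = None,
    mrna_factors: MrnaFactors | None = None,
    normalize: str = "matched",
    min_matched_markers: int = 10,
    marker_match_warn_frac: float = 0.5,
    n_jobs: int = 1,
) -> DeconvolutionResult:
    """Full pipeline: [liftover] -> feature matching -> count aggregation ->
    TPM-like transform -> marker subset -> weighted constrained fit per sample.

    ``normalize="matched"`` (default) applies the TPM-like transform after
    aggregation onto matched reference peaks, using reference peak lengths;
    ``normalize="full"`` normalizes the complete bulk matrix first and then
    sums normalized values.  A genome-build mismatch without ``chains`` is an
    error; fewer than ``min_matched_markers`` matched marker peaks is fatal,
    and a cell type losing more than half its markers in matching triggers a
    warning.  Samples are fitted independently; ``n_jobs > 1`` fits them in
    parallel with identical, order-independent results.
    """
    if normalize not in ("matched", "full"):
        raise ValueError("normalize must be 'matched' or 'full'")
    bulk_peaks = bulk.peaks
    bulk_values = bulk.values
    if bulk_peaks.genome_build != profile.genome_build:
        if chains is None:
            raise ValueError(
                f"bulk genome build {bulk_peaks.genome_build!r} does not match profile "
                f"build {profile.genome_build!r}; supply a chain file to lift over"
            )
        lifted, source_rows, _dropped = liftover_with_index(
            bulk_peaks, chains, profile.genome_build
        )
        bulk_values = (
            bulk_values[np.array(source_rows)] if source_rows else bulk_values[:0]
        )
        bulk_peaks = lifted
    if len(bulk_peaks) == 0:
        raise ValueError("no bulk peaks remain after liftover")

    bulk_cm = CountsMatrix(bulk_values, bulk_peaks, list(bulk.sample_ids), bulk.sample_meta)
    mapping = match_features(bulk_peaks, profile.peaks)

    if normalize == "full":
        norm_full = tpm_like(bulk_cm)
        bulk_cm = CountsMatrix(norm_full.values, bulk_peaks, list(bulk.sample_ids),
                               bulk.sample_meta)
    matched = aggregate_matched_counts(bulk_cm, mapping, profile.peaks)
    if normalize == "matched":
        norm_values = tpm_like(matched).values
    else:
        norm_values = matched.values

    # subset to the union of marker peaks present in the matched set
    matched_ids = {pid: i for i, pid in enumerate(matched.peaks.ids)}
    profile_index = {pid: i for i, pid in enumerate(profile.peaks.ids)}
    marker_union: list[str] = []
    seen: set[str] = set()
    report_rows = []
    for ct in profile.cell_types:
        ids = profile.marker_ids(ct) if ct in profile.markers else []
        present = [m for m in ids if m in matched_ids]
        if ids and len(present) < marker_match_warn_frac * len(ids):
            warnings.warn(
                f"cell type {ct!r}: only {len(present)}/{len(ids)} markers matched in bulk",
                stacklevel=2,
            )
        report_rows.append({"cell_type": ct, "n_markers": len(ids), "n_matched": len(present)})
        for m in present:
            if m not in seen:
                seen.add(m)
                marker_union.append(m)
    if len(marker_union) < min_matched_markers:
        raise ValueError(
            f"only {len(marker_union)} marker peaks matched; need at least {min_matched_markers}"
        )
    marker_union.sort()
    b_rows = [matched_ids[m] for m in marker_union]
    r_rows = [profile_index[m] for m in marker_union]
    R = profile.R[r_rows, :]
    B = norm_values[b_rows, :]
    w = feature_weights(profile, marker_union)

    cols = profile.cell_types + [UNCHARACTERIZED]
    n_samples = bulk.values.shape[1]
    frac = np.zeros((n_samples, len(cols)))
    residuals = np.zeros(n_samples)
    converged = np.zeros(n_samples, dtype=bool)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        fits = Parallel(n_jobs=n_jobs)(
            delayed(epic_fit_sample)(B[:, k], R, w) for k in range(n_samples)
        )
    else:
        fits = [epic_fit_sample(B[:, k], R, w) for k in range(n_samples)]
    for k, (p, resid, unique) in enumerate(fits):
        p_u = estimate_uncharacterized(p)
        frac[k] = mrna_renormalize(p, p_u, profile.cell_types, mrna_factors)
        residuals[k] = resid
        converged[k] = unique
    fractions = pd.DataFrame(frac, index=list(bulk.sample_ids), columns=cols)
    return DeconvolutionResult(
        fractions,
        pd.Series(residuals, index=list(bulk.sample_ids), name="residual"),
        pd.Series(converged, index=list(bulk.sample_ids), name="converged"),
        len(marker_union),
        pd.DataFrame(report_rows),
    )
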