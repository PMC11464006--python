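"""Differential accessibility engine: TMM, log-CPM, moderated t, BH.

The model is the standard two-group linear model on log-CPM values with
empirical-Bayes variance moderation: per-peak residual variances s2 are shrunk
toward a prior (d0, s0^2) estimated by the method of moments on log s2 under
the scaled-F hierarchy, and tested with a t statistic on d + d0 degrees of
freedom.  Per-observation mean-variance precision weights (the voom trend) are
deliberately not implemented: downstream marker selection consumes only the
log2 fold change and the BH-adjusted p-value, which the moderated-t core
provides.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .counts import CountsMatrix

__all__ = [
    "DAResult",
    "tmm_factors",
    "log_cpm",
    "fit_group_stats",
    "ebayes_moderate",
    "moderated_t",
    "bh_adjust",
    "pairwise_da",
]


@dataclass
class DAResult:
    """Per-peak statistics for one pairwise contrast (group_a minus group_b)."""

    group_a: str
    group_b: str
    peak_ids: list[str]
    lfc: np.ndarray  # log2 fold change, a minus b
    t: np.ndarray
    p: np.ndarray
    padj: np.ndarray
    d: float  # residual degrees of freedom
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance

    def reversed(self) -> "DAResult":
        return DAResult(
            self.group_b, self.group_a, self.peak_ids,
            -self.lfc, -self.t, self.p, self.padj, self.d, self.d0, self.s0_sq,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_id": self.peak_ids,
                "contrast": f"{self.group_a}_vs_{self.group_b}",
                "lfc": self.lfc,
                "t": self.t,
                "p": self.p,
                "padj": self.padj,
            }
        )


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: CountsMatrix | np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For each sample, M (log2 ratio) and
    A (log2 abundance) are computed against the reference over peaks positive
    in both; the stated fractions of M and A extremes are trimmed on both
    sides, and the remaining M values are averaged with inverse approximate
    binomial variances as weights.
    """
    x = counts.values if isinstance(counts, CountsMatrix) else np.asarray(counts, float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array([np.quantile(x[:, k], 0.75) for k in range(x.shape[1])]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.empty(x.shape[1])
    for k in range(x.shape[1]):
        factors[k] = _tmm_pair(x[:, k], x[:, ref], lib[k], lib[ref], trim_m, trim_a)
    # rescale so the factors multiply to 1
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no positive peak with the TMM reference")
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    inv_w = 1.0 / w[keep]
    f = np.sum(inv_w * m[keep]) / np.sum(inv_w)
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def log_cpm(
    counts: CountsMatrix | np.ndarray,
    factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> np.ndarray:
    """log2 counts per million with effective library sizes and a prior count.

    value = log2((c + prior) / (libsize * factor + 2 * prior) * 1e6)
    """
    x = counts.values if isinstance(counts, CountsMatrix) else np.asarray(counts, float)
    lib = x.sum(axis=0)
    if factors is None:
        factors = np.ones(x.shape[1])
    factors = np.asarray(factors, float)
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = lib * factors + 2.0 * prior_count
    return np.log2((x + prior_count) / eff[None, :] * 1e6)


# ---------------------------------------------------------------------------
# Linear model + empirical Bayes
# ---------------------------------------------------------------------------

def fit_group_stats(
    logcpm: np.ndarray, labels: list[str] | np.ndarray
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Group means, pooled within-group residual variance and residual df.

    Returns (means DataFrame with one column per group, s2 vector, d) where
    d = n_samples - n_groups.
    """
    labels = np.asarray(labels)
    if labels.size != logcpm.shape[1]:
        raise ValueError("one label per sample required")
    groups = sorted(set(labels.tolist()))
    d = labels.size - len(groups)
    if d < 1:
        raise ValueError("no residual degrees of freedom (all groups are singletons)")
    means = {}
    rss = np.zeros(logcpm.shape[0])
    for g in groups:
        cols = labels == g
        sub = logcpm[:, cols]
        mu = sub.mean(axis=1)
        means[g] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    s2 = rss / d
    return pd.DataFrame(means), s2, float(d)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for trigamma^{-1}, as used for the scaled-F moment fit
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def ebayes_moderate(s2: np.ndarray, d: float) -> tuple[float, float, np.ndarray]:
    """Method-of-moments fit of the scaled-F prior and posterior variances.

    Matches the mean and variance of log s2 to their digamma/trigamma
    expressions under s2 ~ s0^2 F(d, d0); if the observed dispersion of log s2
    does not exceed the sampling component trigamma(d/2), the prior df d0 is
    infinite and every posterior variance equals s0^2.  Peaks with s2 = 0 (or
    non-finite) are excluded from the moment fit but still moderated.
    """
    s2 = np.asarray(s2, float)
    use = np.isfinite(s2) & (s2 > 0)
    if use.sum() < 2:
        raise ValueError("need at least two peaks with positive finite variance")
    z = np.log(s2[use])
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        post = (d0 * s0_sq + d * np.where(use, s2, 0.0)) / (d0 + d)
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
        post = np.full_like(s2, s0_sq)
    return d0, s0_sq, post


def moderated_t(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    s2_post: np.ndarray,
    n_a: int,
    n_b: int,
    d: float,
    d0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistic and two-sided p-value on d + d0 degrees of freedom."""
    if (np.asarray(s2_post) <= 0).any():
        raise ValueError("posterior variances must be positive")
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d + d0)
    return t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Pairwise differential accessibility
# ---------------------------------------------------------------------------

def pairwise_da(
    counts: CountsMatrix,
    labels: list[str] | np.ndarray,
    prior_count: float = 0.5,
) -> list[DAResult]:
    """Moderated-t differential accessibility for every unordered group pair.

    TMM factors and log-CPM are computed once over all samples; each contrast
    then fits the two-group model, moderates variances across peaks and
    BH-adjusts within the contrast.  Groups representing external tissues
    participate exactly like cell types, so markers are also tested against
    non-TME chromatin.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    factors = tmm_factors(counts)
    lc = log_cpm(counts, factors, prior_count=prior_count)
    peak_ids = list(counts.peaks.ids)
    results: list[DAResult] = []
    for ga, gb in itertools.combinations(groups, 2):
        cols = (labels == ga) | (labels == gb)
        sub = lc[:, cols]
        sub_labels = labels[cols]
        means, s2, d = fit_group_stats(sub, sub_labels)
        d0, s0_sq, post = ebayes_moderate(s2, d)
        n_a = int((sub_labels == ga).sum())
        n_b = int((sub_labels == gb).sum())
        t, p = moderated_t(
            means[ga].to_numpy(), means[gb].to_numpy(), post, n_a, n_b, d, d0
        )
        results.append(
            DAResult(
                ga, gb, peak_ids,
                means[ga].to_numpy() - means[gb].to_numpy(),
                t, p, bh_adjust(p), d, d0, s0_sq,
            )
        )
    return results
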