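"""Outlier and pleiotropy diagnostics run before the main MR fit.

MR-PRESSO simulates the no-pleiotropy null: observed leave-one-out residual
sums of squares are compared with the distribution obtained by redrawing
summary statistics from their reported sampling distributions, giving a
global heterogeneity p-value, per-variant outlier p-values (Bonferroni
adjusted), and a distortion test for the outlier-corrected estimate.

Radial MR reformulates IVW in radial coordinates: with first-order weights
W_j = beta_exp_j^2 / se_out_j^2 the radial slope is algebraically identical
to the IVW estimate, and each variant's contribution Q_j = W_j (ratio_j -
theta)^2 is an approximate chi-square(1) outlier statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientInstrumentsError
from .summaries import HarmonizedSet
from .uvmr import MREstimate, ivw

__all__ = ["PressoResult", "RadialResult", "mr_presso", "radial_ivw", "union_outliers"]


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results."""

    global_rss: float
    global_pval: float
    per_snp_pval: np.ndarray
    per_snp_pval_adjusted: np.ndarray
    outlier_ids: list[str]
    corrected: MREstimate | None
    distortion_pval: float | None
    n_sim: int
    seed: int
    variant_ids: list[str] = field(default_factory=list)


@dataclass
class RadialResult:
    """Radial-MR fit with per-variant Q contributions and outlier flags."""

    theta: float
    q_total: float
    per_snp_q: np.ndarray
    per_snp_pval: np.ndarray
    outlier_ids: list[str]
    iterations: int
    variant_ids: list[str] = field(default_factory=list)


def _loo_thetas(bx, by, w):
    """Leave-one-out IVW slopes, vectorized over the left-out index."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global test, per-variant outlier test, and distortion test.

    Observed RSS uses leave-one-out IVW expectations; ``n_sim`` simulated
    datasets redraw both exposure and outcome betas from their reported
    normals.  P-values use the add-one Monte-Carlo rule, so the smallest
    attainable value is 1/(n_sim + 1).  Outliers are variants whose
    Bonferroni-adjusted per-variant p falls below ``outlier_alpha``; the
    corrected estimate is IVW on the remainder.
    """
    if h.n_variants < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    bx, sx, by, sy = h.single(0)
    j = h.n_variants
    w = 1.0 / sy ** 2
    rng = np.random.default_rng(seed)

    theta_loo = _loo_thetas(bx, by, w)
    rss_j = w * (by - theta_loo * bx) ** 2
    rss = float(np.sum(rss_j))

    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    w_row = w[None, :]
    s_xy = np.sum(w_row * bx_star * by_star, axis=1, keepdims=True)
    s_xx = np.sum(w_row * bx_star ** 2, axis=1, keepdims=True)
    theta_loo_star = (s_xy - w_row * bx_star * by_star) / (s_xx - w_row * bx_star ** 2)
    rss_star_j = w_row * (by_star - theta_loo_star * bx_star) ** 2
    rss_star = rss_star_j.sum(axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss)) / (n_sim + 1))
    per_snp = (1 + np.sum(rss_star_j >= rss_j[None, :], axis=0)) / (n_sim + 1)
    per_snp_adj = np.minimum(1.0, per_snp * j)
    out_mask = per_snp_adj < outlier_alpha
    outlier_ids = [v for v, m in zip(h.variant_ids, out_mask) if m]

    corrected = None
    distortion_pval = None
    keep = ~out_mask
    if keep.sum() >= 2:
        corrected = ivw(h.subset(keep))
    if outlier_ids and corrected is not None:
        theta_full = ivw(h).theta
        d_obs = abs(corrected.theta - theta_full)
        n_out = int(out_mask.sum())
        d_rand = np.empty(n_sim)
        idx = np.arange(j)
        for i in range(n_sim):
            removed = rng.choice(idx, size=n_out, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[removed] = False
            wk, bxk, byk = w[mask], bx[mask], by[mask]
            d_rand[i] = np.sum(wk * bxk * byk) / np.sum(wk * bxk * bxk) - theta_full
        distortion_pval = float((1 + np.sum(np.abs(d_rand) >= d_obs)) / (n_sim + 1))

    return PressoResult(
        global_rss=rss, global_pval=global_pval,
        per_snp_pval=per_snp, per_snp_pval_adjusted=per_snp_adj,
        outlier_ids=outlier_ids, corrected=corrected,
        distortion_pval=distortion_pval, n_sim=n_sim, seed=seed,
        variant_ids=list(h.variant_ids),
    )


def radial_ivw(h: HarmonizedSet, alpha: float = 0.05,
               iterate: bool = True) -> RadialResult:
    """Radial (modified second-stage) IVW with per-variant Q outlier tests.

    Variants with beta_exp = 0 are excluded with a warning (their ratio is
    undefined).  When ``iterate``, outliers (per-variant chi-square(1)
    p < ``alpha``) are removed and the fit repeated until none remain or
    fewer than 2 variants are left.
    """
    if h.n_variants < 2:
        raise InsufficientInstrumentsError("radial MR needs >= 2 variants")
    zero = h.single(0)[0] == 0
    if zero.any():
        bad = [v for v, z in zip(h.variant_ids, zero) if z]
        warnings.warn(f"excluding variants with beta_exp = 0: {bad}", stacklevel=2)
        h = h.subset(~zero)

    current = h
    removed: list[str] = []
    iterations = 0
    while True:
        iterations += 1
        bx, _, by, sy = current.single(0)
        big_w = bx ** 2 / sy ** 2
        ratios = by / bx
        theta = float(np.sum(big_w * ratios) / np.sum(big_w))
        q_j = big_w * (ratios - theta) ** 2
        pvals = sps.chi2.sf(q_j, 1)
        out_mask = pvals < alpha
        if not iterate or not out_mask.any() or (~out_mask).sum() < 2:
            all_out = removed + [v for v, m in zip(current.variant_ids, out_mask) if m]
            return RadialResult(
                theta=theta, q_total=float(q_j.sum()),
                per_snp_q=q_j, per_snp_pval=pvals,
                outlier_ids=all_out, iterations=iterations,
                variant_ids=list(current.variant_ids),
            )
        removed += [v for v, m in zip(current.variant_ids, out_mask) if m]
        current = current.subset(~out_mask)


def union_outliers(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
                   alpha: float = 0.05) -> tuple[HarmonizedSet, list[str]]:
    """Remove the union of MR-PRESSO and radial-MR outliers from ``h``.

    The pre-filtering step applied before the main estimator battery; with
    fewer than 4 variants MR-PRESSO is skipped and only radial MR runs.
    Returns the filtered set and the removed ids.
    """
    flagged: set[str] = set()
    if h.n_variants >= 4:
        flagged |= set(mr_presso(h, n_sim=n_sim, seed=seed,
                                 outlier_alpha=alpha).outlier_ids)
    if h.n_variants >= 2:
        flagged |= set(radial_ivw(h, alpha=alpha, iterate=True).outlier_ids)
    if not flagged:
        return h, []
    keep = [v not in flagged for v in h.variant_ids]
    if sum(keep) < 2:  # refuse to strip the set below a fittable size
        return h, []
    return h.subset(np.array(keep)), sorted(flagged)
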