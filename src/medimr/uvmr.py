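"""Univariable two-sample MR estimators and heterogeneity statistics.

The estimator battery mirrors standard sensitivity-analysis practice: the
inverse-variance-weighted (IVW) estimate is the main analysis, with MR-Egger
(directional-pleiotropy intercept), the weighted median (valid when at least
half the weight is on valid instruments), and the simple/weighted mode-based
estimates (valid when the largest cluster of instruments is pleiotropy-free)
as sensitivity estimators, plus Cochran's Q for heterogeneity.

Everything consumes a :class:`~medimr.summaries.HarmonizedSet` with a single
exposure column.  The model-object surface is :class:`UnivariableMR`, whose
``fit`` returns a single :class:`MREstimate` and whose ``fit_all`` returns a
:class:`UVMRResults` battery with a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import DomainError, InsufficientInstrumentsError
from .summaries import HarmonizedSet

__all__ = [
    "MREstimate",
    "UnivariableMR",
    "UVMRResults",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "mode_estimate",
]

#: normal 95% critical value, used for all normal-based intervals
Z95 = 1.96

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

_METHOD_ALIASES = {
    "wmedian": "weighted_median",
    "smode": "simple_mode",
    "wmode": "weighted_mode",
}


@dataclass
class MREstimate:
    """One method's causal estimate on the outcome scale (log-odds for binary)."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    exposure: str = "exposure"
    outcome: str = "outcome"
    or_scale: tuple[float, float, float] | None = None
    q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def summary(self) -> str:
        parts = [
            f"{self.method}: theta = {self.theta:.4f} (SE {self.se:.4f}), "
            f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}], "
            f"p = {self.pval:.3g}, n_snp = {self.n_snp}"
        ]
        if self.or_scale is not None:
            o, lo, hi = self.or_scale
            parts.append(f"  OR = {o:.3f} [{lo:.3f}, {hi:.3f}]")
        if self.q is not None:
            parts.append(f"  Cochran's Q = {self.q:.3f} (p = {self.q_pval:.3g})")
        if self.egger_intercept is not None:
            parts.append(
                f"  Egger intercept = {self.egger_intercept:.4f} "
                f"(p = {self.egger_intercept_pval:.3g})"
            )
        return "\n".join(parts)


def _finish(method: str, theta: float, se: float, n_snp: int, h: HarmonizedSet | None,
            *, pval: float | None = None, ci: tuple[float, float] | None = None,
            **extras) -> MREstimate:
    if pval is None:
        z = theta / se if se > 0 else np.inf * np.sign(theta)
        pval = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if ci is None:
        ci = (theta - Z95 * se, theta + Z95 * se)
    est = MREstimate(
        method=method, theta=float(theta), se=float(se),
        ci_low=float(ci[0]), ci_high=float(ci[1]), pval=float(pval),
        n_snp=int(n_snp), **extras,
    )
    if h is not None:
        est.exposure = h.exposure_names[0]
        est.outcome = h.outcome_name
        if h.outcome_type == "binary":
            est.or_scale = (float(np.exp(est.theta)),
                            float(np.exp(est.ci_low)), float(np.exp(est.ci_high)))
    return est


def _single(h: HarmonizedSet, min_snps: int, method: str):
    if h.n_exposures != 1:
        raise ValueError(f"{method} requires a single-exposure HarmonizedSet")
    if h.n_variants < min_snps:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {min_snps} variants, got {h.n_variants}")
    return h.single(0)


# ---------------------------------------------------------------------------
# estimators


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               h: HarmonizedSet | None = None) -> MREstimate:
    """Single-instrument ratio estimate theta = beta_y / beta_x.

    The standard error is the first-order approximation |se_y / beta_x|
    (uncertainty in beta_x ignored).
    """
    if beta_x == 0:
        raise DomainError("wald ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return _finish("wald", theta, se, 1, h)


def ivw(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of beta_out on beta_exp through
    the origin with weights 1/se_out^2.

    Under ``multiplicative_random`` (the default) the fixed-effect SE is
    inflated by max(1, sqrt(Q/(J-1))), which reduces to the fixed-effect SE
    when the instruments are homogeneous.  A single variant degrades to the
    Wald ratio with a warning.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    bx, sx, by, sy = _single(h, 1, "ivw")
    if h.n_variants == 1:
        warnings.warn("single variant: IVW degrades to the Wald ratio", stacklevel=2)
        est = wald_ratio(bx[0], sx[0], by[0], sy[0], h)
        est.method = "ivw"
        return est
    w = 1.0 / sy ** 2
    s_xx = float(np.sum(w * bx * bx))
    if s_xx == 0:
        raise DomainError("all exposure betas are zero")
    theta = float(np.sum(w * bx * by) / s_xx)
    se_fixed = s_xx ** -0.5
    q, q_pval = cochran_q(h, theta)
    se = se_fixed
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (h.n_variants - 1)))
    return _finish("ivw", theta, se, h.n_variants, h, q=q, q_pval=q_pval)


def cochran_q(h: HarmonizedSet, theta: float) -> tuple[float, float]:
    """Cochran's Q = sum_j (beta_out_j - theta*beta_exp_j)^2 / se_out_j^2
    with a chi-square (J-1 df) p-value."""
    bx, _, by, sy = _single(h, 2, "cochran_q")
    q = float(np.sum(((by - theta * bx) / sy) ** 2))
    q_pval = float(sps.chi2.sf(q, h.n_variants - 1))
    return q, q_pval


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: WLS of beta_out on beta_exp with an intercept.

    Variants are first oriented so beta_exp >= 0 (both betas flipped where
    needed), the convention that makes the intercept interpretable as average
    directional pleiotropy.  SEs are inflated by max(1, sqrt(Q_res/(J-2)))
    and inference is t-based with J-2 df for both slope and intercept.
    """
    bx, sx, by, sy = _single(h, 3, "egger")
    sign = np.where(bx < 0, -1.0, 1.0)
    bxo, byo = bx * sign, by * sign
    w = 1.0 / sy ** 2
    design = sm.add_constant(bxo)
    fit = sm.WLS(byo, design, weights=w).fit()
    alpha, theta = fit.params
    df = h.n_variants - 2
    q_res = float(np.sum(w * (byo - fit.fittedvalues) ** 2))
    disp = max(1.0, np.sqrt(q_res / df))
    se_alpha, se_theta = np.sqrt(np.diag(fit.normalized_cov_params)) * disp
    tcrit = sps.t.ppf(0.975, df)
    pval = float(2 * sps.t.sf(abs(theta / se_theta), df))
    p_alpha = float(2 * sps.t.sf(abs(alpha / se_alpha), df))
    return _finish(
        "egger", theta, se_theta, h.n_variants, h,
        pval=pval, ci=(theta - tcrit * se_theta, theta + tcrit * se_theta),
        q=q_res, q_pval=float(sps.chi2.sf(q_res, df)),
        egger_intercept=float(alpha), egger_intercept_se=float(se_alpha),
        egger_intercept_pval=p_alpha,
    )


def _ratio_weights(bx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Inverse-variance weights of the per-variant ratios, normalized."""
    w = (bx / sy) ** 2
    return w / w.sum()


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    th = ratios[order]
    w = weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2  # cumulative midpoint of each variant's mass
    return float(np.interp(0.5, s, th))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    j = bx.size
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    vals = np.fromiter((point_fn(bxs[i], bys[i]) for i in range(n_boot)),
                       dtype=float, count=n_boot)
    return float(np.std(vals, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate over per-variant ratios.

    Ratios are sorted with normalized inverse-variance weights
    w_j = (beta_exp_j/se_out_j)^2; the estimate interpolates the ratio at
    cumulative weight 0.5.  The SE is the standard deviation of the estimator
    over ``n_boot`` parametric-bootstrap replicates (betas resampled from
    their reported normals, fixed seed).
    """
    bx, sx, by, sy = _single(h, 3, "weighted_median")

    def point(bx_i, by_i):
        return _weighted_median_point(by_i / bx_i, _ratio_weights(bx_i, sy))

    theta = point(bx, by)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return _finish("weighted_median", theta, se, h.n_variants, h)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float,
                grid_points: int = 1000) -> float:
    j = ratios.size
    sd = float(np.std(ratios, ddof=1))
    mad = float(sps.median_abs_deviation(ratios, scale="normal"))
    b = phi * 0.9 * min(sd, mad) * j ** (-0.2)
    if not (b > 0) or not np.isfinite(b):
        # degenerate spread: more than half the ratios coincide
        return float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * b, ratios.max() + 3 * b, grid_points)
    dens = (weights[:, None] * sps.norm.pdf((grid[None, :] - ratios[:, None]) / b)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimate(h: HarmonizedSet, weighted: bool = False, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode-based estimate: argmax of a normal-kernel density over ratios.

    Bandwidth b = phi * 0.9 * min(sd, mad) * J^(-1/5) with the MAD scaled to
    be SD-consistent; the density is evaluated on 1,000 grid points spanning
    [min - 3b, max + 3b], unweighted (simple mode) or with the weighted-median
    weights (weighted mode).  SE by the same parametric bootstrap.
    """
    if not phi > 0:
        raise DomainError("phi must be positive")
    bx, sx, by, sy = _single(h, 3, "mode")
    method = "weighted_mode" if weighted else "simple_mode"

    def point(bx_i, by_i):
        ratios = by_i / bx_i
        w = _ratio_weights(bx_i, sy) if weighted else np.full(ratios.size, 1.0 / ratios.size)
        return _mode_point(ratios, w, phi)

    theta = point(bx, by)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return _finish(method, theta, se, h.n_variants, h)


# ---------------------------------------------------------------------------
# model surface


@dataclass
class UVMRResults:
    """A battery of univariable estimates with a Table-1 shaped summary."""

    estimates: list[MREstimate]

    def __getitem__(self, method: str) -> MREstimate:
        method = _METHOD_ALIASES.get(method, method)
        for e in self.estimates:
            if e.method == method:
                return e
        raise KeyError(method)

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.estimates:
            row = {
                "method": e.method, "n_snp": e.n_snp,
                "theta": e.theta, "se": e.se,
                "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval,
                "q": e.q, "q_pval": e.q_pval,
                "egger_intercept": e.egger_intercept,
                "egger_intercept_pval": e.egger_intercept_pval,
            }
            if e.or_scale is not None:
                row["or"], row["or_low"], row["or_high"] = e.or_scale
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return self.to_frame().to_string(index=False, float_format=lambda x: f"{x:.4g}")


class UnivariableMR:
    """Univariable two-sample MR model over a harmonized single-exposure set.

    Examples
    --------
    >>> model = UnivariableMR(harmonized)          # doctest: +SKIP
    >>> res = model.fit("ivw")                     # doctest: +SKIP
    >>> battery = model.fit_all(seed=7)            # doctest: +SKIP
    >>> print(battery.summary())                   # doctest: +SKIP
    """

    def __init__(self, harmonized: HarmonizedSet):
        if harmonized.n_exposures != 1:
            raise ValueError("UnivariableMR requires exactly one exposure")
        self.data = harmonized

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        method = _METHOD_ALIASES.get(method, method)
        if method == "ivw":
            return ivw(self.data, **kwargs)
        if method == "egger":
            return egger(self.data)
        if method == "weighted_median":
            return weighted_median(self.data, **kwargs)
        if method == "simple_mode":
            return mode_estimate(self.data, weighted=False, **kwargs)
        if method == "weighted_mode":
            return mode_estimate(self.data, weighted=True, **kwargs)
        if method == "wald":
            bx, sx, by, sy = self.data.single(0)
            return wald_ratio(bx[0], sx[0], by[0], sy[0], self.data)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, methods=DEFAULT_METHODS, n_boot: int = 1000,
                seed: int = 0) -> UVMRResults:
        """Fit the requested estimators; bootstrap methods get distinct
        seeds derived deterministically from ``seed``."""
        children = np.random.SeedSequence(seed).spawn(len(methods))
        out = []
        for method, child in zip(methods, children):
            method = _METHOD_ALIASES.get(method, method)
            kwargs = {}
            if method in ("weighted_median", "simple_mode", "weighted_mode"):
                kwargs = {"n_boot": n_boot, "seed": int(child.generate_state(1)[0] % 2**31)}
            out.append(self.fit(method, **kwargs))
        return UVMRResults(out)
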