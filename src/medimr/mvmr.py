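"""Multivariable MR: joint regression of outcome on several exposures' effects.

MV-IVW regresses outcome associations on the (J x K) exposure effect matrix
without intercept, weights 1/se_out^2, giving each exposure's direct effect
adjusted for the others.  MVMR-Egger adds an intercept after orienting all
variants to one exposure's positive direction, testing for directional
pleiotropy in the multivariable model.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.linalg import qr

from .exceptions import CollinearityError, InsufficientInstrumentsError
from .summaries import HarmonizedSet
from .uvmr import MREstimate, Z95, _finish

__all__ = ["mvmr_ivw", "mvmr_egger", "MultivariableMR", "MVMRResults"]


def _check_rank(h: HarmonizedSet, design: np.ndarray, w: np.ndarray) -> None:
    wx = np.sqrt(w)[:, None] * design
    rank = np.linalg.matrix_rank(wx)
    if rank < design.shape[1]:
        # column-pivoted QR points at the exposures entangled in the deficiency
        _, _, piv = qr(wx, pivoting=True, mode="economic")
        offending = sorted(h.exposure_names[i] for i in piv[rank:]
                           if i < len(h.exposure_names))
        raise CollinearityError(
            f"exposure effect matrix is rank deficient (rank {rank} < "
            f"{design.shape[1]}); offending exposures: {offending}",
            exposures=offending,
        )


def _per_exposure_estimates(h: HarmonizedSet, params, ses, pvals, cis, method,
                            q, q_pval, **extras) -> list[MREstimate]:
    out = []
    for i, name in enumerate(h.exposure_names):
        est = _finish(method, params[i], ses[i], h.n_variants, h,
                      pval=pvals[i], ci=cis[i], q=q, q_pval=q_pval, **extras)
        est.exposure = name
        out.append(est)
    return out


def mvmr_ivw(h: HarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: WLS of beta_out on the exposure matrix, no intercept.

    Per-exposure SEs are inflated by max(1, sqrt(Q/(J-k))); Q and its
    chi-square (J-k df) p-value are attached to every estimate.  Inference is
    normal-based, matching univariable IVW (to which this reduces exactly at
    k = 1).
    """
    j, k = h.n_variants, h.n_exposures
    if j < k + 1:
        raise InsufficientInstrumentsError(f"MV-IVW needs >= {k + 1} variants, got {j}")
    w = 1.0 / h.se_out ** 2
    _check_rank(h, h.beta_exp, w)
    fit = sm.WLS(h.beta_out, h.beta_exp, weights=w).fit()
    resid = h.beta_out - h.beta_exp @ fit.params
    q = float(np.sum(w * resid ** 2))
    df = j - k
    q_pval = float(sps.chi2.sf(q, df))
    disp = max(1.0, np.sqrt(q / df))
    ses = np.sqrt(np.diag(fit.normalized_cov_params)) * disp
    pvals = 2 * sps.norm.sf(np.abs(fit.params / ses))
    cis = [(p - Z95 * s, p + Z95 * s) for p, s in zip(fit.params, ses)]
    return _per_exposure_estimates(h, fit.params, ses, pvals, cis,
                                   "mvmr_ivw", q, q_pval)


def mvmr_egger(h: HarmonizedSet, orient_to: str | int = 0) -> list[MREstimate]:
    """Multivariable MR-Egger: WLS with intercept after orienting all variants
    so the ``orient_to`` exposure's betas are non-negative.

    t-based inference with J - k - 1 df; the shared intercept estimate and
    its p-value are attached to every per-exposure estimate.
    """
    j, k = h.n_variants, h.n_exposures
    if j < k + 2:
        raise InsufficientInstrumentsError(
            f"MVMR-Egger needs >= {k + 2} variants, got {j}")
    if isinstance(orient_to, str):
        orient_to = h.exposure_names.index(orient_to)
    sign = np.where(h.beta_exp[:, orient_to] < 0, -1.0, 1.0)
    bx = h.beta_exp * sign[:, None]
    by = h.beta_out * sign
    w = 1.0 / h.se_out ** 2
    design = sm.add_constant(bx)
    _check_rank(h, design, w)
    fit = sm.WLS(by, design, weights=w).fit()
    resid = by - design @ fit.params
    q = float(np.sum(w * resid ** 2))
    df = j - k - 1
    q_pval = float(sps.chi2.sf(q, df))
    disp = max(1.0, np.sqrt(q / df))
    ses = np.sqrt(np.diag(fit.normalized_cov_params)) * disp
    tcrit = sps.t.ppf(0.975, df)
    pvals = 2 * sps.t.sf(np.abs(fit.params / ses), df)
    alpha, alpha_se, alpha_p = fit.params[0], ses[0], pvals[0]
    cis = [(p - tcrit * s, p + tcrit * s) for p, s in zip(fit.params[1:], ses[1:])]
    return _per_exposure_estimates(
        h, fit.params[1:], ses[1:], pvals[1:], cis, "mvmr_egger", q, q_pval,
        egger_intercept=float(alpha), egger_intercept_se=float(alpha_se),
        egger_intercept_pval=float(alpha_p),
    )


class MVMRResults:
    """Per-exposure multivariable estimates with a Table-2 shaped summary."""

    def __init__(self, estimates: list[MREstimate]):
        self.estimates = estimates

    def __getitem__(self, exposure: str) -> MREstimate:
        for e in self.estimates:
            if e.exposure == exposure:
                return e
        raise KeyError(exposure)

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.estimates:
            row = {
                "exposure": e.exposure, "method": e.method, "n_snp": e.n_snp,
                "theta": e.theta, "se": e.se, "ci_low": e.ci_low,
                "ci_high": e.ci_high, "pval": e.pval,
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


class MultivariableMR:
    """Multivariable MR model over a harmonized multi-exposure set."""

    def __init__(self, harmonized: HarmonizedSet):
        if harmonized.n_exposures < 1:
            raise ValueError("at least one exposure required")
        self.data = harmonized

    def fit(self, method: str = "ivw", **kwargs) -> MVMRResults:
        if method == "ivw":
            return MVMRResults(mvmr_ivw(self.data))
        if method == "egger":
            return MVMRResults(mvmr_egger(self.data, **kwargs))
        raise ValueError(f"unknown method {method!r}")
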