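"""Two-step mediation calculus on MR estimates.

With beta1 the exposure-to-mediator effect (SD per SD), beta2 the
mediator-to-outcome effect adjusted for the exposure (log-odds per SD, from
multivariable MR), and ``total`` the exposure-to-outcome total effect
(log-odds), the indirect effect is the product beta1*beta2 and the mediated
proportion is (beta1*beta2)/total.  Confidence intervals come from the delta
method: by default only the product's variance is propagated (the total
effect treated as fixed in the ratio), first-order, with switches for the
full ratio delta and the second-order product term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DomainError
from .uvmr import MREstimate, Z95

__all__ = ["MediationResult", "ScreenResult", "mediation_proportion",
           "bonferroni_threshold"]


@dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition with delta-method CI."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    indirect: float
    se_indirect: float
    proportion: float
    se_prop: float
    ci_low: float
    ci_high: float
    pval: float
    indirect_or: float

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    @property
    def ci_pct(self) -> tuple[float, float]:
        return (100.0 * self.ci_low, 100.0 * self.ci_high)

    def summary(self) -> str:
        lo, hi = self.ci_pct
        return (
            f"indirect effect = {self.indirect:.4f} (SE {self.se_indirect:.4f}), "
            f"OR scale exp(indirect) = {self.indirect_or:.3f}\n"
            f"mediated proportion = {self.proportion_pct:.2f}% "
            f"(95% CI [{lo:.2f}%, {hi:.2f}%], p = {self.pval:.3g})"
        )


def mediation_proportion(beta1: float, se1: float, beta2: float, se2: float,
                         total: float, se_total: float,
                         propagate_total: bool = False,
                         second_order: bool = False) -> MediationResult:
    """Mediated proportion (beta1*beta2)/total with a delta-method CI.

    ``se_indirect^2 = beta1^2 se2^2 + beta2^2 se1^2`` (plus ``se1^2 se2^2``
    when ``second_order``); no covariance term is included since beta1 and
    beta2 come from separate regressions.  By default the total effect is
    treated as fixed in the ratio, ``se_prop = se_indirect/|total|``;
    ``propagate_total`` switches to the full ratio delta method.
    """
    if total == 0:
        raise DomainError("mediated proportion undefined for total effect 0")
    indirect = beta1 * beta2
    var_ind = beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2
    if second_order:
        var_ind += se1 ** 2 * se2 ** 2
    se_indirect = float(np.sqrt(var_ind))
    proportion = indirect / total
    if propagate_total:
        se_prop = float(np.sqrt(var_ind / total ** 2
                                + indirect ** 2 * se_total ** 2 / total ** 4))
    else:
        se_prop = se_indirect / abs(total)
    z = proportion / se_prop if se_prop > 0 else 0.0
    pval = float(2 * sps.norm.sf(abs(z))) if se_prop > 0 else 1.0
    if indirect == 0:
        pval = 1.0
    return MediationResult(
        beta1=float(beta1), se1=float(se1), beta2=float(beta2), se2=float(se2),
        total=float(total), se_total=float(se_total),
        indirect=float(indirect), se_indirect=se_indirect,
        proportion=float(proportion), se_prop=se_prop,
        ci_low=float(proportion - Z95 * se_prop),
        ci_high=float(proportion + Z95 * se_prop),
        pval=pval,
        indirect_or=float(np.exp(indirect)),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if m < 1:
        raise DomainError("m must be >= 1")
    if not (0 < alpha < 1):
        raise DomainError("alpha must lie in (0, 1)")
    return alpha / m


@dataclass
class ScreenResult:
    """One candidate mediator's screening outcome at a Bonferroni threshold."""

    candidate_name: str
    estimate: MREstimate
    bonferroni_threshold: float
    passed: bool

    @classmethod
    def from_estimate(cls, name: str, estimate: MREstimate,
                      threshold: float) -> "ScreenResult":
        return cls(name, estimate, threshold, bool(estimate.pval < threshold))
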