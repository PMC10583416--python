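"""Approximate-Bayes-factor colocalization of two traits over a gene region.

Under a single-causal-variant assumption per trait, each variant's evidence
is a Wakefield log approximate Bayes factor computed from its estimated
effect and standard error with a normal effect-size prior.  Summing
configurations yields posterior probabilities for five hypotheses:

    H0  neither trait associated in the region
    H1  trait 1 only
    H2  trait 2 only
    H3  both traits, two distinct causal variants
    H4  both traits, one shared causal variant

All hypothesis arithmetic is done in log space with log-sum-exp so large z
scores cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import DomainError, EmptyOverlapError
from .summaries import SummaryStats

__all__ = ["ColocResult", "wakefield_labf", "colocalize", "DEFAULT_PRIORS"]

#: per-variant prior probabilities (p1, p2, p12): association with trait 1
#: only, trait 2 only, and both, the field-standard defaults
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

#: default effect-scale prior standard deviations by trait type
PRIOR_SD = {"quantitative": 0.2, "binary": 0.15}

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocResult:
    """Per-variant log ABFs and posterior probabilities for H0-H4."""

    variant_ids: list[str]
    labf_trait1: np.ndarray
    labf_trait2: np.ndarray
    pp: dict[str, float]
    priors: tuple[float, float, float]

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]

    def summary(self) -> str:
        lines = [f"Colocalization over {len(self.variant_ids)} variants "
                 f"(priors p1={self.priors[0]:g}, p2={self.priors[1]:g}, "
                 f"p12={self.priors[2]:g})"]
        lines += [f"  PP.{h} = {self.pp[h]:.4f}" for h in HYPOTHESES]
        return "\n".join(lines)


def wakefield_labf(beta, se, prior_sd: float) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor for one association.

    With V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se the log ABF of
    the normal-effect model against the point null is
    0.5 * [ln(1 - r) + r * z^2].  Vectorized over beta/se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be positive")
    if not prior_sd > 0:
        raise DomainError("prior_sd must be positive")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z * z)
    return float(out) if out.ndim == 0 else out


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b, -inf at equality."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def colocalize(trait1: SummaryStats, trait2: SummaryStats,
               priors: tuple[float, float, float] = DEFAULT_PRIORS,
               prior_sd1: float | None = None,
               prior_sd2: float | None = None) -> ColocResult:
    """Colocalize two traits over the shared variants of a region.

    The hypothesis weights are, up to the common normalizer,
    H0 = 1, H1 = p1 * S1, H2 = p2 * S2, H4 = p12 * S12, and
    H3 = p1 * p2 * (S1 * S2 - S12), where S1, S2 sum each trait's per-variant
    ABFs and S12 sums the products at the *same* variant.  With a single
    variant H3 is exactly zero.
    """
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0 or p1 + p2 + p12 >= 1:
        raise DomainError("priors must be positive with p1 + p2 + p12 < 1")
    shared = [v for v in trait1.variant_ids if v in trait2]
    if not shared:
        raise EmptyOverlapError("no shared variants between the two traits")
    if prior_sd1 is None:
        prior_sd1 = PRIOR_SD[trait1.trait_type]
    if prior_sd2 is None:
        prior_sd2 = PRIOR_SD[trait2.trait_type]

    r1 = [trait1.get(v) for v in shared]
    r2 = [trait2.get(v) for v in shared]
    labf1 = wakefield_labf([r.beta for r in r1], [r.se for r in r1], prior_sd1)
    labf2 = wakefield_labf([r.beta for r in r2], [r.se for r in r2], prior_sd2)
    labf1 = np.atleast_1d(labf1)
    labf2 = np.atleast_1d(labf2)

    log_s1 = logsumexp(labf1)
    log_s2 = logsumexp(labf2)
    log_s12 = logsumexp(labf1 + labf2)

    log_h = np.array([
        0.0,
        np.log(p1) + log_s1,
        np.log(p2) + log_s2,
        np.log(p1) + np.log(p2) + _log_diff_exp(log_s1 + log_s2, log_s12),
        np.log(p12) + log_s12,
    ])
    log_norm = logsumexp(log_h)
    pp = np.exp(log_h - log_norm)
    pp = pp / pp.sum()  # pin the sum to 1 exactly
    return ColocResult(
        variant_ids=shared,
        labf_trait1=labf1,
        labf_trait2=labf2,
        pp=dict(zip(HYPOTHESES, pp.tolist())),
        priors=(p1, p2, p12),
    )
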