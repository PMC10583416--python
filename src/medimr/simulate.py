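"""Seeded generator of two-sample GWAS summary statistics with known truth.

The generator emulates the data structure of a drug-target mediation MR
study: an exposure (a biomarker-scaled drug-target proxy) instrumented by a
block of cis variants, a panel of candidate mediators of which one sits on
the causal chain, and a binary outcome generated on the log-odds scale under

    beta_med_j = beta1 * beta_x_j + pleiotropy_j          (exposure variants)
    beta_out_j = (theta_direct + beta1*beta2) * beta_x_j + pleiotropy'_j

Each mediator additionally carries its own block of instrument variants
(metabolites are heritable in their own right), which is what identifies the
mediator's direct effect in multivariable MR.  Everything is generated
directly on the summary scale: per-variant standard errors follow the
standardized-trait form 1/sqrt(2*p*(1-p)*n) and observed effects are truth
plus normal noise, all from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .exceptions import DomainError
from .summaries import LDMatrix, SummaryStats, VariantAssociation, write_ld_matrix, write_summary_stats

__all__ = [
    "Pleiotropy",
    "SimulationConfig",
    "StudyTruth",
    "SyntheticStudy",
    "simulate_mr_study",
    "simulate_coloc_region",
]

# non-palindromic allele pairs so no variant is dropped in harmonization
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]

_TINY_P = 5e-324  # smallest positive double; keeps pval inside (0, 1]


@dataclass(frozen=True)
class Pleiotropy:
    """Per-variant direct-on-outcome effect distribution.

    ``none`` fixes all draws at zero, ``balanced`` draws N(0, sd),
    ``directional`` draws N(mean, sd) and violates the zero-average
    (InSIDE-style) assumption IVW relies on.
    """

    kind: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(size)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, size)
        if self.kind == "directional":
            return rng.normal(self.mean, self.sd, size)
        raise ValueError(f"unknown pleiotropy kind {self.kind!r}")


def _default_theta_direct() -> float:
    # direct effect chosen so the default total effect is ln(0.51),
    # the headline exposure-on-outcome odds ratio magnitude
    return float(np.log(0.51) - 0.42 * np.log(0.88))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-sample MR dataset.

    Defaults echo the magnitudes of the motivating analysis: 10 cis
    instruments for the exposure, beta1 = 0.42 SD mediator per SD exposure,
    mediator-on-outcome log-odds beta2 = ln(0.88), total effect ln(0.51),
    and GWAS sample sizes of 300,000.
    """

    n_snps: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exp: int = 300_000
    n_med: int = 300_000
    n_out: int = 300_000
    theta_direct: float = field(default_factory=_default_theta_direct)
    beta1_true: float = 0.42
    beta2_true: float = field(default_factory=lambda: float(np.log(0.88)))
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    n_mediator_panel: int = 20
    n_med_snps: int = 10
    h2_exposure: float = 0.015
    h2_mediator: float = 0.02
    n_outliers: int = 0
    outlier_scale: float = 10.0
    overlap_rho: float = 0.0
    seed: int = 0

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.beta1_true * self.beta2_true

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DomainError("maf_range must lie within (0, 0.5]")
        if min(self.n_exp, self.n_med, self.n_out) <= 0:
            raise DomainError("sample sizes must be positive")
        if self.n_snps < 1:
            raise DomainError("n_snps must be >= 1")
        if self.n_mediator_panel < 0:
            raise DomainError("n_mediator_panel must be >= 0")
        if not (0 < self.h2_exposure < 0.1):
            raise DomainError("infeasible variance budget: exposure instrument "
                              "h2 must lie in (0, 0.1)")
        if not (0 <= self.h2_mediator < 0.1):
            raise DomainError("infeasible variance budget: mediator h2 must "
                              "lie in [0, 0.1)")
        if not (-1 < self.overlap_rho < 1):
            raise DomainError("overlap_rho must lie in (-1, 1)")
        if self.n_outliers > self.n_snps:
            raise DomainError("more outliers requested than exposure variants")


@dataclass
class StudyTruth:
    """Ground truth behind one synthetic study."""

    theta_total: float
    theta_direct: float
    beta1_true: float
    beta2_true: float
    proportion_true: float
    beta_x_true: np.ndarray
    pleiotropy_outcome: np.ndarray
    pleiotropy_mediator: np.ndarray
    outlier_ids: list[str]
    true_mediator: str | None

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["beta_x_true"] = self.beta_x_true.tolist()
        d["pleiotropy_outcome"] = self.pleiotropy_outcome.tolist()
        d["pleiotropy_mediator"] = self.pleiotropy_mediator.tolist()
        return d


@dataclass
class SyntheticStudy:
    """One simulated study: exposure, mediator panel, outcome, LD, truth."""

    exposure_stats: SummaryStats
    mediator_stats: list[SummaryStats]
    outcome_stats: SummaryStats
    ld: LDMatrix
    truth: StudyTruth
    config: SimulationConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary_stats(self.exposure_stats, out / "exposure.tsv")
        write_summary_stats(self.outcome_stats, out / "outcome.tsv")
        for m in self.mediator_stats:
            write_summary_stats(m, out / f"{m.trait_name}.tsv")
        write_ld_matrix(self.ld, out / "ld.tsv")
        (out / "truth.json").write_text(
            json.dumps(self.truth.to_json_dict(), indent=2, sort_keys=True) + "\n")


def _standard_se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _records(ids, chroms, poss, eas, oas, eafs, betas, ses) -> list[VariantAssociation]:
    z = betas / ses
    pvals = np.maximum(2 * sps.norm.sf(np.abs(z)), _TINY_P)
    return [
        VariantAssociation(
            variant_id=ids[i], chrom=chroms[i], pos=int(poss[i]),
            effect_allele=eas[i], other_allele=oas[i], eaf=float(eafs[i]),
            beta=float(betas[i]), se=float(ses[i]), pval=float(pvals[i]), n=1.0,
        )
        for i in range(len(ids))
    ]


def simulate_mr_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate one seeded synthetic study under the configured causal chain.

    The first mediator in the panel carries the causal chain (beta1, beta2);
    the remainder are null mediators (no exposure effect, no outcome effect)
    with their own genetic instruments.  Observed sample sizes in the output
    records are the configured GWAS n for each trait.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_exp_snps = config.n_snps
    n_panel = config.n_mediator_panel
    n_blocks = n_panel  # one instrument block per mediator
    n_total = n_exp_snps + n_blocks * config.n_med_snps

    ids = [f"rs{i + 1}" for i in range(n_total)]
    mafs = rng.uniform(*config.maf_range, size=n_total)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_total)
    eas = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    chroms = ["16"] * n_exp_snps
    poss = list(31_480_000 + 10_000 * np.arange(n_exp_snps))
    for b in range(n_blocks):
        chroms += [str(1 + b % 22)] * config.n_med_snps
        poss += list(50_000_000 * (1 + b // 22) + 1_000_000 * np.arange(config.n_med_snps)
                     + 100_000 * (b % 22))

    exp_slice = slice(0, n_exp_snps)

    def block_slice(b: int) -> slice:
        start = n_exp_snps + b * config.n_med_snps
        return slice(start, start + config.n_med_snps)

    def draw_effects(h2: float, maf: np.ndarray) -> np.ndarray:
        share = rng.uniform(0.5, 1.5, size=maf.size)
        h2_j = h2 * share / share.sum()
        signs = rng.choice([-1.0, 1.0], size=maf.size)
        return signs * np.sqrt(h2_j / (2 * maf * (1 - maf)))

    beta_x = draw_effects(config.h2_exposure, mafs[exp_slice])
    gammas = [draw_effects(config.h2_mediator, mafs[block_slice(b)])
              for b in range(n_blocks)]

    pleio_out = config.pleiotropy.draw(rng, n_exp_snps)
    pleio_med = config.pleiotropy.draw(rng, n_exp_snps)

    se_exp = _standard_se(mafs, config.n_exp)
    se_med = _standard_se(mafs, config.n_med)
    se_out = _standard_se(mafs, config.n_out)

    outlier_ids: list[str] = []
    outlier_offset = np.zeros(n_exp_snps)
    if config.n_outliers:
        chosen = rng.choice(n_exp_snps, size=config.n_outliers, replace=False)
        outlier_offset[chosen] = config.outlier_scale * se_out[exp_slice][chosen]
        outlier_ids = [ids[i] for i in sorted(chosen)]

    # true marginal effects over the full variant universe
    true_exp = np.zeros(n_total)
    true_exp[exp_slice] = beta_x
    true_out = np.zeros(n_total)
    true_out[exp_slice] = config.theta_total * beta_x + pleio_out + outlier_offset
    true_med = np.zeros((n_panel, n_total))
    med_names = [f"metabolite_{m + 1:02d}" for m in range(n_panel)]
    for m in range(n_panel):
        true_med[m, block_slice(m)] = gammas[m]
    if n_panel >= 1:
        true_med[0, exp_slice] = config.beta1_true * beta_x + pleio_med
        true_out[block_slice(0)] += config.beta2_true * gammas[0]

    z_exp = rng.standard_normal(n_total)
    obs_exp = true_exp + z_exp * se_exp
    obs_out = true_out + rng.standard_normal(n_total) * se_out
    obs_med = np.empty((n_panel, n_total))
    rho = config.overlap_rho
    for m in range(n_panel):
        z_m = rng.standard_normal(n_total)
        if rho:
            # participant overlap between the exposure and mediator GWAS
            z_m = rho * z_exp + np.sqrt(1 - rho ** 2) * z_m
        obs_med[m] = true_med[m] + z_m * se_med

    def stats(name, ttype, betas, ses, n) -> SummaryStats:
        recs = _records(ids, chroms, poss, eas, oas, mafs, betas, ses)
        recs = [VariantAssociation(r.variant_id, r.chrom, r.pos, r.effect_allele,
                                   r.other_allele, r.eaf, r.beta, r.se, r.pval,
                                   float(n)) for r in recs]
        return SummaryStats(name, ttype, recs)

    exposure_stats = stats("exposure", "quantitative", obs_exp, se_exp, config.n_exp)
    outcome_stats = stats("outcome", "binary", obs_out, se_out, config.n_out)
    mediator_stats = [
        stats(med_names[m], "quantitative", obs_med[m], se_med, config.n_med)
        for m in range(n_panel)
    ]

    theta_total = config.theta_total
    proportion = (config.beta1_true * config.beta2_true / theta_total
                  if theta_total != 0 else float("nan"))
    truth = StudyTruth(
        theta_total=theta_total, theta_direct=config.theta_direct,
        beta1_true=config.beta1_true, beta2_true=config.beta2_true,
        proportion_true=proportion,
        beta_x_true=beta_x,
        pleiotropy_outcome=pleio_out, pleiotropy_mediator=pleio_med,
        outlier_ids=outlier_ids,
        true_mediator=med_names[0] if n_panel else None,
    )
    return SyntheticStudy(exposure_stats, mediator_stats, outcome_stats,
                          LDMatrix.identity(ids), truth, config)


def simulate_coloc_region(m: int, ld_rho: float, scenario: str,
                          n1: int, n2: int, seed: int,
                          lam: float = 6.0,
                          maf_range: tuple[float, float] = (0.1, 0.5),
                          ) -> tuple[SummaryStats, SummaryStats, LDMatrix, dict]:
    """Simulate an LD-structured region for colocalization tests.

    Builds an AR(1) LD matrix with correlation ``ld_rho``; per scenario the
    causal variant(s) are shared (H4), distinct (H3), one-trait-only
    (H1/H2), or absent (H0).  Marginal z scores are drawn from
    N(R @ lambda, R) — the standard multivariate-normal model of marginal
    GWAS statistics under LD — and converted to beta/se using per-variant
    standard errors.
    """
    if m < 2:
        raise DomainError("region must contain at least 2 variants")
    if not abs(ld_rho) < 1:
        raise DomainError("|ld_rho| must be < 1")
    scenario = scenario.upper()
    if scenario not in ("H0", "H1", "H2", "H3", "H4"):
        raise ValueError(f"unknown scenario {scenario!r}")

    rng = np.random.default_rng(seed)
    idx = np.arange(m)
    big_r = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(big_r + 1e-12 * np.eye(m))

    lam1 = np.zeros(m)
    lam2 = np.zeros(m)
    causal1 = causal2 = None
    if scenario == "H4":
        causal1 = causal2 = int(rng.integers(m))
    elif scenario == "H3":
        causal1, causal2 = map(int, rng.choice(m, size=2, replace=False))
    elif scenario == "H1":
        causal1 = int(rng.integers(m))
    elif scenario == "H2":
        causal2 = int(rng.integers(m))
    if causal1 is not None:
        lam1[causal1] = lam
    if causal2 is not None:
        lam2[causal2] = lam

    mafs = rng.uniform(*maf_range, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    eas = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    ids = [f"rsr{i + 1}" for i in range(m)]
    chroms = ["16"] * m
    poss = 31_480_000 + 1_000 * idx

    def trait(name, lam_vec, n) -> SummaryStats:
        z = big_r @ lam_vec + chol @ rng.standard_normal(m)
        se = _standard_se(mafs, n)
        recs = _records(ids, chroms, poss, eas, oas, mafs, z * se, se)
        recs = [VariantAssociation(r.variant_id, r.chrom, r.pos, r.effect_allele,
                                   r.other_allele, r.eaf, r.beta, r.se, r.pval,
                                   float(n)) for r in recs]
        return SummaryStats(name, "quantitative", recs)

    t1 = trait("trait1", lam1, n1)
    t2 = trait("trait2", lam2, n2)
    truth = {"scenario": scenario, "causal1": causal1, "causal2": causal2,
             "lam": lam, "ld_rho": ld_rho}
    return t1, t2, LDMatrix(ids, big_r), truth
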