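"""End-to-end two-step mediation MR pipeline and report writer.

Stage order: exposure instrument selection -> outlier pre-filtering
(MR-PRESSO + radial union) -> the univariable estimator battery on
exposure -> outcome (the Table-1 surface) -> mediator screen 1
(exposure -> each candidate, Bonferroni 0.05/M) -> mediator screen 2
(survivors -> outcome with their own instruments, Bonferroni 0.05/m1) ->
multivariable MR adjusting each surviving mediator for the exposure
(Bonferroni 0.05/m2, the Table-2 surface) -> product-of-coefficients
mediation proportions with delta-method CIs.

Bonferroni family sizes are the *actual* counts at each stage, mirroring the
168 -> 20 -> 2 cascade convention of the motivating analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import EmptyOverlapError
from .instruments import InstrumentSet, select_biomarker_instruments
from .mediation import MediationResult, ScreenResult, bonferroni_threshold, mediation_proportion
from .mvmr import mvmr_egger, mvmr_ivw
from .robustness import mr_presso, union_outliers
from .summaries import (HarmonizedSet, LDMatrix, SummaryStats, harmonize,
                        read_ld_matrix, read_summary_stats)
from .uvmr import DEFAULT_METHODS, MREstimate, UnivariableMR

__all__ = ["PipelineSettings", "PipelineConfig", "PipelineReport",
           "TwoStepPipeline", "run_two_step_pipeline", "write_report"]

logger = logging.getLogger("medimr.pipeline")


@dataclass
class PipelineSettings:
    """Thresholds, estimator settings, and seeds for one pipeline run."""

    p_exposure: float = 1e-4          # biomarker significance for exposure instruments
    r2_exposure: float = 0.8          # permissive cis clumping
    window_exposure_kb: float = 250.0
    p_mediator: float = 5e-8          # genome-wide threshold for mediator instruments
    r2_mediator: float = 0.01
    window_mediator_kb: float = 10_000.0
    alpha: float = 0.05               # family-wise level for each Bonferroni stage
    methods: tuple = DEFAULT_METHODS
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    outlier_filter: bool = True       # apply MR-PRESSO + radial union everywhere
    invert_sign: bool = False         # flip exposure axis to "per 1 SD lowering"
    palindrome_policy: str = "drop_all"


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (JSON-compatible key-value file)."""

    exposure_path: str
    outcome_path: str
    ld_path: str
    mediator_paths: dict[str, str]  # mediator name -> summary-stats path
    out_dir: str | None = None
    exposure_type: str = "quantitative"
    outcome_type: str = "binary"
    settings: PipelineSettings = field(default_factory=PipelineSettings)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        settings = PipelineSettings(**raw.pop("settings", {}))
        if isinstance(settings.methods, list):
            settings.methods = tuple(settings.methods)
        meds = raw.pop("mediator_paths")
        if isinstance(meds, list):
            meds = {Path(p).stem: p for p in meds}
        return cls(settings=settings, mediator_paths=meds, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["settings"]["methods"] = list(self.settings.methods)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """All stage outputs plus provenance for one run."""

    table1: pd.DataFrame
    screen1: list[ScreenResult]
    screen2: list[ScreenResult]
    table2: pd.DataFrame
    mediation: dict[str, MediationResult]
    provenance: dict
    skipped: list[str] = field(default_factory=list)
    instruments: InstrumentSet | None = None
    outliers_removed: list[str] = field(default_factory=list)
    total_estimate: MREstimate | None = None

    def screen_frame(self, which: int) -> pd.DataFrame:
        results = self.screen1 if which == 1 else self.screen2
        rows = []
        for s in results:
            rows.append({
                "candidate": s.candidate_name,
                "theta": s.estimate.theta if s.estimate else np.nan,
                "se": s.estimate.se if s.estimate else np.nan,
                "pval": s.estimate.pval if s.estimate else np.nan,
                "n_snp": s.estimate.n_snp if s.estimate else 0,
                "bonferroni_threshold": s.bonferroni_threshold,
                "passed": s.passed,
            })
        cols = ["candidate", "theta", "se", "pval", "n_snp",
                "bonferroni_threshold", "passed"]
        return pd.DataFrame(rows, columns=cols)

    def mediation_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.mediation.items():
            lo, hi = m.ci_pct
            rows.append({
                "mediator": name,
                "beta1": m.beta1, "se1": m.se1,
                "beta2": m.beta2, "se2": m.se2,
                "total": m.total, "se_total": m.se_total,
                "indirect": m.indirect, "indirect_or": m.indirect_or,
                "proportion_pct": m.proportion_pct,
                "ci_low_pct": lo, "ci_high_pct": hi, "pval": m.pval,
            })
        cols = ["mediator", "beta1", "se1", "beta2", "se2", "total", "se_total",
                "indirect", "indirect_or", "proportion_pct", "ci_low_pct",
                "ci_high_pct", "pval"]
        return pd.DataFrame(rows, columns=cols)

    def forest_frame(self) -> pd.DataFrame:
        cols = ["method", "or", "or_low", "or_high", "pval"]
        if self.table1.empty or "or" not in self.table1.columns:
            return pd.DataFrame(columns=cols)
        return self.table1[cols].copy()


_EMPTY_TABLE1 = pd.DataFrame(columns=[
    "method", "n_snp", "theta", "se", "ci_low", "ci_high", "pval",
    "q", "q_pval", "egger_intercept", "egger_intercept_pval",
    "or", "or_low", "or_high"])
_EMPTY_TABLE2 = pd.DataFrame(columns=[
    "mediator", "method", "n_snp", "theta", "se", "ci_low", "ci_high", "pval",
    "q", "q_pval", "egger_intercept", "egger_intercept_pval",
    "or", "or_low", "or_high"])


class TwoStepPipeline:
    """In-memory pipeline over already-loaded summary statistics.

    ``mediators`` is the full candidate panel (each a SummaryStats); the
    exposure and every mediator must be quantitative-scale, the outcome may
    be binary (log-odds) or quantitative.
    """

    def __init__(self, exposure: SummaryStats, mediators: list[SummaryStats],
                 outcome: SummaryStats, ld: LDMatrix,
                 settings: PipelineSettings | None = None):
        self.settings = settings or PipelineSettings()
        if self.settings.invert_sign:
            df = exposure.to_frame()
            df["beta"] = -df["beta"]
            exposure = SummaryStats.from_frame(
                df, exposure.trait_name + "_lowering", exposure.trait_type)
        self.exposure = exposure
        self.mediators = mediators
        self.outcome = outcome
        self.ld = ld
        # deterministic per-stage seeds derived from the configured seed
        ss = np.random.SeedSequence(self.settings.seed)
        self._stage_seeds = [int(s.generate_state(1)[0] % 2 ** 31)
                             for s in ss.spawn(6 + 2 * len(mediators))]

    # -- stage helpers ------------------------------------------------------

    def _filter(self, h: HarmonizedSet, seed: int) -> tuple[HarmonizedSet, list[str]]:
        if not self.settings.outlier_filter:
            return h, []
        return union_outliers(h, n_sim=self.settings.n_sim, seed=seed,
                              alpha=self.settings.alpha)

    def _harmonized(self, exposure_stats: SummaryStats, outcome_stats: SummaryStats,
                    ids) -> HarmonizedSet:
        return harmonize([exposure_stats.subset(ids)], outcome_stats.subset(ids),
                         palindrome_policy=self.settings.palindrome_policy)

    # -- run ----------------------------------------------------------------

    def run(self) -> PipelineReport:
        s = self.settings
        skipped: list[str] = []
        provenance = {
            "version": __version__, "seed": s.seed,
            "settings": {**asdict(s), "methods": list(s.methods)},
        }

        def empty_report(reason: str, instruments=None) -> PipelineReport:
            logger.info("pipeline stopped early: %s", reason)
            return PipelineReport(
                table1=_EMPTY_TABLE1.copy(), screen1=[], screen2=[],
                table2=_EMPTY_TABLE2.copy(), mediation={},
                provenance=provenance, skipped=skipped, instruments=instruments)

        # stage 1: exposure instruments
        instr = select_biomarker_instruments(
            self.exposure, s.p_exposure, self.ld,
            r2_threshold=s.r2_exposure, window_kb=s.window_exposure_kb)
        logger.info("exposure instruments: %d selected (log %s)",
                    len(instr), instr.selection_log)
        if len(instr) == 0:
            skipped += ["uvmr", "screen1", "screen2", "mvmr", "mediation"]
            return empty_report("no exposure instruments", instr)
        exposure_instr_stats = instr.to_stats(self.exposure.trait_type)

        # stage 2: harmonize against the outcome and pre-filter outliers
        try:
            h_main = self._harmonized(exposure_instr_stats, self.outcome,
                                      instr.variant_ids)
        except EmptyOverlapError:
            skipped += ["uvmr", "screen1", "screen2", "mvmr", "mediation"]
            return empty_report("no instrument overlap with outcome", instr)
        h_main, removed = self._filter(h_main, self._stage_seeds[0])
        if removed:
            logger.info("outlier pre-filter removed %d variants: %s",
                        len(removed), removed)

        # stage 3: univariable battery (Table 1 surface)
        model = UnivariableMR(h_main)
        battery = model.fit_all(methods=s.methods, n_boot=s.n_boot,
                                seed=self._stage_seeds[1])
        table1 = battery.to_frame()
        if h_main.n_variants >= 4:
            presso = mr_presso(h_main, n_sim=s.n_sim, seed=self._stage_seeds[2],
                               outlier_alpha=s.alpha)
            est = presso.corrected if presso.corrected is not None else battery["ivw"]
            row = {"method": "mr_presso", "n_snp": est.n_snp, "theta": est.theta,
                   "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
                   "pval": est.pval, "q": presso.global_rss,
                   "q_pval": presso.global_pval}
            if est.or_scale is not None:
                row["or"], row["or_low"], row["or_high"] = est.or_scale
            table1 = pd.concat([table1, pd.DataFrame([row])], ignore_index=True)
        total_est = battery["ivw"]

        # stage 4: screen 1 — exposure -> each candidate mediator
        n_panel = len(self.mediators)
        if n_panel == 0:
            skipped += ["screen1", "screen2", "mvmr", "mediation"]
            return PipelineReport(table1, [], [], _EMPTY_TABLE2.copy(), {},
                                  provenance, skipped, instr, removed, total_est)
        thr1 = bonferroni_threshold(s.alpha, n_panel)
        screen1: list[ScreenResult] = []
        for i, med in enumerate(self.mediators):
            try:
                h1 = self._harmonized(exposure_instr_stats, med, instr.variant_ids)
                h1, _ = self._filter(h1, self._stage_seeds[6 + i])
                est1 = UnivariableMR(h1).fit("ivw")
            except (EmptyOverlapError, ValueError) as exc:
                logger.info("screen1 skipped %s: %s", med.trait_name, exc)
                continue
            screen1.append(ScreenResult.from_estimate(med.trait_name, est1, thr1))
        m1 = [r for r in screen1 if r.passed]
        logger.info("screen1: %d/%d mediators pass p < %.3g",
                    len(m1), n_panel, thr1)
        if not m1:
            skipped += ["screen2", "mvmr", "mediation"]
            return PipelineReport(table1, screen1, [], _EMPTY_TABLE2.copy(), {},
                                  provenance, skipped, instr, removed, total_est)

        # stage 5: screen 2 — surviving mediators -> outcome, own instruments
        thr2 = bonferroni_threshold(s.alpha, len(m1))
        med_by_name = {m.trait_name: m for m in self.mediators}
        med_instruments: dict[str, InstrumentSet] = {}
        screen2: list[ScreenResult] = []
        for i, cand in enumerate(m1):
            med = med_by_name[cand.candidate_name]
            mi = select_biomarker_instruments(
                med, s.p_mediator, self.ld,
                r2_threshold=s.r2_mediator, window_kb=s.window_mediator_kb)
            if len(mi) == 0:
                logger.info("screen2: no instruments for %s", med.trait_name)
                continue
            med_instruments[med.trait_name] = mi
            try:
                h2 = self._harmonized(mi.to_stats(med.trait_type), self.outcome,
                                      mi.variant_ids)
                h2, _ = self._filter(h2, self._stage_seeds[6 + n_panel + i])
                est2 = UnivariableMR(h2).fit("ivw")
            except (EmptyOverlapError, ValueError) as exc:
                logger.info("screen2 skipped %s: %s", med.trait_name, exc)
                continue
            screen2.append(ScreenResult.from_estimate(med.trait_name, est2, thr2))
        m2 = [r for r in screen2 if r.passed]
        logger.info("screen2: %d/%d mediators pass p < %.3g",
                    len(m2), len(m1), thr2)
        if not m2:
            skipped += ["mvmr", "mediation"]
            return PipelineReport(table1, screen1, screen2, _EMPTY_TABLE2.copy(),
                                  {}, provenance, skipped, instr, removed, total_est)

        # stage 6: multivariable MR adjusting each mediator for the exposure
        thr3 = bonferroni_threshold(s.alpha, len(m2))
        table2_rows = []
        mediation: dict[str, MediationResult] = {}
        beta1_by_name = {r.candidate_name: r.estimate for r in screen1}
        for cand in m2:
            med = med_by_name[cand.candidate_name]
            union_ids = list(dict.fromkeys(
                instr.variant_ids + med_instruments[med.trait_name].variant_ids))
            union_ids = [v for v in union_ids
                         if v in self.exposure and v in med and v in self.outcome]
            try:
                h_mv = harmonize(
                    [self.exposure.subset(union_ids), med.subset(union_ids)],
                    self.outcome.subset(union_ids),
                    palindrome_policy=s.palindrome_policy)
                iv_est = mvmr_ivw(h_mv)
                eg_est = mvmr_egger(h_mv, orient_to=0)
            except (EmptyOverlapError, ValueError) as exc:
                logger.info("mvmr skipped %s: %s", med.trait_name, exc)
                continue

            def row(e: MREstimate, med_name: str) -> dict:
                r = {"mediator": med_name, "method": e.method, "n_snp": e.n_snp,
                     "theta": e.theta, "se": e.se, "ci_low": e.ci_low,
                     "ci_high": e.ci_high, "pval": e.pval, "q": e.q,
                     "q_pval": e.q_pval, "egger_intercept": e.egger_intercept,
                     "egger_intercept_pval": e.egger_intercept_pval}
                if e.or_scale is not None:
                    r["or"], r["or_low"], r["or_high"] = e.or_scale
                return r

            beta2_est = iv_est[1]  # mediator coefficient, exposure-adjusted
            table2_rows.append(row(beta2_est, med.trait_name))
            table2_rows.append(row(eg_est[1], med.trait_name))
            if beta2_est.pval < thr3:
                beta1_est = beta1_by_name[med.trait_name]
                mediation[med.trait_name] = mediation_proportion(
                    beta1_est.theta, beta1_est.se,
                    beta2_est.theta, beta2_est.se,
                    total_est.theta, total_est.se)
        table2 = (pd.DataFrame(table2_rows) if table2_rows
                  else _EMPTY_TABLE2.copy())
        logger.info("mediation: %d mediators pass MVMR p < %.3g", len(mediation), thr3)
        if not mediation:
            skipped.append("mediation")

        return PipelineReport(table1, screen1, screen2, table2, mediation,
                              provenance, skipped, instr, removed, total_est)


def run_two_step_pipeline(config: PipelineConfig) -> PipelineReport:
    """Load the configured files, run the pipeline, and write reports if
    an output directory is configured."""
    exposure = read_summary_stats(config.exposure_path, "exposure",
                                  config.exposure_type)
    outcome = read_summary_stats(config.outcome_path, "outcome",
                                 config.outcome_type)
    mediators = [read_summary_stats(path, name, "quantitative")
                 for name, path in config.mediator_paths.items()]
    ld = read_ld_matrix(config.ld_path)
    pipeline = TwoStepPipeline(exposure, mediators, outcome, ld, config.settings)
    report = pipeline.run()
    report.provenance["config_hash"] = config.config_hash()
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: PipelineReport, out_dir) -> list[Path]:
    """Write the TSV report set plus run.json; byte-stable for equal reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        written.append(path)

    emit(report.table1, "table1.tsv")
    emit(report.screen_frame(1), "screen1.tsv")
    emit(report.screen_frame(2), "screen2.tsv")
    emit(report.table2, "table2.tsv")
    emit(report.mediation_frame(), "mediation.tsv")
    emit(report.forest_frame(), "forest_data.tsv")
    run = {
        "provenance": report.provenance,
        "skipped": report.skipped,
        "outliers_removed": report.outliers_removed,
        "n_instruments": len(report.instruments) if report.instruments else 0,
    }
    path = out / "run.json"
    path.write_text(json.dumps(run, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
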