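"""Instrument selection: significance filtering, greedy LD clumping, F statistics.

Two selection styles are provided.  Biomarker instruments follow the usual
genome-wide recipe (p < 5e-8, clump to near-independence, r^2 < 0.01 within
10,000 kb).  Drug-target instruments restrict to cis variants in the target
gene region that also move the downstream biomarker (p < 1e-4), optionally
gate on colocalization evidence (PP.H4 above a threshold), and clump
permissively (r^2 < 0.8 within 250 kb); with ``invert_sign`` the exposure
axis is flipped so effects are per 1 SD *lowering* of the biomarker, the
natural direction for pharmacological inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .summaries import LDMatrix, SummaryStats, VariantAssociation

__all__ = [
    "InstrumentSet",
    "clump",
    "f_statistics",
    "select_biomarker_instruments",
    "select_drug_target_instruments",
    "WEAK_F_CUTOFF",
]

#: conventional weak-instrument cutoff for the per-variant F statistic
WEAK_F_CUTOFF = 10.0


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-variant strength."""

    exposure_name: str
    variants: list[VariantAssociation]
    f_stats: np.ndarray
    weak_flags: np.ndarray
    selection_log: list[tuple[str, int, int]] = field(default_factory=list)
    reason: Optional[str] = None  # why the set is empty, when it is

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def to_stats(self, trait_type: str = "quantitative") -> SummaryStats:
        return SummaryStats(self.exposure_name, trait_type, list(self.variants))


def f_statistics(betas, ses) -> np.ndarray:
    """Per-variant F = (beta/se)^2, the squared Wald z."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    return (betas / ses) ** 2


def clump(variants, ld: LDMatrix, r2_threshold: float, window_kb: float) -> list[str]:
    """Greedy p-value clumping.

    ``variants`` is an iterable of (variant_id, pos, pval).  Repeatedly keep
    the unremoved variant with the smallest p-value (ties broken by
    lexicographic variant_id) and remove all unkept variants with
    r^2 >= ``r2_threshold`` AND |delta pos| <= ``window_kb`` * 1000.  Both
    conditions must trip: correlated variants further apart than the window
    survive.  Returns kept ids in selection order.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    entries = [(str(v), int(p), float(pv)) for v, p, pv in variants]
    for vid, _, _ in entries:
        if vid not in ld:
            raise KeyError(f"variant {vid!r} absent from LD matrix")
    window_bp = window_kb * 1000.0
    remaining = sorted(entries, key=lambda e: (e[2], e[0]))
    kept: list[str] = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top[0])
        i_top = ld.index_of(top[0])
        survivors = []
        for e in remaining:
            r2 = ld.r[i_top, ld.index_of(e[0])] ** 2
            if r2 >= r2_threshold and abs(e[1] - top[1]) <= window_bp:
                continue
            survivors.append(e)
        remaining = survivors
    return kept


def _build_set(name: str, records: list[VariantAssociation],
               log: list[tuple[str, int, int]], reason: str | None = None) -> InstrumentSet:
    f = f_statistics([r.beta for r in records], [r.se for r in records]) \
        if records else np.empty(0)
    return InstrumentSet(
        exposure_name=name,
        variants=records,
        f_stats=f,
        weak_flags=f < WEAK_F_CUTOFF,
        selection_log=log,
        reason=reason,
    )


def select_biomarker_instruments(stats: SummaryStats, p_threshold: float,
                                 ld: LDMatrix, r2_threshold: float = 0.01,
                                 window_kb: float = 10_000) -> InstrumentSet:
    """Genome-wide instrument selection: p-value filter then LD clumping.

    An empty result (no variant below ``p_threshold``) is returned with the
    selection log rather than raised.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    log: list[tuple[str, int, int]] = []
    survivors = [r for r in stats.records if r.pval < p_threshold]
    log.append(("pval_filter", len(stats.records), len(survivors)))
    if not survivors:
        return _build_set(stats.trait_name, [], log, reason="no significant variants")
    kept_ids = clump([(r.variant_id, r.pos, r.pval) for r in survivors],
                     ld, r2_threshold, window_kb)
    log.append(("clump", len(survivors), len(kept_ids)))
    index = {r.variant_id: r for r in survivors}
    return _build_set(stats.trait_name, [index[v] for v in kept_ids], log)


def select_drug_target_instruments(eqtl: SummaryStats, biomarker: SummaryStats,
                                   gene_region: tuple[str, int, int],
                                   p_threshold: float,
                                   ld: LDMatrix,
                                   coloc_gate=None, pp_threshold: float = 0.7,
                                   r2_threshold: float = 0.8,
                                   window_kb: float = 250,
                                   invert_sign: bool = True) -> InstrumentSet:
    """Cis drug-target instrument selection gated on colocalization.

    Intersects eQTL variants inside ``gene_region`` with biomarker
    associations at ``pval < p_threshold``; if ``coloc_gate`` (a ColocResult)
    is given and its PP.H4 falls below ``pp_threshold``, returns an empty set
    with the reason recorded.  Survivors are clumped; the returned exposure
    betas are the *biomarker* effects, negated when ``invert_sign`` so the
    exposure reads as biomarker decrease (inhibition).
    """
    if not (0 < pp_threshold < 1):
        raise ValueError("pp_threshold must lie in (0, 1)")
    chrom, start, end = gene_region
    if start > end:
        raise ValueError("malformed gene region: start > end")
    name = f"{biomarker.trait_name}_lowering" if invert_sign else biomarker.trait_name
    log: list[tuple[str, int, int]] = []

    region = eqtl.in_region(str(chrom), int(start), int(end))
    log.append(("eqtl_region", len(eqtl), len(region)))
    if len(region) == 0:
        return _build_set(name, [], log, reason="no eQTL variants in region")

    candidates = [biomarker.get(v) for v in region.variant_ids if v in biomarker]
    survivors = [r for r in candidates if r.pval < p_threshold]
    log.append(("biomarker_filter", len(region), len(survivors)))
    if not survivors:
        return _build_set(name, [], log, reason="no biomarker-significant variants")

    if coloc_gate is not None and coloc_gate.pp_h4 < pp_threshold:
        log.append(("coloc_gate", len(survivors), 0))
        return _build_set(name, [], log, reason="colocalization failed")
    if coloc_gate is not None:
        log.append(("coloc_gate", len(survivors), len(survivors)))

    kept_ids = clump([(r.variant_id, r.pos, r.pval) for r in survivors],
                     ld, r2_threshold, window_kb)
    log.append(("clump", len(survivors), len(kept_ids)))
    index = {r.variant_id: r for r in survivors}
    records = [index[v] for v in kept_ids]
    if invert_sign:
        records = [replace(r, beta=-r.beta) for r in records]
    return _build_set(name, records, log)
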