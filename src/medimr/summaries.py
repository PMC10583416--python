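"""Data model, file I/O, and allele harmonization for two-sample GWAS summary statistics.

Summary statistics live in tab-separated files with the canonical columns
``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n``;
``column_map`` lets callers read files with arbitrary source headers.  The
:func:`harmonize` step aligns every trait's effect allele to the first
exposure's, resolving strand flips by complement and palindromic (A/T, C/G)
variants by allele frequency, before any estimator sees the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyOverlapError, FormatError

__all__ = [
    "VariantAssociation",
    "SummaryStats",
    "LDMatrix",
    "HarmonizedSet",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "harmonize",
    "CANONICAL_COLUMNS",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: effect-allele frequency band inside which a palindromic variant cannot be
#: oriented by frequency and is dropped
EAF_AMBIGUITY_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is per copy of ``effect_allele``: SD units for quantitative
    traits, log-odds for binary traits.  ``eaf`` may be ``None`` when the
    source GWAS did not report allele frequencies.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float

    def validation_error(self) -> str | None:
        """Return the first invariant violation as a short reason, or None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "nonpositive se"
        if not math.isfinite(self.beta):
            return "nonfinite beta"
        if not (0 < self.pval <= 1):
            return "pval outside (0,1]"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf outside [0,1]"
        if not (self.n > 0):
            return "nonpositive n"
        return None

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryStats:
    """One trait's GWAS summary records, keyed by unique variant_id."""

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    records: list[VariantAssociation]
    load_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids: {dup[:5]}")
        self._index = {r.variant_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> VariantAssociation:
        return self._index[variant_id]

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def subset(self, variant_ids) -> "SummaryStats":
        """Restrict to the given ids (silently skipping absent ones)."""
        keep = [self._index[v] for v in variant_ids if v in self._index]
        return SummaryStats(self.trait_name, self.trait_type, keep)

    def in_region(self, chrom: str, start: int, end: int) -> "SummaryStats":
        keep = [r for r in self.records if r.chrom == str(chrom) and start <= r.pos <= end]
        return SummaryStats(self.trait_name, self.trait_type, keep)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta, "se": r.se, "pval": r.pval, "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait_name: str, trait_type: str) -> "SummaryStats":
        records = []
        rejected = []
        for row in df.itertuples(index=False):
            eaf = getattr(row, "eaf", np.nan)
            rec = VariantAssociation(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=None if pd.isna(eaf) else float(eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=float(row.n),
            )
            reason = rec.validation_error()
            if reason is None:
                records.append(rec)
            else:
                rejected.append({"variant_id": rec.variant_id, "reason": reason})
        report = pd.DataFrame(rejected, columns=["variant_id", "reason"])
        return cls(trait_name, trait_type, records, load_report=report)


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) for an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise FormatError(f"LD matrix shape {self.r.shape} != ({m}, {m})")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} absent from LD matrix") from None

    def r2(self, id1: str, id2: str) -> float:
        return float(self.r[self.index_of(id1), self.index_of(id2)] ** 2)

    def submatrix(self, variant_ids) -> "LDMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, variant_ids) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure(s) x outcome effect matrix ready for MR.

    Rows are variants; exposure effects are a (J, K) matrix so the same
    container feeds univariable (K=1) and multivariable estimators.  All
    effects are oriented to the first exposure's effect allele.
    """

    variant_ids: list[str]
    exposure_names: list[str]
    beta_exp: np.ndarray  # (J, K)
    se_exp: np.ndarray    # (J, K)
    beta_out: np.ndarray  # (J,)
    se_out: np.ndarray    # (J,)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    outcome_name: str = "outcome"
    outcome_type: str = "binary"
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    effect_allele: list[str] | None = None
    other_allele: list[str] | None = None
    eaf_exp: np.ndarray | None = None  # (J, K)
    eaf_out: np.ndarray | None = None  # (J,)

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        if self.beta_exp.shape[0] == 1 and len(self.variant_ids) > 1:
            self.beta_exp = self.beta_exp.T
            self.se_exp = self.se_exp.T
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        j = len(self.variant_ids)
        k = len(self.exposure_names)
        if self.beta_exp.shape != (j, k) or self.se_exp.shape != (j, k):
            raise ValueError("exposure matrix shape mismatch")
        if self.beta_out.shape != (j,) or self.se_out.shape != (j,):
            raise ValueError("outcome vector shape mismatch")
        if j and (np.any(self.se_exp <= 0) or np.any(self.se_out <= 0)):
            raise ValueError("all standard errors must be positive")
        if j and not (
            np.all(np.isfinite(self.beta_exp)) and np.all(np.isfinite(self.beta_out))
        ):
            raise ValueError("missing values in retained rows")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    variant_ids=None, exposure_names=None, **kw) -> "HarmonizedSet":
        """Build directly from effect arrays (ids auto-generated); test/simulation helper."""
        beta_exp = np.atleast_2d(np.asarray(beta_exp, dtype=float))
        if beta_exp.shape[0] == 1 and np.size(beta_out) > 1:
            beta_exp = beta_exp.T
        se_exp = np.asarray(se_exp, dtype=float).reshape(beta_exp.shape)
        j, k = beta_exp.shape
        if variant_ids is None:
            variant_ids = [f"snp{i + 1}" for i in range(j)]
        if exposure_names is None:
            exposure_names = [f"exposure{i + 1}" for i in range(k)]
        return cls(list(variant_ids), list(exposure_names), beta_exp, se_exp,
                   np.asarray(beta_out, float), np.asarray(se_out, float), **kw)

    def subset(self, keep) -> "HarmonizedSet":
        """Restrict to a boolean mask or list of variant ids, preserving order."""
        if isinstance(keep, (list, tuple, set, frozenset)) and not isinstance(keep, np.ndarray):
            mask = np.array([v in set(keep) for v in self.variant_ids])
        else:
            mask = np.asarray(keep, dtype=bool)
        ids = [v for v, m in zip(self.variant_ids, mask) if m]
        return HarmonizedSet(
            ids, list(self.exposure_names),
            self.beta_exp[mask], self.se_exp[mask],
            self.beta_out[mask], self.se_out[mask],
            dropped=list(self.dropped),
            outcome_name=self.outcome_name, outcome_type=self.outcome_type,
            chrom=None if self.chrom is None else self.chrom[mask],
            pos=None if self.pos is None else self.pos[mask],
            effect_allele=None if self.effect_allele is None
            else [a for a, m in zip(self.effect_allele, mask) if m],
            other_allele=None if self.other_allele is None
            else [a for a, m in zip(self.other_allele, mask) if m],
            eaf_exp=None if self.eaf_exp is None else self.eaf_exp[mask],
            eaf_out=None if self.eaf_out is None else self.eaf_out[mask],
        )

    def single(self, exposure: int | str = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_x, se_x, beta_y, se_y) for one exposure column."""
        if isinstance(exposure, str):
            exposure = self.exposure_names.index(exposure)
        return (self.beta_exp[:, exposure], self.se_exp[:, exposure],
                self.beta_out, self.se_out)


# ---------------------------------------------------------------------------
# file I/O


def read_summary_stats(path, trait_name: str, trait_type: str = "quantitative",
                       column_map: dict[str, str] | None = None) -> SummaryStats:
    """Read a delimited summary-statistics table into a validated SummaryStats.

    ``column_map`` maps canonical field names to source column headers; fields
    not mentioned are looked up under their canonical names.  Rows violating
    field invariants are rejected with a per-row reason in ``.load_report``.
    """
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise FormatError(f"empty or undelimited summary-statistics file: {path}") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"empty summary-statistics file: {path}")
    column_map = column_map or {}
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif canonical != "eaf":  # eaf may be genuinely absent
            raise FormatError(f"missing mandatory column {canonical!r} in {path}")
    df = df.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    return SummaryStats.from_frame(df[CANONICAL_COLUMNS], trait_name, trait_type)


def write_summary_stats(stats: SummaryStats, path) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_matrix(path) -> LDMatrix:
    """Read a TSV LD matrix with a leading id column and id header row.

    Symmetry is enforced within 1e-8 then the matrix is symmetrized and the
    diagonal pinned to 1 exactly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"LD matrix is not square: shape {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError("LD matrix row ids do not match column ids")
    r = df.to_numpy(dtype=float)
    if np.any(np.abs(r) > 1 + 1e-8):
        raise FormatError("LD matrix entry with |r| > 1")
    if np.max(np.abs(r - r.T)) > 1e-8:
        raise FormatError("LD matrix asymmetric beyond tolerance 1e-8")
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return LDMatrix([str(v) for v in df.index], r)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# harmonization


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


def _eaf_outside_window(eaf: float | None) -> bool:
    lo, hi = EAF_AMBIGUITY_WINDOW
    return eaf is not None and not (lo <= eaf <= hi)


def _align_record(ref: VariantAssociation, rec: VariantAssociation):
    """Align one trait's record to the reference effect/other alleles.

    Returns (flip, reason): ``flip`` is True when the record's beta must be
    negated (and eaf mirrored); ``reason`` is non-None when the variant must
    be dropped.  Palindromic variants are resolved by the caller.
    """
    pair = (rec.effect_allele, rec.other_allele)
    ref_pair = (ref.effect_allele, ref.other_allele)
    if pair == ref_pair:
        return False, None
    if pair == ref_pair[::-1]:
        return True, None
    comp = _complement_pair(*pair)
    if comp == ref_pair:
        return False, None
    if comp == ref_pair[::-1]:
        return True, None
    return False, "incompatible alleles"


def harmonize(exposures: list[SummaryStats] | SummaryStats, outcome: SummaryStats,
              palindrome_policy: str = "drop_all") -> HarmonizedSet:
    """Align outcome and all exposures to the first exposure's effect allele.

    Exact allele matches are kept as-is; swapped effect/other alleles negate
    beta and mirror eaf; strand-complement matches are resolved by
    complementing before aligning.  Palindromic (A/T, C/G) variants cannot be
    disambiguated by allele labels: under ``drop_all`` they are removed, under
    ``infer_by_eaf`` they are kept only when every trait's eaf lies outside
    the ambiguity window and are oriented by frequency agreement with the
    reference.  Missing eaf on a palindromic variant always drops it.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    if not exposures:
        raise ValueError("at least one exposure required")
    if palindrome_policy not in ("drop_all", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    traits = list(exposures) + [outcome]
    ref_stats = exposures[0]
    shared = [v for v in ref_stats.variant_ids if all(v in t for t in traits[1:])]
    dropped: list[tuple[str, str]] = []
    for v in ref_stats.variant_ids:
        if v not in shared:
            missing_in = next(t.trait_name for t in traits[1:] if v not in t)
            dropped.append((v, f"missing in {missing_in}"))
    if not shared:
        raise EmptyOverlapError("no shared variants between exposures and outcome")

    k = len(exposures)
    kept_ids: list[str] = []
    beta_exp, se_exp, eaf_exp = [], [], []
    beta_out, se_out, eaf_out = [], [], []
    chroms, poss, eas, oas = [], [], [], []

    for v in shared:
        ref = ref_stats.get(v)
        recs = [t.get(v) for t in traits]
        flips: list[bool] = []
        reason = None
        if ref.is_palindromic:
            if palindrome_policy == "drop_all":
                reason = "palindromic"
            elif any(r.eaf is None for r in recs):
                reason = "palindromic missing eaf"
            elif not all(_eaf_outside_window(r.eaf) for r in recs):
                reason = "palindromic ambiguous"
            else:
                # orient by frequency agreement with the reference trait:
                # same side of 0.5 -> same orientation, opposite -> flip
                ref_side = ref.eaf > 0.5
                for rec in recs:
                    _, align_reason = _align_record(ref, rec)
                    if align_reason is not None:
                        reason = align_reason
                        break
                    flips.append((rec.eaf > 0.5) != ref_side)
        else:
            for rec in recs:
                flip, align_reason = _align_record(ref, rec)
                if align_reason is not None:
                    reason = align_reason
                    break
                flips.append(flip)
        if reason is not None:
            dropped.append((v, reason))
            continue

        def oriented(rec: VariantAssociation, flip: bool):
            beta = -rec.beta if flip else rec.beta
            eaf = None if rec.eaf is None else (1 - rec.eaf if flip else rec.eaf)
            return beta, rec.se, eaf

        row_b, row_s, row_f = [], [], []
        for rec, flip in zip(recs[:k], flips[:k]):
            b, s, f = oriented(rec, flip)
            row_b.append(b)
            row_s.append(s)
            row_f.append(np.nan if f is None else f)
        b_out, s_out, f_out = oriented(recs[k], flips[k])

        kept_ids.append(v)
        beta_exp.append(row_b)
        se_exp.append(row_s)
        eaf_exp.append(row_f)
        beta_out.append(b_out)
        se_out.append(s_out)
        eaf_out.append(np.nan if f_out is None else f_out)
        chroms.append(ref.chrom)
        poss.append(ref.pos)
        eas.append(ref.effect_allele)
        oas.append(ref.other_allele)

    if not kept_ids:
        raise EmptyOverlapError("all shared variants dropped during harmonization")

    return HarmonizedSet(
        variant_ids=kept_ids,
        exposure_names=[e.trait_name for e in exposures],
        beta_exp=np.array(beta_exp, dtype=float),
        se_exp=np.array(se_exp, dtype=float),
        beta_out=np.array(beta_out, dtype=float),
        se_out=np.array(se_out, dtype=float),
        dropped=dropped,
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
        effect_allele=eas,
        other_allele=oas,
        eaf_exp=np.array(eaf_exp, dtype=float),
        eaf_out=np.array(eaf_out, dtype=float),
    )


def harmonized_to_stats(h: HarmonizedSet) -> tuple[list[SummaryStats], SummaryStats]:
    """Rebuild aligned SummaryStats from a HarmonizedSet (reference orientation).

    P-values are recomputed from the Wald z score; sample size is not tracked
    through harmonization and is written as 1.
    """
    from scipy import stats as sps

    if h.effect_allele is None:
        raise ValueError("HarmonizedSet lacks allele annotations")

    def build(name, ttype, beta, se, eaf):
        recs = []
        for i, v in enumerate(h.variant_ids):
            z = beta[i] / se[i]
            recs.append(VariantAssociation(
                variant_id=v, chrom=str(h.chrom[i]), pos=int(h.pos[i]),
                effect_allele=h.effect_allele[i], other_allele=h.other_allele[i],
                eaf=None if eaf is None or np.isnan(eaf[i]) else float(eaf[i]),
                beta=float(beta[i]), se=float(se[i]),
                pval=float(max(2 * sps.norm.sf(abs(z)), 5e-324)), n=1.0,
            ))
        return SummaryStats(name, ttype, recs)

    exps = [
        build(nm, "quantitative", h.beta_exp[:, j], h.se_exp[:, j],
              None if h.eaf_exp is None else h.eaf_exp[:, j])
        for j, nm in enumerate(h.exposure_names)
    ]
    out = build(h.outcome_name, h.outcome_type, h.beta_out, h.se_out, h.eaf_out)
    return exps, out
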