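"""Align study records to the reference panel and reconstruct missing fields.

Each record is re-oriented so that its effect allele is the reference ALT
allele, resolving allele swaps and strand flips; palindromic (A/T, C/G)
sites are resolved by allele-frequency comparison when both minor allele
frequencies are below an ambiguity threshold and dropped otherwise.  Missing
standard errors are recovered from the effect size and p-value, and missing
allele frequencies are filled from the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .types import ReferencePanel, SumstatsTable, VALID_ALLELES

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_TINY_P = np.finfo(float).tiny


class AlignmentCode(str, Enum):
    EXACT = "EXACT"
    SWAP = "SWAP"
    STRAND = "STRAND"
    STRAND_SWAP = "STRAND_SWAP"
    AMBIGUOUS_RESOLVED = "AMBIGUOUS_RESOLVED"
    AMBIGUOUS_DROPPED = "AMBIGUOUS_DROPPED"
    MISMATCH = "MISMATCH"
    NOT_IN_REFERENCE = "NOT_IN_REFERENCE"


@dataclass
class AlignmentOutcome:
    code: AlignmentCode
    sign_flip: bool = False
    eaf_complemented: bool = False


@dataclass
class HarmonizationReport:
    counts: dict = field(default_factory=dict)
    n_se_recovered: int = 0
    n_af_filled: int = 0
    outcomes: pd.Series | None = None  # per-SNP AlignmentCode, indexed by SNP id

    def count(self, code: AlignmentCode) -> None:
        self.counts[code.value] = self.counts.get(code.value, 0) + 1


def is_palindromic(a: str, b: str) -> bool:
    """True for A/T and C/G pairs, where strand cannot be told from alleles."""
    return COMPLEMENT[a] == b


def align_alleles(
    ea: str,
    oa: str,
    ref_alleles: tuple[str, str],
    study_eaf: float | None = None,
    ref_af: float = np.nan,
    ambiguity_threshold: float = 0.4,
) -> AlignmentOutcome:
    """Orient one record's alleles against the reference (REF, ALT) pair.

    ``ref_af`` is the reference ALT frequency.  Returns the outcome code and
    whether the effect sign and the reported frequency must be flipped to
    express the record on the ALT allele.
    """
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise ValueError(f"invalid alleles {ea}/{oa}")
    ref, alt = ref_alleles

    if is_palindromic(ea, oa):
        if {ea, oa} != {ref, alt}:
            return AlignmentOutcome(AlignmentCode.MISMATCH)
        # strand is unknowable from the alleles; use frequencies
        if study_eaf is None or np.isnan(study_eaf) or np.isnan(ref_af):
            return AlignmentOutcome(AlignmentCode.AMBIGUOUS_DROPPED)
        maf_study = min(study_eaf, 1 - study_eaf)
        maf_ref = min(ref_af, 1 - ref_af)
        if maf_study >= ambiguity_threshold or maf_ref >= ambiguity_threshold:
            return AlignmentOutcome(AlignmentCode.AMBIGUOUS_DROPPED)
        if abs(study_eaf - ref_af) <= abs((1 - study_eaf) - ref_af):
            return AlignmentOutcome(AlignmentCode.AMBIGUOUS_RESOLVED)
        return AlignmentOutcome(
            AlignmentCode.AMBIGUOUS_RESOLVED, sign_flip=True, eaf_complemented=True
        )

    if (ea, oa) == (alt, ref):
        return AlignmentOutcome(AlignmentCode.EXACT)
    if (ea, oa) == (ref, alt):
        return AlignmentOutcome(AlignmentCode.SWAP, sign_flip=True, eaf_complemented=True)
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (alt, ref):
        return AlignmentOutcome(AlignmentCode.STRAND)
    if (cea, coa) == (ref, alt):
        return AlignmentOutcome(
            AlignmentCode.STRAND_SWAP, sign_flip=True, eaf_complemented=True
        )
    return AlignmentOutcome(AlignmentCode.MISMATCH)


def z_from_p(p: float, sign_source: float) -> float:
    """Two-sided p-value to signed Z, the sign copied from ``sign_source``.

    ``z_from_p(1, x) == 0``; p-values below the smallest positive normal
    double are clamped (with a warning) to avoid quantile overflow.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p < _TINY_P:
        warnings.warn(f"p={p} clamped to {_TINY_P} for quantile inversion")
        p = _TINY_P
    z = stats.norm.isf(p / 2.0)
    return z if sign_source >= 0 else -z


def recover_se(beta: float, p: float) -> float | None:
    """Standard error implied by an effect size and its two-sided p-value.

    Returns None when unrecoverable (beta = 0 or p = 1, where |Z| = 0).
    """
    if beta == 0 or not (0 < p < 1):
        return None
    z = abs(z_from_p(p, 1.0))
    if z == 0:
        return None
    return abs(beta) / z


def harmonize_study(
    table: SumstatsTable,
    panel: ReferencePanel,
    ambiguity_threshold: float = 0.4,
) -> tuple[SumstatsTable, HarmonizationReport]:
    """Harmonize a whole study to the reference panel.

    Records are matched on SNP id with chromosome/position verification (an
    id match at a discordant position counts as absent from the reference).
    Retained records are oriented to the reference ALT allele; mismatching
    and unresolvable palindromic records are dropped; records absent from
    the reference are retained but flagged in the report.  Output is sorted
    by (CHR, POS).
    """
    report = HarmonizationReport()
    ref = panel.snp_map.set_index("SNP")
    df = table.df.copy()

    codes: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    flip = np.zeros(len(df), dtype=bool)
    new_ea = df["EA"].to_numpy(dtype=object).copy()
    new_oa = df["OA"].to_numpy(dtype=object).copy()
    ref_af_col = np.full(len(df), np.nan)

    for i, rec in enumerate(df.itertuples(index=False)):
        if rec.SNP not in ref.index:
            out = AlignmentOutcome(AlignmentCode.NOT_IN_REFERENCE)
        else:
            r = ref.loc[rec.SNP]
            if str(r["CHR"]) != str(rec.CHR) or int(r["POS"]) != int(rec.POS):
                out = AlignmentOutcome(AlignmentCode.NOT_IN_REFERENCE)
            else:
                out = align_alleles(
                    rec.EA,
                    rec.OA,
                    (r["REF"], r["ALT"]),
                    study_eaf=rec.EAF,
                    ref_af=float(r["AF"]),
                    ambiguity_threshold=ambiguity_threshold,
                )
                if out.code not in (
                    AlignmentCode.MISMATCH,
                    AlignmentCode.AMBIGUOUS_DROPPED,
                ):
                    new_ea[i], new_oa[i] = r["ALT"], r["REF"]
                    ref_af_col[i] = float(r["AF"])
        report.count(out.code)
        codes.append(out.code.value)
        flip[i] = out.sign_flip
        if out.code in (AlignmentCode.MISMATCH, AlignmentCode.AMBIGUOUS_DROPPED):
            keep[i] = False

    report.outcomes = pd.Series(codes, index=df["SNP"].to_numpy(), name="outcome")

    df["EA"], df["OA"] = new_ea, new_oa
    sign = np.where(flip, -1.0, 1.0)
    df["BETA"] = df["BETA"] * sign
    df["Z"] = df["Z"] * sign
    df.loc[flip, "EAF"] = 1.0 - df.loc[flip, "EAF"]

    # fill missing allele frequencies from the reference
    fill_af = df["EAF"].isna() & ~np.isnan(ref_af_col)
    df.loc[fill_af, "EAF"] = ref_af_col[fill_af]
    report.n_af_filled = int((fill_af & keep).sum())

    # recover missing SEs from beta + p
    need_se = df["SE"].isna() & df["BETA"].notna() & df["P"].notna() & keep
    for i in np.flatnonzero(need_se.to_numpy()):
        se = recover_se(float(df.at[i, "BETA"]), float(df.at[i, "P"]))
        if se is not None:
            df.at[i, "SE"] = se
            report.n_se_recovered += 1

    # complete the statistic triplet where derivable
    z_missing = df["Z"].isna()
    have_bs = df["BETA"].notna() & df["SE"].notna()
    df.loc[z_missing & have_bs, "Z"] = (
        df.loc[z_missing & have_bs, "BETA"] / df.loc[z_missing & have_bs, "SE"]
    )
    z_missing = df["Z"].isna()
    have_pb = df["P"].notna() & df["BETA"].notna()
    for i in np.flatnonzero((z_missing & have_pb).to_numpy()):
        df.at[i, "Z"] = z_from_p(float(df.at[i, "P"]), float(df.at[i, "BETA"]))
    p_missing = df["P"].isna() & df["Z"].notna()
    df.loc[p_missing, "P"] = 2.0 * stats.norm.sf(np.abs(df.loc[p_missing, "Z"]))

    out_df = df.loc[keep].reset_index(drop=True)
    result = SumstatsTable(table.metadata, out_df).sort()
    return result, report
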