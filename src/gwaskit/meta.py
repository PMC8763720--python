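"""Meta-analysis of harmonized studies: fixed-effect inverse-variance
weighting and the sample-size-weighted Z-score (Stouffer) method, plus a
pre-flight compatibility check."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qc import genomic_control_lambda, estimate_trait_variance, InsufficientDataError
from .types import SumstatsTable

META_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF",
    "BETA", "SE", "Z", "P", "N", "K", "HET_Q", "HET_I2",
]


@dataclass
class MetaCompatibilityReport:
    lambda_gc: list[float | None]
    trait_variance: list[float | None]
    n_shared: int
    pairwise_overlap: pd.DataFrame
    orientation_conflicts: pd.Series  # per table (vs first), count of EA/OA conflicts


def check_meta_inputs(tables: list[SumstatsTable]) -> MetaCompatibilityReport:
    """Sanity checks before meta-analysis.

    Reports per-table λGC and implied trait variance, SNP overlap counts,
    and allele-orientation agreement on shared SNPs (which must be perfect
    after harmonization to a common reference).
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least two studies")
    ids = [set(t.df["SNP"]) for t in tables]
    shared = set.intersection(*ids)
    if not shared:
        raise ValueError("no SNP shared by all studies")

    k = len(tables)
    overlap = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            overlap[i, j] = len(ids[i] & ids[j])
    names = [t.metadata.study_id for t in tables]

    first = tables[0].df.set_index("SNP")[["EA", "OA"]]
    conflicts = {}
    for t in tables[1:]:
        other = t.df.set_index("SNP")[["EA", "OA"]]
        common = first.index.intersection(other.index)
        conflicts[t.metadata.study_id] = int(
            ((first.loc[common, "EA"] != other.loc[common, "EA"])
             | (first.loc[common, "OA"] != other.loc[common, "OA"])).sum()
        )

    lams, tvs = [], []
    for t in tables:
        try:
            lams.append(genomic_control_lambda(t))
        except InsufficientDataError:
            lams.append(None)
        tvs.append(estimate_trait_variance(t))

    return MetaCompatibilityReport(
        lambda_gc=lams,
        trait_variance=tvs,
        n_shared=len(shared),
        pairwise_overlap=pd.DataFrame(overlap, index=names, columns=names),
        orientation_conflicts=pd.Series(conflicts),
    )


def _long_frame(tables: list[SumstatsTable]) -> pd.DataFrame:
    frames = []
    for t in tables:
        f = t.df.copy()
        f["_study"] = t.metadata.study_id
        f["Z"] = t.zscores()
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def meta_ivw(
    tables: list[SumstatsTable], min_studies: int = 1, complete_cases: bool = False
) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Per SNP: w_i = 1/se_i², beta = Σw_i b_i / Σw_i, se = (Σw_i)^{-1/2};
    Cochran's Q = Σ w_i (b_i − beta)² and I² = max(0, 1 − (k−1)/Q).  SNPs
    present in fewer than all studies are combined over those available
    (dropped instead when ``complete_cases``).
    """
    long = _long_frame(tables)
    long = long[long["BETA"].notna() & long["SE"].notna() & (long["SE"] > 0)]
    k_all = len(tables)

    rows = []
    for snp, g in long.groupby("SNP", sort=False):
        k = len(g)
        if k < min_studies or (complete_cases and k < k_all):
            continue
        w = 1.0 / g["SE"].to_numpy() ** 2
        b = g["BETA"].to_numpy()
        sw = w.sum()
        beta = float((w * b).sum() / sw)
        se = float(sw ** -0.5)
        z = beta / se
        q = float((w * (b - beta) ** 2).sum())
        i2 = max(0.0, 1.0 - (k - 1) / q) if q > 0 else 0.0
        n = g["N"].to_numpy(dtype=float)
        eaf = g["EAF"].to_numpy(dtype=float)
        if np.isfinite(n).all() and np.isfinite(eaf).all():
            eaf_out = float((n * eaf).sum() / n.sum())
        else:
            eaf_out = float(np.nanmean(eaf)) if np.isfinite(eaf).any() else np.nan
        rows.append(
            {
                "SNP": snp,
                "CHR": g["CHR"].iloc[0],
                "POS": g["POS"].iloc[0],
                "EA": g["EA"].iloc[0],
                "OA": g["OA"].iloc[0],
                "EAF": eaf_out,
                "BETA": beta,
                "SE": se,
                "Z": z,
                "P": float(2.0 * stats.norm.sf(abs(z))),
                "N": float(np.nansum(n)) if np.isfinite(n).any() else np.nan,
                "K": k,
                "HET_Q": q,
                "HET_I2": i2,
            }
        )
    return pd.DataFrame(rows, columns=META_COLUMNS)


def meta_zscore(
    tables: list[SumstatsTable], min_studies: int = 1, complete_cases: bool = False
) -> pd.DataFrame:
    """Sample-size-weighted Z-score (Stouffer) meta-analysis.

    z_meta = Σ √n_i z_i / √(Σ n_i); yields direction and significance only
    (no pooled effect size).  SNPs lacking n in a contributing record are
    skipped for that record; ``skipped_missing_n`` on the result counts
    SNPs lost entirely.
    """
    long = _long_frame(tables)
    long = long[long["Z"].notna()]
    k_all = len(tables)

    rows = []
    n_skipped = 0
    for snp, g in long.groupby("SNP", sort=False):
        n = g["N"].to_numpy(dtype=float)
        if not np.isfinite(n).all():
            n_skipped += 1
            continue
        k = len(g)
        if k < min_studies or (complete_cases and k < k_all):
            continue
        z = g["Z"].to_numpy(dtype=float)
        z_meta = float((np.sqrt(n) * z).sum() / np.sqrt(n.sum()))
        eaf = g["EAF"].to_numpy(dtype=float)
        eaf_out = (
            float((n * eaf).sum() / n.sum()) if np.isfinite(eaf).all() else np.nan
        )
        rows.append(
            {
                "SNP": snp,
                "CHR": g["CHR"].iloc[0],
                "POS": g["POS"].iloc[0],
                "EA": g["EA"].iloc[0],
                "OA": g["OA"].iloc[0],
                "EAF": eaf_out,
                "BETA": np.nan,
                "SE": np.nan,
                "Z": z_meta,
                "P": float(2.0 * stats.norm.sf(abs(z_meta))),
                "N": float(n.sum()),
                "K": k,
                "HET_Q": np.nan,
                "HET_I2": np.nan,
            }
        )
    out = pd.DataFrame(rows, columns=META_COLUMNS)
    out.attrs["skipped_missing_n"] = n_skipped
    return out
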