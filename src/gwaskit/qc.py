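"""Study-level quality control for harmonized summary statistics.

Four checks: (1) allele-frequency concordance with the reference and
consistency of reported p-values with the p implied by beta/SE, (2) the
shape (skewness) of the effect-size distribution, (3) the phenotypic
variance implied by the per-SNP standard errors, and (4) the genomic
control factor λGC.  A SNP failing any per-SNP check is an outlier; a study
with more than ``outlier_fraction_max`` outliers, or an asymmetric effect
distribution, is not recommended for upload (the verdict is advisory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .types import ReferencePanel, SumstatsTable

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...

MIN_RECORDS = 10


class InsufficientDataError(ValueError):
    """Too few usable records for a study-level statistic."""


@dataclass
class QcThresholds:
    """Cutoffs for the QC battery (all configurable)."""

    af_delta: float = 0.2
    logp_delta: float = 1.0  # decades of disagreement tolerated
    skewness_max: float = 0.5
    outlier_fraction_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("af_delta", "logp_delta", "skewness_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.outlier_fraction_max < 1):
            raise ValueError("outlier_fraction_max must be in (0,1)")


@dataclass
class QcReport:
    flags: pd.DataFrame  # per-SNP: SNP, af_outlier, pz_outlier, checked
    lambda_gc: float | None
    trait_variance: float | None
    effect_skewness: float | None
    outlier_fraction: float
    n_checked: int
    n_flagged: int
    verdict: str
    thresholds: QcThresholds = field(default_factory=QcThresholds)

    def to_dict(self) -> dict:
        return {
            "lambda_gc": self.lambda_gc,
            "trait_variance": self.trait_variance,
            "effect_skewness": self.effect_skewness,
            "outlier_fraction": self.outlier_fraction,
            "n_checked": self.n_checked,
            "n_flagged": self.n_flagged,
            "verdict": self.verdict,
        }


def _ref_af_for(table: SumstatsTable, panel: ReferencePanel) -> pd.Series:
    """Reference ALT frequency per record; NaN where the record is absent
    from the panel (or its coordinates disagree)."""
    ref = panel.snp_map.set_index("SNP")
    df = table.df
    af = pd.Series(np.nan, index=df.index)
    in_ref = df["SNP"].isin(ref.index)
    sub = df.loc[in_ref]
    r = ref.loc[sub["SNP"]]
    match = (
        (r["CHR"].to_numpy().astype(str) == sub["CHR"].to_numpy().astype(str))
        & (r["POS"].to_numpy() == sub["POS"].to_numpy())
    )
    af.loc[sub.index[match]] = r["AF"].to_numpy()[match]
    return af


def af_concordance(
    table: SumstatsTable, panel: ReferencePanel, af_delta: float = 0.2
) -> pd.DataFrame:
    """Flag SNPs whose reported frequency departs from the reference by more
    than ``af_delta``; unmatched or frequency-less SNPs are unchecked."""
    df = table.df
    ref_af = _ref_af_for(table, panel)
    checked = df["EAF"].notna() & ref_af.notna()
    flag = checked & ((df["EAF"] - ref_af).abs() > af_delta)
    return pd.DataFrame(
        {"SNP": df["SNP"], "af_checked": checked, "af_outlier": flag}
    )


def pz_concordance(table: SumstatsTable, logp_delta: float = 1.0) -> pd.DataFrame:
    """Flag SNPs whose reported p disagrees with the p implied by beta/SE by
    more than ``logp_delta`` decades."""
    df = table.df
    checked = df["BETA"].notna() & df["SE"].notna() & df["P"].notna() & (df["SE"] > 0)
    z = np.zeros(len(df))
    z[checked] = (df.loc[checked, "BETA"] / df.loc[checked, "SE"]).to_numpy()
    # log10 p from the normal tail, stable for large |z|
    logp_computed = np.log10(2.0) + stats.norm.logsf(np.abs(z)) / np.log(10.0)
    with np.errstate(divide="ignore"):
        logp_reported = np.log10(df["P"].to_numpy(dtype=float))
    flag = checked & (np.abs(logp_reported - logp_computed) > logp_delta)
    return pd.DataFrame(
        {"SNP": df["SNP"], "pz_checked": checked, "pz_outlier": flag}
    )


def effect_distribution_stats(
    table: SumstatsTable, skewness_max: float = 0.5
) -> tuple[float, bool]:
    """Sample skewness g1 = m3/m2^{3/2} of the effect sizes and whether the
    distribution counts as symmetric (|g1| <= skewness_max)."""
    betas = table.df["BETA"].dropna().to_numpy()
    if len(betas) < MIN_RECORDS:
        raise InsufficientDataError(
            f"need >= {MIN_RECORDS} effect sizes, have {len(betas)}"
        )
    g1 = float(stats.skew(betas, bias=True))
    return g1, abs(g1) <= skewness_max


def genomic_control_lambda(table: SumstatsTable) -> float:
    """λGC = median(z²) / median of the 1-df chi-square (0.4549)."""
    z = table.zscores().dropna().to_numpy()
    if len(z) < MIN_RECORDS:
        raise InsufficientDataError(f"need >= {MIN_RECORDS} z-scores, have {len(z)}")
    return float(np.median(z**2) / CHI2_1DF_MEDIAN)


def estimate_trait_variance(table: SumstatsTable) -> float | None:
    """Median over SNPs of se² · n · 2·eaf·(1−eaf): the phenotypic variance
    implied by the summary statistics under an additive model."""
    df = table.df
    ok = df["SE"].notna() & df["N"].notna() & df["EAF"].notna() & (df["SE"] > 0)
    if not ok.any():
        return None
    sub = df.loc[ok]
    v = sub["SE"] ** 2 * sub["N"] * 2.0 * sub["EAF"] * (1.0 - sub["EAF"])
    return float(v.median())


def qc_verdict(
    table: SumstatsTable,
    panel: ReferencePanel,
    thresholds: QcThresholds | None = None,
) -> QcReport:
    """Run the full battery and issue the advisory upload verdict.

    A SNP is an outlier if any per-SNP flag is set; SNPs unchecked by every
    per-SNP check are excluded from the outlier denominator.  The study is
    not recommended iff outlier_fraction > outlier_fraction_max (strict) or
    |skewness| > skewness_max.
    """
    th = thresholds or QcThresholds()
    af = af_concordance(table, panel, th.af_delta)
    pz = pz_concordance(table, th.logp_delta)
    flags = af.merge(pz, on="SNP")
    flags["checked"] = flags["af_checked"] | flags["pz_checked"]
    flags["outlier"] = flags["af_outlier"] | flags["pz_outlier"]

    n_checked = int(flags["checked"].sum())
    n_flagged = int(flags["outlier"].sum())
    outlier_fraction = n_flagged / n_checked if n_checked else 0.0

    try:
        skew, symmetric = effect_distribution_stats(table, th.skewness_max)
    except InsufficientDataError:
        skew, symmetric = None, True
    try:
        lam = genomic_control_lambda(table)
    except InsufficientDataError:
        lam = None
    tv = estimate_trait_variance(table)

    bad = outlier_fraction > th.outlier_fraction_max or not symmetric
    return QcReport(
        flags=flags[["SNP", "af_outlier", "pz_outlier", "checked", "outlier"]],
        lambda_gc=lam,
        trait_variance=tv,
        effect_skewness=skew,
        outlier_fraction=outlier_fraction,
        n_checked=n_checked,
        n_flagged=n_flagged,
        verdict="not_recommended" if bad else "recommended",
        thresholds=th,
    )


def qc_plots(
    table: SumstatsTable, panel: ReferencePanel, out_dir: str | Path
) -> list[Path]:
    """Diagnostic plots: effect-size histogram, study-vs-reference frequency
    scatter, and a p-value QQ plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    df = table.df

    fig, ax = plt.subplots()
    ax.hist(df["BETA"].dropna(), bins=50)
    ax.set_xlabel("effect size")
    ax.set_ylabel("SNPs")
    p = out_dir / "beta_hist.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    ref_af = _ref_af_for(table, panel)
    ok = df["EAF"].notna() & ref_af.notna()
    fig, ax = plt.subplots()
    ax.scatter(ref_af[ok], df.loc[ok, "EAF"], s=4, alpha=0.5)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("reference ALT frequency")
    ax.set_ylabel("study effect-allele frequency")
    p = out_dir / "eaf_vs_ref.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    pv = np.sort(df["P"].dropna().to_numpy())
    if len(pv):
        exp = -np.log10((np.arange(len(pv)) + 0.5) / len(pv))
        fig, ax = plt.subplots()
        ax.scatter(exp, -np.log10(pv), s=4)
        lim = max(exp.max(), -np.log10(pv.min() + 1e-320))
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        p = out_dir / "qq.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
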