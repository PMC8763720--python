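"""LD-score computation and LD-score regression.

The regression of per-SNP association chi-square on LD scores separates
polygenic signal (the slope, scaled to SNP heritability) from confounding
(the intercept).  The cross-trait analogue regresses z1·z2 products on LD
scores to estimate the genetic covariance and, after scaling by the two
heritabilities, the genetic correlation.  Standard errors come from a
leave-one-block-out jackknife over contiguous position-sorted blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ReferencePanel, SumstatsTable

MIN_HAPLOTYPES = 50


@dataclass
class LdScores:
    """Per-SNP LD scores l_j = 1 + Σ adjusted r² within the window."""

    df: pd.DataFrame  # SNP CHR POS L2 MONO
    window: int
    n_ref: int

    def lookup(self, snp_ids: pd.Series) -> pd.Series:
        return snp_ids.map(self.df.set_index("SNP")["L2"])

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class H2Estimate:
    h2: float
    intercept: float
    h2_se: float
    intercept_se: float
    m_snps: int
    n_blocks: int
    # step-1 (unweighted-by-heteroskedasticity) estimates, reused for
    # cross-trait weighting
    h2_step1: float = np.nan
    intercept_step1: float = np.nan


@dataclass
class RgEstimate:
    rho_g: float
    rg: float
    rg_se: float
    cross_intercept: float
    h2_1: float
    h2_2: float
    m_snps: int
    out_of_range: bool = False  # |rg| > 1 (sampling noise)


def compute_ld_scores(panel: ReferencePanel, window: int = 100) -> LdScores:
    """LD scores from the haplotype panel with a SNP-count window.

    For SNP j, l_j = 1 + Σ_{0<|k−j|<=window} r̃²_jk over SNPs on the same
    chromosome, with the small-sample adjustment r̃² = r² − (1−r²)/(n−2)
    that makes r̃² unbiased for 0 under independence.  Monomorphic SNPs get
    l = 1 and a flag.
    """
    n = panel.n_haplotypes
    if n < MIN_HAPLOTYPES:
        raise ValueError(f"panel has {n} haplotypes; need >= {MIN_HAPLOTYPES}")
    H = panel.haplotypes.astype(np.float64)
    mean = H.mean(axis=0)
    sd = H.std(axis=0)
    mono = sd == 0
    X = np.zeros_like(H)
    nz = ~mono
    X[:, nz] = (H[:, nz] - mean[nz]) / sd[nz]

    m = panel.n_snps
    l2 = np.ones(m)
    chrom = panel.snp_map["CHR"].to_numpy()
    for d in range(1, min(window, m - 1) + 1):
        r = (X[:, :-d] * X[:, d:]).mean(axis=0)
        same_chr = chrom[:-d] == chrom[d:]
        valid = same_chr & nz[:-d] & nz[d:]
        r2 = r**2
        r2_adj = np.where(valid, r2 - (1.0 - r2) / (n - 2), 0.0)
        l2[:-d] += r2_adj
        l2[d:] += r2_adj
    l2[mono] = 1.0

    df = panel.snp_map[["SNP", "CHR", "POS"]].copy()
    df["L2"] = l2
    df["MONO"] = mono
    return LdScores(df=df, window=window, n_ref=n)


def write_ld_scores(scores: LdScores, path) -> None:
    """Conventional l2.ldscore-style TSV (CHR, SNP, POS, L2)."""
    out = scores.df[["CHR", "SNP", "POS", "L2"]].rename(columns={"POS": "BP"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ld_scores(path) -> LdScores:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"BP": "POS"})
    df["MONO"] = False
    return LdScores(df=df[["SNP", "CHR", "POS", "L2", "MONO"]], window=-1, n_ref=-1)


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _block_bounds(n: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    return [(edges[b], edges[b + 1]) for b in range(n_blocks)]


def _jackknife(estimate_fn, n: int, n_blocks: int) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-block-out jackknife; returns (full estimate, SEs)."""
    full = np.atleast_1d(estimate_fn(np.ones(n, dtype=bool)))
    thetas = []
    for lo, hi in _block_bounds(n, n_blocks):
        mask = np.ones(n, dtype=bool)
        mask[lo:hi] = False
        thetas.append(np.atleast_1d(estimate_fn(mask)))
    thetas = np.asarray(thetas)
    mean = thetas.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((thetas - mean) ** 2).sum(axis=0))
    return full, se


def _merge_scores(table: SumstatsTable, scores: LdScores) -> pd.DataFrame:
    df = table.sort().df.copy()
    df["Z"] = SumstatsTable(table.metadata, df).zscores()
    merged = df.merge(scores.df[["SNP", "L2"]], on="SNP", how="inner")
    merged = merged[merged["Z"].notna()]
    return merged.reset_index(drop=True)


def estimate_h2(
    table: SumstatsTable,
    scores: LdScores,
    m: int | None = None,
    n: float | None = None,
    n_blocks: int = 20,
    intercept_one: bool = False,
) -> H2Estimate:
    """SNP heritability by weighted regression of chi-square on N·l/M.

    Two-step weighting: an initial 1/max(l,1) fit, then heteroskedasticity
    weights 1/(2(N·l·ĥ²/M + intercept)²·max(l,1)) from the step-1 estimates.
    ``m`` is the number of SNPs the heritability is spread over (defaults to
    the number of scored SNPs); ``n`` the GWAS sample size (defaults to the
    table's median N).
    """
    merged = _merge_scores(table, scores)
    if m is None:
        m = len(scores)
    if n is None:
        n_med = merged["N"].median()
        if not np.isfinite(n_med):
            raise ValueError("sample size n not given and N column empty")
        n = float(n_med)
    n_snps = len(merged)
    if n_snps < 10 * n_blocks:
        raise ValueError(
            f"{n_snps} SNPs with z and LD scores < 10*n_blocks={10 * n_blocks}; "
            "reduce n_blocks"
        )

    chi2 = merged["Z"].to_numpy() ** 2
    l = merged["L2"].to_numpy()
    x = n * l / m
    lmax = np.maximum(l, 1.0)

    def design(mask, intercept):
        if intercept:
            return np.column_stack([x[mask], np.ones(mask.sum())])
        return x[mask][:, None]

    w1 = 1.0 / lmax
    if intercept_one:
        c1 = _wls(chi2 - 1.0, design(np.ones(n_snps, bool), False), w1)
        h2_1, int_1 = float(c1[0]), 1.0
    else:
        c1 = _wls(chi2, design(np.ones(n_snps, bool), True), w1)
        h2_1, int_1 = float(c1[0]), float(c1[1])

    # Step-2 weights are cross-fitted: each block's weights come from a
    # step-1 fit that excludes the block, so a SNP's own noise never enters
    # its weight (in-sample weighting otherwise attenuates the slope at
    # desk-scale SNP counts).
    w2 = np.empty(n_snps)
    for lo, hi in _block_bounds(n_snps, n_blocks):
        mask = np.ones(n_snps, bool)
        mask[lo:hi] = False
        if intercept_one:
            cb = _wls(chi2[mask] - 1.0, design(mask, False), w1[mask])
            hb, ib = float(cb[0]), 1.0
        else:
            cb = _wls(chi2[mask], design(mask, True), w1[mask])
            hb, ib = float(cb[0]), float(cb[1])
        ev_b = n * l[lo:hi] * np.clip(hb, 0.0, 2.0) / m + max(ib, 0.1)
        w2[lo:hi] = 1.0 / (2.0 * ev_b**2 * lmax[lo:hi])

    def fit(mask) -> np.ndarray:
        if intercept_one:
            c = _wls(chi2[mask] - 1.0, design(mask, False), w2[mask])
            return np.array([c[0], 1.0])
        c = _wls(chi2[mask], design(mask, True), w2[mask])
        return np.array([c[0], c[1]])

    full, se = _jackknife(fit, n_snps, n_blocks)
    return H2Estimate(
        h2=float(full[0]),
        intercept=float(full[1]),
        h2_se=float(se[0]),
        intercept_se=float(se[1]) if not intercept_one else 0.0,
        m_snps=n_snps,
        n_blocks=n_blocks,
        h2_step1=h2_1,
        intercept_step1=int_1,
    )


def genetic_correlation(
    t1: SumstatsTable,
    t2: SumstatsTable,
    scores: LdScores,
    m: int | None = None,
    n1: float | None = None,
    n2: float | None = None,
    n_blocks: int = 20,
    intercept_one: bool = False,
) -> RgEstimate:
    """Genetic correlation by cross-trait LD-score regression.

    Regresses z1·z2 on √(n1·n2)·l/M; the slope is the genetic covariance
    ρg and the intercept absorbs sample overlap.  rg = ρg/√(ĥ²₁·ĥ²₂); the
    jackknife SE is computed on rg itself (all three regressions re-fit per
    deleted block).  All heteroskedasticity weights are built from step-1
    estimates, so a trait against itself reproduces the h² regression and
    returns rg = 1 exactly.
    """
    m1 = _merge_scores(t1, scores)
    m2 = _merge_scores(t2, scores)
    merged = m1.merge(m2, on="SNP", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no overlapping SNPs between the two studies")
    if m is None:
        m = len(scores)
    if n1 is None:
        n1 = float(m1["N"].median())
    if n2 is None:
        n2 = float(m2["N"].median())
    n_snps = len(merged)
    if n_snps < 10 * n_blocks:
        raise ValueError(
            f"{n_snps} shared SNPs < 10*n_blocks={10 * n_blocks}; reduce n_blocks"
        )

    z1 = merged["Z_1"].to_numpy()
    z2 = merged["Z_2"].to_numpy()
    l = merged["L2_1"].to_numpy()
    lmax = np.maximum(l, 1.0)
    y = z1 * z2
    x = np.sqrt(n1 * n2) * l / m
    ones = np.ones(n_snps)
    w1 = 1.0 / lmax

    def step1(resp, xx, nn):
        if intercept_one:
            c = _wls(resp - 1.0, xx[:, None], w1)
            return float(c[0]), 1.0
        c = _wls(resp, np.column_stack([xx, ones]), w1)
        return float(c[0]), float(c[1])

    x1 = n1 * l / m
    x2 = n2 * l / m
    h1_s1, i1_s1 = step1(z1**2, x1, n1)
    h2_s1, i2_s1 = step1(z2**2, x2, n2)
    rho_s1, ic_s1 = step1(y, x, np.sqrt(n1 * n2))

    ev1 = x1 * np.clip(h1_s1, 0.0, 2.0) + max(i1_s1, 0.1)
    ev2 = x2 * np.clip(h2_s1, 0.0, 2.0) + max(i2_s1, 0.1)
    # sign-symmetric cross term: weights (which use evc²) are then invariant
    # to negating either trait, making rg exactly sign-equivariant
    s = 1.0 if rho_s1 >= 0 else -1.0
    evc = x * np.clip(abs(rho_s1), 0.0, 2.0) + max(s * ic_s1, 0.1)
    w_h1 = 1.0 / (2.0 * ev1**2 * lmax)
    w_h2 = 1.0 / (2.0 * ev2**2 * lmax)
    w_rg = 1.0 / ((ev1 * ev2 + evc**2) * lmax)

    def fit_one(resp, xx, w, mask) -> tuple[float, float]:
        if intercept_one:
            c = _wls(resp[mask] - 1.0, xx[mask][:, None], w[mask])
            return float(c[0]), 1.0
        c = _wls(resp[mask], np.column_stack([xx[mask], ones[mask]]), w[mask])
        return float(c[0]), float(c[1])

    def estimate(mask) -> np.ndarray:
        h1, _ = fit_one(z1**2, x1, w_h1, mask)
        h2, _ = fit_one(z2**2, x2, w_h2, mask)
        rho, ic = fit_one(y, x, w_rg, mask)
        if h1 > 0 and h2 > 0:
            rg = rho / np.sqrt(h1 * h2)
        else:
            rg = np.nan
        return np.array([rho, rg, ic, h1, h2])

    full, se = _jackknife(estimate, n_snps, n_blocks)
    rho_g, rg, ic, h1, h2 = full
    return RgEstimate(
        rho_g=float(rho_g),
        rg=float(rg),
        rg_se=float(se[1]),
        cross_intercept=float(ic),
        h2_1=float(h1),
        h2_2=float(h2),
        m_snps=n_snps,
        out_of_range=bool(np.isfinite(rg) and abs(rg) > 1),
    )
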