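"""Locus-level colocalization of two traits from summary statistics.

Three complementary views of one region: the SMR test asks whether the top
association is shared by both traits; the HEIDI test asks whether the
pattern of effects across linked SNPs is consistent with a single shared
causal variant (heterogeneity indicates distinct variants in LD); and the
θ metric scores the overall similarity of the two association profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ReferencePanel, SumstatsTable

DEFAULT_REGION_HALF_WIDTH = 500_000  # bp around the top SNP


@dataclass
class RegionProfiles:
    """Paired z-score vectors and signed LD over one locus.

    All z-scores must share one allele orientation (harmonize both studies
    to the same panel first).  ``top_index`` marks the instrument: the most
    significant trait-2 (exposure) SNP.
    """

    snp_ids: list[str]
    z_trait1: np.ndarray
    z_trait2: np.ndarray
    ld: np.ndarray  # signed r
    top_index: int

    def __post_init__(self) -> None:
        self.z_trait1 = np.asarray(self.z_trait1, dtype=float)
        self.z_trait2 = np.asarray(self.z_trait2, dtype=float)
        self.ld = np.asarray(self.ld, dtype=float)
        k = len(self.snp_ids)
        if not (self.z_trait1.shape == self.z_trait2.shape == (k,)):
            raise ValueError("z vectors must match snp_ids length")
        if self.ld.shape != (k, k):
            raise ValueError("ld matrix shape mismatch")
        if not 0 <= self.top_index < k:
            raise ValueError("top_index out of range")


@dataclass
class ColocResult:
    t_smr: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    theta: float


def ld_matrix(panel: ReferencePanel) -> np.ndarray:
    """Signed haplotype correlation matrix of the panel's SNPs
    (monomorphic SNPs get zero off-diagonal correlation)."""
    H = panel.haplotypes.astype(float)
    sd = H.std(axis=0)
    X = np.zeros_like(H)
    nz = sd > 0
    X[:, nz] = (H[:, nz] - H[:, nz].mean(axis=0)) / sd[nz]
    R = X.T @ X / H.shape[0]
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def build_region(
    t1: SumstatsTable,
    t2: SumstatsTable,
    panel: ReferencePanel,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> RegionProfiles:
    """Assemble paired z profiles and LD for one locus.

    SNPs present in both studies and the panel (within the region, if one is
    given) are used; the instrument is the SNP with the largest |z| for
    trait 2.  When no region is given, a window of ±500 kb around that SNP
    is taken.
    """
    d1 = t1.df.assign(Z=t1.zscores())[["SNP", "CHR", "POS", "Z"]]
    d2 = t2.df.assign(Z=t2.zscores())[["SNP", "Z"]]
    merged = d1.merge(d2, on="SNP", suffixes=("1", "2")).dropna(subset=["Z1", "Z2"])
    merged = merged[merged["SNP"].isin(set(panel.snp_map["SNP"]))]
    if chrom is not None:
        merged = merged[merged["CHR"].astype(str) == str(chrom)]
        if start is not None:
            merged = merged[merged["POS"] >= start]
        if end is not None:
            merged = merged[merged["POS"] <= end]
    if merged.empty:
        raise ValueError("no shared SNPs in the requested region")
    if chrom is None:
        top = merged.loc[merged["Z2"].abs().idxmax()]
        merged = merged[
            (merged["CHR"] == top["CHR"])
            & (merged["POS"] - top["POS"]).abs().le(DEFAULT_REGION_HALF_WIDTH)
        ]
    merged = merged.sort_values("POS").reset_index(drop=True)

    sub = panel.subset(merged["SNP"])
    order = {s: i for i, s in enumerate(sub.snp_map["SNP"])}
    merged = merged.iloc[np.argsort(merged["SNP"].map(order).to_numpy())].reset_index(
        drop=True
    )
    R = ld_matrix(sub)
    top_index = int(np.argmax(np.abs(merged["Z2"].to_numpy())))
    return RegionProfiles(
        snp_ids=list(merged["SNP"]),
        z_trait1=merged["Z1"].to_numpy(),
        z_trait2=merged["Z2"].to_numpy(),
        ld=R,
        top_index=top_index,
    )


def smr_test(z1: float, z2: float) -> tuple[float, float]:
    """SMR statistic T = z1²z2²/(z1²+z2²) with its 1-df chi-square p-value.

    Approximates the Wald statistic of the two-stage (exposure → outcome)
    effect; undefined (NaN, NaN) when both z are zero.
    """
    q1, q2 = z1 * z1, z2 * z2
    if q1 + q2 == 0:
        return float("nan"), float("nan")
    t = q1 * q2 / (q1 + q2)
    return float(t), float(stats.chi2.sf(t, df=1))


def select_heidi_snps(
    region: RegionProfiles,
    p_instrument_max: float = 1.6e-4,
    r2_min: float = 0.05,
    r2_max: float = 0.9,
    max_snps: int = 20,
) -> list[int]:
    """Choose the LD-linked SNP set for the HEIDI test.

    Keeps trait-2 SNPs below ``p_instrument_max`` with r² to the top SNP in
    [r2_min, r2_max]; greedily prunes mutually redundant pairs (r² > r2_max)
    keeping the smaller p; caps the set at ``max_snps`` by ascending p.  The
    top SNP is always included.
    """
    t = region.top_index
    z2 = region.z_trait2
    p2 = 2.0 * stats.norm.sf(np.abs(z2))
    r2 = region.ld[t] ** 2

    cand = [
        i
        for i in range(len(z2))
        if i != t and p2[i] < p_instrument_max and r2_min <= r2[i] <= r2_max
    ]
    cand.sort(key=lambda i: p2[i])
    kept: list[int] = []
    for i in cand:
        if all(region.ld[i, j] ** 2 <= r2_max for j in kept):
            kept.append(i)
    kept = kept[: max_snps - 1]
    return [t] + kept


def heidi_test(
    region: RegionProfiles,
    selected: list[int],
    mc_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float | None, int]:
    """Heterogeneity-in-dependent-instruments test on z-score ratios.

    Under a single shared causal variant, the ratio b_i = z1_i/z2_i is the
    same at every linked SNP; heterogeneity of d_i = b_i − b_top signals
    distinct causal variants.  The covariance of d comes from the LD matrix
    via the delta method for ratios (independent cohorts assumed), and the
    null tail of T = Σ(d_i/sd_i)² — a weighted sum of 1-df chi-squares — is
    evaluated by seeded Monte Carlo from the eigenvalues of the correlation
    matrix of the standardized d.

    Returns (p, number of SNPs used); p is None when fewer than 3 SNPs are
    available.
    """
    sel = list(selected)
    if len(sel) < 3:
        return None, len(sel)
    t = region.top_index
    if t not in sel:
        raise ValueError("selected set must include the top SNP")
    others = [i for i in sel if i != t]

    z1 = region.z_trait1
    z2 = region.z_trait2
    R = region.ld
    idx = others + [t]
    k = len(others)

    # delta method: b_i = z1_i/z2_i with cov(z1_i,z1_j)=cov(z2_i,z2_j)=r_ij
    # and cov(z1,z2)=0 across cohorts
    g1 = np.array([1.0 / z2[i] for i in idx])          # ∂b/∂z1
    g2 = np.array([-z1[i] / z2[i] ** 2 for i in idx])  # ∂b/∂z2
    Rs = R[np.ix_(idx, idx)]
    cov_b = np.outer(g1, g1) * Rs + np.outer(g2, g2) * Rs

    # d_i = b_i - b_top: contrast matrix
    A = np.zeros((k, k + 1))
    A[:, :k] = np.eye(k)
    A[:, k] = -1.0
    cov_d = A @ cov_b @ A.T

    sd = np.sqrt(np.diag(cov_d))
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        warnings.warn("degenerate d covariance; ridge-regularizing")
        cov_d = cov_d + 1e-8 * np.eye(k)
        sd = np.sqrt(np.diag(cov_d))
    corr_d = cov_d / np.outer(sd, sd)
    eig = np.linalg.eigvalsh((corr_d + corr_d.T) / 2.0)
    if eig.min() < 1e-10:
        if eig.min() < -1e-8:
            warnings.warn("singular d covariance; ridge-regularizing diagonal")
        corr_d = corr_d + 1e-8 * np.eye(k)
        eig = np.linalg.eigvalsh((corr_d + corr_d.T) / 2.0)
    eig = np.clip(eig, 0.0, None)

    b = z1[idx] / z2[idx]
    d = b[:k] - b[k]
    T = float(np.sum((d / sd) ** 2))

    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((mc_draws, k)) ** 2 @ eig
    p = float((np.count_nonzero(draws >= T) + 1) / (mc_draws + 1))
    return p, k + 1


def theta_metric(region: RegionProfiles) -> float:
    """Cosine similarity of the two orientation-harmonized z profiles.

    θ = Σ z1_i z2_i / √(Σz1² · Σz2²) ∈ [−1, 1]; NaN if either profile is
    identically zero.
    """
    z1, z2 = region.z_trait1, region.z_trait2
    n1 = np.sqrt(np.sum(z1**2))
    n2 = np.sqrt(np.sum(z2**2))
    if n1 == 0 or n2 == 0:
        return float("nan")
    return float(np.clip(np.dot(z1, z2) / (n1 * n2), -1.0, 1.0))


def coloc_region(
    region: RegionProfiles,
    p_instrument_max: float = 1.6e-4,
    r2_min: float = 0.05,
    r2_max: float = 0.9,
    max_snps: int = 20,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> ColocResult:
    """Run SMR at the instrument, HEIDI on the selected set, and θ over the
    whole region."""
    t = region.top_index
    t_smr, p_smr = smr_test(region.z_trait1[t], region.z_trait2[t])
    selected = select_heidi_snps(region, p_instrument_max, r2_min, r2_max, max_snps)
    p_heidi, n_heidi = heidi_test(region, selected, mc_draws=mc_draws, seed=seed)
    return ColocResult(
        t_smr=t_smr,
        p_smr=p_smr,
        p_heidi=p_heidi,
        n_heidi_snps=n_heidi,
        theta=theta_metric(region),
    )
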