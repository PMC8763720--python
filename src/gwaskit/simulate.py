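"""Synthetic-data generator: LD-structured haplotype panels, additive
polygenic phenotypes, per-SNP linear-regression scans, and targeted data
corruptions.

The haplotype model is a first-order Markov copy chain: each SNP's allele
either copies the previous SNP's allele on the same haplotype (with a
probability calibrated so the adjacent-SNP Pearson correlation equals
``ld_rho``) or is redrawn from its own frequency — giving geometric r²
decay with distance, the feature LD scores, clumping and HEIDI need.
Every operation is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import COMPLEMENT
from .types import ReferencePanel, StudyMetadata, SumstatsTable

#: non-palindromic allele pairs cycled across simulated SNPs (REF, ALT)
_ALLELE_PAIRS = (("A", "G"), ("T", "C"), ("G", "T"), ("C", "A"))


@dataclass
class SimConfig:
    n_individuals: int = 1000
    m_snps: int = 1000
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.3
    n_causal: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if self.n_causal > self.m_snps:
            raise ValueError("n_causal cannot exceed m_snps")


@dataclass
class SimTruth:
    causal_indices: np.ndarray
    causal_betas: np.ndarray  # standardized-genotype scale
    h2_realized: float
    n_resampled_monomorphic: int = 0


def simulate_panel(config: SimConfig) -> ReferencePanel:
    """Phased haplotypes with geometric LD decay, deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    n2 = 2 * config.n_individuals
    m = config.m_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    # Copy chain: allele j equals allele j-1 on the same haplotype with
    # probability ld_rho, else a fresh Bernoulli(maf_j) draw.  Copying keeps
    # realized frequencies smooth along the chromosome, so the adjacent
    # correlation is ~ld_rho and r² decays geometrically with distance.
    H = np.empty((n2, m), dtype=np.int8)
    H[:, 0] = rng.random(n2) < maf[0]
    for j in range(1, m):
        copy = rng.random(n2) < config.ld_rho
        fresh = (rng.random(n2) < maf[j]).astype(np.int8)
        H[:, j] = np.where(copy, H[:, j - 1], fresh)

    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    snp_map = pd.DataFrame(
        {
            "SNP": [f"rs{j + 1}" for j in range(m)],
            "CHR": "1",
            "POS": np.arange(m, dtype=np.int64) * 1000 + 1,
            "REF": [p[0] for p in pairs],
            "ALT": [p[1] for p in pairs],
            "AF": H.mean(axis=0),
        }
    )
    return ReferencePanel(snp_map, H)


def concat_panels(panels: list[ReferencePanel]) -> ReferencePanel:
    """Stack panels over the same individuals as successive chromosomes.

    Blocks simulated with different ``ld_rho`` give a panel whose LD scores
    vary across the genome — the leverage LD-score regression needs.  SNPs
    are renamed ``rs1..rsM`` to stay unique; chromosomes are labeled 1..k.
    """
    n = {p.n_haplotypes for p in panels}
    if len(n) != 1:
        raise ValueError("all panels must cover the same individuals")
    maps = []
    offset = 0
    for k, p in enumerate(panels):
        sm = p.snp_map.copy()
        sm["CHR"] = str(k + 1)
        sm["SNP"] = [f"rs{offset + j + 1}" for j in range(len(sm))]
        offset += len(sm)
        maps.append(sm)
    snp_map = pd.concat(maps, ignore_index=True)
    H = np.hstack([p.haplotypes for p in panels])
    return ReferencePanel(snp_map, H)


def simulate_phenotype(
    panel: ReferencePanel, config: SimConfig
) -> tuple[np.ndarray, SimTruth]:
    """Additive polygenic phenotype with target heritability ``h2``.

    Causal SNPs are sampled uniformly; their effects (on the standardized
    genotype scale) are N(0, h2/n_causal).  Environmental noise is scaled
    and the phenotype standardized so the sample variance is exactly 1;
    ``h2_realized`` is the realized genetic variance fraction.
    """
    rng = np.random.default_rng(config.seed + 1)
    G = panel.dosages().astype(float)
    n, m = G.shape
    sd = G.std(axis=0)
    poly = np.flatnonzero(sd > 0)
    if len(poly) < config.n_causal:
        raise ValueError("not enough polymorphic SNPs for the causal set")
    n_resampled = 0
    causal = rng.choice(m, size=config.n_causal, replace=False)
    while np.any(sd[causal] == 0):
        n_resampled += int((sd[causal] == 0).sum())
        causal = rng.choice(poly, size=config.n_causal, replace=False)
    causal = np.sort(causal)

    betas = (
        rng.normal(0.0, np.sqrt(config.h2 / config.n_causal), size=config.n_causal)
        if config.h2 > 0
        else np.zeros(config.n_causal)
    )
    Gs = (G[:, causal] - G[:, causal].mean(axis=0)) / sd[causal]
    g = Gs @ betas
    e = rng.standard_normal(n) * np.sqrt(max(1.0 - config.h2, 0.0))
    y = g + e
    scale = y.std()
    if scale == 0:
        raise ValueError("degenerate phenotype (zero variance)")
    y = (y - y.mean()) / scale
    g_scaled = (g - g.mean()) / scale
    h2_realized = float(g_scaled.var())
    truth = SimTruth(
        causal_indices=causal,
        causal_betas=betas / scale,
        h2_realized=h2_realized,
        n_resampled_monomorphic=n_resampled,
    )
    return y, truth


def gwas_scan(
    panel: ReferencePanel,
    phenotype: np.ndarray,
    metadata: StudyMetadata | None = None,
) -> SumstatsTable:
    """Per-SNP simple linear regression of the phenotype on allele dosage.

    Produces a complete canonical table: beta, se, two-sided p from the t
    distribution with n−2 df, Z = beta/se, effect-allele (ALT) frequency and
    n.  Monomorphic SNPs get missing statistics.
    """
    y = np.asarray(phenotype, dtype=float)
    G = panel.dosages().astype(float)
    n, m = G.shape
    if len(y) != n:
        raise ValueError("phenotype length must equal panel individual count")
    if metadata is None:
        metadata = StudyMetadata(
            study_id="scan", trait_name="simulated", domain="complex_trait",
            sample_size=n,
        )

    yc = y - y.mean()
    syy = float(yc @ yc)
    xm = G.mean(axis=0)
    sxx = ((G - xm) ** 2).sum(axis=0)
    sxy = (G - xm).T @ yc

    poly = sxx > 0
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    beta[poly] = sxy[poly] / sxx[poly]
    sse = syy - beta[poly] * sxy[poly]
    sse = np.clip(sse, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[poly] = np.sqrt(sse / ((n - 2) * sxx[poly]))
    z = np.full(m, np.nan)
    ok = poly & (se > 0)
    z[ok] = beta[ok] / se[ok]
    # exact fit: infinite t, p underflows to 0-adjacent
    exact = poly & (se == 0) & (beta != 0)
    z[exact] = np.sign(beta[exact]) * np.inf
    p = np.full(m, np.nan)
    p[poly] = 2.0 * stats.t.sf(np.abs(z[poly]), df=n - 2)

    df = pd.DataFrame(
        {
            "SNP": panel.snp_map["SNP"],
            "CHR": panel.snp_map["CHR"],
            "POS": panel.snp_map["POS"],
            "EA": panel.snp_map["ALT"],
            "OA": panel.snp_map["REF"],
            "EAF": xm / 2.0,
            "BETA": beta,
            "SE": se,
            "P": p,
            "Z": np.where(np.isinf(z), np.nan, z),
            "N": float(n),
        }
    )
    return SumstatsTable(metadata, df)


CORRUPTION_KINDS = ("af_flip", "p_scramble", "beta_inflate", "strand_error")


def corrupt_sumstats(
    table: SumstatsTable,
    kind: str,
    fraction: float,
    seed: int = 0,
    candidates: np.ndarray | None = None,
) -> tuple[SumstatsTable, np.ndarray]:
    """Inject a controlled data error into round(fraction·m) records.

    Kinds: ``af_flip`` (eaf → 1−eaf), ``p_scramble`` (permute p among the
    victims), ``beta_inflate`` (beta → 10·beta, se untouched),
    ``strand_error`` (complement both alleles without re-orienting).
    Victims are drawn with the given seed, optionally restricted to
    ``candidates`` (row indices); the victim index array is returned.
    """
    if kind not in CORRUPTION_KINDS:
        raise ValueError(f"kind must be one of {CORRUPTION_KINDS}")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    out = table.copy()
    m = out.n_records
    n_victims = round(fraction * m)
    if n_victims == 0:
        return out, np.array([], dtype=int)
    pool = np.arange(m) if candidates is None else np.asarray(candidates, dtype=int)
    if n_victims > len(pool):
        raise ValueError(f"{n_victims} victims requested but only {len(pool)} candidates")
    rng = np.random.default_rng(seed)
    victims = np.sort(rng.choice(pool, size=n_victims, replace=False))

    df = out.df
    if kind == "af_flip":
        df.loc[victims, "EAF"] = 1.0 - df.loc[victims, "EAF"]
    elif kind == "p_scramble":
        vals = df.loc[victims, "P"].to_numpy()
        df.loc[victims, "P"] = rng.permutation(vals)
    elif kind == "beta_inflate":
        df.loc[victims, "BETA"] = 10.0 * df.loc[victims, "BETA"]
    elif kind == "strand_error":
        df.loc[victims, "EA"] = df.loc[victims, "EA"].map(COMPLEMENT)
        df.loc[victims, "OA"] = df.loc[victims, "OA"].map(COMPLEMENT)
    return out, victims
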