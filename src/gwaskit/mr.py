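"""Multi-instrument Mendelian randomization between two harmonized studies.

Instruments are genome-wide-significant exposure SNPs thinned by LD
clumping against the reference panel.  Three estimators of the causal
effect of exposure on outcome: inverse-variance-weighted ratio (IVW),
Egger regression (free intercept as a directional-pleiotropy gauge), and
the weighted median (consistent with up to half the weight on invalid
instruments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ld_matrix
from .types import ReferencePanel, SumstatsTable

DEFAULT_P_MAX = 5e-8
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_CLUMP_WINDOW = 500_000  # bp


@dataclass
class Instrument:
    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float


@dataclass
class MrResult:
    method: str  # ivw | egger | weighted_median
    estimate: float
    se: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None


def select_instruments(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    panel: ReferencePanel,
    p_max: float = DEFAULT_P_MAX,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_window: int = DEFAULT_CLUMP_WINDOW,
) -> list[Instrument]:
    """Significant exposure SNPs, LD-clumped, joined to the outcome.

    Iterates by ascending exposure p; a SNP is discarded when its r² with an
    already-retained SNP within ``clump_window`` bp exceeds ``clump_r2``.
    """
    exp = exposure.df
    sig = exp[exp["P"].notna() & (exp["P"] < p_max)].copy()
    sig = sig[sig["SNP"].isin(set(panel.snp_map["SNP"]))]
    if sig.empty:
        raise ValueError(
            f"no exposure SNP with p < {p_max}; relax p_max to obtain instruments"
        )
    sig = sig.sort_values("P").reset_index(drop=True)

    sub = panel.subset(sig["SNP"])
    R = ld_matrix(sub)
    pos_in_sub = {s: i for i, s in enumerate(sub.snp_map["SNP"])}

    kept_rows = []
    for row in sig.itertuples(index=False):
        i = pos_in_sub[row.SNP]
        ok = True
        for kept in kept_rows:
            j = pos_in_sub[kept.SNP]
            if (
                str(kept.CHR) == str(row.CHR)
                and abs(int(kept.POS) - int(row.POS)) <= clump_window
                and R[i, j] ** 2 > clump_r2
            ):
                ok = False
                break
        if ok:
            kept_rows.append(row)

    out = outcome.df.set_index("SNP")
    instruments = []
    for row in kept_rows:
        if row.SNP not in out.index:
            continue
        o = out.loc[row.SNP]
        if any(
            x is None or (isinstance(x, float) and np.isnan(x))
            for x in (row.BETA, row.SE, o["BETA"], o["SE"])
        ):
            continue
        instruments.append(
            Instrument(
                snp_id=row.SNP,
                beta_x=float(row.BETA),
                se_x=float(row.SE),
                beta_y=float(o["BETA"]),
                se_y=float(o["SE"]),
            )
        )
    if not instruments:
        raise ValueError("no clumped instrument found in the outcome study")
    return instruments


def _ratios(instruments: list[Instrument]) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and first-order delta-method SEs; zero-
    beta_x instruments are dropped with a warning."""
    ok = [i for i in instruments if i.beta_x != 0]
    if len(ok) < len(instruments):
        warnings.warn(f"dropped {len(instruments) - len(ok)} instrument(s) with beta_x = 0")
    w = np.array([i.beta_y / i.beta_x for i in ok])
    se = np.array([i.se_y / abs(i.beta_x) for i in ok])
    return w, se


def mr_ivw(instruments: list[Instrument]) -> MrResult:
    """Inverse-variance-weighted mean of the per-instrument ratios."""
    w, se = _ratios(instruments)
    if len(w) < 2:
        raise ValueError("IVW needs >= 2 usable instruments")
    wt = 1.0 / se**2
    est = float((wt * w).sum() / wt.sum())
    se_est = float(wt.sum() ** -0.5)
    z = est / se_est
    return MrResult(
        method="ivw",
        estimate=est,
        se=se_est,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=len(w),
    )


def mr_egger(instruments: list[Instrument]) -> MrResult:
    """Egger regression: WLS of beta_y on beta_x with a free intercept.

    Instruments are re-oriented so beta_x >= 0 (intercept interpretability);
    weights 1/se_y².  The intercept estimates directional pleiotropy.
    """
    import statsmodels.api as sm

    if len(instruments) < 3:
        raise ValueError("Egger needs >= 3 instruments")
    bx = np.array([i.beta_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    sy = np.array([i.se_y for i in instruments])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx.std(), 0):
        raise ValueError("degenerate design: all beta_x identical after orientation")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    slope, intercept = fit.params[1], fit.params[0]
    # multiplicative random-effects scale, floored at 1 (fixed-effect floor):
    # an apparently underdispersed fit must not shrink the SEs below the
    # sampling noise the per-instrument SEs imply
    infl = np.sqrt(max(1.0, fit.scale) / fit.scale)
    se_slope = float(fit.bse[1] * infl)
    z = slope / se_slope
    return MrResult(
        method="egger",
        estimate=float(slope),
        se=se_slope,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=len(instruments),
        egger_intercept=float(intercept),
        egger_intercept_se=float(fit.bse[0] * infl),
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (cumulative weight crossing 0.5)."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw = cw / w.sum()
    return float(np.interp(0.5, cw, v))


def mr_weighted_median(
    instruments: list[Instrument], n_boot: int = 1000, seed: int = 0
) -> MrResult:
    """Weighted median of ratio estimates; SE by seeded parametric bootstrap
    (instrument effects redrawn from their normal sampling distributions)."""
    if len(instruments) < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    w, se = _ratios(instruments)
    wt = 1.0 / se**2
    est = weighted_median(w, wt)

    ok = [i for i in instruments if i.beta_x != 0]
    bx = np.array([i.beta_x for i in ok])
    sx = np.array([i.se_x for i in ok])
    by = np.array([i.beta_y for i in ok])
    sy = np.array([i.se_y for i in ok])
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        nz = bxs != 0
        r = bys[nz] / bxs[nz]
        rse = sy[nz] / np.abs(bxs[nz])
        boot[b] = weighted_median(r, 1.0 / rse**2)
    se_est = float(boot.std(ddof=1))
    z = est / se_est if se_est > 0 else np.inf
    return MrResult(
        method="weighted_median",
        estimate=est,
        se=se_est,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=len(w),
    )


def run_mr(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    panel: ReferencePanel,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median"),
    p_max: float = DEFAULT_P_MAX,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_window: int = DEFAULT_CLUMP_WINDOW,
    seed: int = 0,
) -> pd.DataFrame:
    """Instrument selection plus the requested estimators, as one frame."""
    instruments = select_instruments(
        exposure, outcome, panel, p_max=p_max, clump_r2=clump_r2, clump_window=clump_window
    )
    dispatch = {
        "ivw": lambda: mr_ivw(instruments),
        "egger": lambda: mr_egger(instruments),
        "weighted_median": lambda: mr_weighted_median(instruments, seed=seed),
    }
    rows = []
    for m in methods:
        res = dispatch[m]()
        rows.append(
            {
                "method": res.method,
                "estimate": res.estimate,
                "se": res.se,
                "p": res.p,
                "n_instruments": res.n_instruments,
                "egger_intercept": res.egger_intercept,
                "egger_intercept_se": res.egger_intercept_se,
            }
        )
    return pd.DataFrame(rows)
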