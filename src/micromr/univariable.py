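"""Univariable two-sample MR estimators and sensitivity statistics.

Implements the Wald ratio, fixed-effect and multiplicative-random-effects IVW,
MR-Egger regression with its intercept (directional pleiotropy) test, Cochran's
Q heterogeneity statistic, the Steiger directionality test, Benjamini–Hochberg
FDR adjustment, and the screen driver that runs the whole battery across an
exposure panel.

Conventions: p-values use the normal reference (the two-sample MR convention;
a t reference is available via ``use_t``); the multiplicative random-effects
SE scale factor floors at 1, so over-dispersion widens intervals but
under-dispersion never shrinks them.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import (
    HarmonizedInstrumentSet,
    LDMatrix,
    SummaryDataset,
    apply_exclusion_list,
    harmonize,
    ld_clump,
    select_instruments,
)

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "SteigerResult",
    "ScreenResultRow",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "cochran_q",
    "bh_fdr",
    "steiger_test",
    "leave_one_out",
    "run_univariable_screen",
]

_Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclasses.dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds (beta) scale with its
    exponentiated (odds-ratio) counterpart and optional Egger intercept."""

    method: str  # wald_ratio | ivw_fe | ivw_mre | egger
    theta_hat: float
    se: float
    pvalue: float
    n_snps: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.theta_hat - _Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.theta_hat + _Z95 * self.se

    @property
    def or_point(self) -> float:
        return math.exp(self.theta_hat)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)


@dataclasses.dataclass
class HeterogeneityResult:
    q: float
    df: int
    q_pvalue: float


@dataclasses.dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_forward: bool
    pvalue: float


@dataclasses.dataclass
class ScreenResultRow:
    exposure_id: str
    outcome_id: str
    estimate: MREstimate | None
    heterogeneity: HeterogeneityResult | None = None
    egger: MREstimate | None = None
    steiger: SteigerResult | None = None
    fdr_adjusted_p: float = float("nan")
    tier: str = "null"  # significant_fdr | potential | null
    error: str | None = None

    @property
    def raw_p(self) -> float:
        return self.estimate.pvalue if self.estimate else float("nan")


def _two_sided_p(z: float) -> float:
    # floored at the smallest positive double so downstream FDR stays defined
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-instrument causal estimate beta_y / beta_x with first-order
    delta-method SE ``se_y / |beta_x|``."""
    if beta_x == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return MREstimate("wald_ratio", theta, se, _two_sided_p(theta / se), 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se_fe = denom**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fe, q


def ivw(
    instruments: HarmonizedInstrumentSet,
    effects_model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate: zero-intercept weighted regression
    of outcome on exposure effects with weights 1/se_y^2.

    ``multiplicative_random`` inflates the fixed-effect SE by
    ``max(1, sqrt(Q / (J - 1)))``; with a single instrument it reduces exactly
    to the Wald ratio.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    j = len(instruments)
    if j < 1:
        raise InsufficientInstrumentsError("IVW requires at least 1 instrument")
    bx, by, sy = instruments.beta_x, instruments.beta_y, instruments.se_y
    if j == 1:
        # degenerate case: identically the Wald ratio
        est = wald_ratio(float(bx[0]), float(instruments.se_x[0]), float(by[0]), float(sy[0]))
        method = "ivw_mre" if effects_model == "multiplicative_random" else "ivw_fe"
        return dataclasses.replace(est, method=method)
    theta, se, q = _ivw_core(bx, by, sy)
    method = "ivw_fe"
    if effects_model == "multiplicative_random" and j >= 2:
        se *= max(1.0, math.sqrt(q / (j - 1)))
        method = "ivw_mre"
    elif effects_model == "multiplicative_random":
        method = "ivw_mre"  # single instrument: scale undefined, floors at 1
    return MREstimate(method, theta, se, _two_sided_p(theta / se), j)


def mr_egger(instruments: HarmonizedInstrumentSet, use_t: bool = False) -> MREstimate:
    """Weighted regression of outcome on exposure effects with a free
    intercept; the slope is the causal estimate and the intercept estimates
    average directional pleiotropy.

    Instruments are first oriented so every exposure effect is positive (the
    estimator's standard convention, which also makes the result invariant to
    allele re-coding).  Both SEs are inflated by ``max(1, sqrt(Q_e/(J-2)))``.
    """
    j = len(instruments)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    sign = np.where(instruments.beta_x < 0, -1.0, 1.0)
    bx = instruments.beta_x * sign
    by = instruments.beta_y * sign
    sy = instruments.se_y
    if np.ptp(bx) == 0:
        raise np.linalg.LinAlgError("all exposure effects equal: Egger slope unidentifiable")
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    cov = np.linalg.inv(xtwx) * max(1.0, q / (j - 2))
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    if use_t:
        pfun = lambda z: float(min(1.0, 2.0 * stats.t.sf(abs(z), j - 2)))
    else:
        pfun = _two_sided_p
    return MREstimate(
        "egger",
        slope,
        se_slope,
        pfun(slope / se_slope),
        j,
        intercept=inter,
        intercept_se=se_inter,
        intercept_p=pfun(inter / se_inter),
    )


def cochran_q(instruments: HarmonizedInstrumentSet, theta_hat: float, df_loss: int = 1) -> HeterogeneityResult:
    """Cochran's Q = sum (beta_y - theta*beta_x)^2 / se_y^2 against
    chi-square with J - df_loss degrees of freedom (df_loss=2 after Egger)."""
    j = len(instruments)
    if j < 2:
        raise InsufficientInstrumentsError("Q requires at least 2 instruments")
    q = float(np.sum((instruments.beta_y - theta_hat * instruments.beta_x) ** 2 / instruments.se_y**2))
    df = j - df_loss
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def steiger_test(
    instruments: HarmonizedInstrumentSet, n_exposure: int, n_outcome: int
) -> SteigerResult:
    """Directionality check: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-variant r^2 comes from the t-statistic, ``r2 = t^2/(t^2 + n - 2)``,
    summed per trait; the aggregate correlations (square roots of the sums)
    are Fisher-transformed and compared by a z-test.
    """
    if min(n_exposure, n_outcome) <= 3:
        raise ValueError("sample sizes must exceed 3")

    def _r2(beta, se, n):
        t2 = (beta / se) ** 2
        return float(np.sum(t2 / (t2 + n - 2)))

    r2x = _r2(instruments.beta_x, instruments.se_x, n_exposure)
    r2y = _r2(instruments.beta_y, instruments.se_y, n_outcome)
    rx = math.sqrt(min(r2x, 1.0 - 1e-12))
    ry = math.sqrt(min(r2y, 1.0 - 1e-12))
    z = (np.arctanh(rx) - np.arctanh(ry)) / math.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3)
    )
    return SteigerResult(r2x, r2y, r2x > r2y, _two_sided_p(float(z)))


def leave_one_out(instruments: HarmonizedInstrumentSet) -> pd.DataFrame:
    """IVW estimate dropping each instrument in turn (influence utility)."""
    rows = []
    for i, vid in enumerate(instruments.variant_ids):
        mask = np.ones(len(instruments), bool)
        mask[i] = False
        sub = HarmonizedInstrumentSet(
            instruments.exposure_id,
            instruments.outcome_id,
            instruments.table.iloc[mask].reset_index(drop=True),
            instruments.exclusions,
        )
        est = ivw(sub)
        rows.append(dict(dropped=vid, theta_hat=est.theta_hat, se=est.se, pvalue=est.pvalue))
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ScreenConfig:
    iv_p_threshold: float = 1e-5
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000
    palindrome_maf: float = 0.3
    f_min: float = 10.0
    fdr_alpha: float = 0.2
    potential_alpha: float = 0.05
    excluded_variants: tuple = ()


def run_univariable_screen(
    exposures: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    config: ScreenConfig | None = None,
    ld: LDMatrix | None = None,
) -> list[ScreenResultRow]:
    """Run the full univariable battery for each exposure against one outcome.

    Per exposure: instrument selection → (optional) LD clumping → manual
    exclusions → harmonization/F filter → Wald ratio (1 IV) or IVW-MRE (≥2),
    with Q, Egger and Steiger attached where defined.  Raw p-values are
    BH-adjusted across exposures and each row is tiered: ``significant_fdr``
    (adjusted p < fdr_alpha), ``potential`` (raw p < potential_alpha), else
    ``null``.  Per-exposure failures are recorded in the row, never raised.
    """
    config = config or ScreenConfig()
    rows: list[ScreenResultRow] = []
    for exposure in exposures:
        row = ScreenResultRow(exposure.trait_id, outcome.trait_id, None)
        try:
            ds = select_instruments(exposure, config.iv_p_threshold)
            if ld is not None and len(ds) > 1:
                ds = ld_clump(ds, ld, config.clump_r2, config.clump_window_kb)
            if config.excluded_variants:
                ds = apply_exclusion_list(ds, config.excluded_variants, "secondary_trait")
            hs = harmonize(ds, outcome, config.palindrome_maf, config.f_min)
            j = len(hs)
            if j == 0:
                raise InsufficientInstrumentsError("no instruments survived filtering")
            if j == 1:
                r = hs.table.iloc[0]
                row.estimate = wald_ratio(r["beta_x"], r["se_x"], r["beta_y"], r["se_y"])
            else:
                row.estimate = ivw(hs, "multiplicative_random")
                row.heterogeneity = cochran_q(hs, row.estimate.theta_hat)
            if j >= 3:
                try:
                    row.egger = mr_egger(hs)
                except np.linalg.LinAlgError:
                    pass
            n_exp = int(exposure.table["n"].iloc[0])
            n_out = int(outcome.table["n"].iloc[0])
            row.steiger = steiger_test(hs, n_exp, n_out)
        except (InsufficientInstrumentsError, ZeroDivisionError, KeyError, ValueError) as exc:
            row.error = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    ok = [r for r in rows if r.estimate is not None]
    if ok:
        adj = bh_fdr([r.raw_p for r in ok])
        for r, a in zip(ok, adj):
            r.fdr_adjusted_p = float(a)
            if a < config.fdr_alpha:
                r.tier = "significant_fdr"
            elif r.raw_p < config.potential_alpha:
                r.tier = "potential"
            else:
                r.tier = "null"
    return rows


def screen_to_frame(rows: Sequence[ScreenResultRow]) -> pd.DataFrame:
    """Forest-plot-ready table (one row per exposure–outcome pair)."""
    out = []
    for r in rows:
        e = r.estimate
        out.append(
            dict(
                exposure=r.exposure_id,
                outcome=r.outcome_id,
                method=e.method if e else None,
                nsnp=e.n_snps if e else 0,
                beta=e.theta_hat if e else np.nan,
                se=e.se if e else np.nan,
                OR=e.or_point if e else np.nan,
                or_low=e.or_low if e else np.nan,
                or_high=e.or_high if e else np.nan,
                pval=e.pvalue if e else np.nan,
                p_adjust=r.fdr_adjusted_p,
                significance=r.tier,
                q=r.heterogeneity.q if r.heterogeneity else np.nan,
                q_pval=r.heterogeneity.q_pvalue if r.heterogeneity else np.nan,
                egger_intercept_p=r.egger.intercept_p if r.egger else np.nan,
                steiger_forward=r.steiger.direction_forward if r.steiger else None,
                error=r.error,
            )
        )
    return pd.DataFrame(out)
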