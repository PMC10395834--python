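"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier test.

Three stages over a harmonized instrument set:

* **global test** — the observed residual sum of squares (RSS), built from
  leave-one-out IVW predictions so no instrument predicts itself, is compared
  with RSS values recomputed on parametric draws of the summary statistics;
* **outlier test** — each instrument's observed squared standardized residual
  is compared with its own simulated distribution, Bonferroni-corrected;
* **distortion test** — the shift between the raw and the outlier-removed IVW
  estimate is compared with shifts from removing random same-size subsets.

Empirical p-values use the plus-one correction, so they are never exactly 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .gwas_io import HarmonizedInstrumentSet
from .univariable import InsufficientInstrumentsError, MREstimate, ivw

__all__ = ["PressoResult", "presso_global", "presso_outlier", "presso_distortion", "run_presso"]


@dataclasses.dataclass
class PressoResult:
    rss_observed: float
    global_p: float
    per_variant_p: np.ndarray | None = None
    outlier_ids: list = dataclasses.field(default_factory=list)
    theta_raw: MREstimate | None = None
    theta_corrected: MREstimate | None = None
    distortion_p: float | None = None
    n_simulations: int = 0
    seed: int = 0
    note: str | None = None


def _loo_residuals(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Standardized residuals of each instrument against the IVW fit that
    excludes it.  Works on 1-D arrays or (n_sims, J) matrices."""
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    theta_loo = (sxy - w * bx * by) / (sxx - w * bx**2)
    return (by - theta_loo * bx) / sy, theta_loo


def presso_global(
    instruments: HarmonizedInstrumentSet, n_simulations: int = 1000, seed: int = 0
) -> PressoResult:
    """Global pleiotropy test; returns RSS, its empirical p, and the
    per-variant simulated residual comparison used by the outlier stage."""
    j = len(instruments)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 instruments")
    bx, sx = instruments.beta_x, instruments.se_x
    by, sy = instruments.beta_y, instruments.se_y

    resid_obs, theta_loo = _loo_residuals(bx, by, sy)
    rss_obs = float(np.sum(resid_obs**2))

    rng = np.random.default_rng(seed)
    pred = (theta_loo * bx).ravel()
    bx_sim = rng.normal(bx, sx, size=(n_simulations, j))
    by_sim = rng.normal(pred, sy, size=(n_simulations, j))
    resid_sim, _ = _loo_residuals(bx_sim, by_sim, sy)
    rss_sim = np.sum(resid_sim**2, axis=1)

    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (1.0 + n_simulations)
    per_variant_p = (1.0 + np.sum(resid_sim**2 >= resid_obs.ravel() ** 2, axis=0)) / (
        1.0 + n_simulations
    )
    return PressoResult(
        rss_observed=rss_obs,
        global_p=float(global_p),
        per_variant_p=per_variant_p,
        n_simulations=n_simulations,
        seed=seed,
    )


def presso_outlier(
    instruments: HarmonizedInstrumentSet,
    n_simulations: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Flag instruments whose Bonferroni-adjusted per-variant empirical p is
    below ``outlier_alpha``."""
    result = presso_global(instruments, n_simulations, seed)
    j = len(instruments)
    adj = np.minimum(result.per_variant_p * j, 1.0)
    flagged = np.flatnonzero(adj < outlier_alpha)
    result.outlier_ids = [instruments.variant_ids[i] for i in flagged]
    return result


def _subset(instruments: HarmonizedInstrumentSet, keep: np.ndarray) -> HarmonizedInstrumentSet:
    return HarmonizedInstrumentSet(
        instruments.exposure_id,
        instruments.outcome_id,
        instruments.table.iloc[keep].reset_index(drop=True),
        instruments.exclusions,
    )


def presso_distortion(
    instruments: HarmonizedInstrumentSet,
    outlier_ids: list,
    n_simulations: int = 1000,
    seed: int = 0,
) -> PressoResult:
    """Compare the raw-vs-corrected estimate shift with shifts obtained by
    removing random subsets of the same size (two-sided empirical p)."""
    j = len(instruments)
    theta_raw = ivw(instruments)
    if not outlier_ids:
        return PressoResult(
            rss_observed=float("nan"),
            global_p=float("nan"),
            theta_raw=theta_raw,
            theta_corrected=theta_raw,
            note="no outliers flagged; distortion test skipped",
            n_simulations=n_simulations,
            seed=seed,
        )
    outlier_idx = [instruments.variant_ids.index(v) for v in outlier_ids]
    keep = np.setdiff1d(np.arange(j), outlier_idx)
    if keep.size < 2:
        raise InsufficientInstrumentsError("too few instruments left after outlier removal")
    theta_corr = ivw(_subset(instruments, keep))
    d_obs = theta_raw.theta_hat - theta_corr.theta_hat

    rng = np.random.default_rng(seed)
    d_null = np.empty(n_simulations)
    for b in range(n_simulations):
        drop = rng.choice(j, size=len(outlier_idx), replace=False)
        d_null[b] = theta_raw.theta_hat - ivw(_subset(instruments, np.setdiff1d(np.arange(j), drop))).theta_hat
    p = (1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1.0 + n_simulations)
    return PressoResult(
        rss_observed=float("nan"),
        global_p=float("nan"),
        outlier_ids=list(outlier_ids),
        theta_raw=theta_raw,
        theta_corrected=theta_corr,
        distortion_p=float(p),
        n_simulations=n_simulations,
        seed=seed,
    )


def run_presso(
    instruments: HarmonizedInstrumentSet,
    n_simulations: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Full global → outlier → distortion sequence."""
    result = presso_outlier(instruments, n_simulations, seed, outlier_alpha)
    dist = presso_distortion(instruments, result.outlier_ids, n_simulations, seed + 1)
    result.theta_raw = dist.theta_raw
    result.theta_corrected = dist.theta_corrected
    result.distortion_p = dist.distortion_p
    result.note = dist.note
    return result
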