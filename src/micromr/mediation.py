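"""Two-step MR mediation: diet → gut microbe → disease pathways.

The total effect ``b1`` (exposure→outcome), the exposure→mediator effect
``b2`` and the mediator→outcome effect ``b3`` are each estimated by
univariable two-sample MR with trait-appropriate instrument thresholds
(genome-wide 5e-8 for dietary exposures, relaxed 1e-5 for microbial traits).
The indirect effect is the coefficient product ``b = b2*b3`` with the
delta-method standard error ``sqrt(b2^2 se3^2 + b3^2 se2^2)``; the mediated
proportion is ``100*b/b1`` and is deliberately not clipped (it can exceed
100% or go negative when direct and indirect paths oppose).

The reported mediation probability is the one-sided upper-tail normal
probability P(indirect <= 0), i.e. small when the indirect effect is reliably
positive; a two-sided option is available.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryDataset, harmonize, select_instruments
from .univariable import InsufficientInstrumentsError, MREstimate, ivw, wald_ratio

__all__ = [
    "MediationResult",
    "indirect_effect",
    "mediated_proportion",
    "direction_consistency",
    "run_two_step",
    "round_half_away",
]


@dataclasses.dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    b1: float  # total effect
    b2: float  # exposure -> mediator
    b3: float  # mediator -> outcome
    b: float  # indirect effect b2*b3
    se_b: float
    p: float
    proportion: float  # percent, unclipped
    direction_consistent: bool
    estimates: dict = dataclasses.field(default_factory=dict)

    @property
    def pathway(self) -> str:
        return f"{self.exposure_id}-{self.mediator_id}-{self.outcome_id}"


def indirect_effect(
    b2: float, se2: float, b3: float, se3: float, two_sided: bool = False
) -> tuple[float, float, float]:
    """Coefficient-product indirect effect with delta-method SE.

    Returns (b, se_b, p) where b = b2*b3 and
    se_b = sqrt(b2^2*se3^2 + b3^2*se2^2).
    """
    if min(se2, se3) <= 0:
        raise ValueError("standard errors must be > 0")
    b = b2 * b3
    se_b = math.sqrt(b2**2 * se3**2 + b3**2 * se2**2)
    if se_b == 0:
        p = 0.5 if b == 0 else (0.0 if b > 0 else 1.0)
    else:
        z = b / se_b
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if two_sided else float(stats.norm.cdf(-z))
    return b, se_b, p


def mediated_proportion(b: float, b1: float) -> float:
    """Percent of the total effect transmitted through the mediator,
    100*b/b1; sign-preserving and unclipped."""
    if b1 == 0:
        raise ZeroDivisionError("mediated proportion undefined for b1 = 0")
    return 100.0 * b / b1


def direction_consistency(results: list[MediationResult]) -> tuple[list[MediationResult], int]:
    """Flag pathways whose indirect effect shares the total effect's sign;
    returns (consistent subset, count)."""
    for r in results:
        r.direction_consistent = math.copysign(1.0, r.b) == math.copysign(1.0, r.b1) and r.b != 0
    consistent = [r for r in results if r.direction_consistent]
    return consistent, len(consistent)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for reported tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclasses.dataclass
class TwoStepConfig:
    diet_p_threshold: float = 5e-8
    microbe_p_threshold: float = 1e-5
    palindrome_maf: float = 0.3
    f_min: float = 10.0
    two_sided: bool = False


def _estimate_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    p_threshold: float,
    config: TwoStepConfig,
) -> MREstimate:
    ds = select_instruments(exposure, p_threshold)
    hs = harmonize(ds, outcome, config.palindrome_maf, config.f_min)
    if len(hs) == 0:
        raise InsufficientInstrumentsError(
            f"no instruments for {exposure.trait_id} -> {outcome.trait_id}"
        )
    if len(hs) == 1:
        r = hs.table.iloc[0]
        return wald_ratio(r["beta_x"], r["se_x"], r["beta_y"], r["se_y"])
    return ivw(hs, "multiplicative_random")


def run_two_step(
    exposure: SummaryDataset,
    mediator: SummaryDataset,
    outcome: SummaryDataset,
    config: TwoStepConfig | None = None,
) -> MediationResult:
    """Estimate b1, b2, b3 by univariable MR and assemble the decomposition."""
    config = config or TwoStepConfig()
    est_b1 = _estimate_pair(exposure, outcome, config.diet_p_threshold, config)
    est_b2 = _estimate_pair(exposure, mediator, config.diet_p_threshold, config)
    # the mediator->outcome step must not reuse the exposure's instruments:
    # any direct exposure->outcome effect they carry would leak into b3
    exposure_ivs = set(
        select_instruments(exposure, config.diet_p_threshold).table["variant_id"]
    )
    mediator_own = mediator.with_table(
        mediator.table[~mediator.table["variant_id"].isin(exposure_ivs)]
    )
    est_b3 = _estimate_pair(mediator_own, outcome, config.microbe_p_threshold, config)
    b, se_b, p = indirect_effect(
        est_b2.theta_hat, est_b2.se, est_b3.theta_hat, est_b3.se, config.two_sided
    )
    b1 = est_b1.theta_hat
    proportion = mediated_proportion(b, b1) if b1 != 0 else float("nan")
    return MediationResult(
        exposure_id=exposure.trait_id,
        mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
        b1=b1,
        b2=est_b2.theta_hat,
        b3=est_b3.theta_hat,
        b=b,
        se_b=se_b,
        p=p,
        proportion=proportion,
        direction_consistent=math.copysign(1.0, b) == math.copysign(1.0, b1) and b != 0,
        estimates=dict(total=est_b1, exposure_mediator=est_b2, mediator_outcome=est_b3),
    )


def results_to_frame(results: list[MediationResult], ndigits: int = 2) -> pd.DataFrame:
    """Report table with display rounding (internal values stay unrounded)."""
    rows = []
    for r in results:
        rows.append(
            dict(
                pathway=r.pathway,
                b1=round_half_away(r.b1, ndigits),
                b2=round_half_away(r.b2, ndigits),
                b3=round_half_away(r.b3, ndigits),
                b=round_half_away(r.b, ndigits),
                se_b=round_half_away(r.se_b, ndigits),
                p=round_half_away(r.p, ndigits),
                proportion=round_half_away(r.proportion, ndigits),
                consistent=r.direction_consistent,
            )
        )
    return pd.DataFrame(rows)
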