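"""Approximate-Bayes-factor colocalization of two association profiles.

For each variant the Wakefield approximate Bayes factor summarizes the
evidence for a nonzero effect; per-hypothesis evidence is accumulated over the
single-causal-variant configurations:

* H0 — no association with either trait;
* H1 / H2 — association with one trait only;
* H3 — both traits associated, distinct causal variants;
* H4 — both traits associated, one shared causal variant.

A posterior PP.H4 above the decision threshold (default 0.8) indicates that
the instrument region drives both traits through the same variant — which for
MR is an exclusion-restriction warning, flagged as ``mr_assumption_violated``.

All accumulation is in log space (log-sum-exp), so long profiles with large z
scores do not overflow.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["ColocResult", "approx_bayes_factor", "log_abf", "colocalize"]


@dataclasses.dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    log_abf1: np.ndarray
    log_abf2: np.ndarray
    priors: tuple
    mr_assumption_violated: bool

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def log_abf(beta, se, prior_effect_sd: float = 0.15) -> np.ndarray:
    """Log Wakefield approximate Bayes factor for one association.

    With z = beta/se, V = se^2, W = prior_effect_sd^2 and shrinkage
    r = W/(V+W):  log ABF = 0.5*[log(1-r) + r*z^2].
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    v = se**2
    w = prior_effect_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def approx_bayes_factor(beta: float, se: float, prior_effect_sd: float = 0.15) -> float:
    """Wakefield ABF on the natural scale (convenience wrapper)."""
    return float(np.exp(log_abf(beta, se, prior_effect_sd)))


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def colocalize(
    profile1: pd.DataFrame,
    profile2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    pp_h4_threshold: float = 0.8,
) -> ColocResult:
    """Colocalize two traits' (variant_id, beta, se) profiles over one locus.

    Priors are per-variant probabilities: ``p1``/``p2`` of being causal for
    one trait only, ``p12`` of being the shared causal variant.
    """
    if len(profile1) < 2:
        raise ValueError("colocalization requires at least 2 variants")
    if list(profile1["variant_id"]) != list(profile2["variant_id"]):
        raise ValueError("profiles must share an identical, aligned variant list")

    l1 = log_abf(profile1["beta"].to_numpy(), profile1["se"].to_numpy(), prior_sd1)
    l2 = log_abf(profile2["beta"].to_numpy(), profile2["se"].to_numpy(), prior_sd2)

    s1 = float(logsumexp(l1))  # sum over variants: trait-1 causal somewhere
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))  # shared variant configurations
    # distinct-variant configurations: all ordered pairs minus the diagonal
    s3 = _log_diff_exp(s1 + s2, s12)

    log_weights = np.array(
        [
            0.0,  # H0
            math.log(p1) + s1,
            math.log(p2) + s2,
            math.log(p1) + math.log(p2) + s3,
            math.log(p12) + s12,
        ]
    )
    post = np.exp(log_weights - logsumexp(log_weights))
    post /= post.sum()
    return ColocResult(
        *(float(x) for x in post),
        log_abf1=l1,
        log_abf2=l2,
        priors=(p1, p2, p12),
        mr_assumption_violated=bool(post[4] > pp_h4_threshold),
    )
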