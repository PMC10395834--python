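"""Synthetic GWAS summary statistics with known causal ground truth.

Each generator emulates the two-sample summary-data setting: latent per-variant
effects are drawn, then observed betas are the latent values plus sampling
noise whose SE follows the standard GWAS calibration
``se = 1 / sqrt(2 * n * eaf * (1 - eaf))`` for a standardized trait (the same
form approximates the log-odds scale for binary traits).  Sample-size defaults
mirror the real setting the pipeline targets: a microbiome GWAS of a few
thousand participants as the exposure and a biobank disease GWAS of a couple
hundred thousand as the outcome.

All randomness flows from one root seed through named child streams
(``numpy.random.SeedSequence``), so the same spec reproduces byte-identical
outputs and each stage can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_io import LDMatrix, SummaryDataset

__all__ = [
    "UnivariableSimSpec",
    "MultivariableSimSpec",
    "MediationSimSpec",
    "ColocSimSpec",
    "simulate_univariable",
    "simulate_multivariable",
    "simulate_mediation",
    "simulate_coloc_region",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent child generator for a named stream under one root seed."""
    digest = int.from_bytes(stream.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(digest,)))


def _se_from_n(n: float, eaf: np.ndarray, case_fraction: float | None = None) -> np.ndarray:
    """Per-variant GWAS standard error.

    Standardized continuous trait: ``1/sqrt(2*n*eaf*(1-eaf))``.  Binary trait
    on the log-odds scale: the same divided by ``sqrt(cf*(1-cf))`` — at a few
    percent case fraction the phenotypic variance is far below 1 and the
    constant-variance form would overstate precision several-fold.
    """
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    if case_fraction is not None:
        if not 0 < case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        se = se / np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _normal_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)


def _draw_alleles(rng: np.random.Generator, j: int, palindromic_fraction: float):
    """Effect/other allele pairs; a configurable fraction strand-ambiguous."""
    pal = rng.random(j) < palindromic_fraction
    ea = rng.choice(_BASES, size=j)
    oa = np.empty(j, dtype=ea.dtype)
    for i in range(j):
        if pal[i]:
            oa[i] = _COMPLEMENT[ea[i]]
        else:
            choices = [b for b in "ACGT" if b != ea[i] and b != _COMPLEMENT[ea[i]]]
            oa[i] = rng.choice(choices)
    return ea, oa


def _dataset(
    trait_id: str,
    trait_type: str,
    vids: Sequence[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> SummaryDataset:
    table = pd.DataFrame(
        dict(
            variant_id=list(vids),
            chrom=chrom,
            pos=pos,
            effect_allele=ea,
            other_allele=oa,
            eaf=eaf,
            beta=beta,
            se=se,
            pval=_normal_p(beta / se),
            n=n,
        )
    )
    return SummaryDataset(trait_id, trait_type, table)


@dataclasses.dataclass
class UnivariableSimSpec:
    """One exposure→outcome pair with optional pleiotropy and outliers.

    Defaults give a well-powered microbial-trait scenario: 50 instruments with
    SNP-exposure effects of SD 0.3 on the standardized trait (instrument F
    statistics running into the hundreds at n_exposure = 7,738, the strength
    reported for lead microbial-QTL variants), a causal effect of 0.2 on the
    outcome log-odds, and a biobank-scale outcome GWAS.
    """

    n_variants: int = 50
    theta: float = 0.2
    gamma_sd: float = 0.3
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violation
    pleiotropy_sd: float = 0.05
    pleiotropy_mean: float = 0.05  # directional mode only
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    outlier_sign: str = "random"  # random | up: one-signed outliers bias the fit
    n_exposure: int = 7_738
    n_outcome: int = 220_000
    outcome_case_fraction: float | None = 0.03  # None => continuous outcome
    palindromic_fraction: float = 0.2
    allele_flip_fraction: float = 0.3  # outcome rows re-coded to exercise harmonization
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violation"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if min(self.gamma_sd, self.pleiotropy_sd) < 0:
            raise ValueError("SDs must be >= 0")


def simulate_univariable(spec: UnivariableSimSpec):
    """Generate (exposure, outcome, LDMatrix, truth) for one pair.

    True SNP-exposure effects ``gamma ~ N(0, gamma_sd^2)``; direct (pleiotropic)
    outcome effects ``alpha`` per mode; true SNP-outcome effects
    ``Gamma = theta * gamma + alpha``.  A fraction of variants are planted as
    outliers whose direct effect is ``outlier_scale`` outcome-SEs in a random
    direction.  The LD matrix is identity (instruments are pre-clumped); the
    outcome table re-codes a fraction of variants (swapped alleles, negated
    beta, complemented EAF) so harmonization is exercised end to end.
    """
    j = spec.n_variants
    rng = _rng(spec.seed, "univariable")
    eaf = rng.uniform(0.05, 0.95, j)
    gamma = rng.normal(0.0, spec.gamma_sd, j)
    if spec.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    elif spec.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, spec.pleiotropy_sd, j)
    elif spec.pleiotropy_mode == "directional":
        # directional relative to the exposure-increasing allele: re-coding a
        # variant flips gamma and alpha together, so the mean survives the
        # positive-orientation convention of the Egger fit.  Drawn uniform on
        # (0, 2*mean), the usual simulation design for one-signed pleiotropy.
        alpha = np.sign(gamma) * rng.uniform(0.0, 2.0 * spec.pleiotropy_mean, j)
    else:  # inside_violation: direct effects correlated with instrument strength
        alpha = 0.5 * spec.pleiotropy_sd / max(spec.gamma_sd, 1e-12) * gamma + rng.normal(
            0.0, 0.5 * spec.pleiotropy_sd, j
        )

    se_x = _se_from_n(spec.n_exposure, eaf)
    se_y = _se_from_n(spec.n_outcome, eaf, spec.outcome_case_fraction)

    n_outliers = int(round(spec.outlier_fraction * j))
    outlier_idx = rng.choice(j, size=n_outliers, replace=False) if n_outliers else np.array([], int)
    if spec.outlier_sign == "up":
        # one-signed on the causal-ratio scale: displace relative to the
        # exposure-increasing allele so every outlier biases the fit upward
        signs = np.sign(gamma[outlier_idx])
    else:
        signs = rng.choice([-1.0, 1.0], size=n_outliers)
    alpha = alpha.copy()
    # outliers are planted at outlier_scale residual-SDs of the instrument's
    # Wald deviation (outcome noise plus exposure noise scaled by theta), so
    # "scale 5" means a genuine 5-sigma pleiotropic displacement
    resid_sd = np.sqrt(se_y**2 + spec.theta**2 * se_x**2)
    alpha[outlier_idx] += signs * spec.outlier_scale * resid_sd[outlier_idx]

    big_gamma = spec.theta * gamma + alpha
    beta_x = gamma + rng.normal(0.0, se_x)
    beta_y_true_coded = big_gamma + rng.normal(0.0, se_y)

    vids = [f"rs{1000 + i}" for i in range(j)]
    chrom = np.array([str(1 + i % 22) for i in range(j)])
    pos = np.array([1_000_000 + 2_000_000 * (i // 22) for i in range(j)])
    ea, oa = _draw_alleles(rng, j, spec.palindromic_fraction)

    exposure = _dataset(
        "exposure", "exposure", vids, chrom, pos, ea, oa, eaf, beta_x, se_x, spec.n_exposure
    )

    # outcome table: same variants, a fraction re-coded to the other allele
    flip = rng.random(j) < spec.allele_flip_fraction
    ea_y = np.where(flip, oa, ea)
    oa_y = np.where(flip, ea, oa)
    eaf_y = np.where(flip, 1 - eaf, eaf)
    beta_y = np.where(flip, -beta_y_true_coded, beta_y_true_coded)
    outcome = _dataset(
        "outcome", "outcome", vids, chrom, pos, ea_y, oa_y, eaf_y, beta_y, se_y, spec.n_outcome
    )

    positions = pd.DataFrame(dict(variant_id=vids, chrom=chrom, pos=pos))
    ld = LDMatrix.identity(vids, positions)
    truth = dict(
        theta=spec.theta,
        gamma=gamma,
        alpha=alpha,
        big_gamma=big_gamma,
        outlier_ids=[vids[i] for i in outlier_idx],
        flipped_ids=[vids[i] for i in np.flatnonzero(flip)],
    )
    return exposure, outcome, ld, truth


@dataclasses.dataclass
class MultivariableSimSpec:
    """Panel of correlated exposures with a known causal subset."""

    n_variants: int = 100
    n_exposures: int = 3
    causal_subset: dict = dataclasses.field(default_factory=lambda: {0: 0.25})
    exposure_correlation: np.ndarray | None = None  # default identity
    gamma_sd: float = 0.3
    n_exposure: int = 7_738
    n_outcome: int = 220_000
    outcome_case_fraction: float | None = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_exposures
        if self.exposure_correlation is None:
            self.exposure_correlation = np.eye(k)
        self.exposure_correlation = np.asarray(self.exposure_correlation, float)
        if self.exposure_correlation.shape != (k, k):
            raise ValueError("exposure_correlation must be K x K")
        if not np.allclose(self.exposure_correlation, self.exposure_correlation.T):
            raise ValueError("exposure_correlation must be symmetric")
        if np.min(np.linalg.eigvalsh(self.exposure_correlation)) < -1e-8:
            raise ValueError("exposure_correlation must be positive semidefinite")
        if any(not 0 <= c < k for c in self.causal_subset):
            raise ValueError("causal_subset indices out of range")


def simulate_multivariable(spec: MultivariableSimSpec):
    """Generate (list of exposure datasets, outcome dataset, truth).

    Per-variant SNP-exposure effect vectors are drawn multivariate normal with
    the requested cross-exposure correlation; true outcome effects are the
    linear combination over the causal subset.
    """
    j, k = spec.n_variants, spec.n_exposures
    rng = _rng(spec.seed, "multivariable")
    eaf = rng.uniform(0.05, 0.95, j)
    # allow correlation exactly 1 (duplicated exposures) via eigendecomposition
    w, v = np.linalg.eigh(spec.exposure_correlation)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    gamma = rng.normal(0.0, 1.0, (j, k)) @ root.T * spec.gamma_sd

    theta = np.zeros(k)
    for idx, effect in spec.causal_subset.items():
        theta[idx] = effect
    big_gamma = gamma @ theta

    se_x = _se_from_n(spec.n_exposure, eaf)
    se_y = _se_from_n(spec.n_outcome, eaf, spec.outcome_case_fraction)
    beta_x = gamma + rng.normal(0.0, se_x[:, None], (j, k))
    beta_y = big_gamma + rng.normal(0.0, se_y)

    vids = [f"rs{1000 + i}" for i in range(j)]
    chrom = np.array([str(1 + i % 22) for i in range(j)])
    pos = np.array([1_000_000 + 2_000_000 * (i // 22) for i in range(j)])
    ea, oa = _draw_alleles(rng, j, 0.0)

    exposures = [
        _dataset(
            f"exposure_{m}", "exposure", vids, chrom, pos, ea, oa, eaf,
            beta_x[:, m], se_x, spec.n_exposure,
        )
        for m in range(k)
    ]
    outcome = _dataset(
        "outcome", "outcome", vids, chrom, pos, ea, oa, eaf, beta_y, se_y, spec.n_outcome
    )
    truth = dict(theta=theta, causal_subset=dict(spec.causal_subset), gamma=gamma)
    return exposures, outcome, truth


@dataclasses.dataclass
class MediationSimSpec:
    """Exposure→mediator→outcome triad with a known effect decomposition.

    The implied total effect is ``b1 = true_direct + true_b2 * true_b3``.
    Defaults model a dietary exposure (biobank-scale GWAS, strong instruments)
    acting partly through a microbial mediator.
    """

    true_b2: float = 0.5  # exposure -> mediator
    true_b3: float = 0.4  # mediator -> outcome
    true_direct: float = 0.2  # exposure -> outcome, not via mediator
    n_exposure_instruments: int = 100  # dietary traits: biobank GWAS, many loci
    n_mediator_instruments: int = 30  # microbial traits: small GWAS, few loci
    exposure_gamma_sd: float = 0.1
    mediator_gamma_sd: float = 0.3  # microbial trait: same lead-mbQTL strength as UnivariableSimSpec
    n_exposure: int = 350_000
    n_mediator: int = 7_738
    n_outcome: int = 220_000
    outcome_case_fraction: float | None = 0.03
    seed: int = 0

    @property
    def true_b1(self) -> float:
        return self.true_direct + self.true_b2 * self.true_b3


def simulate_mediation(spec: MediationSimSpec):
    """Generate summary datasets for all three traits over the union of the
    exposure's and the mediator's instruments, plus the truth record.

    Exposure instruments affect the mediator through b2 and the outcome through
    ``b1 = direct + b2*b3``; mediator instruments affect the outcome through b3
    and the exposure not at all — so each pairwise analysis recovers its
    coefficient when instruments are selected per trait.
    """
    rng = _rng(spec.seed, "mediation")
    je, jm = spec.n_exposure_instruments, spec.n_mediator_instruments
    j = je + jm
    eaf = rng.uniform(0.05, 0.95, j)

    gamma_e = np.zeros(j)
    gamma_e[:je] = rng.normal(0.0, spec.exposure_gamma_sd, je)
    delta_m = np.zeros(j)
    delta_m[je:] = rng.normal(0.0, spec.mediator_gamma_sd, jm)

    true_exposure = gamma_e
    true_mediator = spec.true_b2 * gamma_e + delta_m
    true_outcome = spec.true_direct * gamma_e + spec.true_b3 * true_mediator

    se_e = _se_from_n(spec.n_exposure, eaf)
    se_m = _se_from_n(spec.n_mediator, eaf)
    se_o = _se_from_n(spec.n_outcome, eaf, spec.outcome_case_fraction)

    beta_e = true_exposure + rng.normal(0.0, se_e)
    beta_m = true_mediator + rng.normal(0.0, se_m)
    beta_o = true_outcome + rng.normal(0.0, se_o)

    vids = [f"rs{1000 + i}" for i in range(j)]
    chrom = np.array([str(1 + i % 22) for i in range(j)])
    pos = np.array([1_000_000 + 2_000_000 * (i // 22) for i in range(j)])
    ea, oa = _draw_alleles(rng, j, 0.0)

    exposure = _dataset("diet", "exposure", vids, chrom, pos, ea, oa, eaf, beta_e, se_e, spec.n_exposure)
    mediator = _dataset("microbe", "mediator", vids, chrom, pos, ea, oa, eaf, beta_m, se_m, spec.n_mediator)
    outcome = _dataset("disease", "outcome", vids, chrom, pos, ea, oa, eaf, beta_o, se_o, spec.n_outcome)
    truth = dict(
        b1=spec.true_b1,
        b2=spec.true_b2,
        b3=spec.true_b3,
        direct=spec.true_direct,
        indirect=spec.true_b2 * spec.true_b3,
        exposure_instrument_ids=vids[:je],
        mediator_instrument_ids=vids[je:],
    )
    return exposure, mediator, outcome, truth


@dataclasses.dataclass
class ColocSimSpec:
    """Two association profiles over one locus under a named sharing scenario."""

    n_variants: int = 200
    scenario: str = "shared_causal"  # shared_causal | distinct_causal | one_trait_only | no_signal
    effect_z: float = 8.0  # causal-variant effect in SE units
    n_trait1: int = 7_738
    n_trait2: int = 220_000
    trait2_case_fraction: float | None = 0.03
    ld_decay: float = 0.9  # AR(1) correlation between adjacent variants
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("shared_causal", "distinct_causal", "one_trait_only", "no_signal"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must be in [0, 1)")


def simulate_coloc_region(spec: ColocSimSpec):
    """Generate two per-variant (beta, se) profiles over shared variants.

    LD follows an AR(1) structure ``r_ij = ld_decay^|i-j|``; marginal effects
    are the LD-smeared causal effects; observed betas add correlated sampling
    noise with covariance ``se_i * r_ij * se_j``.  For ``distinct_causal`` the
    two causal variants are placed at the locus ends (low mutual LD).
    """
    j = spec.n_variants
    rng = _rng(spec.seed, "coloc")
    idx = np.arange(j)
    r = spec.ld_decay ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(j))

    eaf = rng.uniform(0.1, 0.9, j)
    se1 = _se_from_n(spec.n_trait1, eaf)
    se2 = _se_from_n(spec.n_trait2, eaf, spec.trait2_case_fraction)

    causal1 = np.zeros(j)
    causal2 = np.zeros(j)
    mid, lo, hi = j // 2, j // 10, j - 1 - j // 10
    if spec.scenario == "shared_causal":
        causal1[mid] = spec.effect_z * se1[mid]
        causal2[mid] = spec.effect_z * se2[mid]
    elif spec.scenario == "distinct_causal":
        causal1[lo] = spec.effect_z * se1[lo]
        causal2[hi] = spec.effect_z * se2[hi]
    elif spec.scenario == "one_trait_only":
        causal1[mid] = spec.effect_z * se1[mid]

    beta1 = r @ causal1 + se1 * (chol @ rng.normal(0.0, 1.0, j))
    beta2 = r @ causal2 + se2 * (chol @ rng.normal(0.0, 1.0, j))

    vids = [f"rs{1000 + i}" for i in range(j)]
    profile1 = pd.DataFrame(dict(variant_id=vids, beta=beta1, se=se1))
    profile2 = pd.DataFrame(dict(variant_id=vids, beta=beta2, se=se2))
    truth = dict(
        scenario=spec.scenario,
        causal1=int(np.argmax(np.abs(causal1))) if causal1.any() else None,
        causal2=int(np.argmax(np.abs(causal2))) if causal2.any() else None,
    )
    return profile1, profile2, truth
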