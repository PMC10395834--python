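"""Bayesian model averaging over multivariable MR models (MR-BMA).

Candidate exposures (e.g. correlated microbial taxa) compete to explain the
outcome associations of a union instrument set.  Every subset S of exposures
is a model: in inverse-variance-whitened coordinates the outcome effects are
regressed on the subset's SNP-exposure effect columns with independent
Normal(0, prior_sd^2) priors on the causal effects, giving a closed-form
Gaussian marginal likelihood.  Model posteriors combine this evidence with a
binomial prior ``prior_prob^|S| * (1-prior_prob)^(K-|S|)``.

Two summaries rank the exposures:

* **MIP** — marginal inclusion probability, the summed posterior of all
  models containing the exposure;
* **MACE** — model-averaged causal effect, the posterior-weighted conditional
  estimate over models containing the exposure (a conservative direct-effect
  summary, shrunk by models that omit it).

The model space is enumerated exhaustively when K <= 15; above that (or on
request) a seeded shotgun stochastic search with add/delete/swap moves
evaluates at most ``search_budget`` models and posteriors are normalized over
the evaluated space.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gwas_io import SummaryDataset, harmonize, select_instruments
from .univariable import ivw

__all__ = [
    "BMAInput",
    "BMAResult",
    "prepare_bma_input",
    "model_log_evidence",
    "bma_rank",
    "bma_diagnostics",
    "mip_permutation_pvalues",
]


@dataclasses.dataclass
class BMAInput:
    """Harmonized design for model averaging: J union instruments x K exposures."""

    exposure_ids: list
    variant_ids: list
    beta_x: np.ndarray  # (J, K) SNP-exposure effects, outcome allele coding
    beta_y: np.ndarray  # (J,)
    se_y: np.ndarray  # (J,)
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        j, k = self.beta_x.shape
        if not (len(self.beta_y) == len(self.se_y) == j == len(self.variant_ids)):
            raise ValueError("dimension mismatch in BMAInput")
        if k != len(self.exposure_ids):
            raise ValueError("exposure_ids length must match beta_x columns")
        if j <= k:
            raise ValueError("need more instruments than exposures (J > K)")
        if not np.all(np.isfinite(self.beta_x)) or not np.all(np.isfinite(self.beta_y)):
            raise ValueError("missing cells in BMA design")

    @property
    def whitened(self):
        x = self.beta_x / self.se_y[:, None]
        y = self.beta_y / self.se_y
        return x, y


@dataclasses.dataclass
class BMAResult:
    models: pd.DataFrame  # subset, size, log_prior, log_evidence, posterior
    mip: pd.Series
    mace: pd.Series
    hyperparameters: dict

    def ranking(self, mip_threshold: float = 0.1, top_k: int = 10) -> pd.DataFrame:
        """Exposures sorted by MIP with threshold and top-k selection flags."""
        frame = pd.DataFrame({"mip": self.mip, "mace": self.mace})
        frame = frame.sort_values("mip", ascending=False)
        frame["rank"] = np.arange(1, len(frame) + 1)
        frame[f"mip_gt_{mip_threshold}"] = frame["mip"] > mip_threshold
        frame[f"top{top_k}"] = frame["rank"] <= top_k
        return frame.rename_axis("exposure").reset_index()


class DegenerateInputError(ValueError):
    """Fewer than two exposures survive preparation; use univariable MR."""


def prepare_bma_input(
    exposures: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    p_threshold: float = 1e-5,
    correlation_bound: float = 0.985,
    palindrome_maf: float = 0.3,
) -> BMAInput:
    """Build the union-instrument design and prune near-duplicate exposures.

    Instruments significant for *any* exposure at ``p_threshold`` are pooled;
    each exposure is harmonized against the outcome over that union (no
    per-exposure strength filter — weak columns are informative zeros in
    MVMR), and effects are re-coded to the outcome's effect alleles so all
    columns share one orientation.  Exposure pairs whose instrument-effect
    vectors correlate above ``correlation_bound`` in absolute value are
    pruned greedily, keeping the exposure with the smaller univariable IVW p.
    """
    if len(exposures) < 2:
        raise DegenerateInputError("MR-BMA needs at least 2 candidate exposures")
    union: list[str] = []
    for exp in exposures:
        for vid in select_instruments(exp, p_threshold).table["variant_id"]:
            if vid not in union:
                union.append(vid)
    if not union:
        raise DegenerateInputError("no instrument reaches the selection threshold")

    out_beta = outcome.table.set_index("variant_id")["beta"]
    columns = {}
    kept_sets = []
    harmonized = {}
    for exp in exposures:
        sub = exp.with_table(exp.table[exp.table["variant_id"].isin(union)])
        hs = harmonize(sub, outcome, palindrome_maf, f_min=0.0)
        harmonized[exp.trait_id] = hs
        tab = hs.table.set_index("variant_id")
        # sign that maps the harmonized (exposure-allele) coding to outcome coding
        flip = np.where(
            np.sign(tab["beta_y"]) == np.sign(out_beta.loc[tab.index]), 1.0, -1.0
        )
        columns[exp.trait_id] = tab["beta_x"] * flip
        kept_sets.append(set(tab.index))
    shared = [v for v in union if all(v in s for s in kept_sets)]
    if len(shared) <= len(exposures):
        raise DegenerateInputError("too few shared instruments across exposures")

    x = np.column_stack([columns[e.trait_id].loc[shared].to_numpy() for e in exposures])
    y = out_beta.loc[shared].to_numpy(float)
    se_y = outcome.table.set_index("variant_id")["se"].loc[shared].to_numpy(float)

    # univariable p per exposure (tie-break for pruning)
    uni_p = {}
    for exp in exposures:
        hs = harmonized[exp.trait_id]
        strong = select_instruments(exp, p_threshold).table["variant_id"]
        mask = hs.table["variant_id"].isin(set(strong))
        sub = dataclasses.replace(hs, table=hs.table[mask].reset_index(drop=True))
        try:
            uni_p[exp.trait_id] = ivw(sub).pvalue if len(sub) else 1.0
        except Exception:
            uni_p[exp.trait_id] = 1.0

    ids = [e.trait_id for e in exposures]
    keep = list(range(len(ids)))
    pruned = []
    corr = np.corrcoef(x, rowvar=False)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(keep), 2):
            if abs(corr[a, b]) > correlation_bound:
                drop = a if uni_p[ids[a]] > uni_p[ids[b]] else b
                keep.remove(drop)
                pruned.append((ids[drop], f"correlated>{correlation_bound}"))
                changed = True
                break
    if len(keep) < 2:
        raise DegenerateInputError(
            "fewer than 2 exposures survive correlation pruning; run univariable MR"
        )
    return BMAInput(
        exposure_ids=[ids[i] for i in keep],
        variant_ids=list(shared),
        beta_x=x[:, keep],
        beta_y=y,
        se_y=se_y,
        provenance=dict(
            union_size=len(union),
            shared_instruments=len(shared),
            pruned_exposures=pruned,
            p_threshold=p_threshold,
            correlation_bound=correlation_bound,
        ),
    )


def model_log_evidence(
    input: BMAInput, subset: Sequence[int], prior_sd: float = 0.5
) -> float:
    """Gaussian log marginal likelihood of an exposure subset.

    In whitened coordinates y ~ N(X_S theta, I) with theta ~ N(0, prior_sd^2 I):
    ``log evidence = -0.5 * (logdet M + y' M^-1 y)`` where
    ``M = prior_sd^2 X_S X_S' + I``; the -J/2*log(2*pi) constant is dropped
    (shared by all models, it cancels in posteriors).  The empty subset gives
    the null model.
    """
    x, y = input.whitened
    subset = sorted(subset)
    if not subset:
        return float(-0.5 * (y @ y))
    xs = x[:, subset]
    k = xs.shape[1]
    if np.linalg.matrix_rank(xs) < k:
        raise np.linalg.LinAlgError(f"collinear exposure subset {subset}")
    a = np.eye(k) + prior_sd**2 * (xs.T @ xs)
    sign, logdet = np.linalg.slogdet(a)
    xty = xs.T @ y
    quad = y @ y - prior_sd**2 * (xty @ np.linalg.solve(a, xty))
    return float(-0.5 * (logdet + quad))


def _conditional_estimates(input: BMAInput, subset: Sequence[int], prior_sd: float) -> np.ndarray:
    """Posterior-mean causal effects of the subset's exposures (ridge form)."""
    x, y = input.whitened
    xs = x[:, sorted(subset)]
    k = xs.shape[1]
    a = xs.T @ xs + np.eye(k) / prior_sd**2
    return np.linalg.solve(a, xs.T @ y)


def _log_prior(size: int, k: int, prior_prob: float) -> float:
    return size * math.log(prior_prob) + (k - size) * math.log1p(-prior_prob)


def bma_rank(
    input: BMAInput,
    prior_prob: float = 0.1,
    prior_sd: float = 0.5,
    search_budget: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> BMAResult:
    """Compute model posteriors and the per-exposure MIP/MACE summaries.

    ``method``: ``"exhaustive"`` enumerates all 2^K subsets, ``"sss"`` runs
    the shotgun stochastic search, ``"auto"`` picks exhaustive for K <= 15.
    """
    k = len(input.exposure_ids)
    if method == "auto":
        method = "exhaustive" if k <= 15 else "sss"

    evaluated: dict[frozenset, float] = {}

    def evaluate(subset: frozenset) -> float:
        if subset not in evaluated:
            try:
                ev = model_log_evidence(input, subset, prior_sd)
            except np.linalg.LinAlgError:
                ev = -np.inf
            evaluated[subset] = ev
        return evaluated[subset]

    if method == "exhaustive":
        for size in range(k + 1):
            for combo in itertools.combinations(range(k), size):
                evaluate(frozenset(combo))
    elif method == "sss":
        rng = np.random.default_rng(seed)
        evaluate(frozenset())
        for j in range(k):
            evaluate(frozenset([j]))
        current = max(evaluated, key=lambda s: evaluated[s] + _log_prior(len(s), k, prior_prob))
        stale = 0  # consecutive moves that discovered nothing new
        while len(evaluated) < min(search_budget, 2**k) and stale < 50:
            neighbors = []
            cur = set(current)
            for j in range(k):
                if j not in cur:
                    neighbors.append(frozenset(cur | {j}))
                else:
                    neighbors.append(frozenset(cur - {j}))
            for j_in in cur:
                for j_out in range(k):
                    if j_out not in cur:
                        neighbors.append(frozenset((cur - {j_in}) | {j_out}))
            before = len(evaluated)
            scores = np.array(
                [evaluate(s) + _log_prior(len(s), k, prior_prob) for s in neighbors]
            )
            stale = stale + 1 if len(evaluated) == before else 0
            probs = np.exp(scores - logsumexp(scores))
            probs /= probs.sum()
            current = neighbors[int(rng.choice(len(neighbors), p=probs))]
    else:
        raise ValueError(f"unknown method {method!r}")

    subsets = list(evaluated)
    log_post = np.array(
        [evaluated[s] + _log_prior(len(s), k, prior_prob) for s in subsets]
    )
    post = np.exp(log_post - logsumexp(log_post))
    post /= post.sum()

    mip = np.zeros(k)
    mace = np.zeros(k)
    rows = []
    for s, lp, p in zip(subsets, log_post, post):
        idx = sorted(s)
        cond = _conditional_estimates(input, idx, prior_sd) if idx else np.array([])
        for pos, j in enumerate(idx):
            mip[j] += p
            mace[j] += p * cond[pos]
        rows.append(
            dict(
                subset=tuple(input.exposure_ids[j] for j in idx),
                size=len(idx),
                log_evidence=evaluated[s],
                log_posterior_unnorm=lp,
                posterior=p,
                conditional_estimates=tuple(float(c) for c in cond),
            )
        )
    models = pd.DataFrame(rows).sort_values("posterior", ascending=False).reset_index(drop=True)
    return BMAResult(
        models=models,
        mip=pd.Series(mip, index=input.exposure_ids, name="mip"),
        mace=pd.Series(mace, index=input.exposure_ids, name="mace"),
        hyperparameters=dict(
            prior_prob=prior_prob,
            prior_sd=prior_sd,
            search_budget=search_budget,
            seed=seed,
            method=method,
            models_evaluated=len(subsets),
        ),
    )


def bma_diagnostics(
    input: BMAInput,
    result: BMAResult,
    top_models: int = 5,
    cd_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-variant influence diagnostics for the top posterior models.

    For each model: Cook's distance from the whitened least-squares fit and
    the heterogeneity contribution ``q_j`` (squared whitened residual).
    Variants with Cd above the threshold (default 4/J) in any top model are
    flagged as influence points; re-run the analysis without them via
    :func:`exclude_variants`.
    """
    x, y = input.whitened
    j_total = len(input.variant_ids)
    threshold = cd_threshold if cd_threshold is not None else 4.0 / j_total
    name_to_idx = {name: i for i, name in enumerate(input.exposure_ids)}
    rows = []
    top = result.models[result.models["size"] > 0].head(top_models)
    for rank, model in enumerate(top.itertuples(), start=1):
        idx = [name_to_idx[n] for n in model.subset]
        xs = x[:, idx]
        k = xs.shape[1]
        hat = xs @ np.linalg.pinv(xs.T @ xs) @ xs.T
        fitted = hat @ y
        resid = y - fitted
        h = np.clip(np.diag(hat), 0.0, 1.0 - 1e-9)
        dof = max(j_total - k, 1)
        sigma2 = float(resid @ resid) / dof
        cd = resid**2 * h / (k * sigma2 * (1.0 - h) ** 2)
        for vi, vid in enumerate(input.variant_ids):
            rows.append(
                dict(
                    model_rank=rank,
                    model=model.subset,
                    variant_id=vid,
                    cooks_distance=float(cd[vi]),
                    q_contribution=float(resid[vi] ** 2),
                    influential=bool(cd[vi] > threshold),
                )
            )
    return pd.DataFrame(rows)


def exclude_variants(input: BMAInput, variant_ids: Sequence[str]) -> BMAInput:
    """Re-run hook: the same design without the listed variants."""
    drop = set(variant_ids)
    keep = [i for i, v in enumerate(input.variant_ids) if v not in drop]
    prov = dict(input.provenance)
    prov["excluded_variants"] = sorted(drop)
    return BMAInput(
        exposure_ids=list(input.exposure_ids),
        variant_ids=[input.variant_ids[i] for i in keep],
        beta_x=input.beta_x[keep],
        beta_y=input.beta_y[keep],
        se_y=input.se_y[keep],
        provenance=prov,
    )


def mip_permutation_pvalues(
    input: BMAInput,
    observed: BMAResult,
    n_permutations: int = 100,
    seed: int = 0,
    **rank_kwargs,
) -> pd.Series:
    """Optional empirical MIP p-values by permuting the outcome effects."""
    rng = np.random.default_rng(seed)
    k = len(input.exposure_ids)
    exceed = np.zeros(k)
    for _ in range(n_permutations):
        perm = rng.permutation(len(input.beta_y))
        permuted = dataclasses.replace(
            input, beta_y=input.beta_y[perm], se_y=input.se_y[perm]
        )
        res = bma_rank(permuted, seed=int(rng.integers(2**31)), **rank_kwargs)
        exceed += res.mip.to_numpy() >= observed.mip.to_numpy()
    return pd.Series(
        (1.0 + exceed) / (1.0 + n_permutations), index=input.exposure_ids, name="mip_perm_p"
    )
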