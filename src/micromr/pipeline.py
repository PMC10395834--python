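"""End-to-end orchestration of the MR biomarker pipeline on synthetic data.

The default run emulates the study design at desk scale: a panel of candidate
microbial exposures (a known causal subset among correlated nulls) against a
disease outcome, screened by univariable MR with the sensitivity battery,
ranked by MR-BMA, colocalized, decomposed through a diet→microbe→disease
mediation triad, and merged into the consensus evidence table.  Every stage
writes a TSV under the output directory plus a machine-readable run report;
identical configuration and seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bma import bma_diagnostics, bma_rank, prepare_bma_input
from .coloc import colocalize
from .consensus import build_evidence_table, specificity_screen
from .mediation import results_to_frame, run_two_step
from .presso import run_presso
from .simulate import (
    ColocSimSpec,
    MediationSimSpec,
    MultivariableSimSpec,
    simulate_coloc_region,
    simulate_mediation,
    simulate_multivariable,
)
from .univariable import ScreenConfig, run_univariable_screen, screen_to_frame
from .gwas_io import harmonize, select_instruments

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclasses.dataclass
class RunConfig:
    """All pipeline thresholds (defaults mirror the analysis settings the
    pipeline reproduces) plus the synthetic-scenario shape."""

    # instrument selection / harmonization
    iv_p_microbe: float = 1e-5
    iv_p_other: float = 5e-8
    f_min: float = 10.0
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000
    palindrome_maf: float = 0.3
    # univariable screen
    fdr_alpha: float = 0.2
    potential_alpha: float = 0.05
    # sensitivity
    presso_n_simulations: int = 1000
    pp_h4: float = 0.8
    # BMA
    mip_threshold: float = 0.1
    top_k: int = 10
    corr_prune: float = 0.985
    bma_prior_prob: float = 0.1
    bma_prior_sd: float = 0.5
    bma_budget: int = 10_000
    # consensus
    min_methods: int = 3
    netmoss_score_threshold: float = 1.0
    # synthetic scenario
    n_exposures: int = 6
    n_variants: int = 120
    seed: int = 0
    out_dir: str = "results/pipeline"

    def validate(self) -> None:
        checks = [
            0 < self.iv_p_microbe < 1,
            0 < self.iv_p_other < 1,
            self.f_min >= 0,
            0 < self.clump_r2 < 1,
            self.clump_window_kb > 0,
            0 < self.palindrome_maf <= 0.5,
            0 < self.fdr_alpha < 1,
            0 < self.potential_alpha < 1,
            self.presso_n_simulations >= 10,
            0 < self.pp_h4 < 1,
            0 < self.mip_threshold < 1,
            self.top_k >= 1,
            0 < self.corr_prune <= 1,
            0 < self.bma_prior_prob < 1,
            self.bma_prior_sd > 0,
            self.bma_budget >= 1,
            self.min_methods >= 1,
            self.n_exposures >= 2,
            self.n_variants > self.n_exposures,
        ]
        if not all(checks):
            raise ValueError("RunConfig contains out-of-domain settings")


def load_config(path: str | Path) -> RunConfig:
    """YAML configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    config = RunConfig(**raw)
    config.validate()
    return config


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full pipeline; returns the run report (also written to disk)."""
    config = config or RunConfig()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "settings": dataclasses.asdict(config),
        "versions": {"micromr": __version__, "python": platform.python_version()},
        "stages": {},
        "failures": [],
    }

    # --- synthetic exposure panel -----------------------------------------
    k = config.n_exposures
    corr = np.full((k, k), 0.3)
    np.fill_diagonal(corr, 1.0)
    mv_spec = MultivariableSimSpec(
        n_variants=config.n_variants,
        n_exposures=k,
        causal_subset={0: 0.25},
        exposure_correlation=corr,
        seed=config.seed,
    )
    exposures, outcome, mv_truth = simulate_multivariable(mv_spec)
    report["stages"]["simulate"] = {
        "n_exposures": k,
        "n_variants": config.n_variants,
        "causal_subset": {str(i): v for i, v in mv_truth["causal_subset"].items()},
    }

    screen_config = ScreenConfig(
        iv_p_threshold=config.iv_p_microbe,
        clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
        palindrome_maf=config.palindrome_maf,
        f_min=config.f_min,
        fdr_alpha=config.fdr_alpha,
        potential_alpha=config.potential_alpha,
    )

    # --- univariable screen ------------------------------------------------
    screen_rows = run_univariable_screen(exposures, outcome, screen_config)
    screen_frame = screen_to_frame(screen_rows)
    screen_frame.to_csv(out / "univariable_screen.tsv", sep="\t", index=False)
    report["stages"]["univariable"] = {
        "rows": len(screen_frame),
        "significant_fdr": int((screen_frame["significance"] == "significant_fdr").sum()),
        "errors": int(screen_frame["error"].notna().sum()),
    }

    # --- PRESSO on the causal exposure's instruments -----------------------
    causal = exposures[0]
    hs = harmonize(
        select_instruments(causal, config.iv_p_microbe), outcome,
        config.palindrome_maf, config.f_min,
    )
    presso_rows = []
    if len(hs) >= 4:
        pres = run_presso(hs, config.presso_n_simulations, seed=config.seed)
        presso_rows.append(
            dict(
                exposure=causal.trait_id,
                outcome=outcome.trait_id,
                rss_observed=pres.rss_observed,
                global_p=pres.global_p,
                outliers=",".join(pres.outlier_ids) or "none",
                theta_raw=pres.theta_raw.theta_hat,
                theta_corrected=pres.theta_corrected.theta_hat,
                distortion_p=pres.distortion_p,
            )
        )
    else:
        report["failures"].append({"stage": "presso", "reason": "fewer than 4 instruments"})
    pd.DataFrame(presso_rows).to_csv(out / "presso.tsv", sep="\t", index=False)
    report["stages"]["presso"] = {"rows": len(presso_rows)}

    # --- colocalization at a synthetic shared locus ------------------------
    prof1, prof2, coloc_truth = simulate_coloc_region(
        ColocSimSpec(scenario="distinct_causal", seed=config.seed)
    )
    coloc_result = colocalize(prof1, prof2, pp_h4_threshold=config.pp_h4)
    coloc_frame = pd.DataFrame(
        [
            dict(
                scenario=coloc_truth["scenario"],
                pp_h0=coloc_result.pp_h0,
                pp_h1=coloc_result.pp_h1,
                pp_h2=coloc_result.pp_h2,
                pp_h3=coloc_result.pp_h3,
                pp_h4=coloc_result.pp_h4,
                mr_assumption_violated=coloc_result.mr_assumption_violated,
            )
        ]
    )
    coloc_frame.to_csv(out / "coloc.tsv", sep="\t", index=False)
    report["stages"]["coloc"] = {"pp_h4": coloc_result.pp_h4}

    # --- MR-BMA ranking and identification ---------------------------------
    try:
        bma_input = prepare_bma_input(
            exposures, outcome, config.iv_p_microbe, config.corr_prune, config.palindrome_maf
        )
        ranking = bma_rank(
            bma_input,
            config.bma_prior_prob,
            config.bma_prior_sd,
            config.bma_budget,
            seed=config.seed,
        )
        ranking_frame = ranking.ranking(config.mip_threshold, config.top_k)
        ranking_frame.to_csv(out / "bma_ranking.tsv", sep="\t", index=False)
        diag = bma_diagnostics(bma_input, ranking)
        diag.to_csv(out / "bma_diagnostics.tsv", sep="\t", index=False)
        report["stages"]["bma"] = {
            "exposures": len(bma_input.exposure_ids),
            "instruments": len(bma_input.variant_ids),
            "top_mip": ranking_frame.iloc[0]["exposure"],
            "models_evaluated": ranking.hyperparameters["models_evaluated"],
        }
    except Exception as exc:  # degeneracy recorded, pipeline continues
        ranking = None
        report["failures"].append({"stage": "bma", "reason": str(exc)})

    # --- mediation ----------------------------------------------------------
    med_exposure, med_mediator, med_outcome, med_truth = simulate_mediation(
        MediationSimSpec(seed=config.seed)
    )
    med_result = run_two_step(med_exposure, med_mediator, med_outcome)
    med_frame = results_to_frame([med_result])
    med_frame["true_indirect"] = med_truth["indirect"]
    med_frame.to_csv(out / "mediation.tsv", sep="\t", index=False)
    report["stages"]["mediation"] = {
        "b": med_result.b,
        "proportion": med_result.proportion,
        "consistent": med_result.direction_consistent,
    }

    # --- consensus ----------------------------------------------------------
    specificity = specificity_screen(exposures, [], config.potential_alpha)
    evidence = build_evidence_table(
        screen_rows,
        ranking,
        ranking,
        netmoss_scores=None,
        specificity=specificity,
        potential_alpha=config.potential_alpha,
        mip_threshold=config.mip_threshold,
        top_k=config.top_k,
        min_methods=config.min_methods,
    )
    evidence.to_csv(out / "consensus.tsv", sep="\t", index=False)
    report["stages"]["consensus"] = {
        "rows": len(evidence),
        "robust": int(evidence["robust"].sum()),
    }

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    summary_lines = [
        f"micromr pipeline run (seed {config.seed})",
        f"univariable: {report['stages']['univariable']['significant_fdr']} / "
        f"{report['stages']['univariable']['rows']} exposures significant at FDR<{config.fdr_alpha}"
        " (univariable_screen.tsv)",
        f"coloc PP.H4 = {coloc_result.pp_h4:.3f} (coloc.tsv)",
        f"mediation indirect effect b = {med_result.b:.3f}, proportion = "
        f"{med_result.proportion:.1f}% (mediation.tsv)",
        f"consensus: {report['stages']['consensus']['robust']} robust rows (consensus.tsv)",
    ]
    if ranking is not None:
        summary_lines.insert(
            2, f"BMA top exposure by MIP: {report['stages']['bma']['top_mip']} (bma_ranking.tsv)"
        )
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return report
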