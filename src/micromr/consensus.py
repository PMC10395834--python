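"""Cross-method consensus: merge the evidence streams into one robust-biomarker table.

Four streams vote per (exposure, outcome) pair:

1. univariable MR significance (raw p below the potential threshold);
2. ranking-stage MR-BMA marginal inclusion probability above 0.1;
3. identification-stage MR-BMA membership in the top-10 MIPs;
4. an externally supplied network-shift (NetMoss-style) score at or above a
   cutoff — always an input column, never computed here.

``evidence_count`` counts votes over the streams with available data; a pair
is ``robust`` when at least ``min_methods`` (default 3) agree.  A separate
specificity screen marks exposures with no nominal signal against any
non-target outcome.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from .bma import BMAResult
from .gwas_io import LDMatrix, SummaryDataset
from .univariable import ScreenConfig, ScreenResultRow, run_univariable_screen

__all__ = ["EvidenceRow", "build_evidence_table", "specificity_screen", "unique_taxon_view"]


@dataclasses.dataclass
class EvidenceRow:
    exposure_id: str
    outcome_id: str
    univariable_or: float | None
    univariable_p: float | None
    fdr_p: float | None
    ranking_mip: float | None
    identification_mip: float | None
    top10: bool | None
    netmoss_score: float | None
    specific: bool | None
    evidence_count: int
    n_streams_available: int
    robust: bool


def _vote(value, predicate) -> tuple[int, int]:
    """(vote, available) for one stream; missing data contributes neither."""
    if value is None:
        return 0, 0
    return (1 if predicate(value) else 0), 1


def build_evidence_table(
    screen_rows: Sequence[ScreenResultRow],
    ranking: Mapping[str, BMAResult] | BMAResult | None,
    identification: Mapping[str, BMAResult] | BMAResult | None,
    netmoss_scores: pd.DataFrame | None = None,
    specificity: Mapping[str, bool] | None = None,
    potential_alpha: float = 0.05,
    mip_threshold: float = 0.1,
    top_k: int = 10,
    score_threshold: float = 1.0,
    min_methods: int = 3,
) -> pd.DataFrame:
    """Join the evidence streams keyed by (exposure_id, outcome_id).

    ``ranking``/``identification`` may be a single BMAResult (one outcome) or
    a mapping from outcome_id.  ``netmoss_scores`` needs columns
    exposure_id, score (optionally outcome_id).  Raises on duplicate keys.
    """
    keys = [(r.exposure_id, r.outcome_id) for r in screen_rows]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (exposure, outcome) keys in screen rows")

    def _bma_for(bma, outcome_id) -> BMAResult | None:
        if bma is None:
            return None
        if isinstance(bma, Mapping):
            return bma.get(outcome_id)
        return bma

    scores = None
    if netmoss_scores is not None:
        scores = netmoss_scores.set_index(
            ["exposure_id", "outcome_id"] if "outcome_id" in netmoss_scores else "exposure_id"
        )["score"]

    rows = []
    for r in screen_rows:
        rank_res = _bma_for(ranking, r.outcome_id)
        ident_res = _bma_for(identification, r.outcome_id)
        rank_mip = (
            float(rank_res.mip.get(r.exposure_id)) if rank_res is not None and r.exposure_id in rank_res.mip else None
        )
        ident_mip = None
        top10 = None
        if ident_res is not None and r.exposure_id in ident_res.mip:
            ident_mip = float(ident_res.mip.get(r.exposure_id))
            ranking_frame = ident_res.ranking(mip_threshold, top_k).set_index("exposure")
            top10 = bool(ranking_frame.loc[r.exposure_id, f"top{top_k}"])
        score = None
        if scores is not None:
            key = (r.exposure_id, r.outcome_id) if isinstance(scores.index, pd.MultiIndex) else r.exposure_id
            if key in scores.index:
                score = float(scores.loc[key])

        uni_p = r.raw_p if r.estimate else None
        votes = [
            _vote(uni_p, lambda p: p < potential_alpha),
            _vote(rank_mip, lambda m: m > mip_threshold),
            _vote(top10, bool),
            _vote(score, lambda s: s >= score_threshold),
        ]
        count = sum(v for v, _ in votes)
        available = sum(a for _, a in votes)
        rows.append(
            EvidenceRow(
                exposure_id=r.exposure_id,
                outcome_id=r.outcome_id,
                univariable_or=r.estimate.or_point if r.estimate else None,
                univariable_p=uni_p,
                fdr_p=r.fdr_adjusted_p if r.estimate else None,
                ranking_mip=rank_mip,
                identification_mip=ident_mip,
                top10=top10,
                netmoss_score=score,
                specific=None if specificity is None else bool(specificity.get(r.exposure_id, True)),
                evidence_count=count,
                n_streams_available=available,
                robust=count >= min_methods,
            )
        )
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return frame.sort_values(
        ["outcome_id", "evidence_count"], ascending=[True, False]
    ).reset_index(drop=True)


def specificity_screen(
    exposures: Sequence[SummaryDataset],
    non_target_outcomes: Sequence[SummaryDataset],
    alpha: float = 0.05,
    config: ScreenConfig | None = None,
    ld: LDMatrix | None = None,
) -> dict[str, bool]:
    """An exposure is *specific* iff it shows no nominal causal signal
    (p < alpha) against any non-target outcome; vacuously true when the
    non-target panel is empty."""
    specific = {e.trait_id: True for e in exposures}
    for outcome in non_target_outcomes:
        for row in run_univariable_screen(exposures, outcome, config, ld):
            if row.estimate is not None and row.raw_p < alpha:
                specific[row.exposure_id] = False
    return specific


def unique_taxon_view(evidence: pd.DataFrame) -> pd.DataFrame:
    """Roll the per-(exposure, outcome) table up to unique exposures,
    keeping each exposure's best-supported row."""
    best = (
        evidence.sort_values("evidence_count", ascending=False)
        .groupby("exposure_id", as_index=False)
        .first()
    )
    return best.sort_values("evidence_count", ascending=False).reset_index(drop=True)
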