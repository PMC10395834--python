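"""Reading, validation, harmonization and instrument filtering of GWAS summary statistics.

The unit of data is a per-variant summary association (alleles, effect-allele
frequency, beta, SE, p, N).  A :class:`SummaryDataset` holds one trait's table;
:func:`harmonize` pairs an exposure with an outcome dataset, aligning effect
alleles (sign flips, strand complements, palindrome frequency rules) and
filtering weak instruments, producing the :class:`HarmonizedInstrumentSet`
consumed by every causal estimator downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "SummaryDataset",
    "LDMatrix",
    "HarmonizedInstrumentSet",
    "FormatError",
    "read_summary_stats",
    "write_summary_stats",
    "select_instruments",
    "is_palindromic",
    "harmonize",
    "ld_clump",
    "f_statistic",
    "apply_exclusion_list",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_exclusion_list",
]

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """A summary-statistics table does not match the expected layout."""


@dataclasses.dataclass
class SummaryDataset:
    """One trait's per-variant summary associations.

    ``table`` uses the canonical columns; ``variant_id`` is unique.  ``audit``
    records counts of rows dropped at read/validation time keyed by reason.
    """

    trait_id: str
    trait_type: str  # exposure | outcome | mediator
    table: pd.DataFrame
    audit: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("exposure", "outcome", "mediator"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.table["variant_id"].duplicated().any():
            dup = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise FormatError(f"duplicate variant_id {dup!r} in dataset {self.trait_id!r}")

    def __len__(self) -> int:
        return len(self.table)

    def with_table(self, table: pd.DataFrame, **audit) -> "SummaryDataset":
        new_audit = dict(self.audit)
        new_audit.update(audit)
        return SummaryDataset(self.trait_id, self.trait_type, table.reset_index(drop=True), new_audit)


@dataclasses.dataclass
class LDMatrix:
    """Pairwise variant correlations (r, not r^2) with genomic positions."""

    variant_ids: list
    r: np.ndarray
    positions: pd.DataFrame  # columns variant_id, chrom, pos

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    @classmethod
    def identity(cls, variant_ids: Sequence[str], positions: pd.DataFrame) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)), positions)


@dataclasses.dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned exposure/outcome effects for a set of instruments.

    ``table`` columns: variant_id, beta_x, se_x, beta_y, se_y, eaf, f_stat.
    ``exclusions`` columns: variant_id, reason — every input variant appears
    exactly once across the retained table and the exclusion log.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    exclusions: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_x(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(float)

    @property
    def variant_ids(self) -> list:
        return self.table["variant_id"].tolist()


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the per-variant invariants; return (clean, n_dropped)."""
    ok = (
        (df["se"] > 0)
        & (df["eaf"] > 0)
        & (df["eaf"] < 1)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["effect_allele"] != df["other_allele"])
        & df["effect_allele"].isin(list(_VALID_ALLELES))
        & df["other_allele"].isin(list(_VALID_ALLELES))
        & np.isfinite(df["beta"])
    )
    return df.loc[ok], int((~ok).sum())


def read_summary_stats(
    path: str | Path,
    trait_id: str | None = None,
    trait_type: str = "exposure",
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a validated dataset.

    ``column_map`` maps canonical names to the header names actually present
    (covering OpenGWAS/FinnGen export dialects).  Rows violating the
    per-variant invariants are dropped and counted in ``dataset.audit``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise FormatError(f"{path}: empty summary-statistics table")
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[CANONICAL_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df, n_dropped = _validate_rows(df)
    return SummaryDataset(
        trait_id or path.stem,
        trait_type,
        df.reset_index(drop=True),
        audit={"rows_read": len(df) + n_dropped, "rows_invalid": n_dropped},
    )


def write_summary_stats(dataset: SummaryDataset, path: str | Path, sep: str = "\t") -> None:
    dataset.table[CANONICAL_COLUMNS].to_csv(path, sep=sep, index=False)


def select_instruments(dataset: SummaryDataset, p_threshold: float) -> SummaryDataset:
    """Keep variants with association p below ``p_threshold`` (genome-wide or
    relaxed instrument-selection cutoffs, e.g. 5e-8 or 1e-5)."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    kept = dataset.table[dataset.table["pval"] < p_threshold]
    return dataset.with_table(kept, selected_at=p_threshold, n_selected=len(kept))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    a, b = effect_allele.upper(), other_allele.upper()
    if a not in _VALID_ALLELES or b not in _VALID_ALLELES:
        raise ValueError(f"alleles must be A/C/G/T, got {effect_allele!r}/{other_allele!r}")
    return _COMPLEMENT[a] == b


def f_statistic(beta_x, se_x):
    """Per-instrument strength F = (beta/se)^2; values < 10 flag weak instruments."""
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    if np.any(se_x <= 0):
        raise ValueError("se_x must be > 0")
    return (beta_x / se_x) ** 2


def _complement_pair(a: str, b: str) -> tuple[str, str]:
    return _COMPLEMENT[a], _COMPLEMENT[b]


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_maf_limit: float = 0.3,
    f_min: float = 10.0,
) -> HarmonizedInstrumentSet:
    """Align outcome effect alleles to the exposure's and pair the effects.

    Alignment rules, applied per shared variant:

    * same allele pair, same orientation — keep as is;
    * swapped effect/other alleles — flip the outcome beta sign and complement
      its EAF;
    * strand-complement pair — complement first, then apply the two rules above;
    * palindromic (A/T, C/G) variants cannot be resolved by allele letters:
      at intermediate frequency (min(eaf, 1-eaf) > ``palindrome_maf_limit``)
      they are dropped as ``palindrome_ambiguous``; low-frequency palindromes
      are aligned by matching the minor-allele side of the two EAFs.

    Variants missing from either dataset (``unmatched``), with irreconcilable
    alleles (``allele_mismatch``), or with exposure F below ``f_min``
    (``weak_instrument``) are logged.  Every input exposure variant appears in
    the retained set or the exclusion log exactly once.
    """
    if not 0 < palindrome_maf_limit <= 0.5:
        raise ValueError("palindrome_maf_limit must be in (0, 0.5]")
    exp = exposure.table.set_index("variant_id")
    out = outcome.table.set_index("variant_id")
    rows = []
    excl = []
    for vid, ex in exp.iterrows():
        if vid not in out.index:
            excl.append((vid, "unmatched"))
            continue
        oc = out.loc[vid]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = oc["effect_allele"], oc["other_allele"]
        beta_y, eaf_y = float(oc["beta"]), float(oc["eaf"])
        palindromic = is_palindromic(ea_x, oa_x)

        if palindromic:
            if {ea_y, oa_y} != {ea_x, oa_x}:
                excl.append((vid, "allele_mismatch"))
                continue
            maf = min(ex["eaf"], 1 - ex["eaf"])
            if maf > palindrome_maf_limit:
                excl.append((vid, "palindrome_ambiguous"))
                continue
            # letters cannot distinguish strand; align by frequency side only
            same_side = (ex["eaf"] < 0.5) == (eaf_y < 0.5)
            if not same_side:
                beta_y, eaf_y = -beta_y, 1 - eaf_y
        else:
            if {ea_y, oa_y} != {ea_x, oa_x}:
                ea_y, oa_y = _complement_pair(ea_y, oa_y)
                if {ea_y, oa_y} != {ea_x, oa_x}:
                    excl.append((vid, "allele_mismatch"))
                    continue
            if ea_y == ea_x:
                pass
            else:  # swapped orientation
                beta_y, eaf_y = -beta_y, 1 - eaf_y

        f = float(f_statistic(ex["beta"], ex["se"]))
        if f < f_min:
            excl.append((vid, "weak_instrument"))
            continue
        rows.append(
            dict(
                variant_id=vid,
                beta_x=float(ex["beta"]),
                se_x=float(ex["se"]),
                beta_y=beta_y,
                se_y=float(oc["se"]),
                eaf=float(ex["eaf"]),
                f_stat=f,
            )
        )
    table = pd.DataFrame(
        rows, columns=["variant_id", "beta_x", "se_x", "beta_y", "se_y", "eaf", "f_stat"]
    )
    exclusions = pd.DataFrame(excl, columns=["variant_id", "reason"])
    return HarmonizedInstrumentSet(exposure.trait_id, outcome.trait_id, table, exclusions)


def ld_clump(
    dataset: SummaryDataset,
    ld: LDMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
) -> SummaryDataset:
    """Greedy p-value clumping: keep the most significant variant, drop
    same-chromosome neighbours within ``window_kb`` whose squared correlation
    with it is >= ``r2_threshold``; repeat until exhausted.

    Equal p-values are broken by (chrom, pos, variant_id) so the result is
    deterministic.
    """
    if not 0 < r2_threshold < 1:
        raise ValueError("r2_threshold must be in (0, 1)")
    if window_kb <= 0:
        raise ValueError("window_kb must be > 0")
    missing = set(dataset.table["variant_id"]) - set(ld.variant_ids)
    if missing:
        raise KeyError(f"variant(s) missing from LD matrix: {sorted(missing)[:5]}")
    df = dataset.table.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    pos = {row.variant_id: (row.chrom, row.pos) for row in df.itertuples()}
    kept: list[str] = []
    removed: set[str] = set()
    window_bp = window_kb * 1000
    for row in df.itertuples():
        vid = row.variant_id
        if vid in removed:
            continue
        kept.append(vid)
        chrom_i, pos_i = pos[vid]
        for other in df["variant_id"]:
            if other == vid or other in removed or other in kept:
                continue
            chrom_j, pos_j = pos[other]
            if chrom_j == chrom_i and abs(pos_j - pos_i) <= window_bp:
                if ld.r2(vid, other) >= r2_threshold:
                    removed.add(other)
    kept_set = set(kept)
    out = dataset.table[dataset.table["variant_id"].isin(kept_set)]
    return dataset.with_table(out, clumped_removed=len(removed))


def apply_exclusion_list(
    dataset: SummaryDataset, excluded_ids: Iterable[str], reason: str = "manual_exclusion"
) -> SummaryDataset:
    """Remove listed variants (e.g. a manual secondary-trait pleiotropy screen)."""
    excluded = set(excluded_ids)
    present = dataset.table["variant_id"].isin(excluded)
    out = dataset.table[~present]
    return dataset.with_table(
        out,
        **{
            f"excluded_{reason}": int(present.sum()),
            f"excluded_{reason}_noop": len(excluded) - int(present.sum()),
        },
    )


def read_ld_matrix(matrix_path: str | Path, positions_path: str | Path) -> LDMatrix:
    """Read a square tab-separated correlation matrix (variant ids as header
    row and first column) plus a (variant_id, chrom, pos) sidecar."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    positions = pd.read_csv(positions_path, sep="\t")
    return LDMatrix(list(mat.columns), mat.to_numpy(float), positions)


def write_ld_matrix(ld: LDMatrix, matrix_path: str | Path, positions_path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(matrix_path, sep="\t")
    ld.positions.to_csv(positions_path, sep="\t", index=False)


def read_exclusion_list(path: str | Path) -> list[str]:
    """One variant_id per line; anything after whitespace is treated as a note."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line.split()[0])
    return ids
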