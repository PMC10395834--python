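"""Reading, validation, harmonization, clumping and instrument filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from micromr.gwas_io import (
    FormatError,
    LDMatrix,
    SummaryDataset,
    apply_exclusion_list,
    f_statistic,
    harmonize,
    is_palindromic,
    ld_clump,
    read_summary_stats,
    select_instruments,
    write_summary_stats,
)

from conftest import make_dataset


class TestReadWrite:
    def test_well_formed_table_reads_fully(self, toy_dataset, tmp_path):
        path = tmp_path / "stats.tsv"
        write_summary_stats(toy_dataset, path)
        ds = read_summary_stats(path, trait_id="trait")
        assert len(ds) == 3
        assert ds.audit["rows_invalid"] == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        ds = make_dataset(
            rows=[
                ("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.02, 1e-5, 100),
                ("rs2", "1", 2000, "C", "T", 0.4, 0.2, 0.02, 1e-4, 100),
            ]
        )
        path = tmp_path / "stats.tsv"
        write_summary_stats(ds, path)
        # corrupt one row with se = 0
        text = path.read_text().replace("0.02\t0.0001", "0.0\t0.0001")
        path.write_text(text)
        out = read_summary_stats(path)
        assert len(out) == 1
        assert out.audit["rows_invalid"] == 1

    def test_round_trip_preserves_values(self, toy_dataset, tmp_path):
        path = tmp_path / "stats.tsv"
        write_summary_stats(toy_dataset, path)
        back = read_summary_stats(path, trait_id=toy_dataset.trait_id)
        pd.testing.assert_frame_equal(back.table, toy_dataset.table, check_dtype=False)

    def test_missing_column_named_in_error(self, toy_dataset, tmp_path):
        path = tmp_path / "stats.tsv"
        toy_dataset.table.drop(columns=["se"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="se"):
            read_summary_stats(path)

    def test_column_map_handles_dialects(self, toy_dataset, tmp_path):
        path = tmp_path / "stats.tsv"
        renamed = toy_dataset.table.rename(columns={"pval": "P", "variant_id": "SNP"})
        renamed.to_csv(path, sep="\t", index=False)
        ds = read_summary_stats(path, column_map={"pval": "P", "variant_id": "SNP"})
        assert list(ds.table["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("variant_id\tchrom\n")
        with pytest.raises(FormatError, match="empty"):
            read_summary_stats(path)

    def test_duplicate_variant_ids_rejected(self):
        rows = [
            ("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.02, 1e-5, 100),
            ("rs1", "1", 2000, "C", "T", 0.4, 0.2, 0.02, 1e-4, 100),
        ]
        with pytest.raises(FormatError, match="rs1"):
            make_dataset(rows=rows)


class TestSelectInstruments:
    def test_threshold_straddle(self):
        ds = make_dataset(
            rows=[
                ("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.02, 1e-6, 100),
                ("rs2", "1", 2000, "C", "T", 0.4, 0.2, 0.02, 1e-4, 100),
            ]
        )
        assert list(select_instruments(ds, 1e-5).table["variant_id"]) == ["rs1"]

    def test_vacuous_threshold_keeps_all(self, toy_dataset):
        assert len(select_instruments(toy_dataset, 1.0)) == len(toy_dataset)

    def test_matches_brute_force_count(self, rng):
        pvals = rng.uniform(0.0, 1.0, 1000) + 1e-12
        rows = [
            (f"rs{i}", "1", 1000 + i, "A", "G", 0.3, 0.1, 0.02, p, 100)
            for i, p in enumerate(pvals)
        ]
        ds = make_dataset(rows=rows)
        expected = int(sum(p < 0.05 for p in pvals))
        assert len(select_instruments(ds, 0.05)) == expected


class TestPalindromes:
    def test_enumeration_of_all_ordered_pairs(self):
        pairs = [(a, b) for a, b in itertools.permutations("ACGT", 2)]
        truthy = [p for p in pairs if is_palindromic(*p)]
        assert sorted(truthy) == [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")]

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            is_palindromic("A", "N")


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.1, 0.01) == pytest.approx(100.0)
        assert f_statistic(0.0, 0.01) == 0.0

    def test_sign_flip_invariance(self, rng):
        beta = rng.normal(size=50)
        se = rng.uniform(0.01, 0.1, 50)
        np.testing.assert_allclose(f_statistic(beta, se), f_statistic(-beta, se))

    def test_matches_variance_explained_form(self, rng):
        # (beta/se)^2 ~ (n-2) r2/(1-r2) for a simple regression on one SNP
        n, maf, beta_true = 4000, 0.3, 0.12
        g = rng.binomial(2, maf, n)
        y = beta_true * g + rng.normal(0, 1, n)
        gc = g - g.mean()
        beta_hat = float(gc @ y / (gc @ gc))
        resid = y - y.mean() - beta_hat * gc
        se_hat = float(np.sqrt(resid @ resid / (n - 2) / (gc @ gc)))
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        f_direct = (n - 2) * r2 / (1 - r2)
        assert f_statistic(beta_hat, se_hat) == pytest.approx(f_direct, rel=0.01)


def _aligned_outcome(exposure, beta_y, se_y=0.05):
    """Outcome dataset sharing the exposure's variants and allele coding."""
    table = exposure.table.copy()
    table["beta"] = beta_y
    table["se"] = se_y
    return SummaryDataset("out", "outcome", table)


class TestHarmonize:
    def test_swapped_alleles_flip_beta_sign(self):
        exposure = make_dataset(
            rows=[("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.02, 1e-50, 100)]
        )
        outcome = make_dataset(
            trait_id="out",
            trait_type="outcome",
            rows=[("rs1", "1", 1000, "G", "A", 0.7, 0.3, 0.05, 1e-8, 100)],
        )
        hs = harmonize(exposure, outcome)
        assert hs.table.loc[0, "beta_y"] == pytest.approx(-0.3)
        assert hs.table.loc[0, "eaf"] == pytest.approx(0.3)

    def test_strand_complement_aligned(self):
        exposure = make_dataset(
            rows=[("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.02, 1e-50, 100)]
        )
        outcome = make_dataset(
            trait_id="out",
            trait_type="outcome",
            rows=[("rs1", "1", 1000, "T", "C", 0.3, 0.4, 0.05, 1e-8, 100)],
        )
        hs = harmonize(exposure, outcome)
        assert hs.table.loc[0, "beta_y"] == pytest.approx(0.4)

    def test_intermediate_frequency_palindrome_excluded(self):
        exposure = make_dataset(
            rows=[("rs1", "1", 1000, "A", "T", 0.45, 0.3, 0.02, 1e-50, 100)]
        )
        outcome = _aligned_outcome(exposure, 0.2)
        hs = harmonize(exposure, outcome, palindrome_maf_limit=0.3)
        assert len(hs) == 0
        assert list(hs.exclusions["reason"]) == ["palindrome_ambiguous"]

    def test_low_frequency_palindrome_aligned_by_frequency(self):
        exposure = make_dataset(
            rows=[("rs1", "1", 1000, "A", "T", 0.1, 0.3, 0.02, 1e-50, 100)]
        )
        # outcome reports the other side of 0.5 -> effect allele is the complement
        outcome = make_dataset(
            trait_id="out",
            trait_type="outcome",
            rows=[("rs1", "1", 1000, "A", "T", 0.9, 0.2, 0.05, 1e-8, 100)],
        )
        hs = harmonize(exposure, outcome)
        assert hs.table.loc[0, "beta_y"] == pytest.approx(-0.2)

    def test_weak_instruments_logged(self):
        exposure = make_dataset(
            rows=[("rs1", "1", 1000, "A", "G", 0.3, 0.01, 0.02, 0.5, 100)]
        )
        outcome = _aligned_outcome(exposure, 0.2)
        hs = harmonize(exposure, outcome, f_min=10)
        assert list(hs.exclusions["reason"]) == ["weak_instrument"]

    def test_unmatched_and_mismatch_reasons(self):
        exposure = make_dataset(
            rows=[
                ("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.02, 1e-50, 100),
                ("rs2", "1", 2000, "A", "G", 0.3, 0.3, 0.02, 1e-50, 100),
            ]
        )
        outcome = make_dataset(
            trait_id="out",
            trait_type="outcome",
            rows=[("rs1", "1", 1000, "A", "C", 0.3, 0.2, 0.05, 1e-8, 100)],
        )
        hs = harmonize(exposure, outcome)
        reasons = dict(zip(hs.exclusions["variant_id"], hs.exclusions["reason"]))
        assert reasons == {"rs1": "allele_mismatch", "rs2": "unmatched"}

    def test_every_variant_accounted_for(self, rng):
        from micromr.simulate import UnivariableSimSpec, simulate_univariable

        exp, out, _, _ = simulate_univariable(UnivariableSimSpec(seed=11))
        hs = harmonize(exp, out)
        accounted = set(hs.table["variant_id"]) | set(hs.exclusions["variant_id"])
        assert accounted == set(exp.table["variant_id"])
        assert len(hs.table) + len(hs.exclusions) == len(exp)

    def test_idempotence(self):
        from micromr.simulate import UnivariableSimSpec, simulate_univariable

        exp, out, _, _ = simulate_univariable(UnivariableSimSpec(seed=5))
        hs = harmonize(exp, out)
        # feed the harmonized pair back in, in the exposure's coding
        exp2 = exp.with_table(
            exp.table[exp.table["variant_id"].isin(hs.table["variant_id"])]
        )
        out2_table = exp2.table.copy()
        aligned = hs.table.set_index("variant_id")
        out2_table["beta"] = aligned.loc[out2_table["variant_id"], "beta_y"].to_numpy()
        out2_table["se"] = aligned.loc[out2_table["variant_id"], "se_y"].to_numpy()
        out2 = SummaryDataset("out", "outcome", out2_table)
        hs2 = harmonize(exp2, out2)
        pd.testing.assert_frame_equal(
            hs.table.reset_index(drop=True), hs2.table.reset_index(drop=True)
        )

    def test_allele_recode_invariance(self):
        from micromr.simulate import UnivariableSimSpec, simulate_univariable

        exp, out, _, _ = simulate_univariable(
            UnivariableSimSpec(seed=5, palindromic_fraction=0.0)
        )
        flipped = out.table.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            out.table["other_allele"],
            out.table["effect_allele"],
        )
        flipped["beta"] = -out.table["beta"]
        flipped["eaf"] = 1 - out.table["eaf"]
        hs1 = harmonize(exp, out)
        hs2 = harmonize(exp, SummaryDataset("out", "outcome", flipped))
        pd.testing.assert_frame_equal(hs1.table, hs2.table)


class TestLDClump:
    @staticmethod
    def _ld(vids, r, positions):
        return LDMatrix(vids, r, positions)

    def test_dominant_pair_keeps_smaller_p(self):
        ds = make_dataset(
            rows=[
                ("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.02, 1e-8, 100),
                ("rs2", "1", 2000, "C", "T", 0.4, 0.2, 0.02, 1e-6, 100),
            ]
        )
        r = np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        ld = self._ld(["rs1", "rs2"], r, ds.table[["variant_id", "chrom", "pos"]])
        out = ld_clump(ds, ld, r2_threshold=0.01, window_kb=10)
        assert list(out.table["variant_id"]) == ["rs1"]

    def test_independent_variants_all_kept(self, toy_dataset):
        ld = LDMatrix.identity(
            list(toy_dataset.table["variant_id"]),
            toy_dataset.table[["variant_id", "chrom", "pos"]],
        )
        out = ld_clump(toy_dataset, ld)
        assert len(out) == 3

    def test_matches_brute_force_greedy(self, rng):
        j = 20
        vids = [f"rs{i}" for i in range(j)]
        pos = rng.integers(1, 5_000_000, j)
        rows = [
            (vids[i], "1", int(pos[i]), "A", "G", 0.3, 0.1, 0.02,
             float(rng.uniform(1e-10, 1e-2)), 100)
            for i in range(j)
        ]
        ds = make_dataset(rows=rows)
        # random block LD
        blocks = rng.integers(0, 4, j)
        r = np.array(
            [[0.8 if blocks[i] == blocks[k] and i != k else 0.0 for k in range(j)] for i in range(j)]
        ) + np.eye(j)
        ld = LDMatrix(vids, r, ds.table[["variant_id", "chrom", "pos"]])

        out = ld_clump(ds, ld, 0.01, 10_000)

        # brute-force greedy on the same ordering
        order = ds.table.sort_values(["pval", "chrom", "pos", "variant_id"], kind="mergesort")
        posmap = dict(zip(ds.table["variant_id"], ds.table["pos"]))
        kept, removed = [], set()
        for vid in order["variant_id"]:
            if vid in removed:
                continue
            kept.append(vid)
            for other in order["variant_id"]:
                if other in removed or other in kept:
                    continue
                if abs(posmap[other] - posmap[vid]) <= 10_000_000 and ld.r2(vid, other) >= 0.01:
                    removed.add(other)
        assert set(out.table["variant_id"]) == set(kept)

    def test_output_pairwise_below_threshold(self, rng):
        j = 15
        vids = [f"rs{i}" for i in range(j)]
        rows = [
            (vids[i], "1", 1000 + i * 100, "A", "G", 0.3, 0.1, 0.02,
             float(rng.uniform(1e-10, 1e-2)), 100)
            for i in range(j)
        ]
        ds = make_dataset(rows=rows)
        a = rng.normal(size=(j, j + 5))
        r = np.corrcoef(a)
        ld = LDMatrix(vids, r, ds.table[["variant_id", "chrom", "pos"]])
        out = ld_clump(ds, ld, 0.1, 10_000)
        kept = list(out.table["variant_id"])
        for a_, b_ in itertools.combinations(kept, 2):
            assert ld.r2(a_, b_) < 0.1

    def test_missing_variant_raises(self, toy_dataset):
        ld = LDMatrix.identity(["rs1", "rs2"], toy_dataset.table[["variant_id", "chrom", "pos"]])
        with pytest.raises(KeyError, match="rs3"):
            ld_clump(toy_dataset, ld)


def test_ld_matrix_round_trip(tmp_path, toy_dataset):
    from micromr.gwas_io import read_ld_matrix, write_ld_matrix

    vids = list(toy_dataset.table["variant_id"])
    r = np.array([[1.0, 0.2, 0.0], [0.2, 1.0, 0.1], [0.0, 0.1, 1.0]])
    ld = LDMatrix(vids, r, toy_dataset.table[["variant_id", "chrom", "pos"]])
    write_ld_matrix(ld, tmp_path / "ld.tsv", tmp_path / "pos.tsv")
    back = read_ld_matrix(tmp_path / "ld.tsv", tmp_path / "pos.tsv")
    assert back.variant_ids == vids
    np.testing.assert_allclose(back.r, r)


def test_exclusion_list_reader(tmp_path):
    from micromr.gwas_io import read_exclusion_list

    path = tmp_path / "excl.txt"
    path.write_text("# manual screen\nrs1\nrs2\tsecondary-trait hit\n\nrs3\n")
    assert read_exclusion_list(path) == ["rs1", "rs2", "rs3"]


class TestExclusionList:
    def test_present_id_removed(self, toy_dataset):
        out = apply_exclusion_list(toy_dataset, ["rs2"], "secondary_trait")
        assert len(out) == 2
        assert out.audit["excluded_secondary_trait"] == 1

    def test_absent_id_noop(self, toy_dataset):
        out = apply_exclusion_list(toy_dataset, ["rs999"], "secondary_trait")
        assert len(out) == 3
        assert out.audit["excluded_secondary_trait_noop"] == 1

    def test_exclude_all(self, toy_dataset):
        out = apply_exclusion_list(toy_dataset, ["rs1", "rs2", "rs3"])
        assert len(out) == 0
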