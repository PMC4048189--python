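import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoscreen import (
    InsufficientDataError,
    InsufficientReferenceError,
    ScreenConfig,
    export_screen_tables,
    gene_dataset_summary,
    normal_reference,
    read_screen_tables,
    recompute_marked,
    sample_fold_calls,
    screen_collection,
    tumor_vs_adjacent_test,
)
from mitoscreen.screen import mark_overexpressed

from conftest import make_gene_matrix

T2N2 = ["tumor", "tumor", "normal_liver", "normal_liver"]


# ---------------------------------------------------------------------------
# Brute-force per-sample oracle (naive double loops, scipy t test)
# ---------------------------------------------------------------------------

def oracle_screen(gms, genes, cfg):
    """Naive reimplementation of the screen for small instances."""
    per_ds = {}
    for ds_id, gm in gms.items():
        rows = {}
        tumors = [s for s in gm.sample_ids if gm.sample_group[s] == "tumor"]
        refs = [s for s in gm.sample_ids if gm.sample_group[s] == cfg.reference_group]
        for g in genes:
            if g not in gm.values.index:
                rows[g] = dict(fold=np.nan, freq=np.nan, present=False)
                continue
            ref_vals = [gm.values.loc[g, s] for s in refs
                        if not np.isnan(gm.values.loc[g, s])]
            tum_vals = [gm.values.loc[g, s] for s in tumors
                        if not np.isnan(gm.values.loc[g, s])]
            if len(ref_vals) < 2 or len(tum_vals) < 1:
                rows[g] = dict(fold=np.nan, freq=np.nan, present=False)
                continue
            ref = (np.mean(ref_vals) if cfg.reference_stat == "mean"
                   else np.median(ref_vals))
            n_call = 0
            for v in tum_vals:
                if 2.0 ** (v - ref) >= cfg.fold_threshold:
                    n_call += 1
            rows[g] = dict(
                fold=2.0 ** (np.mean(tum_vals) - ref),
                freq=n_call / len(tum_vals),
                present=True,
            )
        per_ds[ds_id] = rows
    marked = {}
    for g in genes:
        passes, present = 0, 0
        for ds_id in gms:
            r = per_ds[ds_id][g]
            if not r["present"]:
                continue
            present += 1
            ok = r["freq"] >= cfg.freq_threshold
            if cfg.require_dataset_fold:
                ok = ok and r["fold"] >= cfg.fold_threshold
            passes += ok
        if present == 0:
            marked[g] = False
        elif cfg.min_datasets_rule == "all_present":
            marked[g] = passes == present
        else:
            marked[g] = passes > present / 2.0
    return per_ds, marked


def _random_gms(rng, n_datasets=2, n_genes=12, n_tumor=6, n_normal=4, na_rate=0.1):
    genes = list(range(101, 101 + n_genes))
    gms = {}
    for d in range(n_datasets):
        vals = rng.normal(8, 1.5, size=(n_genes, n_tumor + n_normal))
        vals[rng.random(vals.shape) < na_rate] = np.nan
        # drop a couple of genes entirely from this dataset
        drop = rng.choice(n_genes, size=2, replace=False)
        vals[drop, :] = np.nan
        gms[f"d{d}"] = make_gene_matrix(
            vals, ["tumor"] * n_tumor + ["normal_liver"] * n_normal,
            genes=genes, dataset_id=f"d{d}",
            samples=[f"d{d}s{j}" for j in range(n_tumor + n_normal)],
        )
    return gms, genes


class TestNormalReference:
    def test_constant_reference(self):
        gm = make_gene_matrix([[9, 3, 3, 3]], ["tumor"] + ["normal_liver"] * 3,
                              genes=[7272])
        cfg = ScreenConfig()
        assert normal_reference(gm, 7272, cfg) == 3.0

    @pytest.mark.parametrize("stat,expected", [("mean", 3.0), ("median", 3.0)])
    def test_mean_and_median_stats(self, stat, expected):
        gm = make_gene_matrix([[9, 2, 4]], ["tumor", "normal_liver", "normal_liver"],
                              genes=[7272])
        assert normal_reference(gm, 7272, ScreenConfig(reference_stat=stat)) == expected

    def test_missing_reference_values_excluded(self):
        gm = make_gene_matrix([[9, 5, np.nan, 7]],
                              ["tumor"] + ["normal_liver"] * 3, genes=[7272])
        assert normal_reference(gm, 7272, ScreenConfig()) == 6.0

    def test_fewer_than_two_reference_samples_errors(self):
        gm = make_gene_matrix([[9, 5, np.nan, np.nan]],
                              ["tumor"] + ["normal_liver"] * 3, genes=[7272])
        with pytest.raises(InsufficientReferenceError):
            normal_reference(gm, 7272, ScreenConfig())


class TestSampleFoldCalls:
    def test_fold_and_call(self):
        gm = make_gene_matrix([[4.1, 3.0, 3.0, 3.0]],
                              ["tumor"] + ["normal_liver"] * 3, genes=[1])
        out = sample_fold_calls(gm, 1, ScreenConfig())
        assert out.loc["s1", "fold"] == pytest.approx(2.0 ** 1.1)
        assert bool(out.loc["s1", "call"]) is True

    def test_identity_fold_not_called(self):
        gm = make_gene_matrix([[3.0, 3.0, 3.0]], ["tumor"] + ["normal_liver"] * 2,
                              genes=[1])
        out = sample_fold_calls(gm, 1, ScreenConfig())
        assert out.loc["s1", "fold"] == 1.0
        assert bool(out.loc["s1", "call"]) is False

    def test_threshold_exactly_met_is_inclusive(self):
        """'no less than 2-fold' includes fold == 2.0 exactly."""
        gm = make_gene_matrix([[4.0, 3.0, 3.0]], ["tumor"] + ["normal_liver"] * 2,
                              genes=[1])
        out = sample_fold_calls(gm, 1, ScreenConfig())
        assert out.loc["s1", "fold"] == 2.0
        assert bool(out.loc["s1", "call"]) is True

    def test_missing_tumor_values_excluded(self):
        gm = make_gene_matrix([[4.0, np.nan, 3.0, 3.0]], T2N2, genes=[1])
        out = sample_fold_calls(gm, 1, ScreenConfig())
        assert list(out.index) == ["s1"]


class TestGeneDatasetSummary:
    def test_fold_and_full_frequency(self):
        gm = make_gene_matrix([[5.0, 5.0, 3.0, 3.0]], T2N2, genes=[1])
        s = gene_dataset_summary(gm, 1, ScreenConfig())
        assert s["fold"] == 4.0
        assert s["freq"] == 1.0
        assert s["present"]

    def test_t_statistic_matches_closed_form(self):
        gm = make_gene_matrix(
            [[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]],
            ["tumor"] * 3 + ["normal_liver"] * 3, genes=[1],
        )
        s = gene_dataset_summary(gm, 1, ScreenConfig())
        # independent oracle: scipy on the same two triples
        t_ref, p_ref = sps.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert t_ref == pytest.approx(-1.224744871391589, abs=1e-12)
        assert s["p_value"] == pytest.approx(p_ref, abs=1e-12)
        assert s["p_value"] == pytest.approx(0.2879, abs=5e-4)

    def test_degenerate_identical_groups(self):
        gm = make_gene_matrix([[3.0, 3.0, 3.0, 3.0]], T2N2, genes=[1])
        s = gene_dataset_summary(gm, 1, ScreenConfig())
        assert s["fold"] == 1.0
        assert s["p_value"] == 1.0
        assert s["zero_variance"]

    def test_absent_gene_reported_not_present(self):
        gm = make_gene_matrix([[3.0, 3.0, 3.0, 3.0]], T2N2, genes=[1])
        s = gene_dataset_summary(gm, 99, ScreenConfig())
        assert s["present"] is False and np.isnan(s["fold"])


class TestMarkOverexpressed:
    def _frames(self, rows):
        """rows: gene -> list of (fold, freq, present) per dataset."""
        ids = [f"d{i}" for i in range(len(next(iter(rows.values()))))]
        out = {}
        for i, d in enumerate(ids):
            out[d] = pd.DataFrame({
                "fold": {g: r[i][0] for g, r in rows.items()},
                "freq": {g: r[i][1] for g, r in rows.items()},
                "p_value": {g: np.nan for g in rows},
                "present": {g: r[i][2] for g, r in rows.items()},
                "zero_variance": {g: False for g in rows},
            })
        return out

    def test_strong_gene_marked_under_every_rule(self):
        rows = {1: [(4.0, 0.5, True), (3.0, 0.4, True), (2.5, 0.35, True)]}
        for rule in ("all_present", "majority_present"):
            res = mark_overexpressed(
                self._frames(rows), ScreenConfig(min_datasets_rule=rule)
            )
            assert bool(res.marked[1])

    def test_frequency_gate_fails(self):
        rows = {1: [(2.5, 0.25, True), (2.5, 0.25, True), (2.5, 0.25, True)]}
        res = mark_overexpressed(self._frames(rows), ScreenConfig())
        assert not bool(res.marked[1])

    def test_majority_vs_all_present(self):
        rows = {1: [(4.0, 0.5, True), (4.0, 0.5, True), (1.2, 0.1, True)]}
        maj = mark_overexpressed(
            self._frames(rows), ScreenConfig(min_datasets_rule="majority_present")
        )
        allp = mark_overexpressed(
            self._frames(rows), ScreenConfig(min_datasets_rule="all_present")
        )
        assert bool(maj.marked[1]) and not bool(allp.marked[1])

    def test_absent_everywhere_not_marked(self):
        rows = {1: [(np.nan, np.nan, False), (np.nan, np.nan, False)]}
        res = mark_overexpressed(self._frames(rows), ScreenConfig())
        assert not bool(res.marked[1])

    def test_dataset_fold_gate_optional(self):
        # freq passes but dataset-level mean fold sits below 2
        rows = {1: [(1.8, 0.5, True), (1.9, 0.6, True)]}
        default = mark_overexpressed(self._frames(rows), ScreenConfig())
        strict = mark_overexpressed(
            self._frames(rows), ScreenConfig(require_dataset_fold=True)
        )
        assert bool(default.marked[1]) and not bool(strict.marked[1])


class TestTumorVsAdjacent:
    def test_matches_scipy_oracle(self):
        gm = make_gene_matrix(
            [[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]],
            ["tumor"] * 3 + ["adjacent_nontumor"] * 3, genes=[1],
        )
        r = tumor_vs_adjacent_test(gm, 1)
        _, p_ref = sps.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_identical_constant_groups_flagged(self):
        gm = make_gene_matrix(
            [[3.0, 3.0, 3.0, 3.0]],
            ["tumor", "tumor", "adjacent_nontumor", "adjacent_nontumor"], genes=[1],
        )
        r = tumor_vs_adjacent_test(gm, 1)
        assert r.p_value == 1.0 and r.zero_variance

    def test_identical_distributions_give_p_one(self):
        gm = make_gene_matrix(
            [[2.0, 3.0, 2.0, 3.0]],
            ["tumor", "tumor", "adjacent_nontumor", "adjacent_nontumor"], genes=[1],
        )
        r = tumor_vs_adjacent_test(gm, 1)
        assert r.p_value == 1.0 and not r.zero_variance

    def test_single_adjacent_sample_errors(self):
        gm = make_gene_matrix(
            [[2.0, 3.0, 2.0]], ["tumor", "tumor", "adjacent_nontumor"], genes=[1],
        )
        with pytest.raises(InsufficientDataError):
            tumor_vs_adjacent_test(gm, 1)

    def test_paired_variant_matches_scipy(self):
        gm = make_gene_matrix(
            [[5.0, 6.0, 7.0, 4.0, 4.5, 6.5]],
            ["tumor"] * 3 + ["adjacent_nontumor"] * 3, genes=[1],
            samples=["t1", "t2", "t3", "a1", "a2", "a3"],
            pairing={"t1": "a1", "t2": "a2", "t3": "a3"},
        )
        r = tumor_vs_adjacent_test(gm, 1, paired=True)
        _, p_ref = sps.ttest_rel([5, 6, 7], [4, 4.5, 6.5])
        assert r.p_value == pytest.approx(p_ref, abs=1e-12)


class TestScreenCollectionProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("rule", ["all_present", "majority_present"])
    def test_oracle_equivalence_small_instances(self, seed, rule):
        """A naive per-sample double loop reproduces fold, freq, marked."""
        rng = np.random.default_rng(seed)
        gms, genes = _random_gms(rng)
        cfg = ScreenConfig(min_datasets_rule=rule)
        res = screen_collection(gms, genes, cfg)
        per_ds, marked = oracle_screen(gms, genes, cfg)
        for ds_id, rows in per_ds.items():
            for g, r in rows.items():
                assert bool(res.present.loc[g, ds_id]) == r["present"]
                if r["present"]:
                    assert res.fold.loc[g, ds_id] == pytest.approx(r["fold"], rel=1e-12)
                    assert res.freq.loc[g, ds_id] == pytest.approx(r["freq"], abs=1e-12)
        for g in genes:
            assert bool(res.marked[g]) == marked[g]

    def test_offset_invariance_of_calls(self):
        """Per-sample constant shifts before median normalization change
        no overexpression call."""
        from mitoscreen import median_normalize
        rng = np.random.default_rng(7)
        gms, genes = _random_gms(rng, n_datasets=1, na_rate=0.0)
        gm = gms["d0"]
        cfg = ScreenConfig()
        base = screen_collection({"d0": median_normalize(gm)}, genes, cfg)
        shifted_vals = gm.values + rng.normal(0, 3, size=gm.values.shape[1])
        shifted = make_gene_matrix(
            shifted_vals.to_numpy(), list(gm.sample_group), genes=list(gm.gene_ids),
            samples=list(gm.sample_ids), dataset_id="d0",
        )
        res = screen_collection({"d0": median_normalize(shifted)}, genes, cfg)
        pd.testing.assert_frame_equal(base.passed, res.passed)
        assert np.allclose(
            base.freq.to_numpy(), res.freq.to_numpy(), equal_nan=True, atol=1e-12
        )

    def test_marked_set_shrinks_as_thresholds_rise(self):
        rng = np.random.default_rng(11)
        gms, genes = _random_gms(rng, n_genes=15)
        base = screen_collection(gms, genes, ScreenConfig())
        for cfg in (
            ScreenConfig(fold_threshold=3.0),
            ScreenConfig(freq_threshold=0.5),
        ):
            tighter = screen_collection(gms, genes, cfg)
            assert set(tighter.marked[tighter.marked].index) <= set(
                base.marked[base.marked].index
            )
            # freq non-increasing in fold_threshold
            if cfg.fold_threshold > 2.0:
                both = base.freq.notna() & tighter.freq.notna()
                ok = (tighter.freq <= base.freq + 1e-12) | ~both
                assert ok.all().all()

    def test_fold_one_when_means_equal(self):
        gm = make_gene_matrix([[4.0, 2.0, 3.0, 3.0]], T2N2, genes=[1])
        s = gene_dataset_summary(gm, 1, ScreenConfig())
        assert s["fold"] == pytest.approx(1.0)

    def test_pooled_rule_runs_and_matches_manual_pool(self):
        rng = np.random.default_rng(3)
        gms, genes = _random_gms(rng, na_rate=0.0)
        res = screen_collection(gms, genes, ScreenConfig(min_datasets_rule="pooled"))
        assert res.marked.dtype == bool
        assert set(res.marked.index) == set(genes)


class TestExportImport:
    def test_roundtrip_reproduces_marked_flags(self, tmp_path):
        rng = np.random.default_rng(5)
        gms, genes = _random_gms(rng)
        cfg = ScreenConfig()
        res = screen_collection(gms, genes, cfg)
        export_screen_tables(res, tmp_path)
        back = read_screen_tables(tmp_path)
        # recompute passes and marks from the exported cells alone
        freq = back["freq"]
        fold = back["fold"]
        present = freq.notna() & fold.notna()
        passed = (freq >= cfg.freq_threshold) & present
        n_present = present.sum(axis=1)
        remarked = (n_present > 0) & (passed.sum(axis=1) > n_present / 2.0)
        marked_col = back["marked_genes"].set_index("entrez_id")["marked"]
        assert (remarked == marked_col.reindex(remarked.index)).all()

    def test_absent_gene_exported_as_na(self, tmp_path):
        gm = make_gene_matrix([[5.0, 5.0, 3.0, 3.0]], T2N2, genes=[1])
        res = screen_collection({"d0": gm}, [1, 2], ScreenConfig())
        export_screen_tables(res, tmp_path)
        text = (tmp_path / "fold_matrix.tsv").read_text()
        assert "NA" in text.splitlines()[2]

    def test_recompute_marked_matches_stored(self):
        rng = np.random.default_rng(13)
        gms, genes = _random_gms(rng)
        res = screen_collection(gms, genes, ScreenConfig())
        assert (recompute_marked(res) == res.marked).all()
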