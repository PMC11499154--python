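import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonoscape import molecules as mo
from clonoscape import synthetic as sy

from .oracles import collapse_oracle, knee_by_largest_drop, random_umi_group


def one_group(counts: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        [("c1", u, "G1", r) for u, r in counts.items()],
        columns=["cell_label", "umi", "feature", "reads"],
    )


def as_counts(df: pd.DataFrame) -> dict[str, int]:
    return dict(zip(df["umi"], df["reads"]))


class TestRsec:
    def test_simple_merge(self):
        out = mo.rsec_correct(one_group({"AAAA": 10, "AAAT": 1}))
        assert as_counts(out) == {"AAAA": 11}

    def test_single_umi_unchanged(self):
        out = mo.rsec_correct(one_group({"ACGT": 7}))
        assert as_counts(out) == {"ACGT": 7}

    def test_recursive_chain(self):
        # AATT -> AAAT (3 >= 2*1-1), then AAAT:4 -> AAAA (8 >= 2*4-1)
        out = mo.rsec_correct(one_group({"AAAA": 8, "AAAT": 3, "AATT": 1}))
        assert as_counts(out) == {"AAAA": 12}

    def test_parent_rule_blocks_merge(self):
        # 2 >= 2*2-1 = 3 fails: equal 2-read neighbours stay apart
        out = mo.rsec_correct(one_group({"AAAA": 2, "AAAT": 2}))
        assert as_counts(out) == {"AAAA": 2, "AAAT": 2}
        # 4 >= 2*3-1 = 5 fails too
        out = mo.rsec_correct(one_group({"AAAA": 4, "AAAT": 3}))
        assert as_counts(out) == {"AAAA": 4, "AAAT": 3}

    def test_equal_singletons_merge_to_smaller_umi(self):
        # 1 >= 2*1-1 holds; ties break toward the lexicographically smaller UMI
        out = mo.rsec_correct(one_group({"AAAT": 1, "AAAA": 1}))
        assert as_counts(out) == {"AAAA": 2}

    def test_groups_are_independent(self):
        df = pd.DataFrame(
            [
                ("c1", "AAAA", "G1", 10),
                ("c1", "AAAT", "G2", 1),  # different feature: no merge
                ("c2", "AAAT", "G1", 1),  # different cell: no merge
            ],
            columns=["cell_label", "umi", "feature", "reads"],
        )
        out = mo.rsec_correct(df)
        assert len(out) == 3
        assert out["reads"].sum() == 12

    def test_unequal_umi_lengths_rejected(self):
        df = one_group({"AAAA": 5})
        df.loc[len(df)] = ("c1", "AAAAA", "G1", 1)
        with pytest.raises(ValueError, match="unequal length"):
            mo.rsec_correct(df)

    def test_conserves_reads_and_shrinks(self, small_config):
        mol, _ = sy.generate_molecule_table(small_config)
        gene, _ = sy.split_tag_molecules(mol)
        out = mo.rsec_correct(gene)
        assert out["reads"].sum() == gene["reads"].sum()
        assert len(out) <= len(gene)
        g_in = gene.groupby(["cell_label", "feature"])["reads"].sum()
        g_out = out.groupby(["cell_label", "feature"])["reads"].sum()
        pd.testing.assert_series_equal(g_in.sort_index(), g_out.sort_index())

    def test_zero_error_data_untouched(self, clean_config):
        mol, truth = sy.generate_molecule_table(clean_config)
        assert truth.true_umi_parent == {}
        gene, _ = sy.split_tag_molecules(mol)
        out = mo.rsec_correct(gene)
        # random Hamming-1 collisions are possible but reads are conserved
        assert out["reads"].sum() == gene["reads"].sum()

    def test_reattaches_planted_errors(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        assert truth.true_umi_parent  # errors were planted
        gene, _ = sy.split_tag_molecules(mol)
        out = mo.rsec_correct(gene)
        out_keys = set(
            zip(out["cell_label"], out["feature"], out["umi"])
        )
        gone = sum(
            (cell, feat, umi) not in out_keys
            for (cell, feat, umi) in truth.true_umi_parent
        )
        # every planted error satisfies the parent rule by construction
        assert gone == len(truth.true_umi_parent)

    @settings(deadline=None, max_examples=150)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_umi_group(rng)
        got = as_counts(mo.rsec_correct(one_group(counts)))
        assert got == collapse_oracle(counts)


class TestDbec:
    def test_bimodal_low_class_removed(self):
        df = one_group(dict(zip(["AAAA", "CCCC", "GGGG", "TTTT", "ACGT", "TGCA"],
                                [1, 1, 1, 9, 10, 11])))
        res = mo.dbec_filter(df)
        assert sorted(res.kept["reads"]) == [9, 10, 11]
        assert sorted(res.removed["reads"]) == [1, 1, 1]
        assert res.status == {"G1": "corrected"}

    def test_unimodal_unchanged(self):
        df = one_group(dict(zip(["AAAA", "CCCC", "GGGG", "TTTT"], [5, 6, 5, 7])))
        res = mo.dbec_filter(df)
        assert len(res.removed) == 0
        assert res.status == {"G1": "pass"}

    def test_single_molecule_unchanged(self):
        res = mo.dbec_filter(one_group({"AAAA": 3}))
        assert len(res.removed) == 0
        assert res.status == {"G1": "pass"}

    def test_empty_table(self):
        res = mo.dbec_filter(one_group({}))
        assert len(res.kept) == 0 and len(res.removed) == 0

    def test_tuple_unpacking(self):
        kept, removed = mo.dbec_filter(one_group({"AAAA": 3}))
        assert len(kept) == 1 and len(removed) == 0

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_never_removes_top_molecule(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        reads = rng.integers(1, 200, size=n)
        umis = ["".join("ACGT"[int(c)] for c in np.base_repr(i, 4).zfill(4)) for i in range(n)]
        df = one_group(dict(zip(umis, reads.tolist())))
        res = mo.dbec_filter(df)
        assert res.kept["reads"].max() == df["reads"].max()


class TestCallCells:
    def test_knee_on_planted_fixture(self):
        cfg = sy.SimConfig(
            seed=2, n_real_cells=100, n_noise_barcodes=900,
            reads_per_real_cell=2000, reads_per_noise_barcode=20,
            n_clonotypes=60, umi_error_rate=0.0, multiplet_rate=0.0,
            tag_noise_rate=0.0,
        )
        mol, truth = sy.generate_molecule_table(cfg)
        gene, _ = sy.split_tag_molecules(mol)
        res = mo.call_cells(gene)
        assert res.n_valid == 100
        assert res.inflection_rank == 100
        assert set(res.valid_labels) == truth.real_cells
        # agrees with the brute-force largest log-log drop oracle
        totals = gene.groupby("cell_label")["reads"].sum().to_numpy()
        assert knee_by_largest_drop(totals) == 100

    def test_flat_curve_no_knee(self, molecules_factory):
        df = molecules_factory(
            [(f"c{i}", "AAAA", "G1", 50) for i in range(20)]
        )
        res = mo.call_cells(df)
        assert res.inflection_rank is None
        assert res.n_valid == 20

    def test_permutation_invariance(self, small_config):
        mol, _ = sy.generate_molecule_table(small_config)
        gene, _ = sy.split_tag_molecules(mol)
        res1 = mo.call_cells(gene)
        shuffled = gene.sample(frac=1.0, random_state=99).reset_index(drop=True)
        res2 = mo.call_cells(shuffled)
        assert res1.valid_labels == res2.valid_labels
        assert res1.inflection_rank == res2.inflection_rank

    def test_too_few_labels_rejected(self, molecules_factory):
        df = molecules_factory([("c1", "AAAA", "G1", 5), ("c2", "AAAT", "G1", 3)])
        with pytest.raises(ValueError, match=">= 3"):
            mo.call_cells(df)


class TestDemultiplex:
    def mk(self, counts_by_cell):
        rows = []
        for cell, tag_counts in counts_by_cell.items():
            for i, (tag, c) in enumerate(tag_counts.items()):
                if c > 0:
                    rows.append((cell, f"{'ACGT'[i % 4] * 4}", tag, c))
        return pd.DataFrame(rows, columns=["cell_label", "umi", "feature", "reads"])

    def test_singlet(self):
        df = self.mk({"c1": {"S1": 50, "S2": 1, "S3": 0}})
        res = mo.demultiplex(df, {"c1"}, thresholds={"S1": 5, "S2": 5, "S3": 5})
        assert res.assignment == {"c1": "S1"}

    def test_multiplet(self):
        df = self.mk({"c1": {"S1": 50, "S2": 45, "S3": 0}})
        res = mo.demultiplex(df, {"c1"}, thresholds={"S1": 5, "S2": 5, "S3": 5})
        assert res.assignment == {"c1": "multiplet"}

    def test_undetermined_zero_counts(self):
        df = self.mk({"c1": {"S1": 50}})
        res = mo.demultiplex(df, {"c1", "c2"}, thresholds={"S1": 5})
        assert res.assignment["c2"] == "undetermined"

    def test_below_threshold_undetermined(self):
        df = self.mk({"c1": {"S1": 3, "S2": 2}})
        res = mo.demultiplex(df, {"c1"}, thresholds={"S1": 5, "S2": 5})
        assert res.assignment == {"c1": "undetermined"}

    def test_thresholds_from_noise_distribution(self, clean_config):
        mol, truth = sy.generate_molecule_table(clean_config)
        _, tags = sy.split_tag_molecules(mol)
        res = mo.demultiplex(tags, truth.real_cells)
        assert res.assignment == truth.cell_to_sample

    def test_multiplet_rate_recovered(self):
        cfg = sy.SimConfig(
            seed=17, n_real_cells=3000, n_noise_barcodes=100,
            n_clonotypes=1500, multiplet_rate=0.06,
        )
        mol, truth = sy.generate_molecule_table(cfg)
        _, tags = sy.split_tag_molecules(mol)
        res = mo.demultiplex(tags, truth.real_cells)
        observed = res.n_multiplets / len(truth.real_cells)
        assert abs(observed - cfg.multiplet_rate) <= 0.02
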