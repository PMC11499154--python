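import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonoscape import synthetic as sy
from clonoscape.cytotoxicity import percent_cytotoxicity

from .oracles import knee_by_largest_drop


class TestSimConfig:
    def test_defaults_valid(self):
        sy.SimConfig().validate()

    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("umi_error_rate", 1.5, "umi_error_rate"),
            ("multiplet_rate", -0.1, "multiplet_rate"),
            ("dominant_clone_size", 2, "dominant_clone_size"),
            ("reads_per_noise_barcode", 500.0, "reads_per_real_cell"),
            ("panel_genes", ("CD8", "CD4"), "FOXP3"),
            ("n_real_cells", 5, "n_real_cells"),
        ],
    )
    def test_invariant_violations_named(self, field, value, match):
        cfg = dataclasses.replace(sy.SimConfig(), **{field: value})
        with pytest.raises(ValueError, match=match):
            cfg.validate()

    def test_generator_rejects_invalid_config(self):
        cfg = dataclasses.replace(sy.SimConfig(), umi_error_rate=2.0)
        with pytest.raises(ValueError, match="umi_error_rate"):
            sy.generate_molecule_table(cfg)


class TestMoleculeGeneration:
    def test_zero_error_rate_identity_parent_map(self, clean_config):
        _, truth = sy.generate_molecule_table(clean_config)
        assert truth.true_umi_parent == {}

    def test_determinism(self, small_config):
        m1, t1 = sy.generate_molecule_table(small_config)
        m2, t2 = sy.generate_molecule_table(small_config)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1.cell_to_sample == t2.cell_to_sample
        assert t1.clonotype_of_cell == t2.clonotype_of_cell
        assert t1.true_umi_parent == t2.true_umi_parent
        assert t1.true_affinity == t2.true_affinity

    def test_knee_position_by_bruteforce_scan(self):
        cfg = sy.SimConfig(
            seed=4, n_real_cells=100, n_noise_barcodes=900,
            reads_per_real_cell=2000, reads_per_noise_barcode=20,
            n_clonotypes=60,
        )
        mol, _ = sy.generate_molecule_table(cfg)
        gene, _ = sy.split_tag_molecules(mol)
        totals = gene.groupby("cell_label")["reads"].sum().to_numpy()
        assert knee_by_largest_drop(totals) == 100

    def test_error_umis_hamming1_and_low_reads(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        assert len(truth.true_umi_parent) > 0
        reads = mol.set_index(["cell_label", "feature", "umi"])["reads"]
        for (cell, feat, obs), parent in truth.true_umi_parent.items():
            assert sum(a != b for a, b in zip(obs, parent)) == 1
            assert reads[(cell, feat, obs)] <= reads[(cell, feat, parent)] // 2

    def test_table_invariants(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        assert not mol.duplicated(["cell_label", "umi", "feature"]).any()
        assert (mol["reads"] >= 1).all()
        assert mol["umi"].str.len().nunique() == 1
        # every real cell is in the sample map and the dominant clone is
        # strictly largest
        truth.validate()
        sizes = truth.clone_sizes()
        dom = sizes[truth.dominant_clonotype_id]
        others = [v for k, v in sizes.items() if k != truth.dominant_clonotype_id]
        assert dom == small_config.dominant_clone_size
        assert dom >= max(others) + 2

    def test_noise_barcodes_read_depleted(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        gene, _ = sy.split_tag_molecules(mol)
        totals = gene.groupby("cell_label")["reads"].sum()
        real = totals[totals.index.isin(truth.real_cells)]
        noise = totals[~totals.index.isin(truth.real_cells)]
        assert real.min() > noise.max()


class TestAirrGeneration:
    def test_dominant_clone_cell_count(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        airr = sy.generate_airr_table(small_config, truth)
        trb = airr[airr["locus"] == "TRB"]
        counts = trb.groupby("sequence_aa")["cell_id"].nunique()
        dom_cells = [
            c for c, ct in truth.clonotype_of_cell.items()
            if ct == truth.dominant_clonotype_id
        ]
        dom_seq = trb.loc[trb["cell_id"] == dom_cells[0], "sequence_aa"].iloc[0]
        assert counts[dom_seq] == small_config.dominant_clone_size

    def test_no_dropout_two_rows_per_cell(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        airr = sy.generate_airr_table(small_config, truth, dropout_frac=0.0)
        per_cell = airr.groupby("cell_id").size()
        assert (per_cell == 2).all()
        assert set(per_cell.index) == truth.real_cells

    def test_dropout_drops_one_chain(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        airr = sy.generate_airr_table(small_config, truth, dropout_frac=0.3)
        per_cell = airr.groupby("cell_id").size()
        assert (per_cell == 1).sum() > 0

    def test_schema_subset_conformance(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        airr = sy.generate_airr_table(small_config, truth, extra_chain_frac=0.1)
        assert list(airr.columns) == [
            "cell_id", "locus", "v_call", "j_call", "junction_aa",
            "sequence_aa", "duplicate_count", "productive",
        ]
        assert airr["locus"].isin(["TRA", "TRB"]).all()
        assert airr["v_call"].str.match(r"TR[AB]V\d+\*01").all()
        assert airr["j_call"].str.match(r"TR[AB]J[\d-]+\*01").all()
        assert airr["junction_aa"].str.match(r"^C[A-Z]+F$").all()
        assert airr["junction_aa"].str.len().between(10, 18).all()
        assert (airr["duplicate_count"] >= 1).all()

    def test_chains_identical_within_distinct_across_clonotypes(self, small_config):
        mol, truth = sy.generate_molecule_table(small_config)
        airr = sy.generate_airr_table(small_config, truth)
        for locus in ("TRA", "TRB"):
            sub = airr[airr["locus"] == locus].copy()
            sub["clone"] = sub["cell_id"].map(truth.clonotype_of_cell)
            per_clone = sub.groupby("clone")["sequence_aa"].nunique()
            assert (per_clone == 1).all()
            seq_of_clone = sub.groupby("clone")["sequence_aa"].first()
            assert seq_of_clone.nunique() == len(seq_of_clone)


class TestGexGeneration:
    def test_pure_cd8_config(self):
        cfg = sy.SimConfig(seed=9, n_real_cells=200, n_noise_barcodes=800,
                           n_clonotypes=100, frac_cd8=1.0)
        _, truth = sy.generate_molecule_table(cfg)
        mats = sy.generate_gex_matrices(cfg, truth)
        for m in mats:
            cd8, cd4, fox = m.gene("CD8"), m.gene("CD4"), m.gene("FOXP3")
            assert (cd8 > 0).all() and (cd4 == 0).all() and (fox == 0).all()

    def test_cd8_fraction_within_binomial_interval(self):
        cfg = sy.SimConfig(seed=13, n_real_cells=5000, n_noise_barcodes=100,
                           n_clonotypes=2500, frac_cd8=0.999, multiplet_rate=0.0)
        _, truth = sy.generate_molecule_table(cfg)
        mats = sy.generate_gex_matrices(cfg, truth)
        n = sum(m.n_cells for m in mats)
        n_cd8 = sum(int((m.gene("CD8") > 0).sum()) for m in mats)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.999)
        assert lo <= n_cd8 <= hi

    def test_panel_genes_are_columns(self, small_config):
        _, truth = sy.generate_molecule_table(small_config)
        mats = sy.generate_gex_matrices(small_config, truth)
        for m in mats:
            assert m.gene_names == list(small_config.panel_genes)

    def test_one_matrix_per_sample_singlets_only(self, small_config):
        _, truth = sy.generate_molecule_table(small_config)
        mats = sy.generate_gex_matrices(small_config, truth)
        assert [m.sample_ids[0] for m in mats] == small_config.sample_ids
        cells = [c for m in mats for c in m.cell_ids]
        assert len(cells) == len(set(cells))
        singlets = {c for c, s in truth.cell_to_sample.items() if s != "multiplet"}
        assert set(cells) == singlets


class TestCytotoxPlate:
    def test_noise_free_inversion(self):
        plate = sy.generate_cytotox_plate(50.0, 0.0, seed=0)
        assert percent_cytotoxicity(plate) == pytest.approx(50.0)

    def test_zero_pct(self):
        plate = sy.generate_cytotox_plate(0.0, 0.0, seed=0)
        assert percent_cytotoxicity(plate) == pytest.approx(0.0)
        assert np.mean(plate.od_effector_plus_target) == pytest.approx(
            np.mean(plate.od_effector_only)
        )

    def test_monte_carlo_recovery(self):
        vals = [
            percent_cytotoxicity(sy.generate_cytotox_plate(72.65, 2.0, seed=s))
            for s in range(1000)
        ]
        assert abs(np.mean(vals) - 72.65) < 0.5

    def test_duplicate_wells(self):
        plate = sy.generate_cytotox_plate(30.0, 1.0, seed=3)
        assert len(plate.od_effector_plus_target) == 2
        assert len(plate.od_spontaneous) == 2

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sy.generate_cytotox_plate(50.0, -1.0, seed=0)

    def test_out_of_range_pct_rejected(self):
        with pytest.raises(ValueError, match="true_pct"):
            sy.generate_cytotox_plate(150.0, 0.0, seed=0)


class TestGroundTruthRoundTrip:
    def test_json_round_trip(self, small_config, tmp_path):
        _, truth = sy.generate_molecule_table(small_config)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = sy.GroundTruth.from_json(path)
        assert back.cell_to_sample == truth.cell_to_sample
        assert back.real_cells == truth.real_cells
        assert back.clonotype_of_cell == truth.clonotype_of_cell
        assert back.dominant_clonotype_id == truth.dominant_clonotype_id
        assert back.true_umi_parent == truth.true_umi_parent
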