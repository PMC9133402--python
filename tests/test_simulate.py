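"""Ground-truth properties of the synthetic-data generator."""

import gzip
import math

import numpy as np
import pandas as pd
import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from tcrspot import pipeline
from tcrspot.capture import BarcodeWhitelist, CloneReadMap, build_spatial_clone_matrix
from tcrspot.repertoire import cefx_specific_clones
from tcrspot.simulate import (
    SimulationConfig,
    emit_fastq,
    generate_whitelist,
    simulate_cefx_tables,
    simulate_cells,
    simulate_repertoire,
    simulate_spatial_umis,
    simulate_tissue,
    toy_segment_references,
)
from tcrspot.io import iter_read_pairs


class TestTissue:
    def test_radius_zero_single_tumor_spot(self):
        cfg = SimulationConfig(seed=1, n_rows=9, n_cols=9, tumor_radius_um=0.0)
        grid = simulate_tissue(cfg)
        assert grid.n_tumor == 1

    def test_huge_radius_all_tumor(self):
        cfg = SimulationConfig(seed=1, n_rows=6, n_cols=6, tumor_radius_um=1e6)
        grid = simulate_tissue(cfg)
        assert grid.n_tumor == len(grid)

    def test_disc_area_fraction_approximated(self):
        cfg = SimulationConfig(seed=1, n_rows=40, n_cols=40, tumor_radius_um=700.0)
        grid = simulate_tissue(cfg)
        # spot density on the hexagonal lattice: 2 / (sqrt(3) * pitch^2)
        density = 2.0 / (math.sqrt(3) * cfg.pitch_um**2)
        expected = math.pi * cfg.tumor_radius_um**2 * density
        assert grid.n_tumor == pytest.approx(expected, rel=0.1)

    def test_hex_neighbors_one_pitch_apart(self):
        cfg = SimulationConfig(seed=1, n_rows=4, n_cols=4)
        grid = simulate_tissue(cfg)
        df = grid.spots
        p0 = df.iloc[0]
        d = np.hypot(df["x"] - p0["x"], df["y"] - p0["y"])
        nearest = np.sort(d[d > 0])[0]
        assert nearest == pytest.approx(cfg.pitch_um)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5, n_rows=6, n_cols=6)
        g1 = simulate_tissue(cfg)
        g2 = simulate_tissue(cfg)
        pd.testing.assert_frame_equal(g1.spots, g2.spots)


class TestWhitelistGeneration:
    def test_pairwise_distance_at_least_three(self):
        rng = np.random.default_rng(2)
        barcodes = generate_whitelist(80, 16, rng)
        arr = np.array([list(b) for b in barcodes])
        for i in range(len(arr)):
            d = (arr != arr[i]).sum(axis=1)
            d[i] = 16
            assert d.min() >= 3


class TestRepertoire:
    def test_zipf_zero_uniform(self):
        cfg = SimulationConfig(seed=3, n_clones=8, zipf_exponent=0.0, total_umis=800)
        table = simulate_repertoire(cfg)
        assert table["weight"].nunique() == 1
        assert (table["n_umis"] == 100).all()

    def test_single_clone(self):
        cfg = SimulationConfig(seed=3, n_clones=1)
        table = simulate_repertoire(cfg)
        assert len(table) == 1 and table["weight"].iloc[0] == pytest.approx(1.0)

    def test_keys_unique_and_deterministic(self):
        cfg = SimulationConfig(seed=4, n_clones=40)
        t1 = simulate_repertoire(cfg)
        t2 = simulate_repertoire(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        keys = t1[["v_gene", "j_gene", "cdr3_aa"]].apply(tuple, axis=1)
        assert keys.nunique() == 40

    def test_cdr3_anchors(self):
        table = simulate_repertoire(SimulationConfig(seed=5, n_clones=20))
        assert table["cdr3_aa"].str.startswith("C").all()
        assert table["cdr3_aa"].str.endswith("F").all()
        assert table["cdr3_nt"].str.startswith("TGT").all()
        assert table["cdr3_nt"].str.endswith("TTT").all()


class TestSpatialPlacement:
    def _setup(self, p_ad, p_bc, seed=6, total=2000):
        cfg = SimulationConfig(
            seed=seed, n_rows=14, n_cols=14, tumor_radius_um=450.0,
            n_clones=10, total_umis=total,
            p_tumor={"AD": p_ad, "BC": p_bc},
        )
        grid = simulate_tissue(cfg)
        table = simulate_repertoire(cfg)
        matrix, molecules = simulate_spatial_umis(table, grid, cfg)
        return cfg, grid, table, matrix, molecules

    def test_p_one_all_in_tumor(self):
        _, grid, table, matrix, _ = self._setup(1.0, 1.0)
        tumor = grid.tumor_barcodes()
        assert all(spot in tumor for _, spot in matrix.counts)

    def test_p_zero_none_in_tumor(self):
        _, grid, table, matrix, _ = self._setup(0.0, 0.0)
        tumor = grid.tumor_barcodes()
        assert not any(spot in tumor for _, spot in matrix.counts)

    def test_binomial_fraction_recovered(self):
        from tcrspot.spatial import clone_tumor_fraction

        cfg, grid, table, matrix, _ = self._setup(0.8, 0.2, total=12_000)
        for row in table.itertuples():
            if row.n_umis < 500:
                continue
            frac = clone_tumor_fraction(row.clone_id, matrix, grid) / 100.0
            p = cfg.p_tumor[row.phenotype]
            ci = 3.3 * math.sqrt(p * (1 - p) / row.n_umis)  # ~99.9% binomial CI
            assert abs(frac - p) < ci

    def test_matrix_consistent_with_molecules(self):
        _, _, _, matrix, molecules = self._setup(0.5, 0.5)
        assert matrix.total_umis == len(
            {(m.clone_id, m.spot_barcode, m.umi) for m in molecules}
        )


class TestEmitFastq:
    def test_error_free_round_trip_recovers_planted_matrix(self, tmp_path, refs):
        cfg = SimulationConfig(
            seed=8, n_rows=10, n_cols=10, tumor_radius_um=350.0,
            n_clones=8, total_umis=300,
        )
        grid = simulate_tissue(cfg)
        table = simulate_repertoire(cfg)
        planted, molecules = simulate_spatial_umis(table, grid, cfg)
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        truth = emit_fastq(molecules, table, refs, cfg, r1, r2)
        wl = BarcodeWhitelist(grid.spots["barcode"])
        matrix, qc = build_spatial_clone_matrix(
            iter_read_pairs(r1, r2), CloneReadMap(mapping=truth), wl,
            umi_len=cfg.umi_len, clone_table=planted.clone_table,
        )
        assert matrix.counts == planted.counts
        assert qc.counts["assigned"] == len(truth)

    def test_read_count_bookkeeping(self, tmp_path, refs):
        cfg = SimulationConfig(seed=9, n_rows=8, n_cols=8, tumor_radius_um=250.0,
                               n_clones=4, total_umis=100, reads_per_umi=3)
        grid = simulate_tissue(cfg)
        table = simulate_repertoire(cfg)
        _, molecules = simulate_spatial_umis(table, grid, cfg)
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        truth = emit_fastq(molecules, table, refs, cfg, r1, r2)
        n_r1 = sum(1 for _ in FastqGeneralIterator(open(r1)))
        assert n_r1 == 3 * len(molecules) == len(truth)

    def test_fastq_valid_and_r1_length(self, tmp_path, refs):
        cfg = SimulationConfig(seed=10, n_rows=8, n_cols=8, tumor_radius_um=250.0,
                               n_clones=3, total_umis=50, r1_pad=4)
        grid = simulate_tissue(cfg)
        table = simulate_repertoire(cfg)
        _, molecules = simulate_spatial_umis(table, grid, cfg)
        r1 = tmp_path / "R1.fastq.gz"
        emit_fastq(molecules, table, refs, cfg, r1, tmp_path / "R2.fastq.gz")
        with gzip.open(r1, "rt") as fh:
            for _, seq, qual in FastqGeneralIterator(fh):
                assert len(seq) == cfg.barcode_len + cfg.umi_len + cfg.r1_pad
                assert len(qual) == len(seq)

    def test_byte_identical_under_fixed_seed(self, tmp_path, refs):
        cfg = SimulationConfig(seed=11, n_rows=8, n_cols=8, tumor_radius_um=250.0,
                               n_clones=3, total_umis=50)
        grid = simulate_tissue(cfg)
        table = simulate_repertoire(cfg)
        _, molecules = simulate_spatial_umis(table, grid, cfg)
        paths = []
        for tag in ("a", "b"):
            r1 = tmp_path / f"R1.{tag}.fastq"
            emit_fastq(molecules, table, refs, cfg, r1, tmp_path / f"R2.{tag}.fastq")
            paths.append(r1)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_barcode_error_rate_matches_binomial(self, tmp_path, refs):
        cfg = SimulationConfig(seed=12, n_rows=10, n_cols=10, tumor_radius_um=300.0,
                               n_clones=5, total_umis=2000, reads_per_umi=1,
                               err_barcode=0.01)
        grid = simulate_tissue(cfg)
        table = simulate_repertoire(cfg)
        _, molecules = simulate_spatial_umis(table, grid, cfg)
        r1 = tmp_path / "R1.fastq"
        emit_fastq(molecules, table, refs, cfg, r1, tmp_path / "R2.fastq")
        wl = set(grid.spots["barcode"])
        n, errs = 0, 0
        for _, seq, _ in FastqGeneralIterator(open(r1)):
            n += 1
            errs += seq[: cfg.barcode_len] not in wl
        expected = 1 - 0.99**16  # ~= 0.149
        assert errs / n == pytest.approx(expected, abs=0.03)


class TestCellsAndCefx:
    def test_planted_phenotype_purity_one_recovers_labels(self):
        from tcrspot.pipeline import run_link

        cfg = SimulationConfig(seed=13, n_clones=15, n_cells=300, total_umis=300,
                               n_rows=10, n_cols=10, tumor_radius_um=350.0)
        table = simulate_repertoire(cfg)
        grid = simulate_tissue(cfg)
        matrix, _ = simulate_spatial_umis(table, grid, cfg)
        cells, _, _ = simulate_cells(table, cfg)
        linked = run_link(matrix, cells)
        truth = dict(zip(table["clone_id"], table["phenotype"]))
        assert len(linked) == len(table)
        for row in linked.itertuples():
            assert row.phenotype == truth[row.clone_id]

    def test_alpha_only_cells_rescuable(self):
        cfg = SimulationConfig(seed=14, n_clones=10, n_cells=400,
                               alpha_only_fraction=0.3)
        table = simulate_repertoire(cfg)
        cells, _, _ = simulate_cells(table, cfg)
        from tcrspot.repertoire import rescue_beta_by_alpha

        n_missing = sum(1 for c in cells if c.beta is None)
        assert n_missing > 0
        rescued = rescue_beta_by_alpha(cells)
        assert all(c.beta is not None for c in rescued)

    def test_cefx_designated_set_recovered(self):
        cfg = SimulationConfig(seed=15, n_clones=30, n_cefx_specific=8)
        table = simulate_repertoire(cfg)
        pos, neg, specific = simulate_cefx_tables(table, cfg)
        assert len(specific) == 8
        assert cefx_specific_clones(pos, neg) == specific

    def test_empty_designated_set(self):
        cfg = SimulationConfig(seed=16, n_clones=10, n_cefx_specific=0)
        table = simulate_repertoire(cfg)
        pos, neg, specific = simulate_cefx_tables(table, cfg)
        assert specific == set()
        assert cefx_specific_clones(pos, neg) == set()

    def test_many_random_tables_recover_exactly(self):
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, n_clones=20, n_cefx_specific=5)
            table = simulate_repertoire(cfg)
            pos, neg, specific = simulate_cefx_tables(table, cfg)
            assert cefx_specific_clones(pos, neg) == specific
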