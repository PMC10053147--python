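import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from riskscreen import (
    CellQCThresholds, CisWindow, SingleCellSimConfig, assign_perturbations,
    call_pairs, cis_genes, qc_cells, simulate_single_cells, tss_positive_control_check,
)
from riskscreen.qtl import test_all_pairs as run_all_pair_tests
from riskscreen.qtl import test_pair as run_pair_test
from riskscreen.qtl import permutation_label_matrix, stratified_permutation_pvalue
from riskscreen.singlecell import SingleCellDataset


def _toy_dataset(counts, assignments, mito=None, guides=None, genes=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = [f"C{i}" for i in range(n_cells)]
    genes = genes if genes is not None else pd.DataFrame(
        {"gene_id": [f"G{j}" for j in range(n_genes)], "contig": "chr1",
         "tss": np.arange(n_genes) * 1000})
    qc = pd.DataFrame({
        "cell_id": cell_ids,
        "mito_fraction": mito if mito is not None else np.zeros(n_cells),
        "total_umis": counts.sum(axis=1),
        "genes_detected": (counts > 0).sum(axis=1),
    })
    guides = guides if guides is not None else pd.DataFrame(
        {"sgrna_id": ["sgE1_a", "sgE1_b", "sgE2_a", "sgNT", "sgTSS_G0"],
         "target_type": ["enhancer", "enhancer", "enhancer", "non_targeting", "tss_control"],
         "target_id": ["E1", "E1", "E2", "", "G0"], "position": [0, 0, 0, -1, -1]})
    return SingleCellDataset(
        matrix=sparse.csr_matrix(counts), cell_ids=cell_ids, genes=genes,
        cell_qc=qc, assignments=pd.DataFrame(assignments,
                                             columns=["cell_id", "sgrna_id", "umi_count", "reads_per_umi"]),
        guides=guides)


class TestSimulation:
    def test_same_seed_identical(self, enhancer_frame):
        cfg = SingleCellSimConfig(n_cells=100, n_genes=50, n_tss_control_genes=2, seed=1)
        a = simulate_single_cells(enhancer_frame, cfg)
        b = simulate_single_cells(enhancer_frame, cfg)
        assert (a.matrix != b.matrix).nnz == 0
        pd.testing.assert_frame_equal(a.assignments, b.assignments)
        pd.testing.assert_frame_equal(a.cell_qc, b.cell_qc)

    def test_zero_cells_empty_dataset_and_qc(self, enhancer_frame):
        cfg = SingleCellSimConfig(n_cells=0, n_genes=20, n_tss_control_genes=2, seed=1)
        ds = simulate_single_cells(enhancer_frame, cfg)
        assert ds.n_cells == 0
        filtered, log = qc_cells(ds)
        assert filtered.n_cells == 0
        assert log["input_cells"] == 0

    def test_planted_knockdown_halves_mean_expression(self, sc_dataset):
        """Monte-Carlo over >= 1000 cells: cells carrying a guide against the
        planted enhancer express the target at ~ 0.5x the unperturbed mean."""
        ds = sc_dataset
        gi = list(ds.genes["gene_id"]).index("G0050")
        pert_cells = set(
            ds.assignments.loc[
                ds.assignments["sgrna_id"].isin(
                    ds.guides.loc[ds.guides["target_id"] == "ENH_0001", "sgrna_id"]),
                "cell_id"])
        mask = np.array([c in pert_cells for c in ds.cell_ids])
        counts = np.asarray(ds.matrix[:, gi].todense()).ravel()
        # normalize by cell totals: size factors are independent of perturbation
        totals = np.asarray(ds.matrix.sum(axis=1)).ravel()
        ratio = (counts[mask] / totals[mask]).mean() / (counts[~mask] / totals[~mask]).mean()
        assert mask.sum() > 200
        assert ratio == pytest.approx(0.5, abs=0.07)

    def test_null_config_no_expression_difference(self, enhancer_frame):
        cfg = SingleCellSimConfig(n_cells=1200, n_genes=100, n_tss_control_genes=0,
                                  n_nt_controls=10, seed=8)
        ds = simulate_single_cells(enhancer_frame, cfg)
        pert = assign_perturbations(ds)
        counts = np.asarray(ds.matrix[:, 10].todense()).ravel()
        totals = np.maximum(np.asarray(ds.matrix.sum(axis=1)).ravel(), 1)
        mask = pert["ENH_0001"].to_numpy()
        ratio = (counts[mask] / totals[mask]).mean() / (counts[~mask] / totals[~mask]).mean()
        assert ratio == pytest.approx(1.0, abs=0.08)

    def test_unknown_planted_gene_rejected(self, enhancer_frame):
        cfg = SingleCellSimConfig(n_cells=10, n_genes=20,
                                  planted_effects={"ENH_0001": ("NOT_A_GENE", -0.5)}, seed=0)
        with pytest.raises(ValueError, match="absent from gene panel"):
            simulate_single_cells(enhancer_frame, cfg)

    def test_invalid_fractional_change_rejected(self):
        with pytest.raises(ValueError, match="> -1"):
            SingleCellSimConfig(planted_effects={"E": ("G", -1.0)}).validate()


class TestCellQC:
    def test_single_umi_cell_removed_and_good_cell_retained(self):
        counts = np.ones((2, 250), dtype=int)
        assigns = [("C0", "sgE1_a", 1, 5),
                   ("C1", "sgE1_a", 1, 3), ("C1", "sgE2_a", 1, 3)]
        ds = _toy_dataset(counts, assigns, mito=[0.02, 0.02])
        filtered, log = qc_cells(ds, CellQCThresholds())
        assert filtered.cell_ids == ["C1"]
        assert log["cells_removed_sgrna_support"] == 1

    def test_low_read_umis_discarded_before_umi_count(self):
        # two UMIs but one has only 2 supporting reads -> cell fails the
        # 2-UMI floor after the read filter
        counts = np.ones((1, 250), dtype=int)
        ds = _toy_dataset(counts, [("C0", "sgE1_a", 1, 2), ("C0", "sgE2_a", 1, 5)])
        filtered, log = qc_cells(ds, CellQCThresholds())
        assert filtered.n_cells == 0
        assert log["assignments_dropped_low_reads"] == 1

    def test_mito_and_gene_detection_filters(self):
        counts = np.ones((3, 250), dtype=int)
        counts[2, 100:] = 0  # 100 genes detected only
        assigns = [(f"C{i}", "sgE1_a", 2, 5) for i in range(3)]
        ds = _toy_dataset(counts, assigns, mito=[0.02, 0.5, 0.02])
        filtered, log = qc_cells(ds, CellQCThresholds())
        assert filtered.cell_ids == ["C0"]
        assert log["cells_removed_mito"] == 1
        assert log["cells_removed_genes_detected"] == 1

    def test_idempotent_and_identity_when_all_pass(self):
        counts = np.ones((2, 250), dtype=int)
        assigns = [("C0", "sgE1_a", 2, 5), ("C1", "sgE2_a", 3, 6)]
        ds = _toy_dataset(counts, assigns, mito=[0.01, 0.02])
        once, log1 = qc_cells(ds, CellQCThresholds())
        assert once.cell_ids == ds.cell_ids  # identity: everyone passes
        twice, log2 = qc_cells(once, CellQCThresholds())
        assert twice.cell_ids == once.cell_ids
        pd.testing.assert_frame_equal(twice.assignments, once.assignments)

    def test_missing_mito_skips_filter_with_warning(self):
        counts = np.ones((1, 250), dtype=int)
        ds = _toy_dataset(counts, [("C0", "sgE1_a", 2, 5)])
        ds.cell_qc = ds.cell_qc.drop(columns=["mito_fraction"])
        with pytest.warns(UserWarning, match="mito"):
            filtered, _ = qc_cells(ds, CellQCThresholds())
        assert filtered.n_cells == 1


class TestPerturbationAssignment:
    def test_multi_enhancer_and_control_cells(self):
        counts = np.ones((2, 250), dtype=int)
        assigns = [("C0", "sgE1_a", 2, 5), ("C0", "sgE1_b", 1, 5), ("C0", "sgE2_a", 1, 5),
                   ("C1", "sgNT", 2, 5)]
        ds = _toy_dataset(counts, assigns)
        ind = assign_perturbations(ds)
        assert ind.loc["C0", "E1"] and ind.loc["C0", "E2"]
        assert not ind.loc["C1"].any()  # NT-only cell: eligible control everywhere

    def test_unmapped_sgrna_rejected(self):
        counts = np.ones((1, 250), dtype=int)
        ds = _toy_dataset(counts, [("C0", "sgMYSTERY", 2, 5)])
        with pytest.raises(ValueError, match="unmapped"):
            assign_perturbations(ds)

    def test_unperturbed_enhancer_not_evaluable(self):
        counts = np.ones((30, 250), dtype=int)
        assigns = [(f"C{i}", "sgE1_a", 2, 5) for i in range(30)]
        ds = _toy_dataset(counts, assigns)
        ind = assign_perturbations(ds)
        r = run_pair_test(ds, ind, "E2", "G1", n_perm=50, seed=0, min_perturbed=5)
        assert not r.evaluable


class TestPairTest:
    def test_constant_expression_degenerate_null(self):
        counts = np.full((40, 250), 3, dtype=int)
        assigns = [(f"C{i}", "sgE1_a" if i < 20 else "sgNT", 2, 5) for i in range(40)]
        ds = _toy_dataset(counts, assigns)
        ind = assign_perturbations(ds)
        r = run_pair_test(ds, ind, "E1", "G5", n_perm=100, seed=0)
        assert r.p == 1.0
        assert r.z == 0.0

    def test_six_cell_toy_matches_exhaustive_enumeration(self):
        """Brute-force oracle: single stratum, 3 of 6 cells perturbed; the
        permutation p converges to the exhaustive tail fraction over all
        C(6,3) labelings (ties counted as extreme, add-one vanishing)."""
        expr = np.array([5.0, 4.0, 1.0, 2.0, 0.5, 0.2])
        perturbed = np.array([True, True, True, False, False, False])
        strata = np.zeros(6, dtype=int)
        obs = expr[perturbed].mean() - expr[~perturbed].mean()
        null = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.zeros(6, dtype=bool)
            lab[list(combo)] = True
            null.append(expr[lab].mean() - expr[~lab].mean())
        exhaustive = np.mean(np.abs(null) >= abs(obs))
        _, p = stratified_permutation_pvalue(expr, perturbed, strata, n_perm=40_000, seed=2)
        assert p == pytest.approx(exhaustive, abs=0.01)

    def test_stratum_margins_preserved_in_every_permutation(self):
        rng = np.random.default_rng(0)
        strata = rng.integers(0, 4, size=60)
        perturbed = rng.random(60) < 0.3
        labels = permutation_label_matrix(perturbed, strata, 200, rng)
        for s in range(4):
            idx = strata == s
            assert (labels[:, idx].sum(axis=1) == perturbed[idx].sum()).all()

    def test_planted_pair_detected(self, sc_filtered):
        ind = assign_perturbations(sc_filtered)
        r = run_pair_test(sc_filtered, ind, "ENH_0001", "G0050", n_perm=400, seed=3)
        assert r.evaluable and r.z < 0 and r.p <= 0.1

    def test_too_few_perturbed_flagged(self):
        counts = np.ones((30, 250), dtype=int)
        assigns = [("C0", "sgE1_a", 2, 5)] + [(f"C{i}", "sgNT", 2, 5) for i in range(1, 30)]
        ds = _toy_dataset(counts, assigns)
        ind = assign_perturbations(ds)
        assert not run_pair_test(ds, ind, "E1", "G1", n_perm=50, seed=0).evaluable


class TestCallsAndControls:
    @pytest.mark.parametrize(
        "p,z,called",
        [(0.05, -2.0, True), (0.05, 2.0, False), (0.1, -0.1, True),
         (0.11, -2.0, False), (0.1, 0.0, False)],
    )
    def test_call_boundaries(self, p, z, called):
        res = pd.DataFrame([{"enhancer_id": "E", "gene_id": "G", "z": z, "p": p,
                             "n_perturbed": 50, "n_control": 500, "evaluable": True}])
        assert bool(call_pairs(res)["called"].iloc[0]) is called

    def test_cis_window_selects_genes_by_distance(self):
        genes = pd.DataFrame({"gene_id": ["A", "B", "C"], "contig": ["chr1", "chr1", "chr2"],
                              "tss": [1_000_000, 4_000_000, 1_000_000]})
        enh = {"contig": "chr1", "start": 990_000, "end": 991_000}
        assert cis_genes(genes, enh, CisWindow(2_000_000)) == ["A"]

    def test_tss_controls_knocked_down(self, sc_filtered):
        rep = tss_positive_control_check(sc_filtered, n_perm=300, seed=1)
        assert rep.evaluable
        assert rep.pass_fraction >= 0.8
        assert not rep.warn

    def test_no_tss_controls_not_evaluable(self):
        counts = np.ones((20, 250), dtype=int)
        assigns = [(f"C{i}", "sgNT", 2, 5) for i in range(20)]
        guides = pd.DataFrame({"sgrna_id": ["sgNT"], "target_type": ["non_targeting"],
                               "target_id": [""], "position": [-1]})
        ds = _toy_dataset(counts, assigns, guides=guides)
        assert not tss_positive_control_check(ds, n_perm=50, seed=0).evaluable

    def test_all_pairs_table_and_null_calibration(self, enhancer_frame):
        """No planted effects: permutation p uniform and the one-sided call
        rate near half the p threshold."""
        from scipy import stats

        cfg = SingleCellSimConfig(n_cells=1200, n_genes=150, mean_umis_per_cell=3000,
                                  n_tss_control_genes=0, n_nt_controls=15, seed=21)
        ds = simulate_single_cells(enhancer_frame, cfg)
        filtered, _ = qc_cells(ds, CellQCThresholds(min_genes_detected=80))
        res = run_all_pair_tests(filtered, enhancer_frame, n_perm=300, seed=5)
        ev = res[res["evaluable"]]
        assert len(ev) > 500
        assert stats.kstest(ev["p"], "uniform").pvalue > 0.01
        rate = call_pairs(res)["called"].mean()
        se = np.sqrt(0.05 * 0.95 / len(ev))
        assert abs(rate - 0.05) < 4 * se + 0.01
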