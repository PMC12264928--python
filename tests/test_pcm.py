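"""PCM pipeline: aggregation, featurization, filters, splits, evaluation."""

import numpy as np
import pandas as pd
import pytest

from assayscope.boosting import BoostingSpec
from assayscope.corpus import BioactivityPoint, BioactivityTable
from assayscope.errors import FeaturizationError, ParameterError
from assayscope.pcm import (
    Z_SCALES, AggregatedDataset, FeatureMatrix, PCMModel, aggregate_measurements,
    apply_feature_filters, build_feature_matrix, evaluate_model,
    feature_importance, featurize_molecule, featurize_protein, murcko_scaffold,
    split_dataset)
from assayscope.synthetic import generate_bioactivity, packaged_smiles


def _table(rows):
    """rows: (compound, smiles, target, pchembl, assay_id)"""
    return BioactivityTable([
        BioactivityPoint(c, s, t, v, a) for c, s, t, v, a in rows])


class TestAggregation:
    def test_control_median_odd(self):
        table = _table([("C1", "CCO", "P1", v, f"A{i}")
                        for i, v in enumerate([6.0, 7.0, 8.0])])
        agg = aggregate_measurements(table, "control")
        assert len(agg) == 1
        assert agg.frame["pchembl"].iloc[0] == 7.0

    def test_control_median_even_midpoint(self):
        table = _table([("C1", "CCO", "P1", 6.0, "A1"), ("C1", "CCO", "P1", 7.0, "A2")])
        agg = aggregate_measurements(table, "control")
        assert agg.frame["pchembl"].iloc[0] == 6.5

    def test_cluster_mode_groups_by_cluster(self):
        table = _table([("C1", "CCO", "P1", 6.0, "A1"), ("C1", "CCO", "P1", 6.0, "A2"),
                        ("C1", "CCO", "P1", 8.0, "A3")])
        agg = aggregate_measurements(table, "cluster",
                                     assignment={"A1": 0, "A2": 0, "A3": 1})
        assert len(agg) == 2
        by_cluster = agg.frame.set_index("context_id")["pchembl"]
        assert by_cluster[0] == 6.0 and by_cluster[1] == 8.0

    def test_unresolvable_rows_dropped_and_counted(self):
        table = _table([("C1", "CCO", "P1", 6.0, "A1"), ("C1", "CCO", "P1", 7.0, "GONE")])
        agg = aggregate_measurements(table, "cluster", assignment={"A1": 0})
        assert len(agg) == 1
        assert agg.provenance[0]["n_unresolved_dropped"] == 1

    def test_cluster_mode_requires_assignment(self):
        with pytest.raises(ParameterError):
            aggregate_measurements(_table([("C1", "CCO", "P1", 6.0, "A1")]), "cluster")

    def test_multitask_pivot(self):
        table = _table([("C1", "CCO", "P1", 6.0, "A1"), ("C1", "CCO", "P1", 8.0, "A2"),
                        ("C2", "CCN", "P1", 5.0, "A1")])
        agg = aggregate_measurements(table, "cluster", assignment={"A1": 0, "A2": 1})
        pairs, Y, mask, tasks = agg.to_multitask()
        assert Y.shape == (2, 2) and tasks == [0, 1]
        assert mask.sum() == 3  # (C2, task 1) unobserved


class TestMoleculeFeaturization:
    def test_2048_bits_and_determinism(self):
        fp = featurize_molecule("c1ccccc1O")
        assert fp.shape == (2048,) and set(np.unique(fp)) <= {0, 1}
        assert np.array_equal(fp, featurize_molecule("c1ccccc1O"))

    def test_benzene_differs_from_hexane(self):
        assert not np.array_equal(featurize_molecule("c1ccccc1"),
                                  featurize_molecule("CCCCCC"))

    def test_salt_stripped_before_fingerprinting(self):
        assert np.array_equal(featurize_molecule("c1ccccc1C(=O)O.[Na+]"),
                              featurize_molecule("c1ccccc1C(=O)O"))

    def test_unparsable_smiles_is_error(self):
        with pytest.raises(FeaturizationError):
            featurize_molecule("not_a_smiles((")


class TestProteinFeaturization:
    def test_vector_length_is_three_per_column(self):
        aln = {"P1": "ACDEF", "P2": "ACDEF"}
        assert featurize_protein(aln, "P1").shape == (15,)

    def test_gap_positions_are_zero(self):
        vec = featurize_protein({"P1": "A-C"}, "P1")
        assert np.all(vec[3:6] == 0.0)

    def test_alanine_z_scales(self):
        vec = featurize_protein({"P1": "A"}, "P1")
        assert vec == pytest.approx([0.07, -1.73, 0.09])

    def test_unknown_residue_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="unknown residue"):
            vec = featurize_protein({"P1": "AXA"}, "P1")
        assert np.all(vec[3:6] == 0.0)

    def test_missing_accession_is_error(self):
        with pytest.raises(ParameterError, match="ZZZ"):
            featurize_protein({"P1": "ACD"}, "ZZZ")

    def test_fasta_roundtrip(self, tmp_path):
        from assayscope.synthetic import write_alignment_fasta

        aln = {"P1": "ACDEF", "P2": "ACDFF"}
        write_alignment_fasta(aln, tmp_path / "aln.fasta")
        vec = featurize_protein(tmp_path / "aln.fasta", "P2")
        assert vec.shape == (15,)

    def test_all_twenty_residues_tabulated(self):
        assert len(Z_SCALES) == 20
        assert all(len(v) == 3 for v in Z_SCALES.values())


class TestFeatureFilters:
    def test_constant_column_dropped(self, rng):
        X = rng.normal(size=(50, 4))
        X[:, 2] = 3.14
        mask = apply_feature_filters(X)
        assert not mask[2] and mask[[0, 1, 3]].all()

    def test_duplicated_column_single_survivor(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 2] = X[:, 0]
        mask = apply_feature_filters(X)
        assert mask[0] and not mask[2]

    def test_planted_correlation_drops_later_column(self, rng):
        X = rng.normal(size=(200, 5))
        X[:, 4] = 0.9 * X[:, 1] + np.sqrt(1 - 0.81) * rng.normal(size=200)
        # empirical |r| > 0.8 -> the later column of the pair goes
        mask = apply_feature_filters(X)
        assert mask[1] and not mask[4]

    def test_mask_depends_only_on_training_rows(self, rng):
        X = rng.normal(size=(100, 6))
        train = X[:80]
        mask1 = apply_feature_filters(train)
        mask2 = apply_feature_filters(train)  # unrelated test rows changed nothing
        assert np.array_equal(mask1, mask2)

    def test_all_columns_dropped_is_error(self):
        with pytest.raises(ParameterError):
            apply_feature_filters(np.ones((10, 3)))


def _dataset(n, rng, n_scaffold_cores=25):
    cores = packaged_smiles()[:n_scaffold_cores]
    frame = pd.DataFrame({
        "compound_id": [f"C{i}" for i in range(n)],
        "smiles": [cores[i % len(cores)] for i in range(n)],
        "target_accession": ["P1"] * n,
        "context_id": [None] * n,
        "pchembl": rng.normal(6.5, 1, size=n),
        "n_measurements": 1,
    })
    return AggregatedDataset(frame=frame, mode="control")


class TestSplits:
    def test_random_split_sizes(self, rng):
        split = split_dataset(_dataset(1000, rng), "random", 0.1, seed=0)
        assert len(split.test_idx) == 100
        assert len(split.train_idx) == 900

    def test_random_split_deterministic(self, rng):
        ds = _dataset(100, rng)
        s1 = split_dataset(ds, "random", seed=5)
        s2 = split_dataset(ds, "random", seed=5)
        assert np.array_equal(s1.test_idx, s2.test_idx)

    def test_scaffold_split_zero_overlap(self, rng):
        ds = _dataset(200, rng)
        split = split_dataset(ds, "scaffold", seed=1)
        scaffolds = ds.frame["smiles"].map(murcko_scaffold)
        assert not (set(scaffolds[split.train_idx]) & set(scaffolds[split.test_idx]))

    def test_scaffold_split_fraction_within_tolerance(self, rng):
        # molecules drawn across the whole packaged library: >= 20 scaffolds
        smiles = packaged_smiles()[::4][:300]
        frame = pd.DataFrame({
            "compound_id": [f"C{i}" for i in range(len(smiles))],
            "smiles": smiles, "target_accession": "P1", "context_id": None,
            "pchembl": rng.normal(6.5, 1, size=len(smiles)), "n_measurements": 1})
        ds = AggregatedDataset(frame=frame, mode="control")
        assert frame["smiles"].map(murcko_scaffold).nunique() >= 20
        for seed in (0, 1, 2):
            split = split_dataset(ds, "scaffold", 0.1, seed=seed)
            assert abs(len(split.test_idx) / len(smiles) - 0.1) <= 0.05

    def test_single_scaffold_is_error(self, rng):
        ds = _dataset(20, rng, n_scaffold_cores=1)
        with pytest.raises(ParameterError, match="single scaffold"):
            split_dataset(ds, "scaffold", seed=0)

    def test_too_few_rows_is_error(self, rng):
        with pytest.raises(ParameterError):
            split_dataset(_dataset(5, rng), "random", seed=0)


class _FixedModel:
    """Prediction stub for metric tests."""

    def __init__(self, pred):
        self._pred = np.asarray(pred, dtype=float)

    def predict(self, X):
        return self._pred


class TestEvaluateModel:
    def test_perfect_predictions(self):
        y = np.array([5.0, 6.0, 7.0, 8.0])
        report = evaluate_model(_FixedModel(y[:, None]), np.zeros((4, 1)), y)
        assert (report.r2, report.rmse, report.kendall_tau) == (1.0, 0.0, 1.0)

    def test_reversed_ranking_tau(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        report = evaluate_model(_FixedModel(-y[:, None]), np.zeros((4, 1)), y)
        assert report.kendall_tau == -1.0

    def test_multitask_weighted_average(self):
        # two tasks with R^2 0.5 (n=10) and 1.0 (n=30) -> weighted 0.875
        rng = np.random.default_rng(0)
        y1 = rng.normal(size=10)
        y2 = rng.normal(size=30)
        resid = y1 - y1.mean()
        pred1 = y1 - resid * np.sqrt(0.5)  # SSE = 0.5 * SST -> R^2 = 0.5
        Y = np.full((40, 2), np.nan)
        Y[:10, 0] = y1
        Y[10:, 1] = y2
        pred = np.zeros((40, 2))
        pred[:10, 0] = pred1
        pred[10:, 1] = y2
        report = evaluate_model(_FixedModel(pred), np.zeros((40, 1)), Y)
        assert report.r2 == pytest.approx(0.875)
        assert report.per_task["n"].tolist() == [10, 30]

    def test_small_task_excluded_from_weighting(self):
        Y = np.full((5, 2), np.nan)
        Y[:4, 0] = [1, 2, 3, 4.0]
        Y[4, 1] = 9.0  # single observation: excluded
        pred = np.zeros((5, 2))
        pred[:4, 0] = [1, 2, 3, 4.0]
        with pytest.warns(UserWarning, match="fewer than 2"):
            report = evaluate_model(_FixedModel(pred), np.zeros((5, 1)), Y)
        assert report.n == 4


class TestFeatureImportance:
    def test_block_attribution_and_proportions(self, rng):
        from assayscope.boosting import train_single_task

        X = rng.integers(0, 2, (200, 6)).astype(float)
        y = 3.0 * X[:, 1] + 0.01 * rng.normal(size=200)
        model = train_single_task(X, y, BoostingSpec(max_trees=30, min_points_per_leaf=5),
                                  seed=0)
        blocks = {"molecule": (0, 4), "protein": (4, 6)}
        ranked, proportions = feature_importance(model, blocks, top_k=6)
        assert ranked.iloc[0]["feature"] == 1
        assert ranked.iloc[0]["block"] == "molecule"
        assert proportions.sum() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def fitted():
    bio = generate_bioactivity(n_targets=5, n_compounds_per_target=30,
                               offset_sd=0.5, noise_sd=0.3, seed=4)
    agg = aggregate_measurements(bio.table, "control")
    features = build_feature_matrix(agg, bio.alignment)
    spec = BoostingSpec(max_trees=40, min_points_per_leaf=10)
    model = PCMModel(features, y=agg.frame["pchembl"].to_numpy(), spec=spec)
    split = split_dataset(agg, "random", seed=0)
    return model, split, model.fit(split, seed=0)


class TestPCMModelEndToEnd:
    def test_blocks_partition_columns(self, fitted):
        model, _, _ = fitted
        fm = model.features
        assert fm.blocks["molecule"] == (0, 2048)
        assert fm.blocks["protein"][1] == fm.X.shape[1]

    def test_fit_deterministic(self, fitted):
        model, split, result = fitted
        again = model.fit(split, seed=0)
        assert np.array_equal(result.column_mask, again.column_mask)
        assert result.metrics.r2 == again.metrics.r2

    def test_summary_mentions_metrics(self, fitted):
        _, _, result = fitted
        text = result.summary()
        assert "test R^2" in text and "realized trees" in text

    def test_metadata_roundtrip(self, fitted, tmp_path):
        import json

        _, _, result = fitted
        result.save_metadata(tmp_path / "model.json")
        meta = json.loads((tmp_path / "model.json").read_text())
        assert meta["realized_trees"] == result.n_trees
        assert meta["spec"]["max_trees"] == 40
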