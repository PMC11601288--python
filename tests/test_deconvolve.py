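import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from subspot.deconvolve import (
    ReferenceProfile,
    aggregate_protein_subspots,
    compute_reference_profiles,
    export_wnn_inputs,
    predict_labels,
    split_spots,
    train_label_classifier,
)
from subspot.grid import SpotComposition, compute_composition
from subspot.preprocess import ProteinMatrix


def make_comp(beta_rows, types, spots=None):
    spots = spots or [f"1x{k + 1}" for k in range(len(beta_rows))]
    beta = pd.DataFrame(beta_rows, index=pd.Index(spots, name="spot"), columns=types)
    counts = (beta * 4).round().astype(int)
    return SpotComposition(beta=beta, n_cells=counts, undefined_spots=[])


class TestReferenceProfiles:
    def test_one_cell_per_type(self):
        counts = pd.DataFrame(
            [[2.0, 0.0, 2.0], [1.0, 1.0, 0.0]],
            index=pd.Index(["c1", "c2"], name="cell"),
            columns=["g1", "g2", "g3"],
        )
        labels = pd.Series(["A", "B"], index=counts.index)
        ref = compute_reference_profiles(counts, labels)
        # each cell scaled to the median total (3 counts here), then averaged alone
        target = np.median([4.0, 2.0])
        np.testing.assert_allclose(ref.mu.loc["A"], counts.loc["c1"] * target / 4.0)
        np.testing.assert_allclose(ref.mu.loc["B"], counts.loc["c2"] * target / 2.0)

    def test_two_identical_cells_average_to_either(self):
        counts = pd.DataFrame([[1.0, 3.0]] * 2, index=pd.Index(["c1", "c2"], name="cell"), columns=["g1", "g2"])
        labels = pd.Series(["A", "A"], index=counts.index)
        ref = compute_reference_profiles(counts, labels, norm="raw")
        np.testing.assert_allclose(ref.mu.loc["A"], [1.0, 3.0])

    def test_matches_group_mean_oracle(self, rng):
        counts = pd.DataFrame(
            rng.poisson(5.0, size=(30, 8)).astype(float),
            index=pd.Index([f"c{i}" for i in range(30)], name="cell"),
            columns=[f"g{j}" for j in range(8)],
        )
        counts += 0.1  # avoid zero totals
        labels = pd.Series(np.repeat(["A", "B", "C"], 10), index=counts.index)
        ref = compute_reference_profiles(counts, labels)
        target = np.median(counts.sum(axis=1))
        normed = counts.mul(target / counts.sum(axis=1), axis=0)
        for t in ["A", "B", "C"]:
            oracle = normed[labels == t].mean(axis=0)
            np.testing.assert_allclose(ref.mu.loc[t], oracle, rtol=1e-12)

    def test_unlabeled_cell_rejected(self):
        counts = pd.DataFrame([[1.0]], index=pd.Index(["c1"], name="cell"), columns=["g"])
        with pytest.raises(ValueError):
            compute_reference_profiles(counts, pd.Series(dtype=object))


class TestSplitSpots:
    def test_hand_worked_example(self):
        # x=8, beta=(0.5, 0.5), mu_j=(2, 6): denominator 4, split (2, 6)
        x = pd.DataFrame([[8.0]], index=pd.Index(["1x1"], name="spot"), columns=["g"])
        comp = make_comp([[0.5, 0.5]], ["A", "B"], spots=["1x1"])
        mu = ReferenceProfile(pd.DataFrame([[2.0], [6.0]], index=["A", "B"], columns=["g"]))
        out = split_spots(x, comp, mu)
        assert out.x.loc[("1x1", "A"), "g"] == pytest.approx(2.0)
        assert out.x.loc[("1x1", "B"), "g"] == pytest.approx(6.0)

    def test_one_hot_composition_takes_everything(self):
        x = pd.DataFrame([[5.0, 7.0]], index=pd.Index(["1x1"], name="spot"), columns=["g1", "g2"])
        comp = make_comp([[1.0, 0.0]], ["A", "B"], spots=["1x1"])
        mu = ReferenceProfile(pd.DataFrame([[1.0, 1.0], [9.9, 0.4]], index=["A", "B"], columns=["g1", "g2"]))
        out = split_spots(x, comp, mu)
        np.testing.assert_allclose(out.x.loc[("1x1", "A")], [5.0, 7.0])
        assert ("1x1", "B") not in out.x.index

    def test_zero_count_spot_splits_to_zero(self):
        x = pd.DataFrame([[0.0]], index=pd.Index(["1x1"], name="spot"), columns=["g"])
        comp = make_comp([[0.5, 0.5]], ["A", "B"], spots=["1x1"])
        mu = ReferenceProfile(pd.DataFrame([[2.0], [6.0]], index=["A", "B"], columns=["g"]))
        assert (split_spots(x, comp, mu).x.to_numpy() == 0).all()

    def test_beta_fallback_on_zero_denominator(self):
        x = pd.DataFrame([[4.0]], index=pd.Index(["1x1"], name="spot"), columns=["g"])
        comp = make_comp([[0.25, 0.75]], ["A", "B"], spots=["1x1"])
        mu = ReferenceProfile(pd.DataFrame([[0.0], [0.0]], index=["A", "B"], columns=["g"]))
        out = split_spots(x, comp, mu, fallback="beta")
        np.testing.assert_allclose(out.x["g"].to_numpy(), [1.0, 3.0])
        assert out.report["n_fallback_entries"] == 1
        out_drop = split_spots(x, comp, mu, fallback="drop")
        assert (out_drop.x.to_numpy() == 0).all()

    def test_missing_type_named_in_error(self):
        x = pd.DataFrame([[4.0]], index=pd.Index(["1x1"], name="spot"), columns=["g"])
        comp = make_comp([[0.5, 0.5]], ["A", "Bizarre"], spots=["1x1"])
        mu = ReferenceProfile(pd.DataFrame([[1.0]], index=["A"], columns=["g"]))
        with pytest.raises(ValueError, match="Bizarre"):
            split_spots(x, comp, mu)

    def test_undefined_spots_skipped_and_reported(self):
        x = pd.DataFrame(
            [[4.0], [6.0]], index=pd.Index(["1x1", "9x9"], name="spot"), columns=["g"]
        )
        comp = make_comp([[1.0, 0.0]], ["A", "B"], spots=["1x1"])
        mu = ReferenceProfile(pd.DataFrame([[1.0], [1.0]], index=["A", "B"], columns=["g"]))
        out = split_spots(x, comp, mu)
        assert out.report["n_spots_skipped_undefined"] == 1
        assert "9x9" in out.report["skipped_spots"]

    def test_degenerate_mu_reduces_to_proportional_allocation(self, rng):
        genes = [f"g{j}" for j in range(6)]
        x = pd.DataFrame(rng.poisson(20, (4, 6)).astype(float), index=pd.Index([f"s{i}" for i in range(4)], name="spot"), columns=genes)
        beta_rows = rng.dirichlet([1, 1, 1], size=4)
        comp = make_comp(beta_rows, ["A", "B", "C"], spots=list(x.index))
        mu = ReferenceProfile(pd.DataFrame(np.tile(rng.uniform(1, 5, 6), (3, 1)), index=["A", "B", "C"], columns=genes))
        out = split_spots(x, comp, mu)
        for (s, t), row in out.x.iterrows():
            expected = x.loc[s] * comp.beta.loc[s, t]
            np.testing.assert_allclose(row, expected, rtol=1e-9)

    def test_mass_conservation_on_simulation(self, sim, labelled_cells):
        comp = compute_composition(sim.assignment, labelled_cells, types=list(sim.truth.cell_types))
        counts = sim.counts.loc[sim.counts.sum(axis=1) > 0]
        out = split_spots(counts, comp, ReferenceProfile(sim.truth.mu_true))
        assert out.conservation_error(counts) < 1e-9

    def test_permutation_equivariance_in_genes_and_types(self, rng):
        genes = [f"g{j}" for j in range(5)]
        x = pd.DataFrame(rng.poisson(10, (3, 5)).astype(float), index=pd.Index(["s0", "s1", "s2"], name="spot"), columns=genes)
        beta_rows = rng.dirichlet([1, 1], size=3)
        mu_vals = rng.uniform(0.5, 3.0, (2, 5))
        comp = make_comp(beta_rows, ["A", "B"], spots=list(x.index))
        mu = ReferenceProfile(pd.DataFrame(mu_vals, index=["A", "B"], columns=genes))
        base = split_spots(x, comp, mu)
        perm = list(reversed(genes))
        comp2 = make_comp(beta_rows[:, ::-1], ["B", "A"], spots=list(x.index))
        mu2 = ReferenceProfile(pd.DataFrame(mu_vals[::-1, ::-1], index=["B", "A"], columns=perm))
        shuffled = split_spots(x[perm], comp2, mu2)
        reordered = shuffled.x.loc[base.x.index, genes]
        np.testing.assert_allclose(reordered.to_numpy(), base.x.to_numpy(), rtol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_conservation_property_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n_spots, n_types, n_genes = 4, 3, 6
        x = pd.DataFrame(
            rng.poisson(15, (n_spots, n_genes)).astype(float),
            index=pd.Index([f"s{i}" for i in range(n_spots)], name="spot"),
            columns=[f"g{j}" for j in range(n_genes)],
        )
        beta_rows = rng.dirichlet(np.ones(n_types), size=n_spots)
        mu_vals = rng.uniform(0, 2, (n_types, n_genes))
        mu_vals[rng.uniform(size=mu_vals.shape) < 0.3] = 0.0  # provoke zero denominators
        comp = make_comp(beta_rows, ["A", "B", "C"], spots=list(x.index))
        mu = ReferenceProfile(pd.DataFrame(mu_vals, index=["A", "B", "C"], columns=x.columns))
        out = split_spots(x, comp, mu, fallback="beta")
        totals = out.x.groupby(level="spot", sort=False).sum()
        np.testing.assert_allclose(totals.to_numpy(), x.loc[totals.index].to_numpy(), rtol=1e-9, atol=1e-9)


class TestProteinAggregation:
    def _setup(self, rng, n=200):
        spots = [f"1x{1 + (i % 5)}" for i in range(n)]
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(1, n + 1),
                "x": rng.uniform(0, 100, n),
                "y": rng.uniform(0, 100, n),
                "area": 10.0,
                "label": rng.choice(["A", "B"], n),
            }
        )
        vals = pd.DataFrame(
            rng.uniform(0, 1, (n, 2)),
            index=pd.Index(cells["cell_id"], name="cell_id"),
            columns=["m1", "m2"],
        )
        anchors = pd.DataFrame({"q05": 0.0, "q95": 1.0}, index=["m1", "m2"])
        pm = ProteinMatrix(values=vals, anchors=anchors)
        assignment = pd.Series(spots, index=vals.index)
        return cells, pm, assignment

    def test_single_cell_subspot_equals_cell(self, rng):
        cells, pm, assignment = self._setup(rng, n=1)
        means, meta = aggregate_protein_subspots(cells, pm, assignment)
        np.testing.assert_allclose(means.iloc[0], pm.values.iloc[0])
        assert meta.iloc[0]["n_cells"] == 1

    def test_mean_of_two(self):
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "x": [0.0, 2.0], "y": [0.0, 4.0], "area": 1.0, "label": ["A", "A"]}
        )
        vals = pd.DataFrame({"m": [0.2, 0.6]}, index=pd.Index([1, 2], name="cell_id"))
        pm = ProteinMatrix(values=vals, anchors=pd.DataFrame({"q05": [0.0], "q95": [1.0]}, index=["m"]))
        assignment = pd.Series(["1x1", "1x1"], index=vals.index)
        means, meta = aggregate_protein_subspots(cells, pm, assignment)
        assert means.loc[("1x1", "A"), "m"] == pytest.approx(0.4)
        assert (meta.loc[("1x1", "A"), ["x", "y"]] == [1.0, 2.0]).all()

    def test_matches_group_mean_oracle(self, rng):
        cells, pm, assignment = self._setup(rng)
        means, meta = aggregate_protein_subspots(cells, pm, assignment)
        for (spot, typ), row in means.iterrows():
            members = [
                cid
                for cid in cells["cell_id"]
                if assignment.loc[cid] == spot and cells.set_index("cell_id").loc[cid, "label"] == typ
            ]
            oracle = pm.values.loc[members].mean(axis=0)
            np.testing.assert_allclose(row, oracle, rtol=1e-12)
            assert meta.loc[(spot, typ), "n_cells"] == len(members)


class TestLabelClassifier:
    def _separable(self, rng, n=100):
        labels = np.repeat(["A", "B"], n // 2)
        x = np.where(labels[:, None] == "A", rng.normal(0.2, 0.02, (n, 3)), rng.normal(0.8, 0.02, (n, 3)))
        return pd.DataFrame(x, index=pd.Index(range(n), name="cell_id"), columns=["m1", "m2", "m3"]), pd.Series(labels, index=range(n))

    def test_separable_types_perfect_holdout_f1(self, rng):
        X, y = self._separable(rng)
        clf = train_label_classifier(X, y, seed=0)
        assert clf.holdout_f1 == {"A": 1.0, "B": 1.0}

    def test_self_prediction_zero_errors(self, rng):
        X, y = self._separable(rng)
        clf = train_label_classifier(X, y, seed=0)
        pred, scores = predict_labels(clf, X)
        assert (pred == y).all()
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_accuracy_near_bayes_rule_for_overlapping_gaussians(self, rng):
        # equal-prior 1D Gaussians at -1/+1, sd 1: Bayes accuracy = Phi(1)
        n = 4000
        labels = np.repeat(["A", "B"], n // 2)
        x = np.where(labels == "A", rng.normal(-1, 1, n), rng.normal(1, 1, n))
        order = rng.permutation(n)
        X = pd.DataFrame({"m": x[order]}, index=pd.Index(range(n), name="cell_id"))
        y = pd.Series(labels[order], index=range(n))
        train, test = slice(0, 3000), slice(3000, 4000)
        clf = train_label_classifier(X.iloc[train], y.iloc[train], seed=1)
        pred, _ = predict_labels(clf, X.iloc[test])
        acc = (pred == y.iloc[test]).mean()
        bayes = stats.norm.cdf(1.0)
        assert abs(acc - bayes) < 0.05

    def test_single_class_and_sparse_class_rejected(self, rng):
        X, y = self._separable(rng)
        with pytest.raises(ValueError, match="2 classes"):
            train_label_classifier(X, pd.Series("A", index=y.index), seed=0)
        y_sparse = y.copy()
        y_sparse.iloc[:48] = "B"  # leaves 2 A's
        with pytest.raises(ValueError, match="5 pivots"):
            train_label_classifier(X, y_sparse, seed=0)


class TestExportWnnInputs:
    def _subspots(self, sim, labelled_cells):
        comp = compute_composition(sim.assignment, labelled_cells, types=list(sim.truth.cell_types))
        counts = sim.counts.loc[sim.counts.sum(axis=1) > 0]
        out = split_spots(counts, comp, ReferenceProfile(sim.truth.mu_true))
        markers = sim.truth.markers
        vals = sim.cells.set_index("cell_id")[markers]
        vals = (vals - vals.min()) / (vals.max() - vals.min())
        pm = ProteinMatrix(values=vals, anchors=pd.DataFrame({"q05": 0.0, "q95": 1.0}, index=markers))
        protein, meta = aggregate_protein_subspots(sim.cells, pm, sim.assignment)
        out.protein, out.meta = protein, meta
        return out, counts

    def test_roundtrip_preserves_integer_rna(self, sim, labelled_cells, tmp_path):
        out, counts = self._subspots(sim, labelled_cells)
        # integer RNA values survive the MatrixMarket round trip bit-exactly
        out.x = out.x.round()
        report = export_wnn_inputs(out, tmp_path)
        from scipy import io as spio

        mat = np.asarray(spio.mmread(str(tmp_path / "rna.mtx")).todense()).T
        np.testing.assert_array_equal(mat, out.x.to_numpy())
        ids = (tmp_path / "barcodes.tsv").read_text().splitlines()
        assert ids == [f"{s}|{t}" for s, t in out.x.index]
        prot = pd.read_csv(tmp_path / "protein.csv", index_col="subspot")
        assert list(prot.index) == ids
        assert report["n_subspots"] == len(ids)

    def test_row_count_matches_positive_beta_with_cells(self, sim, labelled_cells, tmp_path):
        out, _ = self._subspots(sim, labelled_cells)
        report = export_wnn_inputs(out, tmp_path)
        # composition comes from the cells themselves, so every beta>0 pair has >=1 cell
        assert report["n_excluded_no_protein"] == 0
        assert report["n_subspots"] == len(out.x)

    def test_missing_protein_rejected(self, sim, labelled_cells, tmp_path):
        comp = compute_composition(sim.assignment, labelled_cells, types=list(sim.truth.cell_types))
        counts = sim.counts.loc[sim.counts.sum(axis=1) > 0]
        out = split_spots(counts, comp, ReferenceProfile(sim.truth.mu_true))
        with pytest.raises(ValueError, match="protein"):
            export_wnn_inputs(out, tmp_path)
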