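"""Binned marginals and the ensemble entropy matrix."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import serkit as sk
from serkit.entropy import PARAMETER_PAIRS, PARAMETERS
from serkit.errors import ValidationError


def hand_entropy(probabilities):
    """Independent −Σ p ln p with 0 ln 0 = 0 (plain Python loop)."""
    return -sum(p * math.log(p) for p in np.ravel(probabilities) if p > 0)


def hand_bin_index(value, edges):
    """Half-open bins, final bin closed."""
    for k in range(len(edges) - 2):
        if edges[k] <= value < edges[k + 1]:
            return k
    return len(edges) - 2


def _series_from(values_by_param, n_residues=50):
    return sk.PropertySeries(
        sequence_id="t", n_residues=n_residues,
        data=pd.DataFrame(values_by_param))


class TestMakeBins:
    def test_equal_width_edges(self):
        series = _series_from({
            "Rg": np.linspace(10, 20, 8), "delta": np.linspace(0.1, 0.9, 8),
            "Re": np.linspace(5, 50, 8)})
        spec = sk.make_bins(series, sk.BinSpec(n=4, ranges={
            "Rg": (10, 20), "delta": (0, 1), "Re": (5, 50)}))
        np.testing.assert_allclose(spec.edges_for("Rg"), [10, 12.5, 15, 17.5, 20])

    def test_pooled_edges_cover_all_series(self):
        a = _series_from({"Rg": [10.0, 12.0], "delta": [0.2, 0.4], "Re": [5.0, 9.0]})
        b = _series_from({"Rg": [18.0, 20.0], "delta": [0.5, 0.8], "Re": [30.0, 40.0]})
        spec = sk.make_bins([a, b], sk.BinSpec(n=4))
        edges = spec.edges_for("Rg")
        assert edges[0] <= 10.0 and edges[-1] >= 20.0
        # pooled delta defaults to the theoretical [0, 1]
        np.testing.assert_allclose(spec.edges_for("delta"), [0, 0.25, 0.5, 0.75, 1.0])

    def test_constant_series_pooled_errors(self):
        series = _series_from({
            "Rg": [5.0, 5.0], "delta": [0.5, 0.5], "Re": [7.0, 7.0]})
        with pytest.raises(ValidationError, match="explicit range"):
            sk.make_bins(series, sk.BinSpec(n=4))

    def test_max_falls_inside_last_bin(self):
        series = _series_from({
            "Rg": np.linspace(10, 20, 10), "delta": np.linspace(0, 1, 10),
            "Re": np.linspace(5, 50, 10)})
        spec = sk.make_bins(series, sk.BinSpec(n=4))
        d = sk.marginal_1d(series, "Rg", spec)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestMarginals:
    def test_even_fill(self):
        series = _series_from({
            "Rg": [10.5, 11, 13, 14, 15.5, 16, 18, 19],
            "delta": [0.5] * 8, "Re": [10.0] * 8})
        spec = sk.make_bins(series, sk.BinSpec(n=4, ranges={
            "Rg": (10, 20), "delta": (0, 1), "Re": (5, 15)}))
        d = sk.marginal_1d(series, "Rg", spec)
        np.testing.assert_allclose(d.probabilities, [0.25] * 4)

    def test_single_bin_occupancy(self):
        series = _series_from({
            "Rg": [10.1, 10.2, 10.3, 10.4], "delta": [0.5] * 4, "Re": [10.0] * 4})
        spec = sk.make_bins(series, sk.BinSpec(n=4, ranges={
            "Rg": (10, 20), "delta": (0, 1), "Re": (5, 15)}))
        np.testing.assert_allclose(
            sk.marginal_1d(series, "Rg", spec).probabilities, [1, 0, 0, 0])

    def test_2d_grid_matches_hand_tally(self):
        rg = [10.5, 12.6, 12.7, 17.6, 19.0, 19.5]
        delta = [0.1, 0.3, 0.8, 0.3, 0.9, 0.95]
        series = _series_from({"Rg": rg, "delta": delta, "Re": [10.0] * 6})
        spec = sk.make_bins(series, sk.BinSpec(n=4, ranges={
            "Rg": (10, 20), "delta": (0, 1), "Re": (5, 15)}))
        d = sk.marginal_2d(series, ("Rg", "delta"), spec)
        tally = Counter(
            (hand_bin_index(x, spec.edges_for("Rg")),
             hand_bin_index(y, spec.edges_for("delta")))
            for x, y in zip(rg, delta))
        expected = np.zeros((4, 4))
        for (i, j), c in tally.items():
            expected[i, j] = c / 6
        np.testing.assert_allclose(d.probabilities, expected, atol=1e-12)

    def test_out_of_range_values_clipped_not_dropped(self):
        series = _series_from({
            "Rg": [8.0, 25.0, 12.0, 13.0], "delta": [0.5] * 4, "Re": [10.0] * 4})
        spec = sk.make_bins(series, sk.BinSpec(n=4, ranges={
            "Rg": (10, 20), "delta": (0, 1), "Re": (5, 15)}))
        d = sk.marginal_1d(series, "Rg", spec)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(d.probabilities, [0.5, 0.25, 0, 0.25])

    def test_axis_marginals_of_grid_match_1d(self, small_series, resolved_spec):
        for px, py in PARAMETER_PAIRS:
            grid = sk.marginal_2d(small_series, (px, py), resolved_spec).probabilities
            np.testing.assert_allclose(
                grid.sum(axis=1),
                sk.marginal_1d(small_series, px, resolved_spec).probabilities,
                atol=1e-12)
            np.testing.assert_allclose(
                grid.sum(axis=0),
                sk.marginal_1d(small_series, py, resolved_spec).probabilities,
                atol=1e-12)


class TestEntropies:
    def test_flat_four_bins_hits_printed_limit(self):
        d = sk.Distribution1D("Rg", np.linspace(0, 1, 5), np.full(4, 0.25))
        assert sk.entropy_1d(d) == pytest.approx(1.386, abs=5e-4)
        assert sk.entropy_1d(d) == pytest.approx(math.log(4), rel=1e-12)

    def test_point_mass_is_zero(self):
        d = sk.Distribution1D("Rg", np.linspace(0, 1, 5), np.array([1.0, 0, 0, 0]))
        assert sk.entropy_1d(d) == 0.0

    def test_half_half_is_ln2(self):
        d = sk.Distribution1D("Rg", np.linspace(0, 1, 5), np.array([0.5, 0.5, 0, 0]))
        assert sk.entropy_1d(d) == pytest.approx(math.log(2), rel=1e-12)

    def test_flat_grid_hits_printed_limit(self):
        d = sk.Distribution2D(("Rg", "delta"), np.linspace(0, 1, 5),
                              np.linspace(0, 1, 5), np.full((4, 4), 1 / 16))
        assert sk.entropy_2d(d) == pytest.approx(2.773, abs=5e-4)

    def test_single_cell_is_zero(self):
        p = np.zeros((4, 4)); p[2, 1] = 1.0
        d = sk.Distribution2D(("Rg", "delta"), np.linspace(0, 1, 5),
                              np.linspace(0, 1, 5), p)
        assert sk.entropy_2d(d) == 0.0

    def test_product_grid_is_additive(self, rng):
        px = rng.dirichlet(np.ones(4))
        py = rng.dirichlet(np.ones(4))
        grid = np.outer(px, py)
        d2 = sk.Distribution2D(("Rg", "delta"), np.linspace(0, 1, 5),
                               np.linspace(0, 1, 5), grid)
        assert sk.entropy_2d(d2) == pytest.approx(
            hand_entropy(px) + hand_entropy(py), rel=1e-10)


class TestEnsembleEntropyMatrix:
    def test_matches_hand_tally_on_20_row_fixture(self, small_series, resolved_spec):
        m = sk.ensemble_entropy_matrix(small_series, resolved_spec)
        # independent oracle: hand binning + plain-loop entropy
        edges = {p: resolved_spec.edges_for(p) for p in PARAMETERS}
        idx = {p: [hand_bin_index(v, edges[p]) for v in small_series.values(p)]
               for p in PARAMETERS}
        for a, p in enumerate(PARAMETERS):
            counts = Counter(idx[p])
            probs = [counts.get(k, 0) / 20 for k in range(4)]
            assert m.matrix[a, a] == pytest.approx(hand_entropy(probs), rel=1e-12)
        index = {p: i for i, p in enumerate(PARAMETERS)}
        for px, py in PARAMETER_PAIRS:
            counts = Counter(zip(idx[px], idx[py]))
            probs = [c / 20 for c in counts.values()]
            i, j = index[px], index[py]
            assert m.matrix[i, j] == pytest.approx(hand_entropy(probs), rel=1e-12)

    def test_degenerate_axis_collapses_joint_to_marginal(self):
        rng = np.random.default_rng(2)
        series = _series_from({
            "Rg": rng.uniform(10, 20, 200), "delta": np.full(200, 0.5),
            "Re": rng.uniform(5, 50, 200)})
        spec = sk.make_bins(series, sk.BinSpec(n=4, ranges={
            "Rg": (10, 20), "delta": (0, 1), "Re": (5, 50)}))
        m = sk.ensemble_entropy_matrix(series, spec)
        assert m.matrix[1, 1] == pytest.approx(0.0, abs=1e-12)  # s(delta) = 0
        assert m.matrix[0, 1] == pytest.approx(m.matrix[0, 0], rel=1e-12)

    def test_row_permutation_invariance(self, small_series, resolved_spec):
        perm = np.random.default_rng(3).permutation(len(small_series))
        shuffled = sk.PropertySeries(
            sequence_id="t", n_residues=small_series.n_residues,
            data=small_series.data.iloc[perm])
        a = sk.ensemble_entropy_matrix(small_series, resolved_spec)
        b = sk.ensemble_entropy_matrix(shuffled, resolved_spec)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_entropy_bounds_and_joint_inequalities(self, rng, resolved_spec):
        ln_n = math.log(4)
        for _ in range(25):
            n_rows = int(rng.integers(5, 400))
            series = _series_from({
                "Rg": rng.uniform(10, 20, n_rows),
                "delta": rng.beta(2, 2, n_rows),
                "Re": rng.uniform(15, 45, n_rows)})
            m = sk.ensemble_entropy_matrix(series, resolved_spec).matrix
            diag = np.diag(m)
            assert np.all(diag >= -1e-12) and np.all(diag <= ln_n + 1e-12)
            for (px, py) in PARAMETER_PAIRS:
                i = PARAMETERS.index(px); j = PARAMETERS.index(py)
                joint = m[i, j]
                assert joint <= 2 * ln_n + 1e-12
                assert joint >= max(m[i, i], m[j, j]) - 1e-12
                assert joint <= m[i, i] + m[j, j] + 1e-12

    def test_serialization_round_trip(self, small_series, resolved_spec, tmp_path):
        m = sk.ensemble_entropy_matrix(small_series, resolved_spec)
        path = tmp_path / "m.json"
        m.to_json(path)
        back = sk.EnsembleEntropyMatrix.from_json(path)
        np.testing.assert_allclose(back.matrix, m.matrix, rtol=1e-12)
        assert back.spec.fingerprint == m.spec.fingerprint
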