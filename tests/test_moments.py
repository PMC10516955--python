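"""Moment vectors, GMM weights and the GMM cost."""

import numpy as np
import pytest

import snapgmm as sg
from snapgmm.moments import MomentLevel, moment_labels

from conftest import make_self_consistent


@pytest.mark.parametrize(
    "p, level, expected",
    [
        (6, MomentLevel.FULL, 27),
        (5, MomentLevel.FULL, 20),
        (4, MomentLevel.FULL, 14),
        (1, MomentLevel.MEANS, 1),
        (6, MomentLevel.MEANS, 6),
        (6, MomentLevel.MEANS_VARS, 12),
    ],
)
def test_moment_length(p, level, expected):
    assert sg.moment_length(p, level) == expected


def brute_force_moments(m, level):
    """Independent two-pass loop computation of the stacked moment vector."""
    n, p = m.shape
    means = [sum(m[c, i] for c in range(n)) / n for i in range(p)]
    out = list(means)
    if level in (MomentLevel.MEANS_VARS, MomentLevel.FULL):
        for i in range(p):
            out.append(sum((m[c, i] - means[i]) ** 2 for c in range(n)) / (n - 1))
    if level is MomentLevel.FULL:
        for i in range(p):
            for j in range(i + 1, p):
                out.append(
                    sum((m[c, i] - means[i]) * (m[c, j] - means[j])
                        for c in range(n)) / (n - 1)
                )
    return np.array(out)


class TestComputeMoments:
    def test_two_point_sample(self):
        mv = sg.compute_moments(np.array([[1.0], [3.0]]), MomentLevel.FULL)
        np.testing.assert_allclose(mv.values, [2.0, 2.0])
        assert mv.labels == ["mean:s1", "var:s1"]

    def test_means_are_column_averages(self):
        m = np.arange(12.0).reshape(4, 3)
        mv = sg.compute_moments(m, MomentLevel.MEANS)
        np.testing.assert_allclose(mv.values, m.mean(axis=0))

    @pytest.mark.parametrize("level", list(MomentLevel))
    def test_matches_brute_force(self, level):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 10, size=(5, 3))
        mv = sg.compute_moments(m, level)
        np.testing.assert_allclose(mv.values, brute_force_moments(m, level))

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError, match="2 cells"):
            sg.compute_moments(np.ones((1, 3)), MomentLevel.MEANS)

    def test_prefix_property(self):
        """MEANS is a prefix of MEANS_VARS which is a prefix of FULL."""
        rng = np.random.default_rng(8)
        m = rng.lognormal(0, 0.5, size=(30, 4))
        v1 = sg.compute_moments(m, MomentLevel.MEANS).values
        v2 = sg.compute_moments(m, MomentLevel.MEANS_VARS).values
        v3 = sg.compute_moments(m, MomentLevel.FULL).values
        np.testing.assert_array_equal(v2[: v1.size], v1)
        np.testing.assert_array_equal(v3[: v2.size], v2)

    def test_label_ordering(self):
        labels = moment_labels(["A", "B", "C"], MomentLevel.FULL)
        assert labels == [
            "mean:A", "mean:B", "mean:C",
            "var:A", "var:B", "var:C",
            "cov:A:B", "cov:A:C", "cov:B:C",
        ]


class TestWeights:
    def test_identity(self):
        w = sg.weight_from_data(np.random.default_rng(0).uniform(size=(10, 2)),
                                MomentLevel.FULL, method="identity")
        np.testing.assert_array_equal(w, np.eye(5))

    def test_single_species_means_diagonal(self):
        """For one species at MEANS level the contribution vector is the
        abundance itself, so the weight is n / s^2 (up to the tiny ridge)."""
        rng = np.random.default_rng(1)
        y = rng.lognormal(1, 0.3, size=(200, 1))
        w = sg.weight_from_data(y, MomentLevel.MEANS, method="diagonal", ridge=0.0)
        s2 = y[:, 0].var(ddof=1)
        np.testing.assert_allclose(w[0, 0], len(y) / s2, rtol=1e-12)

    def test_inverse_contract(self):
        rng = np.random.default_rng(2)
        y = rng.lognormal(1, 0.4, size=(500, 3))
        level = MomentLevel.FULL
        w = sg.weight_from_data(y, level, method="inverse_cov")
        from snapgmm.moments import _contributions

        u = _contributions(y, level)
        L = u.shape[1]
        sigma = np.cov(u, rowvar=False) / len(y)
        ridge = 1e-6 * np.trace(sigma) / L
        np.testing.assert_allclose(w @ (sigma + ridge * np.eye(L)), np.eye(L),
                                   atol=1e-8)

    def test_inverse_cov_blocks_are_psd(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            y = rng.lognormal(0, 0.5, size=(100, 3))
            w = sg.weight_from_data(y, MomentLevel.FULL)
            eig = np.linalg.eigvalsh(w)
            assert eig.min() >= -1e-10

    def test_small_sample_falls_back_to_diagonal(self, caplog):
        rng = np.random.default_rng(5)
        y = rng.lognormal(0, 0.5, size=(10, 4))  # 14 moments > 10 cells
        with caplog.at_level("WARNING", logger="snapgmm.moments"):
            w = sg.weight_from_data(y, MomentLevel.FULL, method="inverse_cov")
        assert "falling back" in caplog.text
        off_diag = w - np.diag(np.diag(w))
        assert np.abs(off_diag).max() == 0.0


class TestCost:
    def _mv(self, values):
        vals = np.asarray(values, float)
        labels = [f"mean:s{i}" for i in range(vals.size)]
        return sg.MomentVector(MomentLevel.MEANS, labels, vals)

    def test_zero_at_equality(self):
        mv = self._mv([1.0, 2.0])
        assert sg.gmm_cost(mv, mv, np.eye(2)) == 0.0

    def test_identity_weight_is_squared_distance(self):
        assert sg.gmm_cost(self._mv([1, 2]), self._mv([0, 0]), np.eye(2)) == 5.0

    def test_quadratic_form_by_hand(self):
        w = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert sg.gmm_cost(self._mv([1, 0]), self._mv([0, 0]), w) == 2.0

    def test_label_mismatch_rejected(self):
        a = self._mv([1.0])
        b = sg.MomentVector(MomentLevel.MEANS, ["mean:other"], [1.0])
        with pytest.raises(ValueError, match="labels"):
            sg.gmm_cost(a, b, np.eye(1))


class TestTotalCost:
    def test_self_consistent_truth_is_zero(self, linear6, linear6_selfconsistent):
        weights = [
            sg.weight_from_data(y, MomentLevel.FULL)
            for _, y in linear6_selfconsistent.observations
        ]
        c = sg.total_cost(linear6, linear6.free_values(), linear6_selfconsistent,
                          MomentLevel.FULL, weights)
        assert 0 <= c < 1e-10

    def test_nonnegative_everywhere(self, linear6, linear6_selfconsistent):
        weights = [
            sg.weight_from_data(y, MomentLevel.FULL)
            for _, y in linear6_selfconsistent.observations
        ]
        rng = np.random.default_rng(6)
        for _ in range(5):
            free = rng.uniform(0.01, 2.0, size=6)
            assert sg.total_cost(linear6, free, linear6_selfconsistent,
                                 MomentLevel.FULL, weights) >= 0

    def test_truth_beats_perturbation(self, linear6, linear6_selfconsistent):
        weights = [
            sg.weight_from_data(y, MomentLevel.FULL)
            for _, y in linear6_selfconsistent.observations
        ]
        at_truth = sg.total_cost(linear6, linear6.free_values(),
                                 linear6_selfconsistent, MomentLevel.FULL, weights)
        perturbed = sg.total_cost(linear6, 2.0 * linear6.free_values(),
                                  linear6_selfconsistent, MomentLevel.FULL, weights)
        assert at_truth < perturbed

    def test_permutation_invariance(self, linear6, linear6_cells):
        """Permuting species order consistently in model and data leaves
        the cost unchanged."""
        ds = make_self_consistent(linear6, linear6_cells, [1.5])
        perm = [3, 0, 5, 1, 4, 2]
        text = linear6.to_bngl()
        # rebuild a network with permuted species declarations
        lines = text.splitlines()
        sp_start = lines.index("begin species") + 1
        block = lines[sp_start:sp_start + 6]
        lines[sp_start:sp_start + 6] = [block[i] for i in perm]
        net_p = sg.parse_bngl("\n".join(lines))
        ds_p = sg.SnapshotDataset(
            x0=ds.x0[:, perm],
            observations=[(t, y[:, perm]) for t, y in ds.observations],
        )
        free = 1.7 * linear6.free_values()
        for level in (MomentLevel.MEANS, MomentLevel.FULL):
            w = [sg.weight_from_data(y, level) for _, y in ds.observations]
            wp = [sg.weight_from_data(y, level) for _, y in ds_p.observations]
            c = sg.total_cost(linear6, free, ds, level, w)
            cp = sg.total_cost(net_p, free, ds_p, level, wp)
            assert c == pytest.approx(cp, rel=1e-8)
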