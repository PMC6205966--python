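"""Quantile normalization, median polish and developmental profiles."""

from statistics import median

import numpy as np
import pandas as pd
import pytest

from panscan.expression import (
    mean_replicate_profile,
    median_polish,
    quantile_normalize,
    summarize_probesets,
)
from panscan.synthetic_data import simulate_expression


def _df(rows, index=None, columns=None):
    return pd.DataFrame(rows, index=index, columns=columns, dtype=float)


class TestQuantileNormalize:
    def test_hand_computed_2x2_example(self):
        out = quantile_normalize(_df([[1, 4], [3, 2]]))
        assert out.to_numpy().tolist() == [[1.5, 3.5], [3.5, 1.5]]

    def test_identical_columns_unchanged(self):
        X = _df([[1, 1], [5, 5], [2, 2]])
        assert np.allclose(quantile_normalize(X), X)

    def test_column_sums_equal(self):
        rng = np.random.default_rng(1)
        X = _df(rng.uniform(1, 100, size=(20, 5)))
        out = quantile_normalize(X)
        sums = out.sum(axis=0).to_numpy()
        assert np.allclose(sums, sums[0])

    def test_idempotent_to_1e12(self):
        rng = np.random.default_rng(2)
        X = _df(rng.uniform(1, 100, size=(30, 4)))
        once = quantile_normalize(X)
        twice = quantile_normalize(once)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12

    def test_ties_get_mean_of_tied_reference_values(self):
        X = _df([[1, 10], [1, 20], [2, 30]])
        out = quantile_normalize(X)
        # reference distribution: mean of (1,1,2) and (10,20,30) -> (5.5,10.5,16)
        assert out.iloc[:, 0].tolist() == [8.0, 8.0, 16.0]
        assert out.iloc[:, 1].tolist() == [5.5, 10.5, 16.0]

    def test_rank_preservation_within_columns(self):
        rng = np.random.default_rng(3)
        X = _df(rng.uniform(1, 100, size=(25, 3)))
        out = quantile_normalize(X)
        for j in range(3):
            assert (X.iloc[:, j].rank() == out.iloc[:, j].rank()).all()

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(_df([[1, np.nan], [2, 3]]))


def _oracle_polish(mat, tol=0.01, max_iter=10):
    """Independent transcription of the row/column median sweep using plain
    Python loops and statistics.median."""
    z = [list(map(float, row)) for row in mat]
    nr, nc = len(z), len(z[0])
    t, r, c = 0.0, [0.0] * nr, [0.0] * nc
    last = None
    for _ in range(max_iter):
        for i in range(nr):
            m = median(z[i])
            r[i] += m
            for j in range(nc):
                z[i][j] -= m
        m = median(c)
        t += m
        c = [x - m for x in c]
        for j in range(nc):
            m = median([z[i][j] for i in range(nr)])
            c[j] += m
            for i in range(nr):
                z[i][j] -= m
        m = median(r)
        t += m
        r = [x - m for x in r]
        total = sum(abs(x) for row in z for x in row)
        if last is not None and abs(last - total) < tol:
            break
        last = total
    return t, r, c, z


class TestMedianPolish:
    def test_additive_matrix_recovered_exactly(self):
        row = np.array([0.0, 1.0, -1.0, 2.0])
        col = np.array([0.5, -0.5, 0.0])
        X = 5.0 + row[:, None] + col[None, :]
        overall, r, c, resid = median_polish(X)
        assert np.allclose(resid, 0.0)
        assert np.allclose(overall + r[:, None] + c[None, :], X)

    def test_constant_matrix(self):
        overall, r, c, resid = median_polish(np.full((3, 4), 7.5))
        assert overall == 7.5
        assert np.allclose(r, 0) and np.allclose(c, 0) and np.allclose(resid, 0)

    def test_reconstruction_identity_always_holds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 5))
        overall, r, c, resid = median_polish(X)
        assert np.allclose(overall + r[:, None] + c[None, :] + resid, X,
                           atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_sweep_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(5, 2, size=(4, 3))
        X[rng.integers(4), rng.integers(3)] += 10  # one outlier cell
        overall, r, c, resid = median_polish(X)
        t2, r2, c2, z2 = _oracle_polish(X.tolist())
        assert abs(overall - t2) < 1e-9
        assert np.allclose(r, r2, atol=1e-9)
        assert np.allclose(c, c2, atol=1e-9)
        assert np.allclose(resid, np.array(z2), atol=1e-9)


class TestSummarizeProbesets:
    def _pm(self, intensities, probe_map, design=None):
        from panscan.expression import ProbeMatrix

        design = design or {a: (float(i), 1)
                            for i, a in enumerate(intensities.columns)}
        return ProbeMatrix(intensities=intensities, probe_map=probe_map,
                           design=design)

    def test_identical_probe_rows_collapse_to_that_row(self):
        # the polish of identical rows returns exactly the (normalized) row
        rng = np.random.default_rng(11)
        other = rng.uniform(4, 64, size=(6, 3))
        row = [4.0, 8.0, 16.0]
        X = _df(np.vstack([row, row, row, other]),
                index=[f"p{i}" for i in range(9)], columns=list("abc"))
        pmap = {f"p{i}": ("g1" if i < 3 else f"x{i}") for i in range(9)}
        out = summarize_probesets(self._pm(X, pmap))
        norm = quantile_normalize(np.log2(X))
        assert np.allclose(out.loc["g1"], norm.loc["p0"])

    def test_global_scaling_shifts_by_log2(self):
        rng = np.random.default_rng(6)
        X = _df(rng.uniform(4, 64, size=(6, 4)),
                index=[f"p{i}" for i in range(6)], columns=list("abcd"))
        pmap = {f"p{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        base = summarize_probesets(self._pm(X, pmap))
        doubled = summarize_probesets(self._pm(2.0 * X, pmap))
        assert np.allclose(doubled.to_numpy(), base.to_numpy() + 1.0)

    def test_single_probe_probeset_degenerates_to_probe_row(self):
        rng = np.random.default_rng(7)
        X = _df(rng.uniform(4, 64, size=(4, 3)),
                index=[f"p{i}" for i in range(4)], columns=list("abc"))
        pmap = {"p0": "lonely", "p1": "g", "p2": "g", "p3": "g"}
        pm = self._pm(X, pmap)
        out = summarize_probesets(pm)
        norm = quantile_normalize(np.log2(X))
        assert np.allclose(out.loc["lonely"], norm.loc["p0"])


class TestMeanReplicateProfile:
    def _expr(self):
        return _df([[2.0, 4.0, 1.0, 1.0]], index=["g1"],
                   columns=["a1", "a2", "b1", "b2"])

    def test_replicates_averaged_per_time_point(self):
        design = {"a1": (8.0, 1), "a2": (8.0, 2), "b1": (10.0, 1), "b2": (10.0, 2)}
        profs = mean_replicate_profile(self._expr(), design)
        assert profs[0].time_points == (8.0, 10.0)
        assert profs[0].values == (3.0, 1.0)

    def test_replicate_order_irrelevant(self):
        d1 = {"a1": (8.0, 1), "a2": (8.0, 2), "b1": (10.0, 1), "b2": (10.0, 2)}
        d2 = {"a1": (8.0, 2), "a2": (8.0, 1), "b1": (10.0, 2), "b2": (10.0, 1)}
        p1 = mean_replicate_profile(self._expr(), d1)
        p2 = mean_replicate_profile(self._expr(), d2)
        assert p1 == p2

    def test_missing_genes_listed_in_error(self):
        design = {"a1": (8.0, 1), "a2": (8.0, 2), "b1": (10.0, 1), "b2": (10.0, 2)}
        with pytest.raises(KeyError, match="gX"):
            mean_replicate_profile(self._expr(), design, genes=["g1", "gX"])


class TestExpressionRecovery:
    def test_noise_free_recovery_is_tight(self):
        """Without measurement noise the only deviation left is the residual
        distortion of quantile normalization on the differentially
        expressed minority, which must stay small at the default density."""
        pm, truth = simulate_expression(noise_sd=0.0, seed=3)
        out = summarize_probesets(pm)
        got = out.sub(out.mean(axis=1), axis=0).loc[truth.index]
        want = truth.sub(truth.mean(axis=1), axis=0)
        err = np.abs(got.to_numpy() - want.to_numpy())
        assert err.mean() < 0.03

    def test_profiles_constant_when_no_effects_no_noise(self):
        pm, _ = simulate_expression(n_probesets=4, probes_per_set=5,
                                    effect_sd=0.0, noise_sd=0.0, seed=4)
        out = summarize_probesets(pm)
        assert np.allclose(out.std(axis=1), 0.0, atol=1e-9)
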