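import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqreplay import sequenceness as sq
from seqreplay import task
from seqreplay.decoding import ReactivationMatrix

from conftest import random_reactivation


def brute_force_transitions(values, rate, lag_ms, nuisance_lags_ms):
    """Independent oracle: explicit design construction, normal equations.

    Loops over target states and predictor columns one by one and solves
    (X'X) b = X'y with a direct solve — no shared code with the package
    implementation.
    """
    n, s = values.shape
    lag = int(round(lag_ms * rate / 1000.0))
    nuis = [int(round((lag_ms + off) * rate / 1000.0))
            for off in (nuisance_lags_ms or [])]
    all_lags = [lag] + nuis
    start = max(all_lags)
    beta = np.zeros((s, s))
    for i in range(s):  # target state
        y = []
        X = []
        for t in range(start, n):
            y.append(values[t, i])
            row = []
            for L in all_lags:
                for j in range(s):
                    row.append(values[t - L, j])
            row.append(1.0)
            X.append(row)
        X = np.asarray(X)
        y = np.asarray(y)
        b = np.linalg.solve(X.T @ X, X.T @ y)
        for j in range(s):
            beta[j, i] = b[j]  # predictor j at t-lag -> target i
    return beta


class TestEmpiricalTransitions:
    def test_constructed_shift(self):
        rng = np.random.default_rng(0)
        n, s, lag = 400, 4, 5
        vals = rng.uniform(0.1, 0.9, size=(n, s))
        vals[lag:, 1] = vals[:-lag, 0]  # state 1 copies state 0, shifted
        Y = ReactivationMatrix(values=vals, rate=100.0)
        b = sq.empirical_transitions(Y, 50.0, nuisance_lags_ms=None)
        assert b.beta[0, 1] == pytest.approx(1.0, abs=1e-6)
        mask = np.ones((s, s), dtype=bool)
        mask[0, 1] = False
        assert np.abs(b.beta[mask]).max() < 0.2

    def test_iid_noise_mean_zero(self):
        betas = []
        for seed in range(30):
            Y = random_reactivation(300, 4, seed)
            b = sq.empirical_transitions(Y, 50.0, nuisance_lags_ms=None)
            betas.append(b.beta)
        mean = np.mean(betas, axis=0)
        assert np.abs(mean).max() < 0.05

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        s = int(rng.integers(3, 5))
        lag_ms = float(rng.choice([20, 30, 50]))
        nuis = (100.0, 200.0) if seed % 2 else None
        Y = random_reactivation(n, s, seed + 1000)
        b = sq.empirical_transitions(Y, lag_ms, nuis)
        expected = brute_force_transitions(Y.values, 100.0, lag_ms, nuis)
        assert np.allclose(b.beta, expected, atol=1e-8)

    def test_too_short_raises(self):
        Y = random_reactivation(50, 4, 0)
        with pytest.raises(ValueError):
            sq.empirical_transitions(Y, 50.0)

    def test_rank_deficiency_reported(self):
        vals = np.full((300, 4), 0.5)  # constant columns: collinear with const
        Y = ReactivationMatrix(values=vals, rate=100.0)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            sq.empirical_transitions(Y, 50.0, nuisance_lags_ms=None)


class TestProjectSequenceness:
    def test_counting(self, study1):
        P = study1.rule_order  # 6 edges, chains -> no symmetric pairs
        b = sq.TransitionEstimate(beta=P.copy(), lag_ms=50.0)
        zf, zb = sq.project_sequenceness(b, P)
        assert zf == 6.0
        assert zb == 0.0

    def test_transpose_swaps(self, study1):
        P = study1.rule_order
        b = sq.TransitionEstimate(beta=P.T.copy(), lag_ms=50.0)
        zf, zb = sq.project_sequenceness(b, P)
        assert zf == 0.0
        assert zb == 6.0

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        beta = rng.standard_normal((8, 8))
        P = task.chain_transition_matrix([[0, 1, 2, 3], [4, 5, 6, 7]], 8)
        zf, zb = sq.project_sequenceness(sq.TransitionEstimate(beta, 10.0), P)
        manual_f = sum(beta[i, j] for i, j in task.edges_of(P))
        manual_b = sum(beta[j, i] for i, j in task.edges_of(P))
        assert zf == pytest.approx(manual_f)
        assert zb == pytest.approx(manual_b)

    def test_shape_mismatch(self):
        b = sq.TransitionEstimate(beta=np.zeros((4, 4)), lag_ms=10.0)
        with pytest.raises(ValueError):
            sq.project_sequenceness(b, np.zeros((5, 5)))


class TestSequencenessCurve:
    @pytest.mark.parametrize("seed", range(10))
    def test_antisymmetry(self, seed, study1):
        Y = random_reactivation(400, 8, seed)
        grid = sq.LagGrid(np.array([10.0, 30.0, 50.0]))
        a = sq.sequenceness_curve(Y, study1.rule_order, grid, None)
        b = sq.sequenceness_curve(Y, study1.rule_order.T, grid, None)
        assert np.allclose(a.diff, -b.diff, atol=1e-12)
        assert np.allclose(a.zf, b.zb) and np.allclose(a.zb, b.zf)

    def test_peak_tiebreak_smallest_lag(self):
        curve = sq.SequencenessCurve(
            lags_ms=np.array([10.0, 20.0, 30.0]),
            zf=np.array([1.0, 1.0, 0.0]),
            zb=np.zeros(3),
        )
        assert curve.peak_lag_ms() == 10.0

    def test_default_grid(self):
        grid = sq.LagGrid.default(100.0)
        assert grid.lags_ms[0] == 10.0
        assert grid.lags_ms[-1] == 600.0
        assert len(grid.lags_ms) == 60

    def test_off_grid_lag_rejected(self):
        with pytest.raises(ValueError):
            sq.LagGrid(np.array([15.0])).samples(100.0)


class TestNuisanceRegressors:
    def test_alpha_inflation_controlled(self):
        """A shared 10 Hz oscillation inflates |diff| without the nuisance
        lags and is suppressed with them (paired, fixed seeds)."""
        grid = sq.LagGrid(np.arange(10.0, 110.0, 10.0))
        P = task.chain_transition_matrix([[0, 1, 2, 3], [4, 5, 6, 7]], 8)
        inflated, controlled = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 3000
            t = np.arange(n) / 100.0
            phases = rng.uniform(0, 2 * np.pi, 8)
            amps = rng.uniform(0.5, 1.5, 8)
            alpha = np.sin(2 * np.pi * 10 * t[:, None] + phases) * amps
            vals = 0.5 + 0.2 * alpha + 0.05 * rng.standard_normal((n, 8))
            Y = ReactivationMatrix(values=np.clip(vals, 1e-3, 1 - 1e-3), rate=100.0)
            raw = sq.sequenceness_curve(Y, P, grid, None)
            ctl = sq.sequenceness_curve(Y, P, grid, sq.DEFAULT_NUISANCE_MS)
            inflated.append(np.abs(raw.diff).max())
            controlled.append(np.abs(ctl.diff).max())
        assert np.mean(inflated) > 2 * np.mean(controlled)


class TestPermutationNull:
    def test_identity_only_rejected(self):
        Y = random_reactivation(300, 4, 0)
        P = task.chain_transition_matrix([[0, 1, 2, 3]], 4)
        with pytest.raises(ValueError):
            sq.permutation_null(Y, P, sq.LagGrid(np.array([10.0])),
                                perms=[(0, 1, 2, 3)])

    def test_identity_excluded_from_sampled(self):
        Y = random_reactivation(300, 4, 0)
        P = task.chain_transition_matrix([[0, 1, 2, 3]], 4)
        null = sq.permutation_null(Y, P, sq.LagGrid(np.array([10.0, 20.0])),
                                   perms=23, seed=0, nuisance_lags_ms=None)
        assert (0, 1, 2, 3) not in null.permutations
        assert len(null.permutations) == 23

    def test_requesting_too_many_perms(self):
        Y = random_reactivation(300, 3, 0)
        P = task.chain_transition_matrix([[0, 1, 2]], 3)
        with pytest.raises(ValueError):
            sq.permutation_null(Y, P, sq.LagGrid(np.array([10.0])), perms=10)

    def test_relabeling_identity(self):
        """Projecting onto the row/col-permuted P equals projecting the
        inverse-relabeled beta onto P."""
        rng = np.random.default_rng(7)
        beta = rng.standard_normal((4, 4))
        P = task.chain_transition_matrix([[0, 1, 2, 3]], 4)
        for perm in itertools.permutations(range(4)):
            perm = tuple(perm)
            inv = tuple(int(k) for k in np.argsort(perm))
            Pp = sq.permute_matrix(P, perm)
            a = sq.project_sequenceness(sq.TransitionEstimate(beta, 1.0), Pp)
            b = sq.project_sequenceness(
                sq.TransitionEstimate(sq.permute_matrix(beta, inv), 1.0), P
            )
            assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_threshold_monotone_in_perms(self):
        Y = random_reactivation(500, 4, 3)
        P = task.chain_transition_matrix([[0, 1, 2, 3]], 4)
        grid = sq.LagGrid(np.array([10.0, 20.0, 30.0]))
        pool = [p for p in itertools.permutations(range(4)) if p != (0, 1, 2, 3)]
        thresholds = []
        for k in (5, 10, 23):
            null = sq.permutation_null(Y, P, grid, perms=pool[:k],
                                       nuisance_lags_ms=None)
            thresholds.append(null.threshold)
        assert thresholds[0] <= thresholds[1] <= thresholds[2]

    def test_injected_exceeds_noise_does_not(self, study1):
        rng = np.random.default_rng(11)
        n = 2000
        vals = np.clip(rng.uniform(0.2, 0.4, size=(n, 8)), 1e-3, 1)
        # inject forward chain pairs of the rule order at 30 ms
        for t0 in range(50, n - 20, 40):
            chain = [0, 1, 2, 3] if (t0 // 40) % 2 else [4, 5, 6, 7]
            for k, s in enumerate(chain):
                vals[t0 + 3 * k, s] += 0.5
        Y = ReactivationMatrix(values=np.clip(vals, 0, 1 - 1e-3), rate=100.0)
        grid = sq.LagGrid(np.arange(10.0, 110.0, 10.0))
        curve = sq.sequenceness_curve(Y, study1.rule_order, grid, None)
        null = sq.permutation_null(Y, study1.rule_order, grid, perms=50,
                                   seed=0, nuisance_lags_ms=None)
        assert np.abs(curve.diff).max() > null.threshold
        Ynoise = random_reactivation(n, 8, 12)
        c2 = sq.sequenceness_curve(Ynoise, study1.rule_order, grid, None)
        n2 = sq.permutation_null(Ynoise, study1.rule_order, grid, perms=50,
                                 seed=0, nuisance_lags_ms=None)
        assert np.abs(c2.diff).max() <= n2.threshold


@settings(max_examples=10, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_antisymmetry_property(seed):
    Y = random_reactivation(250, 4, seed)
    P = task.chain_transition_matrix([[0, 1, 2, 3]], 4)
    grid = sq.LagGrid(np.array([10.0, 40.0]))
    a = sq.sequenceness_curve(Y, P, grid, None)
    b = sq.sequenceness_curve(Y, P.T, grid, None)
    assert np.allclose(a.diff, -b.diff, atol=1e-12)


class TestLengthN:
    def _chained_Y(self, seed, lag=5, n=4000, strength=0.6):
        """Full 4-chains of states 0..3 injected at a fixed lag."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 0.3, size=(n, 4))
        for t0 in range(50, n - 30, 60):
            for k in range(4):
                vals[t0 + k * lag, k] += strength
        return ReactivationMatrix(values=np.clip(vals, 0, 0.999), rate=100.0)

    def _pairwise_Y(self, seed, lag=5, n=4000, strength=0.6):
        """A->B and B->C pairs at the lag, but never chained triples."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 0.3, size=(n, 4))
        pairs = [(0, 1), (1, 2), (2, 3)]
        for idx, t0 in enumerate(range(50, n - 30, 60)):
            a, b = pairs[idx % 3]
            vals[t0, a] += strength
            vals[t0 + lag, b] += strength
        return ReactivationMatrix(values=np.clip(vals, 0, 0.999), rate=100.0)

    def test_chained_positive_length3(self):
        Y = self._chained_Y(0)
        grid = sq.LagGrid(np.array([30.0, 50.0, 70.0]))
        curve = sq.lengthn_sequenceness(Y, [[0, 1, 2, 3]], grid, n=3)
        assert curve.peak_lag_ms() == 50.0
        assert curve.diff[1] > 0

    def test_chained_positive_length4(self):
        Y = self._chained_Y(1)
        grid = sq.LagGrid(np.array([30.0, 50.0, 70.0]))
        curve = sq.lengthn_sequenceness(Y, [[0, 1, 2, 3]], grid, n=4)
        assert curve.diff[1] > 0

    def test_pairwise_only_no_length3(self, study1):
        from seqreplay.sequenceness import sequenceness_curve

        Y = self._pairwise_Y(2)
        grid = sq.LagGrid(np.array([50.0]))
        pairwise = sequenceness_curve(
            Y, task.chain_transition_matrix([[0, 1, 2, 3]], 4), grid, None
        )
        assert pairwise.diff[0] > 0.05  # pairwise structure is present
        l3_pair = sq.lengthn_sequenceness(self._pairwise_Y(2), [[0, 1, 2, 3]],
                                          grid, n=3)
        l3_chain = sq.lengthn_sequenceness(self._chained_Y(2), [[0, 1, 2, 3]],
                                           grid, n=3)
        assert abs(l3_pair.diff[0]) < 0.25 * l3_chain.diff[0]

    def test_n_bounds(self):
        Y = random_reactivation(500, 4, 0)
        with pytest.raises(ValueError):
            sq.lengthn_sequenceness(Y, [[0, 1, 2, 3]], n=2)
        with pytest.raises(ValueError):
            sq.lengthn_sequenceness(Y, [[0, 1, 2]], n=4)
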