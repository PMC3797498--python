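"""RDA, permutation F-tests, forward selection and variation partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecoassembly import (
    adjusted_r2,
    forward_select,
    partial_rda,
    permutation_f_test,
    rda,
    variation_partitioning,
)
from ecoassembly.data import ValidationError


def _frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestRda:
    def test_exact_linear_response_gives_r2_one(self, rng):
        x = rng.standard_normal((20, 3))
        y = x @ rng.standard_normal((3, 5))
        assert rda(y, x).r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictor_gives_r2_zero(self):
        n = 16
        t = np.arange(n, dtype=float)
        y = np.column_stack([np.sin(2 * np.pi * t / n)])
        x = np.column_stack([np.cos(2 * np.pi * t / n)])
        assert rda(y, x).r2 == pytest.approx(0.0, abs=1e-10)

    def test_single_response_matches_ols_oracle(self, rng):
        x = rng.standard_normal((25, 4))
        y = x @ rng.standard_normal(4) + rng.standard_normal(25)
        res = rda(y, x)
        # independent oracle: normal equations on the centered design
        xc = np.column_stack([np.ones(25), x])
        beta = np.linalg.solve(xc.T @ xc, xc.T @ y)
        fitted = xc @ beta
        want = ((fitted - y.mean()) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert res.r2 == pytest.approx(want, abs=1e-10)

    def test_r2_equals_sum_of_canonical_eigenvalues_over_total(self, rng):
        x = rng.standard_normal((20, 3))
        y = x @ rng.standard_normal((3, 6)) + 0.5 * rng.standard_normal((20, 6))
        res = rda(y, x)
        yc = y - y.mean(axis=0)
        total_var = (yc**2).sum() / (20 - 1)
        assert res.r2 == pytest.approx(res.canonical_eigenvalues.sum() / total_var, rel=1e-10)

    def test_r2_invariant_to_reparameterization(self, rng):
        x = rng.standard_normal((20, 3))
        y = x @ rng.standard_normal((3, 4)) + rng.standard_normal((20, 4))
        t = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        assert rda(y, x @ t).r2 == pytest.approx(rda(y, x).r2, abs=1e-10)

    def test_rank_deficient_predictors_named(self, rng):
        x = rng.standard_normal((15, 2))
        bad = _frame(np.column_stack([x, x[:, 0] + x[:, 1]]))
        # any one of the linearly dependent columns may be reported
        with pytest.raises(ValidationError, match=r"dependent columns: \['v[0-2]'\]"):
            rda(rng.standard_normal((15, 3)), bad)

    def test_too_many_predictors_rejected(self, rng):
        with pytest.raises(ValidationError, match="n=5"):
            rda(rng.standard_normal((5, 2)), rng.standard_normal((5, 4)))


class TestPartialRda:
    def test_empty_conditioning_reduces_to_rda(self, rng):
        x = rng.standard_normal((18, 3))
        y = x @ rng.standard_normal((3, 4)) + rng.standard_normal((18, 4))
        full = rda(y, x)
        part = partial_rda(y, x, None)
        assert part.r2 == pytest.approx(full.r2, abs=1e-12)

    def test_predictor_inside_conditioning_span_explains_nothing(self, rng):
        w = rng.standard_normal((18, 3))
        x = w @ rng.standard_normal((3, 2))  # X entirely within span(W)
        y = rng.standard_normal((18, 4))
        res = partial_rda(y, x, w)
        assert res.r2 == 0.0
        assert res.adj_r2 == 0.0

    def test_sum_of_squares_additivity(self, rng):
        w = rng.standard_normal((20, 2))
        x = rng.standard_normal((20, 2))
        y = (
            x @ rng.standard_normal((2, 5))
            + w @ rng.standard_normal((2, 5))
            + rng.standard_normal((20, 5))
        )
        r2_w = rda(y, w).r2
        r2_xw = rda(y, np.hstack([x, w])).r2
        semi = partial_rda(y, x, w).r2
        assert r2_xw == pytest.approx(r2_w + semi, abs=1e-10)


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 25, 4) == pytest.approx(1.0)

    def test_zero_predictors_identity(self):
        assert adjusted_r2(0.37, 25, 0) == pytest.approx(0.37)

    def test_hand_computed_value(self):
        # 1 - 0.5 * 24 / 20 = 0.4
        assert adjusted_r2(0.5, 25, 4) == pytest.approx(0.4, abs=1e-12)

    def test_undefined_when_saturated(self):
        with pytest.raises(ValidationError):
            adjusted_r2(0.5, 5, 4)

    def test_adjustment_shrinks(self, rng):
        for _ in range(10):
            r2 = rng.uniform(0.01, 0.99)
            m = rng.integers(1, 10)
            assert adjusted_r2(r2, 30, int(m)) < r2


class TestPermutationFTest:
    def test_matches_classical_anova_f_for_single_response(self, rng):
        x = rng.standard_normal((25, 3))
        y = x @ rng.standard_normal(3) + rng.standard_normal(25)
        f, _ = permutation_f_test(y, x, n_perm=9, seed=0)
        # classical oracle via explicit sums of squares
        xc = np.column_stack([np.ones(25), x])
        beta = np.linalg.solve(xc.T @ xc, xc.T @ y)
        ss_reg = ((xc @ beta - y.mean()) ** 2).sum()
        ss_res = ((y - xc @ beta) ** 2).sum()
        want = (ss_reg / 3) / (ss_res / (25 - 3 - 1))
        assert f == pytest.approx(want, rel=1e-10)

    def test_strong_signal_reaches_p_floor(self, rng):
        x = rng.standard_normal((20, 2))
        y = x @ rng.standard_normal((2, 4)) + 0.01 * rng.standard_normal((20, 4))
        _, p = permutation_f_test(y, x, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_conditioned_test_ignores_w_explained_signal(self, rng):
        w = rng.standard_normal((25, 2))
        y = w @ rng.standard_normal((2, 5)) + 0.3 * rng.standard_normal((25, 5))
        x = rng.standard_normal((25, 2))  # pure noise given W
        _, p = permutation_f_test(y, x, w, n_perm=199, seed=1)
        assert p > 0.05


class TestForwardSelect:
    def _selection_oracle(self, y, cand):
        """Brute-force greedy max-added-R^2 order, by exhaustive refits."""
        yc = y - y.mean(axis=0)
        ss_tot = (yc**2).sum()
        chosen: list[int] = []
        remaining = list(range(cand.shape[1]))
        order = []
        while remaining:
            best, best_r2 = None, -np.inf
            for j in remaining:
                cols = chosen + [j]
                x = cand[:, cols]
                xc = np.column_stack([np.ones(len(y)), x])
                beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
                r2 = ((xc @ beta) ** 2).sum() / ss_tot
                if r2 > best_r2 + 1e-12:
                    best, best_r2 = j, r2
            order.append(best)
            chosen.append(best)
            remaining.remove(best)
        return order

    def test_greedy_order_matches_brute_force_oracle(self, rng):
        cand = rng.standard_normal((20, 5))
        y = (
            cand[:, [1, 3]] @ np.array([[2.0, 0.5, 1.0], [1.0, -1.5, 0.5]])
            + 0.3 * rng.standard_normal((20, 3))
        )
        res = forward_select(
            y, _frame(cand), alpha=1.0, n_perm=19, seed=0
        )  # alpha=1: never stop on significance
        want = self._selection_oracle(y, cand)
        got = [int(v[1:]) for v in res.selected]
        assert got[: len(res.selected)] == want[: len(res.selected)]

    def test_true_predictor_selected_first(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(900 + rep)
            cand = r.standard_normal((25, 10))
            signal = cand[:, 4]
            y = np.column_stack(
                [signal + r.standard_normal(25), signal + r.standard_normal(25)]
            )
            res = forward_select(y, _frame(cand), alpha=0.05, n_perm=99, seed=rep)
            hits += bool(res.selected) and res.selected[0] == "v4"
        assert hits >= 19

    def test_all_noise_usually_selects_nothing_strong(self, rng):
        # family-wise alpha over 10 candidates is inflated but far below 1
        picks = 0
        for rep in range(30):
            r = np.random.default_rng(7000 + rep)
            y = r.standard_normal((20, 4))
            res = forward_select(y, _frame(r.standard_normal((20, 10))),
                                 alpha=0.05, n_perm=99, seed=rep)
            picks += len(res.selected) > 0
        assert picks < 30  # never selects everything every time

    def test_adjusted_r2_cumulative_nondecreasing(self, rng):
        cand = rng.standard_normal((25, 6))
        y = cand @ rng.standard_normal((6, 4)) + rng.standard_normal((25, 4))
        res = forward_select(y, _frame(cand), alpha=0.05, n_perm=99, seed=3)
        cum = [s.adj_r2_cum for s in res.steps]
        assert all(b >= a - 1e-12 for a, b in zip(cum, cum[1:]))
        assert all(s.p_value <= 0.05 for s in res.steps)

    def test_max_select_cap_respected(self, rng):
        cand = rng.standard_normal((25, 8))
        y = cand @ rng.standard_normal((8, 3))
        res = forward_select(y, _frame(cand), alpha=1.0, n_perm=19, seed=0, max_select=3)
        assert len(res.selected) == 3
        assert res.stopped_by == "max_select"

    def test_deterministic_given_seed(self, rng):
        cand = rng.standard_normal((20, 5))
        y = cand @ rng.standard_normal((5, 3)) + rng.standard_normal((20, 3))
        a = forward_select(y, _frame(cand), n_perm=49, seed=11)
        b = forward_select(y, _frame(cand), n_perm=49, seed=11)
        assert a.selected == b.selected
        assert [s.p_value for s in a.steps] == [s.p_value for s in b.steps]


class TestVariationPartitioning:
    def test_fractions_sum_to_one_exactly(self, rng):
        for rep in range(5):
            r = np.random.default_rng(rep)
            y = r.standard_normal((20, 6))
            e = _frame(r.standard_normal((20, 3)), "e")
            s = _frame(r.standard_normal((20, 2)), "s")
            part = variation_partitioning(y, e, s, n_perm=None)
            total = (
                part.fraction_E_given_S
                + part.fraction_intersection
                + part.fraction_S_given_E
                + part.residual
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_spatial_block_reduction(self, rng):
        y = rng.standard_normal((20, 5))
        e = _frame(rng.standard_normal((20, 3)), "e")
        part = variation_partitioning(y, e, None, n_perm=None)
        want = rda(y, e).adj_r2
        assert part.fraction_E_given_S == pytest.approx(want, abs=1e-12)
        assert part.fraction_S_given_E == 0.0
        assert part.fraction_intersection == 0.0

    def test_identical_blocks_share_everything(self, rng):
        y = rng.standard_normal((20, 5))
        block = rng.standard_normal((20, 3))
        e = _frame(block, "e")
        s = _frame(block.copy(), "s")
        part = variation_partitioning(y, e, s, n_perm=None)
        assert part.fraction_E_given_S == pytest.approx(0.0, abs=1e-10)
        assert part.fraction_S_given_E == pytest.approx(0.0, abs=1e-10)
        assert part.fraction_intersection == pytest.approx(rda(y, e).adj_r2, abs=1e-10)

    def test_conditional_fraction_p_values_present(self, rng):
        y = rng.standard_normal((20, 5))
        e = _frame(rng.standard_normal((20, 2)), "e")
        s = _frame(rng.standard_normal((20, 2)), "s")
        part = variation_partitioning(y, e, s, n_perm=99, seed=0)
        for p in (part.p_E_given_S, part.p_S_given_E, part.p_total):
            assert p is not None and 1 / 100 <= p <= 1.0

    def test_matches_vegan_varpart_reference(self):
        """Frozen cross-check against vegan::varpart (Hellinger response,
        same inputs regenerated from the seed): adjusted-R^2 fractions
        [a]=0.13648146, [b]=0.06352722, [c]=-0.09555487, resid=0.89554619."""
        from ecoassembly.data import CommunityMatrix, hellinger_transform

        r = np.random.default_rng(99)
        counts = r.poisson(5, (10, 8)) + (r.random((10, 8)) < 0.3)
        counts[counts.sum(1) == 0, 0] = 1
        e = r.standard_normal((10, 3))
        s = r.standard_normal((10, 2))
        y = hellinger_transform(CommunityMatrix(pd.DataFrame(counts)))
        part = variation_partitioning(y, pd.DataFrame(e), pd.DataFrame(s), n_perm=None)
        assert part.fraction_E_given_S == pytest.approx(0.13648146, abs=1e-7)
        assert part.fraction_S_given_E == pytest.approx(0.06352722, abs=1e-7)
        assert part.fraction_intersection == pytest.approx(-0.09555487, abs=1e-7)
        assert part.residual == pytest.approx(0.89554619, abs=1e-7)

    def test_both_blocks_empty_rejected(self, rng):
        with pytest.raises(ValidationError, match="empty"):
            variation_partitioning(rng.standard_normal((10, 3)), None, None)
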