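"""Hellinger transform, RDA, forward selection and variation partitioning."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metacommunity.varpart import (
    RDA,
    adjusted_r2,
    forward_select,
    hellinger,
    rda_fit,
    time_dummies,
    variation_partition,
)


def vp_fixture():
    rng = np.random.default_rng(303)
    n = 30
    x1 = rng.normal(size=(n, 2))
    x2 = rng.normal(size=(n, 2))
    x3 = rng.normal(size=(n, 2))
    b1 = rng.normal(size=(2, 8))
    b2 = rng.normal(size=(2, 8))
    y = x1 @ b1 + 0.5 * x2 @ b2 + rng.normal(size=(n, 8))
    return y, x1, x2, x3


class TestHellinger:
    def test_uniform_row(self):
        out = hellinger(np.array([[1, 1, 1, 1]]))
        assert np.allclose(out, 0.5)

    def test_concentrated_row(self):
        assert hellinger(np.array([[4, 0]])).tolist() == [[1.0, 0.0]]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_have_unit_sum_of_squares(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 20, size=(6, 9)).astype(float)
        m[:, 0] += 1  # no zero-sum rows
        out = hellinger(m)
        assert np.allclose((out ** 2).sum(axis=1), 1.0)

    def test_zero_sum_row_names_site(self):
        with pytest.raises(ValueError, match="row 1"):
            hellinger(np.array([[1, 2], [0, 0]]))


class TestRda:
    def test_responses_as_predictors_r2_one(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(12, 3))
        res = rda_fit(y, y)
        assert res.r2 == pytest.approx(1.0)

    def test_adjusted_r2_arithmetic(self):
        assert adjusted_r2(0.5, n=10, m=3) == pytest.approx(0.25)

    def test_empty_conditioning_equals_plain(self):
        y, x1, _, _ = vp_fixture()
        plain = rda_fit(y, x1)
        empty_cond = RDA(y, x1, condition=np.zeros((len(y), 0))).fit()
        assert empty_cond.r2 == pytest.approx(plain.r2, abs=1e-12)
        assert empty_cond.q == 0

    def test_matches_vegan_global_rda(self):
        """R2 / adjusted R2 frozen from vegan::rda + RsquareAdj."""
        y, x1, _, _ = vp_fixture()
        res = rda_fit(y, x1)
        assert res.r2 == pytest.approx(0.6393516952, abs=1e-9)
        assert res.adj_r2 == pytest.approx(0.6126370059, abs=1e-9)

    def test_singular_predictors_rejected(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(10, 3))
        x = rng.normal(size=(10, 2))
        x_sing = np.column_stack([x, x[:, 0]])
        with pytest.raises(np.linalg.LinAlgError):
            RDA(y, x_sing)

    def test_permutation_p_detects_signal_and_null(self):
        y, x1, _, x3 = vp_fixture()
        sig = rda_fit(y, x1, n_perm=199, seed=0)
        noise = rda_fit(y - x1 @ np.linalg.lstsq(x1, y, rcond=None)[0], x3,
                        n_perm=199, seed=0)
        assert sig.perm_p < 0.05
        assert noise.perm_p > 0.05


class TestForwardSelection:
    def test_single_true_predictor_recovered(self):
        """Only the true predictor is ever admitted.

        The adjusted-R2 bound (candidate model must stay at or below the
        global model, as in the double-stopping criterion) can legitimately
        return an empty selection when pure-noise predictors drag the global
        bound below the true predictor's own adjusted R2, so the guarantee
        is conditional: a nonempty selection is exactly {a}.
        """
        exact, nonempty = 0, 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            x = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
            y = np.outer(x["a"], rng.normal(size=4)) + 0.8 * rng.normal(size=(40, 4))
            res = forward_select(y, x, n_perm=199, seed=s)
            assert res.global_p < 0.05  # the gate always sees the signal
            if res.names:
                nonempty += 1
                if res.names == ["a"]:
                    exact += 1
        assert nonempty >= 5
        assert exact >= int(0.9 * nonempty)

    def test_pure_noise_fails_global_gate(self):
        gate_closed = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(s + 400)
            x = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
            y = rng.normal(size=(30, 4))
            res = forward_select(y, x, n_perm=199, seed=s)
            if not res.names and res.reason == "global test non-significant":
                gate_closed += 1
        assert gate_closed >= 17

    def test_never_exceeds_global_bound(self):
        y, x1, x2, x3 = vp_fixture()
        x = pd.DataFrame(np.column_stack([x1, x2, x3]),
                         columns=[f"v{i}" for i in range(6)])
        res = forward_select(y, x, n_perm=99, seed=5)
        assert res.names
        for _, cum_adj, _p in res.selected:
            assert cum_adj <= res.global_adj_r2 + 1e-12


class TestVariationPartitioning:
    def test_matches_vegan_varpart(self):
        """All eight adjusted-R2 fractions frozen from vegan::varpart."""
        y, x1, x2, x3 = vp_fixture()
        vp = variation_partition(y, x1, x2, x3, n_perm=0)
        expected = {
            "env": 0.635524232,
            "spa": 0.130177303,
            "time": -0.002831309,
            "env_spa": -0.035220304,
            "spa_time": -0.004838012,
            "env_time": 0.007667895,
            "env_spa_time": 0.004665183,
            "residual": 0.264855012,
        }
        for k, v in expected.items():
            assert vp.fractions[k] == pytest.approx(v, abs=1e-8), k

    def test_fractions_sum_to_one(self):
        y, x1, x2, x3 = vp_fixture()
        vp = variation_partition(y, x1, x2, x3, n_perm=0)
        assert vp.fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_identical_sets_have_no_pure_fractions(self):
        y, x1, _, x3 = vp_fixture()
        vp = variation_partition(y, x1, x1, x3, n_perm=0)
        assert vp.fractions["env"] == pytest.approx(0.0, abs=1e-10)
        assert vp.fractions["spa"] == pytest.approx(0.0, abs=1e-10)
        assert vp.fractions["env_spa"] > 0.1

    def test_orthogonal_designs_have_no_shared_fractions(self):
        rng = np.random.default_rng(7)
        n = 48
        q, _ = np.linalg.qr(rng.normal(size=(n, 6)))
        e, s_, t = q[:, :2], q[:, 2:4], q[:, 4:6]
        y = e @ rng.normal(size=(2, 5)) + s_ @ rng.normal(size=(2, 5)) \
            + t @ rng.normal(size=(2, 5)) + 0.3 * rng.normal(size=(n, 5))
        vp = variation_partition(y, e, s_, t, n_perm=0)
        single_e = rda_fit(y, e).adj_r2
        assert abs(vp.fractions["env_spa"]) < 0.05
        assert abs(vp.fractions["env_time"]) < 0.05
        assert abs(vp.fractions["spa_time"]) < 0.05
        assert vp.fractions["env"] == pytest.approx(single_e, abs=0.06)

    def test_role_symmetry(self):
        # rotating the sets (E,S,T) -> (S,T,E) must rotate the fractions
        y, x1, x2, x3 = vp_fixture()
        a = variation_partition(y, x1, x2, x3, n_perm=0).fractions
        b = variation_partition(y, x2, x3, x1, n_perm=0).fractions
        assert b["env"] == pytest.approx(a["spa"], abs=1e-10)
        assert b["spa"] == pytest.approx(a["time"], abs=1e-10)
        assert b["time"] == pytest.approx(a["env"], abs=1e-10)
        assert b["env_spa"] == pytest.approx(a["spa_time"], abs=1e-10)
        assert b["env_time"] == pytest.approx(a["env_spa"], abs=1e-10)
        assert b["spa_time"] == pytest.approx(a["env_time"], abs=1e-10)
        assert b["env_spa_time"] == pytest.approx(a["env_spa_time"], abs=1e-10)
        assert b["residual"] == pytest.approx(a["residual"], abs=1e-10)

    def test_empty_time_set_noted(self):
        y, x1, x2, _ = vp_fixture()
        vp = variation_partition(y, x1, x2, None, n_perm=0)
        assert vp.fractions["time"] == 0.0
        assert vp.fractions["env_time"] == 0.0
        assert any("time set empty" in n for n in vp.notes)

    def test_pure_fraction_permutation_p(self):
        y, x1, x2, x3 = vp_fixture()
        vp = variation_partition(y, x1, x2, x3, n_perm=99, seed=11)
        assert vp.pure_p["env"] < 0.05  # x1 drives y by construction


def test_time_dummies_drop_first_level():
    d = time_dummies(pd.Series(["P1", "P1", "P2", "P3"]))
    assert d.shape == (4, 2)
    assert set(d.sum()) <= {1.0, 2.0}
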