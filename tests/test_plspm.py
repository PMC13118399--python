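"""PLS path modeling: closed-form collapses, effect decomposition
identities, bootstrap behavior and PC1 scores."""

import numpy as np
import pandas as pd
import pytest

from aggrekey.plspm import (PathModel, PathSpec, bootstrap_paths, effects,
                            fit_plspm, pc1_scores)


def _std(v):
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std(ddof=1)


@pytest.fixture
def chain_data(rng):
    """20 samples on a planted causal chain x -> m -> y."""
    n = 20
    x = rng.normal(size=n)
    m = 0.8 * x + rng.normal(0, 0.5, n)
    y = 0.7 * m + rng.normal(0, 0.5, n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


class TestSingleIndicatorCollapse:
    def test_two_block_path_is_pearson_correlation(self, chain_data):
        spec = PathSpec(blocks={"X": ("x",), "Y": ("y",)},
                        inner=(("X", "Y"),))
        model = fit_plspm(chain_data, spec)
        r = np.corrcoef(chain_data["x"], chain_data["y"])[0, 1]
        assert model.path_matrix.loc["Y", "X"] == pytest.approx(r, abs=1e-9)
        assert model.r_squared["Y"] == pytest.approx(r ** 2, abs=1e-9)

    def test_chain_total_effect_is_product_of_ols_paths(self, chain_data):
        spec = PathSpec(blocks={"X": ("x",), "M": ("m",), "Y": ("y",)},
                        inner=(("X", "M"), ("M", "Y")))
        model = fit_plspm(chain_data, spec)
        b_xm = np.corrcoef(chain_data["x"], chain_data["m"])[0, 1]
        b_my = np.corrcoef(chain_data["m"], chain_data["y"])[0, 1]
        eff = effects(model).set_index(["source", "target"])
        assert eff.loc[("X", "Y"), "total"] == pytest.approx(
            b_xm * b_my, abs=1e-9)
        assert eff.loc[("X", "Y"), "direct"] == 0.0

    def test_collapses_to_standardized_ols_path_analysis(self, rng):
        """All-single-indicator model with a collider: path coefficients
        equal multiple-OLS coefficients on standardized variables."""
        n = 30
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n) + 0.5 * x1
        y = 0.6 * x1 - 0.4 * x2 + rng.normal(0, 0.4, n)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        spec = PathSpec(blocks={"A": ("x1",), "B": ("x2",), "Y": ("y",)},
                        inner=(("A", "B"), ("A", "Y"), ("B", "Y")))
        model = fit_plspm(data, spec)
        xs = np.column_stack([_std(x1), _std(x2)])
        beta = np.linalg.lstsq(xs, _std(y), rcond=None)[0]
        assert model.path_matrix.loc["Y", "A"] == pytest.approx(beta[0], abs=1e-6)
        assert model.path_matrix.loc["Y", "B"] == pytest.approx(beta[1], abs=1e-6)


class TestOuterModel:
    def test_duplicated_indicator_block(self, chain_data):
        data = chain_data.assign(x2=chain_data["x"])
        spec = PathSpec(blocks={"X": ("x", "x2"), "Y": ("y",)},
                        inner=(("X", "Y"),))
        model = fit_plspm(data, spec)
        lx = model.loadings["X"]
        assert lx["x"] == pytest.approx(lx["x2"], abs=1e-9)
        assert lx["x"] == pytest.approx(1.0, abs=1e-9)
        assert model.scores["X"].to_numpy() == pytest.approx(
            _std(data["x"]), abs=1e-6)

    def test_latent_scores_standardized_and_sign_aligned(self, rng):
        n = 25
        f = rng.normal(size=n)
        data = pd.DataFrame({
            "a1": f + rng.normal(0, 0.3, n), "a2": f + rng.normal(0, 0.3, n),
            "b1": 0.7 * f + rng.normal(0, 0.5, n),
            "b2": 0.7 * f + rng.normal(0, 0.5, n)})
        spec = PathSpec(blocks={"A": ("a1", "a2"), "B": ("b1", "b2")},
                        inner=(("A", "B"),))
        model = fit_plspm(data, spec)
        for l in ("A", "B"):
            s = model.scores[l]
            assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
            first = model.spec.blocks[l][0]
            assert np.corrcoef(s, data[first])[0, 1] > 0
        assert 0 <= model.gof <= 1

    def test_path_coefficients_invariant_to_indicator_rescaling(self, rng):
        n = 25
        f = rng.normal(size=n)
        data = pd.DataFrame({
            "a1": f + rng.normal(0, 0.3, n), "a2": f + rng.normal(0, 0.3, n),
            "y": 0.6 * f + rng.normal(0, 0.4, n)})
        spec = PathSpec(blocks={"A": ("a1", "a2"), "Y": ("y",)},
                        inner=(("A", "Y"),))
        m1 = fit_plspm(data, spec)
        scaled = data.assign(a1=data["a1"] * 1000.0, y=data["y"] / 50.0)
        m2 = fit_plspm(scaled, spec)
        assert m1.path_matrix.loc["Y", "A"] == pytest.approx(
            m2.path_matrix.loc["Y", "A"], abs=1e-6)


class TestEffects:
    def _model_with_b(self, b: pd.DataFrame) -> PathModel:
        spec = PathSpec(
            blocks={l: (l.lower(),) for l in b.index},
            inner=tuple((s, t) for t in b.index for s in b.columns
                        if b.loc[t, s] != 0))
        return PathModel(spec=spec, scores=pd.DataFrame(),
                         outer_weights={}, loadings={}, path_matrix=b,
                         path_table=pd.DataFrame(), r_squared={},
                         communality=pd.Series(dtype=float), gof=0.0,
                         iterations=1, converged=True)

    def test_chain_and_direct_edge_sum(self):
        lat = ["X", "M", "Y"]
        b = pd.DataFrame(0.0, index=lat, columns=lat)
        b.loc["M", "X"] = 0.5
        b.loc["Y", "M"] = 0.4
        b.loc["Y", "X"] = 0.3
        eff = effects(self._model_with_b(b)).set_index(["source", "target"])
        assert eff.loc[("X", "Y"), "indirect"] == pytest.approx(0.20)
        assert eff.loc[("X", "Y"), "total"] == pytest.approx(0.50)

    def test_matches_matrix_series_oracle(self, rng):
        """Total effects on a random DAG equal the truncated power series
        sum_k B^k, evaluated independently."""
        lat = list("ABCDE")
        b = pd.DataFrame(0.0, index=lat, columns=lat)
        for i in range(len(lat)):
            for j in range(i):
                if rng.random() < 0.6:
                    b.iloc[i, j] = rng.normal()
        eff = effects(self._model_with_b(b))
        bm = b.to_numpy()
        series = np.zeros_like(bm)
        power = np.eye(len(lat))
        for _ in range(len(lat)):
            power = power @ bm
            series += power
        for _, row in eff.iterrows():
            i, j = lat.index(row["target"]), lat.index(row["source"])
            assert row["total"] == pytest.approx(series[i, j], abs=1e-10)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathSpec(blocks={"A": ("a",), "B": ("b",)},
                     inner=(("A", "B"), ("B", "A")))


class TestBootstrap:
    def test_strong_path_ci_excludes_zero(self, chain_data):
        spec = PathSpec(blocks={"X": ("x",), "M": ("m",), "Y": ("y",)},
                        inner=(("X", "M"), ("M", "Y")))
        out = bootstrap_paths(chain_data, spec, n_boot=199, seed=4)
        row = out.set_index(["source", "target"]).loc[("X", "M")]
        assert row["ci_low"] > 0
        assert row["p_value"] < 0.05

    def test_reproducible_and_rejects_zero_resamples(self, chain_data):
        spec = PathSpec(blocks={"X": ("x",), "Y": ("y",)}, inner=(("X", "Y"),))
        a = bootstrap_paths(chain_data, spec, n_boot=49, seed=2)
        b = bootstrap_paths(chain_data, spec, n_boot=49, seed=2)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            bootstrap_paths(chain_data, spec, n_boot=0)


class TestFitDiagnostics:
    def test_nonconvergence_raises(self, chain_data):
        data = chain_data.assign(x2=chain_data["x"] * 0.5
                                 + chain_data["y"])
        spec = PathSpec(blocks={"X": ("x", "x2"), "Y": ("y", "m")},
                        inner=(("X", "Y"),))
        with pytest.raises(RuntimeError, match="converge"):
            fit_plspm(data, spec, tol=0.0, max_iter=2)

    def test_constant_indicator_rejected(self, chain_data):
        data = chain_data.assign(c=1.0)
        spec = PathSpec(blocks={"X": ("x", "c"), "Y": ("y",)},
                        inner=(("X", "Y"),))
        with pytest.raises(ValueError, match="constant"):
            fit_plspm(data, spec)

    def test_unknown_scheme_rejected(self, chain_data):
        spec = PathSpec(blocks={"X": ("x",), "Y": ("y",)}, inner=(("X", "Y"),))
        with pytest.raises(ValueError, match="scheme"):
            fit_plspm(chain_data, spec, scheme="nope")


class TestPC1Scores:
    def test_rank_one_matrix_explains_everything(self, rng):
        base = rng.uniform(1, 5, 12)
        abund = pd.DataFrame([base, base * 3.0],
                             index=["B_a", "B_b"])
        pc = pc1_scores(abund, ["B_a", "B_b"])
        assert pc.variance_explained == pytest.approx(1.0, abs=1e-9)
        assert pc.scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_equal_variance_split(self):
        n = 400
        rng = np.random.default_rng(0)
        abund = pd.DataFrame(rng.normal(size=(4, n)) + 10,
                             index=[f"B_g{i}" for i in range(4)])
        pc = pc1_scores(abund, list(abund.index))
        assert pc.variance_explained == pytest.approx(0.25, abs=0.05)

    def test_matches_eigendecomposition_oracle(self, rng):
        abund = pd.DataFrame(rng.uniform(1, 9, size=(5, 15)),
                             index=[f"B_g{i}" for i in range(5)])
        pc = pc1_scores(abund, list(abund.index))
        x = abund.T
        xs = (x - x.mean()) / x.std(ddof=1)
        cov = np.cov(xs.T)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, -1]
        oracle = xs.to_numpy() @ lead
        r = np.corrcoef(pc.scores, oracle)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert pc.variance_explained == pytest.approx(
            evals[-1] / evals.sum(), abs=1e-9)

    def test_constant_genus_dropped_with_warning(self, rng):
        abund = pd.DataFrame(
            [rng.uniform(size=10), np.ones(10), rng.uniform(size=10)],
            index=["B_a", "B_b", "B_c"])
        with pytest.warns(UserWarning, match="constant"):
            pc = pc1_scores(abund, ["B_a", "B_b", "B_c"])
        assert "B_b" not in pc.loadings.index

    def test_all_constant_rejected(self):
        abund = pd.DataFrame(np.ones((2, 8)), index=["B_a", "B_b"])
        with pytest.raises(ValueError):
            pc1_scores(abund, ["B_a", "B_b"])
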