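import numpy as np
import pytest

from sarmatrix.freewilson import diagnostics, fit, predict_cell, predict_virtual_cells
from sarmatrix.synthetic_data import SimConfig, make_matrix

from conftest import grid_matrix


def complete_grid(values: np.ndarray):
    rows = [f"r{i}" for i in range(values.shape[0])]
    cols = [f"c{j}" for j in range(values.shape[1])]
    return grid_matrix(
        {(r, c): values[i, j] for i, r in enumerate(rows) for j, c in enumerate(cols)},
        rows,
        cols,
    )


class TestFit:
    def test_constant_matrix(self):
        m = complete_grid(np.full((3, 3), 7.0))
        model = fit(m)
        (comp,) = model.components
        assert comp.mu == pytest.approx(7.0)
        assert all(a == pytest.approx(0.0) for a in comp.alpha.values())
        assert all(b == pytest.approx(0.0) for b in comp.beta.values())
        assert comp.rmse == pytest.approx(0.0, abs=1e-12)
        assert predict_cell(model, "r0", "c1") == pytest.approx(7.0)

    def test_complete_2x2_closed_form(self):
        model = fit(complete_grid(np.array([[6.0, 7.0], [8.0, 9.0]])))
        (comp,) = model.components
        assert comp.mu == pytest.approx(7.5)
        assert comp.alpha == pytest.approx({"r0": -1.0, "r1": 1.0})
        assert comp.beta == pytest.approx({"c0": -0.5, "c1": 0.5})
        assert comp.rmse == pytest.approx(0.0, abs=1e-12)
        assert comp.dof == 1 and not comp.saturated

    def test_three_observed_2x2_exact_fit(self, three_obs_2x2):
        model = fit(three_obs_2x2)
        (comp,) = model.components
        assert comp.rmse == pytest.approx(0.0, abs=1e-12)
        assert comp.saturated
        assert predict_cell(model, "r2", "c2") == pytest.approx(9.0)

    def test_zero_sum_constraints_per_component(self):
        matrix, _ = make_matrix(SimConfig(seed=2, n_cliffs=0))
        model = fit(matrix)
        for comp in model.components:
            assert sum(comp.alpha.values()) == pytest.approx(0.0, abs=1e-9)
            assert sum(comp.beta.values()) == pytest.approx(0.0, abs=1e-9)

    def test_disconnected_matrix_fits_per_component(self):
        m = grid_matrix(
            {("r1", "c1"): 6.0, ("r1", "c2"): 7.0, ("r2", "c3"): 9.0, ("r3", "c3"): 8.0},
            ["r1", "r2", "r3"],
            ["c1", "c2", "c3"],
        )
        model = fit(m)
        assert len(model.components) == 2
        # prediction across components is refused, within a component allowed
        assert predict_cell(model, "r1", "c3") is None
        assert predict_cell(model, "r2", "c3") is not None


class TestPredictions:
    @pytest.mark.parametrize("seed", range(10))
    def test_complete_grid_matches_row_col_mean_oracle(self, seed):
        """Least squares equals row_mean + col_mean - grand_mean on full grids."""
        rng = np.random.default_rng(seed)
        values = rng.normal(6.5, 1.0, (rng.integers(2, 6), rng.integers(2, 6)))
        matrix = complete_grid(values)
        model = fit(matrix)
        grand = values.mean()
        for i, r in enumerate(matrix.rows):
            for j, c in enumerate(matrix.columns):
                oracle = values[i].mean() + values[:, j].mean() - grand
                assert predict_cell(model, r, c) == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_recovery_with_missing_cells(self, seed):
        config = SimConfig(
            n_scaffolds=5, n_substituents=6, noise_sd=0.0,
            missing_frac=0.3, n_cliffs=0, seed=seed,
        )
        matrix, truth = make_matrix(config)
        model = fit(matrix)
        for r, c in matrix.virtual_cells():
            assert predict_cell(model, r, c) == pytest.approx(
                truth.truth[(r, c)], abs=1e-6
            )

    def test_noise_unbiased_and_error_monotone(self):
        biases, rmses = [], []
        for sigma in (0.0, 0.1, 0.3):
            errs = []
            for seed in range(15):
                config = SimConfig(
                    n_scaffolds=5, n_substituents=6, noise_sd=sigma,
                    missing_frac=0.2, n_cliffs=0, seed=seed,
                )
                matrix, truth = make_matrix(config)
                model = fit(matrix)
                errs += [
                    predict_cell(model, r, c) - truth.truth[(r, c)]
                    for r, c in matrix.virtual_cells()
                ]
            errs = np.array(errs)
            biases.append(errs.mean())
            rmses.append(np.sqrt((errs**2).mean()))
        assert abs(biases[0]) < 1e-9
        assert abs(biases[2]) < 0.1  # mean error stays near zero under noise
        assert rmses[0] < rmses[1] < rmses[2]

    def test_permutation_equivariance(self):
        values = {("r1", "c1"): 6.0, ("r1", "c2"): 7.0, ("r2", "c1"): 8.0}
        m = grid_matrix(values, ["r1", "r2"], ["c1", "c2"])
        mp = grid_matrix(values, ["r2", "r1"], ["c2", "c1"])
        model, model_p = fit(m), fit(mp)
        for r in ("r1", "r2"):
            for c in ("c1", "c2"):
                ref = predict_cell(model, r, c)
                assert predict_cell(model_p, r, c) == pytest.approx(ref)
        assert model.components[0].alpha == pytest.approx(model_p.components[0].alpha)

    def test_predict_virtual_cells_fills_in_place(self, three_obs_2x2):
        model = fit(three_obs_2x2)
        n = predict_virtual_cells(three_obs_2x2, model)
        assert n == 1
        assert three_obs_2x2.cells[("r2", "c2")].predicted_p == pytest.approx(9.0)


class TestDiagnostics:
    def test_complete_additive_grid_perfect_fit(self):
        alpha = np.array([0.0, 0.5, -0.5, 1.0])
        beta = np.array([0.2, -0.2, 0.6, -0.6])
        values = 7.0 + alpha[:, None] + beta[None, :]
        diag = diagnostics(fit(complete_grid(values)))
        (comp,) = diag["components"]
        assert comp["r2"] == pytest.approx(1.0)
        assert comp["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_degrees_of_freedom_and_saturation_flags(self, three_obs_2x2):
        full = diagnostics(fit(complete_grid(np.array([[6.0, 7.0], [8.0, 9.5]]))))
        assert full["components"][0]["dof"] == 1
        assert not full["components"][0]["saturated"]
        sat = diagnostics(fit(three_obs_2x2))
        assert sat["components"][0]["dof"] == 0
        assert sat["components"][0]["saturated"]
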