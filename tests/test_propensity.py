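import numpy as np
import pytest
from scipy import stats

import hetsynth as hs
from hetsynth.propensity import OUTSIDE, GridSpec


# ---------------------------------------------------------------------------
# Propensity model
# ---------------------------------------------------------------------------

class TestFitPropensity:
    def test_shifted_variable_selected(self, two_region):
        model = hs.fit_propensity(two_region)
        assert "age" in model.selected  # strongly region-shifted by design
        assert all(model.pvalues[c] < model.alpha for c in model.selected)

    def test_predictions_in_unit_interval(self, two_region):
        model = hs.fit_propensity(two_region)
        p = model.predict(two_region.data)
        assert np.all((p > 0) & (p < 1))

    def test_null_variable_rarely_selected(self):
        """Type-I behavior: a balanced variable passes the p < 0.05 cutoff
        in only a small fraction of seeded null replicates."""
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            df = {
                "g": rng.integers(0, 2, 400),
                "x_null": rng.standard_normal(400),
            }
            import pandas as pd
            table = hs.CohortTable(pd.DataFrame(df),
                                   {"g": "group", "x_null": "continuous"})
            model = hs.fit_propensity(table)
            hits += "x_null" in model.selected
        assert hits <= 10  # ~5% expected; allow 10/100

    def test_requires_both_classes(self, two_region):
        with pytest.raises(ValueError):
            hs.fit_propensity(two_region, group=np.zeros(two_region.n_rows))


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

class TestAssignCells:
    def test_basic_binning(self):
        spec = GridSpec(0.5, np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        cells = hs.assign_cells(np.array([[0.0, 0.0], [0.9, 0.9]]), spec)
        np.testing.assert_array_equal(cells, [[0, 0], [1, 1]])

    def test_ceiling_cell_count(self):
        spec = GridSpec(0.3, np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        assert spec.shape == (4, 4)

    def test_upper_bound_maps_to_last_cell(self):
        spec = GridSpec(0.5, np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        cells = hs.assign_cells(np.array([[1.0, 1.0]]), spec)
        np.testing.assert_array_equal(cells, [[1, 1]])

    def test_outside_sentinel(self):
        spec = GridSpec(0.5, np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        cells = hs.assign_cells(np.array([[2.0, 0.5], [-0.1, 0.2]]), spec)
        assert np.all(cells == OUTSIDE)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(-2, 2, size=(1000, 2))
        spec = hs.grid_from_points(z, d=0.37)
        cells = hs.assign_cells(z, spec)
        n1, n2 = spec.shape
        for k in range(len(z)):
            i = j = None
            for ii in range(n1):
                lo = spec.mins[0] + ii * spec.d
                hi = lo + spec.d if ii < n1 - 1 else spec.maxs[0] + 1e-12
                if lo <= z[k, 0] < hi or (ii == n1 - 1 and z[k, 0] <= spec.maxs[0]):
                    i = ii
                    break
            for jj in range(n2):
                lo = spec.mins[1] + jj * spec.d
                if lo <= z[k, 1] < lo + spec.d or (jj == n2 - 1 and z[k, 1] <= spec.maxs[1]):
                    j = jj
                    break
            assert (cells[k, 0], cells[k, 1]) == (i, j)


class TestAveragePS:
    def test_simple_mean(self):
        spec = GridSpec(1.0, np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        z = np.array([[0.2, 0.2], [0.8, 0.8]])
        cells = hs.assign_cells(z, spec)
        p_bar, counts = hs.average_ps_per_cell(cells, np.array([0.2, 0.4]), spec)
        assert p_bar[0, 0] == pytest.approx(0.3)
        assert counts[0, 0] == 2

    def test_empty_cell_is_undefined_not_zero(self):
        spec = GridSpec(0.5, np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        z = np.array([[0.1, 0.1]])
        p_bar, _ = hs.average_ps_per_cell(hs.assign_cells(z, spec),
                                          np.array([0.5]), spec)
        assert np.isnan(p_bar[1, 1])

    def test_matches_brute_force_means(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(500, 2))
        ps = rng.uniform(0.05, 0.95, 500)
        spec = hs.grid_from_points(z, resolution=8)
        cells = hs.assign_cells(z, spec)
        p_bar, _ = hs.average_ps_per_cell(cells, ps, spec)
        for i in range(spec.shape[0]):
            for j in range(spec.shape[1]):
                member = (cells[:, 0] == i) & (cells[:, 1] == j)
                if member.sum():
                    assert p_bar[i, j] == pytest.approx(ps[member].mean())
                else:
                    assert np.isnan(p_bar[i, j])


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

class TestWeights:
    @pytest.mark.parametrize("p,delta,expected", [
        (0.7, 0.1, 0.0),            # outside the band
        (0.55, 0.1, 1 / 0.55),      # upper branch
        (0.45, 0.1, 1 / 0.55),      # symmetric lower branch
        (0.5, 0.1, 2.0),            # continuity at 0.5
    ])
    def test_overlap_branches(self, p, delta, expected):
        w = hs.overlap_weights(np.array([[p]]), delta)
        assert w[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize("p,delta,expected", [
        (0.6, 0.05, 0.0),
        (0.25, 0.05, 4.0),
        (0.5, 0.05, 2.0),
    ])
    def test_group_branches(self, p, delta, expected):
        w = hs.group_weights(np.array([[p]]), delta)
        assert w[0, 0] == pytest.approx(expected)

    def test_group_weight_capped(self):
        w = hs.group_weights(np.array([[1e-9]]), 0.1)
        assert w[0, 0] == 100.0

    def test_overlap_symmetric_in_p(self):
        p = np.array([[0.42, 0.58, 0.47, 0.53]])
        np.testing.assert_allclose(hs.overlap_weights(p, 0.1),
                                   hs.overlap_weights(1 - p, 0.1))

    def test_undefined_cells_get_zero(self):
        p = np.array([[np.nan, 0.5]])
        assert hs.overlap_weights(p, 0.1)[0, 0] == 0.0
        assert hs.group_weights(p, 0.1)[0, 0] == 0.0

    def test_normalize(self):
        w = hs.normalize_weights(np.array([1.0, 1.0, 2.0]))
        np.testing.assert_allclose(w, [0.25, 0.25, 0.5])
        assert w.sum() == pytest.approx(1.0)

    def test_normalize_keeps_zeros(self):
        w = hs.normalize_weights(np.array([0.0, 3.0]))
        assert w[0] == 0.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="admissible"):
            hs.normalize_weights(np.zeros(4))


# ---------------------------------------------------------------------------
# Weighted rejection sampling
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def grid_setup(two_region):
    pipe = hs.TransformPipeline.fit(two_region, {"rdelay": "bimodal"},
                                    bimodal={"max_iter": 200})
    t01 = pipe.forward(two_region)
    model = hs.train_vae(t01, hs.VAEConfig(epochs=40, seed=9), pipeline=pipe)
    ps = hs.fit_propensity(two_region).predict(two_region.data)
    return model, t01, ps


class TestWeightedSampling:
    def test_equal_weights_match_prior_mass(self, grid_setup):
        """With all defined cells equally weighted, accepted latent points
        follow the prior restricted to the grid box (chi-square GOF, 1%)."""
        model, t01, ps = grid_setup
        grid = hs.build_latent_grid(model, t01, ps, delta=0.2, resolution=6)
        grid.w = (grid.counts > 0).astype(float)
        grid.w_bar = hs.normalize_weights(grid.w)
        _, z_acc, _ = hs.weighted_prior_sampling(
            model, grid, 20_000, seed=13, return_latent=True)
        cells = hs.assign_cells(z_acc, grid.spec)
        n1, n2 = grid.spec.shape
        obs = np.zeros((n1, n2))
        np.add.at(obs, (cells[:, 0], cells[:, 1]), 1)
        # expected mass: product of per-axis normal probabilities, restricted
        # to defined cells and renormalized
        def axis_probs(mn, mx, n):
            edges = mn + grid.spec.d * np.arange(n + 1)
            edges[-1] = mx  # the box truncates the outermost cell
            return np.diff(stats.norm.cdf(edges))
        mass = np.outer(axis_probs(grid.spec.mins[0], grid.spec.maxs[0], n1),
                        axis_probs(grid.spec.mins[1], grid.spec.maxs[1], n2))
        mass[grid.w == 0] = 0.0
        mass /= mass.sum()
        keep = mass.ravel() * len(z_acc) >= 5  # merge sparse cells
        o, e = obs.ravel()[keep], mass.ravel()[keep] * len(z_acc)
        o = np.append(o, len(z_acc) - o.sum())
        e = np.append(e, len(z_acc) - e.sum())
        if e[-1] <= 0:
            o, e = o[:-1], e[:-1]
        chi2 = float(np.sum((o - e) ** 2 / e))
        pval = stats.chi2.sf(chi2, df=len(e) - 1)
        assert pval > 0.01

    def test_zero_weight_cells_receive_no_samples(self, grid_setup):
        model, t01, ps = grid_setup
        grid = hs.build_latent_grid(model, t01, ps, delta=0.1)
        _, z_acc, _ = hs.weighted_prior_sampling(
            model, grid, 2000, seed=17, return_latent=True)
        cells = hs.assign_cells(z_acc, grid.spec)
        assert np.all(cells[:, 0] != OUTSIDE)
        assert np.all(grid.w[cells[:, 0], cells[:, 1]] > 0)

    def test_two_cell_frequency_ratio(self, grid_setup):
        """A two-cell toy grid with weights 2/3 and 1/3: accepted draws hit
        the cells in the weight-times-prior-mass proportion."""
        model, t01, ps = grid_setup
        grid = hs.build_latent_grid(model, t01, ps, delta=0.2, resolution=4)
        # the two best-populated cells carry weights 2/3 and 1/3
        flat = np.argsort(grid.counts.ravel())[::-1][:2]
        (a_i, a_j), (b_i, b_j) = (np.unravel_index(f, grid.counts.shape)
                                  for f in flat)
        grid.w = np.zeros_like(grid.w)
        grid.w[a_i, a_j] = 2 / 3
        grid.w[b_i, b_j] = 1 / 3
        grid.w_bar = hs.normalize_weights(grid.w)
        _, z_acc, _ = hs.weighted_prior_sampling(
            model, grid, 6000, seed=19, return_latent=True)
        cells = hs.assign_cells(z_acc, grid.spec)
        n_a = int(np.sum((cells[:, 0] == a_i) & (cells[:, 1] == a_j)))

        def cell_mass(i, j):
            lo0 = grid.spec.mins[0] + i * grid.spec.d
            hi0 = min(lo0 + grid.spec.d, grid.spec.maxs[0])
            lo1 = grid.spec.mins[1] + j * grid.spec.d
            hi1 = min(lo1 + grid.spec.d, grid.spec.maxs[1])
            return ((stats.norm.cdf(hi0) - stats.norm.cdf(lo0)) *
                    (stats.norm.cdf(hi1) - stats.norm.cdf(lo1)))

        m_a, m_b = cell_mass(a_i, a_j), cell_mass(b_i, b_j)
        expected = (2 * m_a) / (2 * m_a + 1 * m_b)
        se = np.sqrt(expected * (1 - expected) / len(z_acc))
        assert abs(n_a / len(z_acc) - expected) < 3 * se + 0.02

    def test_acceptance_floor_abort(self, grid_setup):
        model, t01, ps = grid_setup
        grid = hs.build_latent_grid(model, t01, ps, delta=0.2)
        # one far-corner admissible cell only -> acceptance ~ 0
        grid.w = np.zeros_like(grid.w)
        grid.w[0, 0] = 1.0
        grid.w_bar = hs.normalize_weights(grid.w)
        with pytest.raises(RuntimeError, match="admissible region too small"):
            hs.weighted_prior_sampling(model, grid, 1000, seed=23,
                                       acceptance_floor=1e-3)

    def test_overlap_sample_mean_between_group_means(self, grid_setup, two_region):
        """Overlap-weighted synthetic data for the region-shifted variable
        lands between the two region means."""
        model, t01, ps = grid_setup
        grid = hs.build_latent_grid(model, t01, ps, delta=0.2)
        syn, _ = hs.weighted_prior_sampling(model, grid, 2000, seed=29)
        m0 = two_region.data.loc[two_region.data.region == 0, "age"].mean()
        m1 = two_region.data.loc[two_region.data.region == 1, "age"].mean()
        lo, hi = sorted([m0, m1])
        assert lo < syn.data["age"].mean() < hi


def test_normalization_invariant_after_recompute(grid_setup):
    model, t01, ps = grid_setup
    for delta in (0.05, 0.1, 0.2):
        for mode in ("overlap", "group"):
            try:
                grid = hs.build_latent_grid(model, t01, ps, mode=mode, delta=delta)
            except ValueError:
                continue  # no admissible region at this delta
            assert grid.w_bar.sum() == pytest.approx(1.0)
            assert np.all(grid.w >= 0)


def test_latent_heatmap_writes_file(grid_setup, two_region, tmp_path):
    model, t01, ps = grid_setup
    grid = hs.build_latent_grid(model, t01, ps, delta=0.2)
    out = tmp_path / "latent.png"
    hs.latent_heatmap(model, t01, two_region.data["region"].to_numpy(),
                      grid, str(out))
    assert out.exists() and out.stat().st_size > 0
    out2 = tmp_path / "weights.png"
    hs.latent_heatmap(model, t01, two_region.data["region"].to_numpy(),
                      grid, str(out2), shade="w_bar")
    assert out2.exists()
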