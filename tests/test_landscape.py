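import dataclasses

import numpy as np
import pytest
from scipy import stats

from edaphoniche import (
    LandscapeConfig,
    PolygonLayer,
    RasterGrid,
    SoilMapStack,
    SpeciesResponseParams,
    default_species,
    displace_map,
    generate_landscape,
    sample_plots,
    simulate_abundances,
)
from edaphoniche.core import GridSpec
import shapely


class TestGenerateLandscape:
    def test_single_class_is_degenerate(self):
        cfg = LandscapeConfig(
            extent=(0, 0, 5000, 5000), cell_size=500, n_classes=1,
            class_patch_scale=2000, seed=3,
        )
        stack, truth = generate_landscape(cfg)
        assert (truth.class_index == 0).all()
        only = next(iter(stack.prob_layers.values()))
        assert (only.data == 1.0).all()
        assert set(stack.polygons.classes) == {"Acrisols"}

    def test_same_seed_is_bit_identical(self, small_config):
        s1, t1 = generate_landscape(small_config)
        s2, t2 = generate_landscape(small_config)
        np.testing.assert_array_equal(t1.cation_field.data, t2.cation_field.data)
        np.testing.assert_array_equal(t1.class_index, t2.class_index)
        np.testing.assert_array_equal(s1.cec.data, s2.cec.data)
        for name in s1.prob_layers:
            np.testing.assert_array_equal(s1.prob_layers[name].data, s2.prob_layers[name].data)
        assert all(
            a.equals(b) for a, b in zip(s1.polygons.geometries, s2.polygons.geometries)
        )

    def test_probability_vectors_sum_to_one_and_truth_dominates(self, small_landscape):
        stack, truth = small_landscape
        total = sum(l.data for l in stack.prob_layers.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        stacked = np.stack([stack.prob_layers[n].data for n in truth.class_names])
        assert (np.argmax(stacked, axis=0) == truth.class_index).all()

    def test_cec_correlation_hits_target(self, small_landscape, small_config):
        stack, truth = small_landscape
        r = np.corrcoef(truth.log_cation.ravel(), stack.cec.data.ravel())[0, 1]
        assert abs(r - small_config.cec_correlation) < 0.05

    def test_within_class_spread_matches_lognormal_law(self):
        """log-sd 2.3 classes span >= 2 orders of magnitude, as a direct
        lognormal quantile computation predicts."""
        sd = 2.3
        cfg = LandscapeConfig(
            extent=(0, 0, 40_000, 40_000), cell_size=500, n_classes=4,
            class_patch_scale=8000,
            class_cation_params=tuple((mu, sd) for mu in (-1.0, 0.0, 1.0, 2.0)),
            seed=5,
        )
        _, truth = generate_landscape(cfg)
        # oracle: for n >= 50 iid lognormal draws, the max/min ratio exceeds
        # exp(sd * (q(1-1/n) - q(1/n))) with high probability; at n=50,
        # sd=2.3 that bound is far above 100.
        ok = 0
        classes_checked = 0
        for k in range(cfg.n_classes):
            vals = truth.cation_field.data[truth.class_index == k]
            if len(vals) < 50:
                continue
            classes_checked += 1
            if vals.max() / vals.min() >= 100:
                ok += 1
        assert classes_checked >= 2
        assert ok >= 0.8 * classes_checked

    def test_impossible_correlation_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(cec_correlation=1.5)

    def test_subcell_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            LandscapeConfig(extent=(0, 0, 100, 100), cell_size=500)


class TestDisplaceMap:
    def test_zero_displacement_is_identity(self, small_landscape):
        stack, _ = small_landscape
        out = displace_map(stack, 0.0, 0.0)
        np.testing.assert_array_equal(out.cec.data, stack.cec.data)
        assert all(a.equals(b) for a, b in zip(out.polygons.geometries, stack.polygons.geometries))

    def test_stripe_shift_flips_every_interior_class(self):
        """A vertical two-class striping shifted by one stripe width assigns
        every interior cell the neighboring stripe's class (oracle: the
        stripe geometry itself)."""
        w = 1000.0
        spec = GridSpec((0.0, 0.0), 500.0, 4, 8)
        stripe = np.tile(np.repeat([0, 1], 2), 2)  # columns: AABB AABB
        a = RasterGrid(spec, np.tile((stripe == 0).astype(float), (4, 1)))
        b = RasterGrid(spec, np.tile((stripe == 1).astype(float), (4, 1)))
        polys = [shapely.box(x, 0, x + w, 2000) for x in np.arange(0, 4000, w)]
        layer = PolygonLayer(polys, ["A", "B", "A", "B"])
        stack = SoilMapStack(layer, {"A": a, "B": b}, RasterGrid(spec, np.ones((4, 8))))
        out = displace_map(stack, w, 0.0)
        interior = slice(2, None)  # first stripe's cells are vacated
        # after a one-stripe shift, class A claims exactly B's old columns
        np.testing.assert_array_equal(out.prob_layers["A"].data[:, interior],
                                      b.data[:, interior])
        # every non-missing cell's dominant class flips
        flipped = out.prob_layers["A"].data[:, interior] == a.data[:, interior]
        assert not flipped.any()

    def test_off_extent_displacement_rejected(self, small_landscape):
        stack, _ = small_landscape
        width = stack.spec.extent[2] - stack.spec.extent[0]
        with pytest.raises(ValueError, match="off the analysis extent"):
            displace_map(stack, 10 * width, 0.0)


class TestSamplePlots:
    def test_noise_free_measurements_equal_truth(self, small_landscape):
        _, truth = small_landscape
        plots = sample_plots(truth, 50, 0.0, seed=1)
        for p in plots:
            assert p.cation_cmolkg == p.true_cation

    def test_noise_moment_matches_stated_law(self, small_landscape):
        _, truth = small_landscape
        plots = sample_plots(truth, 1000, 0.5, seed=2)
        logratio = np.log([p.cation_cmolkg / p.true_cation for p in plots])
        assert abs(logratio.std(ddof=1) - 0.5) < 0.05

    def test_determinism_and_positivity(self, small_landscape):
        _, truth = small_landscape
        p1 = sample_plots(truth, 20, 0.3, seed=9)
        p2 = sample_plots(truth, 20, 0.3, seed=9)
        assert [(p.x, p.y, p.cation_cmolkg) for p in p1] == [
            (p.x, p.y, p.cation_cmolkg) for p in p2
        ]
        assert all(p.cation_cmolkg > 0 for p in p1)

    def test_invalid_n_rejected(self, small_landscape):
        _, truth = small_landscape
        with pytest.raises(ValueError):
            sample_plots(truth, 0, 0.1, seed=1)


class TestSimulateAbundances:
    def test_mean_count_at_optimum_matches_response_height(self, small_landscape):
        """Plots sitting exactly at a taxon's optimum draw counts whose mean
        over many replicates is the response amplitude (within 3 standard
        errors of the Poisson mean)."""
        _, truth = small_landscape
        sp = SpeciesResponseParams("t", true_optimum=1.0, true_tolerance=0.5, max_abundance=6.0)
        reps = 10_000
        plots = sample_plots(truth, reps, 0.0, seed=1)
        for p in plots:
            p.true_cation = float(np.exp(sp.true_optimum))
        counts = simulate_abundances(plots, [sp], seed=8)["t"].to_numpy()
        se = np.sqrt(sp.max_abundance / reps)
        assert abs(counts.mean() - sp.max_abundance) < 3 * se

    def test_flat_response_limit(self, small_plots):
        sp = SpeciesResponseParams("flat", 0.0, 1e6, 7.0)
        ab = simulate_abundances(small_plots, [sp], seed=4)
        assert abs(ab["flat"].mean() - 7.0) < 0.5

    def test_zero_amplitude_gives_zero_counts(self, small_plots):
        sp = SpeciesResponseParams("none", 0.0, 1.0, 0.0)
        ab = simulate_abundances(small_plots, [sp], seed=4)
        assert (ab["none"] == 0).all()

    def test_missing_true_cation_rejected(self, small_plots):
        plots = [dataclasses.replace(p, true_cation=None) for p in small_plots[:3]]
        with pytest.raises(ValueError, match="true cation"):
            simulate_abundances(plots, default_species(), seed=1)
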