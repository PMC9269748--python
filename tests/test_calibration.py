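"""Calibration machinery: objective self-consistency, Latin hypercube
stratification, multistart determinism and warm-start recovery."""

import numpy as np
import pandas as pd
import pytest

from p53ddr.calibration import (
    FitConfig,
    GfpDataset,
    fit,
    lhs_sample,
    minimal_cost_family,
    objective,
    select_from_family,
)
from p53ddr.model import RATE_PARAM_NAMES
from p53ddr.params import DEFAULT_OBSERVABLE_MAP, DEFAULT_PARAMS
from p53ddr.synth import GfpGeneratorConfig, generate_gfp_dataset


@pytest.fixture(scope="module")
def clean_dataset():
    """Noise-free normalized dataset from the packaged ground truth."""
    ds, truth = generate_gfp_dataset(GfpGeneratorConfig(seed=0, noise_sd=0.0, replicates=1))
    return ds, truth


class TestGfpDataset:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            GfpDataset(pd.DataFrame({"reporter": ["p53"]}))

    def test_unknown_reporter_rejected(self):
        df = pd.DataFrame(
            {"reporter": ["gfp"], "concentration_index": [1], "replicate": [1],
             "time_h": [1.0], "intensity": [0.5]}
        )
        with pytest.raises(ValueError, match="reporters"):
            GfpDataset(df)

    def test_out_of_band_intensity_rejected(self):
        df = pd.DataFrame(
            {"reporter": ["p53"], "concentration_index": [1], "replicate": [1],
             "time_h": [1.0], "intensity": [1.5]}
        )
        with pytest.raises(ValueError, match="intensities"):
            GfpDataset(df)

    def test_replicate_means(self):
        df = pd.DataFrame(
            {"reporter": ["p53", "p53"], "concentration_index": [1, 1],
             "replicate": [1, 2], "time_h": [1.0, 1.0], "intensity": [0.2, 0.4]}
        )
        means = GfpDataset(df).replicate_means()
        assert len(means) == 1
        assert means["intensity"].iloc[0] == pytest.approx(0.3)

    def test_tsv_round_trip(self, clean_dataset, tmp_path):
        ds, _ = clean_dataset
        path = tmp_path / "gfp.tsv"
        ds.to_tsv(path)
        back = GfpDataset.from_tsv(path)
        pd.testing.assert_frame_equal(back.records, ds.records)


class TestFitConfig:
    def test_ec1_must_be_fixed(self):
        with pytest.raises(ValueError, match="EC1"):
            FitConfig(fixed={})

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            FitConfig(bounds={"kp": (2.0, 1.0)})


class TestObjective:
    def test_noise_free_self_consistency(self, clean_dataset):
        """Data generated from (params, map) has near-zero cost.

        The generator min-max normalizes the observables, an affine map the
        profiled scaling/offset absorb exactly.
        """
        ds, truth = clean_dataset
        cost = objective(truth["params"], None, ds, sim_rtol=1e-8, sim_atol=1e-10)
        assert cost == pytest.approx(0.0, abs=1e-10)

    def test_hand_squared_residual(self):
        """Single record at the steady state: residual fixed by the map."""
        p = DEFAULT_PARAMS
        from p53ddr.model import steady_state

        ss = steady_state(p)
        datum = 0.6
        model_obs = 0.4
        omap_scaling = model_obs / (ss.P53 + ss.P53p)
        omap = DEFAULT_OBSERVABLE_MAP
        omap = type(omap)(
            scaling={"p53": omap_scaling, "mdm2": 1, "p21": 1, "btg2": 1},
            offset={r: 0.0 for r in ("p53", "mdm2", "p21", "btg2")},
        )
        df = pd.DataFrame(
            {"reporter": ["p53"], "concentration_index": [1], "replicate": [1],
             "time_h": [1e-6], "intensity": [datum]}
        )
        # EC1 stress barely acts by t = 1e-6: observable ~ scaled steady state
        cost = objective(p, omap, GfpDataset(df))
        assert cost == pytest.approx((datum - model_obs) ** 2, abs=1e-6)

    def test_duplicate_replicates_average_not_double(self, clean_dataset):
        """An identical extra replicate leaves the replicate-mean cost
        unchanged; a duplicated *mean record* would double it."""
        ds, truth = clean_dataset
        doubled = GfpDataset(
            pd.concat([ds.records, ds.records.assign(replicate=99)], ignore_index=True)
        )
        assert objective(truth["params"], None, doubled) == pytest.approx(
            objective(truth["params"], None, ds), abs=1e-12
        )

    def test_failed_integration_is_inf(self, clean_dataset):
        ds, _ = clean_dataset
        bad = DEFAULT_PARAMS.replace(ks_p53_RNA=-1.0)
        assert objective(bad, None, ds) == float("inf")


class TestLhsSample:
    def test_two_point_stratification(self):
        pts = lhs_sample({"x": (1.0, 10.0)}, n=2, seed=0)
        logs = np.log10(pts[:, 0])
        assert ((0 <= logs) & (logs <= 1)).all()
        assert (logs < 0.5).sum() == 1 and (logs >= 0.5).sum() == 1

    def test_deterministic(self):
        a = lhs_sample({"x": (0.1, 10), "y": (1, 100)}, n=7, seed=3)
        b = lhs_sample({"x": (0.1, 10), "y": (1, 100)}, n=7, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_stratum_occupancy_all_ones(self):
        n = 100
        pts = lhs_sample({"a": (1e-2, 1e2), "b": (1e-4, 1e2)}, n=n, seed=1)
        for dim, (lo, hi) in enumerate([(1e-2, 1e2), (1e-4, 1e2)]):
            u = (np.log10(pts[:, dim]) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
            occupancy = np.histogram(u, bins=n, range=(0, 1))[0]
            assert (occupancy == 1).all()

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample({"x": (1, 2)}, n=0, seed=0)


def _warm_config(n_starts=1, **kw):
    """Every parameter fixed at truth except a handful, tightly bounded."""
    free = ["tau", "kp", "ks_mdm2_p53p"]
    bounds = {n: (getattr(DEFAULT_PARAMS, n) / 5, getattr(DEFAULT_PARAMS, n) * 5) for n in free}
    fixed = {n: getattr(DEFAULT_PARAMS, n) for n in RATE_PARAM_NAMES if n not in free}
    return FitConfig(n_starts=n_starts, bounds=bounds, fixed=fixed, max_nfev=40, **kw)


class TestFit:
    def test_warm_start_reaches_noise_floor(self, clean_dataset):
        ds, _ = clean_dataset
        results = fit(ds, _warm_config(n_starts=2, seed=4))
        assert results[0].cost < 1e-4

    def test_ranked_costs_non_decreasing(self, clean_dataset):
        ds, _ = clean_dataset
        results = fit(ds, _warm_config(n_starts=3, seed=5))
        costs = [r.cost for r in results]
        assert costs == sorted(costs)
        assert [r.rank for r in results] == list(range(len(results)))

    def test_multistart_deterministic(self, clean_dataset):
        ds, _ = clean_dataset
        a = fit(ds, _warm_config(n_starts=2, seed=6))
        b = fit(ds, _warm_config(n_starts=2, seed=6))
        assert [r.cost for r in a] == [r.cost for r in b]

    def test_cost_increases_under_data_corruption(self, clean_dataset):
        """Perturbing one datum away from the best-fit curve cannot lower
        the optimal cost."""
        ds, _ = clean_dataset
        base = fit(ds, _warm_config(n_starts=2, seed=7))[0].cost
        corrupted = ds.records.copy()
        corrupted.loc[corrupted.index[100], "intensity"] = np.clip(
            corrupted["intensity"].iloc[100] + 0.4, -0.2, 1.2
        )
        worse = fit(GfpDataset(corrupted), _warm_config(n_starts=2, seed=7))[0].cost
        assert worse >= base - 1e-12

    def test_missing_reporter_rejected(self, clean_dataset):
        ds, _ = clean_dataset
        partial = GfpDataset(ds.records[ds.records["reporter"] != "btg2"])
        with pytest.raises(ValueError, match="btg2"):
            fit(partial, _warm_config())

    def test_ratio_of_p53_mrna_rates_recovered(self, clean_dataset):
        """The ks/kd ratio for p53 mRNA (basal level) is identifiable when
        the observable map is held at truth."""
        ds, truth = clean_dataset
        free = ["ks_p53_RNA", "kd_p53_RNA"]
        bounds = {n: (getattr(DEFAULT_PARAMS, n) / 10, getattr(DEFAULT_PARAMS, n) * 10) for n in free}
        fixed = {n: getattr(DEFAULT_PARAMS, n) for n in RATE_PARAM_NAMES if n not in free}
        cfg = FitConfig(n_starts=3, bounds=bounds, fixed=fixed, seed=8, max_nfev=60)
        best = fit(ds, cfg)[0]
        truth_ratio = DEFAULT_PARAMS.ks_p53_RNA / DEFAULT_PARAMS.kd_p53_RNA
        fit_ratio = best.params.ks_p53_RNA / best.params.kd_p53_RNA
        assert fit_ratio == pytest.approx(truth_ratio, rel=0.10)


class TestFamilySelection:
    def test_family_within_relative_tolerance(self, clean_dataset):
        ds, _ = clean_dataset
        results = fit(ds, _warm_config(n_starts=3, seed=9))
        family = minimal_cost_family(results, rel_tol=1e-6)
        assert family, "family must contain at least the best fit"
        cmin = results[0].cost
        assert all(r.converged and r.cost - cmin <= 1e-6 * cmin for r in family)

    def test_deterministic_selection_is_lowest_rank(self, clean_dataset):
        ds, _ = clean_dataset
        results = fit(ds, _warm_config(n_starts=2, seed=10))
        family = minimal_cost_family(results, rel_tol=10.0)
        assert select_from_family(family).rank == min(r.rank for r in family)

    def test_seeded_selection_reproducible(self, clean_dataset):
        ds, _ = clean_dataset
        results = fit(ds, _warm_config(n_starts=3, seed=11))
        family = minimal_cost_family(results, rel_tol=10.0)
        assert select_from_family(family, seed=1) == select_from_family(family, seed=1)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            select_from_family([])
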