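import numpy as np
import pytest

from rarethin import synthetic as syn
from rarethin.survey import SurveyDataset


class TestEnvironment:
    @pytest.fixture(scope="class")
    def env(self):
        return syn.make_environment(resolution=0.2, days=tuple(range(30)), seed=5)

    def test_deterministic_under_seed(self):
        a = syn.make_environment(resolution=0.4, days=(0, 1), seed=3)
        b = syn.make_environment(resolution=0.4, days=(0, 1), seed=3)
        assert np.array_equal(a.static["depth"], b.static["depth"])
        assert np.array_equal(a.dynamic["sst_mean"], b.dynamic["sst_mean"])

    def test_field_bounds(self, env):
        assert env.static["depth"].min() >= 5.0
        sst = env.dynamic["sst_mean"]
        assert sst.min() >= 5.0 and sst.max() <= 25.0
        assert env.dynamic["ssh_sd"].min() > 0.0
        assert env.dynamic["current"].min() > 0.0
        for name, arr in {**env.static, **env.dynamic}.items():
            assert np.all(np.isfinite(arr)), name

    def test_dynamic_fields_cover_every_day(self, env):
        for name in ("sst_mean", "sst_var", "sst_grad", "ssh_mean", "ssh_sd", "current"):
            assert env.dynamic[name].shape[0] == 30

    def test_positive_lag1_autocorrelation(self, env):
        """Daily SST anomalies persist from day to day."""
        sst = env.dynamic["sst_mean"]
        seas = sst.mean(axis=(1, 2))
        anom = (sst - sst.mean(axis=0)).reshape(30, -1)
        cells = anom[:, :: max(anom.shape[1] // 200, 1)]
        r = np.mean([
            np.corrcoef(cells[:-1, j], cells[1:, j])[0, 1]
            for j in range(cells.shape[1])
        ])
        assert r > 0.3

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            syn.make_environment(resolution=-0.1)
        with pytest.raises(ValueError):
            syn.make_environment(extent=(-1.0, -1.0, 44.0, 48.0))


class TestSurveyDesign:
    @pytest.fixture(scope="class")
    def design(self):
        env = syn.make_environment(resolution=0.2, days=(0, 6, 180, 186), seed=2)
        return env, syn.make_survey_design(env, n_segments=1500)

    def test_exact_segment_count(self, design):
        _, seg = design
        assert len(seg) == 1500

    def test_non_terminal_segments_are_ten_km(self, design):
        _, seg = design
        last = seg.groupby("transect_id")["segment_id"].idxmax()
        non_terminal = seg.drop(index=last)
        assert np.allclose(non_terminal["length_km"], 10.0)

    def test_midpoints_inside_extent(self, design):
        env, seg = design
        lon0, lon1, lat0, lat1 = env.extent
        assert seg["lon_mid"].between(lon0, lon1).all()
        assert seg["lat_mid"].between(lat0, lat1).all()

    def test_covariates_complete(self, design):
        _, seg = design
        assert not seg[list(syn.COVARIATES)].isna().any().any()

    def test_dolphin_like_preset_size(self):
        env = syn.make_environment(resolution=0.4, days=(0, 180), seed=0)
        seg = syn.make_survey_design(env, n_segments=3320)
        assert len(seg) == 3320  # 277 + 3,043 of the emulated table


class TestVirtualTaxa:
    def test_narrow_depth_restriction(self):
        tax = syn.build_virtual_taxon("narrow")
        f = tax.responses["depth"]
        assert f(np.array([2000.0]))[0] <= f(np.array([50.0]))[0] - 5.0

    def test_narrow_support_smaller_than_broad(self):
        narrow = syn.build_virtual_taxon("narrow")
        broad = syn.build_virtual_taxon("broad")
        depths = np.linspace(10, 4500, 200)
        # suitability relative to each taxon's own maximum along depth
        sn = np.exp(narrow.responses["depth"](depths))
        sb = np.exp(broad.responses["depth"](depths))
        frac_n = np.mean(sn / sn.max() > 0.05)
        frac_b = np.mean(sb / sb.max() > 0.05)
        assert frac_n < frac_b
        assert np.all(np.isfinite(broad.responses["depth"](depths)))

    def test_broad_usable_over_full_depth_range(self):
        broad = syn.build_virtual_taxon("broad")
        depths = np.linspace(10, 4500, 100)
        assert np.all(np.exp(broad.responses["depth"](depths)) > 0.1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            syn.build_virtual_taxon("medium")

    def test_group_size_defaults_from_totals(self):
        assert syn.build_virtual_taxon("broad").group_size_mean == pytest.approx(
            14477 / 277
        )
        assert syn.build_virtual_taxon("narrow").group_size_mean == pytest.approx(
            16658 / 1455
        )


class TestSimulation:
    @pytest.fixture(scope="class")
    def world(self):
        env = syn.make_environment(resolution=0.25, days=(0, 6, 180, 186), seed=4)
        seg = syn.make_survey_design(env, n_segments=1200)
        return env, seg

    def test_calibration_is_exact_in_expectation(self, world):
        _, seg = world
        tax = syn.build_virtual_taxon("narrow", target_sightings=400)
        a0 = syn.calibrate_intercept(seg, tax)
        area = seg["length_km"] * 2 * seg["half_width_km"]
        expected = float(np.sum(area * np.exp(a0 + tax.log_response(seg))))
        assert expected == pytest.approx(400.0, rel=1e-10)

    def test_realised_sightings_near_target(self, world):
        _, seg = world
        tax = syn.build_virtual_taxon("narrow", target_sightings=400)
        totals = [
            len(syn.simulate_survey(seg, tax, seed=s)[0].sightings)
            for s in range(12)
        ]
        assert np.mean(totals) == pytest.approx(400.0, rel=0.10)

    def test_group_sizes_positive_and_deterministic(self, world):
        _, seg = world
        tax = syn.build_virtual_taxon("broad", target_sightings=120)
        ds1, t1 = syn.simulate_survey(seg, tax, seed=9)
        ds2, t2 = syn.simulate_survey(seg, tax, seed=9)
        assert (ds1.sightings["group_size"] >= 1).all()
        assert ds1.sightings.equals(ds2.sightings)
        assert np.array_equal(t1.sighting_intensity, t2.sighting_intensity)

    def test_dataset_satisfies_invariants(self, world):
        _, seg = world
        tax = syn.build_virtual_taxon("narrow", target_sightings=300)
        ds, _ = syn.simulate_survey(seg, tax, seed=1)
        assert isinstance(ds, SurveyDataset)  # construction re-validates
        bk = ds.bookkeeping(tax.name)
        counts = ds.counts(tax.name)
        assert bk.n_z + int((counts > 0).sum()) == ds.n_segments

    def test_narrow_taxon_occupies_smaller_support(self, world):
        """The narrow taxon's time-averaged intensity is confined to a
        strictly smaller share of the domain than the broad taxon's."""
        env, _ = world
        grid = env.to_grid()
        support = {}
        for kind in ("broad", "narrow"):
            tax = syn.build_virtual_taxon(kind, target_sightings=300)
            resp = np.zeros((grid.n_days, grid.n_cells))
            for v, f in tax.responses.items():
                resp += f(grid.covariates[v])
            inten = np.exp(resp).mean(axis=0)
            support[kind] = float(np.mean(inten / inten.max() > 0.01))
        assert support["narrow"] < support["broad"]


def test_single_sighting_fixture_structure():
    ds = syn.single_sighting_fixture(100, 20, taxon="t")
    counts = ds.counts("t")
    assert int((counts > 0).sum()) == 20
    assert counts.max() == 1
    with pytest.raises(ValueError):
        syn.single_sighting_fixture(10, 11)


def test_scenario_reproducible_end_to_end():
    a = syn.build_scenario("broad", seed=3, n_segments=400, target_sightings=40,
                           resolution=0.4, days=(0, 180))
    b = syn.build_scenario("broad", seed=3, n_segments=400, target_sightings=40,
                           resolution=0.4, days=(0, 180))
    assert a.dataset.sightings.equals(b.dataset.sightings)
    assert a.dataset.segments.equals(b.dataset.segments)
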