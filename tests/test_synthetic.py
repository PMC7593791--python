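import numpy as np
import pytest

from clubnet.errors import ValidationError
from clubnet.connectome import pearson_connectivity
from clubnet.synthetic import (
    CohortSpec,
    default_planted,
    generate_cohort,
    generate_cohort_full,
    generate_latent_connectome,
    generate_timeseries,
    null_spec,
    overlap_pathlength_proxy,
    region_labels,
)


class TestSpec:
    def test_default_sizes_match_study(self):
        spec = CohortSpec()
        assert spec.n_per_group == {"HC": 28, "SCD": 19, "aMCI": 29}
        assert spec.n_subjects == 76
        assert spec.n_regions == 90

    def test_planted_sets_are_subsets(self):
        spec = CohortSpec()
        assert set(spec.planted_hubs) <= set(range(90))
        assert set(spec.planted_connectors) <= set(range(90))
        assert spec.planted_overlap == tuple(
            sorted(set(spec.planted_hubs) & set(spec.planted_connectors)))
        assert len(spec.planted_overlap) >= 1

    def test_validation(self):
        with pytest.raises(ValidationError):
            CohortSpec(club_attenuation={"HC": 0.0, "SCD": 1, "aMCI": 1})
        with pytest.raises(ValidationError):
            CohortSpec(n_per_group={"HC": 0, "SCD": 1, "aMCI": 1})
        with pytest.raises(ValidationError):
            CohortSpec(planted_hubs=(95,))

    def test_default_planted_spread(self):
        hubs, conns = default_planted(90, 5)
        assign = CohortSpec().community_assignment()
        # hubs cover several communities
        assert len(set(assign[list(hubs)])) >= 4


class TestLatent:
    def test_null_attenuation_groups_identical(self):
        spec = null_spec(CohortSpec(seed=3))
        a = generate_latent_connectome(spec, "HC", 7)
        b = generate_latent_connectome(spec, "aMCI", 7)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_attenuation_reduces_hub_hub_weights_only(self):
        spec = CohortSpec(seed=3)
        hc = generate_latent_connectome(spec, "HC", 7)
        am = generate_latent_connectome(spec, "aMCI", 7)
        hubs = list(spec.planted_hubs)
        hub_pair_mask = np.zeros((90, 90), dtype=bool)
        hub_pair_mask[np.ix_(hubs, hubs)] = True
        np.fill_diagonal(hub_pair_mask, False)
        assert (am.weights[hub_pair_mask] <= hc.weights[hub_pair_mask]).all()
        ratio = am.weights[hub_pair_mask] / hc.weights[hub_pair_mask]
        assert ratio.mean() == pytest.approx(0.7, abs=0.02)

    def test_symmetry_invariants(self):
        spec = CohortSpec(seed=1)
        lat = generate_latent_connectome(spec, "SCD", 2)
        w = lat.weights
        np.testing.assert_array_equal(w, w.T)
        assert (np.diag(w) == 0).all()
        assert (w >= 0).all()
        # within-community mean exceeds between-community mean
        assign = lat.community_assignment
        same = assign[:, None] == assign[None, :]
        off = ~np.eye(90, dtype=bool)
        assert w[same & off].mean() > w[~same].mean()

    def test_hub_rowsum_exceeds_median(self):
        spec = CohortSpec(seed=5)
        lat = generate_latent_connectome(spec, "HC", 11)
        rowsums = lat.weights.sum(axis=0)
        for h in spec.planted_hubs:
            assert rowsums[h] > np.median(rowsums)

    def test_connector_mass_even_across_communities(self):
        spec = CohortSpec(seed=5)
        lat = generate_latent_connectome(spec, "HC", 11)
        assign = spec.community_assignment()
        for c in spec.planted_connectors:
            masses = np.array([lat.weights[c][assign == s].sum()
                               for s in range(spec.n_communities)])
            rel = (masses.max() - masses.min()) / masses.mean()
            assert rel < 0.10

    def test_seed_determinism(self):
        spec = CohortSpec(seed=9)
        a = generate_latent_connectome(spec, "HC", 4)
        b = generate_latent_connectome(spec, "HC", 4)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestTimeseries:
    def test_determinism(self):
        spec = CohortSpec(seed=2, n_regions=30, n_communities=3)
        lat = generate_latent_connectome(spec, "HC", 1)
        a = generate_timeseries(lat, 50, 0.3, 42)
        b = generate_timeseries(lat, 50, 0.3, 42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_diagonal_latent_gives_near_zero_correlations(self):
        from clubnet.synthetic import LatentConnectome
        n = 20
        lat = LatentConnectome(np.zeros((n, n)), np.zeros(n, dtype=int))
        ts = generate_timeseries(lat, 2000, 0.5, 3,
                                 labels=tuple(f"r{i}" for i in range(n)))
        C = pearson_connectivity(ts)
        off = ~np.eye(n, dtype=bool)
        assert np.abs(C.r[off]).mean() < 0.1

    def test_block_structure_recovered(self):
        spec = CohortSpec(seed=4, n_regions=30, n_communities=3,
                          planted_hubs=(), planted_connectors=())
        lat = generate_latent_connectome(spec, "HC", 5)
        ts = generate_timeseries(lat, 400, 0.3, 6)
        C = pearson_connectivity(ts)
        assign = lat.community_assignment
        same = assign[:, None] == assign[None, :]
        off = ~np.eye(30, dtype=bool)
        assert C.r[same & off].mean() > C.r[~same].mean()

    def test_small_T_warning(self, caplog):
        spec = CohortSpec(seed=2, n_regions=30, n_communities=3)
        lat = generate_latent_connectome(spec, "HC", 1)
        with caplog.at_level("WARNING", logger="clubnet.synthetic"):
            generate_timeseries(lat, 10, 0.3, 0)
        assert any("small" in r.message for r in caplog.records)


class TestCohort:
    def test_manifest_has_76_rows_by_default_sizes(self, small_spec):
        # full default sizes on the small-region spec (fast)
        from dataclasses import replace
        spec = replace(small_spec, n_per_group=dict(
            {"HC": 28, "SCD": 19, "aMCI": 29}))
        records, tsmap = generate_cohort(spec)
        assert len(records) == 76
        assert len(tsmap) == 76
        assert sum(r.group == "SCD" for r in records) == 19

    def test_repeatability(self, small_spec):
        r1, t1 = generate_cohort(small_spec)
        r2, t2 = generate_cohort(small_spec)
        assert r1 == r2
        for sid in t1:
            np.testing.assert_array_equal(t1[sid].values, t2[sid].values)

    def test_ages_and_sex_ranges(self, small_spec):
        records, _ = generate_cohort(small_spec)
        for r in records:
            assert 55 <= r.age <= 90
            assert r.sex in ("F", "M")
            assert r.lmt_delayed is not None

    def test_zero_slope_decouples_cognition(self):
        spec = null_spec(CohortSpec(
            seed=21, n_regions=30, n_communities=3, n_timepoints=60,
            n_per_group={"HC": 26, "SCD": 25, "aMCI": 25}))
        cohort = generate_cohort_full(spec)
        lmt = np.array([r.lmt_delayed for r in cohort.records])
        proxies = np.array([cohort.proxies[r.subject_id]
                            for r in cohort.records])
        r = np.corrcoef(lmt, proxies)[0, 1]
        assert abs(r) < 0.2

    def test_positive_slope_couples_cognition(self):
        spec = CohortSpec(seed=22, n_regions=30, n_communities=3,
                          n_timepoints=60,
                          n_per_group={"HC": 26, "SCD": 25, "aMCI": 25})
        cohort = generate_cohort_full(spec)
        lmt = np.array([r.lmt_delayed for r in cohort.records])
        proxies = np.array([cohort.proxies[r.subject_id]
                            for r in cohort.records])
        r = np.corrcoef(lmt, proxies)[0, 1]
        assert r > 0.5

    def test_proxy_definition(self):
        spec = CohortSpec(seed=1)
        lat = generate_latent_connectome(spec, "HC", 0)
        ov = spec.planted_overlap
        expected = 1.0 / (lat.weights[list(ov)].sum() /
                          (len(ov) * (90 - 1)))
        assert overlap_pathlength_proxy(lat, ov) == pytest.approx(expected)


class TestLabels:
    def test_region_labels(self):
        assert len(region_labels(90)) == 90
        assert region_labels(90)[28] == "INS.L"
        assert region_labels(12) == tuple(f"R{i:03d}" for i in range(1, 13))
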