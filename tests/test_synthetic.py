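"""Synthetic study generator: marginals, occupancy process, diel clocks,
record emission and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from occudiel.data import build_history, collapse_bursts
from occudiel.synthetic import (
    NegativeBinomialSpec,
    ScaledBetaSpec,
    SyntheticStudy,
    VonMisesMixture,
    default_config,
    true_overlap,
)

TWO_PI = 2.0 * np.pi


def big_site_config(n_sites):
    cfg = default_config(seed=7, n_sites=n_sites, n_occasions=3)
    cfg.min_spacing = 0.0  # marginal checks only; spacing is irrelevant here
    return cfg


class TestCovariates:
    def test_count_and_bounded_marginals_match_targets(self):
        covs = SyntheticStudy(big_site_config(10_000)).generate_covariates()
        # overdispersed human counts: mean within 10% of the 53.9 target
        assert covs["human_count"].mean() == pytest.approx(53.9, rel=0.10)
        assert (covs["human_count"] >= 0).all()
        assert covs["human_count"].std() > 5 * covs["human_count"].mean()
        assert covs["canopy_pct"].between(0, 100).all()
        assert covs["canopy_pct"].mean() == pytest.approx(39.52, rel=0.05)
        assert covs["forest_km2"].between(0, np.pi * 0.25).all()
        for c in ("dist_water", "dist_road", "dist_settlement"):
            assert (covs[c] >= 0).all()

    def test_zero_sd_spec_gives_constant_column(self):
        cfg = big_site_config(50)
        cfg.covariate_specs = {"canopy_pct": ScaledBetaSpec(39.52, 0.0, 0, 100)}
        covs = SyntheticStudy(cfg).generate_covariates()
        assert (covs["canopy_pct"] == 39.52).all()

    def test_underdispersed_negbin_spec_rejected(self):
        with pytest.raises(ValueError, match="overdispersion"):
            NegativeBinomialSpec(mean=10.0, sd=3.0)

    def test_minimum_spacing_enforced(self):
        cfg = default_config(seed=3, n_sites=40)
        covs = SyntheticStudy(cfg).generate_covariates()
        xy = covs[["x", "y"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.min_spacing

    def test_same_seed_byte_identical(self):
        a = SyntheticStudy(default_config(seed=11, n_sites=20)).generate()
        b = SyntheticStudy(default_config(seed=11, n_sites=20)).generate()
        assert a.covariates.to_csv(index=False) == b.covariates.to_csv(index=False)
        assert a.records.to_csv(index=False) == b.records.to_csv(index=False)


class TestOccupancyProcess:
    def saturated_config(self, psi_logit, p_logit):
        cfg = default_config(seed=2, n_sites=25, n_occasions=5)
        cfg.species = ["tiger"]
        cfg.occupancy_coefs = {"tiger": {"(Intercept)": psi_logit}}
        cfg.detection_coefs = {"tiger": {"(Intercept)": p_logit}}
        return cfg

    def test_saturated_probabilities_give_all_ones(self):
        study = SyntheticStudy(self.saturated_config(20.0, 20.0))
        hist, _ = study.simulate_histories(study.generate_covariates())
        assert hist["tiger"].y.all()

    def test_impossible_occupancy_gives_all_zeros(self):
        study = SyntheticStudy(self.saturated_config(-20.0, 20.0))
        hist, _ = study.simulate_histories(study.generate_covariates())
        assert not hist["tiger"].y.any()

    def test_missing_covariate_column_is_dimension_mismatch(self):
        cfg = self.saturated_config(0.0, 0.0)
        cfg.occupancy_coefs["tiger"]["no_such_covariate"] = 1.0
        study = SyntheticStudy(cfg)
        with pytest.raises(KeyError, match="mismatch"):
            study.simulate_histories(study.generate_covariates())

    def test_naive_occupancy_matches_closed_form(self):
        # psi=0.54, p=0.74, 500 sites x 14 occasions:
        # E[naive] = psi * (1 - (1-p)^14)
        from scipy.special import logit

        cfg = default_config(seed=5, n_sites=500, n_occasions=14)
        cfg.min_spacing = 0.0
        cfg.species = ["tiger"]
        cfg.occupancy_coefs = {"tiger": {"(Intercept)": float(logit(0.54))}}
        cfg.detection_coefs = {"tiger": {"(Intercept)": float(logit(0.74))}}
        study = SyntheticStudy(cfg)
        hist, _ = study.simulate_histories(study.generate_covariates())
        naive = hist["tiger"].naive_occupancy
        expect = 0.54 * (1 - (1 - 0.74) ** 14)
        se = np.sqrt(expect * (1 - expect) / 500)
        assert abs(naive - expect) < 3 * se

    def test_naive_never_systematically_exceeds_true_psi(self):
        ds = SyntheticStudy(default_config(seed=9, n_sites=200)).generate()
        for sp, h in ds.histories.items():
            naive = h.naive_occupancy
            true_mean = ds.truth.psi[sp].mean()
            se = np.sqrt(true_mean * (1 - true_mean) / 200)
            assert naive <= true_mean + 3 * se


class TestDielClocks:
    def test_point_mass_limit(self, rng):
        mix = VonMisesMixture((1.0,), (5000.0,), (1.0,))
        t = mix.sample(2000, rng)
        r = np.hypot(np.cos(t).mean(), np.sin(t).mean())
        circ_sd = np.sqrt(-2 * np.log(r))
        assert circ_sd < 0.05

    def test_antipodal_symmetry_kills_resultant(self, rng):
        mix = VonMisesMixture((0.0, np.pi), (8.0, 8.0), (0.5, 0.5))
        t = mix.sample(10_000, rng)
        r = np.hypot(np.cos(t).mean(), np.sin(t).mean())
        assert r < 0.05

    def test_default_tiger_mixture_is_bimodal_crepuscular(self):
        cfg = default_config(seed=4)
        samples = SyntheticStudy(cfg).simulate_diel_times({"tiger": 10_000})
        hours = samples["tiger"].times * 24 / TWO_PI
        counts, _ = np.histogram(hours, bins=12, range=(0, 24))
        top2 = set(np.argsort(counts)[-2:])
        assert top2 == {9, 1}  # the 18-20 h and 2-4 h bins

    def test_zero_events_allowed(self):
        cfg = default_config(seed=4)
        out = SyntheticStudy(cfg).simulate_diel_times({"tiger": 0})
        assert out["tiger"].n == 0

    def test_invalid_mixture_specs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            VonMisesMixture((0.0,), (1.0,), (0.9,))
        with pytest.raises(ValueError, match="> 0"):
            VonMisesMixture((0.0,), (0.0,), (1.0,))

    def test_true_overlap_of_identical_specs_is_one(self):
        cfg = default_config(seed=0)
        mix = cfg.diel_mixtures["tiger"]
        assert true_overlap(mix, mix) == pytest.approx(1.0, abs=1e-9)

    def test_true_overlap_matrix_in_unit_interval(self):
        cfg = default_config(seed=0, n_sites=10, n_occasions=2)
        study = SyntheticStudy(cfg)
        _, truth = study.simulate_histories(study.generate_covariates())
        d = truth.diel_overlap
        assert np.allclose(np.diag(d.to_numpy()), 1.0)
        assert ((d >= 0) & (d <= 1 + 1e-12)).all().all()


class TestEmitRecords:
    def test_single_event_three_photos_one_burst(self):
        cfg = default_config(seed=8, n_sites=2, n_occasions=1)
        cfg.species = ["tiger"]
        cfg.occupancy_coefs = {"tiger": {"(Intercept)": 20.0}}
        cfg.detection_coefs = {"tiger": {"(Intercept)": 20.0}}
        cfg.count_specs = {}
        study = SyntheticStudy(cfg)
        covs = study.generate_covariates()
        hist, _ = study.simulate_histories(covs)
        rec = study.emit_records(hist, covs)
        one_site = rec[rec.site_id == rec.site_id.iloc[0]]
        assert len(one_site) == 3
        assert one_site["burst_id"].nunique() == 1

    def test_empty_history_gives_header_only(self, tmp_path):
        cfg = default_config(seed=8, n_sites=3, n_occasions=2)
        cfg.species = ["tiger"]
        cfg.occupancy_coefs = {"tiger": {"(Intercept)": -20.0}}
        cfg.detection_coefs = {"tiger": {"(Intercept)": 0.0}}
        cfg.count_specs = {}
        study = SyntheticStudy(cfg)
        covs = study.generate_covariates()
        hist, _ = study.simulate_histories(covs)
        rec = study.emit_records(hist, covs)
        path = tmp_path / "records.csv"
        rec.to_csv(path, index=False)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("site_id")

    def test_round_trip_reproduces_histories(self):
        ds = SyntheticStudy(default_config(seed=13, n_sites=40, n_occasions=8)).generate()
        events = collapse_bursts(ds.records)
        for sp, h in ds.histories.items():
            rebuilt = build_history(events, sp, ds.effort)
            assert rebuilt.site_ids == h.site_ids
            np.testing.assert_array_equal(rebuilt.y, h.y)

    def test_emitted_counts_reproduce_covariate_totals(self):
        from occudiel.data import LIVESTOCK_SPECIES, count_covariate

        ds = SyntheticStudy(default_config(seed=21, n_sites=30, n_occasions=5)).generate()
        human = count_covariate(ds.records, "human",
                                site_ids=list(ds.covariates["site_id"]))
        np.testing.assert_array_equal(human.to_numpy(),
                                      ds.covariates["human_count"].to_numpy())
        lives = count_covariate(ds.records, LIVESTOCK_SPECIES,
                                site_ids=list(ds.covariates["site_id"]))
        np.testing.assert_array_equal(lives.to_numpy(),
                                      ds.covariates["livestock_count"].to_numpy())
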