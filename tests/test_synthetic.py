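import numpy as np
import pytest
from scipy import stats

from aftclock.data_model import Apoe4, Marker
from aftclock.synthetic import (
    CohortConfig,
    DEFAULT_CURVES,
    TwoScannerConfig,
    config_from_dict,
    generate_cohort,
    sample_visit_schedule,
)
from aftclock.transforms import DEFAULT_MARKER_SPECS


class TestVisitSchedules:
    def test_degenerate_count_gives_one_visit_per_marker(self):
        cfg = CohortConfig(
            visit_probs={m: (0.0, 1.0, 0.0, 0.0) for m in CohortConfig().markers}
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            sched = sample_visit_schedule(cfg, rng)
            assert all(len(ages) == 1 for ages in sched.values())

    def test_fixed_gap_arithmetic(self):
        cfg = CohortConfig(
            visit_probs={m: (0.0, 0.0, 0.0, 1.0) for m in CohortConfig().markers},
            gap_mean=2.5,
            gap_sd=0.0,
            extra_visits_rate=0.0,
        )
        sched = sample_visit_schedule(cfg, np.random.default_rng(1), entry_age=70.0)
        for ages in sched.values():
            assert np.allclose(ages, [70.0, 72.5, 75.0])

    def test_zero_count_fraction_matches_configuration(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(123)
        n = 10000
        missing = sum(
            len(sample_visit_schedule(cfg, rng)[Marker.TAU_PET]) == 0
            for _ in range(n)
        )
        assert 0.38 <= missing / n <= 0.42

    def test_count_frequencies_match_configured_categorical(self):
        """Chi-square goodness of fit on the amyloid visit-count margin."""
        cfg = CohortConfig(extra_visits_rate=0.0)
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        n = 10000
        for _ in range(n):
            c = min(len(sample_visit_schedule(cfg, rng)[Marker.AMYLOID_PET]), 3)
            counts[c] += 1
        expected = np.array(cfg.visit_probs[Marker.AMYLOID_PET]) * n
        keep = expected > 0
        chi2 = float(np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep]))
        pval = 1 - stats.chi2.cdf(chi2, df=keep.sum() - 1)
        assert pval > 0.01

    def test_shared_schedule_groups_reuse_visit_ages(self):
        cfg = CohortConfig(
            schedule_groups={
                Marker.TAU_PET: "stage",
                Marker.WMH_PCT: "stage",
            }
        )
        sched = sample_visit_schedule(cfg, np.random.default_rng(5), entry_age=70.0)
        assert np.array_equal(sched[Marker.TAU_PET], sched[Marker.WMH_PCT])


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        from aftclock.data_model import write_long_table

        for i, d in enumerate(
            generate_cohort(CohortConfig(n_participants=40, seed=11))[0]
            for _ in range(2)
        ):
            write_long_table(d, tmp_path / f"v{i}.csv", tmp_path / f"c{i}.csv")
        assert (tmp_path / "v0.csv").read_bytes() == (tmp_path / "v1.csv").read_bytes()
        assert (tmp_path / "c0.csv").read_bytes() == (tmp_path / "c1.csv").read_bytes()

    def test_prefix_stability_under_cohort_growth(self):
        small, _ = generate_cohort(CohortConfig(n_participants=10, seed=3))
        large, _ = generate_cohort(CohortConfig(n_participants=40, seed=3))
        small_ids = set(small.participant_ids)
        large_by_pid = {
            pid: [o for o in large.observations if o.participant_id == pid]
            for pid in small_ids
        }
        for o in small.observations:
            match = [
                b
                for b in large_by_pid[o.participant_id]
                if b.marker is o.marker and b.age == o.age
            ]
            assert len(match) == 1 and match[0].raw_value == o.raw_value

    def test_noise_free_degenerate_case_lies_on_the_curve(self):
        cfg = CohortConfig(
            n_participants=30,
            seed=2,
            tau=np.full(4, 1e-9),
            sigma=np.full(4, 1e-12),
            beta=np.zeros((4, 5)),
        )
        ds, truth = generate_cohort(cfg)
        for o in ds.observations:
            k = list(cfg.markers).index(o.marker)
            expected = float(truth.curves[o.marker](o.age))
            assert o.transformed_value == pytest.approx(expected, abs=1e-6)

    def test_raw_values_respect_marker_domains(self):
        ds, _ = generate_cohort(CohortConfig(n_participants=400, seed=17))
        for o in ds.observations:
            if o.marker in (Marker.AMYLOID_PET, Marker.TAU_PET):
                assert o.raw_value > 0
            elif o.marker is Marker.WMH_PCT:
                assert o.raw_value >= 0
            elif o.marker is Marker.FA_GCC:
                assert 0.0 < o.raw_value < 1.0

    def test_realized_shift_correlation_matches_configured_R(self):
        cfg = CohortConfig(n_participants=5000, seed=42)
        _, truth = generate_cohort(cfg)
        emp = np.corrcoef(truth.u.T)
        assert emp[0, 1] == pytest.approx(cfg.R[0, 1], abs=0.03)
        assert emp[2, 3] == pytest.approx(cfg.R[2, 3], abs=0.03)

    def test_apoe_effect_shifts_amyloid_by_nine_years(self):
        cfg = CohortConfig(n_participants=5000, seed=42)
        ds, truth = generate_cohort(cfg)
        carriers = np.array(
            [c.apoe4 is Apoe4.CARRIER for c in ds.covariates]
        )
        noncarriers = np.array(
            [c.apoe4 is Apoe4.NONCARRIER for c in ds.covariates]
        )
        shift = truth.total_shift()[:, 0]
        diff = shift[carriers].mean() - shift[noncarriers].mean()
        assert diff == pytest.approx(9.0, abs=0.5)

    def test_non_psd_R_rejected_before_sampling(self):
        R = np.full((4, 4), 0.99)
        np.fill_diagonal(R, 1.0)
        R[0, 1] = R[1, 0] = -0.99  # impossible with the other entries
        with pytest.raises(ValueError, match="positive definite"):
            generate_cohort(CohortConfig(n_participants=5, R=R))


class TestScannerArtifact:
    def test_pre_switch_visits_are_labeled_and_biased(self):
        cfg = CohortConfig(n_participants=300, seed=21, scanner=TwoScannerConfig())
        ds, _ = generate_cohort(cfg)
        scanners = {o.scanner for o in ds.observations if o.marker is Marker.WMH_PCT}
        assert scanners == {"A", "B"}
        assert all(
            o.scanner is None
            for o in ds.observations
            if o.marker is Marker.AMYLOID_PET
        )

    def test_harmonization_recovers_reference_scale(self):
        from aftclock.harmonization import harmonize_dataset

        cfg = CohortConfig(
            n_participants=400,
            seed=22,
            scanner=TwoScannerConfig(
                extra_noise_sd={"wmh_pct": 0.0, "fa_gcc": 0.0}
            ),
        )
        ds, truth = generate_cohort(cfg)
        harmonized = harmonize_dataset(ds)
        spec = DEFAULT_MARKER_SPECS[Marker.FA_GCC]
        k = list(cfg.markers).index(Marker.FA_GCC)
        pid_idx = {p: i for i, p in enumerate(truth.participant_ids)}
        resid = []
        for o in harmonized.observations:
            if o.marker is not Marker.FA_GCC or o.scanner != "B*":
                continue
            i = pid_idx[o.participant_id]
            t = o.age + truth.covariate_shift[i, k] + truth.u[i, k]
            resid.append(spec.forward(o.raw_value) - truth.curves[Marker.FA_GCC](t))
        resid = np.array(resid)
        assert len(resid) > 50
        # residuals shrink back to the generative noise scale
        assert np.std(resid) < 3 * truth.sigma[k]


class TestConfigParsing:
    def test_dict_round_trip_of_key_fields(self):
        cfg = config_from_dict(
            {
                "n_participants": 12,
                "markers": ["amyloid_pet", "tau_pet", "wmh_pct", "fa_gcc"],
                "tau": [5, 5, 5, 5],
                "R": np.eye(4).tolist(),
                "curves": {
                    m.value: DEFAULT_CURVES[m].to_dict() for m in CohortConfig().markers
                },
                "schedule_groups": {"tau_pet": "g1", "wmh_pct": "g1"},
            }
        )
        assert cfg.n_participants == 12
        assert cfg.schedule_groups[Marker.TAU_PET] == "g1"
        assert np.allclose(cfg.R, np.eye(4))

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            config_from_dict({"n_participant": 5})
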