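import numpy as np
import pytest

import mfcoupling as mfc
from mfcoupling.exceptions import ValidationError


class TestPlantedKlsOracle:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0, 1, 0, 1), 1.0),
            ((0, 1, 1, 1), np.exp(-1.0)),
            ((0, 1, 0, 2), np.exp(-1.125)),
        ],
    )
    def test_hand_values(self, args, expected):
        assert mfc.planted_kls_oracle(*args) == pytest.approx(expected, abs=1e-12)

    def test_equal_scale_closed_form(self):
        # with equal scales the oracle reduces to exp(-dmu^2 / sigma^2)
        assert mfc.planted_kls_oracle(1.0, 0.5, 2.0, 0.5) == pytest.approx(
            np.exp(-4.0)
        )

    def test_symmetry(self):
        assert mfc.planted_kls_oracle(0, 1, 2, 3) == mfc.planted_kls_oracle(
            2, 3, 0, 1
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            mfc.planted_kls_oracle(0, 0.0, 1, 1)


class TestNearestCorrelation:
    def test_identity_is_fixed_point(self):
        assert np.allclose(mfc.nearest_correlation(np.eye(4)), np.eye(4))

    def test_valid_correlation_unchanged(self, rng):
        x = rng.standard_normal((50, 5))
        c = np.corrcoef(x, rowvar=False)
        assert np.allclose(mfc.nearest_correlation(c), c, atol=1e-7)

    def test_non_psd_input_repaired(self):
        """(0.9, 0.9, -0.9) pattern is not PSD; output must be."""
        c = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        out = mfc.nearest_correlation(c)
        assert np.linalg.eigvalsh(out).min() >= -1e-8
        assert np.allclose(np.diag(out), 1.0)
        assert np.allclose(out, out.T)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            mfc.nearest_correlation(np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestGenerateTimeseries:
    def test_identity_target_small_off_diagonal(self):
        ts = mfc.generate_timeseries(np.eye(5), 10_000, seed=0)
        c = np.corrcoef(ts, rowvar=False)
        off = np.abs(c[~np.eye(5, dtype=bool)])
        assert off.mean() < 0.05

    def test_strong_pair_recovered(self):
        target = np.eye(3)
        target[0, 1] = target[1, 0] = 0.9
        ts = mfc.generate_timeseries(target, 10_000, seed=1)
        c = np.corrcoef(ts, rowvar=False)
        assert c[0, 1] == pytest.approx(0.9, abs=0.05)

    def test_determinism(self):
        a = mfc.generate_timeseries(np.eye(4), 100, seed=7)
        b = mfc.generate_timeseries(np.eye(4), 100, seed=7)
        assert np.array_equal(a, b)

    def test_asymmetric_target_rejected(self):
        bad = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValidationError):
            mfc.generate_timeseries(bad, 10)


class TestCohortConfig:
    def test_infeasible_gamma_rejected(self):
        cfg = mfc.CohortConfig(
            n_regions=4,
            coupling_fidelity=np.array([0.2, 0.5, 0.95, 0.99]),
            group_effect=0.1,
        )
        with pytest.raises(ValidationError):
            cfg.resolved()

    def test_nonpositive_scale_rejected(self):
        cfg = mfc.CohortConfig(n_regions=3, region_sigma=np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValidationError):
            cfg.resolved()

    def test_defaults_resolve(self):
        cfg = mfc.CohortConfig(n_regions=10).resolved()
        assert len(cfg.region_mu) == 10
        assert (cfg.coupling_fidelity >= 0).all()
        assert (cfg.coupling_fidelity + cfg.group_effect <= 1).all()


class TestGenerateCohort:
    def test_seeded_determinism_bit_identical(self):
        cfg = mfc.CohortConfig(
            n_regions=6,
            n_subjects_per_group=2,
            n_voxels_per_region=50,
            timeseries_length=20,
        )
        a = mfc.generate_cohort(cfg, seed=11)
        b = mfc.generate_cohort(cfg, seed=11)
        for sa, sb in zip(a.subjects, b.subjects):
            assert all(
                np.array_equal(x, y)
                for x, y in zip(sa.voxels.samples, sb.voxels.samples)
            )
            assert np.array_equal(sa.timeseries.values, sb.timeseries.values)
            assert np.array_equal(sa.gamma_subject, sb.gamma_subject)
        assert a.cohort.equals(b.cohort)

    def test_region_means_within_clt_bound(self):
        """With 5000 voxels the empirical region means stay within three
        standard errors of the configured locations."""
        cfg = mfc.CohortConfig(
            n_regions=8,
            n_subjects_per_group=1,
            n_voxels_per_region=5_000,
            timeseries_length=10,
            subject_mu_jitter_sd=0.0,
            group_effect=0.0,
        )
        co = mfc.generate_cohort(cfg, seed=5)
        for s in co.subjects:
            for mu, sigma, vals in zip(
                co.config.region_mu, co.config.region_sigma, s.voxels.samples
            ):
                se = sigma / np.sqrt(vals.size)
                assert abs(vals.mean() - mu) < 3 * se

    def test_no_group_effect_means_identical_gamma_profiles(self):
        """With group_effect 0 and all noise terms off, case and control
        subjects share the planted coupling profile exactly."""
        cfg = mfc.CohortConfig(
            n_regions=6,
            n_subjects_per_group=3,
            n_voxels_per_region=20,
            timeseries_length=10,
            group_effect=0.0,
            gamma_subject_sd=0.0,
            site_shift=np.zeros(2),
            n_sites=2,
        )
        co = mfc.generate_cohort(cfg, seed=2)
        cases = [s.gamma_subject for s in co.subjects if s.group == "case"]
        controls = [s.gamma_subject for s in co.subjects if s.group == "control"]
        for c in cases + controls:
            assert np.array_equal(c, cases[0])

    def test_cohort_table_is_valid(self, small_cohort):
        table = mfc.CohortTable(small_cohort.cohort)
        scores = table.df.loc[table.is_case, "symptom_score"]
        assert scores.between(0, 52).all()
        assert set(table.df["site"].unique()) == {"site-0", "site-1"}

    def test_pipeline_kls_tracks_oracle_across_pairs(self, rng):
        """Spearman agreement between the KDE pipeline's similarities and
        the closed-form oracle across all pairs of a Gaussian design."""
        from scipy.stats import spearmanr

        cfg = mfc.CohortConfig(
            n_regions=8,
            n_subjects_per_group=1,
            n_voxels_per_region=5_000,
            timeseries_length=10,
            subject_mu_jitter_sd=0.0,
            group_effect=0.0,
        )
        co = mfc.generate_cohort(cfg, seed=9)
        msn = mfc.build_msn(co.voxel_samples[0])
        iu = np.triu_indices(8, k=1)
        rho = spearmanr(msn.values[iu], co.s_true[iu]).statistic
        assert rho > 0.95


class TestDefaultGeometry:
    def test_partition_covers_all_regions(self):
        part = mfc.default_partition(96)
        assert sorted(part.mapping) == list(range(1, 97))
        assert set(part.networks) == set(mfc.YEO7_LABELS)
        assert all(len(part.members(n)) > 0 for n in part.networks)

    def test_centroids_on_unit_sphere_split_by_hemisphere(self):
        cent = mfc.default_centroids(96)
        xyz = cent[["x", "y", "z"]].to_numpy()
        assert np.allclose(np.linalg.norm(xyz, axis=1), 1.0, atol=1e-9)
        assert (cent["hemisphere"] == "L").sum() == 48
        assert (cent.loc[cent["hemisphere"] == "L", "x"] <= 0).all()
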