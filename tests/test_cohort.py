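"""Synthetic-cohort generator: determinism, structure, generative links."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from idiomap import cohort
from idiomap.cohort import (
    BehaviourLink,
    CohortConfig,
    CohortConfigError,
    GroupSpec,
    balanced_config,
    generate_behaviour,
    generate_bold_run,
    generate_cohort,
    generate_composite_atlas,
    table1_config,
)

from conftest import group_mean_variability


class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = balanced_config(seed=3, n_per_group=10, n_rois=20)
        p1, m1 = generate_cohort(cfg)
        p2, m2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seeds_differ(self):
        p1, m1 = generate_cohort(balanced_config(seed=1, n_per_group=10,
                                                 n_rois=20))
        p2, m2 = generate_cohort(balanced_config(seed=2, n_per_group=10,
                                                 n_rois=20))
        assert not np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_reference_cohort_composition(self, table1_cohort):
        phenotype, matrix = table1_cohort
        assert len(phenotype) == 80
        counts = phenotype["group"].value_counts().to_dict()
        assert counts == {"TDC": 33, "ASC-IA": 28, "ASC-II": 19}
        # impaired subgroup is all-male in this preset
        ii = phenotype[phenotype["group"] == "ASC-II"]
        assert (ii["sex"] == "M").all()
        assert (phenotype[phenotype["group"] == "TDC"]["sex"] == "M").sum() == 25

    def test_phenotype_schema(self, table1_cohort):
        phenotype, matrix = table1_cohort
        for col in ("id", "group", "diagnostic_group", "adhd", "age",
                    "sex", "mean_fd") + cohort.MEASURES:
            assert col in phenotype.columns
        assert (phenotype["mean_fd"] > 0).all()
        lo, hi = 8.0, 30.0
        assert phenotype["age"].between(lo, hi).all()
        # binary diagnostic label consistent with subgroup label
        is_tdc = phenotype["group"] == "TDC"
        assert (phenotype.loc[is_tdc, "diagnostic_group"] == "TDC").all()
        assert (phenotype.loc[~is_tdc, "diagnostic_group"] == "ASC").all()
        assert list(matrix.index) == list(phenotype["id"])

    @pytest.mark.parametrize("mutate", [
        dict(n=1), dict(deviation_sd=0.0), dict(deviation_sd=-1.0),
    ])
    def test_invalid_group_spec(self, mutate):
        base = dict(name="G", n=5, deviation_sd=1.0)
        base.update(mutate)
        with pytest.raises(CohortConfigError):
            CohortConfig(group_specs=(GroupSpec(**base),)).validate()

    def test_invalid_config(self):
        g = GroupSpec("G", 5, 1.0)
        with pytest.raises(CohortConfigError):
            CohortConfig(group_specs=(g,), n_rois=1).validate()
        with pytest.raises(CohortConfigError):
            CohortConfig(group_specs=(g,), age_variability_slope=0.1
                         ).validate()
        with pytest.raises(CohortConfigError):
            CohortConfig(group_specs=()).validate()

    def test_variability_ordering_under_amplified_deviation(self):
        """Doubling one group's deviation sd drives its mean variability
        above the others in nearly every replicate."""
        wins = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = balanced_config(seed=seed, n_per_group=15, n_rois=60,
                                  deviation_sds=(1.0, 1.0, 2.0))
            ph, mat = generate_cohort(cfg)
            gm = group_mean_variability(ph, mat)
            if gm["ASC-II"] > gm["ASC-IA"] and gm["ASC-II"] > gm["TDC"]:
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_monotonicity_in_deviation_sd(self):
        """Group-mean variability increases with the generative sd."""
        means = []
        for sd in (0.5, 1.0, 2.0):
            vals = []
            for seed in range(40):
                cfg = balanced_config(seed=seed, n_per_group=12, n_rois=50,
                                      deviation_sds=(1.0, 1.0, sd))
                ph, mat = generate_cohort(cfg)
                vals.append(group_mean_variability(ph, mat)["ASC-II"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_fd_marginal_calibration(self):
        """Generated mean-FD follows the configured log-normal."""
        passes = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = balanced_config(seed=seed, n_per_group=40, n_rois=10)
            ph, _ = generate_cohort(cfg)
            g = cfg.group_specs[0]
            sub = ph[ph["group"] == g.name]["mean_fd"]
            _, p = stats.kstest(np.log(sub), "norm",
                               args=(np.log(g.fd_median), g.fd_log_sd))
            if p >= 0.01:
                passes += 1
        assert passes >= 0.95 * n_rep

    def test_negative_age_effect_on_latent_scale(self, table1_cohort):
        phenotype, _ = table1_cohort
        tdc = phenotype[phenotype["group"] == "TDC"]
        r = np.corrcoef(tdc["age"], np.log(tdc["latent_sigma"]))[0, 1]
        assert r < 0


class TestGenerateBehaviour:
    def test_unknown_form_rejected(self):
        with pytest.raises(CohortConfigError):
            generate_behaviour(np.ones(5), BehaviourLink(form="cubic"),
                               np.random.default_rng(0))

    def test_null_link_uncorrelated(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(1.0, 0.5, 2000)
        score = generate_behaviour(latent, BehaviourLink("null"), rng)
        assert abs(np.corrcoef(latent, score)[0, 1]) < 0.05

    def test_linear_link_noise_free_limit(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(1.0, 0.5, 200)
        score = generate_behaviour(
            latent, BehaviourLink("linear", 2.0, 3.0, noise_sd=0.0), rng)
        assert np.corrcoef(latent, score)[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(score, 2.0 + 3.0 * latent)

    def test_quadratic_link_leaves_structured_residuals(self):
        """A linear fit misses the quadratic signal; adding the squared
        term captures it."""
        rng = np.random.default_rng(1)
        latent = rng.normal(1.0, 0.6, 400)
        score = generate_behaviour(
            latent, BehaviourLink("quadratic", 0.0, 5.0, center=1.0,
                                  noise_sd=0.5), rng)
        lin = np.polyfit(latent, score, 1)
        resid = score - np.polyval(lin, latent)
        quad = np.polyfit(latent, score, 2)
        resid2 = score - np.polyval(quad, latent)
        assert (resid**2).sum() > 2 * (resid2**2).sum()

    def test_lognormal_noise_moments(self):
        rng = np.random.default_rng(0)
        score = generate_behaviour(
            np.zeros(20000),
            BehaviourLink("null", 0.0, noise_sd=2.0,
                          noise_family="lognormal"), rng)
        assert np.mean(score) == pytest.approx(0.0, abs=0.1)
        assert np.std(score) == pytest.approx(2.0, rel=0.1)
        assert stats.skew(score) > 1.0


class TestCompositeAtlas:
    def test_component_counts_sum(self):
        img = generate_composite_atlas((24, 28, 24), [200, 50, 34], seed=0)
        data = np.asarray(img.get_fdata()).astype(int)
        labels = np.unique(data)
        labels = labels[labels > 0]
        assert len(labels) == 284
        assert labels.min() == 1 and labels.max() == 284

    def test_single_parcel_covers_foreground(self):
        img = generate_composite_atlas((6, 6, 6), [1], seed=0)
        data = np.asarray(img.get_fdata()).astype(int)
        assert set(np.unique(data)) <= {0, 1}
        assert (data == 1).sum() >= 1

    def test_small_volume(self):
        img = generate_composite_atlas((4, 4, 4), [3, 2], seed=1)
        data = np.asarray(img.get_fdata()).astype(int)
        labels = np.unique(data)
        assert set(labels[labels > 0]) == {1, 2, 3, 4, 5}
        assert (data > 0).sum() <= 64

    def test_too_small_volume_rejected(self):
        with pytest.raises(CohortConfigError):
            generate_composite_atlas((2, 2, 2), [10], seed=0)

    def test_every_label_occupied(self):
        img = generate_composite_atlas((10, 10, 10), [30, 10], seed=2)
        data = np.asarray(img.get_fdata()).astype(int)
        counts = np.bincount(data.ravel(), minlength=41)[1:]
        assert (counts >= 1).all()


class TestBoldRun:
    def test_seeded_determinism(self):
        from idiomap import glm

        atlas = generate_composite_atlas((6, 6, 6), [5], seed=0)
        design = glm.build_design_matrix(glm.standard_timing())
        vec = np.arange(1.0, 6.0)
        img1, mot1 = generate_bold_run(vec, atlas, design, noise_sd=1.0,
                                       seed=9)
        img2, mot2 = generate_bold_run(vec, atlas, design, noise_sd=1.0,
                                       seed=9)
        np.testing.assert_array_equal(np.asarray(img1.dataobj),
                                      np.asarray(img2.dataobj))
        pd.testing.assert_frame_equal(mot1, mot2)

    def test_vector_atlas_mismatch(self):
        from idiomap import glm

        atlas = generate_composite_atlas((6, 6, 6), [5], seed=0)
        design = glm.build_design_matrix(glm.standard_timing())
        with pytest.raises(CohortConfigError):
            generate_bold_run(np.ones(7), atlas, design, seed=0)

    def test_motion_table_shape(self):
        from idiomap import glm

        atlas = generate_composite_atlas((6, 6, 6), [5], seed=0)
        design = glm.build_design_matrix(glm.standard_timing())
        _, motion = generate_bold_run(np.ones(5), atlas, design, seed=0)
        assert motion.shape == (design.values.shape[0], 6)
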