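"""Phantom-cohort generator: determinism, planted structure, perturbations."""

import numpy as np
import pytest

from marginrad.prep import compute_adc
from marginrad.synthetic import PhantomConfig, generate_cohort, perturb_segmentation


def dice(a, b):
    return 2 * np.sum(a & b) / (a.sum() + b.sum())


class TestGenerateCohort:
    def test_bitwise_deterministic(self):
        cfg = PhantomConfig(n_cases=5, seed=7)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(PhantomConfig(n_cases=5, seed=7))
        for a, b in zip(c1, c2):
            assert np.array_equal(a.t2.values, b.t2.values)
            assert np.array_equal(a.dwi_b800.values, b.dwi_b800.values)
            assert np.array_equal(a.masks.cavity, b.masks.cavity)
            assert a.label == b.label and a.followup_time == b.followup_time

    def test_noiseless_dwi_inverts_to_prescribed_adc(self):
        cfg = PhantomConfig(n_cases=4, seed=5, noise_sd=0.0)
        case = generate_cohort(cfg)[0]
        adc = compute_adc(case.dwi_b0, case.dwi_b800, 800.0)
        m = case.masks.uterus
        assert np.max(np.abs(adc.values[m] - case.adc_field[m])) < 1e-12

    def test_structure_invariants(self, small_cohort):
        for case in small_cohort:
            assert case.masks.cavity.any()
            assert not np.any(case.masks.cavity & ~case.masks.uterus)
            assert 0 < case.followup_time <= 36.0
            assert case.t2.shape == case.dwi_b0.shape == case.dwi_b800.shape

    def test_label_fraction_converges(self):
        frac = 0.32
        counts = []
        for seed in range(30):
            cfg = PhantomConfig(n_cases=20, residual_fraction=frac, seed=seed)
            rng_labels = generate_cohort.__wrapped__ if hasattr(generate_cohort, "__wrapped__") else None
            cases = generate_cohort(cfg)
            counts.append(sum(c.label == "residual" for c in cases))
        mean = np.mean(counts) / 20
        # 30*20 = 600 Bernoulli draws: 4 sigma band
        assert abs(mean - frac) < 4 * np.sqrt(frac * (1 - frac) / 600)

    def test_margin_flag_rates(self):
        cfg = PhantomConfig(n_cases=400, seed=3, pm_sensitivity=0.65, pm_specificity=0.70)
        cases = generate_cohort(cfg)
        res = [c for c in cases if c.label == "residual"]
        non = [c for c in cases if c.label == "nonresidual"]
        sens = np.mean([c.margin_positive for c in res])
        spec = np.mean([not c.margin_positive for c in non])
        assert abs(sens - 0.65) < 4 * np.sqrt(0.65 * 0.35 / len(res))
        assert abs(spec - 0.70) < 4 * np.sqrt(0.70 * 0.30 / len(non))

    def test_grid_too_small_raises(self):
        cfg = PhantomConfig(n_cases=4, seed=1, grid_shape=(20, 20, 10))
        with pytest.raises(ValueError, match="grid too small"):
            generate_cohort(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PhantomConfig(n_cases=3)
        with pytest.raises(ValueError):
            PhantomConfig(residual_fraction=0.0)
        with pytest.raises(ValueError):
            PhantomConfig(texture_effect=-1.0)


class TestPerturbSegmentation:
    def test_zero_jitter_identity(self, small_cohort):
        masks = small_cohort[0].masks
        out = perturb_segmentation(masks, 0.0, rng_seed=1)
        assert np.array_equal(out.uterus, masks.uterus)
        assert np.array_equal(out.cavity, masks.cavity)

    def test_dice_band_at_1mm(self, small_cohort):
        for i, case in enumerate(small_cohort):
            out = perturb_segmentation(case.masks, 1.0, rng_seed=100 + i)
            d = dice(case.masks.cavity, out.cavity)
            assert 0.7 < d < 1.0

    def test_distinct_seeds_equal_magnitude(self, small_cohort):
        # displacement fields are normalized to the requested RMS, so the
        # boundary displaced volume (mask symmetric difference, summed over
        # the large uterus surface) agrees across seeds
        masks = small_cohort[0].masks
        outs = [perturb_segmentation(masks, 1.0, rng_seed=s) for s in (1, 2)]
        assert not np.array_equal(outs[0].cavity, outs[1].cavity)
        xors = [np.sum(out.uterus ^ masks.uterus) for out in outs]
        assert abs(xors[0] - xors[1]) / max(xors) < 0.2

    def test_topology_preserved(self, small_cohort):
        from scipy import ndimage

        out = perturb_segmentation(small_cohort[0].masks, 1.5, rng_seed=9)
        _, n_cav = ndimage.label(out.cavity)
        assert n_cav == 1
        assert not np.any(out.cavity & ~out.uterus)


class TestNullEffect:
    def test_texture_effect_zero_classes_identical_in_distribution(self):
        """With texture_effect=0 the two classes are generated by one law:
        per-feature two-sample t-tests reject at ~alpha."""
        from scipy import stats
        from marginrad.pipeline import extract_cohort, manifest_frame
        from marginrad.features import PrepConfig

        pvals = []
        for seed in range(6):
            cfg = PhantomConfig(n_cases=16, texture_effect=0.0, seed=seed)
            cases = generate_cohort(cfg)
            feats = extract_cohort(cases, PrepConfig(erosion_px=1))
            labels = manifest_frame(cases)["label"] == "residual"
            if labels.sum() < 3 or (~labels).sum() < 3:
                continue
            for col in feats.columns:
                x = feats.loc[labels.values, col]
                z = feats.loc[~labels.values, col]
                if x.std() == 0 and z.std() == 0:
                    continue
                pvals.append(stats.ttest_ind(x, z).pvalue)
        pvals = np.asarray(pvals)
        reject = np.mean(pvals < 0.01)
        # binomial slack around the nominal 1% level (correlated features
        # inflate the variance, hence the generous band)
        assert reject < 0.06
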