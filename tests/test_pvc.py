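"""GTM construction, constrained inversion, SUVR normalization, ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from parcelpvc import (
    GTMModel,
    ParcelTable,
    PSFModel,
    build_gtm,
    cortical_wm_ratio,
    default_activity_map,
    invert_gtm,
    normalize_suvr,
    simulate_pet,
)
from parcelpvc.forward import FWHM_TO_SIGMA
from parcelpvc.pvc import GTMatrix
from parcelpvc.volumes import LabelVolume


def _table(rows):
    return ParcelTable(
        pd.DataFrame(
            rows,
            columns=["label", "name", "tissue_class", "hemi", "paired_wm_label", "is_reference"],
        )
    )


class TestBuildGTM:
    def test_fwhm_zero_gives_identity(self, small_phantom):
        labels, parcels = small_phantom
        g = build_gtm(labels, parcels, PSFModel(0.0), include_background=False)
        np.testing.assert_allclose(g.weights, np.eye(len(parcels.labels)), atol=1e-12)

    def test_rows_sum_to_one_with_background(self, small_phantom):
        labels, parcels = small_phantom
        g = build_gtm(labels, parcels, PSFModel(8.0), include_background=True)
        np.testing.assert_allclose(g.weights.sum(axis=1), 1.0, atol=1e-6)
        assert g.weights.min() >= -1e-12 and g.weights.max() <= 1 + 1e-12
        assert np.all(np.diag(g.weights) > 0)

    def test_two_half_volumes_match_brute_force_oracle(self):
        # two touching half-volumes filling the grid, FWHM = 2 voxels
        arr = np.ones((12, 12, 12), dtype=int)
        arr[6:, :, :] = 2
        labels = LabelVolume(arr, np.eye(4))
        table = _table([
            (1, "a", "deepgm", "bi", np.nan, True),
            (2, "b", "deepgm", "bi", np.nan, False),
        ])
        psf = PSFModel(2.0)
        g = build_gtm(labels, table, psf, include_background=False)
        sigma = 2.0 * FWHM_TO_SIGMA
        oracle = np.empty((2, 2))
        for j, lab in enumerate((1, 2)):
            blurred = ndimage.gaussian_filter(
                (arr == lab).astype(float), sigma, mode="constant", truncate=4.0
            )
            for i, lab_i in enumerate((1, 2)):
                oracle[i, j] = blurred[arr == lab_i].mean()
        np.testing.assert_allclose(g.weights, oracle, atol=1e-9)

    def test_empty_parcel_reported(self, small_phantom):
        labels, parcels = small_phantom
        df = parcels.df.copy()
        df.loc[len(df)] = [999, "ghost", "deepgm", "bi", np.nan, False]
        with pytest.raises(ValueError, match="999"):
            build_gtm(labels, ParcelTable(df), PSFModel(8.0))


# hand-derived 2x2 KKT case: G near-collinear, unconstrained optimum negative
G2 = np.array([[0.8, 0.6], [0.6, 0.8]])
T2 = np.array([1.0, 0.4])
# unconstrained: G^-1 t = (2, -1); constrained: T2 clamped to 0, T1 refit:
# T1 = g1.t / g1.g1 = (0.8 + 0.24) / (0.64 + 0.36) = 1.04
UNCONSTRAINED = np.array([2.0, -1.0])
CONSTRAINED = np.array([1.04, 0.0])


def _gtm2():
    return GTMatrix(G2, [1, 2], PSFModel(8.0))


class TestInvertGTM:
    def test_identity_matrix_returns_observations(self):
        g = GTMatrix(np.eye(3), [1, 2, 3], PSFModel(0.0))
        obs = {1: 0.5, 2: 1.5, 3: 0.0}
        for mode in ("unconstrained", "constrained"):
            res = invert_gtm(g, obs, mode=mode)
            np.testing.assert_allclose(res.corrected.to_numpy(), [0.5, 1.5, 0.0], atol=1e-12)

    def test_forward_then_invert_recovers_truth(self, rng):
        n = 6
        base = np.eye(n) * 0.6 + 0.05
        truth = rng.uniform(0.1, 2.0, n)
        g = GTMatrix(base, list(range(1, n + 1)), PSFModel(8.0))
        obs = dict(zip(g.parcel_order, base @ truth))
        res = invert_gtm(g, obs, mode="constrained")
        np.testing.assert_allclose(res.corrected.to_numpy(), truth, rtol=1e-6)

    def test_unconstrained_reproduces_nonphysical_negative(self):
        res = invert_gtm(_gtm2(), {1: T2[0], 2: T2[1]}, mode="unconstrained")
        np.testing.assert_allclose(res.corrected.to_numpy(), UNCONSTRAINED, atol=1e-9)
        assert res.corrected.min() < 0

    def test_constrained_matches_hand_kkt_solution(self):
        res = invert_gtm(_gtm2(), {1: T2[0], 2: T2[1]}, mode="constrained")
        np.testing.assert_allclose(res.corrected.to_numpy(), CONSTRAINED, atol=1e-9)
        assert bool(res.at_bound.loc[2])
        res_u = invert_gtm(_gtm2(), {1: T2[0], 2: T2[1]}, mode="unconstrained")
        assert res.residual_norm >= res_u.residual_norm

    def test_constrained_equals_unconstrained_when_feasible(self, rng):
        g = GTMatrix(np.eye(2) * 0.7 + 0.1, [1, 2], PSFModel(8.0))
        truth = np.array([1.0, 0.5])
        obs = dict(zip([1, 2], g.weights @ truth))
        rc = invert_gtm(g, obs, mode="constrained")
        ru = invert_gtm(g, obs, mode="unconstrained")
        np.testing.assert_allclose(rc.corrected, ru.corrected, atol=1e-9)
        assert not rc.at_bound.any()

    def test_ill_conditioned_warning(self):
        g = GTMatrix(np.array([[1.0, 1.0], [1.0, 1.0 + 1e-12]]), [1, 2], PSFModel(8.0))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            invert_gtm(g, {1: 1.0, 2: 1.0}, mode="unconstrained")

    def test_missing_observation_reported(self):
        with pytest.raises(ValueError, match="2"):
            invert_gtm(_gtm2(), {1: 1.0}, mode="constrained")


class TestGTMModelRecovery:
    def test_noiseless_phantom_recovery(self, medium_phantom, medium_pet):
        labels, parcels = medium_phantom
        pet, truth = medium_pet
        model = GTMModel(labels, parcels, PSFModel(8.0))
        res = model.fit(pet, mode="constrained")
        for lab, val in truth.items():
            assert res.corrected.loc[lab] == pytest.approx(val, rel=1e-6)
        # uncorrected ribbon means are badly degraded on the same data
        obs = model.observed_means(pet)
        ribbon_err = [
            abs(obs.loc[l] - truth[int(l)]) / truth[int(l)]
            for l in parcels.labels_of_class("cortex")
        ]
        assert max(ribbon_err) > 0.10

    def test_summary_and_suvr(self, medium_phantom, medium_pet):
        labels, parcels = medium_phantom
        pet, truth = medium_pet
        res = GTMModel(labels, parcels, PSFModel(8.0)).fit(pet)
        s = res.summary()
        assert {"observed_mean", "corrected", "at_bound"} <= set(s.columns)
        suvr = res.suvr("brainstem")
        assert suvr.loc[parcels.reference_label] == pytest.approx(1.0)
        # switching reference rescales by a common factor
        suvr_cb = res.suvr("cerebellum")
        ratio = (suvr / suvr_cb).dropna()
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)


class TestNormalizeSUVR:
    def _parcels(self):
        return _table([
            (5, "brainstem", "brainstem", "bi", np.nan, True),
            (6, "cerebellum", "cerebellum", "bi", np.nan, False),
            (100, "ctx", "cortex", "lh", 200, False),
            (200, "wm", "wm", "lh", np.nan, False),
        ])

    def test_all_equal_values_give_unit_suvr(self):
        values = pd.Series({5: 2.0, 6: 2.0, 100: 2.0, 200: 2.0})
        out = normalize_suvr(values, self._parcels(), "brainstem")
        np.testing.assert_allclose(out, 1.0)

    def test_simple_ratio(self):
        values = pd.Series({5: 3.0, 6: 1.0, 100: 6.0, 200: 3.0})
        out = normalize_suvr(values, self._parcels(), "brainstem")
        assert out.loc[100] == pytest.approx(2.0)
        assert out.loc[5] == 1.0

    def test_nonpositive_reference_refused(self):
        values = pd.Series({5: 0.0, 6: 1.0, 100: 6.0, 200: 3.0})
        with pytest.raises(ValueError, match="positive"):
            normalize_suvr(values, self._parcels(), "brainstem")


class TestCorticalWMRatio:
    def test_three_pair_oracle(self):
        parcels = _table([
            (5, "bs", "brainstem", "bi", np.nan, True),
            (100, "c0", "cortex", "lh", 200, False),
            (101, "c1", "cortex", "lh", 201, False),
            (102, "c2", "cortex", "rh", 202, False),
            (200, "w0", "wm", "lh", np.nan, False),
            (201, "w1", "wm", "lh", np.nan, False),
            (202, "w2", "wm", "rh", np.nan, False),
        ])
        values = pd.Series({5: 1, 100: 2.0, 101: 1.5, 102: 1.0,
                            200: 1.0, 201: 1.5, 202: 2.0})
        ratios, mean = cortical_wm_ratio(values, parcels)
        assert ratios.loc[100] == pytest.approx(2.0)
        assert ratios.loc[101] == pytest.approx(1.0)
        assert mean == pytest.approx((2.0 + 1.0 + 0.5) / 3)

    def test_nonpositive_wm_flagged(self):
        parcels = _table([
            (5, "bs", "brainstem", "bi", np.nan, True),
            (100, "c0", "cortex", "lh", 200, False),
            (200, "w0", "wm", "lh", np.nan, False),
        ])
        ratios, mean = cortical_wm_ratio(pd.Series({5: 1, 100: 2.0, 200: 0.0}), parcels)
        assert np.isnan(ratios.loc[100]) and np.isnan(mean)
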