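"""nMSE / SSIM / VIF behaviour and aggregation."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from ddrecon.metrics import aggregate, nmse, ssim, vif
from ddrecon.synthetic_data import PhantomSpec, gen_phantom


@pytest.fixture
def phantom64():
    return gen_phantom(PhantomSpec(64, 64, seed=5))


class TestNMSE:
    def test_identity_zero(self, phantom64):
        assert nmse(phantom64, phantom64) == 0.0

    def test_zero_prediction_gives_100(self, phantom64):
        assert nmse(phantom64, np.zeros_like(phantom64)) == pytest.approx(100.0)

    def test_double_gives_100(self, phantom64):
        assert nmse(phantom64, 2 * phantom64) == pytest.approx(100.0)

    def test_all_zero_reference_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            nmse(np.zeros((8, 8)), np.ones((8, 8)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            nmse(np.zeros((8, 8)), np.zeros((8, 9)))


class TestSSIM:
    def test_identity_is_one(self, phantom64):
        assert ssim(phantom64, phantom64) == pytest.approx(1.0)

    def test_constant_offset_degrades(self, phantom64):
        assert ssim(phantom64, phantom64 + 0.5) < 1.0

    def test_matches_brute_force_window_oracle(self, rng):
        """Windowed SSIM recomputed by an explicit per-window loop."""
        ref = rng.random((20, 20))
        rec = ref + 0.1 * rng.standard_normal((20, 20))
        score = ssim(ref, rec)

        ax = np.arange(7) - 3
        g = np.exp(-(ax ** 2) / (2 * 1.5 ** 2))
        kern = np.outer(g, g)
        kern /= kern.sum()
        dr = ref.max()
        c1, c2 = (0.01 * dr) ** 2, (0.03 * dr) ** 2
        rp = np.pad(ref, 3, mode="reflect")
        cp = np.pad(rec, 3, mode="reflect")
        vals = []
        for i in range(3, 17):
            for j in range(3, 17):
                wr = rp[i - 3 + 3:i + 4 + 3, j - 3 + 3:j + 4 + 3]
                wc = cp[i - 3 + 3:i + 4 + 3, j - 3 + 3:j + 4 + 3]
                m1 = (kern * wr).sum()
                m2 = (kern * wc).sum()
                v1 = (kern * wr * wr).sum() - m1 * m1
                v2 = (kern * wc * wc).sum() - m2 * m2
                cv = (kern * wr * wc).sum() - m1 * m2
                vals.append(((2 * m1 * m2 + c1) * (2 * cv + c2))
                            / ((m1 * m1 + m2 * m2 + c1) * (v1 + v2 + c2)))
        assert score == pytest.approx(np.mean(vals), abs=1e-9)

    def test_close_to_library_gaussian_ssim(self, rng):
        """Sanity: agrees with an established implementation (which uses a
        wider truncated Gaussian window) to within a percent."""
        from skimage.metrics import structural_similarity
        ref = rng.random((48, 48))
        rec = ref + 0.05 * rng.standard_normal((48, 48))
        lib = structural_similarity(ref, rec, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False,
                                    data_range=float(ref.max()))
        assert abs(ssim(ref, rec) - lib) < 0.01

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.zeros((5, 5)), np.zeros((5, 5)))


class TestVIF:
    def test_identity_is_one(self, phantom64):
        assert vif(phantom64, phantom64) == pytest.approx(1.0, abs=1e-6)

    def test_noise_strictly_degrades(self, phantom64, rng):
        noisy = phantom64 + 0.5 * rng.standard_normal(phantom64.shape)
        assert vif(phantom64, noisy) < vif(phantom64, phantom64)

    def test_matches_formula_level_oracle(self, phantom64, rng):
        """Recompute the per-scale mutual-information ratio directly."""
        rec = phantom64 + 0.05 * rng.standard_normal(phantom64.shape)
        score = vif(phantom64, rec)

        def gk(n, s):
            ax = np.arange(n) - (n - 1) / 2
            g = np.exp(-ax ** 2 / (2 * s * s))
            k = np.outer(g, g)
            return k / k.sum()

        sc = 255.0 / (phantom64.max() - phantom64.min())
        off = phantom64.min()
        ref, dist = (phantom64 - off) * sc, (rec - off) * sc
        num = den = 0.0
        for scale in range(1, 5):
            n = 2 ** (4 - scale + 1) + 1
            k = gk(n, n / 5)
            if scale > 1:
                ref = correlate(ref, k, mode="nearest")[::2, ::2]
                dist = correlate(dist, k, mode="nearest")[::2, ::2]
            mu1, mu2 = correlate(ref, k, mode="nearest"), correlate(dist, k, mode="nearest")
            s1 = np.maximum(correlate(ref * ref, k, mode="nearest") - mu1 * mu1, 0)
            s2 = np.maximum(correlate(dist * dist, k, mode="nearest") - mu2 * mu2, 0)
            s12 = correlate(ref * dist, k, mode="nearest") - mu1 * mu2
            g = s12 / (s1 + 1e-10)
            sv = s2 - g * s12
            g[s1 < 1e-10] = 0
            sv[s1 < 1e-10] = s2[s1 < 1e-10]
            s1 = np.where(s1 < 1e-10, 0.0, s1)
            g[s2 < 1e-10] = 0
            sv[s2 < 1e-10] = 0
            sv[g < 0] = s2[g < 0]
            g[g < 0] = 0
            sv = np.maximum(sv, 1e-10)
            num += np.log10(1 + g * g * s1 / (sv + 2.0)).sum()
            den += np.log10(1 + s1 / 2.0).sum()
        assert score == pytest.approx(num / den, abs=1e-9)

    def test_constant_reference_raises(self):
        with pytest.raises(ValueError, match="constant"):
            vif(np.full((32, 32), 2.0), np.zeros((32, 32)))


class TestAggregate:
    def test_single_record(self):
        rep = aggregate([{"nmse_pct": 1.0, "ssim": 0.9, "vif": 0.8}])
        agg = rep.aggregate()
        assert agg["nmse_pct"] == {"mean": 1.0, "std": 0.0, "n": 1}

    def test_two_records_hand_computed(self):
        rep = aggregate([{"nmse_pct": 1.0, "ssim": 0.0, "vif": 0.0},
                         {"nmse_pct": 3.0, "ssim": 1.0, "vif": 1.0}])
        agg = rep.aggregate()
        assert agg["nmse_pct"]["mean"] == pytest.approx(2.0)
        assert agg["nmse_pct"]["std"] == pytest.approx(np.sqrt(2))

    def test_permutation_invariance(self, rng):
        recs = [{"nmse_pct": float(v), "ssim": float(v) / 10, "vif": float(v) / 5}
                for v in rng.random(6)]
        a = aggregate(recs).aggregate()
        b = aggregate(recs[::-1]).aggregate()
        for key in a:
            assert a[key]["mean"] == pytest.approx(b[key]["mean"])
            assert a[key]["std"] == pytest.approx(b[key]["std"])

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate([])

    def test_report_metadata_records_vif_variant(self):
        rep = aggregate([{"nmse_pct": 1.0, "ssim": 1.0, "vif": 1.0}])
        assert rep.as_dict()["meta"]["vif_variant"] == "pixel-domain"


def test_all_metrics_degrade_monotonically_with_noise(phantom64):
    """Optimal at rec == ref and monotone under increasing corruption."""
    rng = np.random.default_rng(0)
    noise = rng.standard_normal(phantom64.shape)
    levels = [0.0, 0.05, 0.1, 0.2, 0.4]
    n_scores = [nmse(phantom64, phantom64 + s * noise) for s in levels]
    s_scores = [ssim(phantom64, phantom64 + s * noise) for s in levels]
    v_scores = [vif(phantom64, phantom64 + s * noise) for s in levels]
    assert n_scores[0] == 0.0
    assert s_scores[0] == pytest.approx(1.0)
    assert v_scores[0] == pytest.approx(1.0, abs=1e-6)
    assert all(a < b for a, b in zip(n_scores, n_scores[1:]))
    assert all(a > b for a, b in zip(s_scores, s_scores[1:]))
    assert all(a > b for a, b in zip(v_scores, v_scores[1:]))
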