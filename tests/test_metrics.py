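"""Metric implementations against naive double-loop oracles and closed forms."""

import warnings

import numpy as np
import pytest

from nsstfuse import metrics as mx


# ---------------------------------------------------------------------------
# naive oracles (independent double-loop implementations)
# ---------------------------------------------------------------------------

def naive_mi(r, f, levels=256):
    rq = np.clip(np.floor(np.asarray(r, float) * levels / 256.0),
                 0, levels - 1).astype(int)
    fq = np.clip(np.floor(np.asarray(f, float) * levels / 256.0),
                 0, levels - 1).astype(int)
    n = rq.size
    joint = {}
    for u, v in zip(rq.ravel(), fq.ravel()):
        joint[(u, v)] = joint.get((u, v), 0) + 1
    pr, pf = {}, {}
    for (u, v), c in joint.items():
        pr[u] = pr.get(u, 0) + c
        pf[v] = pf.get(v, 0) + c
    mi = 0.0
    for (u, v), c in joint.items():
        p = c / n
        mi += p * np.log2(p / ((pr[u] / n) * (pf[v] / n)))
    return mi


def naive_ssim(x, y, data_range=255.0):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ax = np.arange(11.0) - 5.0
    g = np.exp(-(ax ** 2) / (2 * 1.5 ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    vals = []
    for u in range(x.shape[0] - 10):
        for v in range(x.shape[1] - 10):
            px = x[u:u + 11, v:v + 11]
            py = y[u:u + 11, v:v + 11]
            mx_ = np.sum(w * px)
            my_ = np.sum(w * py)
            sxx = np.sum(w * px * px) - mx_ ** 2
            syy = np.sum(w * py * py) - my_ ** 2
            sxy = np.sum(w * px * py) - mx_ * my_
            vals.append(((2 * mx_ * my_ + c1) * (2 * sxy + c2))
                        / ((mx_ ** 2 + my_ ** 2 + c1) * (sxx + syy + c2)))
    return float(np.mean(vals))


def naive_sd(f):
    f = np.asarray(f, float)
    mu = f.sum() / f.size
    acc = 0.0
    for u in range(f.shape[0]):
        for v in range(f.shape[1]):
            acc += (f[u, v] - mu) ** 2
    return np.sqrt(acc / f.size)


def naive_ei(f):
    f = np.asarray(f, float)
    vals = []
    for u in range(1, f.shape[0]):
        for v in range(1, f.shape[1]):
            dx = f[u, v] - f[u - 1, v]
            dy = f[u, v] - f[u, v - 1]
            vals.append(np.sqrt(dx ** 2 + dy ** 2))
    return float(np.mean(vals))


def naive_ag(f):
    f = np.asarray(f, float)
    acc = 0.0
    for u in range(f.shape[0] - 1):
        for v in range(f.shape[1] - 1):
            fx = f[u + 1, v] - f[u, v]
            fy = f[u, v + 1] - f[u, v]
            acc += np.sqrt((fx ** 2 + fy ** 2) / 2.0)
    return acc / f.size


def naive_ncc(x, y, b):
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    rx = np.empty(n, int)
    rx[np.argsort(x, kind="stable")] = np.arange(n)
    ry = np.empty(n, int)
    ry[np.argsort(y, kind="stable")] = np.arange(n)
    cells = {}
    for i in range(n):
        key = (rx[i] * b // n, ry[i] * b // n)
        cells[key] = cells.get(key, 0) + 1
    acc = 2.0
    for c in cells.values():
        p = c / n
        acc += p * np.log(p) / np.log(b)
    return acc


# ---------------------------------------------------------------------------
# oracle agreement on random 16x16 inputs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def imgs():
    rng = np.random.default_rng(42)
    return [rng.uniform(0, 255, (16, 16)) for _ in range(3)]


class TestOracleAgreement:
    def test_mutual_information(self, imgs):
        a, _, f = imgs
        assert mx.mutual_information(a, f, 16) == pytest.approx(
            naive_mi(a, f, 16), abs=1e-10)

    def test_ssim(self, imgs):
        a, _, f = imgs
        assert mx.ssim(a, f) == pytest.approx(naive_ssim(a, f), abs=1e-10)

    def test_sd(self, imgs):
        assert mx.sd(imgs[2]) == pytest.approx(naive_sd(imgs[2]), abs=1e-10)

    def test_ei(self, imgs):
        assert mx.ei(imgs[2]) == pytest.approx(naive_ei(imgs[2]), abs=1e-10)

    def test_ag(self, imgs):
        assert mx.ag(imgs[2]) == pytest.approx(naive_ag(imgs[2]), abs=1e-10)

    def test_ncc(self, imgs):
        a, b, _ = imgs
        assert mx.ncc(a, b, 4) == pytest.approx(naive_ncc(a, b, 4),
                                                abs=1e-10)

    def test_ssim_against_skimage(self, imgs):
        """Independent cross-check: the reference SSIM of scikit-image."""
        skimage_metrics = pytest.importorskip("skimage.metrics")
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 255, (64, 64))
        y = np.clip(x + rng.normal(0, 20, x.shape), 0, 255)
        ref = skimage_metrics.structural_similarity(
            x, y, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=255.0)
        assert mx.ssim(x, y) == pytest.approx(ref, abs=1e-7)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_mi_of_fair_binary_self_pair_is_one_bit(self):
        r = np.zeros((8, 8))
        r[:, 4:] = 128.0  # two equiprobable gray values
        assert mx.mutual_information(r, r) == pytest.approx(1.0)

    def test_mi_of_constant_reference_is_zero(self, rng):
        f = rng.uniform(0, 255, (8, 8))
        assert mx.mutual_information(np.full((8, 8), 9.0), f) == \
            pytest.approx(0.0)

    def test_mi_fusion_symmetric_in_sources(self, rng):
        a, b, f = (rng.uniform(0, 255, (16, 16)) for _ in range(3))
        assert mx.mi_fusion(a, b, f) == pytest.approx(mx.mi_fusion(b, a, f))

    def test_mi_bounded_by_marginal_entropies(self, rng):
        a = np.floor(rng.uniform(0, 8, (32, 32))) * 32
        f = np.floor(rng.uniform(0, 4, (32, 32))) * 64
        h_a = mx.mutual_information(a, a)
        h_f = mx.mutual_information(f, f)
        assert mx.mutual_information(a, f) <= min(h_a, h_f) + 1e-12

    def test_mssim_of_identical_triple_is_one(self, rng):
        x = rng.uniform(0, 255, (16, 16))
        assert mx.mssim(x, x, x) == pytest.approx(1.0)

    def test_mssim_symmetric_and_below_one_for_noise(self, rng):
        a = rng.uniform(0, 255, (32, 32))
        b = rng.uniform(0, 255, (32, 32))
        assert mx.mssim(a, b, a) == pytest.approx(mx.mssim(b, a, a))
        assert mx.mssim(a, b, a) == pytest.approx(
            0.5 * (1.0 + mx.ssim(b, a)))
        assert mx.mssim(a, b, a) < 1.0

    def test_sd_closed_forms(self):
        assert mx.sd(np.full((8, 8), 3.0)) == 0.0
        f = np.zeros((4, 4))
        f[:2] = 2.0
        assert mx.sd(f) == pytest.approx(1.0)
        assert mx.sd(f + 17.0) == pytest.approx(1.0)

    def test_ei_unit_ramp_and_rotation(self, rng):
        u = np.mgrid[0:16, 0:16][0].astype(float)
        assert mx.ei(u) == pytest.approx(1.0)
        # rotation swaps the roles of the two differences; equality holds
        # up to the excluded boundary row/column
        x = rng.uniform(0, 255, (16, 16))
        assert mx.ei(np.rot90(x)) == pytest.approx(mx.ei(x), rel=2e-2)

    def test_ag_ramp_and_contrast_scaling(self, rng):
        u = np.mgrid[0:16, 0:16][0].astype(float)
        # 15x15 valid forward-difference pixels, each sqrt(1/2), over 256
        assert mx.ag(u) == pytest.approx(np.sqrt(0.5) * 15 * 15 / 256)
        x = rng.uniform(0, 255, (16, 16))
        assert mx.ag(3.0 * x) == pytest.approx(3.0 * mx.ag(x))

    def test_ncc_identical_samples_is_one(self, rng):
        x = rng.normal(size=4096)
        assert mx.ncc(x, x, b=64) == pytest.approx(1.0)

    def test_ncc_independent_samples_near_zero(self, rng):
        x = rng.normal(size=65536)
        y = rng.normal(size=65536)
        assert abs(mx.ncc(x, y, b=4)) < 0.01

    def test_qncie_identical_triple_is_one(self, rng):
        x = rng.uniform(0, 255, (64, 64))
        assert mx.qncie(x, x, x, b=64) == pytest.approx(1.0)

    def test_qncie_independent_noise_near_one_minus_logb3(self, rng):
        imgs = [rng.uniform(0, 255, (256, 256)) for _ in range(3)]
        expected = 1.0 - np.log(3.0) / np.log(256.0)
        assert mx.qncie(*imgs, b=256) == pytest.approx(expected, abs=0.01)

    def test_small_sample_grid_warns(self, rng):
        with pytest.warns(UserWarning, match="rank grid"):
            mx.ncc(rng.normal(size=64), rng.normal(size=64), b=16)


def test_evaluate_all_report_fields(rng):
    a, b = (rng.uniform(0, 255, (32, 32)) for _ in range(2))
    f = 0.5 * (a + b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # coarse rank grid at this size
        report = mx.evaluate_all(a, b, f)
    assert report.mssim <= 1.0
    assert min(report.sd, report.ei, report.ag, report.mi) >= 0.0
    assert 0.0 <= report.qncie <= 1.0
    frame = report.to_frame()
    assert list(frame.columns) == ["EI", "AG", "SD", "MI", "MSSIM", "QNCIE"]
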