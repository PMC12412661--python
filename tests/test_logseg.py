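"""LoG kernels, variational weights, gate, losses, and network contracts."""

import numpy as np
import pytest
from scipy.integrate import quad

import vesselforge.autodiff as ad
from vesselforge.logseg import (GateState, LoGBNet, PoolExhaustedError,
                                SegModelConfig, VariationalGaussian,
                                assemble_balanced_batch, build_log_kernel,
                                classify_patch, combined_objective,
                                dice_coefficient, elbo, kl_gaussian,
                                log_kernel_raw, sample_weights,
                                voxel_percentage)
from vesselforge.logseg.kernels import LoGKernelBank
from vesselforge.logseg.losses import bernoulli_loglik
from vesselforge.logseg.train import tiny_model_config


@pytest.fixture
def rng():
    return np.random.default_rng(3)


# ------------------------------------------------------------------ kernels
@pytest.mark.parametrize("sigma", [0.5, 1.0, 1.5, 2.0, 2.5])
def test_log_kernel_center_value(sigma):
    k = log_kernel_raw(7, sigma)
    assert k[3, 3, 3] == pytest.approx(-2.0 / sigma ** 2, abs=1e-12)


def test_log_kernel_radial_symmetry_and_zero_crossing():
    for sigma in (0.7, 1.3):
        k = log_kernel_raw(9, sigma)
        c = 4
        assert k[c + 1, c, c] == pytest.approx(k[c, c, c + 1], abs=1e-12)
        assert k[c + 1, c, c] == pytest.approx(k[c - 1, c, c], abs=1e-12)
        # sign change across r = sqrt(2) sigma
        r_in = np.sqrt(2) * sigma * 0.9
        r_out = np.sqrt(2) * sigma * 1.1
        val = lambda r: (r**2 - 2 * sigma**2) / sigma**4 * np.exp(
            -r**2 / (2 * sigma**2))
        assert val(r_in) < 0 < val(r_out)


def test_stored_kernels_zero_mean_and_unit_l1():
    bank = LoGKernelBank()
    for k in bank.kernels:
        assert abs(k.mean()) <= 1e-8
        assert np.abs(k).sum() == pytest.approx(1.0)


def test_kernel_scale_selectivity_tracks_tube_radius():
    """The winning bank level is non-decreasing in tube radius."""
    from vesselforge.phantom import straight_tube_spec, make_phantom
    from vesselforge.preprocess import clip_normalize
    bank = LoGKernelBank()
    winners = []
    for radius in (1.0, 2.0, 3.0, 4.0):
        spec = straight_tube_spec(grid_shape=(32, 32, 32), radius=radius,
                                  noise_sd=0.0, blur_sigma=0.0)
        vol, lab, _ = make_phantom(spec)
        vol = clip_normalize(vol)
        winners.append(bank.argmax_level(vol.values, lab.values > 0))
    assert winners == sorted(winners)
    assert winners[-1] > winners[0]


def test_even_kernel_size_rejected():
    with pytest.raises(ValueError):
        build_log_kernel(4, 1.0)


# ---------------------------------------------------------------- variational
def test_sample_weights_moments_and_determinism(rng):
    vg = VariationalGaussian(np.full(8, 1.5), sd=0.3, dtype=np.float64)
    draws = np.stack([sample_weights(vg, np.random.default_rng(i)).data
                      for i in range(10_000)])
    se_mean = 0.3 / np.sqrt(10_000)
    assert np.all(np.abs(draws.mean(axis=0) - 1.5) < 5 * se_mean)
    assert np.all(np.abs(draws.std(axis=0) - 0.3) < 5 * se_mean)
    a = sample_weights(vg, 123).data
    b = sample_weights(vg, 123).data
    np.testing.assert_array_equal(a, b)


def test_sample_weights_degenerate_sd():
    vg = VariationalGaussian(np.array([2.0, -1.0]), sd=1e-30)
    out = sample_weights(vg, 0).data
    np.testing.assert_allclose(out, [2.0, -1.0], atol=1e-25)


def test_kl_gaussian_closed_forms():
    assert kl_gaussian(0.7, 1.3, 0.7, 1.3) == pytest.approx(0.0, abs=1e-12)
    mu = 1.7
    assert kl_gaussian(mu, 1.0, 0.0, 1.0) == pytest.approx(mu ** 2 / 2)
    sig = 0.6
    assert kl_gaussian(0.0, sig, 0.0, 1.0) == pytest.approx(
        (sig ** 2 - 1 - np.log(sig ** 2)) / 2)


def test_kl_gaussian_matches_quadrature():
    qm, qs, pm, ps = 0.4, 0.8, -0.2, 1.3

    def integrand(x):
        q = np.exp(-(x - qm) ** 2 / (2 * qs ** 2)) / (qs * np.sqrt(2 * np.pi))
        p = np.exp(-(x - pm) ** 2 / (2 * ps ** 2)) / (ps * np.sqrt(2 * np.pi))
        return q * np.log(q / p)

    val, _ = quad(integrand, -10, 10)
    assert kl_gaussian(qm, qs, pm, ps) == pytest.approx(val, abs=1e-9)


def test_kl_nonnegative_property(rng):
    for _ in range(50):
        qm, pm = rng.normal(size=2)
        qs, ps = rng.uniform(0.2, 3.0, size=2)
        assert kl_gaussian(qm, qs, pm, ps) >= -1e-12


# ----------------------------------------------------------------------- dice
def test_dice_examples(rng):
    a = (rng.random((6, 6, 6)) > 0.5).astype(float)
    assert dice_coefficient(a, a) == pytest.approx(1.0)
    b = np.zeros((4, 4, 4)); b[0, 0, 0] = 1
    c = np.zeros((4, 4, 4)); c[3, 3, 3] = 1
    assert dice_coefficient(b, c) == 0.0
    g = np.zeros(16); g[:4] = 1
    o = np.zeros(16); o[2:6] = 1
    assert dice_coefficient(o.reshape(4, 2, 2), g.reshape(4, 2, 2)) == \
        pytest.approx(2 * 2 / (4 + 4))
    assert dice_coefficient(np.zeros((3, 3, 3)), np.zeros((3, 3, 3))) == 1.0


def test_dice_symmetric_and_permutation_invariant(rng):
    a = (rng.random(64) > 0.6).astype(float)
    b = (rng.random(64) > 0.4).astype(float)
    assert dice_coefficient(a, b) == pytest.approx(dice_coefficient(b, a))
    perm = rng.permutation(64)
    assert dice_coefficient(a[perm], b[perm]) == pytest.approx(
        dice_coefficient(a, b))


# ----------------------------------------------------------------------- gate
def test_voxel_percentage_counting(rng):
    assert voxel_percentage(np.full((4, 4, 4), 0.9)) == 1.0
    assert voxel_percentage(np.full((4, 4, 4), 0.1)) == 0.0
    vals = rng.random(200)
    k = int(np.sum(vals > 0.5))
    assert voxel_percentage(vals) == pytest.approx(k / 200)


def test_classify_patch_threshold_rule():
    assert classify_patch(0.20, beta=0.15) == "main"
    assert classify_patch(0.05, beta=0.15) == "branch"
    assert classify_patch(0.15, beta=0.15) == "main"  # tie -> main


def test_balanced_batches_from_skewed_stream(rng):
    """5% branch prevalence in, exactly 50/50 batches out."""
    def stream():
        i = 0
        while True:
            vp = 0.05 if rng.random() < 0.05 else 0.5
            yield (i, vp)
            i += 1

    gate = GateState(capacity=10, draw=5, seed=1)
    counts = {"main": 0, "branch": 0}
    s = stream()
    for _ in range(50):
        batch = assemble_balanced_batch(gate, s, classifier=lambda it: it[1])
        assert len(batch) == 10
        for item in batch:
            counts["main" if item[1] >= 0.15 else "branch"] += 1
        assert len(gate.main_pool) == 5 and len(gate.branch_pool) == 5
    assert counts["main"] == counts["branch"]


def test_gate_exhaustion_diagnostic():
    gate = GateState(capacity=4, draw=2)
    with pytest.raises(PoolExhaustedError, match="pools"):
        assemble_balanced_batch(gate, iter([(0, 0.5)] * 3),
                                classifier=lambda it: it[1])


# --------------------------------------------------------------------- elbo
def test_bernoulli_loglik_hand_computed():
    logits = ad.Tensor(np.array([[2.0, -1.0]]))
    labels = np.array([[1.0, 0.0]])
    expected = np.mean([np.log(1 / (1 + np.exp(-2.0))),
                        np.log(1 - 1 / (1 + np.exp(1.0)))])
    assert float(bernoulli_loglik(logits, labels).data) == pytest.approx(
        expected, abs=1e-9)


def test_elbo_monotone_in_kl_scale(rng):
    model = LoGBNet(SegModelConfig(levels=((3, 0.5),), base_channels=4,
                                   depth=1, aspp_channels=4, patch_size=8))
    x = rng.random((1, 8, 8, 8))
    g = (x > 0.5).astype(float)
    lo = float(elbo(x, g, model, rng=5, kl_scale=0.1).data)
    hi = float(elbo(x, g, model, rng=5, kl_scale=1.0).data)
    kl = float(model.kl_total().data)
    assert kl > 0
    assert hi < lo


def test_combined_objective_equals_component_sum(rng):
    model = LoGBNet(SegModelConfig(levels=((3, 0.5),), base_channels=4,
                                   depth=1, aspp_channels=4, patch_size=8))
    x = rng.random((2, 8, 8, 8))
    g = (x > 0.5).astype(float)
    loss, comps = combined_objective(x, g, model, rng=9, kl_scale=0.3)
    assert comps["objective"] == pytest.approx(
        (1 - comps["dice"]) - comps["loglik"] + 0.3 * comps["kl"], rel=1e-6)


# ------------------------------------------------------------------ network
def test_forward_shape_determinism_and_zero_head(rng):
    model = LoGBNet(tiny_model_config())
    x = rng.random((1, 1, 32, 32, 32))
    p1 = model.predict_proba(x)
    p2 = model.predict_proba(x)
    assert p1.shape == (1, 1, 32, 32, 32)
    np.testing.assert_array_equal(p1, p2)
    assert np.all((p1 >= 0) & (p1 <= 1))
    # zeroed final 1x1x1 head -> logits 0 -> probability exactly 0.5
    w, b = model.head
    w.data[:] = 0
    b.data[:] = 0
    np.testing.assert_allclose(model.predict_proba(x), 0.5)


def test_forward_smaller_patch_and_indivisible_error(rng):
    model = LoGBNet(tiny_model_config())
    p = model.predict_proba(rng.random((1, 1, 16, 16, 16)))
    assert p.shape == (1, 1, 16, 16, 16)
    with pytest.raises(ValueError, match="divisible"):
        model.predict_proba(rng.random((1, 1, 15, 15, 15)))


def test_constant_patch_gives_half_log_features(rng):
    model = LoGBNet(SegModelConfig(levels=((5, 1.0),), base_channels=4,
                                   depth=1, aspp_channels=4, patch_size=16,
                                   feature_gain=1.0, feature_bias=0.0))
    x = np.full((1, 1, 16, 16, 16), 0.7)
    with ad.no_grad():
        feats = model.log_stream_forward(x)
    interior = feats.data[0, 0, 4:-4, 4:-4, 4:-4]
    np.testing.assert_allclose(interior, 0.5, atol=1e-7)


def test_checkpoint_round_trip(tmp_path, rng):
    model = LoGBNet(tiny_model_config())
    x = rng.random((1, 1, 16, 16, 16))
    p_before = model.predict_proba(x)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    back = LoGBNet.load(path)
    np.testing.assert_array_equal(back.predict_proba(x), p_before)
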