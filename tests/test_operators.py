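"""Transform operators: linearity, round-trips, masks, differentiability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duodomain import autodiff as ad
from duodomain import operators as op


# -- radon forward ---------------------------------------------------------


def test_radon_zero_image_gives_zero_sinogram(radon64):
    s = op.radon_forward(np.zeros((64, 64)), radon64)
    assert np.all(s.values == 0)


def test_radon_disk_projection_peaks_at_chord_length():
    """Every angle's projection of a centred disk peaks near the diameter."""
    r = 10
    spec = op.TransformSpec("radon", (64, 64), n_angles=30)
    yy, xx = np.mgrid[0:64, 0:64]
    disk = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= r * r).astype(float)
    s = op.radon_forward(disk, spec)
    peaks = s.values.max(axis=1)
    assert np.all(np.abs(peaks - 2 * r) <= 1.5)  # within ~1 px of discretisation


def test_radon_conserves_mass_per_angle(phantom64, radon64):
    s = op.radon_forward(phantom64.image, radon64)
    sums = s.values.sum(axis=1)
    assert np.allclose(sums, phantom64.image.sum(), rtol=1e-10)


def test_radon_is_linear(rng, radon32):
    x = rng.random((32, 32))
    y = rng.random((32, 32))
    a, b = 2.3, -0.7
    lhs = op.radon_forward(a * x + b * y, radon32).values
    rhs = a * op.radon_forward(x, radon32).values + b * op.radon_forward(y, radon32).values
    assert np.allclose(lhs, rhs)


def test_radon_rejects_shape_mismatch(radon64):
    with pytest.raises(ValueError, match="geometry"):
        op.radon_forward(np.zeros((32, 32)), radon64)


# -- radon inverse ---------------------------------------------------------


@pytest.fixture(scope="module")
def shepp64():
    from skimage.data import shepp_logan_phantom
    from skimage.transform import resize

    return resize(shepp_logan_phantom(), (64, 64), anti_aliasing=True)


def test_fbp_roundtrip_beats_dense_angle_oracle(shepp64):
    """180-angle round-trip RMSE stays below an independent dense-angle
    (720 projections) reconstruction's RMSE on the same phantom."""
    from skimage.transform import iradon, radon

    theta = np.linspace(0.0, 180.0, 720, endpoint=False)
    oracle = iradon(radon(shepp64, theta=theta), theta=theta, filter_name="ramp", output_size=64)
    bound = np.sqrt(np.mean((oracle - shepp64) ** 2))

    spec = op.TransformSpec("radon", (64, 64), n_angles=180)
    rec = op.radon_inverse(op.radon_forward(shepp64, spec), spec)
    rmse = np.sqrt(np.mean((rec - shepp64) ** 2))
    assert rmse < bound


def test_fbp_roundtrip_error_shrinks_with_angles(shepp64):
    rmses = []
    for na in (45, 90, 180):
        spec = op.TransformSpec("radon", (64, 64), n_angles=na)
        rec = op.radon_inverse(op.radon_forward(shepp64, spec), spec)
        rmses.append(np.sqrt(np.mean((rec - shepp64) ** 2)))
    assert rmses[0] > rmses[1] > rmses[2]


def test_fbp_is_linear(radon32, rng):
    sino = op.Sinogram(rng.random((48, radon32.n_detectors)), radon32)
    one = op.radon_inverse(sino, radon32)
    double = op.radon_inverse(op.Sinogram(2 * sino.values, radon32), radon32)
    assert np.allclose(double, 2 * one)
    zero = op.radon_inverse(op.Sinogram(np.zeros_like(sino.values), radon32), radon32)
    assert np.all(zero == 0)


def test_unknown_fbp_filter_rejected():
    with pytest.raises(ValueError, match="filter"):
        op.TransformSpec("radon", (32, 32), n_angles=10, filter_name="shepp-nonsense")


def test_angles_must_increase_within_half_turn():
    with pytest.raises(ValueError):
        op.TransformSpec("radon", (32, 32), angles=np.array([10.0, 5.0]))
    with pytest.raises(ValueError):
        op.TransformSpec("radon", (32, 32), angles=np.array([0.0, 180.0]))


# -- fourier ---------------------------------------------------------------


def test_fourier_constant_image_has_single_dc_coefficient(fourier64):
    c = 0.7
    k = op.fourier_forward(np.full((64, 64), c), fourier64)
    mags = np.abs(k.values)
    assert np.isclose(mags[32, 32], c * 64 * 64)
    mags[32, 32] = 0
    assert np.all(mags < 1e-8)


def test_fourier_roundtrip_is_unitary(fourier64, rng):
    x = rng.random((64, 64))
    back = op.fourier_inverse(op.fourier_forward(x, fourier64), fourier64)
    assert np.max(np.abs(back - x)) < 1e-10
    zero = op.fourier_inverse(op.KSpace(np.zeros((64, 64), complex)), fourier64)
    assert np.all(zero == 0)


def test_masked_fourier_zeroes_unsampled_columns(rng):
    mask = op.make_cartesian_gaussian_mask(64, 4, 6, seed=0)
    spec = op.TransformSpec("fourier", (64, 64), mask=mask)
    k = op.fourier_forward(rng.random((64, 64)) + 0.5, spec)
    assert k.mask_applied
    nonzero_cols = np.abs(k.values).sum(axis=0) > 0
    assert nonzero_cols.sum() == round(64 / 4)
    assert np.array_equal(nonzero_cols, mask.columns_sampled)


def test_masked_roundtrip_degrades_with_acceleration():
    from duodomain import synthlab as sl
    from duodomain.metrics import ssim

    ph = sl.make_phantom((64, 64), 5, seed=3)
    scores = {}
    for R in (4, 8):
        pair = sl.simulate_undersampled_mri(ph, R, 6, seed=0)
        scores[R] = ssim(pair.x_s, pair.x_t, data_range=1.0)
    assert scores[4] < 1.0
    assert scores[8] < scores[4]


# -- sampling masks --------------------------------------------------------


def test_mask_reference_case_320_lines():
    m = op.make_cartesian_gaussian_mask(320, 4, 6, seed=5)
    assert m.columns_sampled.sum() == 80
    start = (320 - 6) // 2
    assert m.columns_sampled[start : start + 6].all()


def test_mask_no_acceleration_keeps_all_lines():
    m = op.make_cartesian_gaussian_mask(64, 1, 6, seed=0)
    assert m.columns_sampled.all()


def test_mask_deterministic_given_seed():
    a = op.make_cartesian_gaussian_mask(128, 6, 6, seed=42)
    b = op.make_cartesian_gaussian_mask(128, 6, 6, seed=42)
    assert np.array_equal(a.columns_sampled, b.columns_sampled)


def test_mask_infeasible_budget_rejected():
    with pytest.raises(ValueError, match="budget"):
        op.make_cartesian_gaussian_mask(64, 32, 6, seed=0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n_lines=st.integers(32, 320),
    accel=st.sampled_from([1, 2, 4, 8]),
    n_center=st.integers(1, 8),
    seed=st.integers(0, 1000),
)
def test_mask_cardinality_and_center_property(n_lines, accel, n_center, seed):
    budget = round(n_lines / accel)
    if budget < n_center:
        with pytest.raises(ValueError):
            op.make_cartesian_gaussian_mask(n_lines, accel, n_center, seed)
        return
    m = op.make_cartesian_gaussian_mask(n_lines, accel, n_center, seed)
    assert m.columns_sampled.sum() == budget
    start = (n_lines - n_center) // 2
    assert m.columns_sampled[start : start + n_center].all()


# -- differentiability -----------------------------------------------------


def test_gradients_flow_through_forward_and_inverse(radon32, phantom32):
    """A loss composed through F then F^-1 reaches an upstream trainable map."""
    w = ad.param(np.ones((1, 1, 1, 1)))
    b = ad.param(np.zeros(1))
    x = ad.conv2d(ad.const(phantom32.image[None]), w, b)
    recon = op.fbp_op(op.radon_op(x, radon32), radon32)
    ad.l1_mean(ad.sub(recon, ad.const(0.5 * phantom32.image[None]))).backward()
    assert w.grad is not None and np.abs(w.grad).max() > 0


def test_fourier_ops_adjoint_pair(rng):
    x = rng.normal(size=(2, 16, 16))
    y = rng.normal(size=(2, 16, 16))
    t = ad.param(x)
    out = op.fft2c_op(t)
    out._backward(y)
    assert np.isclose(np.sum(out.data * y), np.sum(x * t.grad), rtol=1e-10)


# -- persistence -----------------------------------------------------------


def test_acquisition_npz_roundtrip(tmp_path, phantom64, radon64, fourier64):
    s = op.radon_forward(phantom64.image, radon64)
    op.save_acquisition(tmp_path / "sino.npz", s)
    loaded = op.load_acquisition(tmp_path / "sino.npz")
    assert np.array_equal(loaded["values"], s.values)
    assert np.array_equal(loaded["angles"], radon64.angles)

    k = op.fourier_forward(phantom64.image, fourier64)
    op.save_acquisition(tmp_path / "k.npz", k)
    loaded = op.load_acquisition(tmp_path / "k.npz")
    assert np.array_equal(loaded["values"], k.values)


def test_mask_text_export(tmp_path):
    m = op.make_cartesian_gaussian_mask(64, 4, 6, seed=1)
    m.save_txt(tmp_path / "mask.txt")
    loaded = np.loadtxt(tmp_path / "mask.txt").astype(bool)
    assert np.array_equal(loaded, m.columns_sampled)
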