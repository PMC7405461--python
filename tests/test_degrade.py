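"""k-space degradation: retention masks, crop/pad, normalization, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import heartsr as h
from heartsr.degrade import build_kspace_mask


class TestKSpaceMask:
    def test_identity_keeps_all(self):
        assert build_kspace_mask(8, 1.0, 1.0).sum() == 8

    def test_half_resolution_central_band(self):
        m = build_kspace_mask(8, 0.5, 1.0)
        assert m.sum() == 4
        assert m[4]  # DC at N//2
        np.testing.assert_array_equal(np.flatnonzero(m), [2, 3, 4, 5])

    def test_partial_fourier_band(self):
        # 64 lines, half resolution, 6/8 partial Fourier -> 24 retained
        m = build_kspace_mask(64, 0.5, 0.75)
        assert m.sum() == 24
        idx = np.flatnonzero(m)
        assert m[32]  # DC retained
        # asymmetric about DC: more retained on the negative-frequency side
        assert (idx < 32).sum() > (idx > 32).sum()

    @pytest.mark.parametrize("n", [32, 64, 96, 128, 160])
    @pytest.mark.parametrize("f", [0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("pf", [0.75, 0.875, 1.0])
    def test_retained_count_grid(self, n, f, pf):
        """Retained lines = round(pf * f * N) over a 60-combination grid,
        with the DC line always kept."""
        m = build_kspace_mask(n, f, pf)
        assert m.sum() == round(pf * f * n)
        assert m[n // 2]

    def test_too_few_lines_raises(self):
        with pytest.raises(ValueError, match="resolution too low"):
            build_kspace_mask(16, 0.25, 0.75)

    @given(
        n=st.sampled_from([16, 32, 48, 64, 128]),
        f=st.floats(0.3, 1.0),
        pf=st.floats(0.55, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_mask_properties(self, n, f, pf):
        try:
            m = build_kspace_mask(n, f, pf)
        except ValueError:
            return  # too few lines is a legitimate rejection
        assert m[n // 2]
        assert 4 <= m.sum() <= n
        # retained indices form one contiguous band
        idx = np.flatnonzero(m)
        assert (np.diff(idx) == 1).all()


class TestCropPad:
    def test_identity(self):
        v = h.Volume(np.random.default_rng(0).random((6, 8, 10)))
        out = h.crop_pad_center(v, (6, 8, 10))
        np.testing.assert_array_equal(out.data, v.data)

    def test_centered_crop_convention(self):
        v = h.Volume(np.arange(10, dtype=float)[:, None, None] * np.ones((10, 1, 1)))
        out = h.crop_pad_center(v, (4, 1, 1))
        np.testing.assert_array_equal(out.data[:, 0, 0], [3, 4, 5, 6])

    def test_symmetric_pad_convention(self):
        v = h.Volume(np.ones((4, 1, 1)))
        out = h.crop_pad_center(v, (10, 1, 1))
        np.testing.assert_array_equal(out.data[:, 0, 0], [0, 0, 0, 1, 1, 1, 1, 0, 0, 0])

    @given(n=st.integers(2, 12), t=st.integers(1, 14))
    @settings(max_examples=40, deadline=None)
    def test_crop_then_pad_preserves_interior(self, n, t):
        rng = np.random.default_rng(0)
        v = h.Volume(rng.random((n, 4, 4)))
        out = h.crop_pad_center(v, (t, 4, 4))
        assert out.shape == (t, 4, 4)


class TestNormalize:
    def test_two_values_map_to_unit_interval(self):
        v = h.Volume(np.array([[[2.0, 4.0]]]))
        out = h.normalize01(v)
        np.testing.assert_array_equal(out.data, [[[0.0, 1.0]]])
        assert out.normalized

    def test_already_normalized_unchanged(self):
        data = np.random.default_rng(1).random((4, 4, 4))
        data.flat[0], data.flat[1] = 0.0, 1.0
        out = h.normalize01(h.Volume(data))
        np.testing.assert_allclose(out.data, data, atol=1e-15)

    def test_constant_volume_warns_and_zeroes(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="heartsr.degrade"):
            out = h.normalize01(h.Volume(np.full((3, 3, 3), 5.0)))
        np.testing.assert_array_equal(out.data, 0.0)
        assert any("constant volume" in r.message for r in caplog.records)


class TestApplyDegradation:
    def test_identity_spec_round_trip(self, default_phantom):
        vol, _, _ = default_phantom
        out = h.apply_degradation(vol, h.DegradationSpec.identity())
        np.testing.assert_allclose(out.data, h.normalize01(vol).data, atol=1e-6)

    def test_clinical_geometry(self):
        """256x256x96 input -> 192x192x96 output in [0, 1] under the
        clinical-protocol spec."""
        rng = np.random.default_rng(0)
        vol = h.Volume(rng.random((256, 256, 96)), spacing=(1.6, 1.6, 1.6))
        out = h.apply_degradation(vol, h.DegradationSpec.clinical_protocol())
        assert out.shape == (192, 192, 96)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_degradation_reduces_ssim_frozen(self, default_phantom, phantom_pair):
        """SSIM(low, high) < 1; exact value frozen from a one-shot run."""
        hr, lr = phantom_pair
        s = h.ssim(lr, hr)
        assert s < 1.0
        np.testing.assert_allclose(s, 0.7660215261016943, rtol=1e-7)

    def test_energy_monotonicity(self, default_phantom):
        """Zeroing k-space lines only removes energy (Parseval); the
        magnitude operation preserves it."""
        from heartsr.degrade import _apply_kspace_masks

        vol, _, _ = default_phantom
        low = _apply_kspace_masks(vol.data, h.DegradationSpec())
        assert np.sum(low**2) < np.sum(vol.data**2)
        ident = _apply_kspace_masks(vol.data, h.DegradationSpec.identity())
        np.testing.assert_allclose(np.sum(ident**2), np.sum(vol.data**2), rtol=1e-10)

    def test_mask_separability(self):
        """Applying the separable 3D mask equals applying the two 1D
        retention vectors sequentially."""
        rng = np.random.default_rng(2)
        data = rng.random((16, 16, 16))
        spec = h.DegradationSpec()
        ksp = np.fft.fftshift(np.fft.fftn(data))
        pm = build_kspace_mask(16, spec.phase_fraction, spec.partial_fourier)
        sm = build_kspace_mask(16, spec.slice_fraction, spec.partial_fourier)
        joint = ksp * (pm[None, :, None] & sm[None, None, :])
        seq = (ksp * pm[None, :, None]) * sm[None, None, :]
        np.testing.assert_allclose(joint, seq, atol=1e-12)

    def test_pair_alignment_zero_offset(self, phantom_pair):
        """Cross-correlation of the pair peaks at zero shift."""
        hr, lr = phantom_pair
        a = hr.data - hr.data.mean()
        b = lr.data - lr.data.mean()
        xc = np.fft.ifftn(np.fft.fftn(a) * np.conj(np.fft.fftn(b))).real
        assert np.unravel_index(np.argmax(xc), xc.shape) == (0, 0, 0)

    def test_nonfinite_input_rejected(self):
        data = np.ones((16, 16, 16))
        vol = h.Volume(data)
        vol.data[0, 0, 0] = np.inf  # bypass constructor check deliberately
        with pytest.raises(ValueError, match="non-finite"):
            h.apply_degradation(vol, h.DegradationSpec())


class TestUpsample:
    def test_same_spacing_identity(self):
        rng = np.random.default_rng(0)
        vol = h.normalize01(h.Volume(rng.random((16, 16, 16)), spacing=(2.0, 2.0, 2.0)))
        out = h.upsample_to_grid(vol, (2.0, 2.0, 2.0))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_slice_doubling_preserves_fov(self):
        """48 slices at 3.2 mm -> 96 slices at 1.6 mm."""
        rng = np.random.default_rng(1)
        vol = h.Volume(rng.random((32, 32, 48)), spacing=(1.6, 1.6, 3.2))
        out = h.upsample_to_grid(vol, (1.6, 1.6, 1.6))
        assert out.shape == (32, 32, 96)
        np.testing.assert_allclose(out.fov, vol.fov, atol=max(vol.spacing))

    def test_band_limited_cosine_exact(self):
        """Sinc interpolation reproduces an in-band cosine analytically."""
        n, s = 32, 2.0
        x = np.arange(n) * s
        f = 2 / (n * s)  # 2 cycles over the FOV: well inside the band
        line = 0.5 + 0.4 * np.cos(2 * np.pi * f * x)
        vol = h.Volume(np.broadcast_to(line[:, None, None], (n, 8, 8)).copy(), spacing=(s, 2.0, 2.0))
        out = h.upsample_to_grid(vol, (1.0, 2.0, 2.0))
        xs = np.arange(out.shape[0]) * out.spacing[0]
        expected = 0.5 + 0.4 * np.cos(2 * np.pi * f * xs)
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        np.testing.assert_allclose(out.data[:, 4, 4], expected, atol=1e-6)

    def test_downsampling_rejected(self):
        vol = h.Volume(np.ones((16, 16, 16)), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="only upsamples"):
            h.upsample_to_grid(vol, (2.0, 2.0, 2.0))
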