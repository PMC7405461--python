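"""Synthetic low-resolution simulation in the Fourier domain.

The simulator mimics how a rapid whole-heart bSSFP acquisition trades
resolution for speed: the volume is Fourier transformed, only a central band
of k-space lines is retained along the phase- and slice-encode axes
(two-fold down-sampling keeps the central 50%), a partial-Fourier factor
(6/8 by default) additionally zeroes the highest positive spatial
frequencies of that band, and the zero-filled k-space is inverse transformed
back to image space where the magnitude is taken.  The frequency-encode
(x) axis is never masked.  Grids are kept at full size throughout (zero-fill
reconstruction), optionally centre-cropped in-plane, and min-max normalized
to [0, 1].

Conventions
-----------
All bands are defined after ``fftshift``, with DC at index ``N // 2``.  For
``k`` retained lines the central band is ``N//2 - ceil(k/2) .. N//2 +
floor(k/2) - 1`` (DC-inclusive; the extra line for odd ``k`` sits on the
negative-frequency side).  Partial Fourier removes the ``k - round(pf * k)``
highest positive-frequency lines of the band by default (``pf_side="high"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .volume import Volume

__all__ = [
    "DegradationSpec",
    "build_kspace_mask",
    "apply_degradation",
    "degrade_pair",
    "crop_pad_center",
    "normalize01",
    "upsample_to_grid",
]

log = logging.getLogger(__name__)

_MIN_RETAINED = 4


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the low-resolution simulator.

    ``phase_fraction`` / ``slice_fraction`` are the fractions of the full
    phase-/slice-encode k-space extent retained (0.5 halves the resolution).
    ``partial_fourier`` further zeroes asymmetrically within the retained
    band (6/8 = 0.75 matches a typical acquisition).  ``standardize_matrix``
    crops/pads the input grid before the transform; ``crop_xy`` centre-crops
    the in-plane matrix afterwards.  ``None`` leaves the grid untouched.
    """

    phase_fraction: float = 0.5
    slice_fraction: float = 0.5
    partial_fourier: float = 0.75
    crop_xy: int | None = None
    standardize_matrix: tuple[int, int, int] | None = None
    pf_side: str = "high"

    def __post_init__(self) -> None:
        for name in ("phase_fraction", "slice_fraction"):
            f = getattr(self, name)
            if not 0 < f <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {f}")
        if not 0.5 < self.partial_fourier <= 1:
            raise ValueError(f"partial_fourier must be in (0.5, 1], got {self.partial_fourier}")
        if self.pf_side not in ("high", "low"):
            raise ValueError(f"pf_side must be 'high' or 'low', got {self.pf_side!r}")
        if self.crop_xy is not None and self.standardize_matrix is not None:
            if self.crop_xy > min(self.standardize_matrix[:2]):
                raise ValueError("crop_xy exceeds the standardized in-plane matrix size")

    @classmethod
    def clinical_protocol(cls) -> "DegradationSpec":
        """The clinical-geometry protocol: 256x256x96 grid, 50% phase and
        slice resolution, 6/8 partial Fourier, 192x192 in-plane crop."""
        return cls(
            phase_fraction=0.5,
            slice_fraction=0.5,
            partial_fourier=0.75,
            crop_xy=192,
            standardize_matrix=(256, 256, 96),
        )

    @classmethod
    def identity(cls) -> "DegradationSpec":
        """A spec that leaves the (normalized) volume unchanged."""
        return cls(phase_fraction=1.0, slice_fraction=1.0, partial_fourier=1.0)

    def to_dict(self) -> dict:
        return {
            "phase_fraction": self.phase_fraction,
            "slice_fraction": self.slice_fraction,
            "partial_fourier": self.partial_fourier,
            "crop_xy": self.crop_xy,
            "standardize_matrix": list(self.standardize_matrix) if self.standardize_matrix else None,
            "pf_side": self.pf_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DegradationSpec":
        d = dict(d)
        if d.get("standardize_matrix") is not None:
            d["standardize_matrix"] = tuple(d["standardize_matrix"])
        return cls(**d)


def build_kspace_mask(axis_length: int, resolution_fraction: float, partial_fourier: float) -> np.ndarray:
    """Boolean retention vector for one encode axis (fftshifted convention).

    The central ``k = round(resolution_fraction * axis_length)`` lines around
    DC are retained, then the ``k - round(partial_fourier * k)`` highest
    positive-frequency lines of that band are zeroed.  DC is always kept.

    Raises
    ------
    ValueError
        If fewer than 4 lines would remain ("resolution too low").
    """
    n = int(axis_length)
    if n < 2 or n % 2:
        raise ValueError(f"axis_length must be even and >= 2, got {axis_length}")
    if not 0 < resolution_fraction <= 1:
        raise ValueError(f"resolution_fraction must be in (0, 1], got {resolution_fraction}")
    if not 0.5 < partial_fourier <= 1:
        raise ValueError(f"partial_fourier must be in (0.5, 1], got {partial_fourier}")

    k = int(round(resolution_fraction * n))
    dc = n // 2
    lo = dc - math.ceil(k / 2)
    hi = dc + k // 2  # exclusive
    mask = np.zeros(n, dtype=bool)
    mask[max(lo, 0) : min(hi, n)] = True

    n_zero = k - int(round(partial_fourier * k))
    if n_zero > 0:
        if mask.sum() - n_zero < _MIN_RETAINED:
            raise ValueError(
                f"resolution too low: {int(mask.sum()) - n_zero} lines would remain "
                f"(axis_length={n}, fraction={resolution_fraction}, pf={partial_fourier})"
            )
        idx = np.flatnonzero(mask)
        mask[idx[-n_zero:]] = False
    mask[dc] = True  # DC line is never discarded
    if mask.sum() < _MIN_RETAINED:
        raise ValueError(
            f"resolution too low: only {int(mask.sum())} lines retained "
            f"(axis_length={n}, fraction={resolution_fraction}, pf={partial_fourier})"
        )
    return mask


def _axis_mask_for(spec: DegradationSpec, axis_length: int, which: str) -> np.ndarray:
    frac = spec.phase_fraction if which == "phase" else spec.slice_fraction
    mask = build_kspace_mask(axis_length, frac, spec.partial_fourier)
    if spec.pf_side == "low":
        # mirror the asymmetry onto the negative-frequency side, keeping DC
        dc = axis_length // 2
        mirrored = mask[::-1].copy()
        mirrored = np.roll(mirrored, (2 * dc + 1) - axis_length)  # reflect about dc
        mirrored[dc] = True
        return mirrored
    return mask


def crop_pad_center(vol: Volume, target: tuple[int, int, int]) -> Volume:
    """Centre-crop axes that exceed ``target``; zero-pad axes that fall short.

    Any off-by-one surplus (odd difference) goes to the high-index side.
    """
    target = tuple(int(t) for t in target)
    if any(t < 1 for t in target):
        raise ValueError(f"target entries must be >= 1, got {target}")
    data = vol.data
    for ax, t in enumerate(target):
        n = data.shape[ax]
        if n > t:
            lo = (n - t) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(lo, lo + t)
            data = data[tuple(sl)]
        elif n < t:
            lo = (t - n) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (lo, t - n - lo)
            data = np.pad(data, pad, mode="constant")
    return vol.with_data(data)


def normalize01(vol: Volume) -> Volume:
    """Min-max scale intensities into [0, 1].

    A constant volume maps to all zeros (with a warning) rather than raising.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot normalize a volume with non-finite values")
    vmin = data.min()
    vmax = data.max()
    if vmax - vmin <= 0:
        log.warning("normalize01: constant volume (value %g) mapped to zeros", vmin)
        return vol.with_data(np.zeros_like(data), normalized=True)
    return vol.with_data((data - vmin) / (vmax - vmin), normalized=True)


def _apply_kspace_masks(data: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """FFT -> separable phase/slice retention -> IFFT -> magnitude."""
    ksp = np.fft.fftshift(np.fft.fftn(data))
    pm = _axis_mask_for(spec, data.shape[1], "phase")
    sm = _axis_mask_for(spec, data.shape[2], "slice")
    ksp *= pm[None, :, None]
    ksp *= sm[None, None, :]
    img = np.fft.ifftn(np.fft.ifftshift(ksp))
    return np.abs(img)


def _finalize(data: np.ndarray, spacing, crop_xy: int | None) -> Volume:
    vol = Volume(data=np.abs(data), spacing=spacing)
    if crop_xy is not None:
        vol = crop_pad_center(vol, (crop_xy, crop_xy, vol.shape[2]))
    return normalize01(vol)


def degrade_pair(vol: Volume, spec: DegradationSpec) -> tuple[Volume, Volume]:
    """Produce the aligned (high-resolution, low-resolution) training pair.

    Both partners go through the same standardization, in-plane crop and
    independent [0, 1] normalization so the pair stays voxel-aligned.
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("input volume contains non-finite values")
    work = vol
    if spec.standardize_matrix is not None:
        work = crop_pad_center(work, spec.standardize_matrix)
    low = _apply_kspace_masks(np.asarray(work.data, dtype=np.float64), spec)
    high = _finalize(work.data, work.spacing, spec.crop_xy)
    lowv = _finalize(low, work.spacing, spec.crop_xy)
    return high, lowv


def apply_degradation(vol: Volume, spec: DegradationSpec) -> Volume:
    """Simulate the low-resolution acquisition of ``vol`` (see module docs)."""
    return degrade_pair(vol, spec)[1]


def upsample_to_grid(vol: Volume, target_spacing: tuple[float, float, float]) -> Volume:
    """Sinc (zero-padded k-space) interpolation onto a finer grid.

    The field of view is preserved; the new matrix per axis is
    ``round(fov / target_spacing)``.  Only upsampling is supported: a target
    grid smaller than the source raises.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    new_shape = tuple(int(round(f / s)) for f, s in zip(vol.fov, target_spacing))
    if any(m < n for m, n in zip(new_shape, vol.shape)):
        raise ValueError(
            f"target grid {new_shape} is smaller than the source grid {vol.shape}; "
            "this operation only upsamples"
        )
    ksp = np.fft.fftshift(np.fft.fftn(np.asarray(vol.data, dtype=np.float64)))
    padded = np.zeros(new_shape, dtype=complex)
    # place the source spectrum centred in the larger k-space
    slices_src = []
    slices_dst = []
    for n, m in zip(vol.shape, new_shape):
        lo = m // 2 - n // 2
        slices_dst.append(slice(lo, lo + n))
        slices_src.append(slice(None))
    padded[tuple(slices_dst)] = ksp
    scale = np.prod(new_shape) / np.prod(vol.shape)  # preserve image amplitude
    img = np.abs(np.fft.ifftn(np.fft.ifftshift(padded))) * scale
    actual_spacing = tuple(f / m for f, m in zip(vol.fov, new_shape))
    return normalize01(Volume(data=img, spacing=actual_spacing))
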