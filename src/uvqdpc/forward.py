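"""Partially coherent image formation under oblique half-ring illumination.

Two forward models are provided.  ``forward_wotf`` is the fast linearized
path: the image spectrum is the weak-object transfer functions applied to
the object's phase and attenuation spectra.  ``forward_abbe`` is the
brute-force source-point (Abbe) sum — coherent imaging of the full complex
transmittance ``exp(iφ − μ)`` for every source point, intensities added —
which makes no weak-object approximation and serves as the reference the
linearized model is validated against.

Simulated images are returned on an arbitrary photon scale anchored so the
background (empty sample) level is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import (
    AcquisitionConfig,
    PupilFunction,
    SourceDistribution,
    TransferFunctions,
    compute_wotf,
    make_annular_pupil,
    make_halfring_source,
)
from .phantom import ComplexPhantom, EffectiveObject, phantom_to_effective_object

__all__ = [
    "DPCStack",
    "forward_wotf",
    "forward_abbe",
    "select_source_points",
    "add_noise",
    "acquire_stack",
]


@dataclass
class DPCStack:
    """One qDPC acquisition: oblique images, matching flat fields, metadata."""

    images: list[np.ndarray]
    backgrounds: list[np.ndarray]
    orientations_deg: list[float]
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.images} | {a.shape for a in self.backgrounds}
        if len(shapes) != 1:
            raise ValueError("all images and backgrounds must share one shape")
        if len(self.images) != len(self.backgrounds) or len(self.images) != len(
            self.orientations_deg
        ):
            raise ValueError("images, backgrounds and orientations must align")
        if len(set(round(a % 360.0, 6) for a in self.orientations_deg)) < 2:
            warnings.warn(
                "fewer than 2 distinct orientations: joint phase/absorption "
                "retrieval will be ill-posed",
                stacklevel=2,
            )
        for b in self.backgrounds:
            if np.any(b <= 0):
                raise ValueError("backgrounds must be strictly positive")

    def __len__(self) -> int:
        return len(self.images)


def forward_wotf(
    obj: EffectiveObject,
    source: SourceDistribution,
    pupil: PupilFunction,
    config: AcquisitionConfig,
) -> np.ndarray:
    """Linearized image: Î(u) = B·δ(u) + h_abs(u)·μ̂(u) + h_ph(u)·φ̂(u).

    Returned in real space on the photon scale with background 1 (the DC
    term B divides out).  Raises if the inverse transform leaves a
    significant imaginary residual, which would indicate a broken transfer
    function symmetry.
    """
    tf = compute_wotf(source, pupil)
    return _forward_from_tf(obj, tf)


def _forward_from_tf(obj: EffectiveObject, tf: TransferFunctions) -> np.ndarray:
    mu_hat = np.fft.fft2(obj.mu)
    phi_hat = np.fft.fft2(obj.phi)
    h_abs = np.fft.ifftshift(tf.h_abs)
    h_ph = np.fft.ifftshift(tf.h_ph)
    delta = np.fft.ifft2(h_abs * mu_hat + h_ph * phi_hat)
    scale = max(np.abs(delta).max(), 1.0)
    if np.abs(delta.imag).max() > 1e-8 * scale:
        raise RuntimeError(
            "forward model produced a non-real intensity; transfer-function "
            "Hermitian symmetry is broken"
        )
    return 1.0 + delta.real / tf.background


def select_source_points(
    source: SourceDistribution, n_points: int | None
) -> SourceDistribution:
    """Subsample a source onto ~``n_points`` pixels of a uniform grid.

    Keeps every nonzero source pixel when ``n_points`` is None; otherwise
    retains pixels on a regular stride chosen so roughly ``n_points``
    survive, preserving their original weights.  The result is itself a
    valid ``SourceDistribution``, so the same discretization can be fed to
    ``compute_wotf`` for like-for-like model comparisons.
    """
    if n_points is None:
        return source
    nz = np.count_nonzero(source.values)
    if nz <= n_points:
        return source
    stride = max(int(np.sqrt(nz / n_points)), 1)
    mask = np.zeros_like(source.values, dtype=bool)
    mask[::stride, ::stride] = True
    values = np.where(mask, source.values, 0.0)
    if not np.any(values > 0):  # stride missed the ring entirely; keep all
        return source
    return SourceDistribution(
        values=values,
        orientation=source.orientation,
        frequency_step=source.frequency_step,
        radial_weight=source.radial_weight,
    )


def forward_abbe(
    obj: EffectiveObject,
    source: SourceDistribution,
    pupil: PupilFunction,
    config: AcquisitionConfig,
    n_source_points: int | None = 64,
) -> np.ndarray:
    """Brute-force partially coherent image (Abbe source-point sum).

    For each source point u_s with weight w_s the complex transmittance
    ``T = exp(iφ − μ)`` is imaged coherently through the pupil displaced to
    u_s, and intensities are summed:

        I(r) = Σ_s w_s · |IFT[ P(u + u_s) · T̂(u) ]|²(r)

    Normalized so an empty object yields the same background level (1) as
    ``forward_wotf``.
    """
    src = select_source_points(source, n_source_points)
    n_used = np.count_nonzero(src.values)
    if n_used < 8:
        warnings.warn(
            f"only {n_used} source points: the partially coherent sum is "
            "undersampled",
            stacklevel=2,
        )
    T = np.exp(1j * obj.phi - obj.mu)
    T_hat = np.fft.fft2(T)
    P = np.fft.ifftshift(pupil.values)
    # iterate over nonzero source pixels; shift the pupil by rolling
    sr, sc = np.nonzero(src.values)
    center = (src.values.shape[0] // 2, src.values.shape[1] // 2)
    intensity = np.zeros_like(obj.phi, dtype=float)
    total_w = 0.0
    for r, c in zip(sr, sc):
        w = src.values[r, c]
        # shifted[u] = P(u + u_s): displace the pupil so u_s sits at the
        # origin of the object spectrum
        shifted = np.roll(P, (center[0] - r, center[1] - c), axis=(0, 1))
        field_ = np.fft.ifft2(shifted * T_hat)
        intensity += w * np.abs(field_) ** 2
        total_w += w * np.abs(pupil.values[r, c]) ** 2
    if total_w <= 0:
        raise ValueError("no source point falls inside the pupil support")
    return intensity / total_w


def add_noise(image: np.ndarray, photon_scale: float, seed: int) -> np.ndarray:
    """Photon (Poisson) counting noise at a mean budget of ``photon_scale``
    photons per unit intensity; deterministic under the seed."""
    if photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    rng = np.random.default_rng(seed)
    return rng.poisson(np.clip(image, 0, None) * photon_scale) / photon_scale


def acquire_stack(
    phantom: ComplexPhantom,
    config: AcquisitionConfig,
    orientations_deg: list[float] | None = None,
    noise_photons: float | None = None,
    seed: int = 0,
    radial_weight: np.ndarray | None = None,
) -> DPCStack:
    """Simulate a full qDPC acquisition: one image + one flat field per
    half-ring orientation, identical optics throughout.

    ``noise_photons`` is the per-pixel photon budget (None = noise-free);
    sample and background frames receive independent noise draws.
    """
    if orientations_deg is None:
        orientations_deg = list(config.orientations_deg)
    if len(set(a % 360.0 for a in orientations_deg)) != len(orientations_deg):
        raise ValueError("orientations must be distinct")
    cfg = config.with_(
        image_shape=phantom.shape, pixel_size_sample=phantom.pixel_size
    )
    pupil = make_annular_pupil(cfg)
    obj = phantom_to_effective_object(phantom, cfg)
    images, backgrounds = [], []
    for i, angle in enumerate(orientations_deg):
        source = make_halfring_source(pupil, angle, radial_weight)
        img = forward_wotf(obj, source, pupil, cfg)
        bg = np.ones_like(img)
        if noise_photons is not None:
            img = add_noise(img, noise_photons, seed + 2 * i)
            bg = np.clip(add_noise(bg, noise_photons, seed + 2 * i + 1), 1e-6, None)
        images.append(img)
        backgrounds.append(bg)
    return DPCStack(
        images=images,
        backgrounds=backgrounds,
        orientations_deg=list(orientations_deg),
        config=cfg,
    )
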