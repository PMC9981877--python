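"""Self-calibration from images: illumination direction and pupil shape.

The half-ring mask angle is generally unknown relative to the image axes
(the rotation mount's sensor is not aligned with the mask), so the mean
illumination direction must be estimated from the data.  A semi-circular
aperture yields an anisotropic transfer function; for an image of small
scatterers the log-magnitude spectrum is dominated by that shape, and its
Radon projection through the center peaks in the direction orthogonal to
the mean illumination.  A naive version of this idea fails on real images
because edge discontinuities and out-of-band noise swamp the anisotropy;
the pipeline here therefore applies a smooth circular crop and
periodic-smooth decomposition before the Fourier transform, masks the
spectrum to the nominal support, and median-filters the Radon profile.

The pupil itself is estimated from images taken with an off-center pinhole
replacing the half-ring: the spectrum of such an image contains two
decentered copies of the pupil, which are located by normalized
cross-correlation against an annulus template, re-centered, averaged and
binarized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from scipy.signal import fftconvolve
from skimage.feature import match_template
from skimage.transform import radon

from .optics import (
    AcquisitionConfig,
    PupilFunction,
    make_annular_pupil,
    make_halfring_source,
)
from .forward import forward_abbe
from .phantom import EffectiveObject

__all__ = [
    "DirectionEstimate",
    "periodic_smooth_decompose",
    "estimate_illumination_direction",
    "estimate_pupil",
    "PupilDetectionError",
]


class PupilDetectionError(RuntimeError):
    """Fewer than two pupil copies could be located in the spectra."""

    def __init__(self, message: str, diagnostic: np.ndarray | None = None):
        super().__init__(message)
        self.diagnostic = diagnostic


@dataclass
class DirectionEstimate:
    """Estimated mean illumination direction.

    ``angle_deg`` is counter-clockwise from +x in [0, 360);
    ``radon_profile`` holds the center-projection value per Radon angle
    (1° steps) and ``confidence`` its peak-to-median ratio.
    """

    angle_deg: float
    radon_profile: np.ndarray
    confidence: float


def periodic_smooth_decompose(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an image into periodic + smooth components (Moisan's method).

    The smooth component absorbs the discontinuity between opposite image
    edges, so the periodic component behaves as if the image tiled the
    plane — its DFT is free of the cross-shaped boundary artifact.  The two
    components sum to the input exactly.
    """
    image = np.asarray(image, float)
    rows, cols = image.shape
    # boundary "charge": difference between opposite edges
    v = np.zeros_like(image)
    v[0, :] += image[-1, :] - image[0, :]
    v[-1, :] += image[0, :] - image[-1, :]
    v[:, 0] += image[:, -1] - image[:, 0]
    v[:, -1] += image[:, 0] - image[:, -1]
    fy = np.cos(2.0 * math.pi * np.arange(rows) / rows)
    fx = np.cos(2.0 * math.pi * np.arange(cols) / cols)
    denom = 2.0 * (fy[:, None] + fx[None, :] - 2.0)
    v_hat = np.fft.fft2(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_hat = v_hat / denom
    s_hat[0, 0] = 0.0  # mean of the smooth part pinned to zero
    smooth = np.fft.ifft2(s_hat).real
    return image - smooth, smooth


def _smooth_disc_mask(shape, radius_px, sigma_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(rr - (shape[0] - 1) / 2.0, cc - (shape[1] - 1) / 2.0)
    return gaussian_filter((d <= radius_px).astype(float), sigma_px)


def estimate_illumination_direction(
    image: np.ndarray,
    config: AcquisitionConfig,
    angle_step_deg: float = 1.0,
    confidence_threshold: float = 1.05,
) -> DirectionEstimate:
    """Estimate the half-ring orientation from one oblique image.

    Pipeline: smooth circular crop (Gaussian-blurred mask, σ = 20 px) →
    periodic component → FFT → log magnitude → smooth mask to the nominal
    support (2NA/λ, 10-px Gaussian edge) → Radon transform → center
    projection per angle → 3-px median filter → argmax.  The argmax angle
    is orthogonal to the illumination axis; the remaining 180° ambiguity is
    resolved by matched filtering against the simulated response of a weak
    point scatterer under both candidate directions.
    """
    image = np.asarray(image, float)
    rows, cols = image.shape
    work = image - image.mean()
    crop_mask = _smooth_disc_mask(image.shape, min(rows, cols) / 2.0 - 1.0, 20.0)
    work = work * crop_mask
    periodic, _ = periodic_smooth_decompose(work)
    spectrum = np.fft.fftshift(np.fft.fft2(periodic))
    log_mag = np.log1p(np.abs(spectrum))
    cutoff = 2.0 * config.na / config.wavelength
    step = 1.0 / (rows * config.pixel_size_sample)
    support_radius = cutoff / step
    log_mag = log_mag * _smooth_disc_mask(image.shape, support_radius, 10.0)

    angles = np.arange(0.0, 180.0, angle_step_deg)
    sinogram = radon(log_mag, theta=angles)
    center_proj = sinogram[sinogram.shape[0] // 2, :]
    profile = median_filter(center_proj, size=3, mode="wrap")
    peak_idx = int(np.argmax(profile))
    confidence = float(profile[peak_idx] / max(np.median(profile), 1e-30))
    if confidence < confidence_threshold:
        warnings.warn(
            f"direction estimate has low confidence ({confidence:.3f}); the "
            "spectrum may be isotropic (full-ring or featureless image)",
            stacklevel=2,
        )
    # The center projection peaks when the integration line runs along the
    # long axis of the spectral lobe, which is orthogonal to the Radon
    # angle and coincident with the illumination axis.  The argmax locates
    # the peak to the angle step; the phase of the second circular
    # harmonic of the (180°-periodic) profile refines it using the full
    # lobe rather than a single speckle-jittered bin.
    z = np.sum((profile - profile.mean()) * np.exp(-2j * np.radians(angles)))
    harm_deg = (-np.degrees(np.angle(z)) / 2.0) % 180.0
    peak_deg = angles[peak_idx]
    if abs((harm_deg - peak_deg + 90.0) % 180.0 - 90.0) > 30.0:
        harm_deg = peak_deg  # multi-lobed profile: trust the raw argmax
    axis_deg = (harm_deg - 90.0) % 180.0
    angle = _resolve_halfplane_sign(image, config, axis_deg)
    return DirectionEstimate(
        angle_deg=angle, radon_profile=profile, confidence=confidence
    )


def _resolve_halfplane_sign(
    image: np.ndarray, config: AcquisitionConfig, axis_deg: float
) -> float:
    """Pick θ or θ+180 by matched filtering with a simulated bead response.

    In the linear weak-object regime a mirrored half-ring merely negates
    the phase contrast, so a linearized template cannot tell the two
    directions apart for phase-dominated scatterers.  The template is
    therefore rendered with the full (nonlinear) Abbe model of a single
    phase-dominated bead, whose second-order terms break the symmetry;
    the candidate whose template correlates better with the flat-field
    image wins.
    """
    cfg = config.with_(image_shape=(64, 64))
    pupil = make_annular_pupil(cfg)
    rr, cc = np.ogrid[:64, :64]
    disc = (((rr - 32) ** 2 + (cc - 32) ** 2) <= 3.0**2).astype(float)
    obj = EffectiveObject(phi=0.4 * disc, mu=0.01 * disc)
    ff = image - image.mean()
    best, best_score = axis_deg, -np.inf
    for cand in (axis_deg, (axis_deg + 180.0) % 360.0):
        source = make_halfring_source(pupil, cand)
        template = forward_abbe(obj, source, pupil, cfg, n_source_points=64) - 1.0
        t = template[32 - 12 : 32 + 13, 32 - 12 : 32 + 13]
        score = float(np.max(match_template(ff, t, pad_input=True)))
        if score > best_score:
            best, best_score = cand, score
    return best % 360.0


def _annulus_template(config: AcquisitionConfig, step: float) -> np.ndarray:
    f_out = config.na / config.wavelength / step
    f_in = config.na_obs / config.wavelength / step
    size = int(2 * math.ceil(f_out) + 5)
    rr, cc = np.ogrid[:size, :size]
    d = np.hypot(rr - size // 2, cc - size // 2)
    return ((d <= f_out) & (d >= f_in)).astype(float)


def estimate_pupil(
    pinhole_images: list[np.ndarray],
    config: AcquisitionConfig,
    binarize: bool = True,
) -> PupilFunction:
    """Recover the (binary) pupil from off-center-pinhole acquisitions.

    Each image spectrum contains two copies of the pupil decentered to ±u_p
    (u_p = pinhole position).  Both copies are located by cross-correlating
    the log spectrum with a zero-mean annulus template (a matched filter;
    locally normalized correlation is unstable against the speckle filling
    the pupil interior), cut out, re-centered and averaged over copies and
    images; the average is binarized at half its 99th percentile.
    """
    if not pinhole_images:
        raise ValueError("at least one pinhole image is required")
    shape = pinhole_images[0].shape
    step = 1.0 / (shape[0] * config.pixel_size_sample)
    template = _annulus_template(config, step)
    tmpl_half = template.shape[0] // 2
    acc = np.zeros(shape, float)
    n_copies = 0
    last_diag = None
    for img in pinhole_images:
        spec = np.fft.fftshift(np.fft.fft2(img - np.mean(img)))
        log_mag = np.log1p(np.abs(spec))
        last_diag = log_mag
        corr = fftconvolve(
            log_mag, (template - template.mean())[::-1, ::-1], mode="same"
        )
        centers = _two_symmetric_peaks(corr)
        if centers is None:
            continue
        if np.allclose(centers[0], centers[1], atol=2):
            warnings.warn(
                "pinhole sits at the pupil center: the two copies coincide "
                "and carry no off-axis information",
                stacklevel=2,
            )
        for r, c in centers:
            patch = _extract_centered(log_mag, (r, c), shape)
            acc += patch / max(patch.max(), 1e-30)
            n_copies += 1
    if n_copies < 2:
        raise PupilDetectionError(
            "could not locate two pupil copies in any spectrum",
            diagnostic=last_diag,
        )
    acc /= n_copies
    if binarize:
        threshold = 0.5 * np.percentile(acc, 99)
        values = (acc >= threshold).astype(np.complex128)
    else:
        values = acc.astype(np.complex128)
    return PupilFunction(
        values=values,
        frequency_step=step,
        na=config.na,
        na_obs=config.na_obs,
        wavelength=config.wavelength,
    )


def _two_symmetric_peaks(corr: np.ndarray):
    """Strongest correlation peak plus its point-symmetric partner."""
    shape = corr.shape
    center = np.array([shape[0] // 2, shape[1] // 2])
    flat = np.argsort(corr, axis=None)[::-1]
    first = np.array(np.unravel_index(flat[0], shape))
    mirror = 2 * center - first
    if not (0 <= mirror[0] < shape[0] and 0 <= mirror[1] < shape[1]):
        return None
    # refine the mirror peak inside a small window (sub-grid asymmetries)
    w = 4
    r0 = max(int(mirror[0]) - w, 0)
    c0 = max(int(mirror[1]) - w, 0)
    win = corr[r0 : int(mirror[0]) + w + 1, c0 : int(mirror[1]) + w + 1]
    dr, dc = np.unravel_index(np.argmax(win), win.shape)
    second = np.array([r0 + dr, c0 + dc])
    return [tuple(first), tuple(second)]


def _extract_centered(arr: np.ndarray, center, shape) -> np.ndarray:
    """Shift ``arr`` so ``center`` lands on the grid center (zero-filled)."""
    out = np.zeros(shape, float)
    shift_r = shape[0] // 2 - int(center[0])
    shift_c = shape[1] // 2 - int(center[1])
    src_r = slice(max(0, -shift_r), min(shape[0], shape[0] - shift_r))
    src_c = slice(max(0, -shift_c), min(shape[1], shape[1] - shift_c))
    dst_r = slice(src_r.start + shift_r, src_r.stop + shift_r)
    dst_c = slice(src_c.start + shift_c, src_c.stop + shift_c)
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out
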