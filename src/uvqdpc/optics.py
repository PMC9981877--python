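"""Optical configuration, pupil/source models and weak-object transfer functions.

The instrument modeled here is a reflection-geometry UVC microscope built
around an all-mirror Cassegrain-type objective.  The secondary mirror
obscures the center of the pupil, so the coherent transfer function is an
annulus between ``na_obs/λ`` and ``na/λ``.  Oblique, partially coherent
illumination is produced by a rotatable half-ring mask in a conjugate pupil
plane; four mask rotations (0°, 90°, 180°, 270°) provide the asymmetry
needed to retrieve both phase and absorption of a weak object.

Closed-form instrument formulas (resolution, depth of field via a truncated
Ewald sphere, temporal coherence length, illumination power budget) live
here as well, since they are functions of the same acquisition parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "AcquisitionConfig",
    "PupilFunction",
    "SourceDistribution",
    "TransferFunctions",
    "make_annular_pupil",
    "make_halfring_source",
    "cosine_radial_profile",
    "compute_wotf",
    "depth_of_field",
    "theoretical_resolution",
    "linepair_resolution",
    "coherence_length",
    "power_budget",
    "frequency_grid",
]


class ConfigurationError(ValueError):
    """Raised when acquisition parameters are physically inconsistent."""


class DegenerateSourceError(ValueError):
    """Raised when an illumination source carries no weight."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters of the annular-pupil qDPC microscope.

    Parameters
    ----------
    wavelength : float
        Center illumination wavelength, nm.
    na : float
        Numerical aperture of the objective.
    na_obs : float
        Equivalent NA of the central (secondary-mirror) obscuration.
    n_medium : float
        Refractive index of the imaging medium (1.0 for the air objective).
    pixel_size_sample : float
        Pixel pitch at the sample plane, nm.
    image_shape : tuple of int
        (rows, cols) of the simulated/acquired images.
    bandwidth : float
        FWHM spectral bandwidth of the LED, nm.
    tau_abs, tau_ph : float
        Tikhonov regularization weights for the absorption and phase
        channels of the inverse solve.
    orientations_deg : tuple of float
        Half-ring mask rotations used for a full acquisition.
    """

    wavelength: float = 275.0
    na: float = 0.65
    na_obs: float = 0.27
    n_medium: float = 1.0
    pixel_size_sample: float = 50.0
    image_shape: tuple[int, int] = (256, 256)
    bandwidth: float = 10.0
    tau_abs: float = 300.0
    tau_ph: float = 300.0
    orientations_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ConfigurationError("wavelength must be positive")
        if self.na <= 0:
            raise ConfigurationError("na must be positive")
        if self.pixel_size_sample <= 0:
            raise ConfigurationError("pixel_size_sample must be positive")
        nyquist = self.wavelength / (4.0 * self.na)
        if self.pixel_size_sample > nyquist:
            warnings.warn(
                f"pixel size {self.pixel_size_sample:.1f} nm exceeds the "
                f"Nyquist limit λ/(4·NA) = {nyquist:.1f} nm; the simulation "
                "will alias the incoherent passband",
                stacklevel=2,
            )

    def require_annulus(self) -> None:
        """Validate the annular-pupil constraint 0 < na_obs < na ≤ n."""
        if not (0.0 < self.na_obs < self.na <= self.n_medium + 1e-12):
            raise ConfigurationError(
                f"annular pupil requires 0 < na_obs < na <= n_medium, got "
                f"na_obs={self.na_obs}, na={self.na}, n={self.n_medium}"
            )

    def with_(self, **kwargs) -> "AcquisitionConfig":
        return replace(self, **kwargs)


def frequency_grid(shape: tuple[int, int], pixel_size: float):
    """Centered spatial-frequency grid (cycles/nm) for an image shape.

    Returns ``(fy, fx)`` 2-D arrays on the fftshift-centered layout: zero
    frequency sits at index ``(rows//2, cols//2)``.
    """
    fy = np.fft.fftshift(np.fft.fftfreq(shape[0], d=pixel_size))
    fx = np.fft.fftshift(np.fft.fftfreq(shape[1], d=pixel_size))
    return np.meshgrid(fy, fx, indexing="ij")


@dataclass
class PupilFunction:
    """Complex pupil on the centered frequency grid.

    ``values[r, c]`` is the coherent transfer function at frequency
    ``((r - rows//2) * frequency_step, (c - cols//2) * frequency_step)``.
    """

    values: np.ndarray
    frequency_step: float  # cycles/nm per pixel
    na: float
    na_obs: float
    wavelength: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def radius_grid(self) -> np.ndarray:
        """|u| in cycles/nm on the centered grid."""
        r = np.arange(self.shape[0]) - self.shape[0] // 2
        c = np.arange(self.shape[1]) - self.shape[1] // 2
        rr, cc = np.meshgrid(r, c, indexing="ij")
        return np.hypot(rr, cc) * self.frequency_step


@dataclass
class SourceDistribution:
    """Nonnegative illumination intensity distribution in the pupil plane."""

    values: np.ndarray
    orientation: np.ndarray  # unit 2-vector (x, y) of the mean direction
    frequency_step: float
    radial_weight: np.ndarray | None = None

    @property
    def total_weight(self) -> float:
        return float(self.values.sum())


@dataclass
class TransferFunctions:
    """Weak-object transfer functions for one illumination orientation.

    ``h_abs`` maps the (double-pass) attenuation exponent μ to intensity,
    ``h_ph`` maps the phase φ; ``background`` is the DC term B = Σ S|P|².
    Sign convention: a weak pure absorber lowers intensity, so
    ``h_abs(0) = −2B``.
    """

    h_abs: np.ndarray
    h_ph: np.ndarray
    background: float
    orientation: np.ndarray


# ---------------------------------------------------------------------------
# pupil / source / WOTF construction
# ---------------------------------------------------------------------------

def make_annular_pupil(config: AcquisitionConfig) -> PupilFunction:
    """Binary annular pupil between ``na_obs/λ`` and ``na/λ``.

    Both edges are closed: support is ``na_obs/λ ≤ |u| ≤ na/λ``.  With
    ``na_obs = 0`` this degenerates to the full disc of a conventional
    objective.
    """
    if config.na_obs >= config.na:
        raise ConfigurationError(
            f"na_obs ({config.na_obs}) must be smaller than na ({config.na})"
        )
    if config.na > config.n_medium + 1e-12:
        raise ConfigurationError("na cannot exceed the medium index")
    shape = tuple(config.image_shape)
    fy, fx = frequency_grid(shape, config.pixel_size_sample)
    rho = np.hypot(fy, fx)
    f_out = config.na / config.wavelength
    f_in = config.na_obs / config.wavelength
    values = ((rho <= f_out) & (rho >= f_in)).astype(np.complex128)
    step = 1.0 / (shape[0] * config.pixel_size_sample)
    return PupilFunction(
        values=values,
        frequency_step=step,
        na=config.na,
        na_obs=config.na_obs,
        wavelength=config.wavelength,
    )


def cosine_radial_profile(pupil: PupilFunction) -> np.ndarray:
    """Cosine-tapered radial weight mimicking the multimode-fiber fall-off.

    Weight 1 at the inner annulus edge decaying as a half-cosine to 0.5 at
    the outer edge, emulating illumination that is weaker at the highest
    spatial frequencies than at intermediate ones.
    """
    fy, fx = _pupil_freqs(pupil)
    rho = np.hypot(fy, fx)
    f_in = pupil.na_obs / pupil.wavelength
    f_out = pupil.na / pupil.wavelength
    t = np.clip((rho - f_in) / max(f_out - f_in, 1e-30), 0.0, 1.0)
    return 0.75 + 0.25 * np.cos(np.pi * t)


def _pupil_freqs(pupil: PupilFunction):
    r = (np.arange(pupil.shape[0]) - pupil.shape[0] // 2) * pupil.frequency_step
    c = (np.arange(pupil.shape[1]) - pupil.shape[1] // 2) * pupil.frequency_step
    return np.meshgrid(r, c, indexing="ij")


def make_halfring_source(
    pupil: PupilFunction,
    angle_deg: float,
    radial_weight: np.ndarray | None = None,
) -> SourceDistribution:
    """Half-ring illumination: the pupil annulus masked to ``u·d ≥ 0``.

    ``d = (cos θ, sin θ)`` with θ counter-clockwise from the +x (column)
    axis.  Pixels exactly on the dividing line are included.
    """
    theta = math.radians(angle_deg)
    d = np.array([math.cos(theta), math.sin(theta)])
    fy, fx = _pupil_freqs(pupil)
    # image rows grow downward; physical y axis points up
    proj = fx * d[0] + (-fy) * d[1]
    # dividing-line pixels are included on both sides; the tolerance guards
    # against cos/sin rounding (cos(90°) is 6e-17, not 0) which would
    # otherwise include only half of the boundary diameter and bias the
    # source's mean direction
    tol = 1e-9 * float(np.abs(proj).max())
    mask = proj >= -tol
    values = np.abs(pupil.values) * mask
    if radial_weight is not None:
        values = values * radial_weight
    return SourceDistribution(
        values=values,
        orientation=d,
        frequency_step=pupil.frequency_step,
        radial_weight=radial_weight,
    )


def compute_wotf(source: SourceDistribution, pupil: PupilFunction) -> TransferFunctions:
    """Weak-object transfer functions for partially coherent illumination.

    With source intensity S and pupil P on one centered grid, define the
    cross-correlations

        C1(u) = Σ_{u'} S(u') P*(u') P(u' + u)
        C2(u) = Σ_{u'} S(u') P(u')  P*(u' − u)

    Then B = C1(0) = Σ S|P|², and

        h_abs = −(C1 + C2)        (Hermitian-symmetric, h_abs(0) = −2B)
        h_ph  =  i (C1 − C2)      (Hermitian-antisymmetric, h_ph(0) = 0)

    Correlations are evaluated as linear (zero-padded) FFT correlations, so
    there is no wrap-around.
    """
    if source.values.shape != pupil.values.shape:
        raise ValueError("source and pupil must share one frequency grid")
    if source.total_weight <= 0:
        raise DegenerateSourceError("source distribution has zero total weight")
    S = source.values
    P = pupil.values
    SP = S * P
    # scipy.signal.correlate(a, b)[u] = Σ a(u'+u) conj(b(u')); 'same' keeps
    # zero lag at index N//2, matching the centered grid.
    # C1(u) = Σ S P* P(u'+u) = correlate(P, S·P) under that convention.
    c1 = signal.correlate(P, SP, mode="same", method="fft")
    # C2(u) = Σ_w S(w+u)P(w+u) P*(w) = correlate(S·P, P)
    c2 = signal.correlate(SP, P, mode="same", method="fft")
    background = float(np.real(np.sum(S * np.abs(P) ** 2)))
    h_abs = -(c1 + c2)
    h_ph = 1j * (c1 - c2)
    return TransferFunctions(
        h_abs=h_abs, h_ph=h_ph, background=background, orientation=source.orientation
    )


# ---------------------------------------------------------------------------
# closed-form instrument formulas
# ---------------------------------------------------------------------------

def depth_of_field(config: AcquisitionConfig) -> float:
    """Depth of field of the obscured pupil, µm (truncated Ewald sphere).

    The generalized pupil of a Cassegrain objective misses the spherical cap
    below the obscuration NA, so its axial frequency extent — and hence the
    depth of field — is set by a *truncated* Ewald sphere:

        Δz = (λ₀/n) / ( sqrt(1 − NA_obs²/n²) − sqrt(1 − NA²/n²) )

    This is longer than for an unobscured objective of equal NA.
    """
    na, na_obs, n = config.na, config.na_obs, config.n_medium
    if not (0.0 <= na_obs < na):
        raise ConfigurationError("requires 0 <= na_obs < na")
    if na > n:
        raise ConfigurationError("na cannot exceed the medium index")
    denom = math.sqrt(1.0 - (na_obs / n) ** 2) - math.sqrt(1.0 - (na / n) ** 2)
    if denom <= 0:
        raise ZeroDivisionError("na == na_obs gives an unbounded depth of field")
    return (config.wavelength / n) / denom * 1e-3  # nm -> µm


def theoretical_resolution(config: AcquisitionConfig) -> float:
    """Coherent two-point resolution Δx = λ/(2·NA), nm."""
    if config.na <= 0:
        raise ConfigurationError("na must be positive")
    return config.wavelength / (2.0 * config.na)


def linepair_resolution(lp_per_mm: float) -> int:
    """Full line-pair period of a bar target, integer nm.

    A target with ``lp_per_mm`` line pairs per millimeter has period
    1e6/lp_per_mm nm; resolving it bounds the resolving power by that
    period.
    """
    if lp_per_mm <= 0:
        raise ValueError("lp_per_mm must be positive")
    return round(1e6 / lp_per_mm)


def coherence_length(config: AcquisitionConfig) -> float:
    """Temporal coherence length L_c = λ²/Δλ, µm.

    Note: for the 275 nm LED the nominal 10 nm bandwidth gives 7.56 µm
    under this convention; a printed figure of 6.8 µm corresponds to an
    effective bandwidth of ≈ 11.1 nm.
    """
    if config.bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return config.wavelength**2 / config.bandwidth * 1e-3  # nm -> µm


def power_budget(
    led_mw: float,
    splitter: float,
    halfmask: float,
    na_obs: float,
    na: float,
    fiber_core_mm: float,
    led_side_mm: float,
) -> float:
    """Illumination power at the sample, mW.

    Multiplies the LED emission by the beam-splitter and half-mask
    transmissions, the pupil-area fraction passed by the obscuration
    (na_obs²/na²), and the fiber-coupling geometric factor (fiber core
    area over square LED emitting area).
    """
    fiber_area = math.pi * (fiber_core_mm / 2.0) ** 2
    led_area = led_side_mm**2
    return led_mw * splitter * halfmask * (na_obs**2 / na**2) * (fiber_area / led_area)
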