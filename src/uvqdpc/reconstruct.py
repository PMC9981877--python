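"""Tikhonov-regularized joint retrieval of phase and absorption.

Each half-ring orientation j contributes one flat-field-corrected
difference image d_j = (I_j − B_j)/B_j whose spectrum, in the weak-object
regime, obeys

    B_j · d̂_j(u) = h_abs,j(u) · μ̂(u) + h_ph,j(u) · φ̂(u)

Stacking all orientations gives, per spatial frequency, an overdetermined
2-unknown linear system solved in closed form from the normal equations
with Tikhonov weights τ_abs, τ_ph on the two channels:

    minimize  Σ_j |h_abs,j μ̂ + h_ph,j φ̂ − B_j d̂_j|² + τ_abs|μ̂|² + τ_ph|φ̂|²

The retrieved double-pass attenuation exponent μ is converted to a
quantitative extinction-coefficient map through the effective axial path:
k = μλ/(4πL), with L defaulting to the instrument's depth of field.  Since
sub-resolution structures are thinner than the depth of field, retrieved
extinction coefficients are lower bounds on the true values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forward import DPCStack
from .optics import (
    AcquisitionConfig,
    TransferFunctions,
    compute_wotf,
    depth_of_field,
    make_annular_pupil,
    make_halfring_source,
)

__all__ = [
    "ReconstructionResult",
    "RegularizationRequiredError",
    "flatfield_correct",
    "solve_qdpc",
    "mu_to_k",
    "reconstruct_stack",
    "bandlimit",
    "incoherent_cutoff",
]


class RegularizationRequiredError(ValueError):
    """The unregularized per-frequency normal matrix is singular."""


@dataclass
class ReconstructionResult:
    """Retrieved maps plus full provenance of the parameters used."""

    phi: np.ndarray
    mu: np.ndarray
    k_map: np.ndarray
    tau_abs: float
    tau_ph: float
    path_length_nm: float
    config: AcquisitionConfig | None = None
    orientations_deg: list[float] | None = None

    def __post_init__(self) -> None:
        for name in ("phi", "mu", "k_map"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")


def flatfield_correct(stack: DPCStack) -> list[np.ndarray]:
    """Per-orientation normalized difference images d_j = (I_j − B_j)/B_j."""
    diffs = []
    for j, (img, bg) in enumerate(zip(stack.images, stack.backgrounds)):
        bad = np.argwhere(bg <= 0)
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"background {j} has a nonpositive pixel at ({r}, {c})"
            )
        diffs.append((img - bg) / bg)
    return diffs


def incoherent_cutoff(config: AcquisitionConfig) -> float:
    """Incoherent frequency cutoff 2·NA/λ in cycles/nm."""
    return 2.0 * config.na / config.wavelength


def _support_mask(shape, pixel_size, cutoff):
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    return np.hypot(FY, FX) <= cutoff


def bandlimit(image: np.ndarray, config: AcquisitionConfig) -> np.ndarray:
    """Project an image onto the incoherent passband |u| ≤ 2NA/λ.

    Useful for in-band comparisons between reconstructions (which carry no
    information beyond the cutoff) and pixel-sharp ground truth.
    """
    mask = _support_mask(image.shape, config.pixel_size_sample, incoherent_cutoff(config))
    return np.fft.ifft2(np.fft.fft2(image) * mask).real


def solve_qdpc(
    diffs: list[np.ndarray],
    transfer: list[TransferFunctions],
    tau_abs: float,
    tau_ph: float,
    config: AcquisitionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-frequency 2x2 Tikhonov solve for (φ, μ).

    Returns real-valued maps.  With both τ = 0 the normal matrix is
    singular wherever the transfer functions lack support (always true at
    least outside the passband), so strictly positive regularization is
    required there; a ``RegularizationRequiredError`` names the condition.
    """
    if len(diffs) < 2 or len(transfer) < 2:
        raise ValueError("at least two orientations are required")
    if len(diffs) != len(transfer):
        raise ValueError("diffs and transfer functions must align")
    shape = diffs[0].shape
    a11 = np.full(shape, complex(tau_abs))
    a22 = np.full(shape, complex(tau_ph))
    a12 = np.zeros(shape, complex)
    rhs_mu = np.zeros(shape, complex)
    rhs_phi = np.zeros(shape, complex)
    for d, tf in zip(diffs, transfer):
        h_a = np.fft.ifftshift(tf.h_abs)
        h_p = np.fft.ifftshift(tf.h_ph)
        y = tf.background * np.fft.fft2(d)
        a11 += np.abs(h_a) ** 2
        a22 += np.abs(h_p) ** 2
        a12 += np.conj(h_a) * h_p
        rhs_mu += np.conj(h_a) * y
        rhs_phi += np.conj(h_p) * y
    # det >= tau_abs * tau_ph, so any positive regularization keeps the
    # system invertible; without it the solve is singular wherever the
    # transfer functions lack support (FFT round-off leaves ~1e-15 there,
    # so test against the support scale rather than exact zero)
    if min(tau_abs, tau_ph) <= 0.0:
        support = a11.real + a22.real  # sum of |h|^2 over both channels
        if np.any(support < 1e-20 * support.max()):
            raise RegularizationRequiredError(
                "singular normal matrix at some frequency; "
                "increase tau_abs/tau_ph"
            )
    det = a11 * a22 - np.abs(a12) ** 2
    mu_hat = (a22 * rhs_mu - a12 * rhs_phi) / det
    phi_hat = (a11 * rhs_phi - np.conj(a12) * rhs_mu) / det
    if config is not None:
        mask = _support_mask(shape, config.pixel_size_sample, incoherent_cutoff(config))
        mu_hat *= mask
        phi_hat *= mask
    return np.fft.ifft2(phi_hat).real, np.fft.ifft2(mu_hat).real


def mu_to_k(
    mu: np.ndarray,
    config: AcquisitionConfig,
    path_length_nm: float | None = None,
) -> np.ndarray:
    """Convert the double-pass attenuation exponent to extinction coefficient.

    Amplitude decays as exp(−2πkz/λ) per pass; the reflection geometry
    doubles the path, so μ = 4πkL/λ over an effective axial extent L and

        k = μ · λ / (4π · L)

    L defaults to the depth of field — the axial slab the instrument
    integrates over — which makes retrieved k an underestimate for
    structures thinner than L.
    """
    if path_length_nm is None:
        path_length_nm = depth_of_field(config) * 1e3  # µm -> nm
    if path_length_nm <= 0:
        raise ValueError("path_length_nm must be positive")
    return mu * config.wavelength / (4.0 * math.pi * path_length_nm)


def reconstruct_stack(
    stack: DPCStack,
    tau_abs: float | None = None,
    tau_ph: float | None = None,
    path_length_nm: float | None = None,
) -> ReconstructionResult:
    """Full retrieval pipeline for one acquisition.

    flat-field correction → per-orientation transfer functions → joint
    Tikhonov solve → μ→k conversion, with every parameter recorded in the
    result.
    """
    cfg = stack.config
    tau_abs = cfg.tau_abs if tau_abs is None else tau_abs
    tau_ph = cfg.tau_ph if tau_ph is None else tau_ph
    diffs = flatfield_correct(stack)
    pupil = make_annular_pupil(cfg)
    transfer = [
        compute_wotf(make_halfring_source(pupil, angle), pupil)
        for angle in stack.orientations_deg
    ]
    phi, mu = solve_qdpc(diffs, transfer, tau_abs, tau_ph, config=cfg)
    if path_length_nm is None:
        path_length_nm = depth_of_field(cfg) * 1e3
    k_map = mu_to_k(mu, cfg, path_length_nm)
    return ReconstructionResult(
        phi=phi,
        mu=mu,
        k_map=k_map,
        tau_abs=tau_abs,
        tau_ph=tau_ph,
        path_length_nm=path_length_nm,
        config=cfg,
        orientations_deg=list(stack.orientations_deg),
    )
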