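"""Seeded synthetic phantoms: LSEC-like cells, bead fields and bar targets.

Liver sinusoidal endothelial cells (LSECs) are extremely thin cells whose
peripheral plasma membrane (0.1–0.2 µm thick) is perforated by
sub-diffraction fenestrations (50–300 nm pores) grouped into sieve plates.
The phantoms here encode, per pixel, the real refractive-index increment
δn over the medium, the extinction coefficient k (imaginary part of the
refractive index) and the local physical thickness, plus ground-truth
labels for every rendered structure — everything the downstream
reconstruction and detection stages can be scored against.

All randomness flows from a single integer seed through one
``numpy.random.Generator``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import AcquisitionConfig

__all__ = [
    "ComplexPhantom",
    "EffectiveObject",
    "LABEL_BACKGROUND",
    "LABEL_MEMBRANE",
    "LABEL_NUCLEUS",
    "LABEL_CLUSTER",
    "make_lsec_phantom",
    "make_bar_target",
    "make_bead_field",
    "phantom_to_effective_object",
]

LABEL_BACKGROUND = 0
LABEL_MEMBRANE = 1
LABEL_NUCLEUS = 2
LABEL_CLUSTER = 3


class AliasingError(ValueError):
    """Requested structure is finer than two pixels."""


@dataclass
class ComplexPhantom:
    """Per-pixel complex-refractive-index ground truth.

    ``delta_n`` is the real refractive-index increment over the medium,
    ``k_map`` the extinction coefficient and ``thickness`` the local
    physical thickness in nm.  ``truth_labels`` uses 0 = background,
    1 = membrane, 2 = nucleus, 3 = fenestration cluster;
    ``truth_clusters`` lists planted clusters as ``(row, col, radius_nm)``.
    """

    delta_n: np.ndarray
    k_map: np.ndarray
    thickness: np.ndarray
    pixel_size: float
    truth_labels: np.ndarray
    truth_clusters: list[tuple[int, int, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.k_map < 0):
            raise ValueError("extinction coefficients must be nonnegative")
        if np.any(self.thickness < 0):
            raise ValueError("thickness must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.k_map.shape


@dataclass
class EffectiveObject:
    """Double-pass weak-object fields seen by the reflection microscope.

    ``phi`` is the accumulated phase in radians and ``mu`` the amplitude
    attenuation exponent; both include the factor 2 of the double pass
    through the sample.  The linearized image model is valid only while
    both stay well below 1.
    """

    phi: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mu < 0):
            raise ValueError("mu must be nonnegative")
        if self.mu.size and (self.mu.max() >= 0.5 or np.abs(self.phi).max() >= 0.5):
            warnings.warn(
                "object exceeds the weak-object regime (max mu or |phi| >= 0.5); "
                "the linearized forward model will be inaccurate",
                stacklevel=2,
            )


def _disc(shape, center, radius_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _ellipse(shape, center, semi_axes, angle_rad):
    rr, cc = np.mgrid[: shape[0], : shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    x = ca * dc + sa * dr
    y = -sa * dc + ca * dr
    return (x / semi_axes[1]) ** 2 + (y / semi_axes[0]) ** 2 <= 1.0


def make_lsec_phantom(
    shape: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 50.0,
    seed: int = 0,
    nucleus_k: float = 8e-4,
    membrane_k: float = 2.7e-4,
    cluster_k: float = 3.4e-4,
    n_clusters: int = 15,
    fenestration_radius_range_nm: tuple[float, float] = (50.0, 300.0),
    delta_n_cell: float = 0.02,
    nucleus_thickness_nm: float = 300.0,
    cluster_radius_range_nm: tuple[float, float] = (350.0, 650.0),
) -> ComplexPhantom:
    """Render a synthetic LSEC with nucleus, thin membrane and sieve plates.

    The cell body is an ellipse; the nucleus a smaller, thicker ellipse
    inside it; the surrounding membrane is 100–200 nm thick (one draw per
    phantom).  Each fenestration cluster (sieve plate) is a small disc on
    the membrane carrying zero-extinction holes (the fenestrations, radii
    drawn from ``fenestration_radius_range_nm``) surrounded by
    elevated-extinction rims — the cytoskeletal protein density is higher
    around the pores — rescaled so the mean extinction over the cluster
    footprint equals ``cluster_k``.  Sub-pixel fenestrations are still
    recorded in the truth and rendered as a single pixel.
    """
    if shape[0] < 128 or shape[1] < 128:
        raise ValueError("phantom shape must be at least 128x128")
    rng = np.random.default_rng(seed)
    delta_n = np.zeros(shape)
    k_map = np.zeros(shape)
    thickness = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)

    center = (shape[0] / 2 + rng.uniform(-5, 5), shape[1] / 2 + rng.uniform(-5, 5))
    cell_axes = (shape[0] * rng.uniform(0.36, 0.42), shape[1] * rng.uniform(0.36, 0.42))
    cell = _ellipse(shape, center, cell_axes, rng.uniform(0, math.pi))
    nuc_axes = (shape[0] * rng.uniform(0.10, 0.14), shape[1] * rng.uniform(0.10, 0.14))
    nuc_center = (center[0] + rng.uniform(-8, 8), center[1] + rng.uniform(-8, 8))
    nucleus = _ellipse(shape, nuc_center, nuc_axes, rng.uniform(0, math.pi)) & cell

    membrane = cell & ~nucleus
    membrane_thickness = rng.uniform(100.0, 200.0)

    labels[membrane] = LABEL_MEMBRANE
    labels[nucleus] = LABEL_NUCLEUS
    k_map[membrane] = membrane_k
    k_map[nucleus] = nucleus_k
    thickness[membrane] = membrane_thickness
    thickness[nucleus] = nucleus_thickness_nm
    delta_n[cell] = delta_n_cell

    truth_clusters: list[tuple[int, int, float]] = []
    # candidate cluster centers: on the membrane, away from nucleus and rim
    margin_px = cluster_radius_range_nm[1] / pixel_size_nm + 2
    placed = 0
    attempts = 0
    while placed < n_clusters and attempts < 200 * max(n_clusters, 1):
        attempts += 1
        r = int(rng.integers(0, shape[0]))
        c = int(rng.integers(0, shape[1]))
        radius_nm = rng.uniform(*cluster_radius_range_nm)
        radius_px = radius_nm / pixel_size_nm
        footprint = _disc(shape, (r, c), radius_px + 1)
        if not membrane[r, c]:
            continue
        if np.any(labels[footprint] != LABEL_MEMBRANE) or not footprint.any():
            continue
        if any(
            (r - r0) ** 2 + (c - c0) ** 2 < (2.2 * margin_px) ** 2
            for r0, c0, _ in truth_clusters
        ):
            continue
        _render_cluster(
            k_map, labels, (r, c), radius_px, rng,
            fenestration_radius_range_nm, pixel_size_nm, cluster_k, membrane_k,
        )
        # fenestrations are through-holes: no material there
        hole = (k_map == 0.0) & _disc(shape, (r, c), radius_px)
        thickness[hole] = 0.0
        delta_n[hole] = 0.0
        truth_clusters.append((r, c, radius_nm))
        placed += 1
    if placed < n_clusters:
        warnings.warn(
            f"placed only {placed}/{n_clusters} clusters on the membrane",
            stacklevel=2,
        )

    return ComplexPhantom(
        delta_n=delta_n,
        k_map=k_map,
        thickness=thickness,
        pixel_size=pixel_size_nm,
        truth_labels=labels,
        truth_clusters=truth_clusters,
        meta={
            "kind": "lsec",
            "seed": seed,
            "membrane_thickness_nm": membrane_thickness,
            "nucleus_k": nucleus_k,
            "membrane_k": membrane_k,
            "cluster_k": cluster_k,
        },
    )


def _render_cluster(
    k_map, labels, center, radius_px, rng,
    fen_radius_range_nm, pixel_size_nm, cluster_k, membrane_k,
):
    """Zero-k holes with elevated-k rims inside a disc; mean pinned to cluster_k."""
    shape = k_map.shape
    disc = _disc(shape, center, radius_px)
    n_fen = int(rng.integers(3, 9))
    hole = np.zeros(shape, bool)
    rim = np.zeros(shape, bool)
    for _ in range(n_fen):
        ang = rng.uniform(0, 2 * math.pi)
        rad = radius_px * math.sqrt(rng.uniform(0, 0.8))
        fr = center[0] + rad * math.sin(ang)
        fc = center[1] + rad * math.cos(ang)
        fen_r_px = rng.uniform(*fen_radius_range_nm) / pixel_size_nm
        h = _disc(shape, (fr, fc), max(fen_r_px, 0.5)) & disc
        if not h.any():  # sub-pixel pore: render as a single pixel
            ir, ic = int(round(fr)), int(round(fc))
            if 0 <= ir < shape[0] and 0 <= ic < shape[1] and disc[ir, ic]:
                h = np.zeros(shape, bool)
                h[ir, ic] = True
        hole |= h
        rim |= _disc(shape, (fr, fc), 1.8 * max(fen_r_px, 0.5) + 1.0) & disc & ~h
    rim &= ~hole
    k_disc = np.where(rim, 2.0 * cluster_k, np.where(hole, 0.0, membrane_k))
    current_mean = k_disc[disc].mean()
    if current_mean > 0:
        k_disc = k_disc * (cluster_k / current_mean)
    k_map[disc] = k_disc[disc]
    labels[disc] = LABEL_CLUSTER


def make_bar_target(
    lp_per_mm: float,
    shape: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 50.0,
    k_contrast: float = 5e-4,
    thickness_nm: float = 150.0,
) -> ComplexPhantom:
    """USAF-style vertical bar target with anti-aliased edges.

    Bars alternate along the column axis with full period 1e6/lp_per_mm nm.
    Edges are rendered by 16x column supersampling so periods close to two
    pixels keep the correct spectral peak.
    """
    period_nm = 1e6 / lp_per_mm
    period_px = period_nm / pixel_size_nm
    if period_px < 2.0:
        raise AliasingError(
            f"{lp_per_mm} lp/mm gives a {period_px:.2f}-pixel period; "
            "at least 2 pixels per period are required"
        )
    over = 16
    x = (np.arange(shape[1] * over) + 0.5) / over  # pixel coordinates
    fine = ((x * pixel_size_nm) % period_nm) < (period_nm / 2.0)
    profile = fine.reshape(shape[1], over).mean(axis=1)
    k_map = np.tile(profile, (shape[0], 1)) * k_contrast
    labels = (k_map > k_contrast / 2).astype(np.int32)
    return ComplexPhantom(
        delta_n=np.zeros(shape),
        k_map=k_map,
        thickness=np.full(shape, float(thickness_nm)),
        pixel_size=pixel_size_nm,
        truth_labels=labels,
        truth_clusters=[],
        meta={"kind": "bar_target", "lp_per_mm": lp_per_mm, "period_px": period_px},
    )


def make_bead_field(
    shape: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 50.0,
    seed: int = 0,
    n_beads: int = 60,
    bead_radius_nm: float = 150.0,
    bead_k: float = 6e-4,
    bead_delta_n: float = 0.03,
    thickness_nm: float = 300.0,
) -> ComplexPhantom:
    """Sparse field of small scatterers (polystyrene-bead-like).

    Used as calibration sample: point-like features make the image spectrum
    reflect the anisotropic transfer function of the half-ring
    illumination.  Beads carry both refractive-index and extinction
    contrast; the phase part is what breaks the 180° symmetry of the
    spectrum-based direction estimate.
    """
    rng = np.random.default_rng(seed)
    delta_n = np.zeros(shape)
    k_map = np.zeros(shape)
    thickness = np.zeros(shape)
    labels = np.zeros(shape, np.int32)
    r_px = bead_radius_nm / pixel_size_nm
    for _ in range(n_beads):
        center = (rng.uniform(0, shape[0]), rng.uniform(0, shape[1]))
        d = _disc(shape, center, max(r_px, 1.0))
        delta_n[d] = bead_delta_n
        k_map[d] = bead_k
        thickness[d] = thickness_nm
        labels[d] = 1
    return ComplexPhantom(
        delta_n=delta_n, k_map=k_map, thickness=thickness,
        pixel_size=pixel_size_nm, truth_labels=labels,
        meta={"kind": "bead_field", "seed": seed},
    )


def phantom_to_effective_object(
    phantom: ComplexPhantom, config: AcquisitionConfig
) -> EffectiveObject:
    """Project a phantom onto double-pass phase and attenuation maps.

    The reflection geometry doubles the optical path, hence the factor 2:

        φ = 2 · (2π/λ) · δn · t        μ = 2 · (2π/λ) · k · t
    """
    factor = 2.0 * (2.0 * math.pi / config.wavelength)
    phi = factor * phantom.delta_n * phantom.thickness
    mu = factor * phantom.k_map * phantom.thickness
    return EffectiveObject(phi=phi, mu=mu)
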