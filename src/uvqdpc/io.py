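"""Readers/writers for stacks, phantoms, reconstructions and run manifests.

Conventions: multi-page 32-bit float TIFF for image data (ImageJ
compatible), a JSON sidecar carrying orientations, acquisition parameters
and the seed, CSV for tabular reports and YAML for configuration.  Images
are row-major with the origin top-left; angles are counter-clockwise from
+x (east); lengths are nm at the sample plane.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .forward import DPCStack
from .optics import AcquisitionConfig
from .phantom import ComplexPhantom
from .reconstruct import ReconstructionResult

logger = logging.getLogger("uvqdpc")

__all__ = [
    "read_config",
    "read_stack",
    "write_stack",
    "write_phantom",
    "read_phantom",
    "write_reconstruction",
    "write_manifest",
    "StackSchemaError",
]

SCHEMA_VERSION = 1


class StackSchemaError(ValueError):
    """Sidecar metadata inconsistent with the TIFF contents."""


_CONFIG_KEYS = {
    "wavelength_nm": "wavelength",
    "bandwidth_nm": "bandwidth",
    "na": "na",
    "na_obs": "na_obs",
    "n_medium": "n_medium",
    "pixel_size_nm": "pixel_size_sample",
    "image_shape": "image_shape",
    "tau_abs": "tau_abs",
    "tau_ph": "tau_ph",
    "orientations_deg": "orientations_deg",
}


def read_config(path: str | Path) -> AcquisitionConfig:
    """Load an AcquisitionConfig from a YAML (or JSON) config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    kwargs = {}
    for file_key, field_name in _CONFIG_KEYS.items():
        if file_key in data:
            value = data[file_key]
            if field_name in ("image_shape", "orientations_deg"):
                value = tuple(value)
            kwargs[field_name] = value
    unknown = set(data) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AcquisitionConfig(**kwargs)


def _config_to_dict(config: AcquisitionConfig) -> dict:
    return {k: getattr(config, v) for k, v in _CONFIG_KEYS.items()}


def write_stack(stack: DPCStack, path: str | Path) -> None:
    """Write a DPC stack as <path>.tif (images then backgrounds) + sidecar."""
    path = Path(path)
    pages = [np.asarray(a, np.float32) for a in stack.images + stack.backgrounds]
    tifffile.imwrite(path.with_suffix(".tif"), np.stack(pages), imagej=True)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "orientations_deg": list(stack.orientations_deg),
        "n_images": len(stack.images),
        "has_backgrounds": True,
        "config": _config_to_dict(stack.config),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> DPCStack:
    """Read a stack written by ``write_stack``; validates sidecar vs pages."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    missing = {"orientations_deg", "config"} - set(sidecar)
    if missing:
        raise StackSchemaError(f"sidecar missing keys: {sorted(missing)}")
    pages = tifffile.imread(path.with_suffix(".tif"))
    if pages.ndim == 2:
        pages = pages[None]
    orientations = [float(a) for a in sidecar["orientations_deg"]]
    n = len(orientations)
    has_bg = sidecar.get("has_backgrounds", True)
    expected = 2 * n if has_bg else n
    if pages.shape[0] != expected:
        raise StackSchemaError(
            f"sidecar declares {n} orientations ({expected} pages expected) "
            f"but TIFF has {pages.shape[0]} pages"
        )
    images = [np.asarray(p, float) for p in pages[:n]]
    if has_bg:
        backgrounds = [np.asarray(p, float) for p in pages[n:]]
    else:
        logger.warning("stack has no background pages; assuming flat fields of 1")
        backgrounds = [np.ones_like(images[0]) for _ in range(n)]
    cfg_dict = {
        v: tuple(sidecar["config"][k]) if v in ("image_shape", "orientations_deg")
        else sidecar["config"][k]
        for k, v in _CONFIG_KEYS.items()
        if k in sidecar["config"]
    }
    config = AcquisitionConfig(**cfg_dict)
    return DPCStack(
        images=images,
        backgrounds=backgrounds,
        orientations_deg=orientations,
        config=config,
    )


def write_phantom(phantom: ComplexPhantom, path: str | Path) -> None:
    """Phantom as 4-page TIFF (delta_n, k, thickness, labels) + truth sidecar."""
    path = Path(path)
    pages = np.stack(
        [
            phantom.delta_n.astype(np.float32),
            phantom.k_map.astype(np.float32),
            phantom.thickness.astype(np.float32),
            phantom.truth_labels.astype(np.float32),
        ]
    )
    tifffile.imwrite(path.with_suffix(".tif"), pages, imagej=True)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "pixel_size_nm": phantom.pixel_size,
        "truth_clusters": [list(map(float, t)) for t in phantom.truth_clusters],
        "meta": phantom.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_phantom(path: str | Path) -> ComplexPhantom:
    path = Path(path)
    pages = tifffile.imread(path.with_suffix(".tif"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ComplexPhantom(
        delta_n=np.asarray(pages[0], float),
        k_map=np.asarray(pages[1], float),
        thickness=np.asarray(pages[2], float),
        pixel_size=float(sidecar["pixel_size_nm"]),
        truth_labels=np.asarray(pages[3], np.int32),
        truth_clusters=[
            (int(r), int(c), float(rad)) for r, c, rad in sidecar["truth_clusters"]
        ],
        meta=sidecar.get("meta", {}),
    )


def write_reconstruction(result: ReconstructionResult, path: str | Path) -> None:
    """phi/mu/k maps as a 3-page float TIFF plus a JSON provenance record."""
    path = Path(path)
    pages = np.stack(
        [
            result.phi.astype(np.float32),
            result.mu.astype(np.float32),
            result.k_map.astype(np.float32),
        ]
    )
    tifffile.imwrite(path.with_suffix(".tif"), pages, imagej=True)
    record = {
        "schema_version": SCHEMA_VERSION,
        "pages": ["phi", "mu", "k"],
        "tau_abs": result.tau_abs,
        "tau_ph": result.tau_ph,
        "path_length_nm": result.path_length_nm,
        "orientations_deg": result.orientations_deg,
        "config": _config_to_dict(result.config) if result.config else None,
    }
    path.with_suffix(".json").write_text(json.dumps(record, indent=2))
    logger.info(
        "reconstruction written: tau_abs=%g tau_ph=%g path_length=%g nm "
        "orientations=%s",
        result.tau_abs,
        result.tau_ph,
        result.path_length_nm,
        result.orientations_deg,
    )


def write_manifest(
    path: str | Path,
    command: str,
    inputs: dict,
    outputs: list[str],
    seed: int | None = None,
    config: AcquisitionConfig | None = None,
) -> None:
    """One manifest per CLI run: full provenance of what produced what."""
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tool": "uvqdpc",
        "version": __version__,
        "command": command,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
        "config": _config_to_dict(config) if config else None,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
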