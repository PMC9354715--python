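"""File formats: multi-page 32-bit float TIFF stacks with JSON sidecars.

A delay stack is stored as three files sharing a stem: ``<stem>.tif`` holds
the AC cube (one page per delay, 32-bit float), ``<stem>_dc.tif`` the DC
transmission image, and ``<stem>.json`` the acquisition metadata (delays in
ps, geometry, wavelengths).  Phantoms and pigment maps follow the same
multi-page-TIFF + sidecar pattern.  Round-trips are bit-exact at 32-bit
float precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .synthetic import AcquisitionMetadata, DelayStack, TissuePhantom
from .unmixing import PigmentMaps

__all__ = [
    "write_stack",
    "read_stack",
    "write_phantom",
    "read_phantom",
    "write_pigment_maps",
    "read_pigment_maps",
    "write_mask",
    "write_rgb_composite",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _dc_path(path: Path) -> Path:
    return path.with_name(path.stem + "_dc.tif")


def _dump_json(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_stack(stack: DelayStack, path: str | Path) -> None:
    """Write AC pages + DC image + metadata sidecar under one stem."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ac = np.moveaxis(stack.ac.astype(np.float32), -1, 0)  # (delay, row, col)
    tifffile.imwrite(path, ac, photometric="minisblack")
    tifffile.imwrite(_dc_path(path), stack.dc.astype(np.float32))
    _dump_json(_sidecar_path(path), dataclasses.asdict(stack.metadata))


def read_stack(path: str | Path) -> DelayStack:
    """Read a stack, validating page count, delay order and sidecar presence."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    doc = json.loads(sidecar.read_text())
    try:
        doc["delays_ps"] = tuple(doc["delays_ps"])
        metadata = AcquisitionMetadata(**doc)
    except (TypeError, KeyError) as exc:
        raise FormatError(f"invalid sidecar {sidecar}: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"sidecar {sidecar} violates metadata invariants: {exc}") from exc

    ac = tifffile.imread(path)
    if ac.ndim == 2:
        ac = ac[None, :, :]
    if ac.shape[0] != len(metadata.delays_ps):
        raise FormatError(
            f"{path} has {ac.shape[0]} pages but sidecar lists "
            f"{len(metadata.delays_ps)} delays"
        )
    dc_path = _dc_path(path)
    if not dc_path.exists():
        raise FormatError(f"missing DC image {dc_path}")
    dc = tifffile.imread(dc_path)
    return DelayStack(
        ac=np.moveaxis(ac, 0, -1).astype(np.float64),
        dc=dc.astype(np.float64),
        metadata=metadata,
    )


def write_phantom(phantom: TissuePhantom, path: str | Path, metadata: AcquisitionMetadata) -> None:
    """Labels as 8-bit page-0 TIFF; concentrations as a 2-page float TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path.with_name(path.stem + "_labels.tif"), phantom.labels.astype(np.uint8))
    conc = np.stack([phantom.conc_eu, phantom.conc_ph]).astype(np.float32)
    tifffile.imwrite(path.with_name(path.stem + "_conc.tif"), conc, photometric="minisblack")
    _dump_json(
        _sidecar_path(path),
        {"pixel_size_um": metadata.pixel_size_um, "pages": ["conc_eu", "conc_ph"]},
    )


def read_phantom(path: str | Path) -> TissuePhantom:
    path = Path(path)
    labels = tifffile.imread(path.with_name(path.stem + "_labels.tif"))
    conc = tifffile.imread(path.with_name(path.stem + "_conc.tif"))
    return TissuePhantom(
        labels=labels.astype(np.uint8),
        conc_eu=conc[0].astype(np.float64),
        conc_ph=conc[1].astype(np.float64),
    )


def write_pigment_maps(maps: PigmentMaps, path: str | Path) -> None:
    """2-page float TIFF (eumelanin, pheomelanin) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.stack([maps.eumelanin, maps.pheomelanin]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _dump_json(
        _sidecar_path(path),
        {
            "pages": ["eumelanin", "pheomelanin"],
            "source_delays_ps": list(maps.source_delays_ps),
            "dc_normalized": maps.dc_normalized,
        },
    )


def read_pigment_maps(path: str | Path) -> PigmentMaps:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    doc = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.shape[0] != 2:
        raise FormatError(f"{path}: expected 2 pages (eumelanin, pheomelanin)")
    return PigmentMaps(
        eumelanin=pages[0].astype(np.float64),
        pheomelanin=pages[1].astype(np.float64),
        source_delays_ps=tuple(doc.get("source_delays_ps", (0.0, 0.5))),
        dc_normalized=bool(doc.get("dc_normalized", True)),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))


def write_rgb_composite(maps: PigmentMaps, path: str | Path) -> None:
    """8-bit RGB rendering: eumelanin in red, pheomelanin in cyan."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _norm(img: np.ndarray) -> np.ndarray:
        peak = img.max()
        return img / peak if peak > 0 else img

    eu = _norm(maps.eumelanin)
    ph = _norm(maps.pheomelanin)
    rgb = np.stack([eu, ph, ph], axis=-1)
    tifffile.imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8), photometric="rgb")
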