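"""File formats: TIFF kymographs with JSON/YAML metadata sidecars.

Acquisition metadata (scan speed, line period, pixel size, direction) lives
in a sidecar file next to the image rather than in private TIFF tags, so it
survives any TIFF dialect.  Rows are time (line index), columns are position
along the vessel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .correction import Direction, ScanParameters
from .simulate import Kymograph

__all__ = [
    "AcquisitionMetadata",
    "MetadataError",
    "read_metadata",
    "write_metadata",
    "read_kymograph",
    "write_kymograph",
]

_REQUIRED = ("v_scan", "t_line", "x_pixel", "direction")


class MetadataError(ValueError):
    """Invalid or incomplete acquisition metadata."""


@dataclass
class AcquisitionMetadata:
    """Sidecar contents describing one line-scan recording.

    ``v_scan`` in mm/s, ``t_line`` in ms, ``x_pixel`` in um.  For
    bidirectional recordings ``n_pixels`` is per sweep (the image is twice
    as wide).  ``extra`` carries provenance (seed, simulation parameters).
    """

    v_scan: float
    t_line: float
    x_pixel: float
    direction: str
    bidirectional: bool = False
    n_pixels: int | None = None
    pixel_rate_hz: float | None = None
    extra: dict | None = None

    def to_scan_parameters(self, n_pixels: int) -> ScanParameters:
        return ScanParameters(
            v_scan=self.v_scan,
            direction=Direction.coerce(self.direction),
            t_line=self.t_line,
            x_pixel=self.x_pixel,
            n_pixels=n_pixels,
        )


def _load_sidecar(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return yaml.safe_load(text)


def read_metadata(path: str | Path) -> AcquisitionMetadata:
    data = _load_sidecar(Path(path))
    if not isinstance(data, dict):
        raise MetadataError(f"metadata file {path} does not contain a mapping")
    missing = [k for k in _REQUIRED if k not in data]
    if missing:
        raise MetadataError(
            f"metadata file {path} is missing required field(s): {', '.join(missing)}"
        )
    known = {f for f in AcquisitionMetadata.__dataclass_fields__}
    kwargs = {k: v for k, v in data.items() if k in known}
    kwargs["extra"] = {**(kwargs.get("extra") or {}), **{k: v for k, v in data.items() if k not in known}}
    meta = AcquisitionMetadata(**kwargs)
    bad = [k for k in ("v_scan", "t_line", "x_pixel") if not (getattr(meta, k) or 0) > 0]
    if bad:
        raise MetadataError(f"metadata field(s) must be positive: {', '.join(bad)}")
    return meta


def write_metadata(meta: AcquisitionMetadata, path: str | Path) -> None:
    data = {k: v for k, v in asdict(meta).items() if v is not None}
    path = Path(path)
    if str(path).endswith((".yaml", ".yml")):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=False) + "\n")


def read_kymograph(path: str | Path, metadata_path: str | Path) -> Kymograph:
    """Load a TIFF kymograph and its sidecar into a validated object.

    Accepts any integer or float pixel type (8- and 16-bit included); the
    image is converted to float.  The sidecar's ``n_pixels`` (if present)
    must be consistent with the image width.
    """
    meta = read_metadata(metadata_path)
    pixels = np.asarray(tifffile.imread(str(path)), dtype=float)
    if pixels.ndim != 2:
        raise MetadataError(f"expected a 2-D space-time image, got shape {pixels.shape}")
    width = pixels.shape[1]
    n_pixels = width // 2 if meta.bidirectional else width
    if meta.bidirectional and width % 2 != 0:
        raise MetadataError("bidirectional image must have an even number of columns")
    if meta.n_pixels is not None and meta.n_pixels != n_pixels:
        raise MetadataError(
            f"metadata n_pixels={meta.n_pixels} inconsistent with image width "
            f"{width} ({'2 sweeps' if meta.bidirectional else '1 sweep'})"
        )
    scan = meta.to_scan_parameters(n_pixels)
    return Kymograph(pixels=pixels, scan=scan, bidirectional=meta.bidirectional)


def write_kymograph(
    kymo: Kymograph,
    path: str | Path,
    metadata_path: str | Path | None = None,
    extra: dict | None = None,
) -> None:
    """Write the image as TIFF and the acquisition metadata as a sidecar."""
    tifffile.imwrite(str(path), kymo.pixels.astype(np.float32))
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".json")
    meta = AcquisitionMetadata(
        v_scan=kymo.scan.v_scan,
        t_line=kymo.scan.t_line,
        x_pixel=kymo.scan.x_pixel,
        direction=kymo.scan.direction.value,
        bidirectional=kymo.bidirectional,
        n_pixels=kymo.scan.n_pixels,
        extra=extra,
    )
    write_metadata(meta, metadata_path)
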