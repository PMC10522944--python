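"""Volume containers and file I/O.

Two containers are shared by every stage of the pipeline:

``GreyVolume``
    A 3D grey-value image as reconstructed from synchrotron micro-CT,
    stored as unsigned 16-bit intensities on an isotropic voxel grid.
``LabelVolume``
    A co-registered corrosion-phase map with four labels:
    0 background / soft tissue, 1 metallic Mg, 2 degraded Mg,
    3 severely degraded Mg.

Axis convention: axis 0 is the scaffold (stacking / vertical) axis;
voxels are isotropic and their edge length is carried in micrometres.

Volumes are written as multi-page TIFF stacks (one page per slice;
uint16 for grey data, uint8 for labels) with a JSON sidecar holding the
voxel size, seed and provenance, or as raw little-endian binary with the
same sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

VALID_LABELS = (0, 1, 2, 3)

LABEL_BACKGROUND = 0
LABEL_METAL = 1
LABEL_DEGRADED = 2
LABEL_SEVERE = 3


@dataclass
class GreyVolume:
    """3D intensity volume with voxel size and provenance metadata.

    ``metadata`` is a free-form record; it may carry beamline parameters
    (e.g. the Paganin length used during phase retrieval) purely as
    annotation -- nothing in the pipeline interprets them.
    """

    intensities: np.ndarray
    voxel_size_um: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.intensities.dtype != np.uint16:
            info = self.intensities
            if info.min() < 0 or info.max() > 65535:
                raise ValueError("intensities must lie in [0, 65535]")
            self.intensities = self.intensities.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def field_of_view_mm(self) -> tuple[float, float, float]:
        """Physical extent per axis in mm (e.g. 2048 voxels at 3.07 um
        span 6.3 mm)."""
        return tuple(n * self.voxel_size_um * 1e-3 for n in self.shape)


@dataclass
class LabelVolume:
    """Corrosion-phase label map on the same grid as its grey volume.

    ``axis_hint`` optionally records the nominal scaffold axis as a unit
    vector in voxel coordinates (default: axis 0).
    """

    labels: np.ndarray
    voxel_size_um: float
    axis_hint: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.labels.dtype != np.uint8:
            self.labels = self.labels.astype(np.uint8, casting="unsafe")
        bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
        if bad.size:
            raise ValueError(f"invalid label values present: {bad.tolist()}")
        if self.axis_hint is not None:
            ax = np.asarray(self.axis_hint, dtype=float)
            n = np.linalg.norm(ax)
            if n == 0:
                raise ValueError("axis_hint must be non-zero")
            self.axis_hint = ax / n

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def field_of_view_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_um * 1e-3 for n in self.shape)

    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: GreyVolume | LabelVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (``.tif``/``.tiff``) or raw
    little-endian binary (any other suffix), plus a JSON sidecar.

    Returns the path of the data file written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, GreyVolume):
        data = volume.intensities
        kind = "grey"
        meta = dict(volume.metadata)
    else:
        data = volume.labels
        kind = "labels"
        meta = {}
    sidecar = {
        "kind": kind,
        "voxel_size_um": float(volume.voxel_size_um),
        "shape": list(data.shape),
        "dtype": str(data.dtype),
        "metadata": meta,
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        data.astype(data.dtype.newbyteorder("<")).tofile(path)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> GreyVolume | LabelVolume:
    """Read a volume written by :func:`write_volume`.

    The JSON sidecar supplies voxel size, shape and dtype; for TIFF data
    without a sidecar, ``voxel_size_um`` must be given and the dtype
    decides the container (uint8 -> labels, uint16 -> grey).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_file = _sidecar_path(path)
    sidecar: dict[str, Any] | None = None
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())

    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        if sidecar is None:
            raise ValueError(f"raw volume {path} requires a JSON sidecar")
        data = np.fromfile(path, dtype=np.dtype(sidecar["dtype"]).newbyteorder("<"))
        data = data.reshape(sidecar["shape"]).astype(sidecar["dtype"])

    if sidecar is not None:
        vs = float(sidecar["voxel_size_um"])
        kind = sidecar.get("kind")
        expected = np.dtype(sidecar["dtype"])
        if data.dtype != expected:
            raise ValueError(
                f"dtype mismatch for {path}: sidecar says {expected}, file holds {data.dtype}"
            )
    else:
        if voxel_size_um is None:
            raise ValueError(f"no sidecar for {path} and no voxel size supplied")
        vs = float(voxel_size_um)
        kind = "labels" if data.dtype == np.uint8 else "grey"

    if kind == "labels":
        return LabelVolume(labels=data, voxel_size_um=vs)
    meta = sidecar.get("metadata", {}) if sidecar else {}
    return GreyVolume(intensities=data, voxel_size_um=vs, metadata=meta)
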