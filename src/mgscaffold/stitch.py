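"""Merging of vertically overlapping scans and 16-bit conversion.

A tall sample is imaged as three or four scans with roughly 750 um
vertical overlap; the reconstructed blocks are merged into one volume
and converted to 16-bit integers before analysis. The merge blends the
overlap linearly (seam-free under slight intensity drift) and can
optionally refine each pair's overlap by maximizing normalized
cross-correlation within +-10 slices of the nominal value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import GreyVolume

REFINE_WINDOW = 10  # slices searched either side of the nominal overlap
MIN_CORRELATION = 0.5


@dataclass
class ScanSeries:
    """Ordered bottom-to-top scans sharing voxel size and lateral shape."""

    scans: list[GreyVolume]
    nominal_overlap_um: float

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError("ScanSeries needs at least one scan")
        vs = self.scans[0].voxel_size_um
        lat = self.scans[0].shape[1:]
        for s in self.scans[1:]:
            if s.voxel_size_um != vs:
                raise ValueError("all scans must share the voxel size")
            if s.shape[1:] != lat:
                raise ValueError("all scans must share lateral dimensions")
        if self.nominal_overlap_um < 0:
            raise ValueError("overlap must be >= 0")

    @property
    def overlap_slices(self) -> int:
        return int(round(self.nominal_overlap_um / self.scans[0].voxel_size_um))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def _refine_overlap(bottom: np.ndarray, top: np.ndarray, nominal: int) -> int:
    """Best overlap (slices) by NCC on a central lateral crop."""
    ny, nx = bottom.shape[1:]
    cy, cx = ny // 4, nx // 4
    sl = (slice(cy, ny - cy or None), slice(cx, nx - cx or None))
    best_ov, best_c = nominal, -np.inf
    max_ov = min(bottom.shape[0], top.shape[0]) - 1
    for ov in range(max(1, nominal - REFINE_WINDOW), min(max_ov, nominal + REFINE_WINDOW) + 1):
        c = _ncc(bottom[-ov:, sl[0], sl[1]], top[:ov, sl[0], sl[1]])
        if c > best_c:
            best_ov, best_c = ov, c
    if best_c < MIN_CORRELATION:
        warnings.warn(
            f"overlap refinement found no correlation above {MIN_CORRELATION} "
            f"(best {best_c:.3f}); falling back to nominal overlap {nominal}",
            stacklevel=3,
        )
        return nominal
    return best_ov


def stitch_scans(series: ScanSeries, refine: bool = False) -> GreyVolume:
    """Merge overlapping scans into one volume.

    Output height is sum of scan heights minus the per-pair overlaps.
    Overlap regions are filled with a linear blend from the lower to the
    upper scan; identical overlap data therefore pass through unchanged,
    making split -> stitch an exact round trip.
    """
    scans = series.scans
    if len(scans) == 1:
        return GreyVolume(
            scans[0].intensities.copy(),
            scans[0].voxel_size_um,
            metadata=dict(scans[0].metadata),
        )
    nominal = series.overlap_slices
    for s in scans:
        if s.shape[0] <= nominal:
            raise ValueError("nominal overlap not smaller than a scan height")

    dtype = scans[0].intensities.dtype
    merged = scans[0].intensities.astype(np.float64)
    for nxt_vol in scans[1:]:
        nxt = nxt_vol.intensities.astype(np.float64)
        ov = _refine_overlap(merged, nxt, nominal) if refine else nominal
        if ov == 0:
            merged = np.concatenate([merged, nxt], axis=0)
            continue
        w = (np.arange(1, ov + 1) / (ov + 1.0))[:, None, None]
        a = merged[-ov:]
        blend = a + w * (nxt[:ov] - a)
        merged = np.concatenate([merged[:-ov], blend, nxt[ov:]], axis=0)
    out = np.clip(np.rint(merged), 0, np.iinfo(dtype).max).astype(dtype)
    return GreyVolume(
        out,
        scans[0].voxel_size_um,
        metadata={"n_scans": len(scans), "nominal_overlap_um": series.nominal_overlap_um},
    )


def to_uint16(
    volume: GreyVolume, clip_low: float = 0.1, clip_high: float = 99.9
) -> GreyVolume:
    """Linearly rescale [P_low, P_high] percentiles to the full 16-bit range.

    Values outside the window are clipped. On data already spanning
    [0, 65535] with clips (0, 100) the mapping is the identity. A
    constant volume maps to zero with a warning.
    """
    if not (0 <= clip_low < clip_high <= 100):
        raise ValueError("need 0 <= clip_low < clip_high <= 100")
    data = volume.intensities.astype(np.float64)
    lo, hi = np.percentile(data, [clip_low, clip_high])
    if hi == lo:
        warnings.warn("constant-valued volume; mapping to zero", stacklevel=2)
        out = np.zeros_like(volume.intensities, dtype=np.uint16)
    else:
        scaled = (np.clip(data, lo, hi) - lo) / (hi - lo) * 65535.0
        out = np.rint(scaled).astype(np.uint16)
    meta = dict(volume.metadata)
    meta["rescale_percentiles"] = [clip_low, clip_high]
    return GreyVolume(out, volume.voxel_size_um, metadata=meta)
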