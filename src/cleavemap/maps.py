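"""Strand-specific cleavage maps: build, normalize, mask, smooth.

A :class:`StrandMap` holds one per-position value vector per strand of a
single reference. Raw maps carry read counts; normalized maps carry RPM
(reads per million mapped reads), the unit in which peak-calling thresholds
are expressed. The RPM denominator is the total mapped read count on both
strands before masking. Smoothing with a Hann window is a display aid for
overview profiles only — peak calling, composition and cross-correlation
operate on unsmoothed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal.windows import hann

from cleavemap.errors import DataError
from cleavemap.synth import ReferenceSequence, StrandRead, Topology


@dataclass(frozen=True)
class StrandMap:
    """Paired per-position top/bottom value tracks over one reference."""

    ref_name: str
    length: int
    topology: Topology
    top: np.ndarray
    bottom: np.ndarray
    units: Literal["raw", "rpm"] = "raw"
    total_mapped: int = 0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        top = np.asarray(self.top, dtype=float)
        bottom = np.asarray(self.bottom, dtype=float)
        if top.shape != (self.length,) or bottom.shape != (self.length,):
            raise DataError("track length does not match reference length")
        mask = self.mask
        if mask is None:
            mask = np.zeros(self.length, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.length,):
            raise DataError("mask length does not match reference length")
        if (top[~mask] < 0).any() or (bottom[~mask] < 0).any():
            raise DataError("unmasked track values must be >= 0")
        object.__setattr__(self, "top", top)
        object.__setattr__(self, "bottom", bottom)
        object.__setattr__(self, "mask", mask)

    def strand(self, which: str) -> np.ndarray:
        if which not in ("top", "bottom"):
            raise DataError(f"unknown strand {which!r}")
        return self.top if which == "top" else self.bottom

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean selector of positions included in downstream statistics."""
        return ~self.mask


def build_strand_map(reads: Iterable[StrandRead], ref: ReferenceSequence) -> StrandMap:
    """Count read 5'-end positions per strand into a raw map."""
    n = len(ref)
    top = np.zeros(n)
    bottom = np.zeros(n)
    total = 0
    for r in reads:
        if not 0 <= r.pos < n:
            raise DataError(f"read at {r.pos} beyond reference {ref.name!r} of length {n}")
        (top if r.strand == "top" else bottom)[r.pos] += 1
        total += 1
    return StrandMap(
        ref_name=ref.name,
        length=n,
        topology=ref.topology,
        top=top,
        bottom=bottom,
        units="raw",
        total_mapped=total,
    )


def normalize_rpm(smap: StrandMap) -> StrandMap:
    """Convert a raw map to reads per million mapped reads."""
    if smap.units != "raw":
        raise DataError("map is already normalized to RPM")
    if smap.total_mapped <= 0:
        raise DataError("cannot normalize a map with zero mapped reads")
    factor = 1e6 / smap.total_mapped
    return replace(smap, top=smap.top * factor, bottom=smap.bottom * factor, units="rpm")


def mask_regions(smap: StrandMap, regions: Sequence) -> StrandMap:
    """Exclude positions inside the given regions from downstream statistics.

    ``total_mapped`` (hence RPM scaling) is unchanged: masking removes
    positions from statistics, not reads from the library.
    """
    mask = smap.mask.copy()
    for region in regions:
        if region.ref_name != smap.ref_name:
            raise DataError(
                f"region on {region.ref_name!r} does not match map reference {smap.ref_name!r}"
            )
        if region.end > smap.length:
            raise DataError(f"region [{region.start},{region.end}) outside reference")
        mask[region.start : region.end] = True
    return replace(smap, mask=mask)


def smooth_hann(
    track: np.ndarray, window: int = 21, topology: Topology = "linear"
) -> np.ndarray:
    """Smooth a track with a unit-sum Hann window (display only).

    The window is the symmetric Hann taper ``w(n) = 0.5*(1 - cos(2*pi*n/(M-1)))``
    normalized to unit sum. Circular topology wraps around the origin and
    conserves the track total exactly; linear topology truncates the kernel
    at the edges and renormalizes so a constant track stays constant.
    """
    if window % 2 == 0 or window < 3:
        raise DataError(f"window must be odd and >= 3, got {window}")
    track = np.asarray(track, dtype=float)
    if window > len(track):
        raise DataError("window longer than track")
    kernel = hann(window, sym=True)
    kernel = kernel / kernel.sum()
    if topology == "circular":
        return convolve1d(track, kernel, mode="wrap")
    smoothed = np.convolve(track, kernel, mode="same")
    coverage = np.convolve(np.ones_like(track), kernel, mode="same")
    return smoothed / coverage
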