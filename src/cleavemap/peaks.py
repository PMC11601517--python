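"""Strand-specific peak calling with the incomplete-fill-in artifact filter.

Peaks are defined exactly as RPM-threshold exceedances per strand — no
local-maximum or FDR machinery. Incomplete fill-in of the 2-nt 5' overhang
misassigns reads one nucleotide inward of the true cleavage position, so a
candidate position whose inward (5') neighbor on the same strand carries
more signal is discarded as a likely artifact: a top-strand position x is
dropped when top[x] < top[x-1], a bottom-strand position x when
bottom[x] < bottom[x+1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from cleavemap.errors import DataError
from cleavemap.maps import StrandMap

#: Strand-specific RPM thresholds used for plasmid-scale and genomic maps.
THRESHOLD_PRESETS = {"plasmid": 3000.0, "ecoli": 10.0, "yeast": 15.0}


@dataclass(frozen=True)
class Peak:
    pos: int
    strand: str
    score: float


def call_peaks(smap: StrandMap, threshold: float = THRESHOLD_PRESETS["plasmid"]) -> list[Peak]:
    """All unmasked positions with strand-specific RPM strictly above threshold."""
    if smap.units != "rpm":
        raise DataError("peak calling requires an RPM-normalized map")
    peaks = []
    for strand in ("top", "bottom"):
        track = smap.strand(strand)
        for pos in range(smap.length):
            if smap.mask[pos]:
                continue
            if track[pos] > threshold:
                peaks.append(Peak(pos=pos, strand=strand, score=float(track[pos])))
    return peaks


def _neighbor_value(smap: StrandMap, strand: str, pos: int) -> float:
    """Same-strand value at a neighboring position; 0 outside a linear end or masked."""
    if smap.topology == "circular":
        pos %= smap.length
    elif pos < 0 or pos >= smap.length:
        return 0.0
    if smap.mask[pos]:
        return 0.0
    return float(smap.strand(strand)[pos])


def filter_fillin_artifacts(peaks: Sequence[Peak], smap: StrandMap) -> list[Peak]:
    """Drop candidate peaks that look like inward-shifted fill-in artifacts.

    The comparison direction (top vs its x-1 neighbor, bottom vs x+1) is the
    reading that removes the one-nucleotide-inward shift this library
    chemistry produces; it is isolated here so an alternative reading can be
    swapped in.
    """
    kept = []
    for pk in peaks:
        inward_neighbor = pk.pos - 1 if pk.strand == "top" else pk.pos + 1
        if smap.strand(pk.strand)[pk.pos] < _neighbor_value(smap, pk.strand, inward_neighbor):
            continue
        kept.append(pk)
    return kept


def top_n_peaks(peaks: Sequence[Peak], n: int = 50) -> list[Peak]:
    """The n highest-score peaks, both strands pooled, ties by position."""
    if n < 1:
        raise DataError("n must be >= 1")
    return sorted(peaks, key=lambda p: (-p.score, p.pos))[:n]
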