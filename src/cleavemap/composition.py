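"""Dyad-oriented base composition, GC-corrected logos, symmetry and motifs.

Every peak is reoriented into the dyad frame before sequences are pooled:
the adaptor-adjacent nucleotide sits at relative position -1 on the top
strand of the oriented window, so top- and bottom-strand peaks of the same
double-strand break yield exact reverse-complement windows. Dyad-relative
positions are numbered -N..-1,+1..+N with no position 0 (the dyad axis lies
between -1 and +1).

Logo letter heights follow the background-relative-entropy convention:
per-position information R = sum_b f_b * log2(f_b / q_b) against a
background determined solely by a G+C fraction, and each letter is drawn
with height f_b * R. Rotational symmetry of a composition matrix is scored
as the mean absolute deviation from the identity
f(p, b) == f(-p, complement(b)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cleavemap.errors import DataError
from cleavemap.maps import StrandMap
from cleavemap.peaks import Peak
from cleavemap.synth import (
    BASES,
    IUPAC_CODES,
    _BASE_INDEX,
    _COMPLEMENT_INDEX,
    ReferenceSequence,
    reverse_complement,
)


def _relative_positions(halfwidth: int) -> list[int]:
    return list(range(-halfwidth, 0)) + list(range(1, halfwidth + 1))


@dataclass(frozen=True)
class CompositionMatrix:
    """Per-dyad-position base fractions pooled over n_sites oriented windows."""

    halfwidth: int
    fractions: np.ndarray  # (2N, 4) rows in -N..-1,+1..+N order, cols A,C,G,T
    n_sites: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (2 * self.halfwidth, 4):
            raise DataError("fractions shape does not match halfwidth")
        if self.n_sites < 1:
            raise DataError("n_sites must be >= 1")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("base fractions must sum to 1 at every position")
        object.__setattr__(self, "fractions", f)

    @property
    def relative_positions(self) -> list[int]:
        return _relative_positions(self.halfwidth)

    def row_index(self, rel_pos: int) -> int:
        N = self.halfwidth
        if rel_pos == 0 or abs(rel_pos) > N:
            raise DataError(f"relative position {rel_pos} outside +/-{N} (no 0)")
        return rel_pos + N if rel_pos < 0 else N + rel_pos - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions,
            index=pd.Index(self.relative_positions, name="position"),
            columns=list(BASES),
        )


@dataclass(frozen=True)
class LogoMatrix:
    """Background-corrected letter heights in bits, plus the background used."""

    halfwidth: int
    heights: np.ndarray  # (2N, 4), f_b * R per letter
    information: np.ndarray  # (2N,), per-position relative entropy R
    background: np.ndarray  # (4,)

    @property
    def relative_positions(self) -> list[int]:
        return _relative_positions(self.halfwidth)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.heights,
            index=pd.Index(self.relative_positions, name="position"),
            columns=list(BASES),
        )


def extract_dyad_window(ref: ReferenceSequence, peak: Peak, halfwidth: int) -> str:
    """Oriented 2N-mer over dyad-relative positions -N..-1,+1..+N.

    A top-strand peak at x is read directly off the top strand with x at
    relative -1. A bottom-strand peak at x is read off the bottom strand
    (reverse complement) so that x again lands at relative -1 of the
    reoriented window. The two windows of one double-strand break are exact
    reverse complements of each other.
    """
    if halfwidth < 1:
        raise DataError("halfwidth must be >= 1")
    x = peak.pos
    if peak.strand == "top":
        return ref.fetch(x - halfwidth + 1, x + halfwidth + 1)
    if peak.strand == "bottom":
        return reverse_complement(ref.fetch(x - halfwidth, x + halfwidth))
    raise DataError(f"unknown strand {peak.strand!r}")


def composition_matrix(windows: Sequence[str]) -> CompositionMatrix:
    """Column-wise base frequencies of equal-width oriented windows."""
    if not windows:
        raise DataError("at least one window is required")
    width = len(windows[0])
    if width % 2 != 0 or width == 0:
        raise DataError("window width must be even and positive (no position 0)")
    counts = np.zeros((width, 4))
    for w in windows:
        if len(w) != width:
            raise DataError("windows have unequal widths")
        for i, ch in enumerate(w.upper()):
            if ch not in _BASE_INDEX:
                raise DataError(f"non-ACGT base {ch!r} in window")
            counts[i, _BASE_INDEX[ch]] += 1
    return CompositionMatrix(
        halfwidth=width // 2,
        fractions=counts / counts.sum(axis=1, keepdims=True),
        n_sites=len(windows),
    )


def gc_corrected_logo(comp: CompositionMatrix, background_gc: float) -> LogoMatrix:
    """Logo heights relative to a background set by a G+C fraction.

    Background is {A: (1-gc)/2, C: gc/2, G: gc/2, T: (1-gc)/2}; the
    per-position information is the Kullback-Leibler divergence (base 2) of
    the observed base fractions from that background, and each letter gets
    height f_b * R. The background GC can be a genome average or a local
    override around the mapped sites when the two differ substantially.
    """
    if not 0.0 < background_gc < 1.0:
        raise DataError("background GC must be strictly between 0 and 1")
    bg = np.array(
        [(1 - background_gc) / 2, background_gc / 2, background_gc / 2, (1 - background_gc) / 2]
    )
    f = comp.fractions
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / bg[None, :]), 0.0)
    info = terms.sum(axis=1)
    info = np.maximum(info, 0.0)  # KL >= 0; clip numerical dust
    return LogoMatrix(
        halfwidth=comp.halfwidth,
        heights=f * info[:, None],
        information=info,
        background=bg,
    )


def symmetry_score(comp: CompositionMatrix) -> float:
    """Mean |f(p, b) - f(-p, complement(b))| over p > 0 and bases; 0 = symmetric."""
    devs = []
    for p in range(1, comp.halfwidth + 1):
        fwd = comp.fractions[comp.row_index(p)]
        rev = comp.fractions[comp.row_index(-p)][_COMPLEMENT_INDEX]
        devs.append(np.abs(fwd - rev))
    return float(np.mean(devs))


def motif_scan(
    ref: ReferenceSequence,
    pattern: str,
    regions: Sequence | None = None,
    scan_bottom: bool = False,
) -> list[int]:
    """0-based top-strand start positions of exact degenerate matches.

    ``pattern`` is an IUPAC string; all overlapping matches are reported.
    With ``scan_bottom`` the reverse complement of the pattern is scanned as
    well (still reported as top-strand start positions) — moot for
    self-reverse-complementary patterns like GNATNC and CNTANG. Circular
    references include matches spanning the origin. ``regions`` restricts
    matches to those fully inside a region on the same reference.
    """
    pattern = pattern.upper()
    allowed = []
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise DataError(f"invalid IUPAC letter {ch!r}")
        allowed.append(set(IUPAC_CODES[ch]))
    patterns = [allowed]
    if scan_bottom:
        rc = reverse_complement_pattern(pattern)
        patterns.append([set(IUPAC_CODES[ch]) for ch in rc])

    m = len(pattern)
    n = len(ref)
    if m > n:
        return []
    seq = ref.seq + (ref.seq[: m - 1] if ref.topology == "circular" else "")
    n_starts = n if ref.topology == "circular" else n - m + 1
    hits = set()
    for pat in patterns:
        for start in range(n_starts):
            if all(seq[start + i] in pat[i] for i in range(m)):
                hits.add(start)
    positions = sorted(hits)
    if regions is not None:
        keep = []
        for pos in positions:
            for region in regions:
                if region.ref_name == ref.name and region.start <= pos and pos + m <= region.end:
                    keep.append(pos)
                    break
        positions = keep
    return positions


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (N<->N, R<->Y, etc.)."""
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A",
        "R": "Y", "Y": "R", "S": "S", "W": "W",
        "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    }
    return "".join(comp[ch] for ch in reversed(pattern.upper()))


@dataclass(frozen=True)
class AverageProfile:
    """Anchored strand-specific profiles: means plus the per-anchor matrices."""

    offsets: np.ndarray  # -H..+H, anchor at 0
    top: np.ndarray  # (2H+1,) mean
    bottom: np.ndarray
    matrix_top: np.ndarray  # (n_anchors, 2H+1) for heat-map rendering
    matrix_bottom: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"top": self.top, "bottom": self.bottom},
            index=pd.Index(self.offsets, name="offset"),
        )


def average_profile_around(
    smap: StrandMap, anchors: Sequence[int], halfwidth: int
) -> AverageProfile:
    """Mean strand-specific signal in windows centered on anchor positions."""
    if len(anchors) == 0:
        raise DataError("anchor list is empty")
    if halfwidth < 1:
        raise DataError("halfwidth must be >= 1")
    n = smap.length
    offsets = np.arange(-halfwidth, halfwidth + 1)
    rows_t, rows_b = [], []
    for a in anchors:
        if not 0 <= a < n:
            raise DataError(f"anchor {a} outside reference")
        if smap.mask[a]:
            raise DataError(f"anchor {a} is masked")
        idx = a + offsets
        if smap.topology == "circular":
            idx = idx % n
        elif idx[0] < 0 or idx[-1] >= n:
            raise DataError(f"window around anchor {a} out of range on linear reference")
        rows_t.append(smap.top[idx])
        rows_b.append(smap.bottom[idx])
    matrix_top = np.vstack(rows_t)
    matrix_bottom = np.vstack(rows_b)
    return AverageProfile(
        offsets=offsets,
        top=matrix_top.mean(axis=0),
        bottom=matrix_bottom.mean(axis=0),
        matrix_top=matrix_top,
        matrix_bottom=matrix_bottom,
    )
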