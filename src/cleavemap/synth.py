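"""Synthetic cleavage libraries with sequence bias and library-prep artifacts.

The generator emulates a topoisomerase-like enzyme that cuts duplex DNA
leaving a 2-nt 5' overhang. The middle of the overhang is a twofold
rotational symmetry axis (the *dyad axis*); dyad-relative positions are
numbered ...,-2,-1,+1,+2,... with no position 0. Internally the event is
anchored at ``dyad_left``, the 0-based coordinate of relative position -1,
so the axis lies between ``dyad_left`` and ``dyad_left + 1``.

Library preparation is modeled after end-capture protocols in which the
covalently attached protein is removed, the 5' overhang is filled in, an
adaptor is ligated and the read is assigned to the nucleotide immediately
next to the adaptor. A double-strand break at ``dyad_left = p`` therefore
produces a top-strand read at ``p`` and a bottom-strand read at ``p + 1``
(the two reads "overlap", giving a +1 strand-to-strand offset). Incomplete
fill-in before ligation misassigns a read one nucleotide inward, the
artifact the downstream peak filter must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from cleavemap.errors import DataError

Topology = Literal["circular", "linear"]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC degenerate nucleotide codes, mapped to the set of bases they match.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named DNA sequence with linear or circular topology."""

    name: str
    seq: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise DataError(f"reference {self.name!r} is empty")
        if self.topology not in ("circular", "linear"):
            raise DataError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def base_indices(self) -> np.ndarray:
        """Sequence as integer codes 0..3 for A,C,G,T (cached per call)."""
        arr = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        out = np.full(arr.shape, -1, dtype=np.int64)
        for base, idx in _BASE_INDEX.items():
            out[arr == ord(base)] = idx
        if (out < 0).any():
            raise DataError(f"reference {self.name!r} contains non-ACGT characters")
        return out

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); circular references wrap, linear raise."""
        n = len(self.seq)
        if end <= start:
            raise DataError(f"empty window [{start}, {end})")
        if self.topology == "circular":
            idx = np.arange(start, end) % n
            return "".join(self.seq[i] for i in idx)
        if start < 0 or end > n:
            raise DataError(
                f"window [{start}, {end}) out of range for linear reference "
                f"{self.name!r} of length {n}"
            )
        return self.seq[start:end]


@dataclass(frozen=True)
class BiasModel:
    """Position-specific multiplicative base preference around the dyad axis.

    ``weights`` has one row per dyad-relative position -W..-1,+1..+W (in that
    order) and one column per base A,C,G,T; entries are strictly positive
    preference factors. ``strength`` is a global exponent: 0 turns the model
    off, larger values sharpen site selection (the generative inverse of a
    measured base-composition bias).
    """

    halfwidth: int
    weights: np.ndarray
    strength: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.halfwidth < 1:
            raise DataError("halfwidth must be >= 1")
        if w.shape != (2 * self.halfwidth, 4):
            raise DataError(
                f"weights shape {w.shape} does not match halfwidth {self.halfwidth}"
            )
        if not (w > 0).all():
            raise DataError("all bias weights must be > 0")
        if self.strength < 0:
            raise DataError("strength must be >= 0")
        object.__setattr__(self, "weights", w)

    @property
    def relative_positions(self) -> list[int]:
        """Dyad-relative positions in row order: -W..-1, +1..+W (no 0)."""
        W = self.halfwidth
        return list(range(-W, 0)) + list(range(1, W + 1))

    def row_index(self, rel_pos: int) -> int:
        W = self.halfwidth
        if rel_pos == 0 or abs(rel_pos) > W:
            raise DataError(f"relative position {rel_pos} outside +/-{W} (no 0)")
        return rel_pos + W if rel_pos < 0 else W + rel_pos - 1

    def is_symmetric(self, atol: float = 1e-12) -> bool:
        """True if weights(p, b) == weights(-p, complement(b)) for all p, b."""
        for p in range(1, self.halfwidth + 1):
            fwd = self.weights[self.row_index(p)]
            rev = self.weights[self.row_index(-p)][_COMPLEMENT_INDEX]
            if not np.allclose(fwd, rev, atol=atol, rtol=0.0):
                return False
        return True

    def expected_composition(self, background: Sequence[float] | None = None) -> np.ndarray:
        """Per-position base fractions the model favors on a given background.

        For independently drawn flanking bases this is the composition a large
        sampled library converges to: ``q_b * w(p,b)**strength``, normalized per
        position. Default background is uniform (GC = 0.5).
        """
        q = np.full(4, 0.25) if background is None else np.asarray(background, float)
        m = (self.weights ** self.strength) * q[None, :]
        return m / m.sum(axis=1, keepdims=True)

    @classmethod
    def uniform(cls, halfwidth: int) -> "BiasModel":
        """All-ones weights: every site equally cleavable."""
        return cls(halfwidth=halfwidth, weights=np.ones((2 * halfwidth, 4)), strength=1.0)

    @classmethod
    def from_motif(cls, motif: str, favor: float = 10.0, strength: float = 1.0) -> "BiasModel":
        """Bias model favoring bases matching an even-length IUPAC motif.

        The motif is centered on the dyad axis: a 6-mer such as GNATNC spans
        relative positions -3..+3. At each determinate position the matching
        base(s) get weight ``favor``; everything else (and every base under
        N) gets weight 1.
        """
        if len(motif) % 2 != 0 or not motif:
            raise DataError("motif length must be even and positive (dyad-centered)")
        motif = motif.upper()
        for ch in motif:
            if ch not in IUPAC_CODES:
                raise DataError(f"invalid IUPAC letter {ch!r} in motif")
        W = len(motif) // 2
        weights = np.ones((2 * W, 4))
        for row, ch in enumerate(motif):
            allowed = IUPAC_CODES[ch]
            if len(allowed) == 4:
                continue
            for b in allowed:
                weights[row, _BASE_INDEX[b]] = favor
        return cls(halfwidth=W, weights=weights, strength=strength)

    @classmethod
    def symmetric_gnatnc(cls, favor: float = 10.0, strength: float = 1.0) -> "BiasModel":
        """The canonical rotationally symmetric dyad signature (G-N-A|T-N-C).

        G at -3 pairs with C at +3 and A at -1 with T at +1 under rotational
        symmetry, so this motif model already satisfies
        weights(p, b) == weights(-p, complement(b)).
        """
        model = cls.from_motif("GNATNC", favor=favor, strength=strength)
        assert model.is_symmetric()
        return model


@dataclass(frozen=True)
class LibraryPrepParams:
    """Library-preparation realism knobs.

    p_nick
        Probability a cleavage event is a single-strand nick rather than a
        DSB (nicks split between strands per ``nick_top_fraction``).
    f_partial
        Probability a read is misassigned one nucleotide inward by
        incomplete fill-in of the 5' overhang (top: p -> p+1, bottom:
        p+1 -> p).
    background_rate
        Expected uniform background reads per position per strand (Poisson),
        emulating a catalytically dead nonspecific control.
    reads_per_event
        Mean read multiplicity per cleaved end (Poisson, shared by the two
        ends of a DSB).
    """

    p_nick: float = 0.0
    f_partial: float = 0.0
    background_rate: float = 0.0
    reads_per_event: float = 1.0
    nick_top_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_nick", "f_partial", "nick_top_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.background_rate < 0 or self.reads_per_event < 0:
            raise DataError("rates must be >= 0")


@dataclass(frozen=True)
class CleavageEvent:
    """A nick or DSB anchored at ``dyad_left`` (coordinate of relative -1)."""

    dyad_left: int
    kind: Literal["dsb", "nick_top", "nick_bottom"] = "dsb"

    def __post_init__(self) -> None:
        if self.kind not in ("dsb", "nick_top", "nick_bottom"):
            raise DataError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class StrandRead:
    """A strand-assigned read 5'-end position (the adaptor-adjacent base)."""

    pos: int
    strand: Literal["top", "bottom"]

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise DataError(f"unknown strand {self.strand!r}")


def generate_reference(
    length: int,
    gc: float = 0.5,
    topology: Topology = "circular",
    seed: int = 0,
    name: str = "synthetic",
) -> ReferenceSequence:
    """Random reference with i.i.d. bases at the requested GC content.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2. Deterministic under a
    fixed seed and parameter set.
    """
    if length < 1:
        raise DataError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise DataError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    seq = "".join(BASES[i] for i in idx)
    return ReferenceSequence(name=name, seq=seq, topology=topology)


def _window_positions(dyad_left: int, halfwidth: int) -> np.ndarray:
    """Absolute coordinates of relative positions -W..-1,+1..+W (unwrapped)."""
    W = halfwidth
    left = np.arange(dyad_left - W + 1, dyad_left + 1)       # -W..-1
    right = np.arange(dyad_left + 1, dyad_left + W + 1)      # +1..+W
    return np.concatenate([left, right])


def site_weight(model: BiasModel, ref: ReferenceSequence, dyad_left: int) -> float:
    """Relative cleavability of the dyad anchored at ``dyad_left``.

    Returns ``(prod_p weights(p, base_at(p)))**strength`` over the model's
    2W dyad-relative positions. Circular references wrap; a linear reference
    whose window runs off an end raises.
    """
    n = len(ref)
    pos = _window_positions(dyad_left, model.halfwidth)
    if ref.topology == "circular":
        pos = pos % n
    elif pos[0] < 0 or pos[-1] >= n:
        raise DataError(
            f"bias window around dyad_left={dyad_left} out of range for "
            f"linear reference of length {n}"
        )
    codes = ref.base_indices[pos]
    w = float(np.prod(model.weights[np.arange(len(pos)), codes]))
    return w ** model.strength


def site_weights(model: BiasModel, ref: ReferenceSequence) -> np.ndarray:
    """Vector of site weights at every dyad_left position.

    Circular references return a length-L vector; linear references return
    a length-L vector with zeros at positions whose window is out of range.
    """
    n = len(ref)
    codes = ref.base_indices
    logw = np.log(model.weights)
    total = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    rel = model.relative_positions
    for row, p in enumerate(rel):
        offset = p + 1 if p < 0 else p
        pos = np.arange(n) + offset
        if ref.topology == "circular":
            pos %= n
            total += logw[row, codes[pos]]
        else:
            ok = (pos >= 0) & (pos < n)
            valid &= ok
            total[ok] += logw[row, codes[pos[ok]]]
    out = np.exp(model.strength * total)
    out[~valid] = 0.0
    return out


def sample_cleavage_events(
    ref: ReferenceSequence,
    model: BiasModel,
    n_events: int,
    prep: LibraryPrepParams,
    seed: int = 0,
) -> list[CleavageEvent]:
    """Draw cleavage events with replacement, P(site) proportional to weight.

    Event kind is a nick with probability ``prep.p_nick`` (split between
    strands by ``prep.nick_top_fraction``), otherwise a DSB.
    """
    if n_events < 0:
        raise DataError("n_events must be >= 0")
    if n_events == 0:
        return []
    w = site_weights(model, ref)
    total = w.sum()
    if total <= 0:
        raise DataError("no valid cleavage site on this reference")
    rng = np.random.default_rng(seed)
    sites = rng.choice(len(w), size=n_events, p=w / total)
    u = rng.random(n_events)
    v = rng.random(n_events)
    events = []
    for s, is_nick_u, strand_v in zip(sites, u, v):
        if is_nick_u < prep.p_nick:
            kind = "nick_top" if strand_v < prep.nick_top_fraction else "nick_bottom"
        else:
            kind = "dsb"
        events.append(CleavageEvent(dyad_left=int(s), kind=kind))
    return events


def simulate_library(
    events: Sequence[CleavageEvent],
    prep: LibraryPrepParams,
    ref_length: int,
    topology: Topology = "circular",
    seed: int = 0,
) -> list[StrandRead]:
    """Turn cleavage events into strand-assigned read positions.

    A DSB at dyad_left = p yields top reads at p and bottom reads at p+1
    (mod length when circular), each end replicated by a single Poisson
    multiplicity shared by both ends (so DSB libraries are exactly
    strand-balanced). A nick yields reads on its strand only. Each read is
    independently shifted one nucleotide inward with probability
    ``f_partial`` (top p -> p+1, bottom p+1 -> p), emulating incomplete
    fill-in of the 2-nt 5' overhang. Uniform Poisson background reads are
    added per position per strand at ``background_rate``.
    """
    rng = np.random.default_rng(seed)
    n = ref_length
    reads: list[StrandRead] = []

    def emit(pos: int, strand: str, count: int) -> None:
        if count <= 0:
            return
        if topology == "circular":
            pos %= n
        elif pos < 0 or pos >= n:
            raise DataError(
                f"read position {pos} out of range for linear reference of length {n}"
            )
        shifted = int(rng.binomial(count, prep.f_partial)) if prep.f_partial > 0 else 0
        inward = 1 if strand == "top" else -1
        for _ in range(count - shifted):
            reads.append(StrandRead(pos=pos, strand=strand))
        if shifted:
            spos = pos + inward
            if topology == "circular":
                spos %= n
            elif spos < 0 or spos >= n:
                raise DataError("fill-in shift out of range on linear reference")
            for _ in range(shifted):
                reads.append(StrandRead(pos=spos, strand=strand))

    for ev in events:
        p = ev.dyad_left
        if topology == "linear" and ev.kind in ("dsb", "nick_bottom") and p + 1 >= n:
            raise DataError(
                f"event at dyad_left={p} needs position {p + 1}, beyond linear reference"
            )
        mult = int(rng.poisson(prep.reads_per_event))
        if ev.kind in ("dsb", "nick_top"):
            emit(p, "top", mult)
        if ev.kind in ("dsb", "nick_bottom"):
            emit(p + 1, "bottom", mult)

    if prep.background_rate > 0:
        for strand in ("top", "bottom"):
            counts = rng.poisson(prep.background_rate, size=n)
            for pos in np.nonzero(counts)[0]:
                for _ in range(int(counts[pos])):
                    reads.append(StrandRead(pos=int(pos), strand=strand))
    return reads
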