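"""Readers and writers for FASTA, BED6, bedGraph pairs and YAML config.

Conventions:

- reads are BED6 single-base intervals; strand ``+`` is the top strand,
  ``-`` the bottom strand;
- a strand map is serialized as one bedGraph file per strand, runs of equal
  value compressed into one interval; masked positions are emitted as
  *absent* intervals (not zeros), so "no signal" and "excluded" stay
  distinguishable on disk.

All readers raise :class:`~cleavemap.errors.DataError` with the offending
file and line number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cleavemap.errors import DataError
from cleavemap.maps import StrandMap
from cleavemap.synth import IUPAC_CODES, ReferenceSequence, StrandRead, Topology

logger = logging.getLogger("cleavemap")


@dataclass(frozen=True)
class Region:
    """A 0-based half-open interval on a named reference."""

    ref_name: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise DataError(f"invalid region [{self.start}, {self.end})")


def read_fasta(path: str | Path, topology: Topology = "linear") -> list[ReferenceSequence]:
    """Load references from FASTA; sequences uppercased, IUPAC letters only."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    refs = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - set(IUPAC_CODES)
        if bad:
            raise DataError(f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}")
        refs.append(ReferenceSequence(name=rec.id, seq=seq, topology=topology))
    return refs


def write_fasta(refs: Sequence[ReferenceSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(r.seq), id=r.name, description="") for r in refs]
    SeqIO.write(records, str(path), "fasta")


def read_reads_bed(path: str | Path) -> list[StrandRead]:
    """Read strand-assigned read positions from BED6 (+=top, -=bottom)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end != start + 1:
                raise DataError(f"{path}:{lineno}: read intervals must be single-base")
            strand_sym = fields[5]
            if strand_sym not in "+-":
                raise DataError(f"{path}:{lineno}: strand must be '+' or '-', got {strand_sym!r}")
            reads.append(StrandRead(pos=start, strand="top" if strand_sym == "+" else "bottom"))
    return reads


def write_reads_bed(reads: Iterable[StrandRead], path: str | Path, ref_name: str = "ref") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            sym = "+" if r.strand == "top" else "-"
            fh.write(f"{ref_name}\t{r.pos}\t{r.pos + 1}\tread{i}\t0\t{sym}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    """Read regions (hotspots, masks) from BED3+ format."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: BED requires >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = fields[3] if len(fields) > 3 else None
            try:
                regions.append(Region(ref_name=fields[0], start=start, end=end, label=label))
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            label = r.label if r.label is not None else "."
            fh.write(f"{r.ref_name}\t{r.start}\t{r.end}\t{label}\n")


def _write_bedgraph_track(
    values: np.ndarray, mask: np.ndarray, ref_name: str, path: Path
) -> None:
    if np.isnan(values[~mask]).any():
        raise DataError("NaN values outside masked regions cannot be serialized")
    with open(path, "w") as fh:
        i, n = 0, len(values)
        while i < n:
            if mask[i]:
                i += 1
                continue
            j = i + 1
            while j < n and not mask[j] and values[j] == values[i]:
                j += 1
            fh.write(f"{ref_name}\t{i}\t{j}\t{values[i]:g}\n")
            i = j


def write_bedgraph_pair(smap: StrandMap, prefix: str | Path) -> tuple[Path, Path]:
    """Write one bedGraph per strand: ``<prefix>.top.bedgraph`` / ``.bottom.bedgraph``."""
    prefix = Path(prefix)
    top_path = prefix.with_name(prefix.name + ".top.bedgraph")
    bottom_path = prefix.with_name(prefix.name + ".bottom.bedgraph")
    _write_bedgraph_track(smap.top, smap.mask, smap.ref_name, top_path)
    _write_bedgraph_track(smap.bottom, smap.mask, smap.ref_name, bottom_path)
    return top_path, bottom_path


def _read_bedgraph_track(path: Path, length: int) -> tuple[str | None, np.ndarray, np.ndarray]:
    values = np.zeros(length)
    covered = np.zeros(length, dtype=bool)
    ref_name = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(f"{path}:{lineno}: bedGraph requires 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed interval or value") from exc
            if not 0 <= start < end <= length:
                raise DataError(f"{path}:{lineno}: interval [{start},{end}) outside length {length}")
            if ref_name is None:
                ref_name = fields[0]
            elif fields[0] != ref_name:
                raise DataError(f"{path}:{lineno}: multiple reference names in one track")
            values[start:end] = value
            covered[start:end] = True
    return ref_name, values, covered


def read_bedgraph_pair(
    prefix: str | Path,
    length: int,
    topology: Topology = "linear",
    units: str = "raw",
    total_mapped: int | None = None,
) -> StrandMap:
    """Inverse of :func:`write_bedgraph_pair`; uncovered positions become masked."""
    prefix = Path(prefix)
    name_t, top, cov_t = _read_bedgraph_track(prefix.with_name(prefix.name + ".top.bedgraph"), length)
    name_b, bottom, cov_b = _read_bedgraph_track(
        prefix.with_name(prefix.name + ".bottom.bedgraph"), length
    )
    ref_name = name_t or name_b or "ref"
    mask = ~(cov_t | cov_b)
    if total_mapped is None:
        total_mapped = int(round(top.sum() + bottom.sum())) if units == "raw" else 0
    return StrandMap(
        ref_name=ref_name,
        length=length,
        topology=topology,
        top=top,
        bottom=bottom,
        units=units,  # type: ignore[arg-type]
        total_mapped=total_mapped,
        mask=mask,
    )


def load_config(path: str | Path) -> dict:
    """Load a flat YAML configuration document."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise DataError(f"{path}: config must be a YAML mapping")
    return cfg
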