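"""Alignment records, PCR-duplicate collapsing, and per-base coverage.

Internal coordinates are 0-based half-open everywhere; conversion happens
only at format boundaries (bedGraph is already 0-based half-open, GFF3 is
handled in :mod:`chapkit.annotate`). Circular chromosomes are supported
throughout: an alignment spanning the origin contributes depth to both
ends of the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np


class AlignmentRecord(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive; may exceed genome length before wrap
    strand: str
    name: str = ""


@dataclass
class CoverageTrack:
    """Per-base depth over one (optionally circular) chromosome."""

    chrom: str
    values: np.ndarray
    sample: str = ""
    condition: str = ""
    replicate: int = 0
    circular: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("track values must be a non-empty 1-D array")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


# ---------------------------------------------------------------------------
# duplicate collapsing
# ---------------------------------------------------------------------------

def collapse_alignments(records: Sequence[AlignmentRecord]) -> list:
    """Remove PCR-duplicate alignments.

    Exactly one record is retained per distinct (chrom, start, end, strand)
    tuple — the first occurrence — and the result is sorted by that tuple.
    Idempotent.
    """
    seen = {}
    for r in records:
        key = (r.chrom, r.start, r.end, r.strand)
        if key not in seen:
            seen[key] = r
    return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# coverage computation
# ---------------------------------------------------------------------------

def compute_coverage(records: Sequence[AlignmentRecord], genome_length: int,
                     circular: bool = True, **track_kw) -> CoverageTrack:
    """Interval-stabbing depth via a difference array.

    ``values[x]`` = number of records whose [start, end) covers x; a record
    spanning the origin of a circular genome wraps. Total mass equals the
    sum of record lengths.
    """
    L = int(genome_length)
    diff = np.zeros(L + 1, dtype=np.int64)
    chrom = records[0].chrom if records else track_kw.pop("chrom", "chr")
    for r in records:
        if r.chrom != chrom:
            raise ValueError("records must be on a single chromosome")
        s, e = r.start, r.end
        if s < 0 or e > L:
            if not circular:
                raise ValueError(f"record [{s},{e}) outside linear genome "
                                 f"of length {L}")
            s %= L
            e = s + (r.end - r.start)
        if e <= L:
            diff[s] += 1
            diff[e] -= 1
        else:  # wraps the origin
            diff[s] += 1
            diff[L] -= 1
            diff[0] += 1
            diff[e - L] -= 1
    values = np.cumsum(diff[:L])
    return CoverageTrack(chrom=chrom, values=values.astype(np.float64),
                         circular=circular, **track_kw)


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def write_track(track: CoverageTrack, path) -> None:
    """Write bedGraph with one line per maximal constant run (zeros
    included, so interval count == run count and round-trips are exact)."""
    v = track.values
    # boundaries of maximal constant runs
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(v)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            x = v[s]
            fh.write(f"{track.chrom}\t{s}\t{e}\t{x:g}\n")


def read_track(path, length: int | None = None, circular: bool = True,
               **track_kw) -> CoverageTrack:
    """Read a sorted, non-overlapping bedGraph; gaps read as depth 0."""
    chrom = None
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            c, s, e, x = line.split("\t")[:4]
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError("multi-chromosome bedGraph not supported")
            ivs.append((int(s), int(e), float(x)))
    if chrom is None:
        raise ValueError(f"empty bedGraph: {path}")
    prev_end = -1
    for s, e, _ in ivs:
        if s < prev_end:
            raise ValueError("bedGraph intervals overlap or are unsorted")
        prev_end = e
    L = length if length is not None else ivs[-1][1]
    values = np.zeros(L, dtype=np.float64)
    for s, e, x in ivs:
        values[s:e] = x
    return CoverageTrack(chrom=chrom, values=values, circular=circular,
                         **track_kw)


# ---------------------------------------------------------------------------
# alignment readers (BED6 / SAM)
# ---------------------------------------------------------------------------

def read_bed(path) -> list:
    """Read BED6 (or BED3; strand defaults to +) alignment intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "+"
            name = f[3] if len(f) >= 4 else ""
            out.append(AlignmentRecord(f[0], int(f[1]), int(f[2]),
                                       strand, name))
    return out


def read_sam(path, fragment: bool = True) -> list:
    """Read primary mapped records from a SAM file via pysam.

    With ``fragment=True`` (default) each properly paired read pair yields
    one fragment interval — leftmost start to rightmost end, taken from the
    forward-oriented mate's template length — mirroring the DNA molecule
    that was sequenced from both ends. Unpaired or improper reads fall back
    to their own interval. With ``fragment=False`` every primary mapped
    read contributes its read interval.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            strand = "-" if a.is_reverse else "+"
            if fragment and a.is_paired and a.is_proper_pair:
                tlen = a.template_length
                if tlen > 0:
                    out.append(AlignmentRecord(
                        a.reference_name, a.reference_start,
                        a.reference_start + tlen, strand,
                        a.query_name or ""))
                # mate with tlen <= 0 is the same fragment; skip it
                continue
            out.append(AlignmentRecord(a.reference_name, a.reference_start,
                                       a.reference_end, strand,
                                       a.query_name or ""))
    return out
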