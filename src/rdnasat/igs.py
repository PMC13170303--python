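"""Delimitation of transcribed spacers and the intergenic spacer (IGS).

The pre-rRNA transcript covers 5'ETS..18S..ITS1..5.8S..ITS2..28S..3'ETS;
the IGS is not transcribed, so RNA-seq coverage drops to (near) zero outside
the transcription unit. Scanning outward from the 18S start and the 28S end
while depth stays above a threshold recovers the ETS boundaries; what is
left between one unit's 3'ETS end and the next unit's 5'ETS start is the
IGS. When no coverage is available the whole inter-gene flank is reported
as IGS (flank-fallback).

The depth threshold is relative to the median depth over the rRNA genes.
Its default (0.001) is deliberately far below typical ETS:gene coverage
ratios: with zero IGS transcription the informative signal is the edge of
the zero-coverage run, and read-length ramps at transcript ends bias any
higher threshold inward by roughly threshold/read-start-rate bases. For
noisy real tracks (background multi-mapping) raise it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from rdnasat.align import KmerIndex, seeded_local_search
from rdnasat.annotate import RdnaUnit
from rdnasat.records import SequenceRecord, encode, reverse_complement

__all__ = [
    "CoverageTrack",
    "IgsInterval",
    "PlacementResult",
    "place_reads",
    "delimit_transcribed",
    "igs_fallback",
    "genomic_proportion",
    "read_depth_tsv",
    "read_depth_sam",
    "track_to_tsv",
]


@dataclass
class CoverageTrack:
    """Per-base read depth over one reference sequence."""

    ref_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass
class IgsInterval:
    """One intergenic spacer on the annotated reference.

    In a tandem context the IGS of the *last* unit wraps across the unit
    junction; coordinates are then reported beyond the reference end
    (start..len+next_ets5_start) rather than modulo the unit.
    """

    unit_id: str
    start: int
    end: int
    method: str  # 'coverage' or 'flank-fallback'

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("negative IGS length")
        if self.method not in ("coverage", "flank-fallback"):
            raise ValueError("unknown method")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlacementResult:
    track: CoverageTrack
    n_placed: int
    n_unplaced: int
    placed_bases: int
    total_bases: int


def place_reads(
    reads: Sequence[SequenceRecord],
    unit: SequenceRecord,
    k: int = 15,
    min_identity: float = 90.0,
) -> PlacementResult:
    """Place each read at its best location on ``unit`` and pile up depth.

    Exact occurrences (either strand) are found by word lookup and string
    comparison; reads without an exact occurrence fall back to the seeded
    aligner and are kept when identity >= ``min_identity``. Multi-mapping
    reads go to the leftmost best location. Unplaced reads are counted.
    """
    depth = np.zeros(len(unit), dtype=np.int64)
    if not reads:
        return PlacementResult(CoverageTrack(unit.id, depth), 0, 0, 0, 0)
    if any(k > len(r) for r in reads):
        raise ValueError("k exceeds a read length")
    index = KmerIndex(unit, k)
    useq = unit.seq
    n_placed = 0
    placed_bases = 0
    total_bases = sum(len(r) for r in reads)
    km_pos = np.zeros(1, dtype=np.int64)
    for read in reads:
        placed = None
        for seq in (read.seq, reverse_complement(read.seq)):
            codes = encode(seq[:k])
            val = np.int64(0)
            for c in codes:
                val = val * 4 + (0 if c == 4 else int(c))
            if 4 in codes:
                break
            _, s_pos = index.lookup(np.array([val], dtype=np.int64), km_pos)
            for s in np.sort(s_pos):
                s = int(s)
                if useq[s : s + len(seq)] == seq:
                    placed = (s, s + len(seq))
                    break
            if placed:
                break
        if placed is None:
            hits = seeded_local_search(
                read, unit, word_size=min(k, len(read)), min_identity=min_identity,
                min_qcov=0.6, search_both_strands=True, index=None,
            )
            if hits:
                best = max(hits, key=lambda h: (h.score, -h.s_start))
                placed = (best.s_start, best.s_end)
        if placed is None:
            continue
        depth[placed[0] : placed[1]] += 1
        n_placed += 1
        placed_bases += placed[1] - placed[0]
    return PlacementResult(
        CoverageTrack(unit.id, depth),
        n_placed,
        len(reads) - n_placed,
        placed_bases,
        total_bases,
    )


def _median_gene_depth(depth: np.ndarray, units: Sequence[RdnaUnit]) -> float:
    pos: list[np.ndarray] = []
    for u in units:
        for g in ("18S", "5.8S", "28S"):
            if g in u.intervals:
                s, e = u.intervals[g]
                pos.append(depth[s:e])
    if not pos:
        raise ValueError("no gene intervals annotated")
    return float(np.median(np.concatenate(pos)))


def delimit_transcribed(
    track: CoverageTrack,
    units: Sequence[RdnaUnit],
    rel_threshold: float = 0.001,
    wrap_last: bool = True,
) -> list[IgsInterval]:
    """Recover ETS boundaries from coverage and emit IGS intervals.

    For each complete unit the transcribed region is extended upstream from
    the 18S start and downstream from the 28S end while depth stays strictly
    above ``rel_threshold`` x median gene depth; the recovered 5'ETS/3'ETS
    intervals are written into ``unit.intervals``. The IGS of unit *i* runs
    from its 3'ETS end to unit *i+1*'s 5'ETS start; with a single unit (or
    for the last unit when ``wrap_last``) the spacer wraps through the unit
    junction using the first unit's 5'ETS start.
    """
    depth = track.depth
    n = len(depth)
    if not (depth > 0).any():
        warnings.warn("all-zero coverage track; falling back to flanking rule")
        return igs_fallback(units)
    complete = [u for u in sorted(units, key=lambda u: u.start) if u.complete]
    if not complete:
        raise ValueError("no complete units to delimit")
    thr = rel_threshold * _median_gene_depth(depth, complete)

    ets5_starts: list[int] = []
    ets3_ends: list[int] = []
    for idx, u in enumerate(complete):
        lo_bound = complete[idx - 1].intervals["28S"][1] if idx > 0 else 0
        hi_bound = complete[idx + 1].intervals["18S"][0] if idx + 1 < len(complete) else n
        s18 = u.intervals["18S"][0]
        e28 = u.intervals["28S"][1]
        p = s18
        while p - 1 >= lo_bound and depth[p - 1] > thr:
            p -= 1
        ets5_starts.append(p)
        q = e28
        while q < hi_bound and depth[q] > thr:
            q += 1
        ets3_ends.append(q)
        u.intervals["ETS5"] = (p, s18)
        u.intervals["ETS3"] = (e28, q)

    out: list[IgsInterval] = []
    for idx, u in enumerate(complete):
        uid = f"{u.array_id}.unit{u.unit_index}"
        if idx + 1 < len(complete):
            start, end = ets3_ends[idx], ets5_starts[idx + 1]
        elif wrap_last:
            start, end = ets3_ends[idx], n + ets5_starts[0]
        else:
            continue
        if end < start:
            warnings.warn(f"transcribed regions overlap around {uid}; empty IGS")
            start = end = min(start, end)
        u.intervals["IGS"] = (start, end)
        out.append(IgsInterval(unit_id=uid, start=start, end=end, method="coverage"))
    if all(i.length == 0 for i in out):
        warnings.warn("coverage is uniform above threshold; IGS empty everywhere")
    return out


def igs_fallback(units: Sequence[RdnaUnit]) -> list[IgsInterval]:
    """IGS by the flanking rule: everything between 28S end and next 18S start.

    Used when no RNA-seq coverage is available; the reported spacer then
    also contains the (undelimited) external transcribed spacers.
    """
    complete = [u for u in sorted(units, key=lambda u: u.start) if u.complete]
    if not complete:
        raise ValueError("igs_fallback requires at least one complete unit")
    out: list[IgsInterval] = []
    for idx, u in enumerate(complete):
        uid = f"{u.array_id}.unit{u.unit_index}"
        e28 = u.intervals["28S"][1]
        if idx + 1 < len(complete):
            nxt = complete[idx + 1].intervals["18S"][0]
        else:
            # wrap through the unit junction in tandem context
            nxt = u.end + (complete[0].intervals["18S"][0] - complete[0].start)
        start, end = e28, max(e28, nxt)
        u.intervals["IGS"] = (start, end)
        out.append(IgsInterval(unit_id=uid, start=start, end=end, method="flank-fallback"))
    return out


def genomic_proportion(n_placed_bases: int, n_total_bases: int) -> float:
    """Percent of sequenced bases attributable to the unit, in [0, 100]."""
    if n_total_bases <= 0:
        raise ValueError("total bases must be positive")
    if n_placed_bases < 0 or n_placed_bases > n_total_bases:
        raise ValueError("placed bases out of range")
    return 100.0 * n_placed_bases / n_total_bases


# ---------------------------------------------------------------------------
# coverage ingestion / export
# ---------------------------------------------------------------------------


def read_depth_tsv(path: str | Path, ref_id: str, length: int) -> CoverageTrack:
    """Read a 2-column (pos, depth) TSV; 1-based positions, gaps depth 0."""
    depth = np.zeros(length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            pos, d = int(fields[0]), int(fields[-1])
            if not (1 <= pos <= length):
                raise ValueError(f"position {pos} outside reference of length {length}")
            depth[pos - 1] = d
    return CoverageTrack(ref_id, depth)


def read_depth_sam(path: str | Path, ref_id: str) -> CoverageTrack:
    """Accumulate per-base depth for one reference from a SAM/BAM file."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        length = None
        for i, name in enumerate(af.references):
            if name == ref_id:
                length = af.lengths[i]
        if length is None:
            raise ValueError(f"reference {ref_id!r} not in SAM header")
        depth = np.zeros(length, dtype=np.int64)
        for rec in af:
            if rec.is_unmapped or rec.reference_name != ref_id:
                continue
            for s, e in rec.get_blocks():
                depth[s:e] += 1
    return CoverageTrack(ref_id, depth)


def track_to_tsv(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#pos\tdepth\n")
        for i, d in enumerate(track.depth, start=1):
            fh.write(f"{i}\t{int(d)}\n")
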