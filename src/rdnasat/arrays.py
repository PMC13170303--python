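"""Reconstruction of tandem 45S rDNA array regions from anchor-gene hits.

The 5.8S rRNA gene is the canonical anchor: it is short, highly conserved
across fishes, and occurs exactly once per 45S unit, so clustered 5.8S hits
delimit tandem arrays. Hits on one contig closer than ``max_gap`` are merged
into a region, which is then extended by a flank on both sides so terminal
units keep their full intergenic spacers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from rdnasat.align import (
    DEFAULT_SCORING,
    KmerIndex,
    LocalAlignment,
    ScoringScheme,
    seeded_local_search,
)
from rdnasat.records import SequenceRecord, reverse_complement

__all__ = [
    "ArrayRegion",
    "find_anchor_hits",
    "cluster_and_extend",
    "extract_arrays",
    "regions_to_bed",
    "regions_to_tsv",
]

DEFAULT_MAX_GAP = 50_000  # must exceed the longest plausible unit (~33 kb)
# flank must exceed the anchor-to-unit-end distance (ITS2 + 28S + 3'ETS + IGS,
# ~7.1 kb under realistic subunit sizes) so terminal units keep their full IGS
DEFAULT_FLANK = 8_000
LENGTH_WARN_CAP = 400_000


@dataclass
class ArrayRegion:
    """A reconstructed genomic region containing >= 1 tandem 45S unit."""

    seq_id: str
    start: int
    end: int
    n_anchor_hits: int
    orientation: str  # '+', '-', or 'mixed'
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty region")
        if self.n_anchor_hits < 1:
            raise ValueError("region must contain at least one anchor hit")
        if self.orientation not in ("+", "-", "mixed"):
            raise ValueError("orientation must be '+', '-' or 'mixed'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}:{self.orientation}"


def find_anchor_hits(
    genome: Sequence[SequenceRecord],
    anchor: SequenceRecord,
    min_identity: float = 80.0,
    min_qcov: float = 0.6,
    word_size: int = 11,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[LocalAlignment]:
    """Locate the anchor gene on both strands of every contig.

    Hits come back in forward-subject coordinates, sorted by
    (contig id, start). Short anchors (< 100 bp) trigger a warning because
    spurious hits become likely.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    if len(anchor) < 100:
        warnings.warn(f"anchor {anchor.id!r} is shorter than 100 bp; hits may be unreliable")
    hits: list[LocalAlignment] = []
    for contig in genome:
        if len(contig) < word_size:
            continue
        hits.extend(
            seeded_local_search(
                anchor,
                contig,
                word_size=word_size,
                min_identity=min_identity,
                min_qcov=min_qcov,
                search_both_strands=True,
                scoring=scoring,
            )
        )
    hits.sort(key=lambda h: (h.subject_id, h.s_start, h.s_end))
    return hits


def cluster_and_extend(
    hits: Sequence[LocalAlignment],
    max_gap: int = DEFAULT_MAX_GAP,
    flank: int = DEFAULT_FLANK,
    genome_lengths: Mapping[str, int] | None = None,
) -> list[ArrayRegion]:
    """Merge nearby anchor hits into flank-extended array regions.

    Hits on the same contig whose inter-hit distance is <= ``max_gap`` share
    a region; each region is extended by ``flank`` on both sides and clipped
    to the contig. Regions whose extended spans touch are merged again so
    output regions are disjoint per contig. Orientation is the majority hit
    strand, 'mixed' on a tie or disagreement.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    genome_lengths = dict(genome_lengths or {})
    for h in hits:
        if genome_lengths and h.subject_id not in genome_lengths:
            raise ValueError(f"hit references unknown contig {h.subject_id!r}")

    by_contig: dict[str, list[LocalAlignment]] = {}
    for h in sorted(hits, key=lambda h: (h.subject_id, h.s_start, h.s_end)):
        by_contig.setdefault(h.subject_id, []).append(h)

    regions: list[ArrayRegion] = []
    for contig_id, chits in by_contig.items():
        contig_len = genome_lengths.get(contig_id)
        groups: list[list[LocalAlignment]] = [[chits[0]]]
        for h in chits[1:]:
            if h.s_start - groups[-1][-1].s_end <= max_gap:
                groups[-1].append(h)
            else:
                groups.append([h])
        # flank-extend, then re-merge any groups whose extended spans overlap
        spans = []
        for g in groups:
            lo = max(0, g[0].s_start - flank)
            hi = max(h.s_end for h in g) + flank
            if contig_len is not None:
                hi = min(hi, contig_len)
            spans.append([lo, hi, g])
        merged: list[list] = [spans[0]]
        for lo, hi, g in spans[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2] = merged[-1][2] + g
            else:
                merged.append([lo, hi, g])
        for lo, hi, g in merged:
            plus = sum(1 for h in g if h.strand == "+")
            minus = len(g) - plus
            orientation = "+" if plus > minus else ("-" if minus > plus else "mixed")
            regions.append(
                ArrayRegion(
                    seq_id=contig_id,
                    start=lo,
                    end=hi,
                    n_anchor_hits=len(g),
                    orientation=orientation,
                )
            )
    regions.sort(key=lambda r: (r.seq_id, r.start))
    return regions


def extract_arrays(
    genome: Sequence[SequenceRecord],
    regions: Sequence[ArrayRegion],
    length_cap: int = LENGTH_WARN_CAP,
) -> list[SequenceRecord]:
    """Extract region sequences, reverse-complementing '-' regions.

    Minus-orientation regions are flipped so downstream annotation always
    sees the 18S -> 28S sense. Lengths beyond ``length_cap`` warn but are
    never truncated.
    """
    by_id = {c.id: c for c in genome}
    out: list[SequenceRecord] = []
    for r in regions:
        contig = by_id.get(r.seq_id)
        if contig is None:
            raise ValueError(f"region references unknown contig {r.seq_id!r}")
        if r.end > len(contig):
            raise ValueError(f"region {r.id} out of bounds for contig of length {len(contig)}")
        seq = contig.seq[r.start : r.end]
        if r.orientation == "-":
            seq = reverse_complement(seq)
        if len(seq) > length_cap:
            warnings.warn(f"extracted array {r.id} exceeds {length_cap} bp ({len(seq)} bp)")
        r.sequence = seq
        out.append(SequenceRecord(r.id, seq))
    return out


def regions_to_bed(regions: Sequence[ArrayRegion], path: str | Path) -> None:
    """Write regions as BED6 (0-based half-open; score = anchor-hit count)."""
    with open(path, "w") as fh:
        for r in regions:
            strand = r.orientation if r.orientation in "+-" else "."
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\tarray\t{r.n_anchor_hits}\t{strand}\n")


def regions_to_tsv(regions: Sequence[ArrayRegion], path: str | Path) -> None:
    """Per-region summary (contig, start, end, anchor hits, length)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tn_anchor_hits\tlength\torientation\n")
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.n_anchor_hits}\t{r.length}\t{r.orientation}\n")
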