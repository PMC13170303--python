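"""Annotation of 18S/ITS1/5.8S/ITS2/28S subunits inside extracted arrays.

Units are phased at the 18S start: a unit spans from its 18S start to the
base before the next unit's 18S start (the last unit runs to the array end).
This sequence-only convention is deterministic without RNA-seq; external
transcribed spacers are reassigned later by coverage-based delimitation.
ITS1 and ITS2 are defined by subtraction (the gaps 18S->5.8S and
5.8S->28S). Units missing a gene, or with genes out of canonical order, are
flagged ``complete=False`` and never silently reordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from rdnasat.align import (
    DEFAULT_SCORING,
    KmerIndex,
    LocalAlignment,
    ScoringScheme,
    seeded_local_search,
    star_align,
)
from rdnasat.records import SequenceRecord

__all__ = [
    "RdnaUnit",
    "UnitConsensus",
    "AnnotatedArray",
    "GeneInterval",
    "annotate_subunits",
    "annotate_array",
    "count_units",
    "build_unit_consensus",
    "units_to_gff3",
]

GENES = ("18S", "5.8S", "28S")

#: maximum gap (bp) when chaining split hits of one gene copy — generous
#: enough to bridge a satellite insertion (<= 430 bp) inside a gene.
CHAIN_GAP = 800

#: minimum aligned query bases for a hit to join a gene chain
MIN_FRAGMENT = 30


@dataclass
class GeneInterval:
    """A (possibly chained) gene hit on an array."""

    gene: str
    start: int
    end: int
    q_covered: int  # total query bases covered by the chained hits
    ref_length: int
    pct_identity: float
    strand: str = "+"

    @property
    def q_coverage(self) -> float:
        return min(1.0, self.q_covered / self.ref_length)


@dataclass
class RdnaUnit:
    """One annotated 45S unit in array coordinates.

    ``intervals`` maps subunit names ({'18S','ITS1','5.8S','ITS2','28S',
    'ETS5','ETS3','IGS'}) to (start, end); ETS/IGS appear only after
    coverage-based delimitation.
    """

    array_id: str
    unit_index: int
    start: int
    end: int
    intervals: dict[str, tuple[int, int]]
    complete: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UnitConsensus:
    sequence: str
    length: int
    support: int


@dataclass
class AnnotatedArray:
    array: SequenceRecord
    units: list[RdnaUnit]

    def unit_sequence(self, unit: RdnaUnit) -> str:
        return self.array.seq[unit.start : unit.end]


def _chain_gene_hits(hits: Sequence[LocalAlignment], gene: str, ref_len: int) -> list[GeneInterval]:
    """Chain same-strand hits of one gene that are separated by <= CHAIN_GAP.

    A gene copy split by an insertion (e.g. a satellite array inside 18S)
    is thereby reported as one interval spanning the insertion.
    """
    out: list[GeneInterval] = []
    for strand in "+-":
        same = sorted((h for h in hits if h.strand == strand), key=lambda h: h.s_start)
        chain: list[LocalAlignment] = []
        for h in same:
            if chain and h.s_start - chain[-1].s_end > CHAIN_GAP:
                out.append(_finish_chain(chain, gene, ref_len, strand))
                chain = []
            chain.append(h)
        if chain:
            out.append(_finish_chain(chain, gene, ref_len, strand))
    out.sort(key=lambda gi: (gi.start, gi.end))
    return out


def _finish_chain(chain: list[LocalAlignment], gene: str, ref_len: int, strand: str) -> GeneInterval:
    covered = sum(h.q_end - h.q_start for h in chain)
    total_cols = sum(h.aligned_cols for h in chain)
    total_match = sum(h.matches for h in chain)
    return GeneInterval(
        gene=gene,
        start=min(h.s_start for h in chain),
        end=max(h.s_end for h in chain),
        q_covered=min(covered, ref_len),
        ref_length=ref_len,
        pct_identity=100.0 * total_match / total_cols,
        strand=strand,
    )


def find_gene_intervals(
    array: SequenceRecord,
    refs: Mapping[str, SequenceRecord],
    min_identity: float = 80.0,
    min_qcov: float = 0.5,
    word_size: int = 11,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> dict[str, list[GeneInterval]]:
    """Locate every copy of each rRNA gene on the array (forward sense).

    Per-copy hits are chained across short insertions; chains below
    ``min_qcov`` of the reference length (e.g. strongly truncated 28S) are
    discarded so the owning unit ends up incomplete.
    """
    index = KmerIndex(array, word_size)
    intervals: dict[str, list[GeneInterval]] = {}
    for gene in GENES:
        ref = refs[gene]
        hits = seeded_local_search(
            ref,
            array,
            word_size=word_size,
            min_identity=min_identity,
            min_qcov=0.01,  # per-fragment; coverage is enforced per chain
            search_both_strands=True,
            scoring=scoring,
            seed_mismatch=0,  # genes are conserved; exact words suffice
            index=index,
        )
        # short spurious word matches must not seed chains: a genuine gene
        # fragment (even one clipped by an insertion) aligns over >= tens of bp
        hits = [h for h in hits if h.q_end - h.q_start >= MIN_FRAGMENT]
        chains = _chain_gene_hits(hits, gene, len(ref))
        intervals[gene] = [c for c in chains if c.q_coverage >= min_qcov and c.pct_identity >= min_identity]
    return intervals


def annotate_subunits(
    array: SequenceRecord,
    refs: Mapping[str, SequenceRecord],
    min_identity: float = 80.0,
    min_qcov: float = 0.5,
    word_size: int = 11,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[RdnaUnit]:
    """Annotate the tandem 45S units of one extracted array.

    ``refs`` must supply '18S', '5.8S' and '28S' reference sequences. Units
    are emitted by walking the array left to right, one per 18S occurrence;
    a unit is complete when 18S, 5.8S and 28S occur in canonical order with
    ITS1/ITS2 derived by subtraction.
    """
    for gene in GENES:
        if gene not in refs:
            raise ValueError(f"missing reference for {gene}")
    per_gene = find_gene_intervals(array, refs, min_identity, min_qcov, word_size, scoring)
    # arrays are orientation-normalized upstream, so units are walked on '+'
    events = sorted(
        (gi for gene in GENES for gi in per_gene[gene] if gi.strand == "+"),
        key=lambda gi: (gi.start, gi.end),
    )
    if not events:
        warnings.warn(f"no rRNA gene hits on array {array.id!r}")
        return []

    starts_18s = [gi.start for gi in events if gi.gene == "18S"]
    units: list[RdnaUnit] = []

    # genes upstream of the first 18S (partial unit at the array edge)
    if starts_18s:
        leading = [gi for gi in events if gi.end <= starts_18s[0]]
    else:
        leading = list(events)
    if leading:
        units.append(
            RdnaUnit(
                array_id=array.id,
                unit_index=0,
                start=0,
                end=starts_18s[0] if starts_18s else len(array),
                intervals={gi.gene: (gi.start, gi.end) for gi in leading},
                complete=False,
            )
        )

    for k, s18 in enumerate(starts_18s):
        unit_start = s18
        unit_end = starts_18s[k + 1] if k + 1 < len(starts_18s) else len(array)
        members = [gi for gi in events if unit_start <= gi.start < unit_end]
        found: dict[str, GeneInterval] = {}
        for gi in members:  # first occurrence per gene along the unit
            found.setdefault(gi.gene, gi)
        ivals: dict[str, tuple[int, int]] = {}
        complete = all(g in found for g in GENES)
        for g in GENES:
            if g in found:
                ivals[g] = (found[g].start, found[g].end)
        if complete:
            g18, g58, g28 = found["18S"], found["5.8S"], found["28S"]
            ordered = g18.end <= g58.start and g58.end <= g28.start
            if ordered:
                ivals["ITS1"] = (g18.end, g58.start)
                ivals["ITS2"] = (g58.end, g28.start)
            else:
                complete = False
        units.append(
            RdnaUnit(
                array_id=array.id,
                unit_index=len(units),
                start=unit_start,
                end=unit_end,
                intervals=ivals,
                complete=complete,
            )
        )
    return units


def annotate_array(array: SequenceRecord, refs: Mapping[str, SequenceRecord], **kwargs) -> AnnotatedArray:
    return AnnotatedArray(array=array, units=annotate_subunits(array, refs, **kwargs))


def count_units(units: Sequence[RdnaUnit]) -> int:
    """Number of units with all three rRNA genes present in order."""
    return sum(1 for u in units if u.complete)


def build_unit_consensus(annotated: Sequence[AnnotatedArray]) -> UnitConsensus:
    """Majority-rule consensus of all complete units across arrays.

    Units are star-aligned onto the median-length unit; columns where the
    gap symbol holds a strict majority are dropped. With a single complete
    unit the consensus is that unit.
    """
    seqs: list[SequenceRecord] = []
    for ann in annotated:
        for u in ann.units:
            if u.complete:
                seqs.append(SequenceRecord(f"{ann.array.id}|unit{u.unit_index}", ann.unit_sequence(u)))
    if not seqs:
        raise ValueError("no complete units to build a consensus from")
    if len(seqs) == 1:
        return UnitConsensus(sequence=seqs[0].seq, length=len(seqs[0]), support=1)
    by_len = sorted(range(len(seqs)), key=lambda i: (len(seqs[i]), i))
    center = seqs[by_len[len(by_len) // 2]]
    _, pfm = star_align(seqs, center)
    cons = pfm.consensus(drop_gap_majority=True)
    return UnitConsensus(sequence=cons, length=len(cons), support=len(seqs))


_GFF_TYPE = {
    "18S": "rRNA_18S",
    "ITS1": "ITS1",
    "5.8S": "rRNA_5_8S",
    "ITS2": "ITS2",
    "28S": "rRNA_28S",
    "ETS5": "ETS",
    "ETS3": "ETS",
    "IGS": "IGS",
}


def units_to_gff3(annotated: Sequence[AnnotatedArray], path: str | Path) -> None:
    """GFF3 export (1-based inclusive) of units and their subunits."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotated:
            for u in ann.units:
                uid = f"{ann.array.id}.unit{u.unit_index}"
                fh.write(
                    f"{ann.array.id}\trdnasat\trRNA_unit\t{u.start + 1}\t{u.end}\t.\t+\t.\t"
                    f"ID={uid};complete={str(u.complete).lower()}\n"
                )
                for name in ("ETS5", "18S", "ITS1", "5.8S", "ITS2", "28S", "ETS3", "IGS"):
                    if name not in u.intervals:
                        continue
                    s, e = u.intervals[name]
                    if e <= s:
                        continue
                    fh.write(
                        f"{ann.array.id}\trdnasat\t{_GFF_TYPE[name]}\t{s + 1}\t{e}\t.\t+\t.\t"
                        f"ID={uid}.{name};Parent={uid}\n"
                    )
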