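"""Detection and characterization of satellite-like monomers.

The classification criteria mirror how short AT-rich satellites (the As51
family is the motivating case: 51 bp, AT-rich) are recognised inside rDNA
intergenic spacers: percent identity to a consensus of at least 50%, query
coverage of at least 60%, tandem organisation, and an advisory — never
exclusionary — monomer length around 50-60 bp.

Degenerate rDNA units are discovered as 18S gene hits that carry a tandem
satellite array in their interior, after partitioning genome-wide satellite
hits into those inside vs outside annotated 45S array regions (the interval
subtraction step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from rdnasat.align import (
    DEFAULT_SCORING,
    KmerIndex,
    ScoringScheme,
    mean_pairwise_identity,
    remove_redundant,
    seeded_local_search,
)
from rdnasat.annotate import GeneInterval, _chain_gene_hits
from rdnasat.arrays import ArrayRegion
from rdnasat.records import SequenceRecord, reverse_complement

__all__ = [
    "SatMonomerHit",
    "MonomerStats",
    "DegenerateLocus",
    "DegenerateScanResult",
    "scan_satellite",
    "group_tandem",
    "unique_monomers",
    "monomer_stats",
    "find_degenerate_insertions",
    "hits_to_bed",
    "hits_to_tsv",
]

MIN_IDENTITY_DEFAULT = 50.0
MIN_QCOV_DEFAULT = 0.6


@dataclass
class SatMonomerHit:
    """One satellite-like monomer on a target sequence."""

    target_id: str
    start: int
    end: int
    strand: str
    pct_identity: float
    sequence: str
    tandem_group: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_sequence(self) -> str:
        """Monomer sequence in the consensus orientation."""
        return self.sequence if self.strand == "+" else reverse_complement(self.sequence)


@dataclass
class MonomerStats:
    n_total: int
    n_unique: int
    identity_min: float
    identity_max: float
    mean_pairwise_identity: float  # NaN when fewer than 2 unique monomers
    n_variants: int


@dataclass
class DegenerateLocus:
    """An 18S gene copy carrying an interior tandem satellite array."""

    seq_id: str
    start: int
    end: int
    strand: str
    n_monomers: int
    monomer_span: int


@dataclass
class DegenerateScanResult:
    inside_hits: list[SatMonomerHit]
    outside_hits: list[SatMonomerHit]
    loci: list[DegenerateLocus]

    @property
    def all_hits(self) -> list[SatMonomerHit]:
        return sorted(self.inside_hits + self.outside_hits, key=lambda h: (h.target_id, h.start))


def scan_satellite(
    target: SequenceRecord,
    consensus: SequenceRecord,
    min_identity: float = MIN_IDENTITY_DEFAULT,
    min_qcov: float = MIN_QCOV_DEFAULT,
    word_size: int = 7,
    scoring: ScoringScheme = DEFAULT_SCORING,
    index: KmerIndex | None = None,
) -> list[SatMonomerHit]:
    """Find satellite-like monomers on both strands of ``target``.

    Hits overlapping a higher-identity hit by more than half of the shorter
    one are removed. Monomer length is reported but never filtered on.
    """
    if len(consensus) < 20:
        raise ValueError("satellite consensus shorter than 20 bp")
    if len(target) < word_size:
        return []
    alns = seeded_local_search(
        consensus,
        target,
        word_size=word_size,
        min_identity=min_identity,
        min_qcov=min_qcov,
        search_both_strands=True,
        scoring=scoring,
        index=index,
    )
    alns = remove_redundant(alns, max_overlap=0.5, prefer="identity")
    alns.sort(key=lambda a: (a.s_start, a.s_end))
    return [
        SatMonomerHit(
            target_id=target.id,
            start=a.s_start,
            end=a.s_end,
            strand=a.strand,
            pct_identity=a.pct_identity,
            sequence=target.seq[a.s_start : a.s_end],
        )
        for a in alns
    ]


def group_tandem(hits: Sequence[SatMonomerHit], max_spacing: int = 51) -> list[SatMonomerHit]:
    """Assign tandem-group ids to runs of nearby same-strand hits.

    Consecutive hits on one target and strand with an inter-hit gap of at
    most ``max_spacing`` (default: one 51-bp monomer length) share a group;
    isolated hits keep ``tandem_group=None``. Returns the hits sorted by
    (target, start), mutated in place.
    """
    ordered = sorted(hits, key=lambda h: (h.target_id, h.start, h.end))
    group_id = 0
    run: list[SatMonomerHit] = []

    def _close_run() -> None:
        nonlocal group_id
        if len(run) >= 2:
            for h in run:
                h.tandem_group = group_id
            group_id += 1
        elif run:
            run[0].tandem_group = None

    for h in ordered:
        if run and (
            h.target_id != run[-1].target_id
            or h.strand != run[-1].strand
            or h.start - run[-1].end > max_spacing
        ):
            _close_run()
            run = []
        run.append(h)
    _close_run()
    return ordered


def unique_monomers(hits: Sequence[SatMonomerHit]) -> list[SequenceRecord]:
    """Orientation-normalized exact deduplication, in first-occurrence order."""
    seen: dict[str, int] = {}
    out: list[SequenceRecord] = []
    for h in sorted(hits, key=lambda h: (h.target_id, h.start, h.end)):
        seq = h.oriented_sequence()
        if seq not in seen:
            seen[seq] = len(out) + 1
            out.append(SequenceRecord(f"monomer_{len(out) + 1}", seq))
    return out


def monomer_stats(hits: Sequence[SatMonomerHit], consensus: SequenceRecord) -> MonomerStats:
    """Identity range vs the consensus plus unique-monomer statistics.

    ``n_variants`` counts distinct deduplicated monomer sequences;
    ``mean_pairwise_identity`` is computed over those unique monomers and is
    NaN when fewer than two exist.
    """
    if not hits:
        raise ValueError("no hits")
    uniq = unique_monomers(hits)
    mpi = mean_pairwise_identity(uniq) if len(uniq) >= 2 else math.nan
    idents = [h.pct_identity for h in hits]
    return MonomerStats(
        n_total=len(hits),
        n_unique=len(uniq),
        identity_min=min(idents),
        identity_max=max(idents),
        mean_pairwise_identity=mpi,
        n_variants=len(uniq),
    )


def find_degenerate_insertions(
    genome: Sequence[SequenceRecord],
    gene_ref_18S: SequenceRecord,
    consensus_sat: SequenceRecord,
    regions: Sequence[ArrayRegion],
    min_gene_identity: float = 80.0,
    min_gene_qcov: float = 0.5,
    sat_min_identity: float = MIN_IDENTITY_DEFAULT,
    sat_min_qcov: float = MIN_QCOV_DEFAULT,
    interior_margin: int = 5,
) -> DegenerateScanResult:
    """Locate degenerate 18S copies carrying interior satellite arrays.

    Steps: (i) satellite monomers are scanned genome-wide; (ii) hits are
    partitioned (by midpoint) into those inside vs outside the annotated 45S
    array regions — the interval-subtraction analog; (iii) every 18S gene
    hit on any contig that contains >= 2 interior monomers forming a tandem
    group is reported with its monomer count and array span.
    """
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.seq_id, IntervalTree()).addi(r.start, r.end)

    inside: list[SatMonomerHit] = []
    outside: list[SatMonomerHit] = []
    loci: list[DegenerateLocus] = []
    for contig in genome:
        hits = scan_satellite(contig, consensus_sat, sat_min_identity, sat_min_qcov)
        group_tandem(hits, max_spacing=len(consensus_sat))
        tree = trees.get(contig.id, IntervalTree())
        for h in hits:
            mid = (h.start + h.end) // 2
            (inside if tree.overlaps_point(mid) else outside).append(h)

        if len(contig) < 11:
            continue
        gene_alns = seeded_local_search(
            gene_ref_18S, contig, word_size=11, min_identity=min_gene_identity,
            min_qcov=0.01, search_both_strands=True, seed_mismatch=0,
        )
        gene_alns = [h for h in gene_alns if h.q_end - h.q_start >= 30]
        chains = [
            gi
            for gi in _chain_gene_hits(gene_alns, "18S", len(gene_ref_18S))
            if gi.q_coverage >= min_gene_qcov and gi.pct_identity >= min_gene_identity
        ]
        for gi in chains:
            interior = [
                h
                for h in hits
                if h.start >= gi.start + interior_margin and h.end <= gi.end - interior_margin
            ]
            tandem = [h for h in interior if h.tandem_group is not None]
            if len(tandem) >= 2:
                loci.append(
                    DegenerateLocus(
                        seq_id=contig.id,
                        start=gi.start,
                        end=gi.end,
                        strand=gi.strand,
                        n_monomers=len(tandem),
                        monomer_span=max(h.end for h in tandem) - min(h.start for h in tandem),
                    )
                )
    return DegenerateScanResult(inside_hits=inside, outside_hits=outside, loci=loci)


def hits_to_bed(hits: Sequence[SatMonomerHit], path: str | Path) -> None:
    """BED6 export; score column carries identity scaled to 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            score = int(round(h.pct_identity * 10))
            name = f"sat" if h.tandem_group is None else f"sat_tg{h.tandem_group}"
            fh.write(f"{h.target_id}\t{h.start}\t{h.end}\t{name}\t{score}\t{h.strand}\n")


def hits_to_tsv(hits: Sequence[SatMonomerHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tstart\tend\tstrand\tpct_identity\tlength\ttandem_group\n")
        for h in hits:
            tg = "" if h.tandem_group is None else str(h.tandem_group)
            fh.write(
                f"{h.target_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.pct_identity:.2f}\t{h.length}\t{tg}\n"
            )
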