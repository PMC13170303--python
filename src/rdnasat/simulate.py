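"""Synthetic 45S rDNA loci with ground truth.

The generator emits genomes with the structure the analysis assumes:
tandem 45S units in canonical order (5'ETS-18S-ITS1-5.8S-ITS2-28S-3'ETS)
followed by a non-transcribed IGS that carries a tandem array of satellite
monomers; optionally degenerate units (truncated 28S, a 4-6-monomer
satellite array near the 18S 5' end spanning <= 430 bp) placed away from
the main arrays; and transcriptome reads whose coverage is high over the
rRNA genes and low over the external transcribed spacers, with none from
the IGS.

Defaults emulate a compact characiform-like locus: a ~10.2 kb unit
(18S 1800, 5.8S 160, 28S 4000 bp; ITS 350/300; ETS 800/400; IGS 2380 bp,
the cross-species median magnitude), three arrays of 5/11/22 units, and a
packaged 51-bp AT-rich satellite template (synthetic — not the real As51
consensus; supply your own FASTA for real analyses) planted at 12 copies
per IGS with 5% per-base divergence drawn from 6 template variants.
Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from rdnasat.records import SequenceRecord

__all__ = [
    "DEFAULT_SAT_MONOMER",
    "SimConfig",
    "TruthMonomer",
    "TruthUnit",
    "TruthArray",
    "TruthDegenerate",
    "TruthManifest",
    "SimResult",
    "PanelSpecies",
    "make_genome",
    "make_transcriptome_reads",
    "make_species_panel",
    "make_diverged_spacer",
    "write_fastq",
]

#: packaged 51-bp AT-rich satellite template (synthetic stand-in sequence,
#: ~69% AT like the As51 family it emulates).
DEFAULT_SAT_MONOMER = "ATTTAAGTCATAAATTTGACTGGATAATAAATTCACGTAATTATTAAAGCT"
assert len(DEFAULT_SAT_MONOMER) == 51

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of one synthetic locus; a fixed seed gives byte-identical output."""

    seed: int = 0
    units_per_array: tuple[int, ...] = (5, 11, 22)
    n_arrays: int | None = None  # derived from units_per_array when None
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: {"18S": 1800, "5.8S": 160, "28S": 4000}
    )
    its_lengths: tuple[int, int] = (350, 300)
    ets_lengths: tuple[int, int] = (800, 400)
    igs_length: int = 2380
    sat_monomer: str = DEFAULT_SAT_MONOMER
    sat_copies_per_igs: int = 12
    sat_divergence: float = 0.05
    indel_rate: float = 0.0
    n_sat_variants: int = 6
    gene_divergence: float = 0.0
    n_degenerate_units: int = 0
    degenerate_n_monomers: int | None = None  # drawn uniformly from 4-6 when None
    degenerate_28s_fraction: float = 0.3
    degenerate_divergence: float = 0.05
    add_5s_decoy: bool = False
    inter_array_gap: int = 65_000
    flank_background: int = 8_000
    read_length: int = 100
    read_depth: int = 400
    gene_ets_ratio: float = 10.0
    contig_id: str = "contig_1"

    def __post_init__(self) -> None:
        self.units_per_array = tuple(int(x) for x in self.units_per_array)
        if self.n_arrays is None:
            self.n_arrays = len(self.units_per_array)
        if self.n_arrays != len(self.units_per_array):
            raise ValueError("n_arrays inconsistent with units_per_array")
        for name in ("igs_length", "inter_array_gap", "flank_background", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.gene_lengths.values()) or set(self.gene_lengths) != {
            "18S",
            "5.8S",
            "28S",
        }:
            raise ValueError("gene_lengths must give positive 18S/5.8S/28S lengths")
        for p in ("sat_divergence", "indel_rate", "gene_divergence", "degenerate_divergence"):
            if not (0.0 <= getattr(self, p) <= 1.0):
                raise ValueError(f"{p} must be a probability")
        if not (0.0 <= self.degenerate_28s_fraction <= 1.0):
            raise ValueError("degenerate_28s_fraction must be in [0, 1]")
        sat_span = self.sat_copies_per_igs * len(self.sat_monomer)
        if self.sat_copies_per_igs and self.igs_length < sat_span + 40:
            raise ValueError(
                f"igs_length {self.igs_length} too short for a {sat_span} bp satellite array"
            )

    @property
    def unit_length(self) -> int:
        return (
            sum(self.gene_lengths.values())
            + sum(self.its_lengths)
            + sum(self.ets_lengths)
            + self.igs_length
        )


@dataclass
class TruthMonomer:
    start: int
    end: int
    variant: int
    realized_divergence: float
    sequence: str
    strand: str = "+"
    in_degenerate: bool = False


@dataclass
class TruthUnit:
    start: int
    end: int
    subunits: dict[str, tuple[int, int]]


@dataclass
class TruthArray:
    start: int
    end: int
    units: list[TruthUnit]


@dataclass
class TruthDegenerate:
    start: int
    end: int
    gene18s: tuple[int, int]
    n_monomers: int
    monomer_span: int


@dataclass
class TruthManifest:
    """Planted coordinates, all on the emitted contig (0-based half-open)."""

    contig_id: str
    contig_length: int
    arrays: list[TruthArray]
    monomers: list[TruthMonomer]
    degenerate: list[TruthDegenerate]

    @property
    def n_units(self) -> int:
        return sum(len(a.units) for a in self.arrays)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            contig_id=d["contig_id"],
            contig_length=d["contig_length"],
            arrays=[
                TruthArray(
                    a["start"],
                    a["end"],
                    [
                        TruthUnit(u["start"], u["end"], {k: tuple(v) for k, v in u["subunits"].items()})
                        for u in a["units"]
                    ],
                )
                for a in d["arrays"]
            ],
            monomers=[TruthMonomer(**m) for m in d["monomers"]],
            degenerate=[
                TruthDegenerate(
                    g["start"], g["end"], tuple(g["gene18s"]), g["n_monomers"], g["monomer_span"]
                )
                for g in d["degenerate"]
            ],
        )


@dataclass
class SimResult:
    genome: list[SequenceRecord]
    refs: dict[str, SequenceRecord]
    sat_consensus: SequenceRecord
    sat_variants: list[str]
    manifest: TruthManifest
    config: SimConfig


@dataclass
class PanelSpecies:
    label: str
    sim: SimResult
    true_igs_length: int
    true_unit_length: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def mutate_seq(
    seq: str,
    sub_rate: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> str:
    """Uniform random substitutions, plus optional 1-3 bp indels."""
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        if indel_rate and rng.random() < indel_rate:
            ln = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                i += ln  # deletion
                continue
            out.append(_random_seq(rng, ln))  # insertion before current base
        ch = seq[i]
        if sub_rate and rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != ch]
            ch = choices[int(rng.integers(0, 3))]
        out.append(ch)
        i += 1
    return "".join(out)


def _realized_divergence(mutant: str, template: str) -> float:
    d = edlib.align(mutant, template, mode="NW")["editDistance"]
    return d / len(template)


def _make_variants(base: str, n_variants: int, rng: np.random.Generator) -> list[str]:
    """Template variants: the base plus copies with 3 fixed substitutions each."""
    variants = [base]
    seen = {base}
    while len(variants) < n_variants:
        v = list(base)
        for p in rng.choice(len(base), size=3, replace=False):
            choices = [b for b in "ACGT" if b != v[p]]
            v[p] = choices[int(rng.integers(0, 3))]
        v = "".join(v)
        if v not in seen:
            seen.add(v)
            variants.append(v)
    return variants


def _build_igs(
    cfg: SimConfig,
    rng: np.random.Generator,
    variants: list[str],
    igs_bg: str,
    igs_offset: int,
) -> tuple[str, list[TruthMonomer]]:
    """One IGS copy: the shared species background with a fresh satellite array.

    Tandem rDNA units within a species homogenise by concerted evolution,
    so the spacer background and the array position are species-level
    templates; only the monomer copies themselves re-mutate per unit.
    """
    if cfg.sat_copies_per_igs == 0:
        return igs_bg, []
    copies: list[tuple[str, int, float]] = []
    for _ in range(cfg.sat_copies_per_igs):
        v = int(rng.integers(0, len(variants)))
        mut = mutate_seq(variants[v], cfg.sat_divergence, rng, cfg.indel_rate)
        copies.append((mut, v, _realized_divergence(mut, variants[v])))
    seq = igs_bg[:igs_offset]
    monomers: list[TruthMonomer] = []
    for mut, v, rd in copies:
        monomers.append(TruthMonomer(len(seq), len(seq) + len(mut), v, rd, mut))
        seq += mut
    seq += igs_bg[igs_offset:]
    return seq, monomers


def _build_unit(
    cfg: SimConfig,
    rng: np.random.Generator,
    refs: dict[str, str],
    spacers: dict[str, str],
    variants: list[str],
    igs_bg: str,
    igs_offset: int,
) -> tuple[str, dict[str, tuple[int, int]], list[TruthMonomer]]:
    parts = []
    sub: dict[str, tuple[int, int]] = {}
    pos = 0
    igs_seq, monomers = _build_igs(cfg, rng, variants, igs_bg, igs_offset)
    layout = [
        ("ETS5", spacers["ETS5"]),
        ("18S", mutate_seq(refs["18S"], cfg.gene_divergence, rng)),
        ("ITS1", spacers["ITS1"]),
        ("5.8S", mutate_seq(refs["5.8S"], cfg.gene_divergence, rng)),
        ("ITS2", spacers["ITS2"]),
        ("28S", mutate_seq(refs["28S"], cfg.gene_divergence, rng)),
        ("ETS3", spacers["ETS3"]),
        ("IGS", igs_seq),
    ]
    for name, seq in layout:
        sub[name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)
    for m in monomers:
        off = sub["IGS"][0]
        m.start += off
        m.end += off
    return "".join(parts), sub, monomers


MAX_DEGENERATE_SPAN = 430


def _build_degenerate_unit(
    cfg: SimConfig,
    rng: np.random.Generator,
    refs: dict[str, str],
    spacers: dict[str, str],
    variants: list[str],
) -> tuple[str, dict, list[TruthMonomer]]:
    """A degenerate unit: 18S carrying an interior satellite array, 28S truncated.

    The array has 4-6 monomers (or ``degenerate_n_monomers``), tandem with
    short spacers, total span <= 430 bp, inserted ~150-250 bp after the 18S
    5' end. All subunits are diverged at ``degenerate_divergence``.
    """
    L = len(cfg.sat_monomer)
    n = cfg.degenerate_n_monomers
    if n is None:
        n = int(rng.integers(4, 7))
    if n * L > MAX_DEGENERATE_SPAN:
        raise ValueError(
            f"{n} monomers of {L} bp cannot fit the {MAX_DEGENERATE_SPAN} bp insertion span"
        )
    max_spacer = min(15, (MAX_DEGENERATE_SPAN - n * L) // max(1, n - 1))
    pieces: list[tuple[str | None, TruthMonomer | None]] = []
    array_seq = ""
    monomers: list[TruthMonomer] = []
    for i in range(n):
        v = int(rng.integers(0, len(variants)))
        mut = mutate_seq(variants[v], cfg.sat_divergence, rng, cfg.indel_rate)
        monomers.append(
            TruthMonomer(
                len(array_seq), len(array_seq) + len(mut), v,
                _realized_divergence(mut, variants[v]), mut, in_degenerate=True,
            )
        )
        array_seq += mut
        if i < n - 1 and max_spacer > 0:
            array_seq += _random_seq(rng, int(rng.integers(0, max_spacer + 1)))
    assert len(array_seq) <= MAX_DEGENERATE_SPAN

    g18 = mutate_seq(refs["18S"], cfg.degenerate_divergence, rng)
    insert_at = int(rng.integers(150, 251))
    g18_ins = g18[:insert_at] + array_seq + g18[insert_at:]
    for m in monomers:
        m.start += insert_at
        m.end += insert_at
    trunc = int(round(cfg.degenerate_28s_fraction * len(refs["28S"])))
    g28 = mutate_seq(refs["28S"][:trunc], cfg.degenerate_divergence, rng) if trunc else ""
    parts = [
        ("18S", g18_ins),
        ("ITS1", mutate_seq(spacers["ITS1"], cfg.degenerate_divergence, rng)),
        ("5.8S", mutate_seq(refs["5.8S"], cfg.degenerate_divergence, rng)),
        ("ITS2", mutate_seq(spacers["ITS2"], cfg.degenerate_divergence, rng)),
        ("28S", g28),
    ]
    sub: dict[str, tuple[int, int]] = {}
    pos = 0
    seq = ""
    for name, s in parts:
        sub[name] = (pos, pos + len(s))
        seq += s
        pos += len(s)
    info = {
        "subunits": sub,
        "n_monomers": n,
        "monomer_span": monomers[-1].end - monomers[0].start,
    }
    return seq, info, monomers


def make_genome(cfg: SimConfig) -> SimResult:
    """Emit the synthetic contig, reference sequences and truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    refs = {g: _random_seq(rng, n) for g, n in cfg.gene_lengths.items()}
    spacers = {
        "ITS1": _random_seq(rng, cfg.its_lengths[0]),
        "ITS2": _random_seq(rng, cfg.its_lengths[1]),
        "ETS5": _random_seq(rng, cfg.ets_lengths[0]),
        "ETS3": _random_seq(rng, cfg.ets_lengths[1]),
    }
    variants = _make_variants(cfg.sat_monomer.upper(), cfg.n_sat_variants, rng)
    nominal_span = cfg.sat_copies_per_igs * len(cfg.sat_monomer)
    igs_bg = _random_seq(rng, cfg.igs_length - nominal_span)
    igs_offset = int(rng.integers(20, len(igs_bg) - 20 + 1)) if cfg.sat_copies_per_igs else 0

    chunks: list[str] = []
    pos = 0

    def _emit(seq: str) -> int:
        nonlocal pos
        chunks.append(seq)
        start = pos
        pos += len(seq)
        return start

    arrays: list[TruthArray] = []
    monomers: list[TruthMonomer] = []
    degenerate: list[TruthDegenerate] = []

    _emit(_random_seq(rng, cfg.flank_background))
    for ai, n_units in enumerate(cfg.units_per_array):
        if ai > 0:
            _emit(_random_seq(rng, cfg.inter_array_gap))
        units: list[TruthUnit] = []
        arr_start = pos
        for _ in range(n_units):
            seq, sub, mono = _build_unit(cfg, rng, refs, spacers, variants, igs_bg, igs_offset)
            ustart = _emit(seq)
            units.append(
                TruthUnit(
                    ustart,
                    ustart + len(seq),
                    {k: (s + ustart, e + ustart) for k, (s, e) in sub.items()},
                )
            )
            for m in mono:
                m.start += ustart
                m.end += ustart
            monomers.extend(mono)
        arrays.append(TruthArray(arr_start, pos, units))

    decoy_5s = _random_seq(rng, 120)
    for _ in range(cfg.n_degenerate_units):
        # degenerate units sit well apart from the arrays (their own locus,
        # as dispersed copies are in real assemblies)
        _emit(_random_seq(rng, cfg.inter_array_gap))
        if cfg.add_5s_decoy:
            _emit((decoy_5s + _random_seq(rng, 80)) * 3)
        seq, info, mono = _build_degenerate_unit(cfg, rng, refs, spacers, variants)
        dstart = _emit(seq)
        for m in mono:
            m.start += dstart
            m.end += dstart
        monomers.extend(mono)
        g18s, g18e = info["subunits"]["18S"]
        degenerate.append(
            TruthDegenerate(
                start=dstart,
                end=dstart + len(seq),
                gene18s=(dstart + g18s, dstart + g18e),
                n_monomers=info["n_monomers"],
                monomer_span=info["monomer_span"],
            )
        )
    _emit(_random_seq(rng, cfg.flank_background))

    contig = SequenceRecord(cfg.contig_id, "".join(chunks))
    manifest = TruthManifest(
        contig_id=cfg.contig_id,
        contig_length=len(contig),
        arrays=arrays,
        monomers=monomers,
        degenerate=degenerate,
    )
    return SimResult(
        genome=[contig],
        refs={g: SequenceRecord(f"ref_{g.replace('.', '_')}", s) for g, s in refs.items()},
        sat_consensus=SequenceRecord("sat_consensus", cfg.sat_monomer.upper()),
        sat_variants=variants,
        manifest=manifest,
        config=cfg,
    )


def make_transcriptome_reads(
    cfg: SimConfig,
    genome: Sequence[SequenceRecord],
    manifest: TruthManifest,
    depth: int | None = None,
    ratio: float | None = None,
) -> list[SequenceRecord]:
    """Reads from the transcribed span (5'ETS..3'ETS) of the first unit.

    The rRNA-gene interior (18S start to 28S end, ITS included) is sampled
    at ``depth``-fold coverage and the two external transcribed spacers at
    ``depth/ratio``; no read comes from the IGS. Read starts are drawn with
    replacement, reads classified by their midpoint. Deterministic per
    config seed (a derived stream).
    """
    depth = cfg.read_depth if depth is None else depth
    ratio = cfg.gene_ets_ratio if ratio is None else ratio
    if depth == 0:
        return []
    if ratio <= 0:
        raise ValueError("gene:ETS ratio must be positive")
    unit = manifest.arrays[0].units[0]
    t0 = unit.subunits["ETS5"][0]
    t1 = unit.subunits["ETS3"][1]
    contig = {c.id: c for c in genome}[manifest.contig_id]
    transcript = contig.seq[t0:t1]
    L = cfg.read_length
    if L > len(transcript):
        raise ValueError("read_length exceeds transcript length")
    g_lo = unit.subunits["18S"][0] - t0
    g_hi = unit.subunits["28S"][1] - t0
    starts = np.arange(0, len(transcript) - L + 1)
    mid = starts + L // 2
    gene_starts = starts[(mid >= g_lo) & (mid < g_hi)]
    ets_starts = starts[(mid < g_lo) | (mid >= g_hi)]
    rng = np.random.default_rng(cfg.seed + 10_007)
    n_gene = int(round(depth * (g_hi - g_lo) / L))
    n_ets = int(round(depth / ratio * (len(transcript) - (g_hi - g_lo)) / L))
    chosen = np.concatenate(
        [
            rng.choice(gene_starts, size=n_gene, replace=True) if len(gene_starts) else [],
            rng.choice(ets_starts, size=n_ets, replace=True) if len(ets_starts) else [],
        ]
    ).astype(int)
    rng.shuffle(chosen)
    return [
        SequenceRecord(f"read_{i:06d}", transcript[s : s + L]) for i, s in enumerate(chosen)
    ]


def make_shotgun_reads(
    cfg: SimConfig,
    genome: Sequence[SequenceRecord],
    n_reads: int = 4000,
) -> list[SequenceRecord]:
    """Uniform genomic reads from the whole contig (for proportion estimates)."""
    rng = np.random.default_rng(cfg.seed + 20_011)
    contig = genome[0]
    L = cfg.read_length
    starts = rng.integers(0, len(contig) - L + 1, size=n_reads)
    return [SequenceRecord(f"gread_{i:06d}", contig.seq[s : s + L]) for i, s in enumerate(starts)]


def make_species_panel(
    n_species: int = 19,
    igs_range: tuple[int, int] = (295, 21_311),
    seed: int = 0,
    base_cfg: SimConfig | None = None,
) -> list[PanelSpecies]:
    """A panel of species differing only in IGS length.

    Unit length therefore varies exclusively through IGS expansion, the
    construction under which the rank correlation between IGS size and unit
    length is exactly 1. IGS lengths are drawn uniformly from ``igs_range``
    (defaults: the observed cross-species extremes, 295-21,311 bp).
    """
    if n_species < 4:
        raise ValueError("need at least 4 species for the correlation analysis")
    lo, hi = igs_range
    if base_cfg is None:
        base_cfg = SimConfig(
            units_per_array=(3,),
            sat_copies_per_igs=4,
            inter_array_gap=5_000,
            flank_background=6_000,
        )
    min_igs = base_cfg.sat_copies_per_igs * len(base_cfg.sat_monomer) + 40
    if not (min_igs <= lo < hi):
        raise ValueError(f"igs_range must satisfy {min_igs} <= lo < hi")
    rng = np.random.default_rng(seed)
    panel: list[PanelSpecies] = []
    for i in range(n_species):
        igs = int(rng.integers(lo, hi + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(base_cfg, igs_length=igs, seed=child_seed, n_arrays=None)
        sim = make_genome(cfg)
        panel.append(
            PanelSpecies(
                label=f"species_{i + 1:02d}",
                sim=sim,
                true_igs_length=igs,
                true_unit_length=cfg.unit_length,
            )
        )
    return panel


def make_diverged_spacer(
    consensus: str,
    n_copies: int,
    divergence: float,
    length: int = 2_000,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> tuple[SequenceRecord, list[TruthMonomer]]:
    """A random spacer with one planted tandem monomer array (test helper)."""
    rng = np.random.default_rng(seed)
    copies = []
    for _ in range(n_copies):
        mut = mutate_seq(consensus, divergence, rng, indel_rate)
        copies.append((mut, _realized_divergence(mut, consensus)))
    span = sum(len(c[0]) for c in copies)
    if length < span + 40:
        raise ValueError("spacer too short for the requested array")
    bg = _random_seq(rng, length - span)
    offset = int(rng.integers(20, len(bg) - 20 + 1))
    seq = bg[:offset]
    monomers = []
    for mut, rd in copies:
        monomers.append(TruthMonomer(len(seq), len(seq) + len(mut), 0, rd, mut))
        seq += mut
    seq += bg[offset:]
    return SequenceRecord(f"spacer_d{divergence:g}_s{seed}", seq), monomers


def write_fastq(reads: Sequence[SequenceRecord], path: str | Path, quality: str = "I") -> None:
    """FASTQ with uniform base quality."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quality * len(r.seq)}\n")
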