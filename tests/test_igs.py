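import numpy as np
import pytest

from rdnasat.annotate import RdnaUnit, annotate_subunits
from rdnasat.arrays import cluster_and_extend, extract_arrays, find_anchor_hits
from rdnasat.igs import (
    CoverageTrack,
    delimit_transcribed,
    genomic_proportion,
    igs_fallback,
    place_reads,
    read_depth_sam,
    read_depth_tsv,
    track_to_tsv,
)
from rdnasat.records import SequenceRecord
from rdnasat.simulate import make_transcriptome_reads

from conftest import SMALL_FLANK, SMALL_MAX_GAP


def _unit(array_id, start, end, iv, complete=True):
    return RdnaUnit(array_id=array_id, unit_index=0, start=start, end=end,
                    intervals=dict(iv), complete=complete)


def _two_unit_track(unit_len, sub, gene_depth=20, ets_depth=2):
    """Deterministic sharp-step track over two tandem units."""
    depth = np.zeros(2 * unit_len, dtype=int)
    for off in (0, unit_len):
        t0 = sub["ETS5"][0] + off
        t1 = sub["ETS3"][1] + off
        depth[t0:t1] = ets_depth
        depth[sub["18S"][0] + off : sub["28S"][1] + off] = gene_depth
    return depth


class TestPlaceReads:
    def test_exact_reads_pile_up_over_their_interval(self, small_sim):
        unit = small_sim.genome[0].slice(3000, 6000, "u")
        reads = [SequenceRecord(f"r{i}", unit.seq[500:600]) for i in range(100)]
        res = place_reads(reads, unit)
        assert res.n_placed == 100 and res.n_unplaced == 0
        assert (res.track.depth[500:600] == 100).all()
        assert res.track.depth[:500].sum() == 0 and res.track.depth[600:].sum() == 0

    def test_unrelated_reads_stay_unplaced(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        unit = SequenceRecord("u", "".join(bases[rng.integers(0, 4, 2000)]))
        reads = [
            SequenceRecord(f"r{i}", "".join(bases[rng.integers(0, 4, 100)])) for i in range(20)
        ]
        res = place_reads(reads, unit)
        assert res.n_placed == 0 and res.n_unplaced == 20
        assert res.track.depth.sum() == 0

    def test_k_longer_than_read_rejected(self):
        unit = SequenceRecord("u", "ACGT" * 100)
        with pytest.raises(ValueError):
            place_reads([SequenceRecord("r", "ACGTACGT")], unit, k=15)

    def test_gene_vs_ets_abundance_preserved(self, small_sim, small_cfg):
        reads = make_transcriptome_reads(
            small_cfg, small_sim.genome, small_sim.manifest, depth=20, ratio=10
        )
        tu = small_sim.manifest.arrays[0].units[0]
        t0, t1 = tu.subunits["ETS5"][0], tu.subunits["ETS3"][1]
        transcript = small_sim.genome[0].slice(t0, t1, "tx")
        res = place_reads(reads, transcript)
        d = res.track.depth
        g = slice(tu.subunits["18S"][0] - t0, tu.subunits["28S"][1] - t0)
        e5 = slice(0, tu.subunits["ETS5"][1] - t0)
        gene_mean = d[g].mean()
        ets_mean = d[e5].mean()
        assert 6 <= gene_mean / ets_mean <= 14


class TestDelimitTranscribed:
    @pytest.fixture()
    def two_units(self, small_sim, small_refs, small_cfg):
        hits = find_anchor_hits(small_sim.genome, small_sim.refs["5.8S"])
        regions = cluster_and_extend(
            hits, max_gap=SMALL_MAX_GAP, flank=SMALL_FLANK,
            genome_lengths={c.id: len(c) for c in small_sim.genome},
        )
        arrays = extract_arrays(small_sim.genome, regions)
        units = [u for u in annotate_subunits(arrays[0], small_refs) if u.complete]
        two = SequenceRecord("two", arrays[0].seq[units[0].start : units[2].start])
        return annotate_subunits(two, small_refs), small_cfg

    def test_sharp_step_recovers_planted_ets(self, two_units, small_sim):
        units, cfg = two_units
        tu = small_sim.manifest.arrays[0].units[0]
        rel = {k: (v[0] - tu.subunits["18S"][0], v[1] - tu.subunits["18S"][0])
               for k, v in tu.subunits.items()}
        unit_len = cfg.unit_length
        # unit phase is 18S-anchored; shift the template layout accordingly
        sub = {k: ((s + unit_len) % unit_len if k == "ETS5" else s, e)
               for k, (s, e) in rel.items()}
        depth = np.zeros(2 * unit_len, dtype=int)
        for off in (0, unit_len):
            depth[rel["18S"][0] + off : rel["28S"][1] + off] = 20
            depth[rel["28S"][1] + off : rel["ETS3"][1] + off] = 2
            e5s, e5e = rel["ETS5"]
            depth[e5s + unit_len + off : min(e5e + unit_len + off, 2 * unit_len)] = 2
        igs = delimit_transcribed(CoverageTrack("two", depth), units, rel_threshold=0.05)
        first = igs[0]
        assert abs(first.start - rel["ETS3"][1]) <= 10
        assert abs(first.end - (rel["ETS5"][0] + unit_len)) <= 10
        u0 = [u for u in units if u.complete][0]
        assert "ETS5" in u0.intervals and "ETS3" in u0.intervals

    def test_uniform_coverage_gives_empty_igs_with_warning(self, two_units):
        units, cfg = two_units
        depth = np.full(2 * cfg.unit_length, 10, dtype=int)
        with pytest.warns(UserWarning):
            igs = delimit_transcribed(CoverageTrack("two", depth), units)
        assert all(i.length == 0 for i in igs)

    def test_zero_threshold_keeps_only_zero_coverage_gap(self, two_units):
        units, cfg = two_units
        complete = [u for u in units if u.complete]
        depth = np.full(2 * cfg.unit_length, 3, dtype=int)
        gap_lo = complete[0].intervals["28S"][1] + 150
        gap_hi = gap_lo + 200
        depth[gap_lo:gap_hi] = 0
        igs = delimit_transcribed(CoverageTrack("two", depth), units, rel_threshold=0.0)
        assert (igs[0].start, igs[0].end) == (gap_lo, gap_hi)

    def test_all_zero_track_falls_back_to_flank_rule(self, two_units):
        units, cfg = two_units
        with pytest.warns(UserWarning, match="falling back"):
            igs = delimit_transcribed(
                CoverageTrack("two", np.zeros(2 * cfg.unit_length, dtype=int)), units
            )
        assert all(i.method == "flank-fallback" for i in igs)

    def test_igs_never_overlaps_gene_intervals(self, two_units, small_sim):
        units, cfg = two_units
        tu = small_sim.manifest.arrays[0].units[0]
        rel = {k: (v[0] - tu.subunits["18S"][0], v[1] - tu.subunits["18S"][0])
               for k, v in tu.subunits.items()}
        depth = np.zeros(2 * cfg.unit_length, dtype=int)
        for off in (0, cfg.unit_length):
            depth[rel["18S"][0] + off : rel["28S"][1] + off] = 20
        igs = delimit_transcribed(CoverageTrack("two", depth), units, rel_threshold=0.05)
        complete = [u for u in units if u.complete]
        for i in igs[:1]:
            for u in complete:
                for g in ("18S", "5.8S", "28S"):
                    gs, ge = u.intervals[g]
                    assert i.end <= gs or ge <= i.start


class TestIgsFallback:
    def test_flanking_rule_length(self):
        units = [
            _unit("a", 0, 9_380, {"18S": (0, 1800), "5.8S": (2000, 2160), "28S": (3000, 7000)}),
            _unit("a", 9_380, 19_000, {"18S": (9_380, 11_180), "5.8S": (11_300, 11_460),
                                       "28S": (12_000, 16_000)}),
        ]
        igs = igs_fallback(units)
        assert igs[0].length == 2_380
        assert igs[0].method == "flank-fallback"

    def test_abutting_genes_zero_length(self):
        units = [
            _unit("a", 0, 5_000, {"18S": (0, 1000), "5.8S": (1500, 1600), "28S": (2000, 5_000)}),
            _unit("a", 5_000, 10_000, {"18S": (5_000, 6_000), "5.8S": (6_500, 6_600),
                                       "28S": (7_000, 10_000)}),
        ]
        assert igs_fallback(units)[0].length == 0

    def test_minimal_observed_spacer_recovered(self):
        units = [
            _unit("a", 0, 7_295, {"18S": (0, 1800), "5.8S": (2000, 2160), "28S": (3000, 7000)}),
            _unit("a", 7_295, 14_000, {"18S": (7_295, 9_095), "5.8S": (9_200, 9_360),
                                       "28S": (10_000, 14_000)}),
        ]
        assert igs_fallback(units)[0].length == 295

    def test_single_incomplete_unit_rejected(self):
        with pytest.raises(ValueError):
            igs_fallback([_unit("a", 0, 100, {}, complete=False)])


class TestGenomicProportion:
    @pytest.mark.parametrize(
        "placed, total, expected",
        [(12, 100_000, 0.012), (0, 10, 0.0), (10, 10, 100.0)],
    )
    def test_values(self, placed, total, expected):
        assert genomic_proportion(placed, total) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            genomic_proportion(0, 0)


class TestCoverageIngestion:
    def test_depth_tsv_round_trip(self, tmp_path):
        track = CoverageTrack("u", np.array([0, 3, 5, 0, 1]))
        path = tmp_path / "depth.tsv"
        track_to_tsv(track, path)
        back = read_depth_tsv(path, "u", 5)
        assert (back.depth == track.depth).all()

    def test_sam_ingestion(self, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:u\tLN:50\n"
            "r1\t0\tu\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
            "r2\t0\tu\t6\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        track = read_depth_sam(sam, "u")
        assert track.depth[0:5].tolist() == [1] * 5
        assert track.depth[5:10].tolist() == [2] * 5
        assert track.depth[10:15].tolist() == [1] * 5
        assert track.depth[15:].sum() == 0
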