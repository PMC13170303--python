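import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdnasat.align import (
    LocalAlignment,
    ScoringScheme,
    alignments_to_tsv,
    mean_pairwise_identity,
    percent_identity,
    seeded_local_search,
    smith_waterman,
    star_align,
)
from rdnasat.records import SequenceRecord, reverse_complement
from rdnasat.simulate import mutate_seq

SIMPLE = ScoringScheme(match=1, mismatch=-2, gap_open=-2, gap_extend=-1)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestSmithWaterman:
    def test_perfect_self_alignment(self):
        aln = smith_waterman(
            SequenceRecord("a", "ACGTACGT"), SequenceRecord("b", "ACGTACGT"), SIMPLE
        )
        assert (aln.score, aln.pct_identity, aln.aligned_cols) == (8, 100.0, 8)
        assert (aln.q_start, aln.q_end, aln.s_start, aln.s_end) == (0, 8, 0, 8)

    def test_disjoint_alphabets_no_alignment(self):
        assert smith_waterman(SequenceRecord("a", "AAAA"), SequenceRecord("b", "TTTT"), SIMPLE) is None

    def test_single_substitution_monomer(self):
        rng = np.random.default_rng(7)
        mono = _random_seq(rng, 51)
        mut = list(mono)
        mut[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[25]]
        aln = smith_waterman(SequenceRecord("m", mono), SequenceRecord("n", "".join(mut)))
        assert (aln.matches, aln.aligned_cols) == (50, 51)
        assert aln.pct_identity == pytest.approx(98.04, abs=0.01)

    def test_n_never_matches(self):
        aln = smith_waterman(SequenceRecord("a", "ACGTNNACGT"), SequenceRecord("b", "ACGTNNACGT"))
        # the optimum avoids paying for the N block twice: either flank alone
        assert aln.matches == 4 or (aln.matches == 8 and aln.aligned_cols > 8)

    def test_score_symmetry_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = SequenceRecord("a", _random_seq(rng, int(rng.integers(10, 80))))
            b = SequenceRecord("b", _random_seq(rng, int(rng.integers(10, 160))))
            x, y = smith_waterman(a, b), smith_waterman(b, a)
            assert (x is None) == (y is None)
            if x is not None:
                assert x.score == y.score

    def test_identity_symmetric_for_homologous_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            s = _random_seq(rng, int(rng.integers(30, 120)))
            t = mutate_seq(s, float(rng.uniform(0, 0.2)), rng, indel_rate=0.01)
            x = smith_waterman(SequenceRecord("a", s), SequenceRecord("b", t))
            y = smith_waterman(SequenceRecord("b", t), SequenceRecord("a", s))
            assert x.pct_identity == pytest.approx(y.pct_identity)


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "matches, cols, expected",
        [(51, 51, 100.0), (25, 50, 50.0), (47, 51, 92.16)],
    )
    def test_values(self, matches, cols, expected):
        aln = LocalAlignment(
            "q", "s", 0, cols, 0, cols, "+", 1, cols, matches,
            100.0 * matches / cols, 1.0,
        )
        assert percent_identity(aln) == pytest.approx(expected, abs=0.005)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            LocalAlignment("q", "s", 0, 0, 0, 1, "+", 1, 0, 0, 0.0, 0.5)


class TestSeededSearch:
    def test_exact_planted_copy_found_and_matches_oracle(self):
        rng = np.random.default_rng(11)
        mono = _random_seq(rng, 51)
        subj = _random_seq(rng, 900) + mono + _random_seq(rng, 1000)
        hits = seeded_local_search(SequenceRecord("q", mono), SequenceRecord("s", subj))
        assert len(hits) == 1
        h = hits[0]
        assert (h.s_start, h.s_end, h.pct_identity) == (900, 951, 100.0)
        oracle = smith_waterman(SequenceRecord("q", mono), SequenceRecord("s", subj))
        assert (oracle.s_start, oracle.s_end) == (h.s_start, h.s_end)

    def test_heavily_diverged_copy_rejected(self):
        rng = np.random.default_rng(13)
        mono = _random_seq(rng, 51)
        copy = mutate_seq(mono, 0.6, rng)  # ~40% identity, below the 50% floor
        subj = _random_seq(rng, 800) + copy + _random_seq(rng, 800)
        hits = seeded_local_search(
            SequenceRecord("q", mono), SequenceRecord("s", subj), min_identity=50.0
        )
        assert hits == []

    def test_reverse_strand_reported_on_forward_coordinates(self):
        rng = np.random.default_rng(17)
        mono = _random_seq(rng, 51)
        subj = _random_seq(rng, 500) + reverse_complement(mono) + _random_seq(rng, 500)
        hits = seeded_local_search(SequenceRecord("q", mono), SequenceRecord("s", subj))
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].s_start, hits[0].s_end) == (500, 551)

    def test_reverse_complementing_subject_flips_strand_only(self):
        rng = np.random.default_rng(19)
        mono = _random_seq(rng, 51)
        copy = mutate_seq(mono, 0.08, rng)
        subj = _random_seq(rng, 400) + copy + _random_seq(rng, 400)
        fwd = seeded_local_search(SequenceRecord("q", mono), SequenceRecord("s", subj))
        rev = seeded_local_search(
            SequenceRecord("q", mono), SequenceRecord("s", reverse_complement(subj))
        )
        assert len(fwd) == len(rev) == 1
        assert fwd[0].strand != rev[0].strand
        assert fwd[0].score == rev[0].score
        assert fwd[0].pct_identity == pytest.approx(rev[0].pct_identity)
        n = len(subj)
        assert (rev[0].s_start, rev[0].s_end) == (n - fwd[0].s_end, n - fwd[0].s_start)

    def test_tandem_copies_all_recovered(self):
        rng = np.random.default_rng(23)
        mono = _random_seq(rng, 51)
        copies = [mutate_seq(mono, 0.05, rng) for _ in range(8)]
        subj = _random_seq(rng, 300) + "".join(copies) + _random_seq(rng, 300)
        hits = seeded_local_search(SequenceRecord("q", mono), SequenceRecord("s", subj))
        assert len(hits) == 8

    def test_word_size_exceeding_query_rejected(self):
        with pytest.raises(ValueError):
            seeded_local_search(
                SequenceRecord("q", "ACGT"), SequenceRecord("s", "ACGTACGT"), word_size=7
            )

    def test_hits_sorted_and_filters_respected(self):
        rng = np.random.default_rng(29)
        mono = _random_seq(rng, 51)
        subj = (
            _random_seq(rng, 200) + mono + _random_seq(rng, 400)
            + mutate_seq(mono, 0.1, rng) + _random_seq(rng, 200)
        )
        hits = seeded_local_search(
            SequenceRecord("q", mono), SequenceRecord("s", subj),
            min_identity=60.0, min_qcov=0.6,
        )
        assert [h.s_start for h in hits] == sorted(h.s_start for h in hits)
        for h in hits:
            assert h.pct_identity >= 60.0
            assert h.q_coverage >= 0.6


class TestStarAlign:
    def test_identical_copies_unanimous(self):
        rng = np.random.default_rng(31)
        center = SequenceRecord("c", _random_seq(rng, 51))
        rows, pfm = star_align([center] * 3, center)
        assert pfm.length == 51
        assert (pfm.counts.sum(axis=0) == 3).all()
        assert (pfm.counts.max(axis=0) == 3).all()
        assert pfm.consensus() == center.seq

    def test_single_deletion_recorded_as_one_gap_column(self):
        rng = np.random.default_rng(37)
        center = _random_seq(rng, 51)
        deleted = center[:20] + center[21:]
        _, pfm = star_align([SequenceRecord("d", deleted)], SequenceRecord("c", center))
        assert pfm.length == 51
        assert pfm.counts[4].sum() == 1

    def test_majority_base_recovers_center_under_divergence(self):
        rng = np.random.default_rng(41)
        center = _random_seq(rng, 60)
        agree = 0
        total = 0
        for rep in range(50):
            copies = [
                SequenceRecord(f"m{i}", mutate_seq(center, 0.05, rng)) for i in range(5)
            ]
            _, pfm = star_align(copies, SequenceRecord("c", center))
            cons = pfm.consensus(drop_gap_majority=False)
            agree += sum(a == b for a, b in zip(cons, center))
            total += len(center)
        assert agree / total >= 0.90

    def test_empty_monomer_list_rejected(self):
        with pytest.raises(ValueError):
            star_align([], SequenceRecord("c", "ACGT"))


class TestMeanPairwiseIdentity:
    def test_identical_sequences(self):
        recs = [SequenceRecord(f"s{i}", "ACGTACGTAC") for i in range(4)]
        assert mean_pairwise_identity(recs) == 100.0

    def test_no_alignment_counts_as_zero(self):
        recs = [
            SequenceRecord("1", "AAAA"),
            SequenceRecord("2", "TTTT"),
            SequenceRecord("3", "AAAA"),
        ]
        assert mean_pairwise_identity(recs) == pytest.approx(33.33, abs=0.01)

    def test_simulated_monomer_family_range(self):
        rng = np.random.default_rng(43)
        vals = []
        for rep in range(20):
            anc = _random_seq(rng, 51)
            fam = [SequenceRecord(f"m{i}", mutate_seq(anc, 0.05, rng)) for i in range(6)]
            vals.append(mean_pairwise_identity(fam))
        assert all(85.0 <= v <= 100.0 for v in vals)
        assert 88.0 <= float(np.mean(vals)) <= 98.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_identity([SequenceRecord("1", "ACGT")])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n_seqs=st.integers(min_value=1, max_value=6),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_pfm_columns_always_sum_to_n_sequences(n_seqs, seed):
    rng = np.random.default_rng(seed)
    center = _random_seq(rng, 40)
    monomers = [
        SequenceRecord(f"m{i}", mutate_seq(center, 0.1, rng, indel_rate=0.02))
        for i in range(n_seqs)
    ]
    _, pfm = star_align(monomers, SequenceRecord("c", center))
    assert (pfm.counts.sum(axis=0) == n_seqs).all()


def test_tsv_export_one_based_inclusive(tmp_path):
    aln = LocalAlignment("q", "s", 2, 10, 5, 13, "+", 16, 8, 8, 100.0, 0.8)
    path = tmp_path / "hits.tsv"
    alignments_to_tsv([aln], path)
    header, row = path.read_text().splitlines()
    fields = row.split("\t")
    assert header.split("\t")[0] == "qseqid"
    assert fields[4:8] == ["3", "10", "6", "13"]


def test_seeded_hits_agree_with_blastn_short():
    """Independent cross-check of the seeded search against NCBI blastn."""
    if shutil.which("blastn") is None:
        pytest.fail("blastn expected on PATH for the cross-check")
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(47)
    mono = _random_seq(rng, 51)
    copy = mutate_seq(mono, 0.08, rng)
    subj = _random_seq(rng, 700) + copy + _random_seq(rng, 700)
    with tempfile.TemporaryDirectory() as td:
        qf, sf = Path(td) / "q.fa", Path(td) / "s.fa"
        qf.write_text(f">q\n{mono}\n")
        sf.write_text(f">s\n{subj}\n")
        res = subprocess.run(
            [
                "blastn", "-task", "blastn-short", "-query", str(qf), "-subject", str(sf),
                "-outfmt", "6 sstart send pident", "-evalue", "1e-3",
            ],
            capture_output=True, text=True, check=True,
        )
    rows = [line.split("\t") for line in res.stdout.splitlines()]
    assert rows, "blastn found no hit for the planted copy"
    b_start, b_end, b_ident = int(rows[0][0]) - 1, int(rows[0][1]), float(rows[0][2])
    hits = seeded_local_search(SequenceRecord("q", mono), SequenceRecord("s", subj))
    assert len(hits) >= 1
    h = hits[0]
    overlap = min(h.s_end, b_end) - max(h.s_start, b_start)
    assert overlap > 0.8 * min(h.s_end - h.s_start, b_end - b_start)
    assert h.pct_identity == pytest.approx(b_ident, abs=6.0)
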