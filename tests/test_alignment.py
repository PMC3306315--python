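"""Aligner vs brute-force oracle; unique-resolution rules; SAM round trips."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vascde.alignment import (
    Aligner,
    AlignmentHit,
    SamParseError,
    align_read,
    correctly_paired,
    read_sam,
    resolve_pair,
    resolve_single,
    write_sam,
)
from vascde.synthetic import (
    Transcript,
    TranscriptSet,
    generate_transcriptome,
    reverse_complement,
    simulate_reads,
)


# -- independent brute-force oracle ----------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(
        1 for x, y in zip(a, b) if x != y or x == "N" or y == "N"
    )


def naive_hits(read: str, ts: TranscriptSet, max_mm: int) -> set:
    """Plain-Python scan of every offset on both strands."""
    out = set()
    rc = reverse_complement(read)
    for t in ts:
        for pos in range(t.length - len(read) + 1):
            window = t.sequence[pos : pos + len(read)]
            for strand, query in (("+", read), ("-", rc)):
                d = _hamming(window, query)
                if d <= max_mm:
                    out.add((t.gene_id, pos, strand, d))
    return out


def _as_set(hits):
    return {(h.gene_id, h.pos, h.strand, h.mismatches) for h in hits}


class TestAlignRead:
    def test_exact_substring_found(self, small_ts):
        t = small_ts.transcripts[3]
        read = t.sequence[40:70]
        hits = align_read(read, small_ts, max_mismatch=0)
        assert (t.gene_id, 40, "+", 0) in _as_set(hits)
        assert _as_set(hits) == naive_hits(read, small_ts, 0)

    def test_shared_segment_read_hits_both_genes(self, small_ts):
        seg = small_ts.shared_segments[0]
        read = small_ts[seg.gene_a].sequence[seg.pos_a : seg.pos_a + seg.length]
        genes = {h.gene_id for h in align_read(read, small_ts)}
        assert {seg.gene_a, seg.gene_b} <= genes

    def test_unrelated_read_unmappable(self, small_ts):
        rng = np.random.default_rng(99)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 76))
        oracle = naive_hits(read, small_ts, 4)
        assert oracle == set()  # brute-force confirms no placement within 4
        assert align_read(read, small_ts, 4) == []

    def test_reverse_complement_hit(self, small_ts):
        t = small_ts.transcripts[0]
        read = reverse_complement(t.sequence[10:60])
        assert (t.gene_id, 10, "-", 0) in _as_set(align_read(read, small_ts, 0))

    def test_n_counts_as_mismatch(self):
        ts = TranscriptSet([Transcript("g", "ACGTACGTACGT")])
        hits = align_read("ACGTN", ts, max_mismatch=1)
        by_pos = {(h.pos, h.strand): h.mismatches for h in hits}
        assert by_pos[(0, "+")] == 1

    def test_invalid_symbols_rejected(self, small_ts):
        with pytest.raises(ValueError):
            align_read("ACGU", small_ts)
        with pytest.raises(ValueError):
            align_read("", small_ts)

    @given(
        data=st.data(),
        max_mm=st.integers(min_value=0, max_value=4),
    )
    def test_equivalence_with_brute_force(self, data, max_mm):
        """Seeded search finds exactly the brute-force hit set."""
        n_tr = data.draw(st.integers(1, 4))
        transcripts = [
            Transcript(
                f"g{i}",
                data.draw(st.text(alphabet="ACGT", min_size=30, max_size=120)),
            )
            for i in range(n_tr)
        ]
        ts = TranscriptSet(transcripts)
        read = data.draw(st.text(alphabet="ACGTN", min_size=3, max_size=25))
        aligner = Aligner(ts, max_mm)
        assert _as_set(aligner.align(read)) == naive_hits(read, ts, max_mm)


def _hit(gene, pos=0, strand="+", mm=0, mate=None, rid="r"):
    return AlignmentHit(read_id=rid, gene_id=gene, pos=pos, strand=strand,
                        mismatches=mm, mate=mate)


class TestResolveSingle:
    def test_no_hits_unmapped(self):
        a = resolve_single([])
        assert a.status == "unmapped"

    def test_one_hit_unique(self):
        a = resolve_single([_hit("gA", 5)])
        assert a.status == "unique" and a.gene_id == "gA"

    def test_equal_mismatch_tie_ambiguous(self):
        a = resolve_single([_hit("gA", 5, mm=1), _hit("gB", 9, mm=1)])
        assert a.status == "ambiguous" and a.gene_id is None

    def test_better_hit_suppresses_worse(self):
        a = resolve_single([_hit("gA", 5, mm=0), _hit("gB", 9, mm=3)])
        assert a.status == "unique" and a.gene_id == "gA"

    def test_within_gene_tie_is_ambiguous_at_location_scope(self):
        hits = [_hit("gA", 5), _hit("gA", 50)]
        assert resolve_single(hits).status == "ambiguous"
        assert resolve_single(hits, unique_scope="gene").status == "unique"

    def test_mixed_read_ids_rejected(self):
        with pytest.raises(ValueError):
            resolve_single([_hit("gA", rid="r1"), _hit("gB", rid="r2")])


def oracle_resolve_pair(hits1, hits2, unique_scope="location"):
    """Independent exhaustive enumeration of all mate-hit combinations."""
    valid = []
    for h1, h2 in itertools.product(hits1, hits2):
        if h1.gene_id != h2.gene_id or h1.strand == h2.strand:
            continue
        fwd, rev = (h1, h2) if h1.strand == "+" else (h2, h1)
        if fwd.pos <= rev.pos:
            valid.append((h1, h2))
    if not valid:
        return ("unmapped", None)
    best = min(h1.mismatches + h2.mismatches for h1, h2 in valid)
    stratum = [v for v in valid if v[0].mismatches + v[1].mismatches == best]
    genes = {v[0].gene_id for v in stratum}
    if len(stratum) == 1:
        return ("unique", stratum[0][0].gene_id)
    if unique_scope == "gene" and len(genes) == 1:
        return ("unique", stratum[0][0].gene_id)
    return ("ambiguous", None)


class TestResolvePair:
    def test_single_proper_combination_unique(self):
        h1 = [_hit("gA", 10, "+", mate=1)]
        h2 = [_hit("gA", 110, "-", mate=2)]
        a = resolve_pair(h1, h2)
        assert a.status == "unique" and a.gene_id == "gA"

    def test_mates_on_different_genes_unmapped(self):
        a = resolve_pair([_hit("gA", 10, "+", mate=1)],
                         [_hit("gB", 110, "-", mate=2)])
        assert a.status == "unmapped"

    def test_two_valid_pairings_ambiguous(self):
        h1 = [_hit("gA", 10, "+", mate=1), _hit("gB", 10, "+", mate=1)]
        h2 = [_hit("gA", 110, "-", mate=2), _hit("gB", 110, "-", mate=2)]
        assert resolve_pair(h1, h2).status == "ambiguous"

    def test_same_strand_not_properly_paired(self):
        a = resolve_pair([_hit("gA", 10, "+", mate=1)],
                         [_hit("gA", 110, "+", mate=2)])
        assert a.status == "unmapped"

    def test_orientation_requires_forward_mate_upstream(self):
        assert not correctly_paired(_hit("gA", 200, "+"), _hit("gA", 10, "-"))
        assert correctly_paired(_hit("gA", 10, "+"), _hit("gA", 200, "-"))
        # the minus-strand mate may come first in the mate order
        assert correctly_paired(_hit("gA", 200, "-"), _hit("gA", 10, "+"))

    def test_agrees_with_enumeration_oracle_on_random_lists(self, rng):
        genes = ["gA", "gB", "gC"]
        for _ in range(2000):
            def draw(mate):
                k = rng.integers(0, 4)
                return [
                    _hit(genes[rng.integers(0, 3)], int(rng.integers(0, 100)),
                         "+-"[rng.integers(0, 2)], int(rng.integers(0, 5)),
                         mate=mate)
                    for _ in range(k)
                ]
            h1, h2 = draw(1), draw(2)
            a = resolve_pair(h1, h2)
            status, gene = oracle_resolve_pair(h1, h2)
            assert (a.status, a.gene_id) == (status, gene)

    def test_partition_over_simulated_read_set(self, small_ts):
        sim = simulate_reads(small_ts, [1.0] * len(small_ts), 200, 50,
                             paired=True, insert_len=140, seed=21)
        aligner = Aligner(small_ts, 4)
        statuses = []
        for (rid, s1), (_, s2) in zip(sim.mate1, sim.mate2):
            h1 = aligner.align(s1, read_id=rid, mate=1)
            h2 = aligner.align(s2, read_id=rid, mate=2)
            statuses.append(resolve_pair(h1, h2).status)
        counts = {s: statuses.count(s) for s in set(statuses)}
        assert sum(counts.values()) == 200


class TestSamIO:
    def _hits(self):
        return [
            _hit("gA", 4, "+", 0, mate=1, rid="p1"),
            _hit("gA", 90, "-", 2, mate=2, rid="p1"),
            _hit("gB", 7, "-", 1, rid="s1"),
        ]

    def _ts(self):
        return TranscriptSet(
            [Transcript("gA", "A" * 200), Transcript("gB", "C" * 150)]
        )

    def test_round_trip(self, tmp_path):
        path = str(tmp_path / "hits.sam")
        hits = self._hits()
        write_sam(hits, self._ts(), path)
        back = list(read_sam(path))
        assert sorted(back) == sorted(hits)

    def test_flag_semantics(self, tmp_path):
        path = tmp_path / "flags.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:gA\tLN:200\n"
            "r1\t16\tgA\t11\t255\t40M\t*\t0\t0\t*\t*\tNM:i:3\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        hits = list(read_sam(str(path)))
        assert len(hits) == 1  # unmapped record emits nothing
        assert hits[0].strand == "-" and hits[0].pos == 10  # 1-based -> 0-based
        assert hits[0].mismatches == 3

    def test_malformed_record_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:gA\tLN:200\n"
            "r1\tnotaflag\tgA\t11\t255\t*\t*\t0\t0\t*\t*\n"
        )
        with pytest.raises(SamParseError):
            list(read_sam(str(path)))
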