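"""Ungapped read alignment and unique-mapping resolution.

Reads are placed on the transcript set at every offset on both strands and
kept when the Hamming distance is at most ``max_mismatch`` (default 4).
This is a deliberate simplification of a gapped short-read aligner: the
downstream counting and testing statistics only consume the resolved
gene-level assignments, which are insensitive to the aligner's internals.

Resolution implements the correct-pairing rule for paired-end data: every
combination of the two mates' candidate placements is examined; a
combination is correctly paired when both mates land on the same gene, on
opposite strands, in forward/reverse orientation.  A read (or pair) is
"uniquely mapped" when exactly one placement (or placement pair) survives in
the best (minimal-mismatch) stratum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from .synthetic import TranscriptSet

__all__ = [
    "AlignmentHit",
    "ReadAssignment",
    "Aligner",
    "align_read",
    "resolve_single",
    "resolve_pair",
    "read_sam",
    "write_sam",
    "SamParseError",
]

_ENC = str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")
_N_CODE = 4

UniqueScope = Literal["location", "gene"]


class SamParseError(ValueError):
    """Raised when a SAM record cannot be interpreted."""


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One candidate ungapped placement of a read on a transcript."""

    read_id: str
    gene_id: str
    pos: int  # 0-based start on the transcript
    strand: str  # '+' read matches forward strand; '-' its reverse complement does
    mismatches: int
    mate: int | None = None  # 1, 2 or None for single-end

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.mismatches < 0 or self.pos < 0:
            raise ValueError("pos and mismatches must be non-negative")
        if self.mate not in (None, 1, 2):
            raise ValueError("mate must be 1, 2 or None")


@dataclass(frozen=True)
class ReadAssignment:
    """Resolved outcome for one read or read pair."""

    read_id: str
    status: Literal["unique", "ambiguous", "unmapped"]
    gene_id: str | None = None
    hits: tuple[AlignmentHit, ...] = ()

    def __post_init__(self) -> None:
        if self.status == "unique" and self.gene_id is None:
            raise ValueError("unique assignment requires a gene_id")
        if self.status != "unique" and self.gene_id is not None:
            raise ValueError("only unique assignments carry a gene_id")


def _encode(seq: str, what: str) -> np.ndarray:
    arr = np.frombuffer(seq.translate(_ENC).encode("latin-1"), dtype=np.uint8)
    if arr.size == 0:
        raise ValueError(f"empty {what}")
    if arr.max() > _N_CODE:
        raise ValueError(f"{what} contains symbols outside ACGTN")
    return arr


def _revcomp_codes(enc: np.ndarray) -> np.ndarray:
    rev = (3 - enc[::-1]).astype(np.uint8)
    rev[enc[::-1] == _N_CODE] = _N_CODE
    return rev


class Aligner:
    """Exhaustive ungapped (Hamming) aligner over a transcript set.

    Finds *every* placement of a read, on both strands and at every offset,
    with at most ``max_mismatch`` mismatches.  An ``N`` in either the read or
    the reference counts as a mismatch to everything.

    The search is pigeonhole seed-and-extend: the read is split into
    ``max_mismatch + 1`` disjoint seeds, so any qualifying placement matches
    at least one seed exactly; exact seed hits come from a k-mer index of the
    references and each candidate offset is then verified by full Hamming
    comparison.  This is exhaustive — identical output to a naive scan of
    every offset — just faster.  Reads shorter than ``max_mismatch + 1``
    bases fall back to the naive scan.
    """

    def __init__(self, ts: TranscriptSet, max_mismatch: int = 4) -> None:
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.ts = ts
        self.max_mismatch = max_mismatch
        self._enc = [(t.gene_id, _encode(t.sequence, f"transcript {t.gene_id}"))
                     for t in ts]
        self._index: dict[int, dict[bytes, list[tuple[int, int]]]] = {}

    def _seed_index(self, k: int) -> dict[bytes, list[tuple[int, int]]]:
        index = self._index.get(k)
        if index is None:
            index = {}
            for gi, (_, ref) in enumerate(self._enc):
                buf = ref.tobytes()
                for pos in range(len(buf) - k + 1):
                    index.setdefault(buf[pos : pos + k], []).append((gi, pos))
            self._index[k] = index
        return index

    def _verify(self, query: np.ndarray, gi: int, pos: int) -> int | None:
        ref = self._enc[gi][1]
        if pos < 0 or pos + query.size > ref.size:
            return None
        window = ref[pos : pos + query.size]
        mism = (window != query) | (window == _N_CODE) | (query == _N_CODE)
        d = int(mism.sum())
        return d if d <= self.max_mismatch else None

    def align(
        self, read: str, read_id: str = "read", mate: int | None = None
    ) -> list[AlignmentHit]:
        fwd = _encode(read, "read")
        rev = _revcomp_codes(fwd)
        n = fwd.size
        k = n // (self.max_mismatch + 1)
        hits: list[AlignmentHit] = []
        if k == 0:
            # Read too short to seed: scan every offset directly.
            for gi, (gene_id, ref) in enumerate(self._enc):
                for strand, query in (("+", fwd), ("-", rev)):
                    for pos in range(ref.size - n + 1):
                        d = self._verify(query, gi, pos)
                        if d is not None:
                            hits.append(AlignmentHit(read_id, gene_id, pos,
                                                     strand, d, mate))
            hits.sort(key=lambda h: (h.gene_id, h.pos, h.strand))
            return hits

        index = self._seed_index(k)
        for strand, query in (("+", fwd), ("-", rev)):
            qbuf = query.tobytes()
            candidates: set[tuple[int, int]] = set()
            for s in range(self.max_mismatch + 1):
                off = s * k
                for gi, pos in index.get(qbuf[off : off + k], ()):
                    candidates.add((gi, pos - off))
            for gi, pos in candidates:
                d = self._verify(query, gi, pos)
                if d is not None:
                    hits.append(
                        AlignmentHit(read_id, self._enc[gi][0], pos, strand,
                                     d, mate)
                    )
        hits.sort(key=lambda h: (h.gene_id, h.pos, h.strand))
        return hits


def align_read(
    read: str,
    ts: TranscriptSet,
    max_mismatch: int = 4,
    read_id: str = "read",
    mate: int | None = None,
) -> list[AlignmentHit]:
    """Align one read against ``ts``; see :class:`Aligner`.

    Convenience wrapper that re-encodes the references on every call; build
    an :class:`Aligner` once when mapping many reads.
    """
    return Aligner(ts, max_mismatch).align(read, read_id=read_id, mate=mate)


def _check_one_read(hits: Iterable[AlignmentHit]) -> str | None:
    ids = {h.read_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple reads: {sorted(ids)}")
    return next(iter(ids)) if ids else None


def resolve_single(
    hits: Sequence[AlignmentHit],
    unique_scope: UniqueScope = "location",
    read_id: str | None = None,
) -> ReadAssignment:
    """Resolve a single-end read's hits to unique / ambiguous / unmapped.

    Only the minimal-mismatch stratum is considered: a strictly better hit
    suppresses worse ones.  With ``unique_scope='location'`` (default) two
    tied placements anywhere — even within one gene — make the read
    ambiguous; ``'gene'`` collapses within-gene ties.
    """
    rid = _check_one_read(hits) or read_id or "read"
    if not hits:
        return ReadAssignment(read_id=rid, status="unmapped")
    best = min(h.mismatches for h in hits)
    stratum = [h for h in hits if h.mismatches == best]
    genes = {h.gene_id for h in stratum}
    if len(stratum) == 1 or (unique_scope == "gene" and len(genes) == 1):
        return ReadAssignment(
            read_id=rid, status="unique", gene_id=stratum[0].gene_id,
            hits=(stratum[0],),
        )
    return ReadAssignment(read_id=rid, status="ambiguous", hits=tuple(stratum))


def correctly_paired(h1: AlignmentHit, h2: AlignmentHit) -> bool:
    """FR pairing rule: same gene, opposite strands, forward mate upstream.

    No insert-size window is enforced beyond both mates lying on the same
    transcript.
    """
    if h1.gene_id != h2.gene_id or h1.strand == h2.strand:
        return False
    fwd, rev = (h1, h2) if h1.strand == "+" else (h2, h1)
    return fwd.pos <= rev.pos


def resolve_pair(
    hits1: Sequence[AlignmentHit],
    hits2: Sequence[AlignmentHit],
    unique_scope: UniqueScope = "location",
    read_id: str | None = None,
) -> ReadAssignment:
    """Resolve a read pair by examining all combinations of mate placements.

    Every (hit1, hit2) combination is tested with :func:`correctly_paired`;
    among correctly paired combinations only the minimal total-mismatch
    stratum is kept.  The pair is uniquely mapped when exactly one location
    pair survives (or, with ``unique_scope='gene'``, all survivors lie on one
    gene); ambiguous when several survive; unmapped when none pairs
    correctly.
    """
    rid1 = _check_one_read(hits1)
    rid2 = _check_one_read(hits2)
    if rid1 and rid2 and rid1 != rid2:
        raise ValueError(f"mate hits from different reads: {rid1!r} vs {rid2!r}")
    rid = rid1 or rid2 or read_id or "read"
    combos = [
        (h1, h2)
        for h1, h2 in itertools.product(hits1, hits2)
        if correctly_paired(h1, h2)
    ]
    if not combos:
        return ReadAssignment(read_id=rid, status="unmapped")
    best = min(h1.mismatches + h2.mismatches for h1, h2 in combos)
    stratum = [c for c in combos if c[0].mismatches + c[1].mismatches == best]
    genes = {c[0].gene_id for c in stratum}
    if len(stratum) == 1 or (unique_scope == "gene" and len(genes) == 1):
        h1, h2 = stratum[0]
        return ReadAssignment(
            read_id=rid, status="unique", gene_id=h1.gene_id, hits=(h1, h2)
        )
    flat = tuple(h for combo in stratum for h in combo)
    return ReadAssignment(read_id=rid, status="ambiguous", hits=flat)


# ---------------------------------------------------------------------------
# SAM subset I/O (single-segment or paired records aligned to transcripts)
# ---------------------------------------------------------------------------

def write_sam(
    hits: Iterable[AlignmentHit],
    ts: TranscriptSet,
    path: str,
    read_lengths: "dict[tuple[str, int | None], int] | int | None" = None,
) -> None:
    """Write hits as a minimal SAM file (columns 1-11 plus the NM tag).

    Sequences are not stored on hits, so records carry ``*`` for SEQ/QUAL
    and a nominal ``<len>M`` CIGAR.  ``read_lengths`` supplies real lengths
    (an int for uniform reads, or a ``(read_id, mate) -> length`` mapping);
    without it the CIGAR defaults to ``1M``, which still round-trips every
    hit field this package uses (reference, position, strand, NM, mate).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.gene_id, "LN": t.length} for t in ts],
    }
    tid = {t.gene_id: i for i, t in enumerate(ts)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for h in hits:
            if h.gene_id not in tid:
                raise ValueError(f"hit references unknown gene {h.gene_id!r}")
            if isinstance(read_lengths, dict):
                rlen = read_lengths.get((h.read_id, h.mate), 1)
            else:
                rlen = read_lengths or 1
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = h.read_id
            flag = 0
            if h.strand == "-":
                flag |= 0x10
            if h.mate is not None:
                flag |= 0x1 | (0x40 if h.mate == 1 else 0x80)
            rec.flag = flag
            rec.reference_id = tid[h.gene_id]
            rec.reference_start = h.pos
            rec.mapping_quality = 255
            rec.cigartuples = [(0, rlen)]
            rec.set_tag("NM", h.mismatches)
            out.write(rec)


def read_sam(path: str) -> Iterator[AlignmentHit]:
    """Yield :class:`AlignmentHit` from a SAM subset file.

    SAM's 1-based POS arrives via pysam already 0-based; FLAG bits decode
    strand (0x10) and mate (0x1/0x40/0x80); the NM tag carries the mismatch
    count (0 when absent).  Unmapped records (0x4) yield nothing.
    """
    import pysam

    try:
        infile = pysam.AlignmentFile(path, "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise SamParseError(f"{path}: {exc}") from exc
    with infile:
        lineno = len(str(infile.header).splitlines())
        while True:
            lineno += 1
            try:
                rec = next(infile)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise SamParseError(f"{path}: line {lineno}: {exc}") from exc
            if rec.is_unmapped:
                continue
            if rec.reference_name is None or rec.reference_start is None:
                raise SamParseError(
                    f"{path}: line {lineno}: mapped record without position"
                )
            mate: int | None = None
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            yield AlignmentHit(
                read_id=rec.query_name,
                gene_id=rec.reference_name,
                pos=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                mate=mate,
            )
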