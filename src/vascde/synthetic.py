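"""Synthetic transcriptomes, reads, and two-condition count data with known truth.

Everything downstream of this module (alignment, counting, the exact test)
is exercised on data generated here, so each generator records its ground
truth: shared-segment coordinates for the transcriptome, per-read origins
for the read simulator, and per-gene true fold changes for the count
simulator.

The count model is Poisson without overdispersion: pooled-count Fisher
testing is exact under independent Poisson/binomial sampling, and that is
the regime these simulations emulate.  An overdispersion knob is exposed
(negative-binomial mixing) but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Transcript",
    "SharedSegment",
    "TranscriptSet",
    "DESpec",
    "ReadTruth",
    "DEFAULT_FOLD_GRID",
    "generate_transcriptome",
    "simulate_counts",
    "simulate_reads",
    "make_spiked_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default true fold-change grid for spiked genes; spans the observed range of
#: induced genes (from just under 2x up to ~1900x for the strongest inductions).
DEFAULT_FOLD_GRID = (1.0, 1.9, 4.0, 32.0, 250.0, 1900.0)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """One reference transcript (a unigene-style entry)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id!r}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"non-ACGT symbols in {self.gene_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SharedSegment:
    """An engineered identical segment copied between two transcripts."""

    gene_a: str
    gene_b: str
    pos_a: int
    pos_b: int
    length: int


class TranscriptSet:
    """An ordered collection of transcripts with unique gene ids.

    Stands in for a unigene-style transcript database.  ``shared_segments``
    records deliberately duplicated stretches so tests can tell multi-mapping
    reads apart from uniquely placeable ones.
    """

    def __init__(
        self,
        transcripts: Sequence[Transcript],
        shared_segments: Sequence[SharedSegment] = (),
    ) -> None:
        self.transcripts = list(transcripts)
        self.shared_segments = list(shared_segments)
        ids = [t.gene_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in TranscriptSet")
        self._by_id = {t.gene_id: t for t in self.transcripts}

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Transcript:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.transcripts]

    @property
    def lengths(self) -> pd.Series:
        return pd.Series(
            {t.gene_id: t.length for t in self.transcripts}, name="length"
        ).reindex(self.gene_ids)

    def min_length(self) -> int:
        return min(t.length for t in self.transcripts)

    def overlaps_shared(self, gene_id: str, start: int, end: int) -> bool:
        """True if [start, end) on ``gene_id`` intersects any shared segment."""
        for seg in self.shared_segments:
            for g, p in ((seg.gene_a, seg.pos_a), (seg.gene_b, seg.pos_b)):
                if g == gene_id and start < p + seg.length and end > p:
                    return True
        return False


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth origin of one simulated read (one record per mate)."""

    read_id: str
    gene_id: str
    position: int  # 0-based start of the read on its transcript
    strand: str  # '+' if the read equals the transcript substring, '-' if revcomp
    mate: int | None  # 1, 2 or None for single-end
    mismatches: int  # planted substitution errors

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.mate not in (None, 1, 2):
            raise ValueError("mate must be 1, 2 or None")


@dataclass
class DESpec:
    """Specification of a two-condition count experiment.

    ``baseline`` holds per-gene relative expression weights for the control
    condition; ``fold_change`` the true condition-B/condition-A ratio per
    gene.  Each condition's weights are rescaled so its expected total equals
    ``depth`` (a sequencing run delivers a fixed number of fragments), then
    split evenly across ``n_lanes`` lanes.
    """

    gene_ids: list[str]
    baseline: np.ndarray
    fold_change: np.ndarray
    depth: float
    n_lanes: int = 1
    dispersion: float = 0.0  # NB shape 1/size; 0 -> pure Poisson

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        n = len(self.gene_ids)
        if self.baseline.shape != (n,) or self.fold_change.shape != (n,):
            raise ValueError("baseline and fold_change must match gene_ids")
        if np.any(self.baseline < 0) or np.any(self.fold_change < 0):
            raise ValueError("rates and fold changes must be non-negative")
        if not self.baseline.sum() >= 0:
            raise ValueError("baseline weights must be finite")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_lanes < 1:
            raise ValueError("n_lanes must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def frac_non_null(self) -> float:
        """Fraction of genes with a true fold change different from 1."""
        return float(np.mean(self.fold_change != 1.0))

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "fold_change": self.fold_change}
        )


def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int],
    shared_segment_spec: dict | None = None,
    seed: int = 0,
) -> TranscriptSet:
    """Generate ``n_genes`` random transcripts with optional shared segments.

    ``shared_segment_spec`` is ``{"n_pairs": int, "segment_len": int}``; for
    each designated pair an identical ``segment_len``-bp stretch is copied
    from the first gene into the second, guaranteeing that reads drawn from
    it map to (at least) two genes.  Deterministic for a fixed seed.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range!r}")
    spec = {"n_pairs": 0, "segment_len": 0}
    if shared_segment_spec:
        spec.update(shared_segment_spec)
    n_pairs, seg_len = int(spec["n_pairs"]), int(spec["segment_len"])
    if n_pairs < 0 or seg_len < 0:
        raise ValueError("shared_segment_spec values must be non-negative")
    if n_pairs > 0:
        if seg_len < 1:
            raise ValueError("segment_len must be positive when n_pairs > 0")
        if lo < seg_len:
            raise ValueError("minimum transcript length shorter than segment_len")
        if 2 * n_pairs > n_genes:
            raise ValueError("not enough genes for the requested shared pairs")

    rng = np.random.default_rng(seed)
    width = max(len(str(max(n_genes, 1))), 4)
    seqs = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seqs.append(_BASES[rng.integers(0, 4, size=length)].tobytes().decode())

    shared: list[SharedSegment] = []
    # Pairs are (0,1), (2,3), ...: deterministic and disjoint by construction.
    for k in range(n_pairs):
        ia, ib = 2 * k, 2 * k + 1
        pos_a = int(rng.integers(0, len(seqs[ia]) - seg_len + 1))
        pos_b = int(rng.integers(0, len(seqs[ib]) - seg_len + 1))
        segment = seqs[ia][pos_a : pos_a + seg_len]
        seqs[ib] = seqs[ib][:pos_b] + segment + seqs[ib][pos_b + seg_len :]
        shared.append(
            SharedSegment(
                gene_a=f"gene{ia:0{width}d}",
                gene_b=f"gene{ib:0{width}d}",
                pos_a=pos_a,
                pos_b=pos_b,
                length=seg_len,
            )
        )

    transcripts = [
        Transcript(gene_id=f"gene{i:0{width}d}", sequence=s) for i, s in enumerate(seqs)
    ]
    return TranscriptSet(transcripts, shared)


def simulate_counts(
    spec: DESpec, seed: int = 0
) -> tuple["CountTable", pd.DataFrame]:  # noqa: F821 (forward ref, see quantification)
    """Draw per-lane Poisson counts for both conditions of ``spec``.

    Returns a :class:`~vascde.quantification.CountTable` with ``n_lanes``
    columns per condition (labels ``control``/``oe``) and the true fold-change
    table.  Counts are independent Poisson draws with each gene's condition
    rate split evenly across lanes; with ``dispersion`` > 0 the rate is first
    jittered by a Gamma multiplier (negative-binomial marginal).
    """
    from .quantification import CountTable  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    w_a = spec.baseline.astype(float)
    w_b = w_a * spec.fold_change
    counts = {}
    meta = {}
    for cond, w in (("control", w_a), ("oe", w_b)):
        total = w.sum()
        rates = np.zeros_like(w) if total == 0 else w / total * spec.depth
        lane_rates = rates / spec.n_lanes
        for lane in range(1, spec.n_lanes + 1):
            lam = lane_rates
            if spec.dispersion > 0:
                shape = 1.0 / spec.dispersion
                lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
            name = f"{cond}_L{lane}"
            counts[name] = rng.poisson(lam)
            meta[name] = (cond, lane)

    counts_df = pd.DataFrame(counts, index=spec.gene_ids)
    samples = pd.DataFrame(
        {name: {"condition": c, "lane": l} for name, (c, l) in meta.items()}
    ).T
    samples.index.name = "sample_id"
    mapped_total = counts_df.sum(axis=0)
    table = CountTable(counts=counts_df, samples=samples, mapped_total=mapped_total)
    return table, spec.truth_table()


def make_spiked_spec(
    n_genes: int,
    depth: float,
    spikes: Sequence[tuple[float, float]] = (),
    n_lanes: int = 1,
    seed: int = 0,
    baseline_sigma: float = 1.0,
) -> DESpec:
    """Build a DESpec with log-normal null baselines plus spiked genes.

    ``spikes`` is a sequence of ``(fold_change, baseline_cpm)`` pairs; each
    occupies one gene (the first genes in order).  All remaining genes are
    null (fold 1) with log-normal relative expression.  Baselines are scaled
    so that spiked genes sit at the requested control-condition CPM.
    """
    if len(spikes) > n_genes:
        raise ValueError("more spikes than genes")
    rng = np.random.default_rng(seed)
    width = max(len(str(n_genes)), 4)
    gene_ids = [f"gene{i:0{width}d}" for i in range(n_genes)]
    baseline = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n_genes)
    fold = np.ones(n_genes)
    n_spike = len(spikes)
    if n_spike:
        null_mass = baseline[n_spike:].sum()
        spike_cpm = np.array([cpm for _, cpm in spikes], dtype=float)
        if np.any(spike_cpm <= 0) or spike_cpm.sum() >= 1e6:
            raise ValueError("spike CPMs must be positive and sum below 1e6")
        # Solve weights so that spike_i / total == cpm_i / 1e6 in condition A.
        scale = null_mass / (1.0 - spike_cpm.sum() / 1e6)
        baseline[:n_spike] = spike_cpm / 1e6 * scale
        fold[:n_spike] = [f for f, _ in spikes]
    return DESpec(
        gene_ids=gene_ids,
        baseline=baseline,
        fold_change=fold,
        depth=depth,
        n_lanes=n_lanes,
    )


@dataclass
class SimulatedReads:
    """Reads emitted by :func:`simulate_reads` plus their ground truth."""

    reads: list[tuple[str, str]]  # single-end: (read_id, sequence)
    mate1: list[tuple[str, str]] = field(default_factory=list)
    mate2: list[tuple[str, str]] = field(default_factory=list)
    truth: list[ReadTruth] = field(default_factory=list)
    paired: bool = False

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": t.read_id,
                    "gene_id": t.gene_id,
                    "position": t.position,
                    "strand": t.strand,
                    "mate": 0 if t.mate is None else t.mate,
                    "mismatches": t.mismatches,
                }
                for t in self.truth
            ]
        )


def _plant_errors(
    seq: str, error_rate: float, rng: np.random.Generator, max_mismatches: int | None
) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    while True:
        hits = np.flatnonzero(rng.random(arr.size) < error_rate)
        if max_mismatches is None or hits.size <= max_mismatches:
            break
    out = arr.copy()
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        out[i] = rng.choice(choices)
    return out.tobytes().decode(), int(hits.size)


def simulate_reads(
    ts: TranscriptSet,
    abundances: Sequence[float] | dict[str, float],
    n_reads: int,
    read_len: int,
    paired: bool = False,
    insert_len: int | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    max_mismatches: int | None = None,
    id_prefix: str = "read",
) -> SimulatedReads:
    """Simulate reads (or read pairs) from a transcript set.

    Fragments are drawn per gene from ``abundances`` (multinomial), with a
    uniform start position.  Paired mode emits FR-oriented mates with the
    minus-strand mate reverse-complemented; which mate is the forward one is
    randomized (unstranded library).  Substitution errors are planted i.i.d.
    at ``error_rate``; no indels, no quality model (qualities are constant
    when written as FASTQ).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads > 0 and len(ts) == 0:
        raise ValueError("cannot draw reads from an empty TranscriptSet")
    if len(ts) > 0:
        frag_len = read_len if not paired else (insert_len or 0)
        if paired:
            if insert_len is None or insert_len < read_len:
                raise ValueError("paired mode requires insert_len >= read_len")
        if read_len < 1:
            raise ValueError("read_len must be positive")
        if n_reads > 0 and frag_len > ts.min_length():
            raise ValueError(
                f"fragment length {frag_len} exceeds shortest transcript "
                f"({ts.min_length()} bp)"
            )
    if isinstance(abundances, dict):
        weights = np.array([abundances.get(g, 0.0) for g in ts.gene_ids], float)
    else:
        weights = np.asarray(abundances, dtype=float)
        if weights.shape != (len(ts),):
            raise ValueError("abundances must have one weight per transcript")
    if np.any(weights < 0):
        raise ValueError("abundances must be non-negative")

    out = SimulatedReads(reads=[], paired=paired)
    if n_reads == 0:
        return out
    if weights.sum() <= 0:
        raise ValueError("at least one abundance weight must be positive")

    rng = np.random.default_rng(seed)
    probs = weights / weights.sum()
    gene_idx = rng.choice(len(ts), size=n_reads, p=probs)
    width = max(len(str(n_reads)), 6)
    frag_len = insert_len if paired else read_len
    for i, gi in enumerate(gene_idx):
        tr = ts.transcripts[gi]
        start = int(rng.integers(0, tr.length - frag_len + 1))
        rid = f"{id_prefix}{i:0{width}d}"
        if not paired:
            fwd = bool(rng.integers(0, 2))
            window = tr.sequence[start : start + read_len]
            seq = window if fwd else reverse_complement(window)
            seq, nerr = _plant_errors(seq, error_rate, rng, max_mismatches)
            out.reads.append((rid, seq))
            out.truth.append(
                ReadTruth(rid, tr.gene_id, start, "+" if fwd else "-", None, nerr)
            )
        else:
            left = tr.sequence[start : start + read_len]
            right_start = start + frag_len - read_len
            right = reverse_complement(tr.sequence[right_start : right_start + read_len])
            # Unstranded library: mate 1 is the forward (left) read half the time.
            if rng.integers(0, 2):
                m1, m2 = (left, "+", start), (right, "-", right_start)
            else:
                m1, m2 = (right, "-", right_start), (left, "+", start)
            s1, e1 = _plant_errors(m1[0], error_rate, rng, max_mismatches)
            s2, e2 = _plant_errors(m2[0], error_rate, rng, max_mismatches)
            out.mate1.append((rid, s1))
            out.mate2.append((rid, s2))
            out.truth.append(ReadTruth(rid, tr.gene_id, m1[2], m1[1], 1, e1))
            out.truth.append(ReadTruth(rid, tr.gene_id, m2[2], m2[1], 2, e2))
    return out
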