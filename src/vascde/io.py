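"""File formats: FASTA, FASTQ, TSV matrices and result tables.

Sequence formats go through Biopython's SeqIO; SAM through pysam (see
:mod:`vascde.alignment`); tables through pandas.  Every file this package
writes begins with ``#`` provenance comment lines (tool version, seed,
config hash) which all readers skip.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .quantification import CountTable
from .synthetic import Transcript, TranscriptSet

__all__ = [
    "provenance_lines",
    "config_hash",
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_table_tsv",
    "read_table_tsv",
]

FASTQ_QUAL = "I"  # constant Phred+33 quality (Q40) for simulated reads


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, config: dict | None = None) -> list[str]:
    lines = [f"# vasc-de {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    return lines


def _write_comments(handle, comments: Sequence[str] | None) -> None:
    for line in comments or ():
        if not line.startswith("#"):
            line = "# " + line
        handle.write(line.rstrip("\n") + "\n")


# -- FASTA ------------------------------------------------------------------

def write_fasta(ts: TranscriptSet, path: str) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_id, description="")
        for t in ts
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> TranscriptSet:
    transcripts = [
        Transcript(gene_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
    return TranscriptSet(transcripts)


# -- FASTQ ------------------------------------------------------------------

def write_fastq(reads: Iterable[tuple[str, str]], path: str) -> None:
    """Write (read_id, sequence) pairs with constant quality ``I``."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{FASTQ_QUAL * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    """Read FASTQ (Phred+33); non-Phred33 quality symbols are a parse error."""
    out = []
    for rec in SeqIO.parse(path, "fastq"):  # SeqIO rejects qualities < '!'
        out.append((rec.id, str(rec.seq).upper()))
    return out


# -- count / expression matrices -------------------------------------------

def write_counts_tsv(
    ct: CountTable, path: str, comments: Sequence[str] | None = None
) -> None:
    """TSV count matrix; column headers are ``sample:condition:lane`` and a
    comment line carries the per-sample mapped totals."""
    header = [
        f"{s}:{ct.samples.loc[s, 'condition']}:{ct.samples.loc[s, 'lane']}"
        for s in ct.sample_ids
    ]
    totals = ";".join(f"{s}={int(ct.mapped_total[s])}" for s in ct.sample_ids)
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        fh.write(f"# mapped_total: {totals}\n")
        out = ct.counts.copy()
        out.columns = header
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t")


def read_counts_tsv(path: str) -> CountTable:
    totals: dict[str, int] = {}
    with open(path) as fh:
        comments = []
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            comments.append(line)
            pos = fh.tell()
        for line in comments:
            if line.startswith("# mapped_total:"):
                for item in line.split(":", 1)[1].strip().split(";"):
                    key, val = item.split("=")
                    totals[key.strip()] = int(val)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    sample_ids, conditions, lanes = [], [], []
    for col in df.columns:
        parts = col.split(":")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: column header {col!r} is not sample:condition:lane"
            )
        sample_ids.append(parts[0])
        conditions.append(parts[1])
        lanes.append(int(parts[2]))
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count entries")
    if not df.apply(lambda s: (s == s.astype(int)).all()).all():
        raise ValueError(f"{path}: non-integer count entries")
    df.columns = sample_ids
    samples = pd.DataFrame(
        {"condition": conditions, "lane": lanes},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    mapped_total = pd.Series(
        {s: totals.get(s, int(df[s].sum())) for s in sample_ids}
    ).reindex(sample_ids)
    return CountTable(counts=df.astype(int), samples=samples, mapped_total=mapped_total)


# -- generic result tables --------------------------------------------------

def write_table_tsv(
    df: pd.DataFrame, path: str, comments: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        df.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
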