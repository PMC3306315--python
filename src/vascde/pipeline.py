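"""End-to-end synthetic pipeline: simulate -> align -> count -> test -> report.

Given a :class:`~vascde.config.RunConfig`, generates a transcriptome with
engineered shared segments, simulates paired-end reads for a control and an
overexpression condition (a configurable set of spiked genes with a known
fold change), aligns and resolves unique read pairs, counts per gene and
lane, pools lanes per condition, and runs the Fisher/BH/fold-change calling.

All stage randomness derives from the single run seed via spawned seed
sequences, so a repeated run writes byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import Aligner, resolve_pair
from .config import RunConfig
from .de import call_de
from .io import (
    config_hash,
    provenance_lines,
    write_counts_tsv,
    write_fasta,
    write_fastq,
    write_table_tsv,
)
from .quantification import (
    CountTable,
    ResolutionTally,
    concat_samples,
    count_genes,
    pool_by_condition,
    rpkm,
)
from .synthetic import generate_transcriptome, make_spiked_spec, simulate_reads

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("vascde")


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    config: RunConfig
    transcripts: "TranscriptSet"  # noqa: F821
    counts: CountTable
    pooled: CountTable
    rpkm: pd.DataFrame
    de: pd.DataFrame
    truth: pd.DataFrame
    tallies: dict[str, ResolutionTally]
    outdir: Path | None = None


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on synthetic data; optionally write results to disk.

    Output files (all TSV/FASTA/FASTQ/JSON text): ``transcriptome.fasta``,
    per-sample FASTQ mates, ``counts.tsv``, ``rpkm.tsv``, ``de_results.tsv``,
    ``truth.tsv``, ``manifest.json`` and ``log.txt``.
    """
    root = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: _child_seed(child)
        for name, child in zip(
            ("transcriptome", "spec", "reads"), root.spawn(3)
        )
    }
    stage_log: list[str] = []

    def stage(msg: str) -> None:
        log.info(msg)
        stage_log.append(msg)

    stage(f"config: seed={cfg.seed} hash={config_hash(cfg.to_dict())}")

    ts = generate_transcriptome(
        cfg.n_genes,
        (cfg.length_min, cfg.length_max),
        {"n_pairs": cfg.shared_pairs, "segment_len": cfg.shared_segment_len},
        seed=seeds["transcriptome"],
    )
    stage(f"simulate: {len(ts)} transcripts, {len(ts.shared_segments)} shared segments")

    spec = make_spiked_spec(
        n_genes=cfg.n_genes,
        depth=cfg.n_read_pairs,
        spikes=[(cfg.spike_fold, cfg.spike_cpm)] * cfg.n_spikes,
        n_lanes=cfg.n_lanes,
        seed=seeds["spec"],
    )
    # Re-key the abundance spec onto the transcriptome's gene ids.
    spec.gene_ids = ts.gene_ids
    truth = spec.truth_table()
    weights = {"control": spec.baseline, "oe": spec.baseline * spec.fold_change}

    aligner = Aligner(ts, max_mismatch=cfg.max_mismatch)
    read_seed = np.random.SeedSequence(seeds["reads"])
    lane_seeds = iter(read_seed.spawn(2 * cfg.n_lanes))
    per_lane = cfg.n_read_pairs // cfg.n_lanes

    sample_tables: list[CountTable] = []
    tallies: dict[str, ResolutionTally] = {}
    fastqs: dict[str, tuple[list, list]] = {}
    for cond in ("control", "oe"):
        for lane in range(1, cfg.n_lanes + 1):
            sample_id = f"{cond}_L{lane}"
            sim = simulate_reads(
                ts,
                weights[cond],
                n_reads=per_lane,
                read_len=cfg.read_len,
                paired=True,
                insert_len=cfg.insert_len,
                error_rate=cfg.error_rate,
                seed=_child_seed(next(lane_seeds)),
                id_prefix=f"{sample_id}_",
            )
            assignments = []
            for (rid, s1), (_, s2) in zip(sim.mate1, sim.mate2):
                h1 = aligner.align(s1, read_id=rid, mate=1)
                h2 = aligner.align(s2, read_id=rid, mate=2)
                assignments.append(
                    resolve_pair(h1, h2, unique_scope=cfg.unique_scope, read_id=rid)
                )
            table, tally = count_genes(
                assignments,
                ts.gene_ids,
                sample_id,
                condition=cond,
                lane=lane,
                total_def=cfg.total_def,
            )
            sample_tables.append(table)
            tallies[sample_id] = tally
            fastqs[sample_id] = (sim.mate1, sim.mate2)
            stage(
                f"align/count {sample_id}: unique={tally.unique} "
                f"ambiguous={tally.ambiguous} unmapped={tally.unmapped}"
            )

    counts = concat_samples(sample_tables)
    pooled = pool_by_condition(counts)
    expr = rpkm(counts, ts.lengths)
    de = call_de(
        pooled,
        fc_threshold=cfg.fc_threshold,
        fdr=cfg.fdr,
        pseudocount=cfg.pseudocount,
    )
    n_up = int((de["call"] == "up").sum())
    n_down = int((de["call"] == "down").sum())
    stage(f"de: {len(de)} genes tested, {n_up} up, {n_down} down")

    result = PipelineResult(
        config=cfg,
        transcripts=ts,
        counts=counts,
        pooled=pooled,
        rpkm=expr,
        de=de,
        truth=truth,
        tallies=tallies,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = provenance_lines(cfg.seed, cfg.to_dict())
        write_fasta(ts, str(outdir / "transcriptome.fasta"))
        for sample_id, (m1, m2) in fastqs.items():
            write_fastq(m1, str(outdir / f"{sample_id}_R1.fastq"))
            write_fastq(m2, str(outdir / f"{sample_id}_R2.fastq"))
        write_counts_tsv(counts, str(outdir / "counts.tsv"), prov)
        expr_out = expr.reset_index().rename(columns={"index": "gene_id"})
        write_table_tsv(expr_out, str(outdir / "rpkm.tsv"), prov)
        write_table_tsv(de, str(outdir / "de_results.tsv"), prov)
        write_table_tsv(truth, str(outdir / "truth.tsv"), prov)
        manifest = {
            "tool": "vasc-de",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_hash": config_hash(cfg.to_dict()),
            "n_tested": int(len(de)),
            "n_up": n_up,
            "n_down": n_down,
            "tallies": {
                s: {"unique": t.unique, "ambiguous": t.ambiguous,
                    "unmapped": t.unmapped}
                for s, t in tallies.items()
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        (outdir / "log.txt").write_text("\n".join(stage_log) + "\n")
        result.outdir = outdir

    return result
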