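"""Orchestrated run: classify -> motifscan -> dupclass -> kaks -> express.

Each stage consumes the previous stage's output where applicable (motif
scanning runs on the kept genes of the classification stage); stages whose
inputs were not supplied are skipped with a logged notice.  A machine-readable
manifest records the package version, seed, parameters, and a SHA-256 checksum
of every file written — and contains nothing run-dependent beyond those, so
identical configurations produce byte-identical output directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .classify import classify_family, KEEP
from .config import PipelineConfig, load_refs
from .duplication import (
    HomologPair,
    chain_collinear_blocks,
    classify_duplications,
    write_collinearity,
    write_duplication_calls,
)
from .expression import fold_changes, write_expression_calls
from .io_formats import (
    read_cds_fasta,
    read_expression_tsv,
    read_fasta,
    read_gff3_gene_loci,
    read_hmm_tblout,
    read_homolog_pairs,
    read_orthogroups,
    write_classification_report,
)
from .kaks import kaks_table, write_kaks_table
from .motifscan import DEFAULT_MOTIFS, compile_motif, motif_conservation_report

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary_lines: list[str] = []

    kept_genes: dict[str, str] = {}

    # --- classification ---------------------------------------------------
    if cfg.groups and cfg.tblout and cfg.refs:
        groups = read_orthogroups(cfg.groups)
        hits = {
            sub: read_hmm_tblout(path, sub) for sub, path in sorted(cfg.tblout.items())
        }
        refs = load_refs(cfg.refs)
        result = classify_family(
            groups,
            hits,
            refs,
            completion_threshold=cfg.completion_threshold,
            partial_keep_below=cfg.partial_keep_below,
        )
        p = outdir / "decisions.tsv"
        write_classification_report(result.decisions, p)
        written.append(p)
        kept_genes = result.kept_genes
        for sub, thr in sorted(result.thresholds.items()):
            summary_lines.append(
                f"threshold[{sub}]: anchor={thr.anchor_id} "
                f"E-value={thr.evalue_cutoff:.3g}"
            )
        n_keep = sum(1 for d in result.decisions if d.verdict == KEEP)
        summary_lines.append(
            f"classification: {n_keep} kept of {len(result.decisions)} decisions"
        )
    else:
        log.info("classification stage skipped (groups/tblout/refs not supplied)")
        summary_lines.append("classification: skipped")

    # --- motif conservation ----------------------------------------------
    if cfg.fasta and kept_genes:
        records = read_fasta(cfg.fasta)
        patterns = dict(DEFAULT_MOTIFS)
        patterns.update(cfg.motifs)
        models = {
            sub: compile_motif(pat, name=sub)
            for sub, pat in patterns.items()
            if sub in set(kept_genes.values())
        }
        per_gene, summary = motif_conservation_report(
            {r.id: r.sequence for r in records},
            kept_genes,
            models,
            thresholds=cfg.pvalue_thresholds,
            granularity=cfg.granularity,
        )
        p = outdir / "motifs.tsv"
        per_gene.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
        for _, row in summary.iterrows():
            summary_lines.append(
                f"motifs[{row['subfamily']}]: "
                + ", ".join(
                    f"{c}={int(row[c])}" for c in summary.columns if c != "subfamily"
                )
            )
    else:
        log.info("motif stage skipped (no fasta or no kept genes)")
        summary_lines.append("motifs: skipped")

    # --- duplication / collinearity --------------------------------------
    if cfg.gff and cfg.pairs:
        loci = read_gff3_gene_loci(cfg.gff)
        pairs = [
            HomologPair(gene_a=a, gene_b=b, score=s)
            for a, b, s in read_homolog_pairs(cfg.pairs)
        ]
        blocks = chain_collinear_blocks(
            loci,
            pairs,
            min_block_size=cfg.min_block_size,
            max_gap=cfg.max_gap,
            anchor_score=cfg.anchor_score,
            gap_penalty=cfg.gap_penalty,
        )
        calls = classify_duplications(
            loci,
            pairs,
            blocks,
            proximal_rank=cfg.proximal_rank,
            tandem_rank=cfg.tandem_rank,
        )
        p = outdir / "duplication.tsv"
        write_duplication_calls(calls, p)
        written.append(p)
        p = outdir / "collinearity.txt"
        write_collinearity(blocks, p)
        written.append(p)
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.dup_type] = counts.get(c.dup_type, 0) + 1
        summary_lines.append(
            "duplication: "
            + ", ".join(f"{t}={n}" for t, n in sorted(counts.items()))
            + f"; {len(blocks)} collinear blocks"
        )
    else:
        log.info("duplication stage skipped (gff/pairs not supplied)")
        summary_lines.append("duplication: skipped")

    # --- Ka/Ks -------------------------------------------------------------
    if cfg.cds and cfg.cds_pairs:
        cds = read_cds_fasta(cfg.cds)
        pair_ids = [(a, b) for a, b, _ in read_homolog_pairs(cfg.cds_pairs)]
        df = kaks_table(pair_ids, cds)
        p = outdir / "kaks.tsv"
        write_kaks_table(df, p)
        written.append(p)
        valid = df["KaKs"].dropna()
        if len(valid):
            summary_lines.append(
                f"kaks: {len(df)} pairs, mean Ka/Ks={valid.mean():.3f}"
            )
    else:
        log.info("Ka/Ks stage skipped (cds/cds_pairs not supplied)")
        summary_lines.append("kaks: skipped")

    # --- expression --------------------------------------------------------
    if cfg.fpkm:
        table = read_expression_tsv(cfg.fpkm, cfg.control)
        calls = fold_changes(table, direction=cfg.direction)
        p = outdir / "expression.tsv"
        write_expression_calls(calls, p)
        written.append(p)
        n_sig = sum(1 for c in calls if c.label.startswith("significant"))
        summary_lines.append(
            f"expression: {len(calls)} calls, {n_sig} significant"
        )
    else:
        log.info("expression stage skipped (no fpkm supplied)")
        summary_lines.append("expression: skipped")

    # --- summary + manifest -----------------------------------------------
    p = outdir / "summary.txt"
    p.write_text("\n".join(summary_lines) + "\n")
    written.append(p)

    manifest = {
        "package": "genefam",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("outdir", "verbosity")
        },
        "outputs": {f.name: _sha256(f) for f in written},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
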