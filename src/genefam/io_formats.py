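"""Readers and writers for the external formats the pipeline touches.

Parsers are strict: malformed input raises :class:`ParseError` naming the
offending line rather than being silently repaired.  All genomic coordinates
are 1-based inclusive (GFF3 convention); gene *order* along a chromosome, not
base pairs, is what downstream proximity rules consume.

Formats covered
---------------
* FASTA (protein and nucleotide)
* OrthoMCL "groups" text (one cluster per line, ``GID: species|seqid ...``)
* HMMER3 per-target tabular output (tblout)
* GFF3 gene features (via :mod:`gffutils`)
* FPKM expression matrices and homolog-pair lists (TSV)
* the classification report (TSV)
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the 20 standard residues; X marks an unknown residue and is tolerated
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUC_ALPHABET = frozenset("ACGT")

_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


def gene_id_of(seq_id: str) -> str:
    """Collapse a transcript identifier to its gene id.

    Phytozome-style naming appends ``.N`` for the N-th transcript variant;
    ``AT5G07140.1`` -> ``AT5G07140``.  Ids without the suffix pass through.
    """
    return _TRANSCRIPT_SUFFIX.sub("", seq_id)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; ``id`` is the FASTA header token."""

    id: str
    sequence: str
    species: str = ""
    is_longest_variant: bool = True

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains illegal residues {sorted(bad)}"
            )

    @property
    def gene_id(self) -> str:
        return gene_id_of(self.id)


@dataclass(frozen=True)
class Orthogroup:
    """A named cluster of (species, gene_id, transcript_id) members."""

    group_id: str
    members: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"orthogroup {self.group_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"orthogroup {self.group_id!r} has duplicate members")

    @property
    def member_genes(self) -> tuple[str, ...]:
        """Unique member gene ids (transcript variants collapsed), sorted."""
        return tuple(sorted({g for _, g, _ in self.members}))


@dataclass(frozen=True)
class HmmHit:
    """One ranked hit from a profile-HMM search over a proteome."""

    target_id: str
    subfamily: str
    evalue: float
    bitscore: float
    rank: int

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError(f"hit {self.target_id!r}: E-value must be > 0")
        if self.rank < 1:
            raise ValueError(f"hit {self.target_id!r}: rank must be >= 1")

    @property
    def gene_id(self) -> str:
        return gene_id_of(self.target_id)


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    order_index: int  # 1-based rank of the gene along its chromosome by start

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class ExpressionTable:
    """FPKM matrix (genes x conditions) with one designated control column."""

    genes: list[str]
    conditions: list[str]
    control: str
    fpkm: np.ndarray

    def __post_init__(self):
        if self.control not in self.conditions:
            raise ValueError(f"control condition {self.control!r} not in table")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in expression table")
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.genes), len(self.conditions)):
            raise ValueError("FPKM matrix shape does not match genes x conditions")
        if (self.fpkm < 0).any():
            raise ValueError("FPKM values must be non-negative")

    def value(self, gene: str, condition: str) -> float:
        return float(
            self.fpkm[self.genes.index(gene), self.conditions.index(condition)]
        )

    def equals(self, other: "ExpressionTable") -> bool:
        return (
            self.genes == other.genes
            and self.conditions == other.conditions
            and self.control == other.control
            and np.allclose(self.fpkm, other.fpkm)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _read_fasta_raw(path, alphabet: frozenset) -> list[tuple[str, str]]:
    out = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    out.append((header, "".join(chunks)))
                token = line[1:].split()
                if not token:
                    raise ParseError("FASTA header with empty id", path, lineno)
                header, chunks = token[0], []
            else:
                if header is None:
                    raise ParseError(
                        "sequence data before first FASTA header", path, lineno
                    )
                seq = line.upper()
                bad = set(seq) - alphabet
                if bad:
                    raise ParseError(
                        f"illegal residue(s) {sorted(bad)} in sequence",
                        path,
                        lineno,
                    )
                chunks.append(seq)
    if header is not None:
        out.append((header, "".join(chunks)))
    return out


def read_fasta(path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file, preserving entry order."""
    records = []
    for rec_id, seq in _read_fasta_raw(path, AA_ALPHABET):
        if not seq:
            raise ParseError(f"entry {rec_id!r} has an empty sequence", path)
        records.append(ProteinRecord(id=rec_id, sequence=seq, species=species))
    return records


def read_cds_fasta(path) -> dict[str, str]:
    """Read in-frame coding sequences (gaps ``-`` allowed for aligned input)."""
    out: dict[str, str] = {}
    for rec_id, seq in _read_fasta_raw(path, NUC_ALPHABET | {"-", "N"}):
        if rec_id in out:
            raise ParseError(f"duplicate CDS id {rec_id!r}", path)
        out[rec_id] = seq
    return out


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# OrthoMCL groups
# ---------------------------------------------------------------------------


def read_orthogroups(path) -> list[Orthogroup]:
    """Parse an OrthoMCL-style groups file.

    One cluster per line: ``GROUPID: species|seqid species|seqid ...``.
    Singleton clusters (one member) are legal; duplicate group ids are not.
    """
    groups: list[Orthogroup] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError("groups line lacks 'GROUPID:' prefix", path, lineno)
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            if not gid:
                raise ParseError("empty group id", path, lineno)
            if gid in seen:
                raise ParseError(f"duplicate group id {gid!r}", path, lineno)
            seen.add(gid)
            members = []
            for token in rest.split():
                if "|" not in token:
                    raise ParseError(
                        f"member token {token!r} is not 'species|seqid'", path, lineno
                    )
                species, _, seqid = token.partition("|")
                if not species or not seqid:
                    raise ParseError(
                        f"member token {token!r} is not 'species|seqid'", path, lineno
                    )
                members.append((species, gene_id_of(seqid), seqid))
            if not members:
                raise ParseError(f"group {gid!r} has no members", path, lineno)
            try:
                groups.append(Orthogroup(group_id=gid, members=tuple(members)))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return groups


def write_orthogroups(groups: Sequence[Orthogroup], path) -> None:
    with open(path, "w") as fh:
        for g in groups:
            tokens = " ".join(f"{sp}|{tid}" for sp, _, tid in g.members)
            fh.write(f"{g.group_id}: {tokens}\n")


# ---------------------------------------------------------------------------
# HMMER3 tblout
# ---------------------------------------------------------------------------


def read_hmm_tblout(path, subfamily: str) -> list[HmmHit]:
    """Parse a HMMER3 per-target table into ranked hits.

    Ranks follow file order (the threshold rule is positional).  E-values that
    are out of ascending order are tolerated with a logged warning.
    """
    hits: list[HmmHit] = []
    prev_evalue = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"tblout row has {len(fields)} fields; expected >= 6", path, lineno
                )
            try:
                evalue = float(fields[4])
                bitscore = float(fields[5])
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric E-value/score in row: {fields[4]!r} {fields[5]!r}",
                    path,
                    lineno,
                ) from exc
            if evalue <= 0:
                raise ParseError("E-value must be > 0", path, lineno)
            if prev_evalue is not None and evalue < prev_evalue:
                log.warning(
                    "%s:%d: E-values out of ranked order (%g after %g); "
                    "ranks follow file order",
                    path,
                    lineno,
                    evalue,
                    prev_evalue,
                )
            prev_evalue = evalue
            hits.append(
                HmmHit(
                    target_id=fields[0],
                    subfamily=subfamily,
                    evalue=evalue,
                    bitscore=bitscore,
                    rank=len(hits) + 1,
                )
            )
    return hits


def write_hmm_tblout(hits: Sequence[HmmHit], path, query: str = "model") -> None:
    """Write hits in the HMMER3 per-target tabular dialect (subset of columns)."""
    with open(path, "w") as fh:
        fh.write("# target name\taccession\tquery name\taccession\t"
                 "E-value\tscore\tbias\n")
        for h in hits:
            fh.write(
                f"{h.target_id}\t-\t{query}\t-\t{h.evalue:.6g}\t{h.bitscore:.1f}\t0.0\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene loci
# ---------------------------------------------------------------------------


def read_gff3_gene_loci(path) -> list[GeneLocus]:
    """Extract gene features from GFF3 and rank them along each chromosome."""
    # gffutils would auto-name ID-less features; enforce the contract up front
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"GFF3 row has {len(cols)} columns; expected 9", path, lineno
                )
            if cols[2] == "gene" and "ID=" not in cols[8]:
                raise ParseError("gene feature lacks an ID attribute", path, lineno)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="error",
    )
    per_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes["ID"][0]
        per_chrom.setdefault(feat.seqid, []).append(
            (feat.start, feat.end, feat.strand, gene_id)
        )
    loci: list[GeneLocus] = []
    for chrom in sorted(per_chrom):
        entries = sorted(per_chrom[chrom], key=lambda e: (e[0], e[3]))
        for idx, (start, end, strand, gene_id) in enumerate(entries, start=1):
            loci.append(
                GeneLocus(
                    gene_id=gene_id,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    order_index=idx,
                )
            )
    return loci


def write_gff3(loci: Sequence[GeneLocus], path, source: str = "genefam") -> None:
    ordered = sorted(loci, key=lambda l: (l.chromosome, l.start, l.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in ordered:
            fh.write(
                f"{l.chromosome}\t{source}\tgene\t{l.start}\t{l.end}\t.\t"
                f"{l.strand}\t.\tID={l.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# expression + pairs TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(path, control_name: str) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"duplicate gene ids {dupes}", path)
    if control_name not in df.columns:
        raise ParseError(
            f"control condition {control_name!r} not among columns "
            f"{list(df.columns)}",
            path,
        )
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ParseError("negative FPKM value", path)
    return ExpressionTable(
        genes=[str(g) for g in df.index],
        conditions=[str(c) for c in df.columns],
        control=control_name,
        fpkm=values,
    )


def write_expression_tsv(table: ExpressionTable, path) -> None:
    df = pd.DataFrame(table.fpkm, index=table.genes, columns=table.conditions)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_homolog_pairs(path) -> list[tuple[str, str, float]]:
    """Read a 2- or 3-column TSV of homologous gene pairs (optional score)."""
    pairs: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("pair row needs >= 2 columns", path, lineno)
            a, b = fields[0], fields[1]
            if a == b:
                raise ParseError(f"self-pair {a!r}", path, lineno)
            score = 1.0
            if len(fields) >= 3 and fields[2]:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"non-numeric pair score {fields[2]!r}", path, lineno
                    ) from exc
            pairs.append((a, b, score))
    return pairs


def write_homolog_pairs(pairs: Iterable[tuple[str, str, float]], path) -> None:
    with open(path, "w") as fh:
        for a, b, score in pairs:
            fh.write(f"{a}\t{b}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# classification report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "gene_id",
    "subfamily",
    "cluster_id",
    "cluster_type",
    "evalue",
    "verdict",
    "reason_code",
    "ambiguous",
)


def write_classification_report(decisions, path) -> None:
    """TSV report, deterministically ordered by (subfamily, gene_id)."""
    rows = []
    for d in sorted(decisions, key=lambda d: (d.subfamily, d.gene_id)):
        rows.append(
            {
                "gene_id": d.gene_id,
                "subfamily": d.subfamily,
                "cluster_id": d.group_id or "",
                "cluster_type": d.cluster_type or "",
                "evalue": "" if d.evalue is None else f"{d.evalue:.6g}",
                "verdict": d.verdict,
                "reason_code": d.reason_code,
                "ambiguous": "AMBIGUOUS" if d.ambiguous else "",
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
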