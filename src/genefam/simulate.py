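"""Synthetic fixtures with known ground truth for every downstream module.

The generator emits internally consistent inputs for the whole pipeline:

* proteomes where planted family members carry their subfamily's diagnostic
  motif in a randomized kinase-like backbone while decoys do not;
* orthogroup files reflecting the true families, with a controllable
  contamination rate that moves decoys into family clusters;
* ranked profile-HMM hit tables whose E-values are drawn log-uniformly with a
  configurable separation (orders of magnitude) between members and decoys —
  generated directly, not by running a search binary, so the package has no
  runtime dependency on one;
* genomes (GFF3 + homolog-pair TSV) with planted segmental blocks, tandem and
  proximal neighbors, dispersed duplicates, and optional noise pairs;
* aligned codon pairs evolved under a configurable omega (Ka/Ks) and
  synonymous depth;
* FPKM tables with planted fold-change classes.

Each output draws from its own pseudo-random stream derived from the master
seed, so adding one fixture type never perturbs the others, and a fixed seed
reproduces every file byte-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from .classify import ReferenceSet
from .duplication import (
    DISPERSED,
    PROXIMAL,
    SINGLETON,
    TANDEM,
    WGD_SEGMENTAL,
    HomologPair,
)
from .io_formats import (
    ExpressionTable,
    GeneLocus,
    HmmHit,
    Orthogroup,
    ProteinRecord,
    write_fasta,
    write_gff3,
    write_hmm_tblout,
    write_homolog_pairs,
    write_orthogroups,
    write_expression_tsv,
)
from .kaks import GENETIC_CODE, STOP_CODONS, BASES
from .motifscan import AMINO_ACIDS, DEFAULT_MOTIFS, parse_pattern


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all fixture generators; seed fixes every output."""

    seed: int = 0
    # --- family / classification fixtures ---
    species: tuple[str, ...] = ("Ath", "Ghi", "Zma")  # first species anchors refs
    family_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"ZIK": 9, "MEKK": 12, "RAF": 15}
    )
    decoy_count: int = 40
    evalue_separation: float = 10.0  # orders of magnitude member->decoy
    cluster_contamination: float = 0.0
    cluster_size: int = 3  # member genes per multi-gene orthogroup
    backbone_length: tuple[int, int] = (250, 350)
    # --- genome / duplication fixtures ---
    chromosomes: tuple[str, ...] = ("A01", "A02", "D01", "D02")
    genes_per_chromosome: int = 80
    n_segmental_blocks: int = 2
    segmental_block_size: int = 6
    n_tandem: int = 4
    n_proximal: int = 4
    n_dispersed: int = 6
    noise_pair_rate: float = 0.0
    proximal_max_rank: int = 10
    # --- Ka/Ks fixtures ---
    n_cds_pairs: int = 20
    n_codons: int = 300
    omega: float = 0.2
    ks_depth: float = 0.3
    # --- expression fixtures ---
    conditions: tuple[str, ...] = ("CK", "cold", "heat", "drought", "salt")
    control_condition: str = "CK"
    fold_change_classes: tuple[float, ...] = (2.0, 1.3, 1.0, 0.7, 0.4)
    expression_noise_sd: float = 0.0

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator per named output stream."""
        return np.random.default_rng(
            [int(self.seed) % (2**31), zlib.crc32(stream.encode()) % (2**31)]
        )


# ---------------------------------------------------------------------------
# family fixture
# ---------------------------------------------------------------------------


@dataclass
class FamilyTruth:
    members: dict[str, tuple[str, ...]]  # subfamily -> member gene ids
    decoys: tuple[str, ...]
    known: tuple[str, ...]  # previously published gene ids (anchor species)
    species_of_gene: dict[str, str]

    @property
    def all_members(self) -> frozenset:
        return frozenset(g for genes in self.members.values() for g in genes)


@dataclass
class FamilyFixture:
    records: list[ProteinRecord]
    groups: list[Orthogroup]
    hits: dict[str, list[HmmHit]]
    refs: ReferenceSet
    truth: FamilyTruth


def _consensus_realization(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for col in parse_pattern(pattern):
        if col is None:
            out.append(AMINO_ACIDS[rng.integers(20)])
        else:
            choices = sorted(col)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)
    )


def simulate_family(config: SimulationConfig) -> FamilyFixture:
    """Proteomes, orthogroups, and ranked hit tables with planted families.

    Member E-values fall in the strong band 1e-120..1e-70 (log-uniform), the
    worst one is always assigned to an anchor-species reference gene (so the
    threshold rule recovers exactly the member/decoy boundary) and decoys fall
    ``evalue_separation`` orders of magnitude higher.  With contamination
    rate c, round(c * n_members) decoys are moved into family clusters; the
    last cluster of a subfamily is contaminated first, past the 50% completion
    mark, which guarantees partial clusters below the keep cutoff whenever the
    budget allows.
    """
    if not 0 <= config.cluster_contamination <= 1:
        raise ValueError("cluster_contamination must be in [0, 1]")
    if config.evalue_separation < 0:
        raise ValueError("evalue_separation must be >= 0")
    rng_seq = config.rng("family.sequences")
    rng_ev = config.rng("family.evalues")
    rng_cl = config.rng("family.clusters")

    species = config.species
    anchor = species[0]
    members: dict[str, list[str]] = {}
    records: list[ProteinRecord] = []
    species_of: dict[str, str] = {}
    for sub in sorted(config.family_sizes):
        n = config.family_sizes[sub]
        if n < 2:
            raise ValueError(f"family size for {sub} must be >= 2")
        genes = []
        for i in range(n):
            sp = species[i % len(species)]
            gene = f"{sp}{sub}{i + 1:03d}"
            genes.append(gene)
            species_of[gene] = sp
            lo, hi = config.backbone_length
            backbone = _random_protein(int(rng_seq.integers(lo, hi + 1)), rng_seq)
            pattern = DEFAULT_MOTIFS.get(sub, "GTxx(W/Y)MAPE")
            motif = _consensus_realization(pattern, rng_seq)
            pos = int(rng_seq.integers(20, len(backbone) - len(motif) - 20))
            seq = backbone[:pos] + motif + backbone[pos + len(motif):]
            records.append(
                ProteinRecord(id=f"{gene}.1", sequence=seq, species=sp)
            )
        members[sub] = genes
    decoys = []
    for i in range(config.decoy_count):
        sp = species[i % len(species)]
        gene = f"{sp}DEC{i + 1:03d}"
        decoys.append(gene)
        species_of[gene] = sp
        lo, hi = config.backbone_length
        records.append(
            ProteinRecord(
                id=f"{gene}.1",
                sequence=_random_protein(int(rng_seq.integers(lo, hi + 1)), rng_seq),
                species=sp,
            )
        )

    # ranked hit tables: members strong, decoys weak, separated bands
    hits: dict[str, list[HmmHit]] = {}
    sep = config.evalue_separation
    for sub in sorted(members):
        genes = members[sub]
        member_log10 = rng_ev.uniform(-120.0, -70.0, size=len(genes))
        # anchor-species reference must set the threshold: give it the max
        anchor_idx = [i for i, g in enumerate(genes) if g.startswith(anchor)]
        worst = int(np.argmax(member_log10))
        if worst not in anchor_idx:
            swap = anchor_idx[int(rng_ev.integers(len(anchor_idx)))]
            member_log10[worst], member_log10[swap] = (
                member_log10[swap],
                member_log10[worst],
            )
        decoy_lo = -70.0 + sep
        decoy_hi = max(decoy_lo + 1.0, -2.0)
        decoy_log10 = rng_ev.uniform(decoy_lo, decoy_hi, size=len(decoys))
        rows = [
            (f"{g}.1", 10.0 ** e) for g, e in zip(genes, member_log10)
        ] + [(f"{g}.1", 10.0 ** e) for g, e in zip(decoys, decoy_log10)]
        rows.sort(key=lambda r: (r[1], r[0]))
        hits[sub] = [
            HmmHit(
                target_id=tid,
                subfamily=sub,
                evalue=ev,
                bitscore=max(10.0, -10.0 * np.log10(ev)),
                rank=rank,
            )
            for rank, (tid, ev) in enumerate(rows, start=1)
        ]

    # orthogroups: per subfamily one singleton + multi-gene clusters, then
    # decoy clusters; contamination moves decoys into family clusters
    groups: list[Orthogroup] = []
    gid = 0
    contaminated_decoys: set[str] = set()
    for sub in sorted(members):
        genes = list(members[sub])
        singleton_gene = genes.pop()  # last member sits alone
        chunks = [
            genes[i : i + config.cluster_size]
            for i in range(0, len(genes), config.cluster_size)
        ]
        n_cont = round(config.cluster_contamination * len(members[sub]))
        pool = [d for d in decoys if d not in contaminated_decoys]
        assignments: list[list[str]] = [[] for _ in chunks]
        if n_cont and chunks:
            # contaminate the last cluster past majority first (guarantees a
            # partial cluster with completion ratio < 0.5 when budget allows)
            last = len(chunks) - 1
            want_last = len(chunks[last]) + 1
            k = 0
            while n_cont > 0 and pool:
                if len(assignments[last]) < want_last:
                    tgt = last
                else:
                    tgt = k % max(1, len(chunks) - 1) if len(chunks) > 1 else last
                    k += 1
                d = pool.pop(int(rng_cl.integers(len(pool))))
                assignments[tgt].append(d)
                contaminated_decoys.add(d)
                n_cont -= 1
                continue
        for ci, chunk in enumerate(chunks):
            gid += 1
            mem = [
                (species_of[g], g, f"{g}.1") for g in chunk + assignments[ci]
            ]
            groups.append(Orthogroup(group_id=f"OG{gid:04d}", members=tuple(mem)))
        gid += 1
        groups.append(
            Orthogroup(
                group_id=f"OG{gid:04d}",
                members=(
                    (species_of[singleton_gene], singleton_gene,
                     f"{singleton_gene}.1"),
                ),
            )
        )
        members[sub].sort()
    free_decoys = [d for d in decoys if d not in contaminated_decoys]
    for i in range(0, len(free_decoys), 5):
        chunk = free_decoys[i : i + 5]
        gid += 1
        groups.append(
            Orthogroup(
                group_id=f"OG{gid:04d}",
                members=tuple((species_of[d], d, f"{d}.1") for d in chunk),
            )
        )

    ref_members = {
        sub: tuple(
            f"{g}.1" for g in members[sub] if g.startswith(anchor)
        )
        for sub in members
    }
    known = tuple(
        sorted(g for genes in members.values() for g in genes if g.startswith(anchor))
    )
    refs = ReferenceSet(
        members=ref_members, force_include=frozenset(known)
    )
    truth = FamilyTruth(
        members={sub: tuple(sorted(v)) for sub, v in members.items()},
        decoys=tuple(decoys),
        known=known,
        species_of_gene=species_of,
    )
    return FamilyFixture(
        records=records, groups=groups, hits=hits, refs=refs, truth=truth
    )


def write_family_fixture(fix: FamilyFixture, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["proteins"] = outdir / "proteins.faa"
    write_fasta(fix.records, paths["proteins"])
    paths["groups"] = outdir / "groups.txt"
    write_orthogroups(fix.groups, paths["groups"])
    for sub, hits in sorted(fix.hits.items()):
        p = outdir / f"{sub}.tbl"
        write_hmm_tblout(hits, p, query=sub)
        paths[f"tblout:{sub}"] = p
    paths["refs"] = outdir / "refs.yaml"
    with open(paths["refs"], "w") as fh:
        yaml.safe_dump(
            {
                "members": {s: list(m) for s, m in sorted(fix.refs.members.items())},
                "force_include": sorted(fix.refs.force_include),
            },
            fh,
            sort_keys=True,
        )
    paths["truth"] = outdir / "truth_members.tsv"
    rows = []
    for sub, genes in sorted(fix.truth.members.items()):
        for g in genes:
            rows.append((g, sub, "member", fix.truth.species_of_gene[g]))
    for d in fix.truth.decoys:
        rows.append((d, "", "decoy", fix.truth.species_of_gene[d]))
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tsubfamily\trole\tspecies\n")
        for r in sorted(rows):
            fh.write("\t".join(r) + "\n")
    return paths


# ---------------------------------------------------------------------------
# genome fixture
# ---------------------------------------------------------------------------


@dataclass
class GenomeFixture:
    loci: list[GeneLocus]
    pairs: list[HomologPair]
    truth: dict[str, str]  # gene -> planted duplication type


def simulate_genome(config: SimulationConfig) -> GenomeFixture:
    """Ordered gene loci with planted duplication structure.

    Segmental blocks are order-preserving (or inverted, alternating) runs of
    ``segmental_block_size`` paired genes across chromosomes; tandem pairs sit
    at adjacent ranks, proximal pairs within 2..``proximal_max_rank`` ranks on
    one chromosome, dispersed pairs on different chromosomes.  Noise pairs
    (``noise_pair_rate`` x planted pair count) are uniform random gene pairs
    and may corrupt a small fraction of planted types.
    """
    rng = config.rng("genome")
    chroms = config.chromosomes
    n_slots = config.genes_per_chromosome
    used: dict[str, set[int]] = {c: set() for c in chroms}

    def alloc_run(chrom: str, length: int) -> list[int]:
        for _ in range(1000):
            start = int(rng.integers(1, n_slots - length + 2))
            slots = list(range(start, start + length))
            if not used[chrom] & set(slots):
                used[chrom].update(slots)
                return slots
        raise RuntimeError(f"cannot allocate a free run of {length} on {chrom}")

    def gene_at(chrom: str, slot: int) -> str:
        return f"{chrom}g{slot:03d}"

    truth: dict[str, str] = {}
    pairs: list[HomologPair] = []

    for k in range(config.n_segmental_blocks):
        ca = chroms[(2 * k) % len(chroms)]
        cb = chroms[(2 * k + 1) % len(chroms)]
        size = config.segmental_block_size
        run_a = alloc_run(ca, size)
        run_b = alloc_run(cb, size)
        inverted = k % 2 == 1
        partner = list(reversed(run_b)) if inverted else run_b
        for sa, sb in zip(run_a, partner):
            ga, gb = gene_at(ca, sa), gene_at(cb, sb)
            pairs.append(HomologPair(gene_a=ga, gene_b=gb))
            truth[ga] = truth[gb] = WGD_SEGMENTAL

    for k in range(config.n_tandem):
        chrom = chroms[k % len(chroms)]
        s = alloc_run(chrom, 2)
        ga, gb = gene_at(chrom, s[0]), gene_at(chrom, s[1])
        pairs.append(HomologPair(gene_a=ga, gene_b=gb))
        truth[ga] = truth[gb] = TANDEM

    for k in range(config.n_proximal):
        chrom = chroms[(k + 1) % len(chroms)]
        gap = int(rng.integers(2, config.proximal_max_rank + 1))
        s = alloc_run(chrom, gap + 1)
        ga, gb = gene_at(chrom, s[0]), gene_at(chrom, s[-1])
        pairs.append(HomologPair(gene_a=ga, gene_b=gb))
        truth[ga] = truth[gb] = PROXIMAL

    for k in range(config.n_dispersed):
        ca = chroms[k % len(chroms)]
        cb = chroms[(k + 2) % len(chroms)] if len(chroms) > 2 else chroms[
            (k + 1) % len(chroms)
        ]
        if ca == cb:
            cb = chroms[(k + 1) % len(chroms)]
        ga = gene_at(ca, alloc_run(ca, 1)[0])
        gb = gene_at(cb, alloc_run(cb, 1)[0])
        pairs.append(HomologPair(gene_a=ga, gene_b=gb))
        truth[ga] = truth[gb] = DISPERSED

    loci: list[GeneLocus] = []
    strands = "+-"
    for chrom in chroms:
        for slot in range(1, n_slots + 1):
            gene = gene_at(chrom, slot)
            truth.setdefault(gene, SINGLETON)
            start = (slot - 1) * 1000 + 1
            loci.append(
                GeneLocus(
                    gene_id=gene,
                    chromosome=chrom,
                    start=start,
                    end=start + 599,
                    strand=strands[int(rng.integers(2))],
                    order_index=slot,
                )
            )

    n_noise = round(config.noise_pair_rate * len(pairs))
    all_genes = [l.gene_id for l in loci]
    existing = {p.key for p in pairs}
    added = 0
    while added < n_noise:
        i, j = rng.integers(0, len(all_genes), size=2)
        if i == j:
            continue
        p = HomologPair(gene_a=all_genes[int(i)], gene_b=all_genes[int(j)])
        if p.key in existing:
            continue
        existing.add(p.key)
        pairs.append(p)
        added += 1

    return GenomeFixture(loci=loci, pairs=pairs, truth=truth)


def write_genome_fixture(fix: GenomeFixture, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": outdir / "genome.gff3",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth_duplication.tsv",
    }
    write_gff3(fix.loci, paths["gff"])
    write_homolog_pairs(
        [(p.gene_a, p.gene_b, p.score) for p in fix.pairs], paths["pairs"]
    )
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tdup_type\n")
        for g in sorted(fix.truth):
            fh.write(f"{g}\t{fix.truth[g]}\n")
    return paths


# ---------------------------------------------------------------------------
# codon-pair fixture
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


@dataclass
class CdsPairFixture:
    ids: list[tuple[str, str]]
    sequences: dict[str, str]
    true_omega: dict[tuple[str, str], float]


def _evolve(codons: list[str], depth: float, omega: float,
            rng: np.random.Generator) -> list[str]:
    """Propose ~3*L*depth point mutations; accept synonymous ones always,
    nonsynonymous with probability omega, and never create a stop codon."""
    out = list(codons)
    n_prop = int(rng.poisson(3 * len(out) * depth))
    for _ in range(n_prop):
        ci = int(rng.integers(len(out)))
        pos = int(rng.integers(3))
        base = BASES[int(rng.integers(4))]
        codon = out[ci]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        syn = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
        if syn or rng.random() < omega:
            out[ci] = mutant
    return out


def simulate_cds_pairs(config: SimulationConfig) -> CdsPairFixture:
    """Aligned codon pairs diverged under the configured omega and Ks depth.

    Each pair descends from a random ancestral sequence of sense codons; each
    branch receives an expected ``ks_depth / 2`` proposed substitutions per
    nucleotide site, so the pairwise synonymous distance is ~``ks_depth`` and
    the expected Ka/Ks equals ``omega``.  No indels.
    """
    rng = config.rng("cds")
    ids: list[tuple[str, str]] = []
    seqs: dict[str, str] = {}
    omegas: dict[tuple[str, str], float] = {}
    for k in range(config.n_cds_pairs):
        ancestor = [
            _SENSE_CODONS[int(i)]
            for i in rng.integers(0, len(_SENSE_CODONS), size=config.n_codons)
        ]
        a = _evolve(ancestor, config.ks_depth / 2, config.omega, rng)
        b = _evolve(ancestor, config.ks_depth / 2, config.omega, rng)
        id_a, id_b = f"dup{k + 1:03d}a", f"dup{k + 1:03d}b"
        ids.append((id_a, id_b))
        seqs[id_a] = "".join(a)
        seqs[id_b] = "".join(b)
        omegas[(id_a, id_b)] = config.omega
    return CdsPairFixture(ids=ids, sequences=seqs, true_omega=omegas)


def write_cds_fixture(fix: CdsPairFixture, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds": outdir / "cds.fna",
        "pairs": outdir / "cds_pairs.tsv",
        "truth": outdir / "truth_omega.tsv",
    }
    with open(paths["cds"], "w") as fh:
        for sid in fix.sequences:
            fh.write(f">{sid}\n")
            s = fix.sequences[sid]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    with open(paths["pairs"], "w") as fh:
        for a, b in fix.ids:
            fh.write(f"{a}\t{b}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("id_a\tid_b\tomega\n")
        for (a, b), w in fix.true_omega.items():
            fh.write(f"{a}\t{b}\t{w}\n")
    return paths


# ---------------------------------------------------------------------------
# expression fixture
# ---------------------------------------------------------------------------


@dataclass
class ExpressionFixture:
    table: ExpressionTable
    truth: pd.DataFrame  # gene_id, condition, planted_fc, planted_label


def simulate_expression(
    config: SimulationConfig, gene_ids: Sequence[str]
) -> ExpressionFixture:
    """FPKM table with fold-change classes planted cyclically per gene/condition.

    Control FPKM is log-normal (median ~4.5) floored at 2 so that the planted
    down-classes remain representable as non-negative FPKM; treatment FPKM is
    ``fc * (control + 1) - 1`` times optional multiplicative noise, so the
    +1-offset fold change recovers ``fc`` exactly in the noise-free setting.
    """
    rng = config.rng("expression")
    classes = config.fold_change_classes
    conditions = list(config.conditions)
    control = config.control_condition
    if control not in conditions:
        raise ValueError("control condition missing from condition list")
    treat_conditions = [c for c in conditions if c != control]
    fpkm = np.zeros((len(gene_ids), len(conditions)))
    rows = []
    ctrl_idx = conditions.index(control)
    for gi, gene in enumerate(gene_ids):
        ctrl = max(2.0, float(rng.lognormal(mean=1.5, sigma=0.5)))
        fpkm[gi, ctrl_idx] = ctrl
        for ti, cond in enumerate(treat_conditions):
            fc = classes[(gi + ti) % len(classes)]
            treat = fc * (ctrl + 1.0) - 1.0
            if config.expression_noise_sd > 0:
                treat = (treat + 1.0) * float(
                    rng.lognormal(mean=0.0, sigma=config.expression_noise_sd)
                ) - 1.0
            treat = max(0.0, treat)
            fpkm[gi, conditions.index(cond)] = treat
            rows.append(
                {
                    "gene_id": gene,
                    "condition": cond,
                    "planted_fc": fc,
                    "planted_label": expr.label_fold_change(fc),
                }
            )
    table = ExpressionTable(
        genes=list(gene_ids), conditions=conditions, control=control, fpkm=fpkm
    )
    return ExpressionFixture(table=table, truth=pd.DataFrame(rows))


def write_expression_fixture(fix: ExpressionFixture, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fpkm": outdir / "fpkm.tsv",
        "truth": outdir / "truth_expression.tsv",
    }
    write_expression_tsv(fix.table, paths["fpkm"])
    fix.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_all_fixtures(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write every fixture type into one directory."""
    outdir = Path(outdir)
    fam = simulate_family(config)
    paths = write_family_fixture(fam, outdir)
    paths.update(write_genome_fixture(simulate_genome(config), outdir))
    paths.update(write_cds_fixture(simulate_cds_pairs(config), outdir))
    genes = sorted(fam.truth.members.get("RAF", fam.truth.all_members))
    paths.update(
        write_expression_fixture(simulate_expression(config, genes), outdir)
    )
    return paths
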