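"""Ka/Ks estimation for duplicate gene pairs (Nei–Gojobori counting).

Synonymous and nonsynonymous *sites* are counted per codon as the fraction of
the nine single-nucleotide changes that preserve the encoded residue
(mutations creating a stop codon count as nonsynonymous).  Substitutions
between codons differing at several positions are averaged over all minimal
mutational pathways, skipping pathways that pass through a stop codon (all
pathways are used if every ordering is blocked).  The resulting proportions
are corrected for multiple hits with the Jukes–Cantor formula

    d = -(3/4) * ln(1 - (4/3) p)

and the ratio omega = Ka/Ks is reported only when Ks > 0.  omega << 1
indicates purifying selection, ~1 neutral evolution, >> 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import pandas as pd

BASES = "ACGT"

#: the standard genetic code, * = stop
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


class SaturationError(ValueError):
    """Raised when a substitution proportion is beyond the JC correction range."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gapless, in-frame pairwise codon alignment."""

    id_a: str
    id_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists differ in length")
        if not self.codons_a:
            raise ValueError("empty codon alignment")
        for codons, which in ((self.codons_a, self.id_a), (self.codons_b, self.id_b)):
            for c in codons:
                if len(c) != 3 or set(c) - set(BASES):
                    raise ValueError(f"{which}: invalid codon {c!r}")
                if c in STOP_CODONS:
                    raise ValueError(f"{which}: internal stop codon {c}")

    def __len__(self) -> int:
        return len(self.codons_a)

    @classmethod
    def from_sequences(
        cls, id_a: str, seq_a: str, id_b: str, seq_b: str
    ) -> "CodonAlignment":
        """Build from two aligned nucleotide strings, dropping gapped codons.

        A trailing stop codon shared by neither/both sequences is trimmed.
        """
        if len(seq_a) != len(seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(seq_a) % 3:
            raise ValueError("aligned length is not a multiple of 3")
        ca, cb = [], []
        for i in range(0, len(seq_a), 3):
            a, b = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
            if "-" in a or "-" in b or "N" in a or "N" in b:
                continue
            ca.append(a)
            cb.append(b)
        if ca and (ca[-1] in STOP_CODONS or cb[-1] in STOP_CODONS):
            ca.pop()
            cb.pop()
        return cls(id_a=id_a, id_b=id_b, codons_a=tuple(ca), codons_b=tuple(cb))


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None  # None when Ks == 0 or saturated
    syn_subs: float
    nonsyn_subs: float
    syn_sites: float
    nonsyn_sites: float
    saturated: bool = False


def _mutants(codon: str, pos: int) -> Iterable[str]:
    for base in BASES:
        if base != codon[pos]:
            yield codon[: pos] + base + codon[pos + 1 :]


def count_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Per position, the synonymous fraction of the three possible changes;
    changes to stop codons are nonsynonymous.  The two counts sum to 3.
    """
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        syn_changes = sum(
            1 for m in _mutants(codon, pos) if GENETIC_CODE[m] == aa
        )
        syn += syn_changes / 3.0
    return syn, 3.0 - syn


def _step_type(c0: str, c1: str) -> tuple[float, float]:
    """(syn, nonsyn) classification of a single-base codon change."""
    return (1.0, 0.0) if GENETIC_CODE[c0] == GENETIC_CODE[c1] else (0.0, 1.0)


def count_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences per codon pair.

    For k differing positions, every one of the k! orderings of single-base
    steps defines a pathway; pathways whose intermediate codons are stops are
    excluded (all orderings are reinstated if every one is blocked).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        return _step_type(codon_a, codon_b)
    pathways = []
    for order in permutations(diff):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                blocked = True
                break
            steps.append(_step_type(current, nxt))
            current = nxt
        if not blocked:
            pathways.append(steps)
    if not pathways:  # every ordering crosses a stop; fall back to all
        for order in permutations(diff):
            current = codon_a
            steps = []
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                steps.append(_step_type(current, nxt))
                current = nxt
            pathways.append(steps)
    syn = sum(s for path in pathways for s, _ in path) / len(pathways)
    nonsyn = sum(n for path in pathways for _, n in path) / len(pathways)
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction; undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: correction undefined")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def compute_kaks(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka, Ks and their ratio for one aligned pair.

    Sites are averaged between the two sequences; the result is symmetric
    under swapping them.  Saturated proportions (p >= 3/4) flag the result
    and leave the ratio undefined.
    """
    syn_sites = 0.0
    for codons in (alignment.codons_a, alignment.codons_b):
        for c in codons:
            s, _ = count_sites(c)
            syn_sites += s
    syn_sites /= 2.0
    total_sites = 3.0 * len(alignment)
    nonsyn_sites = total_sites - syn_sites

    syn_subs = nonsyn_subs = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        s, n = count_substitutions(ca, cb)
        syn_subs += s
        nonsyn_subs += n

    saturated = False
    ps = syn_subs / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_subs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    try:
        ks = jukes_cantor(ps)
    except SaturationError:
        ks, saturated = float("nan"), True
    try:
        ka = jukes_cantor(pn)
    except SaturationError:
        ka, saturated = float("nan"), True
    ratio: float | None
    if saturated or ks == 0.0 or math.isnan(ks):
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        syn_subs=syn_subs,
        nonsyn_subs=nonsyn_subs,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        saturated=saturated,
    )


def kaks_table(
    pairs: Sequence[tuple[str, str]],
    cds: Mapping[str, str],
) -> pd.DataFrame:
    """Per-pair Ka/Ks table from pre-aligned, in-frame coding sequences."""
    rows = []
    for id_a, id_b in pairs:
        if id_a not in cds or id_b not in cds:
            missing = id_a if id_a not in cds else id_b
            raise KeyError(f"CDS for {missing!r} not found")
        aln = CodonAlignment.from_sequences(id_a, cds[id_a], id_b, cds[id_b])
        res = compute_kaks(aln)
        rows.append(
            {
                "gene_a": id_a,
                "gene_b": id_b,
                "n_codons": len(aln),
                "Ka": res.ka,
                "Ks": res.ks,
                "KaKs": float("nan") if res.ratio is None else res.ratio,
                "syn_subs": res.syn_subs,
                "nonsyn_subs": res.nonsyn_subs,
                "syn_sites": res.syn_sites,
                "nonsyn_sites": res.nonsyn_sites,
                "saturated": res.saturated,
            }
        )
    return pd.DataFrame(rows)


def write_kaks_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
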