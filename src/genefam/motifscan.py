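"""Diagnostic-motif verification by PWM scanning with exact p-values.

Degenerate consensus patterns for the kinase subdomain VIII signatures (for
example ``GTPEFMAPE(L/V/M)(Y/F/L)``) are compiled to log-odds position weight
matrices.  Window scores are assessed against the *exact* null distribution of
scores under i.i.d. background residues, computed by dynamic-programming
convolution of discretized per-column score distributions — the same scheme
FIMO uses.  A protein's best window is reported when its p-value beats the
configured threshold (1e-4 by default, with a relaxed 1e-3 re-scan available).

Pattern syntax: an uppercase residue letter matches itself, ``(A/B/C)``
matches any of the listed residues, and ``x`` is a wildcard scored exactly at
background (log-odds 0).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: floor for log-odds of disallowed residues, in bits; keeps the DP finite
LOG_ODDS_FLOOR = -30.0

#: subdomain VIII consensus signatures per kinase subfamily
DEFAULT_MOTIFS = {
    "ZIK": "GTPEFMAPE(L/V/M)(Y/F/L)",
    "MEKK": "G(T/S)Px(F/Y/W)MAPEV",
    "RAF": "GTxx(W/Y)MAPE",
}

_TOKEN = re.compile(r"\(([A-Z](?:/[A-Z])*)\)|([A-Z])|(x)")


class PatternError(ValueError):
    """Raised for a syntactically invalid consensus pattern."""


def parse_pattern(pattern: str) -> list[frozenset | None]:
    """Tokenize a consensus pattern into per-column residue sets (None = x)."""
    if not pattern:
        raise PatternError("empty motif pattern")
    columns: list[frozenset | None] = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if not m:
            raise PatternError(
                f"cannot parse motif pattern {pattern!r} at position {pos}"
            )
        alt, single, wild = m.groups()
        if wild:
            columns.append(None)
        elif single:
            if single not in _AA_INDEX:
                raise PatternError(f"unknown residue {single!r} in {pattern!r}")
            columns.append(frozenset(single))
        else:
            residues = alt.split("/")
            if not residues:
                raise PatternError(f"empty alternation in {pattern!r}")
            for r in residues:
                if r not in _AA_INDEX:
                    raise PatternError(f"unknown residue {r!r} in {pattern!r}")
            columns.append(frozenset(residues))
        pos = m.end()
    return columns


@dataclass(frozen=True)
class MotifModel:
    """A compiled motif: log-odds PWM over the 20 residues plus background."""

    name: str
    pattern: str
    pwm: np.ndarray  # (L, 20) log2-odds, floored at LOG_ODDS_FLOOR
    background: np.ndarray  # (20,) strictly positive, sums to 1

    def __post_init__(self):
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 20 or self.pwm.shape[0] < 1:
            raise ValueError("PWM must be (L >= 1, 20)")
        if not np.isfinite(self.pwm).all():
            raise ValueError("PWM columns must be finite")
        if (self.background <= 0).any():
            raise ValueError("background must be strictly positive")

    def __len__(self) -> int:
        return self.pwm.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        idx = [_AA_INDEX.get(c) for c in window]
        return float(
            sum(
                self.pwm[j].min() if i is None else self.pwm[j, i]
                for j, i in enumerate(idx)
            )
        )


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    offset: int  # 1-based window start
    window: str
    score: float
    pvalue: float


def compile_motif(
    pattern: str,
    background: np.ndarray | None = None,
    pseudocount: float = 0.0,
    name: str = "",
) -> MotifModel:
    """Compile a degenerate consensus to a log-odds PWM.

    Allowed residues in a column share probability mass ``1 - 20*pseudocount``
    uniformly, and every residue receives ``pseudocount``; a wildcard column
    equals the background exactly (log-odds 0).  Log-odds are log2(p/bg),
    floored at :data:`LOG_ODDS_FLOOR`.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or (background <= 0).any():
        raise ValueError("background must be 20 strictly positive frequencies")
    background = background / background.sum()
    if not 0 <= pseudocount < 1 / 20:
        raise ValueError("pseudocount must be in [0, 0.05)")
    columns = parse_pattern(pattern)
    pwm = np.empty((len(columns), 20))
    for j, residues in enumerate(columns):
        if residues is None:
            pwm[j] = 0.0
            continue
        probs = np.full(20, pseudocount)
        idx = [_AA_INDEX[r] for r in sorted(residues)]
        probs[idx] += (1.0 - 20 * pseudocount) / len(idx)
        with np.errstate(divide="ignore"):
            pwm[j] = np.log2(probs / background)
        pwm[j] = np.maximum(pwm[j], LOG_ODDS_FLOOR)
    return MotifModel(
        name=name or pattern, pattern=pattern, pwm=pwm, background=background
    )


class NullDistribution:
    """Exact distribution of discretized PWM scores under i.i.d. background.

    Each column's scores are mapped to integers on a grid of ``granularity``
    bins spanning that column's range; the distribution of the integer window
    score is then the exact convolution over columns.  Observed windows are
    scored on the same integer grid, so reported p-values are exact for the
    discretized score (and conservative for the real-valued one, since
    per-column scores are rounded half-up onto bin edges shared with the
    null).
    """

    def __init__(self, model: MotifModel, granularity: int = 1000):
        if granularity < 100:
            raise ValueError("granularity must be >= 100 bins per column")
        self.model = model
        self.granularity = granularity
        L = len(model)
        ints = np.zeros((L, 20), dtype=np.int64)
        for j in range(L):
            col = model.pwm[j]
            lo, hi = float(col.min()), float(col.max())
            if hi > lo:
                width = (hi - lo) / granularity
                ints[j] = np.rint((col - lo) / width).astype(np.int64)
            # degenerate column (all equal) stays at 0
        self.column_ints = ints
        # worst-case integer per column, used for unknown residues (X)
        self.column_min = ints.min(axis=1)
        dist = np.ones(1)
        for j in range(L):
            size = int(ints[j].max())
            new = np.zeros(dist.size + size)
            for r in range(20):
                s = int(ints[j, r])
                new[s : s + dist.size] += model.background[r] * dist
            dist = new
        self.pmf = dist
        tail = np.cumsum(dist[::-1])[::-1]
        self.tail = np.minimum(tail, 1.0)

    def int_score(self, window_indices: Sequence[int | None]) -> int:
        total = 0
        for j, i in enumerate(window_indices):
            total += int(self.column_min[j] if i is None else self.column_ints[j, i])
        return total

    def pvalue_of_int(self, int_score: int) -> float:
        if int_score <= 0:
            return 1.0
        if int_score >= self.tail.size:
            int_score = self.tail.size - 1
        return float(self.tail[int_score])

    def score_to_pvalue(self) -> dict[int, float]:
        """Mapping of every achievable integer score to its tail probability."""
        return {s: float(self.tail[s]) for s in range(self.tail.size)}


def exact_score_pvalues(
    model: MotifModel, granularity: int = 1000
) -> NullDistribution:
    """Exact null of discretized scores under the model's background."""
    return NullDistribution(model, granularity=granularity)


def scan_protein(
    model: MotifModel,
    protein_id: str,
    sequence: str,
    pvalue_threshold: float = 1e-4,
    null: NullDistribution | None = None,
    granularity: int = 1000,
) -> MotifHit | None:
    """Best-window scan; returns a hit only if its p-value beats the threshold.

    Unknown residues (X) score at the column minimum, which is conservative.
    Proteins shorter than the motif yield no hit (logged at debug level).
    """
    L = len(model)
    n = len(sequence)
    if n < L:
        log.debug("protein %s shorter than motif (%d < %d)", protein_id, n, L)
        return None
    if null is None:
        null = NullDistribution(model, granularity=granularity)
    seq_idx = np.array(
        [_AA_INDEX.get(c, 20) for c in sequence], dtype=np.int64
    )
    # column_ints extended with a 21st entry per column = column minimum (for X)
    ext = np.concatenate(
        [null.column_ints, null.column_min[:, None]], axis=1
    )
    n_windows = n - L + 1
    scores = np.zeros(n_windows, dtype=np.int64)
    for j in range(L):
        scores += ext[j, seq_idx[j : j + n_windows]]
    best = int(np.argmax(scores))  # leftmost on ties
    best_int = int(scores[best])
    pvalue = null.pvalue_of_int(best_int)
    if pvalue >= pvalue_threshold:
        return None
    window = sequence[best : best + L]
    return MotifHit(
        protein_id=protein_id,
        offset=best + 1,
        window=window,
        score=model.score_window(window),
        pvalue=pvalue,
    )


def motif_conservation_report(
    sequences: Mapping[str, str],
    gene_subfamily: Mapping[str, str],
    models: Mapping[str, MotifModel],
    thresholds: Sequence[float] = (1e-4, 1e-3),
    granularity: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene motif conservation flags plus per-subfamily summary counts.

    ``sequences`` maps transcript (or gene) id -> protein sequence; a gene's
    best p-value over its transcript variants counts.  Returns (per-gene
    table, summary) where the per-gene table has one row per kept gene with
    ``conserved_at_<t>`` flags for each threshold.
    """
    from .io_formats import gene_id_of

    thresholds = sorted(thresholds)
    nulls = {
        sub: NullDistribution(m, granularity=granularity) for sub, m in models.items()
    }
    best_p: dict[str, float] = {}
    for seq_id, seq in sequences.items():
        gene = gene_id_of(seq_id)
        sub = gene_subfamily.get(gene)
        if sub is None or sub not in models:
            continue
        hit = scan_protein(
            models[sub], seq_id, seq, pvalue_threshold=1.1, null=nulls[sub]
        )
        p = hit.pvalue if hit is not None else 1.0
        if gene not in best_p or p < best_p[gene]:
            best_p[gene] = p
    rows = []
    for gene in sorted(gene_subfamily):
        sub = gene_subfamily[gene]
        if sub not in models:
            continue
        p = best_p.get(gene, 1.0)
        row = {"gene_id": gene, "subfamily": sub, "best_pvalue": p}
        for t in thresholds:
            row[f"conserved_at_{t:g}"] = p < t
        rows.append(row)
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        return per_gene, pd.DataFrame()
    summary = (
        per_gene.groupby("subfamily")
        .agg(
            n_genes=("gene_id", "count"),
            **{
                f"n_conserved_at_{t:g}": (f"conserved_at_{t:g}", "sum")
                for t in thresholds
            },
        )
        .reset_index()
    )
    return per_gene, summary
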