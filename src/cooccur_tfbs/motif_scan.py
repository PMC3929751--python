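"""Match-style promoter scanning with core and matrix similarity scores.

A count matrix is turned into a position weight model: pseudocounted
base frequencies ``f``, a per-position information vector
``I(i) = sum_b f(i,b) ln(4 f(i,b))`` (the Kullback-Leibler divergence
from the uniform background, in nats), and a designated *core* of the 5
consecutive positions with the highest total information.  A window is
scored by the information-weighted sum ``sum_i I(i) f(i, b_i)``,
min-max normalised so that the consensus word scores 1 and the
anti-consensus scores 0.  The score over all positions is the matrix
similarity score (MSS); over the core positions only, the core
similarity score (CSS).  A hit must pass the core cutoff first and the
matrix cutoff second, on either strand.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np

from .io_formats import BASES, CountMatrix, PromoterSet, reverse_complement

CORE_WIDTH = 5

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to indices A=0 C=1 G=2 T=3, anything else (N)=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclasses.dataclass(frozen=True)
class ScanParams:
    upstream: int = 1500
    downstream: int = 500
    css_min: float = 0.90
    mss_min: float = 0.80
    both_strands: bool = True

    def __post_init__(self):
        for name in ("css_min", "mss_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclasses.dataclass(frozen=True)
class MotifHit:
    gene: str
    factor_name: str
    start: int          # 0-based offset on the promoter's forward orientation
    strand: str         # "+" or "-"
    css: float
    mss: float
    matched_word: str   # the word as read on the hit strand


@dataclasses.dataclass(frozen=True)
class PWMModel:
    """Scoring model built from a :class:`CountMatrix` by :func:`build_model`."""

    factor_name: str
    f: np.ndarray          # (L, 4) pseudocounted frequencies, rows sum to 1
    I: np.ndarray          # (L,) information weights, nats
    core_idx: np.ndarray   # 5 consecutive positions of maximal total information

    @property
    def L(self) -> int:
        return self.f.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """(L, 5) array of I(i)*f(i,b) with a 5th column for N = per-position minimum."""
        W = self.I[:, None] * self.f
        return np.hstack([W, W.min(axis=1, keepdims=True)])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.f.argmax(axis=1))


def build_model(counts: CountMatrix, pseudocount: float = 0.25) -> PWMModel:
    """Pseudocount the counts, derive frequencies, information weights
    and the 5-position core (leftmost window on ties)."""
    c = counts.counts
    L = c.shape[0]
    if L < CORE_WIDTH:
        raise ValueError(
            f"matrix {counts.factor_name!r} has {L} positions; "
            f"need at least {CORE_WIDTH} to define a core"
        )
    totals = c.sum(axis=1, keepdims=True)
    f = (c + pseudocount) / (totals + 4.0 * pseudocount)
    I = np.sum(f * np.log(4.0 * f), axis=1)
    I = np.maximum(I, 0.0)  # guard tiny negative rounding on uniform columns
    window_sums = np.convolve(I, np.ones(CORE_WIDTH), mode="valid")
    start = int(np.argmax(window_sums))  # argmax is leftmost on ties
    return PWMModel(
        factor_name=counts.factor_name,
        f=f,
        I=I,
        core_idx=np.arange(start, start + CORE_WIDTH),
    )


def similarity(window: str, model: PWMModel, positions: Optional[Sequence[int]] = None) -> float:
    """Min-max normalised information-weighted similarity of ``window``
    to ``model`` over the given positions (all positions by default).

    ``window`` must have one character per scored position; N contributes
    the position's minimum weight.  A degenerate all-uniform selection
    (max == min) scores 1.0 with a warning.
    """
    pos = np.arange(model.L) if positions is None else np.asarray(positions, dtype=int)
    if len(window) != len(pos):
        raise ValueError(f"window length {len(window)} != {len(pos)} scored positions")
    W5 = model.weights[pos]
    idx = encode_sequence(window)
    current = W5[np.arange(len(pos)), idx].sum()
    mins = W5[:, 4].sum()
    maxs = W5[:, :4].max(axis=1).sum()
    if maxs - mins <= 0.0:
        warnings.warn(
            f"matrix {model.factor_name!r}: uniform over scored positions; similarity defined as 1.0",
            stacklevel=2,
        )
        return 1.0
    return float((current - mins) / (maxs - mins))


def _window_scores(seq_idx: np.ndarray, W5: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Normalised similarity for every window start of a sequence.

    Vectorised over offsets: gathers I*f at the scored positions for
    each window and min-max normalises exactly as :func:`similarity`.
    """
    L = W5.shape[0]
    n_off = seq_idx.size - L + 1
    if n_off <= 0:
        return np.empty(0)
    sub = W5[positions]
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, L)[:, positions]
    current = sub[np.arange(len(positions))[None, :], windows].sum(axis=1)
    mins = sub[:, 4].sum()
    maxs = sub[:, :4].max(axis=1).sum()
    if maxs - mins <= 0.0:
        return np.ones(n_off)
    return (current - mins) / (maxs - mins)


def scan_promoter(gene: str, sequence: str, model: PWMModel, params: ScanParams) -> list[MotifHit]:
    """Scan one promoter on both strands; returns hits sorted by start
    then strand ('+' before '-').

    A window is a hit when CSS >= css_min AND MSS >= mss_min (core
    filter first, matrix second).  Reverse-strand hits are reported at
    their forward-orientation start: ``start = len(seq) - rc_start - L``.
    """
    L = model.L
    n = len(sequence)
    if n < L:
        return []
    W5 = model.weights
    all_pos = np.arange(L)
    hits: list[MotifHit] = []
    strands = ["+", "-"] if params.both_strands else ["+"]
    for strand in strands:
        seq = sequence if strand == "+" else reverse_complement(sequence)
        idx = encode_sequence(seq)
        css = _window_scores(idx, W5, model.core_idx)
        cand = np.flatnonzero(css >= params.css_min)
        if cand.size == 0:
            continue
        mss_all = _window_scores(idx, W5, all_pos)
        for off in cand:
            mss = mss_all[off]
            if mss < params.mss_min:
                continue
            word = seq[off : off + L]
            start = int(off) if strand == "+" else n - int(off) - L
            hits.append(
                MotifHit(gene, model.factor_name, start, strand, float(css[off]), float(mss), word)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclasses.dataclass
class ScanResult:
    """Aggregated hits for a gene set against a panel of models."""

    hits: dict[tuple[str, str], list[MotifHit]]  # (gene, factor) -> hits
    factors: list[str]
    genes: list[str]
    skipped_genes: list[str]

    def hits_by_gene(self) -> dict[str, list[MotifHit]]:
        out: dict[str, list[MotifHit]] = {g: [] for g in self.genes}
        for (gene, _), hs in self.hits.items():
            out[gene].extend(hs)
        for hs in out.values():
            hs.sort(key=lambda h: (h.start, h.strand, h.factor_name))
        return out

    def all_hits(self) -> list[MotifHit]:
        by_gene = self.hits_by_gene()
        out: list[MotifHit] = []
        for g in self.genes:
            out.extend(by_gene[g])
        return out

    def factor_totals(self) -> dict[str, int]:
        """Per-factor total hit count over all scanned genes."""
        totals = {f: 0 for f in self.factors}
        for (_, factor), hs in self.hits.items():
            totals[factor] += len(hs)
        return totals

    def factor_gene_counts(self) -> dict[str, int]:
        """Per-factor number of genes with at least one hit."""
        counts = {f: 0 for f in self.factors}
        for (_, factor), hs in self.hits.items():
            if hs:
                counts[factor] += 1
        return counts

    def count_table(self):
        """Genes x factors hit-count table (pandas DataFrame)."""
        import pandas as pd

        tab = pd.DataFrame(0, index=self.genes, columns=self.factors, dtype=int)
        for (gene, factor), hs in self.hits.items():
            tab.loc[gene, factor] = len(hs)
        return tab


def scan_geneset(
    promoter_set: PromoterSet,
    models: Sequence[PWMModel],
    params: ScanParams,
    genes: Optional[Sequence[str]] = None,
) -> ScanResult:
    """Deterministically scan every requested gene with every model.

    Genes missing from ``promoter_set`` are collected in
    ``skipped_genes`` rather than raising.
    """
    requested = list(promoter_set.genes) if genes is None else list(genes)
    skipped = [g for g in requested if g not in promoter_set]
    present = [g for g in requested if g in promoter_set]
    hits: dict[tuple[str, str], list[MotifHit]] = {}
    for gene in present:
        seq = promoter_set[gene].sequence
        for model in models:
            found = scan_promoter(gene, seq, model, params)
            if found:
                hits[(gene, model.factor_name)] = found
    return ScanResult(
        hits=hits,
        factors=[m.factor_name for m in models],
        genes=present,
        skipped_genes=skipped,
    )
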