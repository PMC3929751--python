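"""Readers and writers for the external formats the pipeline touches.

Everything downstream works on the domain types defined here: a
:class:`PromoterSet` of gene-oriented promoter sequences, motif
:class:`CountMatrix` objects parsed from JASPAR ``.pfm`` or a
TRANSFAC-style text block, and plain tab-separated expression /
annotation / design tables.

Coordinate conventions
----------------------
Internally every promoter position is 0-based, half-open, on the gene's
own forward orientation; the TSS of a default promoter (1500 bp upstream
+ 500 bp downstream) sits at offset 1500.  BED output is 0-based
half-open.  The legacy "SMART" position reported alongside BED is 1-based
from the upstream end of the promoter for forward-strand hits and from
the downstream end for reverse-strand hits ("strand 2").
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Mapping
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_UPSTREAM = 1500
DEFAULT_DOWNSTREAM = 500


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ProbeAnnotation:
    """One probe-to-gene mapping; ``gene_symbol is None`` means non-annotated."""

    probe_id: str
    gene_symbol: Optional[str]


@dataclasses.dataclass(frozen=True)
class PromoterRecord:
    sequence: str
    tss_offset: int

    def __len__(self) -> int:
        return len(self.sequence)


class PromoterSet(Mapping[str, PromoterRecord]):
    """Gene symbol -> promoter record, one record per gene."""

    def __init__(self, records: Mapping[str, PromoterRecord]):
        self._records = dict(records)

    def __getitem__(self, gene: str) -> PromoterRecord:
        return self._records[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def genes(self) -> list[str]:
        return list(self._records)

    def subset(self, genes) -> "PromoterSet":
        return PromoterSet({g: self._records[g] for g in genes if g in self._records})


@dataclasses.dataclass(frozen=True)
class CountMatrix:
    """Position frequency matrix: base counts per motif position.

    ``counts`` has shape (L, 4) in A, C, G, T order.  Every position must
    have a positive column sum; counts must be non-negative.
    """

    factor_name: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise FormatError(
                f"count matrix {self.factor_name!r} must be L x 4, got {c.shape}"
            )
        if np.any(c < 0):
            raise FormatError(f"negative count in matrix {self.factor_name!r}")
        if np.any(c.sum(axis=1) <= 0):
            raise FormatError(f"zero-sum position in matrix {self.factor_name!r}")
        object.__setattr__(self, "counts", c)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, default_tss_offset: int = DEFAULT_UPSTREAM) -> PromoterSet:
    """Read promoter FASTA into a :class:`PromoterSet`.

    The gene symbol is the first whitespace-delimited token of each
    header.  Sequences are uppercased and must be over {A,C,G,T,N}.
    Duplicate gene symbols and malformed records raise
    :class:`FormatError` naming the offending line.
    """
    records: dict[str, PromoterRecord] = {}
    name = None
    chunks: list[str] = []
    header_line = 0

    def _flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"line {header_line}: record {name!r} has no sequence")
        records[name] = PromoterRecord(seq, min(default_tss_offset, len(seq)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                if name in records:
                    raise FormatError(f"line {lineno}: duplicate gene symbol {name!r}")
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"line {lineno}: sequence before any FASTA header")
                bad = set(line.upper()) - set("ACGTN")
                if bad:
                    raise FormatError(
                        f"line {lineno}: invalid characters {sorted(bad)} in record {name!r}"
                    )
                chunks.append(line)
        _flush()
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return PromoterSet(records)


def write_fasta(promoters: PromoterSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gene in promoters:
            seq = promoters[gene].sequence
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# motif matrices
# ---------------------------------------------------------------------------

def _jaspar_read(path) -> CountMatrix:
    with open(path) as fh:
        try:
            m = bio_motifs.read(fh, "jaspar")
        except Exception as exc:  # Bio raises bare ValueError/KeyError on bad input
            raise FormatError(f"{path}: not a valid JASPAR matrix: {exc}") from exc
    counts = np.array([m.counts[b] for b in BASES], dtype=float).T
    name = m.name or m.base_id or "unnamed"
    return CountMatrix(str(name), counts)


def _transfac_read(path) -> CountMatrix:
    """Parse a TRANSFAC-style block: NA name line, P0 header, numbered
    rows of A C G T counts with a trailing consensus column."""
    name = None
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("//", "XX")):
                continue
            tag = line.split()[0]
            if tag in ("NA", "ID"):
                if name is None:
                    parts = line.split(None, 1)
                    if len(parts) < 2:
                        raise FormatError(f"line {lineno}: empty {tag} line")
                    name = parts[1].strip()
            elif tag == "P0" or tag == "PO":
                continue
            elif tag[0].isdigit():
                fields = line.split()
                # position index, 4 counts, optional consensus letter
                if len(fields) < 5:
                    raise FormatError(f"line {lineno}: expected 4 counts, got {len(fields) - 1}")
                try:
                    vals = [float(x) for x in fields[1:5]]
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-numeric count") from exc
                if ncols is None:
                    ncols = len(fields)
                elif len(fields) != ncols:
                    raise FormatError(f"line {lineno}: ragged row")
                if any(v < 0 for v in vals):
                    raise FormatError(f"line {lineno}: negative count")
                rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no count rows found")
    return CountMatrix(name or "unnamed", np.array(rows, dtype=float))


def read_matrix(path, dialect: str) -> CountMatrix:
    """Read one count matrix. ``dialect`` is ``"jaspar"`` or ``"transfac"``."""
    if dialect == "jaspar":
        return _jaspar_read(path)
    if dialect == "transfac":
        return _transfac_read(path)
    raise ValueError(f"unknown matrix dialect {dialect!r}")


def write_matrix(matrix: CountMatrix, path, dialect: str) -> None:
    if dialect == "jaspar":
        with open(path, "w") as fh:
            fh.write(f">{matrix.factor_name}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:g}" for v in matrix.counts[:, bi])
                fh.write(f"{base} [ {vals} ]\n")
    elif dialect == "transfac":
        with open(path, "w") as fh:
            fh.write(f"NA {matrix.factor_name}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(matrix.counts, start=1):
                cons = BASES[int(np.argmax(row))]
                fh.write(
                    f"{i:02d} " + " ".join(f"{v:6g}" for v in row) + f" {cons}\n"
                )
            fh.write("//\n")
    else:
        raise ValueError(f"unknown matrix dialect {dialect!r}")


def read_matrices(paths, dialect: str) -> list[CountMatrix]:
    return [read_matrix(p, dialect) for p in paths]


# ---------------------------------------------------------------------------
# promoter extraction from a genome
# ---------------------------------------------------------------------------

def read_tss_table(path) -> pd.DataFrame:
    """TSS table TSV with columns gene, chrom, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "chrom": str})
    missing = {"gene", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise FormatError(f"TSS table missing columns: {sorted(missing)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"invalid strand values: {df.loc[bad, 'strand'].unique()}")
    return df


def extract_promoters(
    genome_fasta,
    tss_table: pd.DataFrame,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> PromoterSet:
    """Cut promoters out of a genome FASTA around each gene's TSS.

    The TSS column is 1-based inclusive.  For a forward-strand gene the
    promoter is the 0-based half-open genomic interval
    ``[tss0 - upstream, tss0 + downstream)`` with ``tss0 = tss - 1``; for
    a reverse-strand gene the mirror interval is taken and
    reverse-complemented, so position 0 of every output sequence is
    ``upstream`` bases 5' of the TSS in the gene's own orientation.
    Overhang beyond a chromosome end is padded with N.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    records: dict[str, PromoterRecord] = {}
    for row in tss_table.itertuples(index=False):
        gene, chrom, tss, strand = row.gene, row.chrom, int(row.tss), row.strand
        if chrom not in genome:
            raise FormatError(f"gene {gene!r}: chromosome {chrom!r} absent from genome FASTA")
        chrom_len = len(genome[chrom])
        tss0 = tss - 1
        if strand == "+":
            start, end = tss0 - upstream, tss0 + downstream
        else:
            start, end = tss0 - (downstream - 1), tss0 + upstream + 1
        left_pad = max(0, -start)
        right_pad = max(0, end - chrom_len)
        core = str(genome[chrom][max(0, start) : min(end, chrom_len)])
        seq = "N" * left_pad + core + "N" * right_pad
        if strand == "-":
            seq = reverse_complement(seq)
        if gene in records:
            raise FormatError(f"duplicate gene {gene!r} in TSS table")
        records[gene] = PromoterRecord(seq, upstream)
    return PromoterSet(records)


# ---------------------------------------------------------------------------
# motif hit output
# ---------------------------------------------------------------------------

def smart_position(start: int, length: int, promoter_length: int, strand: str) -> int:
    """Legacy 1-based hit position: counted from the upstream promoter end
    on strand "+", and from the downstream end for reverse-strand hits."""
    if strand == "+":
        return start + 1
    return promoter_length - (start + length) + 1


def write_hits_bed(hits, promoter_set: PromoterSet, path) -> None:
    """Write motif hits as BED6 plus a parallel ``.tsv`` with scores and
    the legacy position convention.

    BED columns: gene (as chrom), 0-based half-open start/end, factor
    name, score = round(1000 * matrix score), strand.
    """
    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    rows = []
    with open(path, "w") as bed:
        for h in hits:
            if h.gene not in promoter_set:
                raise ValueError(f"hit references unknown gene {h.gene!r}")
            plen = len(promoter_set[h.gene])
            length = len(h.matched_word)
            end = h.start + length
            if h.start < 0 or end > plen:
                raise ValueError(
                    f"hit {h.factor_name}@{h.gene}:{h.start} outside promoter bounds (len {plen})"
                )
            bed.write(
                f"{h.gene}\t{h.start}\t{end}\t{h.factor_name}\t{round(1000 * h.mss)}\t{h.strand}\n"
            )
            rows.append(
                {
                    "gene": h.gene,
                    "factor": h.factor_name,
                    "start": h.start,
                    "end": end,
                    "strand": h.strand,
                    "smart_position": smart_position(h.start, length, plen, h.strand),
                    "css": h.css,
                    "mss": h.mss,
                    "matched_word": h.matched_word,
                }
            )
    write_tsv(pd.DataFrame(rows), tsv_path, comment="motif hits; smart_position is 1-based from the upstream end (+) or downstream end (-)")


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, comment: str = "", index: bool = False) -> None:
    """UTF-8 TSV with an optional leading '#' comment header line."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes/probes x samples table; first column is the row identifier."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty expression table")
    return df


def read_design_tsv(path) -> pd.DataFrame:
    """Design table with columns sample, group, pair; indexed by sample."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"sample", "group", "pair"} - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    return df.set_index("sample")


def read_annotation_tsv(path) -> dict[str, Optional[str]]:
    """Probe -> gene symbol map; empty/NA gene fields become ``None``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = {"probe_id", "gene_symbol"} - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise FormatError(f"duplicate probe ids in annotation: {dups[:5]}")
    out: dict[str, Optional[str]] = {}
    for probe, gene in zip(df["probe_id"], df["gene_symbol"]):
        gene = gene.strip()
        out[probe] = gene if gene and gene.upper() not in ("NA", "NONE", "NULL") else None
    return out
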