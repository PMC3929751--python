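#!/usr/bin/env python
"""Scan every promoter in the universe with the full factor panel using
Match-style core/matrix similarity scoring (CSS >= 0.90, MSS >= 0.80,
both strands).

Reads results/synthetic_study/, writes the universe hit-count table
(the enrichment null's lookup table) and the per-hit BED/TSV for the
selected gene list to results/scan/.
"""

import argparse
from pathlib import Path

from cooccur_tfbs import ScanParams, build_model, scan_geneset, write_hits_bed
from cooccur_tfbs.io_formats import read_fasta, read_matrix, write_tsv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/synthetic_study"))
    ap.add_argument("--selection", type=Path, default=Path("results/selection"))
    ap.add_argument("--out", type=Path, default=Path("results/scan"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    promoters = read_fasta(args.study / "promoters.fasta")
    matrices = [
        read_matrix(p, "jaspar") for p in sorted(args.study.glob("matrix_*.pfm"))
    ]
    models = [build_model(m) for m in matrices]
    result = scan_geneset(promoters, models, ScanParams())

    totals = result.factor_totals()
    gene_counts = result.factor_gene_counts()
    print(f"scanned {len(result.genes)} promoters x {len(models)} factors: "
          f"{sum(totals.values())} hits")
    for name in sorted(totals, key=totals.get, reverse=True)[:5]:
        print(f"  {name}: {totals[name]} hits in {gene_counts[name]} genes")

    counts = result.count_table()
    write_tsv(counts.rename_axis("gene"), args.out / "universe_hit_counts.tsv", index=True)

    selected = (args.selection / "selected_genes.txt").read_text().split()
    by_gene = result.hits_by_gene()
    sel_hits = [h for g in selected for h in by_gene.get(g, [])]
    write_hits_bed(sel_hits, promoters, args.out / "selected_hits.bed")
    print(f"{len(sel_hits)} hits on the {len(selected)} selected genes -> "
          f"{args.out}/selected_hits.bed (+ .tsv)")


if __name__ == "__main__":
    main()
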