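#!/usr/bin/env python
"""Catalog ORFs fully embedded in antisense to annotated genes.

Reads a genome (FASTA + GFF3) — by default the simulated ancestor from
01_simulate_clade.py — scans every annotated CDS for fully embedded
antisense ORFs of at least 20 codons, and writes the catalog as GFF3 and a
protein multi-FASTA under results/orfs/.
"""

import argparse
from pathlib import Path

from asorf.orffinder import DEFAULT_MIN_CODONS, find_embedded_antisense_orfs
from asorf.seqio import GeneFeature, Genome, read_fasta, read_features, write_fasta, write_gff3


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genome", type=Path, default=Path("results/clade/ancestor.fna"))
    ap.add_argument("--features", type=Path, default=Path("results/clade/ancestor.gff"))
    ap.add_argument("--min-codons", type=int, default=DEFAULT_MIN_CODONS)
    ap.add_argument("--outdir", type=Path, default=Path("results/orfs"))
    args = ap.parse_args()

    genome = Genome(args.genome.stem, read_fasta(args.genome),
                    read_features(args.features))
    orfs = find_embedded_antisense_orfs(genome, min_codons=args.min_codons)

    args.outdir.mkdir(parents=True, exist_ok=True)
    feats = [GeneFeature(o.orf_id, o.contig_id, o.start, o.end, o.strand, "CDS")
             for o in orfs]
    extra = {o.orf_id: {"host": ",".join(o.host_gene_ids),
                        "min_codons": str(args.min_codons)} for o in orfs}
    write_gff3(args.outdir / "antisense_orfs.gff", feats, extra_attrs=extra)
    write_fasta(args.outdir / "antisense_orfs.faa",
                {o.orf_id: o.protein for o in orfs})

    n_hosts = len({h for o in orfs for h in o.host_gene_ids})
    lengths = sorted(o.n_codons for o in orfs)
    print(f"{len(orfs)} embedded antisense ORFs (>= {args.min_codons} codons) "
          f"across {n_hosts} host genes")
    if orfs:
        print(f"ORF length range {lengths[0]}..{lengths[-1]} codons, "
              f"median {lengths[len(lengths) // 2]}")
    print(f"wrote {args.outdir}/antisense_orfs.gff and .faa")


if __name__ == "__main__":
    main()
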