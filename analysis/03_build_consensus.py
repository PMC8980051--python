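#!/usr/bin/env python
"""Convert the filtered diploid-style genotypes to haploid consensus
sequences: variant-positions-only FASTA, full-length (16,340 bp) N-filled
FASTA, and the shared positions file."""

from pathlib import Path

import pandas as pd

from mitokit.consensus import (build_variant_sequences, expand_to_full_fasta,
                               write_variant_fasta)
from mitokit.table import read_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"
GENOME_LENGTH = 16340


def main() -> None:
    table = read_vcf(ROOT / "filtered" / "filtered.vcf")
    seqs = build_variant_sequences(table)
    out = ROOT / "consensus"
    out.mkdir(parents=True, exist_ok=True)

    write_variant_fasta(seqs, out / "variant_sequences.fasta")
    records = expand_to_full_fasta(seqs, table.positions, GENOME_LENGTH,
                                   path=out / "full_sequences.fasta")
    pd.DataFrame({
        "index": range(table.n_sites),
        "position": table.positions,
        "ref": table.ref,
    }).to_csv(out / "positions.tsv", sep="\t", index=False)

    lengths = {len(s) for s in records.values()}
    print(f"{len(seqs)} consensus sequences over {table.n_sites} variant positions")
    print(f"full-length records: {sorted(lengths)} bp (all should be {GENOME_LENGTH})")


if __name__ == "__main__":
    main()
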