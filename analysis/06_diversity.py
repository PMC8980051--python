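#!/usr/bin/env python
"""Diversity and population structure: per-breed haplotype/nucleotide
diversity, pairwise-distance hierarchical clustering (cut at 0 nucleotide
differences = haplotypes), AMOVA among/within breeds, and haploid-GRM PCA."""

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from mitokit.diversity import (amova, diversity_stats, haploid_grm,
                               haplotype_classes, hierarchical_clusters,
                               pairwise_difference_matrix, pca, stats_frame)
from mitokit.table import read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"
GENOME_LENGTH = 16340
MIN_BREED_N = 20


def main() -> None:
    records = list(SeqIO.parse(ROOT / "consensus" / "variant_sequences.fasta",
                               "fasta"))
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv").set_index("animal_id")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    overall = diversity_stats(seqs, L=GENOME_LENGTH)
    print(f"overall: n={overall.n_sequences}, S={overall.segregating_sites}, "
          f"k={overall.mean_pairwise_differences:.2f}, "
          f"pi={overall.nucleotide_diversity:.5f}, H={overall.n_haplotypes}, "
          f"Hd={overall.haplotype_diversity:.4f} (SD {overall.haplotype_diversity_sd:.4f}), "
          f"singletons={overall.singletons}")

    by_breed = {}
    for aid, s in zip(ids, seqs):
        by_breed.setdefault(meta.loc[aid, "breed"], []).append(s)
    frame = stats_frame({b: v for b, v in by_breed.items() if len(v) >= MIN_BREED_N},
                        L=GENOME_LENGTH)
    frame.to_csv(out / "diversity_by_breed.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))

    d = pairwise_difference_matrix(seqs)
    pd.DataFrame(d, index=ids, columns=ids).to_csv(out / "distance_matrix.tsv",
                                                   sep="\t")
    labels = hierarchical_clusters(d, 0)
    classes = haplotype_classes(seqs, ids=ids)
    print(f"hierarchical clusters at h=0: {len(set(labels))} "
          f"(haplotype classes: {len(classes)})")

    breeds = [meta.loc[a, "breed"] for a in ids]
    res = amova(d, breeds, n_permutations=199, rng=np.random.default_rng(1))
    with open(out / "amova.txt", "w") as fh:
        fh.write(f"sigma2_among\t{res.sigma2_among:.6f}\n"
                 f"sigma2_within\t{res.sigma2_within:.6f}\n"
                 f"percent_among\t{res.percent_among:.2f}\n"
                 f"percent_within\t{res.percent_within:.2f}\n"
                 f"phi_st\t{res.phi_st:.4f}\np_value\t{res.p_value}\n")
    print(f"AMOVA: {res.percent_among:.1f}% among / {res.percent_within:.1f}% "
          f"within breeds (Phi_ST={res.phi_st:.3f}, p={res.p_value:.3f})")

    grm = haploid_grm(seqs)
    coords = pca(grm, 3)
    pd.DataFrame(coords.components, index=ids,
                 columns=["PC1", "PC2", "PC3"]).to_csv(out / "pca.tsv", sep="\t")
    var_explained = coords.eigenvalues[:3] / coords.eigenvalues.sum()
    print("PCA variance explained:", np.round(var_explained, 3))


if __name__ == "__main__":
    main()
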