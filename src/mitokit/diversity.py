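"""Sequence diversity, haplotype structure, AMOVA and haploid-GRM PCA.

Inputs are equal-length haploid sequences (variant-positions-only by
default).  Positions where either sequence of a pair carries N are
excluded from that pair's comparison (pairwise deletion).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


def _seq_matrix(sequences) -> np.ndarray:
    seqs = [s.bases if hasattr(s, "bases") else s for s in sequences]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must all have the same length")
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def pairwise_difference_matrix(sequences) -> np.ndarray:
    """Symmetric matrix of pairwise nucleotide differences (N-positions excluded)."""
    mat = _seq_matrix(sequences)
    n = mat.shape[0]
    valid = mat != b"N"
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = valid[i][None, :] & valid[i + 1:]
        diff = (mat[i][None, :] != mat[i + 1:]) & both
        d = diff.sum(axis=1)
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return out


def nucleotide_diversity(sequences, L: int | None = None):
    """Mean pairwise differences k and per-site nucleotide diversity pi = k / L.

    ``L`` defaults to the sequence length (use the genome length to express
    pi per genomic site).
    """
    mat = _seq_matrix(sequences)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    if L is None:
        L = mat.shape[1]
    d = pairwise_difference_matrix(sequences)
    iu = np.triu_indices(n, k=1)
    k = float(d[iu].mean())
    return k, k / L


def segregating_sites(sequences) -> int:
    """Number of positions with more than one non-N base among the sequences."""
    mat = _seq_matrix(sequences)
    count = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        bases = set(col[col != b"N"].tolist())
        if len(bases) > 1:
            count += 1
    return count


def haplotype_classes(sequences, ids=None) -> list:
    """Exact-sequence-equality equivalence classes, as lists of member ids."""
    seqs = [s.bases if hasattr(s, "bases") else s for s in sequences]
    if ids is None:
        ids = [getattr(s, "animal_id", i) for i, s in enumerate(sequences)]
    classes: dict = {}
    for aid, seq in zip(ids, seqs):
        classes.setdefault(seq, []).append(aid)
    return sorted(classes.values(), key=lambda m: (len(m), m), reverse=True)


def haplotype_diversity(class_sizes, n: int | None = None):
    """Nei's haplotype (gene) diversity Hd = n (1 - sum p_i^2) / (n - 1) and
    its large-sample SD (Nei 1987 sampling variance):

        V = 2/(n(n-1)) * [ 2(n-2) (sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 ]
    """
    sizes = np.asarray(list(class_sizes), dtype=float)
    if n is None:
        n = int(sizes.sum())
    if n < 2:
        raise ValueError("need at least two sequences")
    if sizes.sum() != n:
        raise ValueError("class sizes must sum to n")
    p = sizes / n
    s2, s3 = float((p ** 2).sum()), float((p ** 3).sum())
    hd = n * (1.0 - s2) / (n - 1)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return hd, float(np.sqrt(max(var, 0.0)))


@dataclasses.dataclass
class DiversityStats:
    n_sequences: int
    segregating_sites: int
    mean_pairwise_differences: float
    nucleotide_diversity: float
    n_haplotypes: int
    haplotype_diversity: float
    haplotype_diversity_sd: float
    singletons: int


def diversity_stats(sequences, L: int | None = None) -> DiversityStats:
    """Full per-population summary (Table-style: S, k, pi, H, Hd, singletons)."""
    classes = haplotype_classes(sequences)
    k, pi = nucleotide_diversity(sequences, L=L)
    hd, sd = haplotype_diversity([len(c) for c in classes])
    return DiversityStats(
        n_sequences=sum(len(c) for c in classes),
        segregating_sites=segregating_sites(sequences),
        mean_pairwise_differences=k,
        nucleotide_diversity=pi,
        n_haplotypes=len(classes),
        haplotype_diversity=hd,
        haplotype_diversity_sd=sd,
        singletons=sum(1 for c in classes if len(c) == 1),
    )


def hierarchical_clusters(distance_matrix: np.ndarray, cut_height: float,
                          method: str = "average") -> np.ndarray:
    """Agglomerative clustering cut at ``cut_height``; returns integer labels.

    At cut height 0 the clusters equal connected components of
    zero-distance pairs, independent of linkage method.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square symmetric")
    if d.shape[0] == 1:
        return np.array([1])
    Z = linkage(squareform(d, checks=False), method=method)
    return fcluster(Z, t=cut_height, criterion="distance")


@dataclasses.dataclass
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    p_value: float | None = None


def amova(distance_matrix: np.ndarray, group_labels, n_permutations: int = 0,
          rng=None) -> AmovaResult:
    """One-level AMOVA (Excoffier-Smouse-Quattro) on squared distances.

    SSD(total) = sum_{i<j} d_ij^2 / N; SSD(within) = per-group pair sums
    divided by group size; sigma2_within = SSD(within)/(N-k);
    sigma2_among = (SSD(among)/(k-1) - sigma2_within) / n_bar with
    n_bar = (N - sum n_g^2 / N) / (k-1).  A negative among-group component
    (possible under the moment estimator) is reported as-is with a warning.
    """
    d = np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(group_labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least two groups")
    if counts.max() < 2:
        raise ValueError("need at least one group with two or more members")

    d2 = d ** 2

    def components(lbl):
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in uniq:
            idx = np.flatnonzero(lbl == g)
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        sizes = np.array([(lbl == g).sum() for g in uniq], dtype=float)
        df_a, df_w = k - 1, n - k
        sigma_w = ss_within / df_w
        n_bar = (n - (sizes ** 2).sum() / n) / df_a
        sigma_a = (ss_among / df_a - sigma_w) / n_bar
        return ss_total, ss_within, ss_among, sigma_a, sigma_w

    ss_total, ss_within, ss_among, sigma_a, sigma_w = components(labels)
    if sigma_a < 0:
        warnings.warn("negative among-group variance component (reported as-is)",
                      stacklevel=2)
    total = sigma_a + sigma_w
    phi = sigma_a / total if total != 0 else 0.0

    p_value = None
    if n_permutations:
        if rng is None:
            rng = np.random.default_rng(0)
        obs = sigma_a
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            if components(perm)[3] >= obs:
                count += 1
        p_value = (count + 1) / (n_permutations + 1)

    return AmovaResult(
        sigma2_among=sigma_a, sigma2_within=sigma_w,
        percent_among=100.0 * sigma_a / total if total != 0 else 0.0,
        percent_within=100.0 * sigma_w / total if total != 0 else 0.0,
        phi_st=phi, df_among=k - 1, df_within=n - k,
        ss_among=ss_among, ss_within=ss_within, ss_total=ss_total,
        p_value=p_value)


def haploid_grm(sequences, collapse_multiallelic: bool = False):
    """Standardized haploid genomic relationship matrix.

    Each polymorphic site contributes one 0/1 indicator per allele other
    than the sample-majority allele (``collapse_multiallelic=True``
    collapses a multi-allelic site to a single majority-vs-rest
    indicator; for biallelic sites both encodings give the same GRM).
    Indicators are standardized by the sample allele frequency,
    z = (x - p) / sqrt(p (1 - p)); monomorphic indicators are excluded.
    GRM = Z Z^T / M over the M indicators.
    """
    mat = _seq_matrix(sequences)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    cols = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        bases, counts = np.unique(col, return_counts=True)
        if len(bases) < 2:
            continue
        major = bases[np.argmax(counts)]
        alleles = [b for b in bases if b != major]
        if collapse_multiallelic:
            cols.append((col != major).astype(float))
        else:
            for b in alleles:
                cols.append((col == b).astype(float))
    if not cols:
        raise ValueError("no polymorphic sites")
    X = np.column_stack(cols)
    p = X.mean(axis=0)
    ok = (p > 0) & (p < 1)
    if (~ok).any():
        log.info("haploid_grm: excluded %d monomorphic indicators", int((~ok).sum()))
    X = X[:, ok]
    p = X.mean(axis=0)
    Z = (X - p) / np.sqrt(p * (1 - p))
    return Z @ Z.T / Z.shape[1]


@dataclasses.dataclass
class GrmPcaResult:
    eigenvalues: np.ndarray
    components: np.ndarray   # animals x n_components, scaled by sqrt(eigenvalue)
    vectors: np.ndarray


def pca(grm: np.ndarray, n_components: int = 3) -> GrmPcaResult:
    """Eigendecomposition of the GRM; coordinates = eigvec * sqrt(eigval)."""
    g = np.asarray(grm, dtype=float)
    if g.shape[0] != g.shape[1] or not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, len(vals))
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    return GrmPcaResult(eigenvalues=vals, components=coords, vectors=vecs[:, :k])


def stats_frame(named_populations: dict, L: int | None = None) -> pd.DataFrame:
    """Per-population diversity table (one row per population)."""
    rows = []
    for name, seqs in named_populations.items():
        s = diversity_stats(seqs, L=L)
        rows.append((name, s.n_sequences, s.segregating_sites,
                     s.mean_pairwise_differences, s.n_haplotypes,
                     s.haplotype_diversity, s.haplotype_diversity_sd,
                     s.nucleotide_diversity, s.singletons))
    return pd.DataFrame(rows, columns=[
        "population", "n", "segregating_sites", "mean_pairwise_diff",
        "n_haplotypes", "Hd", "Hd_sd", "pi", "singletons"])
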