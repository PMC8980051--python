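"""Diversity statistics, clustering, AMOVA and GRM/PCA."""

import itertools

import numpy as np
import pytest

from mitokit.consensus import build_variant_sequences
from mitokit.diversity import (amova, diversity_stats, haploid_grm,
                               haplotype_classes, haplotype_diversity,
                               hierarchical_clusters, nucleotide_diversity,
                               pairwise_difference_matrix, pca, stats_frame)
from mitokit.simulate import (SimConfig, simulate_cohort,
                              simulate_haplogroup_definitions,
                              simulate_population)


def random_sequences(rng, n, length, alphabet="ACGT"):
    letters = np.array(list(alphabet))
    return ["".join(letters[rng.integers(0, len(letters), size=length)])
            for _ in range(n)]


def brute_force_distance(a, b):
    return sum(1 for x, y in zip(a, b) if "N" not in (x, y) and x != y)


class TestPairwiseDistances:
    def test_identity_and_hand_counts(self):
        assert pairwise_difference_matrix(["AAA", "AAA"]).tolist() == [[0, 0], [0, 0]]
        assert pairwise_difference_matrix(["AAA", "ATT"])[0, 1] == 2

    def test_n_positions_excluded(self):
        assert pairwise_difference_matrix(["ANA", "TTT"])[0, 1] == 2
        assert pairwise_difference_matrix(["NNN", "ACG"])[0, 1] == 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(61)
        seqs = random_sequences(rng, 12, 40, alphabet="ACGTN")
        d = pairwise_difference_matrix(seqs)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        for i, j in itertools.combinations(range(12), 2):
            assert d[i, j] == brute_force_distance(seqs[i], seqs[j])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_difference_matrix(["AA", "AAA"])


class TestNucleotideDiversity:
    def test_all_identical_zero(self):
        k, pi = nucleotide_diversity(["ACGT"] * 4)
        assert k == 0 and pi == 0

    def test_three_sequence_manual_enumeration(self):
        k, pi = nucleotide_diversity(["AAA", "AAT", "ATT"], L=3)
        assert k == pytest.approx(4 / 3)
        assert pi == pytest.approx(4 / 9)

    def test_equals_matrix_upper_triangle_mean(self):
        rng = np.random.default_rng(67)
        seqs = random_sequences(rng, 10, 30)
        d = pairwise_difference_matrix(seqs)
        k, pi = nucleotide_diversity(seqs)
        iu = np.triu_indices(10, 1)
        assert k == pytest.approx(d[iu].mean())
        assert pi == pytest.approx(k / 30)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["ACGT"])


class TestHaplotypes:
    def test_all_distinct(self):
        classes = haplotype_classes(["AA", "AT", "TT"], ids=list("abc"))
        assert len(classes) == 3
        assert all(len(c) == 1 for c in classes)

    def test_shared_and_singleton(self):
        classes = haplotype_classes(["AA", "AA", "AT"], ids=list("abc"))
        assert sorted(map(len, classes)) == [1, 2]

    def test_zero_private_rate_haplotypes_equal_haplogroups(self):
        cfg = SimConfig(n_animals=30, n_haplogroups=3, defining_variants_per_group=5,
                        private_mutation_rate=0.0, seed=71)
        table, truth = simulate_cohort(cfg)
        seqs = build_variant_sequences(table)
        assert len(haplotype_classes(seqs)) == 3

    def test_hd_forced_and_hand_values(self):
        assert haplotype_diversity([1, 1])[0] == pytest.approx(1.0)
        assert haplotype_diversity([2, 2])[0] == pytest.approx(2 / 3)
        hd, sd = haplotype_diversity([5])
        assert hd == 0 and sd == 0

    def test_hd_bounds_on_random_partitions(self):
        rng = np.random.default_rng(73)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            cuts = np.sort(rng.choice(np.arange(1, n), size=rng.integers(0, min(6, n)),
                                      replace=False))
            sizes = np.diff(np.concatenate([[0], cuts, [n]]))
            hd, sd = haplotype_diversity(sizes.tolist())
            assert 0.0 <= hd <= 1.0 and sd >= 0.0

    def test_hd_errors(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])
        with pytest.raises(ValueError):
            haplotype_diversity([2, 2], n=5)


class TestHierarchicalClustering:
    @staticmethod
    def partition(labels, ids):
        out = {}
        for lab, aid in zip(labels, ids):
            out.setdefault(lab, set()).add(aid)
        return {frozenset(v) for v in out.values()}

    def test_cut_zero_equals_haplotype_classes_random_fixtures(self):
        rng = np.random.default_rng(79)
        for _ in range(30):
            n = int(rng.integers(4, 20))
            pool = random_sequences(rng, max(2, n // 3), 12)
            seqs = [pool[rng.integers(0, len(pool))] for _ in range(n)]
            ids = list(range(n))
            d = pairwise_difference_matrix(seqs)
            labels = hierarchical_clusters(d, 0)
            clusters = self.partition(labels, ids)
            classes = {frozenset(c) for c in haplotype_classes(seqs, ids=ids)}
            assert clusters == classes

    def test_linkage_choice_irrelevant_at_cut_zero(self):
        rng = np.random.default_rng(83)
        pool = random_sequences(rng, 4, 10)
        seqs = [pool[rng.integers(0, 4)] for _ in range(15)]
        d = pairwise_difference_matrix(seqs)
        parts = [self.partition(hierarchical_clusters(d, 0, method=m), range(15))
                 for m in ("average", "single", "complete")]
        assert parts[0] == parts[1] == parts[2]

    def test_degenerate_cuts(self):
        d = np.zeros((4, 4))
        assert len(set(hierarchical_clusters(d, 0))) == 1
        rng = np.random.default_rng(89)
        seqs = random_sequences(rng, 6, 15)
        d = pairwise_difference_matrix(seqs)
        assert len(set(hierarchical_clusters(d, d.max() + 1))) == 1


def amova_brute_force(d, labels):
    """Independent nested-loop evaluation of the variance-component formulas."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    k = len(groups)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        if len(idx) > 1:
            ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    sizes = [labels.count(g) for g in groups]
    sigma_w = ss_within / (n - k)
    n_bar = (n - sum(s ** 2 for s in sizes) / n) / (k - 1)
    sigma_a = (ss_among / (k - 1) - sigma_w) / n_bar
    return sigma_a, sigma_w


class TestAmova:
    def make_fixture(self, seed, n_groups, per_group=6, length=40):
        rng = np.random.default_rng(seed)
        seqs, labels = [], []
        for g in range(n_groups):
            founder = random_sequences(rng, 1, length)[0]
            for _ in range(per_group):
                s = list(founder)
                for p in rng.choice(length, size=rng.integers(0, 4), replace=False):
                    s[p] = "ACGT"[rng.integers(0, 4)]
                seqs.append("".join(s))
                labels.append(f"G{g}")
        return pairwise_difference_matrix(seqs), labels

    @pytest.mark.parametrize("n_groups,seed", [(2, 97), (5, 101)])
    def test_matches_brute_force(self, n_groups, seed):
        d, labels = self.make_fixture(seed, n_groups)
        res = amova(d, labels)
        sigma_a, sigma_w = amova_brute_force(d, labels)
        assert res.sigma2_among == pytest.approx(sigma_a, abs=1e-9)
        assert res.sigma2_within == pytest.approx(sigma_w, abs=1e-9)
        assert res.percent_among + res.percent_within == pytest.approx(100, abs=1e-9)
        assert -0.05 <= res.phi_st <= 1.0

    def test_internally_identical_groups_zero_within(self):
        seqs = ["AAAA"] * 3 + ["TTTT"] * 3
        d = pairwise_difference_matrix(seqs)
        res = amova(d, ["a"] * 3 + ["b"] * 3)
        assert res.percent_within == pytest.approx(0.0)
        assert res.percent_among == pytest.approx(100.0)

    def test_permuted_labels_center_on_zero(self):
        """Random labels on one panmictic pool: mean among-group component
        over permutations is ~0 (|bias| < 2 SE)."""
        rng = np.random.default_rng(103)
        seqs = random_sequences(rng, 24, 50)
        d = pairwise_difference_matrix(seqs)
        labels = np.array(["a"] * 12 + ["b"] * 12)
        vals = []
        for _ in range(200):
            perm = rng.permutation(labels)
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals.append(amova(d, perm).sigma2_among)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se

    def test_degenerate_grouping_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            amova(d, ["a", "a", "a"])
        with pytest.raises(ValueError):
            amova(np.zeros((2, 2)), ["a", "b"])


class TestGrmPca:
    def test_duplicate_animals_identical_rows(self):
        seqs = ["ACGTAC", "ACGTAC", "TCGAAC", "TGGATC"]
        g = haploid_grm(seqs)
        assert np.allclose(g[0], g[1])
        assert np.allclose(g, g.T)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(107)
        seqs = random_sequences(rng, 8, 25)
        g = haploid_grm(seqs)
        # naive recomputation: indicators per non-majority allele, standardized
        cols = []
        arr = np.array([list(s) for s in seqs])
        for j in range(arr.shape[1]):
            col = arr[:, j]
            bases, counts = np.unique(col, return_counts=True)
            if len(bases) < 2:
                continue
            major = bases[np.argmax(counts)]
            for b in bases:
                if b != major:
                    cols.append((col == b).astype(float))
        Z = []
        for x in cols:
            p = x.mean()
            if 0 < p < 1:
                Z.append((x - p) / np.sqrt(p * (1 - p)))
        Z = np.array(Z).T
        expected = Z @ Z.T / Z.shape[1]
        assert np.allclose(g, expected, atol=1e-12)

    def test_diag_near_one_and_psd(self):
        rng = np.random.default_rng(109)
        seqs = random_sequences(rng, 40, 120)
        g = haploid_grm(seqs)
        assert abs(np.diag(g).mean() - 1.0) < 0.15
        assert np.linalg.eigvalsh(g).min() > -1e-9

    def test_pca_identity_and_rank_one(self):
        res = pca(np.eye(4), 4)
        assert np.allclose(res.eigenvalues, 1.0)
        v = np.array([[1.0], [2.0], [-1.0]])
        res = pca(v @ v.T, 3)
        assert np.sum(res.eigenvalues > 1e-9) == 1

    def test_pca_separates_haplogroups(self):
        cfg = SimConfig(n_animals=40, n_haplogroups=2, defining_variants_per_group=12,
                        private_mutation_rate=1.0, seed=113)
        table, truth = simulate_cohort(cfg)
        seqs = build_variant_sequences(table)
        g = haploid_grm(seqs)
        res = pca(g, 2)
        pc1 = res.components[:, 0]
        lab = np.array([truth.animal_haplogroups[a] for a in table.animals])
        a, b = pc1[lab == "T1"], pc1[lab == "T2"]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert a.max() < b.min() or b.max() < a.min()  # zero overlap

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            pca(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestStatsFrame:
    def test_per_population_table(self, noiseless_cohort):
        table, truth = noiseless_cohort
        seqs = build_variant_sequences(table)
        by_breed = {}
        breed_of = dict(zip(truth.metadata["animal_id"], truth.metadata["breed"]))
        for vs in seqs:
            by_breed.setdefault(breed_of[vs.animal_id], []).append(vs)
        frame = stats_frame({k: v for k, v in by_breed.items() if len(v) >= 2})
        assert (frame["Hd"] <= 1).all() and (frame["pi"] >= 0).all()
        stats = diversity_stats(seqs)
        assert stats.n_haplotypes <= stats.n_sequences
        assert stats.mean_pairwise_differences == pytest.approx(
            stats.nucleotide_diversity * table.n_sites)
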