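"""Masking / imputation cross-validation harness.

Mirrors a reference-panel imputation experiment on mitogenome genotypes:
a random fraction of animals (default 20%) has a random fraction of its
sites (default 10%, drawn per animal) masked; the remainder of the cohort
serves as the reference panel.  Imputation is either the built-in
k-nearest-haplotype imputer (a deliberately simple stand-in that exposes
the same GT:DS:GP interface as Beagle-style output) or externally
produced GT:DS:GP genotypes.  Imputed heteroplasmic genotypes are
resolved to a single base from the alternate-allele dose (DS) and
genotype probabilities (GP), and accuracy is scored as genotype
concordance overall, per original genotype class, and as haplogroup
re-prediction agreement, over replicates.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .consensus import build_variant_sequences, expand_to_full_sequence
from .haplogroup import assign_haplogroup
from .table import MitoVariantTable


@dataclasses.dataclass
class MaskPlan:
    replicate_id: int
    masked_animals: list                 # animal ids (Group I)
    masked_sites: dict                   # animal_id -> sorted site indices
    seed: int

    def cells(self):
        for aid in self.masked_animals:
            for j in self.masked_sites[aid]:
                yield aid, j


@dataclasses.dataclass
class ImputedGenotype:
    gt: tuple                            # phased allele-index pair
    ds: float                            # alternate-allele dose in [0, 2]
    gp: list                             # genotype probabilities, sum to 1

    def validate(self) -> None:
        if not 0.0 <= self.ds <= 2.0 + 1e-9:
            raise ValueError(f"DS out of range: {self.ds}")
        if any(p < 0 for p in self.gp) or abs(sum(self.gp) - 1.0) > 1e-6:
            raise ValueError("GP must be nonnegative and sum to 1")


def make_mask(table: MitoVariantTable, frac_animals: float = 0.2,
              frac_sites: float = 0.1, seed: int = 0,
              replicate_id: int = 0) -> MaskPlan:
    """Choose Group I animals and, per animal, the site indices to mask."""
    if not 0.0 < frac_animals < 1.0 or not 0.0 < frac_sites < 1.0:
        raise ValueError("fractions must lie in (0, 1)")
    if table.is_missing().any():
        raise ValueError("mask plans require a table with no missing genotypes")
    rng = np.random.default_rng(seed)
    n_animals = math.floor(table.n_animals * frac_animals)
    n_sites = math.floor(table.n_sites * frac_sites)
    if n_animals < 1 or n_sites < 1:
        raise ValueError("fractions too small for this table")
    chosen = rng.choice(table.n_animals, size=n_animals, replace=False)
    masked_animals = [table.animals[i] for i in sorted(chosen)]
    masked_sites = {}
    for aid in masked_animals:
        sites = rng.choice(table.n_sites, size=n_sites, replace=False)
        masked_sites[aid] = sorted(int(s) for s in sites)
    return MaskPlan(replicate_id=replicate_id, masked_animals=masked_animals,
                    masked_sites=masked_sites, seed=seed)


def _consensus_matrix(table: MitoVariantTable) -> np.ndarray:
    seqs = build_variant_sequences(table)
    return np.array([list(vs.bases) for vs in seqs])


def _gp_index(a: int, b: int) -> int:
    """VCF genotype ordering: genotype (j, k) with j <= k sits at k(k+1)/2 + j."""
    j, k = min(a, b), max(a, b)
    return k * (k + 1) // 2 + j


def naive_impute(table: MitoVariantTable, plan: MaskPlan, k: int = 5,
                 consensus_matrix: np.ndarray | None = None) -> dict:
    """k-nearest-haplotype imputation of the masked cells.

    For each masked animal, reference haplotypes (Group II consensus
    sequences) are ranked by Hamming distance on the animal's unmasked
    sites; the best haplotype's allele gives the (homoplasmic, phased)
    GT, and DS/GP are the normalized inverse-distance-weighted allele
    votes of the k best haplotypes.  Ties resolve to the lowest panel
    index.  Returns {(animal_id, site_index): ImputedGenotype}.
    """
    panel_ids = [a for a in table.animals if a not in set(plan.masked_animals)]
    if not panel_ids:
        raise ValueError("empty reference panel")
    cons = consensus_matrix if consensus_matrix is not None else _consensus_matrix(table)
    idx_of = {a: i for i, a in enumerate(table.animals)}
    panel_idx = np.array([idx_of[a] for a in panel_ids])
    panel = cons[panel_idx]

    out = {}
    for aid in plan.masked_animals:
        row = cons[idx_of[aid]]
        masked = np.array(plan.masked_sites[aid], dtype=int)
        unmasked = np.setdiff1d(np.arange(table.n_sites), masked)
        dist = (panel[:, unmasked] != row[unmasked][None, :]).sum(axis=1)
        order = np.argsort(dist, kind="stable")[: min(k, len(panel_ids))]
        weights = 1.0 / (1.0 + dist[order].astype(float))
        weights /= weights.sum()
        for j in masked:
            allele_list = [table.ref[j]] + list(table.alt[j])
            lookup = {b: i for i, b in enumerate(allele_list)}
            votes = np.array([lookup[panel[h, j]] for h in order])
            best = int(votes[0])
            ds = float(2.0 * weights[votes != 0].sum())
            n_all = len(allele_list)
            gp = [0.0] * (n_all * (n_all + 1) // 2)
            for v, w in zip(votes, weights):
                gp[_gp_index(int(v), int(v))] += float(w)
            ig = ImputedGenotype(gt=(best, best), ds=ds, gp=gp)
            ig.validate()
            out[(aid, int(j))] = ig
    return out


def resolve_imputed_base(imputed: ImputedGenotype, ref: str, alts) -> str:
    """Resolve one imputed genotype to a base (or "N").

    Homoplasmic GT: its allele's base.  REF/ALT heteroplasmic GT: DS < 1
    gives REF, DS >= 1 gives ALT.  ALT/ALT heteroplasmic GT: equal
    probability mass for the two alleles (the DS = 2 balanced case) gives
    "N"; otherwise the allele with the larger mass summed across the GP
    entries containing it.
    """
    alleles = [ref] + list(alts)
    a, b = imputed.gt
    if a == b:
        return alleles[a]
    n_all = len(alleles)
    expected = n_all * (n_all + 1) // 2
    if len(imputed.gp) != expected:
        raise ValueError(f"GP has {len(imputed.gp)} entries, expected {expected}")
    if 0 in (a, b):
        alt = max(a, b)
        return alleles[alt] if imputed.ds >= 1.0 else ref
    mass = {}
    for x in (a, b):
        mass[x] = sum(p for (j, kk), p in _gp_entries(n_all, imputed.gp) if x in (j, kk))
    if mass[a] == mass[b]:
        return "N"
    return alleles[a] if mass[a] > mass[b] else alleles[b]


def _gp_entries(n_alleles: int, gp):
    out = []
    for kk in range(n_alleles):
        for j in range(kk + 1):
            out.append(((j, kk), gp[_gp_index(j, kk)]))
    return out


@dataclasses.dataclass
class ConcordanceReport:
    overall: float
    per_class: pd.DataFrame              # original class -> total, correct, pct
    confusion: pd.DataFrame              # original class x imputed class counts
    n_cells: int
    haplogroup_agreement: float | None = None


def _class_key(pair) -> str:
    a, b = sorted(int(x) for x in pair)
    return f"{a}/{b}"


def concordance(imputed: dict, table: MitoVariantTable, plan: MaskPlan) -> ConcordanceReport:
    """Score imputed genotypes against the original table over masked cells."""
    idx_of = {a: i for i, a in enumerate(table.animals)}
    missing = [c for c in plan.cells() if c not in imputed]
    if missing:
        raise ValueError(f"{len(missing)} masked cells were not imputed")
    counts: dict = {}
    confusion: dict = {}
    correct = total = 0
    for (aid, j), ig in imputed.items():
        truth = _class_key(table.gt[idx_of[aid], j])
        imp = _class_key(ig.gt)
        tot, cor = counts.get(truth, (0, 0))
        hit = imp == truth
        counts[truth] = (tot + 1, cor + int(hit))
        confusion[(truth, imp)] = confusion.get((truth, imp), 0) + 1
        total += 1
        correct += int(hit)

    per_class = pd.DataFrame(
        [(cls, t, c, 100.0 * c / t) for cls, (t, c) in sorted(counts.items())],
        columns=["class", "total", "correct", "pct_correct"]).set_index("class")
    classes = sorted({c for pair in confusion for c in pair})
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for (tr, im), c in confusion.items():
        conf.loc[tr, im] = c
    return ConcordanceReport(overall=correct / total, per_class=per_class,
                             confusion=conf, n_cells=total)


def imputed_variant_sequences(table: MitoVariantTable, plan: MaskPlan,
                              imputed: dict,
                              consensus_matrix: np.ndarray | None = None) -> dict:
    """Masked animals' variant sequences with masked cells resolved from DS/GP."""
    cons = consensus_matrix if consensus_matrix is not None else _consensus_matrix(table)
    idx_of = {a: i for i, a in enumerate(table.animals)}
    out = {}
    for aid in plan.masked_animals:
        row = cons[idx_of[aid]].copy()
        for j in plan.masked_sites[aid]:
            row[j] = resolve_imputed_base(imputed[(aid, j)], table.ref[j], table.alt[j])
        out[aid] = "".join(row)
    return out


def haplogroup_agreement(imputed_sequences: dict, original_calls: dict,
                         definitions, positions, reference_length: int) -> float:
    """Fraction of masked animals whose re-predicted haplogroup matches.

    Ties are compared as sets of tied groups.
    """
    if not imputed_sequences:
        return 1.0
    agree = 0
    for aid, var_seq in imputed_sequences.items():
        full = expand_to_full_sequence(var_seq, positions, reference_length)
        call = assign_haplogroup(full, definitions, animal_id=aid)
        orig = original_calls[aid]
        same = (set(call.ties) == set(orig.ties)) if (call.ties or orig.ties) \
            else (call.assigned == orig.assigned)
        agree += int(same)
    return agree / len(imputed_sequences)


@dataclasses.dataclass
class ReplicateSummary:
    replicates: pd.DataFrame             # one row per replicate
    mean_overall: float
    sd_overall: float
    mean_haplogroup_agreement: float
    sd_haplogroup_agreement: float
    per_class: pd.DataFrame              # pooled over replicates


def run_replicates(table: MitoVariantTable, definitions, reference_length: int,
                   n_reps: int = 50, frac_animals: float = 0.2,
                   frac_sites: float = 0.1, seed: int = 0, k: int = 5) -> ReplicateSummary:
    """Full cross-validation: mask -> impute -> resolve -> score, n_reps times.

    Replicate r draws its mask from seed + r.  Haplogroup agreement
    compares against calls from the complete (unmasked) data.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    cons = _consensus_matrix(table)
    original_calls = {}
    for i, aid in enumerate(table.animals):
        full = expand_to_full_sequence("".join(cons[i]), table.positions, reference_length)
        original_calls[aid] = assign_haplogroup(full, definitions, animal_id=aid)

    rows = []
    pooled: dict = {}
    for r in range(n_reps):
        plan = make_mask(table, frac_animals, frac_sites, seed=seed + r, replicate_id=r)
        imputed = naive_impute(table, plan, k=k, consensus_matrix=cons)
        rep = concordance(imputed, table, plan)
        seqs = imputed_variant_sequences(table, plan, imputed, consensus_matrix=cons)
        agreement = haplogroup_agreement(seqs, original_calls, definitions,
                                         table.positions, reference_length)
        rows.append((r, rep.overall, agreement, rep.n_cells))
        for cls, row in rep.per_class.iterrows():
            t, c = pooled.get(cls, (0, 0))
            pooled[cls] = (t + int(row["total"]), c + int(row["correct"]))

    reps = pd.DataFrame(rows, columns=["replicate", "overall_concordance",
                                       "haplogroup_agreement", "n_cells"])
    per_class = pd.DataFrame(
        [(cls, t, c, 100.0 * c / t) for cls, (t, c) in sorted(pooled.items())],
        columns=["class", "total", "correct", "pct_correct"]).set_index("class")
    return ReplicateSummary(
        replicates=reps,
        mean_overall=float(reps["overall_concordance"].mean()),
        sd_overall=float(reps["overall_concordance"].std(ddof=1)) if n_reps > 1 else 0.0,
        mean_haplogroup_agreement=float(reps["haplogroup_agreement"].mean()),
        sd_haplogroup_agreement=float(reps["haplogroup_agreement"].std(ddof=1)) if n_reps > 1 else 0.0,
        per_class=per_class)
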