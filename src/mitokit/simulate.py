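"""Synthetic mitochondrial cohort generator.

Emulates the statistical structure of a multi-breed cattle mitogenome
panel: a ~16,340 bp haploid circular genome (treated linearly), haplogroup
founders defined by diagnostic variant sets, per-animal private mutations,
per-site read depths, heteroplasmic genotypes whose prevalence and
allelic-depth balance differ by tissue class (semen-like samples carry few
mitochondria, so NUMT-derived reads produce more balanced depth ratios),
sporadic missing genotypes, and occasional INDELs.

All randomness flows from a single ``numpy`` Generator seeded with
``SimConfig.seed``; identical configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .table import MISSING, MitoVariantTable, write_vcf

BASES = np.array(["A", "C", "G", "T"])

# a pool of plausible source countries assigned round-robin to breeds
_COUNTRIES = ["Australia", "France", "Germany", "China", "India", "USA", "Kenya"]


@dataclasses.dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults give a desk-scale cohort: 4 haplogroups x 25 defining
    variants, 200 animals, somatic heteroplasmy ~0.5% of sites per animal
    versus 5% for semen-like samples, mean depth 30x.
    """

    genome_length: int = 16340
    n_haplogroups: int = 4
    defining_variants_per_group: int = 25
    n_animals: int = 200
    breed_assignments: dict | None = None  # breed -> (haplogroup, count)
    private_mutation_rate: float = 2.0
    heteroplasmy_rate_somatic: float = 0.005
    heteroplasmy_rate_semen: float = 0.05
    depth_mean: float = 30.0
    depth_sd: float = 8.0
    numt_allele_fraction_semen: float = 0.35
    numt_allele_fraction_somatic: float = 0.15
    missing_rate: float = 0.0
    indel_rate: float = 0.0
    low_qual_fraction: float = 0.0
    low_mq_fraction: float = 0.0
    semen_fraction: float = 0.3
    beta_concentration: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "private rate": self.private_mutation_rate >= 0,
            "genome_length": self.genome_length > 0,
            "depth_mean": self.depth_mean > 0,
        }
        for name, ok in rates.items():
            if not ok:
                raise ValueError(f"invalid {name}")
        for name in ("heteroplasmy_rate_somatic", "heteroplasmy_rate_semen",
                     "numt_allele_fraction_semen", "numt_allele_fraction_somatic",
                     "missing_rate", "indel_rate", "low_qual_fraction",
                     "low_mq_fraction", "semen_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.numt_allele_fraction_semen < self.numt_allele_fraction_somatic:
            raise ValueError(
                "semen NUMT allele fraction must be >= somatic "
                "(semen samples show more balanced allelic ratios)")


@dataclasses.dataclass
class HaplogroupDefinitions:
    """Haplogroup name -> {position: defining allele}; plus the reference."""

    groups: dict
    reference: str

    def all_positions(self) -> set:
        out = set()
        for var in self.groups.values():
            out |= set(var)
        return out

    def write(self, path) -> None:
        lines = []
        for name in self.groups:
            toks = ",".join(f"{p}:{a}" for p, a in sorted(self.groups[name].items()))
            lines.append(f"{name}\t{toks}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass
class TruthSet:
    """Ground truth behind a simulated VCF."""

    founder_sequences: dict          # haplogroup -> str
    animal_sequences: dict           # animal_id -> str
    animal_haplogroups: dict         # animal_id -> haplogroup name
    definitions: HaplogroupDefinitions
    metadata: pd.DataFrame

    @property
    def animals(self) -> list:
        return list(self.animal_sequences)


def _random_reference(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, base: str) -> str:
    """Uniform substitution to any base != current (transitions not privileged)."""
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]


def simulate_haplogroup_definitions(config: SimConfig,
                                    rng: np.random.Generator | None = None):
    """Draw a reference sequence, disjoint defining-variant sets and founders.

    Returns ``(definitions, founders)`` where founders maps haplogroup name
    to the reference with that group's defining alleles applied.
    """
    config.validate()
    if config.n_haplogroups < 1:
        raise ValueError("need at least one haplogroup")
    if config.defining_variants_per_group < 1:
        raise ValueError("need at least one defining variant per group")
    n_def = config.n_haplogroups * config.defining_variants_per_group
    if n_def > config.genome_length:
        raise ValueError(
            f"genome of {config.genome_length} bp cannot host {n_def} defining variants")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    reference = _random_reference(rng, config.genome_length)
    positions = rng.choice(config.genome_length, size=n_def, replace=False) + 1
    groups: dict = {}
    founders: dict = {}
    for g in range(config.n_haplogroups):
        name = f"T{g + 1}"
        sl = positions[g * config.defining_variants_per_group:
                       (g + 1) * config.defining_variants_per_group]
        variants = {int(p): _mutate(rng, reference[p - 1]) for p in sorted(sl)}
        groups[name] = variants
        seq = reference.copy()
        for p, a in variants.items():
            seq[p - 1] = a
        founders[name] = "".join(seq)
    defs = HaplogroupDefinitions(groups=groups, reference="".join(reference))
    return defs, founders


def default_breed_assignments(config: SimConfig, group_names: list) -> dict:
    """One breed per haplogroup, animals split as evenly as possible."""
    k = len(group_names)
    base, extra = divmod(config.n_animals, k)
    out = {}
    for i, g in enumerate(group_names):
        out[f"Breed{i + 1}"] = (g, base + (1 if i < extra else 0))
    return out


def simulate_population(definitions: HaplogroupDefinitions, founders: dict,
                        config: SimConfig,
                        rng: np.random.Generator | None = None) -> TruthSet:
    """Expand founders to animals with Poisson private mutations + metadata.

    Private mutations avoid all haplogroup-defining positions so the
    simulated truth labels remain exact.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    assignments = config.breed_assignments or default_breed_assignments(
        config, list(founders))
    total = sum(c for _, c in assignments.values())
    if total != config.n_animals:
        raise ValueError(
            f"breed_assignments counts sum to {total}, expected {config.n_animals}")
    for breed, (hg, _) in assignments.items():
        if hg not in founders:
            raise KeyError(f"unknown haplogroup {hg!r} for breed {breed!r}")

    def_positions = definitions.all_positions()
    free = np.array(sorted(set(range(1, config.genome_length + 1)) - def_positions))

    animal_sequences, animal_haplogroups, meta_rows = {}, {}, []
    idx = 0
    for b, (breed, (hg, count)) in enumerate(assignments.items()):
        country = _COUNTRIES[b % len(_COUNTRIES)]
        founder = np.array(list(founders[hg]))
        for _ in range(count):
            idx += 1
            aid = f"ANI{idx:04d}"
            seq = founder.copy()
            n_mut = rng.poisson(config.private_mutation_rate)
            if n_mut > 0:
                sites = rng.choice(free, size=min(n_mut, len(free)), replace=False)
                for p in sites:
                    seq[p - 1] = _mutate(rng, seq[p - 1])
            sex = "M" if rng.random() < 0.5 else "F"
            if sex == "M" and rng.random() < config.semen_fraction:
                tissue = "semen"
            else:
                tissue = "blood" if rng.random() < 0.8 else "unknown"
            animal_sequences[aid] = "".join(seq)
            animal_haplogroups[aid] = hg
            meta_rows.append((aid, breed, country, sex, tissue))
    meta = pd.DataFrame(meta_rows,
                        columns=["animal_id", "breed", "country", "sex", "tissue"])
    return TruthSet(founder_sequences=dict(founders),
                    animal_sequences=animal_sequences,
                    animal_haplogroups=animal_haplogroups,
                    definitions=definitions,
                    metadata=meta)


def plant_subgroup(truth: TruthSet, animal_ids: list, n_variants: int,
                   seed: int = 0) -> list:
    """Apply ``n_variants`` shared extra substitutions to the given animals.

    Models a not-yet-catalogued subgroup within a haplogroup carrying a
    small set of shared private variants.  Returns the (position, allele)
    list planted.  Positions avoid defining variants and existing
    polymorphism among the given animals.
    """
    rng = np.random.default_rng(seed)
    length = len(next(iter(truth.animal_sequences.values())))
    used = set(truth.definitions.all_positions())
    seqs = {a: np.array(list(truth.animal_sequences[a])) for a in truth.animals}
    ref = np.array(list(truth.definitions.reference))
    for a in truth.animals:
        used |= set((np.flatnonzero(seqs[a] != ref) + 1).tolist())
    free = np.array(sorted(set(range(1, length + 1)) - used))
    sites = rng.choice(free, size=n_variants, replace=False)
    planted = []
    for p in sorted(int(s) for s in sites):
        allele = _mutate(rng, ref[p - 1])
        planted.append((p, allele))
        for a in animal_ids:
            seqs[a][p - 1] = allele
    for a in animal_ids:
        truth.animal_sequences[a] = "".join(seqs[a])
    return planted


def _is_semen_like(row) -> bool:
    return row.sex == "M" and row.tissue in ("semen", "unknown")


def simulate_vcf(truth: TruthSet, config: SimConfig,
                 rng: np.random.Generator | None = None) -> MitoVariantTable:
    """Render the truth set as a diploid-style genotype table (VCF-shaped).

    Every position segregating among the animals (or differing from the
    reference) becomes a site; ``indel_rate`` spikes extra INDEL records;
    heteroplasmy, missingness, depth, QUAL and MQ follow the config.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    ref = np.array(list(truth.definitions.reference))
    L = len(ref)
    animals = truth.animals
    seq_mat = np.array([list(truth.animal_sequences[a]) for a in animals])
    if seq_mat.shape[1] != L:
        raise ValueError("truth sequences must match reference length")

    variable = np.flatnonzero((seq_mat != ref[None, :]).any(axis=0)) + 1
    # spike INDELs at otherwise-invariant positions
    invariant = np.array(sorted(set(range(1, L + 1)) - set(variable.tolist())))
    n_indel = rng.binomial(len(invariant), config.indel_rate) if config.indel_rate else 0
    indel_pos = set()
    if n_indel:
        indel_pos = set(int(p) for p in rng.choice(invariant, size=n_indel, replace=False))
    site_pos = np.array(sorted(set(variable.tolist()) | indel_pos))

    S = len(site_pos)
    N = len(animals)
    tissue_semen = np.array([_is_semen_like(r) for r in truth.metadata.itertuples()])
    het_rate = np.where(tissue_semen, config.heteroplasmy_rate_semen,
                        config.heteroplasmy_rate_somatic)
    numt_frac = np.where(tissue_semen, config.numt_allele_fraction_semen,
                         config.numt_allele_fraction_somatic)

    ref_out, alt_out = [], []
    gt = np.full((N, S, 2), MISSING, dtype=np.int16)
    a_max = 4
    ad = np.zeros((N, S, a_max), dtype=np.int32)
    dp = np.zeros((N, S), dtype=np.int32)

    for j, pos in enumerate(site_pos):
        r = ref[pos - 1]
        if pos in indel_pos:
            # simple insertion record; every animal homozygous REF
            ref_out.append(r)
            alt_out.append([r + _mutate(rng, r)])
            alleles = np.zeros(N, dtype=np.int16)
            allele_list = [r]
        else:
            col = seq_mat[:, pos - 1]
            alts = sorted(set(col.tolist()) - {r})
            ref_out.append(r)
            alt_out.append(alts)
            allele_list = [r] + alts
            lookup = {b: i for i, b in enumerate(allele_list)}
            alleles = np.array([lookup[b] for b in col], dtype=np.int16)

        n_all = len(allele_list) if pos not in indel_pos else 2
        depth = np.maximum(1, np.round(
            rng.normal(config.depth_mean, config.depth_sd, size=N))).astype(np.int32)
        het = rng.random(N) < het_rate
        miss = rng.random(N) < config.missing_rate
        for i in range(N):
            if miss[i]:
                continue
            a = int(alleles[i])
            if het[i] and n_all > 1:
                others = [x for x in range(n_all) if x != a]
                b = others[rng.integers(0, len(others))]
                major_frac = rng.beta(
                    (1 - numt_frac[i]) * config.beta_concentration,
                    numt_frac[i] * config.beta_concentration)
                major_frac = min(max(major_frac, 0.5), 1.0)
                d_major = int(round(depth[i] * major_frac))
                # truth allele stays the strict majority so consensus is exact
                d_major = min(max(d_major, depth[i] - d_major + 1), depth[i])
                lo, hi = sorted((a, b))
                ad[i, j, a] = d_major
                ad[i, j, b] = depth[i] - d_major
                gt[i, j] = (lo, hi)
            else:
                ad[i, j, a] = depth[i]
                gt[i, j] = (a, a)
            dp[i, j] = depth[i]

    qual = np.round(rng.uniform(31, 60, size=S), 2)
    mq = np.round(rng.uniform(31, 60, size=S), 2)
    if config.low_qual_fraction:
        drop = rng.random(S) < config.low_qual_fraction
        qual[drop] = np.round(rng.uniform(5, 29.9, size=int(drop.sum())), 2)
    if config.low_mq_fraction:
        drop = rng.random(S) < config.low_mq_fraction
        mq[drop] = np.round(rng.uniform(5, 29.9, size=int(drop.sum())), 2)

    table = MitoVariantTable(
        positions=site_pos.astype(np.int64),
        ref=ref_out,
        alt=alt_out,
        qual=qual,
        mq=mq,
        animals=animals,
        gt=gt,
        ad=ad,
        dp=dp,
    )
    table.validate()
    return table


def simulate_cohort(config: SimConfig):
    """definitions -> population -> genotype table, from one master seed.

    Returns ``(table, truth)``.  The three stages draw from independent
    streams derived from ``config.seed`` (seed, seed+1, seed+2) so each
    stage is individually reproducible.
    """
    defs, founders = simulate_haplogroup_definitions(config)
    truth = simulate_population(defs, founders, config)
    table = simulate_vcf(truth, config)
    return table, truth


def write_cohort(config: SimConfig, out_dir) -> None:
    """Write VCF, reference FASTA, metadata TSV and definitions file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_cohort(config)
    write_vcf(table, out / "cohort.vcf", contig="MT",
              contig_length=config.genome_length)
    ref = truth.definitions.reference
    with open(out / "reference.fasta", "w") as fh:
        fh.write(">MT\n")
        for i in range(0, len(ref), 60):
            fh.write(ref[i:i + 60] + "\n")
    truth.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.definitions.write(out / "haplogroup_defs.txt")


def read_haplogroup_definitions(path, reference: str) -> HaplogroupDefinitions:
    """Parse the one-line-per-haplogroup definitions file (name TAB pos:allele,...)."""
    groups = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, toks = line.split("\t")
        variants = {}
        for tok in toks.split(","):
            p, a = tok.split(":")
            variants[int(p)] = a
        groups[name] = variants
    return HaplogroupDefinitions(groups=groups, reference=reference)
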