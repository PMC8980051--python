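"""Site- and animal-level quality filters for mitochondrial genotype tables.

Filter order is fixed and logged, because removal counts depend on it:
site filters (QUAL / MQ / minor-allele count / depth cap) -> INDEL and
missing-genotype removal -> animal mean-depth filter -> semen-group
heteroplasmy cap.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .table import MISSING, MitoVariantTable, semen_group_mask

log = logging.getLogger(__name__)


@dataclasses.dataclass
class FilterThresholds:
    min_qual: float = 30.0
    min_mq: float = 30.0
    min_minor_allele_count: int = 2
    dp_cap_sd: float = 3.0
    min_animal_mean_dp: float = 10.0
    max_semen_heteroplasmy: int = 150

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")


def allele_counts(table: MitoVariantTable, j: int) -> np.ndarray:
    """Per-allele genotype-carrier counts at site j.

    Each genotype contributes one count to each distinct allele it carries
    (a heteroplasmic call counts once for each of its two alleles).
    """
    counts = np.zeros(table.n_alleles(j), dtype=int)
    for i in range(table.n_animals):
        a, b = table.gt[i, j]
        if a == MISSING:
            continue
        counts[a] += 1
        if b != a:
            counts[b] += 1
    return counts


def filter_sites(table: MitoVariantTable,
                 thresholds: FilterThresholds | None = None) -> MitoVariantTable:
    """Apply QUAL / MQ / minor-allele-count / depth-cap site filters.

    Minor-allele count: under-count ALT alleles are removed (genotypes
    referencing them set missing); the site is kept only if the
    second-most-frequent allele among REF and the retained ALTs reaches
    the threshold.  Depth cap: per-site mean DP across animals must not
    exceed the grand mean of those per-site means + ``dp_cap_sd`` SDs.
    """
    if table.n_sites == 0:
        raise ValueError("cannot filter an empty table")
    thr = thresholds or FilterThresholds()
    thr.validate()

    out = table.copy()
    keep = np.ones(out.n_sites, dtype=bool)
    removed = {"qual": 0, "mq": 0, "mac": 0, "dp_cap": 0}

    qual_fail = out.qual < thr.min_qual
    mq_fail = (~qual_fail) & (out.mq < thr.min_mq)
    removed["qual"] = int(qual_fail.sum())
    removed["mq"] = int(mq_fail.sum())
    keep &= ~(qual_fail | mq_fail)

    for j in np.flatnonzero(keep):
        counts = allele_counts(out, j)
        bad_alts = [k for k in range(1, len(counts))
                    if 0 < counts[k] < thr.min_minor_allele_count]
        # alleles never observed are irrelevant; under-count ALTs are unqualified
        unqualified = set(bad_alts) | {k for k in range(1, len(counts)) if counts[k] == 0}
        retained_alts = [k for k in range(1, len(counts)) if k not in unqualified]
        if bad_alts:
            for i in range(out.n_animals):
                a, b = out.gt[i, j]
                if a != MISSING and (a in bad_alts or b in bad_alts):
                    out.gt[i, j] = (MISSING, MISSING)
        if not retained_alts:
            keep[j] = False
            removed["mac"] += 1
            continue
        counts = allele_counts(out, j)
        observed = sorted([counts[0]] + [counts[k] for k in retained_alts], reverse=True)
        if len(observed) < 2 or observed[1] < thr.min_minor_allele_count:
            keep[j] = False
            removed["mac"] += 1

    # depth cap over per-site mean depth across animals
    if keep.any():
        site_mean_dp = out.dp.mean(axis=0)
        cap = site_mean_dp[keep].mean() + thr.dp_cap_sd * site_mean_dp[keep].std(ddof=0)
        dp_fail = keep & (site_mean_dp > cap)
        removed["dp_cap"] = int(dp_fail.sum())
        keep &= ~dp_fail

    for crit, n in removed.items():
        log.info("filter_sites: %s removed %d sites", crit, n)
    result = out.select_sites(keep)
    result.filter_report = removed  # type: ignore[attr-defined]
    return result


def drop_indels_and_missing(table: MitoVariantTable) -> MitoVariantTable:
    """Remove INDEL sites and any site with >= 1 missing genotype."""
    indel = table.is_indel_site()
    missing_any = table.is_missing().any(axis=0)
    keep = ~indel & ~missing_any
    log.info("drop_indels_and_missing: %d INDEL sites, %d sites with missing",
             int(indel.sum()), int((missing_any & ~indel).sum()))
    return table.select_sites(keep)


def filter_animals_by_depth(table: MitoVariantTable,
                            thresholds: FilterThresholds | None = None) -> MitoVariantTable:
    """Drop animals whose mean DP across retained sites is below threshold."""
    thr = thresholds or FilterThresholds()
    mean_dp = table.dp.mean(axis=1)
    keep = mean_dp >= thr.min_animal_mean_dp
    log.info("filter_animals_by_depth: removed %d animals", int((~keep).sum()))
    return table.select_animals(keep)


@dataclasses.dataclass
class HeteroplasmyProfile:
    """Heteroplasmy summaries stratified by Semen / Non-semen group."""

    per_animal_counts: pd.Series        # animal_id -> n heteroplasmic sites
    per_site_counts: pd.Series          # position -> n heteroplasmic animals
    ratios: pd.DataFrame                # columns: animal_id, group, ratio
    groups: pd.Series                   # animal_id -> "Semen" / "Non-semen"


def heteroplasmy_profile(table: MitoVariantTable, meta: pd.DataFrame) -> HeteroplasmyProfile:
    """Per-animal/per-site heteroplasmy counts and major:minor AD ratios."""
    semen = semen_group_mask(table, meta)
    het = table.is_het()
    per_animal = pd.Series(het.sum(axis=1), index=table.animals, name="het_sites")
    per_site = pd.Series(het.sum(axis=0), index=table.positions, name="het_animals")
    groups = pd.Series(np.where(semen, "Semen", "Non-semen"), index=table.animals)

    rows = []
    for i, j in zip(*np.nonzero(het)):
        a, b = table.gt[i, j]
        d1, d2 = table.ad[i, j, a], table.ad[i, j, b]
        major, minor = max(d1, d2), min(d1, d2)
        ratio = major / minor if minor > 0 else np.nan
        rows.append((table.animals[i], groups.iloc[i], ratio))
    ratios = pd.DataFrame(rows, columns=["animal_id", "group", "ratio"])
    return HeteroplasmyProfile(per_animal_counts=per_animal,
                               per_site_counts=per_site,
                               ratios=ratios, groups=groups)


def filter_semen_heteroplasmy(table: MitoVariantTable, meta: pd.DataFrame,
                              thresholds: FilterThresholds | None = None) -> MitoVariantTable:
    """Drop Semen-group animals with more heteroplasmic sites than the cap.

    Non-semen animals are never removed by this rule.
    """
    thr = thresholds or FilterThresholds()
    semen = semen_group_mask(table, meta)
    het_counts = table.is_het().sum(axis=1)
    keep = ~(semen & (het_counts > thr.max_semen_heteroplasmy))
    log.info("filter_semen_heteroplasmy: removed %d semen-group animals",
             int((~keep).sum()))
    return table.select_animals(keep)


def apply_filters(table: MitoVariantTable, meta: pd.DataFrame,
                  thresholds: FilterThresholds | None = None):
    """Full fixed-order filter pipeline; returns (table, report DataFrame)."""
    thr = thresholds or FilterThresholds()
    steps = []

    t1 = filter_sites(table, thr)
    steps.append(("site_filters", table.n_sites - t1.n_sites, 0))
    t2 = drop_indels_and_missing(t1)
    steps.append(("indel_missing", t1.n_sites - t2.n_sites, 0))
    t3 = filter_animals_by_depth(t2, thr)
    steps.append(("animal_depth", 0, t2.n_animals - t3.n_animals))
    t4 = filter_semen_heteroplasmy(t3, meta, thr)
    steps.append(("semen_heteroplasmy", 0, t3.n_animals - t4.n_animals))

    report = pd.DataFrame(steps, columns=["criterion", "sites_removed", "animals_removed"])
    return t4, report
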