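"""Haplogroup assignment from full-length N-filled consensus sequences.

Each pre-defined haplogroup is a set of diagnostic variants; a query is
scored against every group by the fraction of its non-missing defining
sites that match.  Exact ties are reported as unresolved (with the
deepest common name prefix, so a T1/T3 tie resolves to level "T"), and
queries informative for no group are unassignable.  Private variants —
query alleles differing from the reference at positions not defining any
group — are reported per animal; shared private variants within a
haplogroup flag putative new subgroups.
"""

from __future__ import annotations

import dataclasses
import os

import pandas as pd

from .simulate import HaplogroupDefinitions

# Cattle control region spans the linear origin; shipped default is a
# configuration value (tail + head intervals, 1-based inclusive).
DEFAULT_DLOOP_INTERVALS = ((15792, 16340), (1, 363))


@dataclasses.dataclass
class HaplogroupCall:
    animal_id: str
    assigned: str | None          # unique group, common prefix for ties, or None
    status: str                   # "assigned" | "unresolved" | "unassignable"
    ties: list                    # all top-scoring groups (empty when unique)
    matched_count: int
    missing_variants: list        # defining (pos, allele) at N positions
    private_variants: list        # (pos, query_base) not defining any group
    scores: dict                  # group -> match fraction (or None if all missing)


def score_group(full_sequence: str, group_definition: dict):
    """(matched, mismatched, missing) counts of a query against one group.

    ``group_definition`` maps 1-based position -> defining allele.  A
    query base of N counts as missing; equal to the defining allele as
    matched; anything else as mismatched.
    """
    matched = mismatched = missing = 0
    for pos, allele in group_definition.items():
        base = full_sequence[pos - 1]
        if base == "N":
            missing += 1
        elif base == allele:
            matched += 1
        else:
            mismatched += 1
    return matched, mismatched, missing


def _common_prefix(names) -> str:
    return os.path.commonprefix(sorted(names))


def assign_haplogroup(full_sequence: str, definitions: HaplogroupDefinitions,
                      animal_id: str = "") -> HaplogroupCall:
    """Assign the group with the highest match fraction over informative sites."""
    if not definitions.groups:
        raise ValueError("empty haplogroup definition set")
    if len(full_sequence) != len(definitions.reference):
        raise ValueError("query length differs from reference length")

    scores, counts = {}, {}
    for name, gdef in definitions.groups.items():
        m, mm, miss = score_group(full_sequence, gdef)
        counts[name] = (m, mm, miss)
        scores[name] = m / (m + mm) if (m + mm) >= 1 else None

    informative = {g: s for g, s in scores.items() if s is not None}
    private = _private_variants(full_sequence, definitions)
    if not informative:
        return HaplogroupCall(animal_id=animal_id, assigned=None,
                              status="unassignable", ties=[], matched_count=0,
                              missing_variants=[], private_variants=private,
                              scores=scores)

    best = max(informative.values())
    if best == 0.0:
        # no group shows a single matching defining allele
        return HaplogroupCall(animal_id=animal_id, assigned=None,
                              status="unassignable", ties=[], matched_count=0,
                              missing_variants=[], private_variants=private,
                              scores=scores)
    top = sorted(g for g, s in informative.items() if s == best)
    if len(top) == 1:
        group = top[0]
        status, ties, assigned = "assigned", [], group
    else:
        group = top[0]  # private/missing lists computed against first tied group
        prefix = _common_prefix(top)
        status, ties, assigned = "unresolved", top, (prefix or None)

    m, _, _ = counts[group]
    missing_vars = [(p, a) for p, a in sorted(definitions.groups[group].items())
                    if full_sequence[p - 1] == "N"]
    return HaplogroupCall(animal_id=animal_id, assigned=assigned, status=status,
                          ties=ties, matched_count=m,
                          missing_variants=missing_vars,
                          private_variants=private, scores=scores)


def _private_variants(full_sequence: str, definitions: HaplogroupDefinitions) -> list:
    """Non-N query bases differing from the reference at non-defining positions."""
    known = definitions.all_positions()
    out = []
    for i, (q, r) in enumerate(zip(full_sequence, definitions.reference)):
        if q != "N" and q != r and (i + 1) not in known:
            out.append((i + 1, q))
    return out


def assign_all(full_sequences: dict, definitions: HaplogroupDefinitions) -> list:
    return [assign_haplogroup(seq, definitions, animal_id=aid)
            for aid, seq in full_sequences.items()]


def restrict_to_region(definitions: HaplogroupDefinitions, intervals) -> HaplogroupDefinitions:
    """Keep only defining variants inside the given 1-based inclusive intervals.

    Groups left without any defining variant are kept (flagged via
    ``empty_groups``) so callers can report them.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("empty interval list")
    L = len(definitions.reference)
    for lo, hi in intervals:
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"interval ({lo}, {hi}) outside reference [1, {L}]")

    def inside(p):
        return any(lo <= p <= hi for lo, hi in intervals)

    groups = {name: {p: a for p, a in gdef.items() if inside(p)}
              for name, gdef in definitions.groups.items()}
    out = HaplogroupDefinitions(groups=groups, reference=definitions.reference)
    out.empty_groups = sorted(n for n, g in groups.items() if not g)  # type: ignore[attr-defined]
    return out


def find_shared_private_variants(calls, metadata: pd.DataFrame | None = None,
                                 min_group_size: int = 2, by_breed: bool = False) -> list:
    """Putative subgroups: private-variant sets shared by >= min_group_size
    animals and exclusive to them within their haplogroup (or breed).

    Returns a list of dicts with keys ``haplogroup`` (and ``breed`` when
    stratifying), ``variants`` (sorted (pos, base) tuples) and ``members``.
    """
    strata: dict = {}
    breed_of = {}
    if metadata is not None:
        breed_of = dict(zip(metadata["animal_id"], metadata["breed"]))
    for call in calls:
        if call.assigned is None:
            continue
        key = (call.assigned, breed_of.get(call.animal_id)) if by_breed else (call.assigned,)
        strata.setdefault(key, []).append(call)

    reports = []
    for key, group_calls in sorted(strata.items()):
        carriers: dict = {}
        for call in group_calls:
            for var in call.private_variants:
                carriers.setdefault(var, set()).add(call.animal_id)
        by_members: dict = {}
        for var, members in carriers.items():
            by_members.setdefault(frozenset(members), []).append(var)
        for members, variants in by_members.items():
            if len(members) >= min_group_size and len(members) < len(group_calls):
                rec = {"haplogroup": key[0],
                       "variants": sorted(variants),
                       "members": sorted(members)}
                if by_breed:
                    rec["breed"] = key[1]
                reports.append(rec)
    reports.sort(key=lambda r: (r["haplogroup"], r["variants"]))
    return reports


def calls_to_frame(calls) -> pd.DataFrame:
    rows = [(c.animal_id, c.assigned, c.status, ";".join(c.ties),
             c.matched_count, len(c.missing_variants), len(c.private_variants))
            for c in calls]
    return pd.DataFrame(rows, columns=["animal_id", "haplogroup", "status", "ties",
                                       "matched", "n_missing", "n_private"])
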