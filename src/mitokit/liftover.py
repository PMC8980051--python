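"""Coordinate and allele liftover between two mitochondrial references.

The default map relates the classical bovine reference sequence
(BRS, V00654, 16,338 bp) to the ARS-UCD1.2 mitochondrial contig
(16,340 bp): the older reference lacks two bases present in the newer
one (target coordinates 222 and 589) and the two references differ at
twelve further positions.  Positions therefore shift by +1 between the
two indel sites and by +2 after the second, and a haplogroup-defining
allele that coincides with the new reference base is no longer a variant
after liftover and is dropped.
"""

from __future__ import annotations

import csv
import dataclasses
from importlib import resources

DELETED = "deleted"


@dataclasses.dataclass(frozen=True)
class DefiningVariant:
    """A haplogroup-defining variant in a named coordinate system."""

    position: int
    allele: str
    haplogroup: str = ""


@dataclasses.dataclass
class LiftoverMap:
    """Piecewise offset map plus base-difference table.

    ``deletions`` are target-coordinate positions absent from the source
    (bases present in the newer reference only).  ``base_differences`` is
    a list of ``(target_pos, target_base, source_pos, source_base)``.
    """

    source_length: int
    target_length: int
    deletions: list
    base_differences: list

    def __post_init__(self) -> None:
        self.deletions = sorted(self.deletions)
        if self.target_length != self.source_length + len(self.deletions):
            raise ValueError("target_length must equal source_length + deletions")
        if any(not 1 <= d <= self.target_length for d in self.deletions):
            raise ValueError("deletion positions outside target coordinates")

    def target_base_at(self, target_pos: int) -> str | None:
        for tp, tb, _, _ in self.base_differences:
            if tp == target_pos:
                return tb
        for d, tb in zip(self.deletions, self._deletion_bases):
            if d == target_pos:
                return tb
        return None

    _deletion_bases: list = dataclasses.field(default_factory=list)


def load_default_map() -> LiftoverMap:
    """The packaged BRS (16,338 bp) -> ARS-UCD1.2_M (16,340 bp) map."""
    path = resources.files("mitokit.data") / "brs_to_ars_map.tsv"
    deletions, deletion_bases, subs = [], [], []
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["type"] == "deletion":
                deletions.append(int(row["target_pos"]))
                deletion_bases.append(row["target_base"])
            else:
                subs.append((int(row["target_pos"]), row["target_base"],
                             int(row["source_pos"]), row["source_base"]))
    m = LiftoverMap(source_length=16338, target_length=16340,
                    deletions=deletions, base_differences=subs)
    m._deletion_bases = deletion_bases
    return m


def lift_position(lift_map: LiftoverMap, source_pos: int) -> int:
    """Map a source-coordinate position to target coordinates.

    With the default map: p <= 221 -> p; positions between the two indel
    sites shift by +1; later positions by +2.
    """
    if not 1 <= source_pos <= lift_map.source_length:
        raise ValueError(
            f"position {source_pos} outside source [1, {lift_map.source_length}]")
    t = source_pos
    for d in lift_map.deletions:
        if t >= d:
            t += 1
    return t


def lift_position_inverse(lift_map: LiftoverMap, target_pos: int):
    """Inverse mapping; target positions absent from the source return ``DELETED``."""
    if not 1 <= target_pos <= lift_map.target_length:
        raise ValueError(
            f"position {target_pos} outside target [1, {lift_map.target_length}]")
    if target_pos in lift_map.deletions:
        return DELETED
    return target_pos - sum(1 for d in lift_map.deletions if d <= target_pos)


def lift_variant_set(lift_map: LiftoverMap, variants, target_reference=None):
    """Lift defining variants; drop those matching the target reference base.

    ``target_reference`` may be a full sequence string or a mapping of
    target position -> base; when omitted, the map's own base-difference
    table supplies target bases where known.  Returns
    ``(lifted, dropped)`` where dropped entries are
    ``(variant, lifted_position, reason)``.
    """
    lifted, dropped = [], []
    for v in variants:
        tpos = lift_position(lift_map, v.position)
        if isinstance(target_reference, str):
            if len(target_reference) != lift_map.target_length:
                raise ValueError("target reference length mismatch")
            base = target_reference[tpos - 1]
        elif target_reference is not None:
            base = target_reference.get(tpos)
        else:
            base = lift_map.target_base_at(tpos)
        if base is not None and base == v.allele:
            dropped.append((v, tpos, "allele equals target reference base"))
        else:
            lifted.append(DefiningVariant(position=tpos, allele=v.allele,
                                          haplogroup=v.haplogroup))
    return lifted, dropped
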