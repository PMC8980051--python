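"""Haploid consensus sequences from diploid-style mitochondrial genotypes.

Homoplasmic genotypes are assigned their allele directly; heteroplasmic
genotypes take the allele with the higher read depth, and a REF/ALT depth
tie resolves to ALT (avoiding reference bias).  An ALT/ALT tie — a case
with no stated convention — resolves to the higher allele index, which
extends the same anti-reference preference; this is logged as a warning.
"""

from __future__ import annotations

import dataclasses
import logging

from .table import MISSING, MitoVariantTable

log = logging.getLogger(__name__)


@dataclasses.dataclass
class VariantSequence:
    """One base per retained variant position, shared position list."""

    animal_id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


def call_consensus_base(genotype, allele_depths, ref: str, alts) -> str:
    """Resolve one genotype to a single base.

    Parameters
    ----------
    genotype : (a, b) allele-index pair, non-missing
    allele_depths : per-allele read depths (length 1 + len(alts))
    ref, alts : site alleles
    """
    a, b = genotype
    if a == MISSING or b == MISSING:
        raise ValueError("cannot call consensus on a missing genotype")
    alleles = [ref] + list(alts)
    if a == b:
        return alleles[a]
    da, db = allele_depths[a], allele_depths[b]
    if da is None or db is None:
        raise ValueError("heteroplasmic genotype without allele depths")
    if da > db:
        return alleles[a]
    if db > da:
        return alleles[b]
    # depth tie: prefer the ALT (higher allele index) over REF
    chosen = max(a, b)
    if min(a, b) != 0:
        log.warning("ALT/ALT depth tie at alleles %d/%d: choosing index %d",
                    a, b, chosen)
    return alleles[chosen]


def build_variant_sequences(table: MitoVariantTable) -> list:
    """One :class:`VariantSequence` per animal; requires no missing, SNPs only."""
    if table.is_missing().any():
        raise ValueError("table contains missing genotypes; filter first")
    if table.is_indel_site().any():
        raise ValueError("table contains INDEL sites; filter first")
    out = []
    for i, aid in enumerate(table.animals):
        bases = []
        for j in range(table.n_sites):
            bases.append(call_consensus_base(
                tuple(int(x) for x in table.gt[i, j]),
                table.ad[i, j], table.ref[j], table.alt[j]))
        out.append(VariantSequence(animal_id=aid, bases="".join(bases)))
    return out


def expand_to_full_sequence(bases: str, positions, reference_length: int = 16340) -> str:
    """Place variant bases at 1-based positions; N everywhere else."""
    seq = ["N"] * reference_length
    if len(bases) != len(positions):
        raise ValueError("bases and positions length mismatch")
    for b, p in zip(bases, positions):
        if not 1 <= p <= reference_length:
            raise ValueError(f"position {p} outside reference of length {reference_length}")
        seq[p - 1] = b
    return "".join(seq)


def expand_to_full_fasta(variant_sequences, positions, reference_length: int = 16340,
                         path=None, line_width: int = 60) -> dict:
    """Full-length N-filled sequences per animal; optionally written as FASTA."""
    records = {
        vs.animal_id: expand_to_full_sequence(vs.bases, positions, reference_length)
        for vs in variant_sequences
    }
    if path is not None:
        with open(path, "w") as fh:
            for aid, seq in records.items():
                fh.write(f">{aid}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i:i + line_width] + "\n")
    return records


def write_variant_fasta(variant_sequences, path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for vs in variant_sequences:
            fh.write(f">{vs.animal_id}\n")
            for i in range(0, len(vs.bases), line_width):
                fh.write(vs.bases[i:i + line_width] + "\n")
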