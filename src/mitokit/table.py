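"""Central genotype container for multi-sample mitochondrial variant data.

The mitogenome is haploid, but short-read callers emit diploid-style
genotypes in which a heteroplasmic position (two alleles observed within
one animal, whether from genuine mixed mitogenome copies or from NUMT
reads misaligned to MT) appears as a het call such as ``0/1`` with split
allele depths.  :class:`MitoVariantTable` keeps that representation: an
animals x sites matrix of allele-index pairs plus per-allele read depths
(AD) and total depth (DP), with site-level POS/REF/ALT/QUAL/MQ.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = -1

TISSUE_SEMEN = "semen"
TISSUE_UNKNOWN = "unknown"


@dataclasses.dataclass
class MitoVariantTable:
    """Animals x sites mitochondrial genotype matrix.

    Attributes
    ----------
    positions : (S,) int array, 1-based, strictly increasing
    ref : list of REF allele strings (length S)
    alt : list of lists of ALT allele strings (length S)
    qual : (S,) float array of phred site qualities
    mq : (S,) float array of RMS mapping qualities
    animals : list of sample ids (length N)
    gt : (N, S, 2) int array of allele indices, ``MISSING`` for ``./.``
    ad : (N, S, A) int array of per-allele depths, zero-padded beyond
        the site's allele count
    dp : (N, S) int array of total read depth
    """

    positions: np.ndarray
    ref: list
    alt: list
    qual: np.ndarray
    mq: np.ndarray
    animals: list
    gt: np.ndarray
    ad: np.ndarray
    dp: np.ndarray

    # ------------------------------------------------------------------ basic
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def n_alleles(self, j: int) -> int:
        return 1 + len(self.alt[j])

    def is_missing(self) -> np.ndarray:
        """(N, S) boolean mask of missing genotypes."""
        return self.gt[:, :, 0] == MISSING

    def is_het(self) -> np.ndarray:
        """(N, S) boolean mask of heteroplasmic (two distinct alleles) calls."""
        present = ~self.is_missing()
        return present & (self.gt[:, :, 0] != self.gt[:, :, 1])

    def is_indel_site(self) -> np.ndarray:
        """(S,) mask of sites where any allele length differs from REF."""
        out = np.zeros(self.n_sites, dtype=bool)
        for j in range(self.n_sites):
            rl = len(self.ref[j])
            out[j] = any(len(a) != rl for a in self.alt[j])
        return out

    # -------------------------------------------------------------- subsetting
    def select_sites(self, mask: np.ndarray) -> "MitoVariantTable":
        idx = np.flatnonzero(np.asarray(mask))
        return MitoVariantTable(
            positions=self.positions[idx].copy(),
            ref=[self.ref[j] for j in idx],
            alt=[list(self.alt[j]) for j in idx],
            qual=self.qual[idx].copy(),
            mq=self.mq[idx].copy(),
            animals=list(self.animals),
            gt=self.gt[:, idx].copy(),
            ad=self.ad[:, idx].copy(),
            dp=self.dp[:, idx].copy(),
        )

    def select_animals(self, mask: np.ndarray) -> "MitoVariantTable":
        idx = np.flatnonzero(np.asarray(mask))
        return MitoVariantTable(
            positions=self.positions.copy(),
            ref=list(self.ref),
            alt=[list(a) for a in self.alt],
            qual=self.qual.copy(),
            mq=self.mq.copy(),
            animals=[self.animals[i] for i in idx],
            gt=self.gt[idx].copy(),
            ad=self.ad[idx].copy(),
            dp=self.dp[idx].copy(),
        )

    def copy(self) -> "MitoVariantTable":
        return self.select_sites(np.ones(self.n_sites, dtype=bool))

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        if self.n_sites and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.ad < 0):
            raise ValueError("allele depths must be nonnegative")
        present = ~self.is_missing()
        if self.n_sites:
            max_allele = self.gt.max()
            widths = np.array([self.n_alleles(j) for j in range(self.n_sites)])
            if present.any() and max_allele >= widths.max():
                raise ValueError("genotype allele index out of range")

    # -------------------------------------------------------------------- I/O
    def to_vcf(self, path, contig: str = "MT", contig_length: int | None = None) -> None:
        write_vcf(self, path, contig=contig, contig_length=contig_length)


def read_vcf(path) -> MitoVariantTable:
    """Load a multi-sample VCF (FORMAT GT:AD:DP, INFO MQ) into a table."""
    vf = pysam.VariantFile(str(path))
    animals = list(vf.header.samples)
    positions, ref, alt, qual, mq = [], [], [], [], []
    gts, ads, dps = [], [], []
    for rec in vf:
        positions.append(rec.pos)
        ref.append(rec.ref)
        alts = list(rec.alts) if rec.alts else []
        alt.append(alts)
        qual.append(rec.qual if rec.qual is not None else np.nan)
        mq.append(float(rec.info.get("MQ", np.nan)))
        n_all = 1 + len(alts)
        row_gt = np.full((len(animals), 2), MISSING, dtype=np.int16)
        row_ad = np.zeros((len(animals), n_all), dtype=np.int32)
        row_dp = np.zeros(len(animals), dtype=np.int32)
        for i, name in enumerate(animals):
            s = rec.samples[name]
            g = s.get("GT")
            if g is not None and g[0] is not None:
                row_gt[i, 0] = g[0]
                row_gt[i, 1] = g[-1]
            a = s.get("AD")
            if a is not None and a[0] is not None:
                a = list(a)[:n_all]
                row_ad[i, : len(a)] = a
            d = s.get("DP")
            if d is not None:
                row_dp[i] = d
        gts.append(row_gt)
        ads.append(row_ad)
        dps.append(row_dp)
    vf.close()

    n_sites = len(positions)
    a_max = max((1 + len(a) for a in alt), default=1)
    gt = np.full((len(animals), n_sites, 2), MISSING, dtype=np.int16)
    ad = np.zeros((len(animals), n_sites, a_max), dtype=np.int32)
    dp = np.zeros((len(animals), n_sites), dtype=np.int32)
    for j in range(n_sites):
        gt[:, j] = gts[j]
        ad[:, j, : ads[j].shape[1]] = ads[j]
        dp[:, j] = dps[j]
    return MitoVariantTable(
        positions=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        qual=np.asarray(qual, dtype=float),
        mq=np.asarray(mq, dtype=float),
        animals=animals,
        gt=gt,
        ad=ad,
        dp=dp,
    )


def write_vcf(table: MitoVariantTable, path, contig: str = "MT",
              contig_length: int | None = None) -> None:
    """Write the table as VCFv4.2 text, deterministically.

    Output is byte-stable for identical tables: headers, float formats and
    field order are fixed.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mitokit",
    ]
    if contig_length is not None:
        lines.append(f"##contig=<ID={contig},length={contig_length}>")
    else:
        lines.append(f"##contig=<ID={contig}>")
    lines += [
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.animals),
    ]
    for j in range(table.n_sites):
        alts = ",".join(table.alt[j]) if table.alt[j] else "."
        n_all = table.n_alleles(j)
        fields = [
            contig,
            str(int(table.positions[j])),
            ".",
            table.ref[j],
            alts,
            f"{table.qual[j]:.2f}",
            ".",
            f"MQ={table.mq[j]:.2f}",
            "GT:AD:DP",
        ]
        for i in range(table.n_animals):
            a, b = table.gt[i, j]
            if a == MISSING:
                fields.append("./.:.:.")
            else:
                ad = ",".join(str(int(x)) for x in table.ad[i, j, :n_all])
                fields.append(f"{a}/{b}:{ad}:{int(table.dp[i, j])}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- metadata
def read_metadata(path) -> pd.DataFrame:
    """Read the animal metadata TSV (animal_id, breed, country, sex, tissue)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"animal_id", "breed", "country", "sex", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def semen_group_mask(table: MitoVariantTable, meta: pd.DataFrame) -> np.ndarray:
    """Boolean mask over table.animals: True = Semen group.

    Semen group: males sampled from semen or from unknown tissue.  Everyone
    else (all females; males from a known non-semen tissue) is Non-semen.
    """
    meta_idx = meta.set_index("animal_id")
    mask = np.zeros(table.n_animals, dtype=bool)
    for i, aid in enumerate(table.animals):
        if aid not in meta_idx.index:
            raise KeyError(f"animal {aid!r} missing from metadata")
        row = meta_idx.loc[aid]
        mask[i] = (row["sex"] == "M") and (row["tissue"] in (TISSUE_SEMEN, TISSUE_UNKNOWN))
    return mask
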