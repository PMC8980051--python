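#!/usr/bin/env python
"""Assign every consensus sequence to a haplogroup; compare whole-genome
with D-loop-only assignment; report shared private variants (putative
subgroups within haplogroups)."""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from mitokit.haplogroup import (assign_all, calls_to_frame,
                                find_shared_private_variants, restrict_to_region)
from mitokit.simulate import read_haplogroup_definitions
from mitokit.table import read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"
DLOOP = [(15792, 16340), (1, 363)]


def main() -> None:
    reference = str(next(SeqIO.parse(ROOT / "cohort" / "reference.fasta", "fasta")).seq)
    defs = read_haplogroup_definitions(ROOT / "cohort" / "haplogroup_defs.txt",
                                       reference)
    full = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(ROOT / "consensus" / "full_sequences.fasta",
                                   "fasta")}
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")

    calls = assign_all(full, defs)
    out = ROOT / "haplogroups"
    out.mkdir(parents=True, exist_ok=True)
    frame = calls_to_frame(calls)
    frame.to_csv(out / "calls.tsv", sep="\t", index=False)
    print("whole-genome mode:")
    print(frame["haplogroup"].value_counts().to_string())
    print("unresolved/unassignable:", int((frame["status"] != "assigned").sum()))

    dloop_defs = restrict_to_region(defs, DLOOP)
    dloop_frame = calls_to_frame(assign_all(full, dloop_defs))
    dloop_frame.to_csv(out / "calls_dloop.tsv", sep="\t", index=False)
    print("D-loop-only mode: unresolved/unassignable:",
          int((dloop_frame["status"] != "assigned").sum()),
          f"(groups without in-region variants: {dloop_defs.empty_groups})")

    shared = find_shared_private_variants(calls, meta, min_group_size=3)
    rows = [(r["haplogroup"], ";".join(f"{p}:{b}" for p, b in r["variants"]),
             len(r["members"]), ",".join(r["members"][:5]) + ("..." if len(r["members"]) > 5 else ""))
            for r in shared]
    pd.DataFrame(rows, columns=["haplogroup", "variants", "n_members", "members"]
                 ).to_csv(out / "shared_private_variants.tsv", sep="\t", index=False)
    print(f"shared private-variant sets (>=3 carriers): {len(shared)}")


if __name__ == "__main__":
    main()
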