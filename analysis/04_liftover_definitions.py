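#!/usr/bin/env python
"""Lift haplogroup-defining variants from the classical bovine reference
(BRS, 16,338 bp) to ARS-UCD1.2_M coordinates (16,340 bp) with the packaged
difference map, dropping variants whose allele coincides with the new
reference base (no longer variants after liftover)."""

from pathlib import Path

import pandas as pd

from mitokit.liftover import DefiningVariant, lift_variant_set, load_default_map

ROOT = Path(__file__).resolve().parent.parent / "results"

# the five defining variants sitting on reference-difference positions,
# plus representative defining variants elsewhere in the genome
BRS_DEFINING_VARIANTS = [
    DefiningVariant(2536, "A", "T"), DefiningVariant(8188, "C", "Q"),
    DefiningVariant(9682, "C", "I"), DefiningVariant(12165, "C", "T3"),
    DefiningVariant(13310, "C", "I"),
    DefiningVariant(169, "T", "T1"), DefiningVariant(1234, "G", "I1"),
    DefiningVariant(7777, "A", "Q1"), DefiningVariant(15000, "C", "T2"),
    DefiningVariant(16100, "T", "P"),
]


def main() -> None:
    lift_map = load_default_map()
    lifted, dropped = lift_variant_set(lift_map, BRS_DEFINING_VARIANTS)
    out = ROOT / "liftover"
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([(v.haplogroup, v.position, v.allele) for v in lifted],
                 columns=["haplogroup", "ars_position", "allele"]
                 ).to_csv(out / "defs_ars.tsv", sep="\t", index=False)
    pd.DataFrame([(v.haplogroup, v.position, pos, reason)
                  for v, pos, reason in dropped],
                 columns=["haplogroup", "brs_position", "ars_position", "reason"]
                 ).to_csv(out / "dropped.tsv", sep="\t", index=False)

    print(f"lifted {len(lifted)} defining variants; dropped {len(dropped)} "
          "that coincide with the ARS-UCD1.2_M reference base:")
    for v, pos, _ in dropped:
        print(f"  BRS {v.position} {v.allele} -> ARS {pos} (no longer variant)")


if __name__ == "__main__":
    main()
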