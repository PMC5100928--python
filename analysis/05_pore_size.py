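#!/usr/bin/env python
"""Excluded-volume pore sizing of the wild-type channel.

Computes vertex-method diameters for the eleven-cation test panel, applies
the permeant/impermeant classification from relative current at -80 mV,
and reports the largest permeant diameter as the lower bound on the
minimum pore diameter (~8.2 A).
"""

from pathlib import Path

from trpa1pore import poresize

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    diameters = poresize.panel_diameters()
    classified = poresize.classify_permeation()
    table = classified.merge(diameters, on="name").sort_values("diameter_A")
    table["diameter_A"] = table["diameter_A"].round(2)
    table.to_csv(OUT / "pore_size.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    cutoff = poresize.estimate_cutoff(classified, diameters)
    print(
        f"\nminimum pore diameter >= {cutoff.cutoff_A:.2f} A "
        f"(largest permeant: {cutoff.largest_permeant}; "
        f"smallest impermeant: {cutoff.smallest_impermeant}, "
        f"{cutoff.smallest_impermeant_A:.2f} A)"
    )
    if cutoff.ordering_violated:
        print("note: an impermeant cation is smaller than the largest permeant one")


if __name__ == "__main__":
    main()
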