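#!/usr/bin/env python
"""Genotype-to-chemotype prediction for the four clade combination patterns.

Builds FASTA input for four archetypal plants -- F x F (cultivated clade),
P x P (southern S. pennellii), hybrid-ASAT2 x P-ASAT3 (northern
S. pennellii), and the multi-allele S. habrochaites pattern -- and runs the
full chain: alignment -> residue calls -> allele union -> pathway
simulation.  Writes results/genotype_chemotype.tsv.
"""

import io
from pathlib import Path

import pandas as pd

from acylsugar import synth
from acylsugar.residues import predict_phenotype


def main() -> None:
    fx = synth.make_reference_fixtures()
    hybrid2 = synth.apply_mutations(fx["Sl-ASAT2-like"], {304: "G"})
    plants = {
        "clade_FxF": {"ASAT2": [fx["Sl-ASAT2-like"]], "ASAT3": [fx["Sl-ASAT3-like"]]},
        "south_pennellii_PxP": {"ASAT2": [fx["Sp-ASAT2-like"]], "ASAT3": [fx["Sp-ASAT3-like"]]},
        "north_pennellii_hybrid2xP3": {"ASAT2": [hybrid2], "ASAT3": [fx["Sp-ASAT3-like"]]},
        "habrochaites_multiallele": {
            "ASAT2": [hybrid2, fx["Sl-ASAT2-like"]],
            "ASAT3": [fx["Sl-ASAT3-like"], fx["Sp-ASAT3-like"]],
        },
    }
    parts = []
    for plant, fams in plants.items():
        for fam, seqs in fams.items():
            for i, seq in enumerate(seqs):
                parts.append(f">{plant}|{fam}|allele{i}\n{seq}\n")
    df = predict_phenotype(io.StringIO("".join(parts)))
    out = Path("results/genotype_chemotype.tsv")
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False))
    summary = df.groupby("plant").plant_phenotype.first()
    print("\nPredicted chemotypes:")
    for plant, pheno in summary.items():
        print(f"    {plant}: {{{pheno}}}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
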