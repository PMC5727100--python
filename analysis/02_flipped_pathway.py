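#!/usr/bin/env python
"""Simulate the cultivated and flipped acylsucrose pathways.

Runs the rule-based engine for four enzyme complements -- cultivated tomato
(ASAT1/2-F/3-F), S. pennellii (ASAT1/3-P/2-P), their union (the transgenic
and F1 situation), and the hybrid-ASAT2 x P-only-ASAT3 combination of
northern S. pennellii -- and writes the reachable states and provenance
edges.  The reaction-order reversal (R4->R3->R3' vs R4->R2->R3) is read off
the provenance, not assumed.
"""

from pathlib import Path

from acylsugar.pathway import (
    DEFAULT_DONORS,
    SL_ENZYMES,
    SP_ENZYMES,
    iC5,
    nC12,
    rules_by_name,
    simulate,
)

SCENARIOS = {
    "cultivated_F": (SL_ENZYMES, DEFAULT_DONORS),
    "pennellii_P": (SP_ENZYMES, frozenset({iC5, nC12})),
    "union_transgenic": (sorted(set(SL_ENZYMES) | set(SP_ENZYMES)), DEFAULT_DONORS),
    "hybrid2_x_P3": (("ASAT1", "ASAT2-F", "ASAT2-P", "ASAT3-P"), DEFAULT_DONORS),
}


def main() -> None:
    outdir = Path("results")
    outdir.mkdir(exist_ok=True)
    for name, (enzymes, donors) in SCENARIOS.items():
        result = simulate(rules_by_name(enzymes), donors)
        result.states_frame().to_csv(outdir / f"pathway_{name}_states.tsv", sep="\t", index=False)
        result.edges_frame().to_csv(outdir / f"pathway_{name}_edges.tsv", sep="\t", index=False)
        phenotype = "".join(sorted(t.value for t in result.phenotype_call)) or "none"
        print(f"{name}: {len(result.reachable)} states, "
              f"{len(result.products)} accumulating products, "
              f"{len(result.dead_ends)} dead ends, chemotype {{{phenotype}}}")
        for p in result.products:
            print(f"    product: {p}")
        for d in result.dead_ends:
            print(f"    dead end (degraded in planta): {d}")
    print(f"wrote state and edge tables under {outdir}/")


if __name__ == "__main__":
    main()
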