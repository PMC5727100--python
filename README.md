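# acylsugar

Tools for the computational side of tomato trichome acylsucrose chemistry:
structure and nomenclature modeling, exact-mass and CID-based annotation of
LC-MS peak lists, rule-based simulation of the F- and P-type biosynthetic
pathways, and prediction of enzyme activity and plant chemotype from
diagnostic protein residues.

## The problem

Glandular trichomes of tomato and its wild relatives secrete acylsucroses —
sucrose esterified with two to four short/medium acyl chains — as defense
metabolites. The field's shorthand `S3:22 (5R2, 12R3, 5R4)` reads: sucrose
backbone, 3 chains, 22 acyl carbons, with a C5 at pyranose position R2, a C12
at R3 and a C5 at R4. Two structural classes occur:

* **F-type**: one chain on the furanose (fructose) ring at R3′, the rest on
  the pyranose (glucose) ring — made by cultivated tomato via
  ASAT1 (→R4), ASAT2-F (→R3), ASAT3-F (→R3′);
* **P-type**: every chain on the pyranose ring — made by *Solanum pennellii*
  via a *flipped* pathway in which the ASAT2/ASAT3 reaction order is
  reversed: ASAT1 (→R4), ASAT3-P (→R2), ASAT2-P (→R3).

A handful of residues in the two BAHD acyltransferases switch the enzymes
between the F and P activities (ASAT2: 135/136 for F, 304 for P; ASAT3: the
161/162/289 triad for P, 354/381/382 for F, with a one-residue deletion in
the 381 region in P-type enzymes), so plant chemotype is predictable from
sequence alone.

This package implements all of that as a library (`src/acylsugar/`):

| module     | what it does |
|------------|--------------|
| `model`    | acylsucrose structures, `S n:m` nomenclature parser/formatter, F/P classification, branching-isomer enumeration |
| `masspec`  | elemental-formula arithmetic, monoisotopic adduct m/z, CID fragment prediction, composition and ring-split inference, peak-list annotation |
| `pathway`  | ASAT rewrite rules, breadth-first pathway closure, dead-end flagging, genotype→chemotype combination logic |
| `residues` | alignment-based residue mapping, F/P enzyme calls, plant-level phenotype prediction |
| `synth`    | deterministic synthetic sequences and peak lists with ground truth |

The narrative analyses live in `analysis/01_exact_masses.py` through
`analysis/05_annotation_roundtrip.py`; each writes its tables under
`results/`.

## Worked example

```python
>>> from acylsugar.model import parse_annotation
>>> from acylsugar.masspec import molecular_formula, adduct_mz
>>> s = parse_annotation("S2:10 (iC5R2, iC5R4)")
>>> str(molecular_formula(s))
'C22H38O13'
>>> round(adduct_mz(molecular_formula(s), "M+formate"), 4)
555.2294
```

That is the diacylsucrose made by ASAT1 + ASAT3-P: sucrose (C12H22O11) plus
two C5 chains (each +C5H8O), observed in negative mode as the [M+formate]−
anion at m/z 555.2294. Simulating the flipped pathway and reading the
chemotype:

```python
>>> from acylsugar.pathway import simulate, rules_by_name, SP_ENZYMES, iC5, nC12
>>> r = simulate(rules_by_name(SP_ENZYMES), {iC5, nC12})
>>> [str(p) for p in r.products]
['S3:15 (iC5R2, iC5R3, iC5R4)-P', 'S3:22 (iC5R2, nC12R3, iC5R4)-P']
>>> sorted(t.value for t in r.phenotype_call)
['P']
```

The two products are the P-type triacylsucroses that accumulate in plants
carrying the *S. pennellii* ASAT2/ASAT3 alleles; the provenance edges show
the acylation order R4 → R2 → R3, the reverse of the cultivated pathway.

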