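# Methods

## Structural model and nomenclature

An acylsucrose is modeled as a partial mapping from eight ring positions —
pyranose R2/R3/R4/R6 and furanose R1′/R3′/R4′/R6′ (spelled `R1p` … in
machine-facing strings) — to acyl chains, each a carbon count ≥ 2 with a
branching class (iso, anteiso, normal, or unspecified). Branching is
"unspecified" as a first-class value because LC-MS cannot distinguish iC5
from aiC5; only NMR resolves it, and `enumerate_isomers` expands the
unresolved structures combinatorially (e.g. the eight S3:15 branching
isomers). The total-chain cap of 8 is the structural bound of one chain per
modeled hydroxyl. Knowledge states degrade gracefully: placements (NMR- or
positive-mode-grade), composition-only (negative-mode-grade), or bare
`S k:m` counts — mass arithmetic needs only the counts.

Classification: **F** requires exactly one furanose chain, at R3′, plus at
least one pyranose chain; **P** requires ≥ 1 chain, all pyranose; any other
placed pattern is *other*; composition-only structures are *unclassifiable*.
The `-F`/`-P` suffix is emitted for classified structures with ≥ 2 chains
(mono-acylsucroses are conventionally written bare) and is cross-checked on
parsing.

## Mass spectrometry model

Monoisotopic masses use C = 12 exactly, H = 1.00782503, O = 15.99491462,
Na = 22.98976928, electron = 0.00054858 Da; ion m/z includes the electron
mass. Acylation adds CnH(2n−2)O per n-carbon chain to sucrose C12H22O11.
The formate adduct is applied as +CHO2 with charge −1. These conventions
reproduce the reference calcd adduct masses (555.2294, 639.2870, 737.3965)
to the printed 4 decimal places, and the package's mass table is checked
against pyteomics' isotope data in the test suite.

CID fragment model:

* negative mode — one carboxylate anion CnH(2n−1)O2− per distinct chain
  length, multiplicity recorded; this reveals chain number and lengths.
* positive mode — glycosidic cleavage into a glucosyl oxocarbenium
  (C6H11O5+) carrying the pyranose-ring chain increments and a fructosyl
  fragment carrying the furanose-ring increments. The fructosyl core is
  taken as the dehydrated C6H9O4+ species: the 18 Da offset between the two
  cores is what makes ring splits mass-distinguishable (with identical
  cores, mirror-image splits would be indistinguishable and the ring
  distribution could never be inferred uniquely). The exact fragment
  species produced in a given instrument vary (protonation, sodiation,
  ketene losses); this dialect is deliberately confined to
  `predict_fragments` for easy revision.

Composition inference enumerates chain-length multisets over a bounded
candidate space (default ≤ 4 chains, lengths {2, 4, 5, 10, 12} — the chain
lengths occurring in tomato-clade acylsucroses) and keeps candidates whose
[M+formate]− or [M−H]− matches the precursor within tolerance and whose
lengths cover the observed carboxylates. Ranking is by |ppm|; ties (distinct
multisets with equal chain count and carbon total share one formula, e.g.
4+4+4+4 vs 2+4+5+5) are broken by how many candidate chain lengths lack an
observed carboxylate, then fewer chains, then lexicographic order. The
default tolerance is 10 ppm (the reference found-vs-calcd discrepancies are
≤ 4 ppm). Retention time is carried through I/O but never scored; no
isotope-pattern fitting or quantification is attempted.

## Pathway engine

Each ASAT activity is a rewrite rule: required-occupied positions,
required-free positions (optionally exact occupancy), a product position,
and an allowed donor set. The six built-in rules:

| rule    | acceptor                     | product | donors |
|---------|------------------------------|---------|--------|
| ASAT1   | sucrose (exactly empty)      | R4      | iC5, aiC5 |
| ASAT2-F | R4 occupied; R2, R3 free     | R3      | iC5, aiC5, nC12 |
| ASAT3-F | R3+R4 occupied; R2, furanose free | R3′ | iC5, aiC5, nC12 |
| ASAT3-P | exactly R4 occupied          | R2      | iC5, aiC5 |
| ASAT2-P | R2+R4 occupied; R3 free      | R3      | iC5, aiC5, nC12 |
| ASAT4   | R3′ occupied; R2 free        | R2      | C2 |

ASAT2-F and ASAT3-F both require R2 free: the R2-acylated diacyl made by
ASAT3-P is not an acceptor for any cultivated-tomato enzyme, and plants
carrying both complements accumulate both product classes — neither fact
would hold if the F-branch enzymes accepted R2-acylated substrates. ASAT1's
aiC5 donor, and ASAT3-P's short-donor-only set (long chains are never
observed at R2), are documented assumptions where direct donor panels were
not reported. Donor preference is qualitative — no rate constants are
modeled, so product sets, not abundances, are the output.

Simulation is the breadth-first closure from sucrose (default `max_steps` 6,
bounded because every application adds a chain). Terminal states with one or
two chains are flagged dead ends — mono- and diacyl intermediates do not
accumulate in planta (they are degraded by acylsucrose hydrolases or
turned over), so the chemotype call is the set of F/P classes among the
remaining terminals. The flipped order (R4→R3→R3′ vs R4→R2→R3) is read off
provenance edges, not hard-coded. `phenotype_from_profiles` turns per-enzyme
F/P capability profiles into an enzyme complement (plus ASAT1) and
simulates; with an F-only ASAT2 and a P-only ASAT3 every route stalls at a
dead-end diacyl and no chemotype is called.

## Residue classifier

Diagnostic coordinates are 1-based positions in the family reference
(cultivated-tomato numbering); queries are projected through a global
pairwise alignment (BLOSUM62, gap open −10, extend −0.5 — fixed and
recorded in every report, since position mapping must be reproducible).
Queries shorter than 300 aa or aligning below 40% identity are rejected as
non-homologs. Percent identity is identical columns over alignment length,
gaps included in the denominator.

Calls: ASAT2 has F activity iff Q135∧Y136 (both residues are needed —
single mutants retain only residual activity) and P activity iff G304.
ASAT3 has P activity iff the full H161∧S162∧V289 triad (partial matches are
reported as weak evidence but never set the call, since single substitutions
confer only partial activity) and F activity iff L354∧H381∧P382. P-type
ASAT3 enzymes carry Ser plus a one-residue deletion in the 381/382 window;
because the gap can legitimately be rendered on either column by an
optimal alignment, the classifier admits 'S'/'-' at both sites. Residues
outside the naturally observed alphabets ({Q,H,P}@135, {Y,C}@136, {C,G}@304;
{Y,H}@161, {C,S}@162, {T,V}@289, {L,V}@354) raise an exception flag rather
than defaulting silently — no rule exists for unseen letters. A
user-extensible list of known nonconforming sequence ids (P-type enzymes
that violate the 354/381 pattern exist in nature) also sets the flag; it
ships empty.

Plant-level prediction unions the activity profiles over alleles
(co-dominance: a heterozygote makes both parents' products) and feeds the
union into the pathway engine.

## Synthetic data

The sequence fixtures are 460-residue uniform-random proteins with the
diagnostic letters planted — synthetic stand-ins, not database records, so
the suite needs no network. The `Sp-*-like` orthologs diverge from the
`Sl-*-like` templates by 5% seeded background substitution away from
diagnostic sites, emulating the > 92% amino-acid identity of the real
ortholog pairs; residues around the ASAT3 indel window are pinned so the
deletion aligns reproducibly. What the fixtures do **not** emulate: real
BAHD composition bias, conserved motifs (HXXXD/DFGWG), indel landscapes, or
any phylogenetic structure — passing recovery tests shows the mapping and
rules are implemented correctly, not that the classifier is robust to
arbitrary real-world divergence (it is exercised to 8% background, within
the ~8% divergence of the real pairs).

Peak-list scenarios emit the precursor adducts and mode-appropriate
fragments for each metabolite with Gaussian *ppm* (not Da) noise, mirroring
ToF behavior, plus uniform decoy peaks; intensities are fixed fractions of
metabolite abundance (formate 1.0, [M−H]− 0.3, fragments 0.6 per chain
multiplicity). No chromatographic peak shapes, isotopologue envelopes or
intensity calibration are simulated. The default round-trip conditions —
2 ppm noise, 20 decoys, 10 ppm matching tolerance — are the regime the
annotation logic is designed for; a 50 ppm-noise negative control in the
test suite documents where recovery breaks down.

## Numerical and scale choices

All generators and simulations are deterministic given their seeds; state
ordering is canonical (chain count, then nomenclature string). The
brute-force inverse check runs over the full default candidate space (125
compositions); the variant-recovery check uses 200 seeded variants (25 per
family × profile); both complete in seconds, which is why no larger sizes
were chosen. Degenerate inputs error loudly: negative element counts,
disallowed donors (distinct from acceptor no-match), occupied product
positions, empty peak lists, non-homologous queries.

## Known limitations

* Enzyme kinetics, donor competition and product abundances are out of
  scope; the engine enumerates reachability.
* The positive-mode fragment dialect is a documented model choice, not an
  instrument-validated fragment table.
* Acylglucoses, hydrolase chemistry and retention-time prediction are not
  modeled.
* The classifier's exception list for nonconforming P-type ASAT3 enzymes is
  empty by default; such sequences still classify by the triad rules but
  are the user's responsibility to curate.
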