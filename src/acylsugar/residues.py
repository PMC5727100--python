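"""Diagnostic-residue classification of ASAT2/ASAT3 proteins.

A handful of active-site-adjacent residues separate the F- and P-type
activities of the two BAHD acyltransferases that flipped their reaction
order in the tomato clade:

* **ASAT2** (Sl-ASAT2 numbering): Gln135+Tyr136 mark the F-type ability to
  acylate the monoacyl acceptor S1:5 (iC5R4) at R3; Gly304 marks the P-type
  ability to acylate the R2-bearing diacyl S2:10 (iC5R2, iC5R4).  Natural
  alphabets observed: {Q,H,P} at 135, {Y,C} at 136, {C,G} at 304.
* **ASAT3** (Sl-ASAT3 numbering): His161+Ser162+Val289 jointly mark P-type
  activity (single matches confer only partial activity and are reported as
  weak evidence, never as a call); Leu354+His381+Pro382 mark F-type
  activity.  P-type ASAT3s carry a single-residue deletion in the 381
  region, so their own numbering runs one behind (Val353/Ser380 in
  Sp-ASAT3); all queries are projected onto Sl numbering by global
  alignment, which makes the two numbering dialects one scheme.

Coordinates are 1-based positions in the family reference sequence; queries
are mapped through a deterministic global alignment (BLOSUM62, affine gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .model import SugarType
from .pathway import ActivityProfile, SimulationResult, phenotype_from_profiles

ASAT2_POSITIONS = (135, 136, 304)
ASAT3_POSITIONS = (161, 162, 289, 354, 381, 382)

#: Residue alphabets observed in nature at each diagnostic site; anything
#: outside raises the exception flag (the study gives no rule for them).
ASAT2_ALPHABETS = {135: "QHP", 136: "YC", 304: "CG"}
# P-type ASAT3s carry Ser plus a one-residue deletion in the 381/382 window;
# depending on where the alignment renders the gap, either site can read 'S'
# or '-', so both letters are admitted at both sites.
ASAT3_ALPHABETS = {161: "YH", 162: "CS", 289: "TV", 354: "LV", 381: "HS-", 382: "PS-"}

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MIN_LENGTH = 300       # plausible BAHD length guard
DEFAULT_IDENTITY_FLOOR = 40.0  # percent; below this the query is not a homolog


class NotHomologError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceScheme:
    """A family reference sequence and its diagnostic positions (1-based)."""

    family: str  # "ASAT2" | "ASAT3"
    reference_id: str
    reference_seq: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.family not in ("ASAT2", "ASAT3"):
            raise ValueError(f"unknown family {self.family!r}")
        for p in self.positions:
            if not 1 <= p <= len(self.reference_seq):
                raise ValueError(f"position {p} outside reference ({len(self.reference_seq)} aa)")


def default_scheme(family: str) -> ReferenceScheme:
    """Scheme backed by the package's synthetic Sl-like reference fixture."""
    from . import synth

    fixtures = synth.make_reference_fixtures()
    if family == "ASAT2":
        return ReferenceScheme(
            "ASAT2", "Sl-ASAT2-like", fixtures["Sl-ASAT2-like"], ASAT2_POSITIONS
        )
    if family == "ASAT3":
        return ReferenceScheme(
            "ASAT3", "Sl-ASAT3-like", fixtures["Sl-ASAT3-like"], ASAT3_POSITIONS
        )
    raise ValueError(f"unknown family {family!r}")


# Alignment parameters are fixed for reproducibility of position mapping and
# recorded in every report.
ALIGN_PARAMS = {"matrix": "BLOSUM62", "open": -10.0, "extend": -0.5}


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ALIGN_PARAMS["matrix"])
    aligner.open_gap_score = ALIGN_PARAMS["open"]
    aligner.extend_gap_score = ALIGN_PARAMS["extend"]
    return aligner


def _align(ref: str, query: str):
    return _aligner().align(ref, query)[0]


def _identity_from_alignment(alignment) -> float:
    ref_idx, query_idx = alignment.indices
    a, b = alignment.sequences
    same = sum(
        1
        for i, j in zip(ref_idx, query_idx)
        if i >= 0 and j >= 0 and a[i] == b[j]
    )
    return 100.0 * same / len(ref_idx)


def percent_identity(a: str, b: str) -> float:
    """Identical columns over alignment length (gaps in the denominator), 0-100."""
    if not a or not b:
        raise ValueError("empty sequence")
    return _identity_from_alignment(_align(a, b))


def map_positions(
    query: str,
    scheme: ReferenceScheme,
    min_length: int = DEFAULT_MIN_LENGTH,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> dict[int, str]:
    """Project the scheme's diagnostic positions onto a query sequence.

    Returns ``{reference position: query residue or '-'}`` read off a global
    alignment to the family reference.  Queries that are too short or align
    below the identity floor are rejected as non-homologs.
    """
    query = str(query).strip().upper()
    if len(query) <= min_length:
        raise ValueError(
            f"query of {len(query)} aa is below the BAHD length guard ({min_length})"
        )
    alignment = _align(scheme.reference_seq, query)
    identity = _identity_from_alignment(alignment)
    if identity < identity_floor:
        raise NotHomologError(
            f"alignment identity {identity:.1f}% below floor {identity_floor}%: "
            f"not an {scheme.family} homolog"
        )
    ref_idx, query_idx = alignment.indices
    by_ref = {int(i): int(j) for i, j in zip(ref_idx, query_idx) if i >= 0}
    out: dict[int, str] = {}
    for pos in scheme.positions:
        j = by_ref[pos - 1]
        out[pos] = query[j] if j >= 0 else "-"
    return out


@dataclass(frozen=True)
class EnzymeCall:
    """Activity profile plus the residue evidence behind it."""

    family: str
    profile: ActivityProfile
    residues: Mapping[int, str]
    evidence: Mapping[str, str]
    exception_flag: bool


def classify_asat2(residues: Mapping[int, str]) -> EnzymeCall:
    """F/P call from ASAT2 residues {135, 136, 304}.

    F-type activity requires Q135 and Y136 together (both substitutions are
    needed to abolish or restore it); P-type activity tracks G304 alone.
    """
    missing = [p for p in ASAT2_POSITIONS if p not in residues]
    if missing:
        raise ValueError(f"residues missing for positions {missing}")
    r135, r136, r304 = (residues[p] for p in ASAT2_POSITIONS)
    has_F = r135 == "Q" and r136 == "Y"
    has_P = r304 == "G"
    exception = any(
        residues[p] not in ASAT2_ALPHABETS[p] for p in ASAT2_POSITIONS
    )
    evidence = {
        "F-rule": f"135={r135},136={r136} ({'match' if has_F else 'no match'} QY)",
        "P-rule": f"304={r304} ({'match' if has_P else 'no match'} G)",
    }
    return EnzymeCall(
        "ASAT2", ActivityProfile(has_F, has_P), dict(residues), evidence, exception
    )


def classify_asat3(
    residues: Mapping[int, str],
    known_exceptions: Iterable[str] = (),
    sequence_id: str | None = None,
) -> EnzymeCall:
    """F/P call from ASAT3 residues {161, 162, 289, 354, 381, 382}.

    P-type activity requires the full H161+S162+V289 triad; one or two
    matches are reported as weak evidence only.  F-type activity requires
    L354+H381+P382.  ``known_exceptions`` is a user-extensible list of
    sequence ids documented to violate the 354/381 pattern.
    """
    missing = [p for p in ASAT3_POSITIONS if p not in residues]
    if missing:
        raise ValueError(f"residues missing for positions {missing}")
    p_triad = {161: "H", 162: "S", 289: "V"}
    f_triad = {354: "L", 381: "H", 382: "P"}
    n_p = sum(residues[p] == aa for p, aa in p_triad.items())
    n_f = sum(residues[p] == aa for p, aa in f_triad.items())
    has_P = n_p == 3
    has_F = n_f == 3
    exception = any(
        residues[p] not in ASAT3_ALPHABETS[p] for p in ASAT3_POSITIONS
    ) or (sequence_id is not None and sequence_id in set(known_exceptions))
    evidence = {
        "P-rule": f"{n_p}/3 of H161,S162,V289"
        + ("" if has_P or n_p == 0 else " (weak-P evidence, not called)"),
        "F-rule": f"{n_f}/3 of L354,H381,P382",
    }
    return EnzymeCall(
        "ASAT3", ActivityProfile(has_F, has_P), dict(residues), evidence, exception
    )


def classify_sequence(
    query: str,
    family: str,
    scheme: ReferenceScheme | None = None,
    sequence_id: str | None = None,
    known_exceptions: Iterable[str] = (),
) -> EnzymeCall:
    """Map a protein sequence onto the family scheme and classify it."""
    scheme = scheme or default_scheme(family)
    residues = map_positions(query, scheme)
    if family == "ASAT2":
        return classify_asat2(residues)
    return classify_asat3(residues, known_exceptions, sequence_id)


# -- plant-level prediction -------------------------------------------------


def parse_family(header: str, family_map: Mapping[str, str] | None = None) -> str:
    """Family from a ``|ASAT2|``/``|ASAT3|`` header tag or a config mapping."""
    seq_id = header.split()[0]
    if family_map and seq_id in family_map:
        return family_map[seq_id]
    for fam in ("ASAT2", "ASAT3"):
        if f"|{fam}|" in header or f"|{fam}" in header.rstrip("|") + "|":
            return fam
    raise ValueError(
        f"cannot determine enzyme family for {header!r}; tag headers with "
        "|ASAT2|/|ASAT3| or provide a family map"
    )


def _parse_plant(header: str) -> str:
    return header.split("|")[0].split()[0]


def predict_phenotype(
    fasta,
    family_map: Mapping[str, str] | None = None,
    plant_map: Mapping[str, str] | None = None,
    schemes: Mapping[str, ReferenceScheme] | None = None,
    known_exceptions: Iterable[str] = (),
) -> pd.DataFrame:
    """Genotype-to-chemotype prediction for FASTA input.

    Headers follow ``plant|FAMILY|allele`` (or supply explicit maps).  Each
    allele is classified; per-plant profiles are the union over alleles
    (co-dominance: an F1 heterozygote makes both parents' products); the
    plant chemotype comes from simulating the implied enzyme complement.

    Returns one row per sequence with its call, plus the plant phenotype.
    """
    records = list(SeqIO.parse(fasta, "fasta"))
    if not records:
        raise ValueError("no sequences in input")
    schemes = schemes or {
        "ASAT2": default_scheme("ASAT2"),
        "ASAT3": default_scheme("ASAT3"),
    }
    rows = []
    plants: dict[str, dict[str, list[EnzymeCall]]] = {}
    for rec in records:
        fam = parse_family(rec.description, family_map)
        plant = (
            plant_map[rec.id] if plant_map and rec.id in plant_map
            else _parse_plant(rec.description)
        )
        call = classify_sequence(
            str(rec.seq), fam, schemes[fam], rec.id, known_exceptions
        )
        plants.setdefault(plant, {"ASAT2": [], "ASAT3": []})[fam].append(call)
        rows.append(
            {
                "sequence_id": rec.id,
                "plant": plant,
                "family": fam,
                "residues": ";".join(
                    f"{p}{aa}" for p, aa in sorted(call.residues.items())
                ),
                "has_F": call.profile.has_F,
                "has_P": call.profile.has_P,
                "exception": call.exception_flag,
            }
        )
    df = pd.DataFrame(rows)

    phenos = {}
    for plant, calls in plants.items():
        if not calls["ASAT2"] or not calls["ASAT3"]:
            raise ValueError(
                f"plant {plant!r} needs at least one ASAT2 and one ASAT3 sequence"
            )
        profile2 = ActivityProfile(
            any(c.profile.has_F for c in calls["ASAT2"]),
            any(c.profile.has_P for c in calls["ASAT2"]),
        )
        profile3 = ActivityProfile(
            any(c.profile.has_F for c in calls["ASAT3"]),
            any(c.profile.has_P for c in calls["ASAT3"]),
        )
        result = phenotype_from_profiles(profile2, profile3)
        phenos[plant] = "".join(
            sorted(t.value for t in result.phenotype_call)
        ) or "none"
    df["plant_phenotype"] = df["plant"].map(phenos)
    df.attrs["alignment"] = dict(ALIGN_PARAMS)
    return df
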