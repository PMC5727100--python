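"""Exact-mass arithmetic and CID-based annotation of acylsucroses.

Acylsucrose identification from LC-ToF MS rests on three measurements:

* the precursor adduct mass (negative mode: usually [M+formate]-, sometimes
  [M-H]-), which fixes the elemental formula and hence the chain count and
  total acyl carbons;
* negative-mode CID carboxylate fragments (CnH(2n-1)O2-), one per distinct
  chain length, which reveal the lengths of the acyl chains;
* positive-mode CID glycosidic cleavage, which splits the molecule into
  glucosyl (pyranose) and fructosyl (furanose) oxocarbenium fragments, each
  carrying its ring's acyl chains -- revealing the ring distribution and so
  the F/P class.

Mass convention: monoisotopic masses with C = 12 exactly, and ion m/z
includes the electron mass.  The positive-mode fragment model (hexosyl
oxocarbenium C6H11O5+ plus per-chain increments) is a documented model of
this package, kept behind :func:`predict_fragments` for easy revision.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AcylSucrose,
    Ring,
    SugarType,
    classify_type,
    format_annotation,
)

# Monoisotopic atomic masses (IUPAC/CODATA).
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503,
    "O": 15.99491462,
    "Na": 22.98976928,
}
ELECTRON_MASS = 0.00054858

#: Default matching tolerance; the study's found-vs-calcd errors are <= 4 ppm.
DEFAULT_TOL_PPM = 10.0

#: Default candidate space for composition inference.
DEFAULT_MAX_CHAINS = 4
DEFAULT_CHAIN_LENGTHS = (2, 4, 5, 10, 12)


class FormulaError(ValueError):
    """Raised when formula arithmetic would go below zero atoms."""


@dataclass(frozen=True)
class ElementalFormula:
    """Integer C/H/O (and Na, for sodiated ions) counts with a charge."""

    c: int = 0
    h: int = 0
    o: int = 0
    na: int = 0
    charge: int = 0

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.o, self.na) < 0:
            raise FormulaError(f"negative element count in {self!r}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.c + other.c,
            self.h + other.h,
            self.o + other.o,
            self.na + other.na,
            self.charge + other.charge,
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        c, h, o, na = (
            self.c - other.c,
            self.h - other.h,
            self.o - other.o,
            self.na - other.na,
        )
        if min(c, h, o, na) < 0:
            raise FormulaError(
                f"subtracting {other} from {self} yields negative counts"
            )
        return ElementalFormula(c, h, o, na, self.charge - other.charge)

    def replace_charge(self, charge: int) -> "ElementalFormula":
        return ElementalFormula(self.c, self.h, self.o, self.na, charge)

    def __str__(self) -> str:
        parts = []
        for sym, n in (("C", self.c), ("H", self.h), ("Na", self.na), ("O", self.o)):
            if n:
                parts.append(f"{sym}{n if n != 1 else ''}")
        body = "".join(parts) or "(empty)"
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            body += sign * abs(self.charge)
        return body


SUCROSE = ElementalFormula(c=12, h=22, o=11)


def chain_increment(carbons: int) -> ElementalFormula:
    """Formula change on esterifying one acyl chain of n carbons: CnH(2n-2)O."""
    if carbons < 2:
        raise ValueError("acyl chain needs >= 2 carbons")
    return ElementalFormula(c=carbons, h=2 * carbons - 2, o=1)


def molecular_formula(s: AcylSucrose) -> ElementalFormula:
    """Neutral formula of an acylsucrose: C12H22O11 plus CnH(2n-2)O per chain."""
    k, m = s.n_chains, s.total_carbons
    return ElementalFormula(c=12 + m, h=22 + 2 * m - 2 * k, o=11 + k)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da; ions include the electron mass."""
    mass = (
        f.c * MONOISOTOPIC["C"]
        + f.h * MONOISOTOPIC["H"]
        + f.o * MONOISOTOPIC["O"]
        + f.na * MONOISOTOPIC["Na"]
    )
    return mass - f.charge * ELECTRON_MASS


@dataclass(frozen=True)
class Adduct:
    """A named ionization adduct; the name fixes the delta and charge."""

    name: str
    delta: ElementalFormula
    charge: int


# Formate is applied as +CHO2 with charge -1, which reproduces the printed
# adduct formulas (C22H38O13 -> C23H39O15-).
# M-H removes one hydrogen; the subtraction happens at application time, so
# its stored delta is empty.
ADDUCTS: dict[str, Adduct] = {
    "M-H": Adduct("M-H", ElementalFormula(), -1),
    "M+formate": Adduct("M+formate", ElementalFormula(c=1, h=1, o=2), -1),
    "M+H": Adduct("M+H", ElementalFormula(h=1), +1),
    "M+Na": Adduct("M+Na", ElementalFormula(na=1), +1),
}
NEGATIVE_ADDUCTS = ("M+formate", "M-H")
POSITIVE_ADDUCTS = ("M+H", "M+Na")


def adduct_mz(f: ElementalFormula, adduct: str | Adduct) -> float:
    """m/z of the singly charged adduct ion of a neutral formula."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None
    if f.charge != 0:
        raise ValueError("adduct_mz expects a neutral formula")
    if adduct.name == "M-H":
        ion = (f - ElementalFormula(h=1)).replace_charge(-1)
    else:
        ion = (f + adduct.delta).replace_charge(adduct.charge)
    return monoisotopic_mass(ion)


def carboxylate_formula(carbons: int) -> ElementalFormula:
    """Negative-mode CID carboxylate anion of an n-carbon chain: CnH(2n-1)O2-."""
    return ElementalFormula(c=carbons, h=2 * carbons - 1, o=2, charge=-1)


#: Glucosyl oxocarbenium core from glycosidic cleavage (pyranose side).
GLUCOSYL_CATION = ElementalFormula(c=6, h=11, o=5, charge=+1)
#: Fructofuranosyl core, observed after water loss (furanose side).  The
#: 18 Da offset makes the two ring fragments mass-distinguishable, which is
#: what lets positive-mode CID resolve the ring distribution.
FRUCTOSYL_CATION = ElementalFormula(c=6, h=9, o=4, charge=+1)


@dataclass(frozen=True)
class Fragment:
    label: str
    formula: ElementalFormula
    mz: float
    multiplicity: int = 1


class CompositionOnlyError(ValueError):
    """Positive-mode fragment prediction needs placements; use negative mode."""


def predict_fragments(s: AcylSucrose, polarity: str) -> list[Fragment]:
    """Predicted CID fragment ions of an acylsucrose.

    Negative mode: one carboxylate anion per distinct chain length
    (duplicates collapsed, multiplicity recorded).  Positive mode: the
    glucosyl (pyranose) and fructosyl (furanose) oxocarbenium fragments, each
    carrying its ring's chain increments; requires placements.
    """
    if polarity == "negative":
        out = []
        for n, mult in sorted(s.composition.items()):
            f = carboxylate_formula(n)
            out.append(Fragment(f"carboxylate-C{n}", f, monoisotopic_mass(f), mult))
        return out
    if polarity == "positive":
        if s.n_chains and not s.placements:
            raise CompositionOnlyError(
                "ring-resolved fragments need placements; composition-only "
                "candidates are annotated in negative mode"
            )
        out = []
        for ring, label, core in (
            (Ring.PYRANOSE, "pyranose", GLUCOSYL_CATION),
            (Ring.FURANOSE, "furanose", FRUCTOSYL_CATION),
        ):
            chains = s.chains_on(ring)
            f = core
            for c in chains:
                f = f + chain_increment(c.carbons)
            out.append(
                Fragment(
                    f"{label}+{len(chains)}chains", f, monoisotopic_mass(f)
                )
            )
        return out
    raise ValueError(f"polarity must be 'negative' or 'positive', got {polarity!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


# -- composition inference -------------------------------------------------


@dataclass(frozen=True)
class CompositionHit:
    candidate: AcylSucrose
    adduct: str
    theoretical_mz: float
    ppm: float


def enumerate_compositions(
    max_chains: int = DEFAULT_MAX_CHAINS,
    chain_lengths: Sequence[int] = DEFAULT_CHAIN_LENGTHS,
) -> list[tuple[int, ...]]:
    """The bounded candidate space of chain-length multisets."""
    out: list[tuple[int, ...]] = []
    for k in range(1, max_chains + 1):
        out.extend(
            itertools.combinations_with_replacement(sorted(chain_lengths), k)
        )
    return out


def infer_composition(
    precursor_mz: float,
    carboxylate_mzs: Iterable[float] = (),
    polarity: str = "negative",
    tol_ppm: float = DEFAULT_TOL_PPM,
    max_chains: int = DEFAULT_MAX_CHAINS,
    chain_lengths: Sequence[int] = DEFAULT_CHAIN_LENGTHS,
) -> list[CompositionHit]:
    """Rank chain-length multisets consistent with a precursor and its CID
    carboxylates.

    A candidate matches if its [M+formate]- or [M-H]- m/z is within
    ``tol_ppm`` of the precursor and every observed carboxylate m/z matches
    the carboxylate of some chain length in the candidate.  Hits are ranked
    by |ppm| of the precursor match; ties (isomeric chain-count/total pairs
    such as 4+4+4+4 vs 2+4+5+5 share one formula) are broken first by how
    many of the candidate's distinct chain lengths lack an observed
    carboxylate, then by fewer chains, then lexicographic composition.  An
    empty list (no candidate in tolerance) is a valid result.
    """
    if polarity != "negative":
        raise ValueError("composition inference is defined for negative mode")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    carbox = list(carboxylate_mzs)
    hits: list[tuple[int, CompositionHit]] = []
    for comp in enumerate_compositions(max_chains, chain_lengths):
        cand = AcylSucrose.from_composition(comp)
        f = molecular_formula(cand)
        best: tuple[float, str, float] | None = None
        for name in NEGATIVE_ADDUCTS:
            theo = adduct_mz(f, name)
            err = ppm_error(precursor_mz, theo)
            if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best[0])):
                best = (err, name, theo)
        if best is None:
            continue
        chain_theos = {n: monoisotopic_mass(carboxylate_formula(n)) for n in comp}
        if not all(
            any(abs(ppm_error(obs, t)) <= tol_ppm for t in chain_theos.values())
            for obs in carbox
        ):
            continue
        unexplained = sum(
            not any(abs(ppm_error(obs, t)) <= tol_ppm for obs in carbox)
            for t in chain_theos.values()
        )
        hits.append((unexplained, CompositionHit(cand, best[1], best[2], best[0])))
    hits.sort(
        key=lambda uh: (
            abs(uh[1].ppm),
            uh[0],
            uh[1].candidate.n_chains,
            uh[1].candidate.composition_only,
        )
    )
    return [h for _, h in hits]


# -- ring-distribution inference -------------------------------------------


@dataclass(frozen=True)
class RingSplit:
    pyranose: tuple[int, ...]
    furanose: tuple[int, ...]


@dataclass(frozen=True)
class RingDistribution:
    """Outcome of positive-mode ring-split inference."""

    splits: tuple[RingSplit, ...]

    @property
    def ambiguous(self) -> bool:
        return len(self.splits) != 1

    @property
    def unique(self) -> RingSplit | None:
        return self.splits[0] if len(self.splits) == 1 else None


def _all_splits(composition: Sequence[int]) -> list[RingSplit]:
    comp = tuple(sorted(composition))
    n = len(comp)
    seen = set()
    out = []
    for mask in range(2**n):
        pyr = tuple(sorted(comp[i] for i in range(n) if mask >> i & 1))
        fur = tuple(sorted(comp[i] for i in range(n) if not mask >> i & 1))
        if len(pyr) > 4 or len(fur) > 4:
            continue  # at most four hydroxyls modeled per ring
        if (pyr, fur) in seen:
            continue
        seen.add((pyr, fur))
        out.append(RingSplit(pyr, fur))
    out.sort(key=lambda s: (len(s.furanose), s.furanose, s.pyranose))
    return out


def _split_fragment_mzs(split: RingSplit) -> tuple[float, float]:
    pyr = GLUCOSYL_CATION
    for n in split.pyranose:
        pyr = pyr + chain_increment(n)
    fur = FRUCTOSYL_CATION
    for n in split.furanose:
        fur = fur + chain_increment(n)
    return monoisotopic_mass(pyr), monoisotopic_mass(fur)


def infer_ring_distribution(
    positive_fragment_mzs: Iterable[float],
    candidate: AcylSucrose,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> RingDistribution:
    """Which ring split of a known composition explains the positive-mode
    glycosidic-cleavage fragments.

    Every split of the composition between the two rings is tested; a split
    is consistent when both its predicted fragment ions match observed peaks
    within ``tol_ppm``.  With no fragments supplied the result is ambiguous
    and lists all splits.
    """
    splits = _all_splits(tuple(candidate.composition.elements()))
    observed = list(positive_fragment_mzs)
    if not observed:
        return RingDistribution(tuple(splits))
    consistent = []
    for split in splits:
        theo = _split_fragment_mzs(split)
        if all(
            any(abs(ppm_error(obs, t)) <= tol_ppm for obs in observed)
            for t in theo
        ):
            consistent.append(split)
    return RingDistribution(tuple(consistent))


# -- peak lists and annotation ---------------------------------------------


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    polarity: str
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity must be negative/positive, got {self.polarity!r}")


def read_peaklist(path, sep: str = "\t") -> list[Peak]:
    """Read a delimited peak table (columns mz, intensity, polarity, optional rt)."""
    df = pd.read_csv(path, sep=sep)
    required = {"mz", "intensity", "polarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    has_rt = "rt" in df.columns
    return [
        Peak(
            float(r.mz),
            float(r.intensity),
            str(r.polarity),
            float(r.rt) if has_rt and pd.notna(r.rt) else None,
        )
        for r in df.itertuples()
    ]


def write_peaklist(peaks: Sequence[Peak], path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "mz": [p.mz for p in peaks],
            "intensity": [p.intensity for p in peaks],
            "polarity": [p.polarity for p in peaks],
            "rt": [p.rt for p in peaks],
        }
    ).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class Annotation:
    candidate: AcylSucrose
    role: str  # precursor | carboxylate-fragment | pyranose-fragment | furanose-fragment
    label: str  # adduct or fragment label
    theoretical_mz: float
    observed_mz: float
    ppm: float
    intensity: float


@dataclass
class AnnotationResult:
    annotations: list[Annotation]
    unmatched: list[Peak]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": [format_annotation(a.candidate) for a in self.annotations],
                "role": [a.role for a in self.annotations],
                "label": [a.label for a in self.annotations],
                "theoretical_mz": [a.theoretical_mz for a in self.annotations],
                "observed_mz": [a.observed_mz for a in self.annotations],
                "ppm": [a.ppm for a in self.annotations],
                "intensity": [a.intensity for a in self.annotations],
            }
        )

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _theoretical_ions(
    candidate: AcylSucrose, polarity: str
) -> list[tuple[str, str, float]]:
    """(role, label, m/z) for every ion a candidate can produce in a polarity."""
    f = molecular_formula(candidate)
    ions: list[tuple[str, str, float]] = []
    adducts = NEGATIVE_ADDUCTS if polarity == "negative" else POSITIVE_ADDUCTS
    for name in adducts:
        ions.append(("precursor", name, adduct_mz(f, name)))
    if polarity == "negative":
        for frag in predict_fragments(candidate, "negative"):
            ions.append(("carboxylate-fragment", frag.label, frag.mz))
    elif candidate.placements or candidate.n_chains == 0:
        for frag in predict_fragments(candidate, "positive"):
            role = frag.label.split("+")[0] + "-fragment"
            ions.append((role, frag.label, frag.mz))
    return ions


def annotate_peaklist(
    peaks: Sequence[Peak],
    candidates: Sequence[AcylSucrose],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> AnnotationResult:
    """Match every candidate's theoretical ions against observed peaks.

    Every (candidate, ion) theoretical m/z within ``tol_ppm`` of an observed
    peak yields one annotation; multiple matches to one peak are all
    reported.  Annotations are sorted by observed m/z then |ppm|; unmatched
    peaks are returned separately.
    """
    if not peaks:
        raise ValueError("empty peak list")
    annotations: list[Annotation] = []
    matched: set[int] = set()
    for cand in candidates:
        for polarity in ("negative", "positive"):
            if not any(p.polarity == polarity for p in peaks):
                continue
            try:
                ions = _theoretical_ions(cand, polarity)
            except CompositionOnlyError:
                continue
            for role, label, theo in ions:
                for i, peak in enumerate(peaks):
                    if peak.polarity != polarity:
                        continue
                    err = ppm_error(peak.mz, theo)
                    if abs(err) <= tol_ppm:
                        matched.add(i)
                        annotations.append(
                            Annotation(
                                cand, role, label, theo, peak.mz, err, peak.intensity
                            )
                        )
    annotations.sort(key=lambda a: (a.observed_mz, abs(a.ppm), a.label))
    unmatched = [p for i, p in enumerate(peaks) if i not in matched]
    return AnnotationResult(annotations, unmatched)
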