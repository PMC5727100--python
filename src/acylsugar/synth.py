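"""Synthetic sequences and peak lists with known ground truth.

Every fixture here is synthetic: the protein fixtures are BAHD-length
stand-ins (not GenBank records) carrying the diagnostic residue letters at
the diagnostic positions, over a deterministic pseudo-random background.
The peak-list generator emits the adduct and CID fragment ions the mass
module predicts, perturbed by Gaussian ppm-scale noise (mirroring ToF mass
accuracy) plus uniform decoy peaks.  Everything is bit-reproducible given
its seed, so the whole suite runs without downloads.

An optional, clearly separate network utility (:func:`fetch_genbank_proteins`)
can pull the real deposited accessions for cross-checks; no test uses it.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AcylSucrose, format_annotation
from .masspec import (
    Peak,
    adduct_mz,
    molecular_formula,
    predict_fragments,
)
from .pathway import ActivityProfile

AA20 = "ACDEFGHIKLMNPQRSTVWY"

TEMPLATE_LENGTH = 460  # typical BAHD acyltransferase length

# Sl (cultivated tomato) diagnostic letters, planted into the templates.
_SL_ASAT2 = {135: "Q", 136: "Y", 304: "C"}
_SL_ASAT3 = {161: "Y", 162: "C", 289: "T", 354: "L", 381: "H", 382: "P"}

# Residues around the ASAT3 381/382 indel region are pinned so the deletion
# aligns reproducibly.
_ASAT3_CONTEXT = {376: "F", 377: "W", 378: "K", 379: "D", 380: "M",
                  383: "E", 384: "N", 385: "G", 386: "R"}

# Sites never touched by background substitutions (diagnostic +/- 2, and the
# pinned indel context for ASAT3).
def _protected_sites(family: str) -> frozenset[int]:
    diag = _SL_ASAT2 if family == "ASAT2" else _SL_ASAT3
    protected = set()
    for p in diag:
        protected.update(range(p - 2, p + 3))
    if family == "ASAT3":
        protected.update(_ASAT3_CONTEXT)
    return frozenset(protected)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def substitute(seq: str, pos: int, aa: str) -> str:
    """Replace the residue at a 1-based position; ``aa`` may be multi-letter
    (insertion) or empty (deletion)."""
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside sequence of {len(seq)} aa")
    return seq[: pos - 1] + aa + seq[pos:]


def apply_mutations(seq: str, mutations: Mapping[int, str]) -> str:
    """Apply {position: replacement} edits, right to left so coordinates hold."""
    for pos in sorted(mutations, reverse=True):
        seq = substitute(seq, pos, mutations[pos])
    return seq


def _background(
    seq: str,
    rate: float,
    protected: frozenset[int],
    rng: np.random.Generator,
) -> str:
    """Per-site substitutions at ``rate``, never at protected sites."""
    chars = list(seq)
    for i in range(len(chars)):
        if (i + 1) in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


@functools.lru_cache(maxsize=1)
def _templates() -> dict[str, str]:
    rng2 = np.random.default_rng(1201)
    t2 = apply_mutations(_random_protein(rng2, TEMPLATE_LENGTH), _SL_ASAT2)
    rng3 = np.random.default_rng(1202)
    t3 = apply_mutations(
        _random_protein(rng3, TEMPLATE_LENGTH), {**_SL_ASAT3, **_ASAT3_CONTEXT}
    )
    return {"ASAT2": t2, "ASAT3": t3}


# The four named ortholog stand-ins diverge from the Sl template by ~5%
# background substitution, emulating the >92% amino-acid identity between
# the cultivated-tomato and S. pennellii orthologs.
FIXTURE_BACKGROUND_RATE = 0.05

# Diagnostic letters of the S. pennellii orthologs.
_SP_ASAT2 = {135: "H", 136: "C", 304: "G"}
_SP_ASAT3 = {161: "H", 162: "S", 289: "V", 354: "V", 381: "S", 382: ""}


@functools.lru_cache(maxsize=1)
def make_reference_fixtures() -> dict[str, str]:
    """The four synthetic ortholog fixtures (deterministic).

    ``Sl-ASAT2-like``/``Sl-ASAT3-like`` carry the cultivated-tomato
    diagnostic letters, ``Sp-*-like`` the S. pennellii letters, including the
    ASAT3 single-residue deletion in the 381/382 region.
    """
    t = _templates()
    rng = np.random.default_rng(1203)
    sp2 = _background(
        apply_mutations(t["ASAT2"], _SP_ASAT2),
        FIXTURE_BACKGROUND_RATE,
        _protected_sites("ASAT2"),
        rng,
    )
    sp3 = _background(
        apply_mutations(t["ASAT3"], _SP_ASAT3),
        FIXTURE_BACKGROUND_RATE,
        # protect in post-deletion coordinates: keep the whole indel window
        frozenset(p - (p > 382) for p in _protected_sites("ASAT3")),
        rng,
    )
    return {
        "Sl-ASAT2-like": t["ASAT2"],
        "Sp-ASAT2-like": sp2,
        "Sl-ASAT3-like": t["ASAT3"],
        "Sp-ASAT3-like": sp3,
    }


def fixtures_fasta() -> str:
    """The reference fixtures as FASTA text (ids tagged with the family)."""
    out = []
    for name, seq in make_reference_fixtures().items():
        family = "ASAT2" if "ASAT2" in name else "ASAT3"
        out.append(f">{name}|{family}|synthetic\n{seq}\n")
    return "".join(out)


# -- the mutagenesis / natural-variant panel --------------------------------


@dataclass(frozen=True)
class PanelEntry:
    name: str
    family: str
    sequence: str
    expected: ActivityProfile


def activity_panel() -> list[PanelEntry]:
    """Synthetic stand-ins for every enzyme whose activity the mutagenesis
    and natural-variant survey established.

    Covers the wild-type parents, the natural hybrid and P-type variants,
    and the site-directed mutants (single-letter edits on the fixture
    sequences, in each sequence's own coordinates).
    """
    fx = make_reference_fixtures()
    t2, sp2 = fx["Sl-ASAT2-like"], fx["Sp-ASAT2-like"]
    t3, sp3 = fx["Sl-ASAT3-like"], fx["Sp-ASAT3-like"]
    rng = np.random.default_rng(1204)
    prot2 = _protected_sites("ASAT2")

    # natural variants: distinct backgrounds, diagnostic letters planted
    la1777 = _background(
        apply_mutations(t2, {304: "G"}), 0.04, prot2, rng
    )  # Q135 Y136 G304: hybrid
    la1926 = _background(
        apply_mutations(t2, {135: "P", 136: "C", 304: "G"}), 0.04, prot2, rng
    )  # P-type with the P135 dialect

    F = ActivityProfile
    entries = [
        PanelEntry("Sl-ASAT2-like", "ASAT2", t2, F(True, False)),
        PanelEntry("Sp-ASAT2-like", "ASAT2", sp2, F(False, True)),
        PanelEntry("LA1777-ASAT2-like", "ASAT2", la1777, F(True, True)),
        PanelEntry("LA1926-ASAT2-like", "ASAT2", la1926, F(False, True)),
        PanelEntry(
            "Sl-ASAT2-like:C304G", "ASAT2",
            apply_mutations(t2, {304: "G"}), F(True, True),
        ),
        PanelEntry(
            "Sp-ASAT2-like:H135Q+C136Y", "ASAT2",
            apply_mutations(sp2, {135: "Q", 136: "Y"}), F(True, True),
        ),
        PanelEntry(
            "LA1926-ASAT2-like:P135Q+C136Y", "ASAT2",
            apply_mutations(la1926, {135: "Q", 136: "Y"}), F(True, True),
        ),
        PanelEntry("Sl-ASAT3-like", "ASAT3", t3, F(True, False)),
        PanelEntry("Sp-ASAT3-like", "ASAT3", sp3, F(False, True)),
        PanelEntry(
            "Sl-ASAT3-like:Y161H+C162S+T289V", "ASAT3",
            apply_mutations(t3, {161: "H", 162: "S", 289: "V"}), F(True, True),
        ),
        PanelEntry(
            "Sp-ASAT3-like:H161Y+S162C+V289T", "ASAT3",
            apply_mutations(sp3, {161: "Y", 162: "C", 289: "T"}), F(False, False),
        ),
        # V->L at the Val site and S->HP at the Ser site restore the F triad
        # (the fixture's deletion removed the residue after the Ser site).
        PanelEntry(
            "Sp-ASAT3-like:V353L+S380HP", "ASAT3",
            apply_mutations(sp3, {354: "L", 381: "HP"}), F(True, True),
        ),
    ]
    return entries


# -- variant generator ------------------------------------------------------

#: Planted diagnostic letters per (family, profile).
PROFILE_RESIDUES = {
    ("ASAT2", "F"): {135: "Q", 136: "Y", 304: "C"},
    ("ASAT2", "P"): {135: "H", 136: "C", 304: "G"},
    ("ASAT2", "hybrid"): {135: "Q", 136: "Y", 304: "G"},
    ("ASAT2", "dead"): {135: "H", 136: "C", 304: "C"},
    ("ASAT3", "F"): {161: "Y", 162: "C", 289: "T", 354: "L", 381: "H", 382: "P"},
    ("ASAT3", "P"): {161: "H", 162: "S", 289: "V", 354: "V", 381: "S", 382: "P"},
    ("ASAT3", "hybrid"): {161: "H", 162: "S", 289: "V", 354: "L", 381: "H", 382: "P"},
    ("ASAT3", "dead"): {161: "Y", 162: "C", 289: "T", 354: "V", 381: "S", 382: "P"},
}

_PROFILE_FLAGS = {
    "F": ActivityProfile(True, False),
    "P": ActivityProfile(False, True),
    "hybrid": ActivityProfile(True, True),
    "dead": ActivityProfile(False, False),
}


@dataclass(frozen=True)
class SequenceScenario:
    """A panel of seeded variant sequences with a planted activity profile."""

    family: str  # ASAT2 | ASAT3
    profile: str  # F | P | hybrid | dead
    background_rate: float = 0.05
    indel_near_381: bool = False  # ASAT3 only: delete the residue after the 381 site
    n_variants: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("ASAT2", "ASAT3"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.profile not in _PROFILE_FLAGS:
            raise ValueError(f"unknown profile {self.profile!r}")
        if not 0.0 <= self.background_rate <= 0.2:
            raise ValueError("background rate must be within [0, 0.2]")
        if self.indel_near_381 and self.family != "ASAT3":
            raise ValueError("the 381-region indel is an ASAT3 feature")


def generate_variants(sc: SequenceScenario) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Seeded variant sequences plus a truth table of expected profiles.

    Each variant is the family template with the profile's diagnostic
    letters planted, optional 381-region deletion, and background
    substitutions that never touch diagnostic sites.
    """
    rng = np.random.default_rng(sc.seed)
    template = _templates()[sc.family]
    planted = dict(PROFILE_RESIDUES[(sc.family, sc.profile)])
    if sc.indel_near_381:
        planted[382] = ""  # single-residue deletion adjacent to the 381 site
    base = apply_mutations(template, planted)
    protected = _protected_sites(sc.family)
    if sc.indel_near_381:
        protected = frozenset(p - (p > 382) for p in protected)
    expected = _PROFILE_FLAGS[sc.profile]
    variants = []
    rows = []
    for i in range(sc.n_variants):
        seq = _background(base, sc.background_rate, protected, rng)
        vid = f"{sc.family}-{sc.profile}-v{i:03d}"
        variants.append((vid, seq))
        rows.append(
            {
                "id": vid,
                "family": sc.family,
                "profile": sc.profile,
                "has_F": expected.has_F,
                "has_P": expected.has_P,
                "indel_near_381": sc.indel_near_381,
            }
        )
    return variants, pd.DataFrame(rows)


def variants_fasta(variants: Sequence[tuple[str, str]], family: str, plant: str = "plant1") -> str:
    return "".join(
        f">{plant}|{family}|{vid}\n{seq}\n" for vid, seq in variants
    )


# -- peak-list generator ----------------------------------------------------


@dataclass(frozen=True)
class SpectrumScenario:
    """A synthetic LC-MS peak list built from known metabolites.

    ``ppm_sigma`` is the Gaussian mass-error scale (ToF-like, proportional
    to m/z); decoys are uniform over ``mz_range``.
    """

    metabolites: tuple[tuple[AcylSucrose, float], ...]  # (structure, abundance)
    ppm_sigma: float = 2.0
    n_decoys: int = 20
    mz_range: tuple[float, float] = (100.0, 1000.0)
    polarity: str = "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0:
            raise ValueError("ppm sigma must be >= 0")
        if any(ab <= 0 for _, ab in self.metabolites):
            raise ValueError("abundances must be positive")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"bad polarity {self.polarity!r}")


# Relative intensities of the ion species of one metabolite, vs its abundance.
_ION_YIELD = {"M+formate": 1.0, "M-H": 0.3, "M+H": 1.0, "M+Na": 0.2, "fragment": 0.6}


def generate_peaklist(sc: SpectrumScenario) -> tuple[list[Peak], pd.DataFrame]:
    """Peaks plus a truth table mapping each peak to its source ion.

    Negative mode emits [M+formate]- and [M-H]- precursors and the
    carboxylate fragments; positive mode emits [M+H]+/[M+Na]+ and the
    glycosidic-cleavage ring fragments (placements required).
    """
    rng = np.random.default_rng(sc.seed)
    peaks: list[Peak] = []
    rows = []

    def emit(theo_mz: float, intensity: float, source: str, role: str, label: str):
        noisy = theo_mz * (1.0 + rng.normal(0.0, sc.ppm_sigma) * 1e-6)
        peaks.append(Peak(noisy, intensity, sc.polarity))
        rows.append(
            {
                "mz": noisy,
                "theoretical_mz": theo_mz,
                "intensity": intensity,
                "polarity": sc.polarity,
                "source": source,
                "role": role,
                "label": label,
            }
        )

    for metabolite, abundance in sc.metabolites:
        name = format_annotation(metabolite)
        f = molecular_formula(metabolite)
        adducts = ("M+formate", "M-H") if sc.polarity == "negative" else ("M+H", "M+Na")
        for ad in adducts:
            emit(adduct_mz(f, ad), abundance * _ION_YIELD[ad], name, "precursor", ad)
        for frag in predict_fragments(metabolite, sc.polarity):
            emit(
                frag.mz,
                abundance * _ION_YIELD["fragment"] * frag.multiplicity,
                name,
                "fragment",
                frag.label,
            )

    lo, hi = sc.mz_range
    median_intensity = float(np.median([p.intensity for p in peaks])) if peaks else 1.0
    for _ in range(sc.n_decoys):
        mz = float(rng.uniform(lo, hi))
        intensity = float(rng.uniform(0.01, 0.5) * median_intensity)
        peaks.append(Peak(mz, intensity, sc.polarity))
        rows.append(
            {
                "mz": mz,
                "theoretical_mz": np.nan,
                "intensity": intensity,
                "polarity": sc.polarity,
                "source": "decoy",
                "role": "decoy",
                "label": "decoy",
            }
        )
    return peaks, pd.DataFrame(rows)


# -- optional network utility (not used by any test) ------------------------


def fetch_genbank_proteins(accessions: Iterable[str], email: str = "user@example.org") -> dict[str, str]:
    """Fetch translated CDS proteins for GenBank nucleotide accessions.

    Network-dependent convenience for cross-checking the synthetic fixtures
    against the real deposited sequences; everything else in this package is
    offline.
    """
    from Bio import Entrez, SeqIO

    Entrez.email = email
    out: dict[str, str] = {}
    for acc in accessions:
        with Entrez.efetch(
            db="nuccore", id=acc, rettype="gb", retmode="text"
        ) as handle:
            rec = SeqIO.read(handle, "genbank")
        for feat in rec.features:
            if feat.type == "CDS" and "translation" in feat.qualifiers:
                out[acc] = feat.qualifiers["translation"][0]
                break
    return out
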