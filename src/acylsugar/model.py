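"""Structural model of acylsucroses and the S n:m nomenclature.

An acylsucrose is a sucrose backbone esterified with short- to medium-length
acyl chains on the hydroxyls of its two rings: the six-membered pyranose
(glucose) ring, positions R2/R3/R4/R6, and the five-membered furanose
(fructose) ring, primed positions R1'/R3'/R4'/R6' (spelled ``R1p`` ... in
machine-facing strings).  The field's shorthand ``S3:22 (5R2, 12R3, 5R4)``
reads: sucrose backbone, three acyl chains, 22 acyl carbons total, with a C5
chain at R2, a C12 at R3 and a C5 at R4.

Two structural classes recur in the tomato clade:

* **F-type** -- exactly one furanose-ring chain, at R3', plus at least one
  pyranose chain (cultivated tomato).
* **P-type** -- every chain on the pyranose ring, none on the furanose ring
  (S. pennellii and some S. habrochaites).

LC-MS cannot distinguish iso- from anteiso-branched chains of the same
length, so chain branching is a first-class "unspecified" value; only NMR
resolves it.
"""

from __future__ import annotations

import enum
import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


class Branching(enum.Enum):
    """Acyl-chain branching class: iso (i), anteiso (ai), straight (n)."""

    ISO = "i"
    ANTEISO = "ai"
    NORMAL = "n"
    UNSPECIFIED = "?"

    def __lt__(self, other: "Branching") -> bool:
        order = {"ai": 0, "i": 1, "n": 2, "?": 3}
        return order[self.value] < order[other.value]


class Ring(enum.Enum):
    PYRANOSE = "pyranose"
    FURANOSE = "furanose"


class RingPosition(enum.Enum):
    """The eight modeled acylation positions on sucrose.

    Primed (furanose) positions are spelled with a trailing ``p``; reports
    render them with a prime mark.
    """

    R2 = "R2"
    R3 = "R3"
    R4 = "R4"
    R6 = "R6"
    R1p = "R1p"
    R3p = "R3p"
    R4p = "R4p"
    R6p = "R6p"

    @property
    def ring(self) -> Ring:
        return Ring.FURANOSE if self.value.endswith("p") else Ring.PYRANOSE

    @property
    def pretty(self) -> str:
        """Rendering with a prime mark, e.g. R3p -> R3'."""
        return self.value[:-1] + "′" if self.value.endswith("p") else self.value


#: Canonical ordering: pyranose R2->R6, then furanose R1'->R6'.
POSITION_ORDER: tuple[RingPosition, ...] = (
    RingPosition.R2,
    RingPosition.R3,
    RingPosition.R4,
    RingPosition.R6,
    RingPosition.R1p,
    RingPosition.R3p,
    RingPosition.R4p,
    RingPosition.R6p,
)

_POSITION_RANK = {p: i for i, p in enumerate(POSITION_ORDER)}

PYRANOSE_POSITIONS = tuple(p for p in POSITION_ORDER if p.ring is Ring.PYRANOSE)
FURANOSE_POSITIONS = tuple(p for p in POSITION_ORDER if p.ring is Ring.FURANOSE)

#: Structural upper bound: one chain per modeled hydroxyl.
MAX_CHAINS = 8


class NomenclatureError(ValueError):
    """Raised when an annotation string is malformed or self-inconsistent."""


@dataclass(frozen=True, order=True)
class AcylChain:
    """An acyl chain: carbon count and branching class.

    ``iC5`` is 3-methylbutanoyl, ``aiC5`` 2-methylbutanoyl, ``nC12``
    dodecanoyl, ``C2`` acetyl.  Branching is structurally meaningful only for
    chains of four or more carbons; acetyl is unbranched by definition.
    """

    carbons: int
    branching: Branching = Branching.UNSPECIFIED

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.branching in (Branching.ISO, Branching.ANTEISO) and self.carbons < 4:
            raise ValueError(
                f"{self.branching.value}-branching requires >= 4 carbons, got C{self.carbons}"
            )

    @property
    def token(self) -> str:
        """Nomenclature token: ``iC5``, ``aiC5``, ``nC12``; bare digits when unspecified."""
        if self.branching is Branching.UNSPECIFIED:
            return str(self.carbons)
        return f"{self.branching.value}C{self.carbons}"


class SugarType(enum.Enum):
    F = "F"
    P = "P"
    OTHER = "other"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class AcylSucrose:
    """A (possibly partially characterized) acylsucrose.

    Either ``placements`` assigns chains to ring positions (NMR-grade
    knowledge), or ``composition_only`` lists chain carbon counts without
    positions (negative-mode MS-grade knowledge).  A bare ``S k:m`` with
    neither is representable via ``declared`` counts alone.
    """

    placements: tuple[tuple[RingPosition, AcylChain], ...] = ()
    composition_only: tuple[int, ...] | None = None
    #: (chain count, total carbons) for bare annotations; redundant otherwise.
    declared: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seen = [p for p, _ in self.placements]
        if len(seen) != len(set(seen)):
            raise ValueError("at most one chain per ring position")
        canonical = tuple(
            sorted(self.placements, key=lambda pc: _POSITION_RANK[pc[0]])
        )
        object.__setattr__(self, "placements", canonical)
        if self.composition_only is not None:
            comp = tuple(sorted(self.composition_only))
            object.__setattr__(self, "composition_only", comp)
            if self.placements and comp != tuple(
                sorted(c.carbons for _, c in self.placements)
            ):
                raise ValueError(
                    "composition_only disagrees with the placed chains"
                )
        if self.n_chains > MAX_CHAINS:
            raise ValueError(f"more than {MAX_CHAINS} chains is not representable")
        if self.declared is not None:
            k, m = self.declared
            if self.placements or self.composition_only is not None:
                if (self.n_chains, self.total_carbons) != (k, m):
                    raise ValueError(
                        f"declared S{k}:{m} disagrees with listed chains "
                        f"(S{self.n_chains}:{self.total_carbons})"
                    )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_placements(
        cls, placements: Mapping[RingPosition, AcylChain]
    ) -> "AcylSucrose":
        return cls(placements=tuple(placements.items()))

    @classmethod
    def from_composition(cls, carbons: Iterable[int]) -> "AcylSucrose":
        return cls(composition_only=tuple(sorted(carbons)))

    @classmethod
    def sucrose(cls) -> "AcylSucrose":
        """The unacylated backbone."""
        return cls(composition_only=())

    # -- derived quantities -------------------------------------------------

    @property
    def placement_map(self) -> dict[RingPosition, AcylChain]:
        return dict(self.placements)

    @property
    def n_chains(self) -> int:
        if self.placements:
            return len(self.placements)
        if self.composition_only is not None:
            return len(self.composition_only)
        if self.declared is not None:
            return self.declared[0]
        raise ValueError("chain count unknown")

    @property
    def total_carbons(self) -> int:
        if self.placements:
            return sum(c.carbons for _, c in self.placements)
        if self.composition_only is not None:
            return sum(self.composition_only)
        if self.declared is not None:
            return self.declared[1]
        raise ValueError("total acyl carbons unknown")

    @property
    def composition(self) -> Counter:
        """Multiset of chain carbon counts (requires placements or composition)."""
        if self.placements:
            return Counter(c.carbons for _, c in self.placements)
        if self.composition_only is not None:
            return Counter(self.composition_only)
        raise ValueError("composition unknown for bare annotation")

    def chains_on(self, ring: Ring) -> tuple[AcylChain, ...]:
        return tuple(c for p, c in self.placements if p.ring is ring)

    def with_chain(self, position: RingPosition, chain: AcylChain) -> "AcylSucrose":
        """A copy with one more chain; errors if the position is occupied."""
        if position in self.placement_map:
            raise ValueError(f"position {position.value} already acylated")
        return AcylSucrose(placements=self.placements + ((position, chain),))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {}
        if self.placements:
            d["placements"] = {
                p.value: {"carbons": c.carbons, "branching": c.branching.value}
                for p, c in self.placements
            }
        if self.composition_only is not None:
            d["composition"] = list(self.composition_only)
        if self.declared is not None and not self.placements and self.composition_only is None:
            d["declared"] = list(self.declared)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcylSucrose":
        placements = tuple(
            (RingPosition(p), AcylChain(v["carbons"], Branching(v["branching"])))
            for p, v in d.get("placements", {}).items()
        )
        comp = d.get("composition")
        declared = d.get("declared")
        return cls(
            placements=placements,
            composition_only=tuple(comp) if comp is not None else None,
            declared=tuple(declared) if declared is not None else None,
        )

    def __str__(self) -> str:
        return format_annotation(self)


def classify_type(s: AcylSucrose) -> SugarType:
    """F/P classification from placements; composition alone is unclassifiable.

    F: exactly one furanose chain, at R3', plus >= 1 pyranose chain.
    P: >= 1 chain, all on the pyranose ring.
    """
    if not s.placements:
        return SugarType.UNCLASSIFIABLE
    pmap = s.placement_map
    furanose = [p for p in pmap if p.ring is Ring.FURANOSE]
    pyranose = [p for p in pmap if p.ring is Ring.PYRANOSE]
    if not furanose and pyranose:
        return SugarType.P
    if furanose == [RingPosition.R3p] and pyranose:
        return SugarType.F
    return SugarType.OTHER


# -- nomenclature ----------------------------------------------------------

_HEAD_RE = re.compile(
    r"^\s*S(?P<k>\d+):(?P<m>\d+)\s*(?:\((?P<chains>[^)]*)\))?\s*(?:-(?P<type>[FP]))?\s*$"
)
_CHAIN_RE = re.compile(
    r"^(?P<br>ai|i|n)?C?(?P<c>\d+)(?P<pos>R(?:[2346]p?|1p))?$"
)


def _parse_chain_token(tok: str) -> tuple[AcylChain, RingPosition | None]:
    m = _CHAIN_RE.match(tok.strip())
    if not m:
        raise NomenclatureError(f"unrecognized chain token {tok!r}")
    branching = Branching(m.group("br")) if m.group("br") else Branching.UNSPECIFIED
    try:
        chain = AcylChain(int(m.group("c")), branching)
    except ValueError as e:
        raise NomenclatureError(str(e)) from e
    pos = None
    if m.group("pos"):
        try:
            pos = RingPosition(m.group("pos"))
        except ValueError as e:
            raise NomenclatureError(f"unknown position token in {tok!r}") from e
    return chain, pos


def parse_annotation(text: str) -> AcylSucrose:
    """Parse ``S<k>:<m>`` nomenclature, e.g. ``S3:22 (5R2, 12R3, 5R4)-P``.

    The chain list is optional; chain tokens optionally carry a branching
    prefix (``iC5``, ``aiC5``, ``nC12``) and a position suffix.  The chain
    count and carbon total are cross-checked against the listed chains, and a
    trailing ``-F``/``-P`` is cross-checked against the placed structure.
    """
    m = _HEAD_RE.match(text)
    if not m:
        raise NomenclatureError(f"cannot parse annotation {text!r}")
    k, total = int(m.group("k")), int(m.group("m"))
    suffix = m.group("type")

    if m.group("chains") is None:
        if k == 0 and total == 0:
            return AcylSucrose.sucrose()
        return AcylSucrose(declared=(k, total))

    tokens = [t for t in m.group("chains").split(",") if t.strip()]
    parsed = [_parse_chain_token(t) for t in tokens]
    if len(parsed) != k:
        raise NomenclatureError(
            f"{text!r}: header declares {k} chains but {len(parsed)} listed"
        )
    carbons = sum(c.carbons for c, _ in parsed)
    if carbons != total:
        raise NomenclatureError(
            f"{text!r}: header declares {total} acyl carbons but chains sum to {carbons}"
        )

    with_pos = [pc for pc in parsed if pc[1] is not None]
    if with_pos and len(with_pos) != len(parsed):
        raise NomenclatureError(
            f"{text!r}: mix of positional and position-free chain tokens"
        )
    if with_pos:
        s = AcylSucrose(placements=tuple((p, c) for c, p in with_pos))
        if suffix is not None and classify_type(s).value != suffix:
            raise NomenclatureError(
                f"{text!r}: -{suffix} suffix contradicts placements "
                f"(classified {classify_type(s).value})"
            )
        return s
    return AcylSucrose.from_composition(c.carbons for c, _ in parsed)


def format_annotation(s: AcylSucrose) -> str:
    """Canonical nomenclature string; inverse of :func:`parse_annotation`.

    Placed chains are listed pyranose R2->R6 then furanose R1'->R6';
    composition-only chains ascending.  A ``-F``/``-P`` suffix is appended for
    classified structures with two or more chains (the paper's convention:
    mono-acylsucroses are written bare).
    """
    head = f"S{s.n_chains}:{s.total_carbons}"
    if s.placements:
        body = ", ".join(f"{c.token}{p.value}" for p, c in s.placements)
        out = f"{head} ({body})"
        cls = classify_type(s)
        if s.n_chains >= 2 and cls in (SugarType.F, SugarType.P):
            out += f"-{cls.value}"
        return out
    if s.composition_only is not None:
        if not s.composition_only:
            return head  # plain sucrose, S0:0
        body = ", ".join(str(c) for c in s.composition_only)
        return f"{head} ({body})"
    return head


def enumerate_isomers(
    s: AcylSucrose,
    allowed_branchings: Mapping[int, Sequence[Branching]],
) -> list[AcylSucrose]:
    """All completions of unspecified-branching chains.

    Each placed chain with unspecified branching is substituted by every
    allowed branching for its carbon count (e.g. C5 in {iso, anteiso}, since
    LC-MS cannot tell them apart).  Output order is the lexicographic product
    over positions in canonical order, branchings sorted ai < i < n.
    """
    if not s.placements:
        raise ValueError("enumerate_isomers requires placements")
    option_lists: list[list[tuple[RingPosition, AcylChain]]] = []
    for pos, chain in s.placements:
        if chain.branching is not Branching.UNSPECIFIED:
            option_lists.append([(pos, chain)])
            continue
        allowed = allowed_branchings.get(chain.carbons)
        if not allowed:
            raise ValueError(
                f"no allowed branchings configured for C{chain.carbons}"
            )
        opts = [
            (pos, AcylChain(chain.carbons, b))
            for b in sorted(set(allowed))
        ]
        option_lists.append(opts)
    return [
        AcylSucrose(placements=tuple(combo))
        for combo in itertools.product(*option_lists)
    ]
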