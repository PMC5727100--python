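"""Rule-based simulator of F- and P-type acylsucrose biosynthesis.

Each trichome ASAT (acylsucrose acyltransferase, a BAHD-family enzyme) is
modeled as a rewrite rule: an occupancy pattern over ring positions that the
acceptor must satisfy, a product position that receives the new chain, and a
set of acyl-CoA donors the enzyme accepts.  Biosynthesis is then the
breadth-first closure from sucrose under all (rule, donor) applications.

The central result this engine expresses: cultivated tomato (S. lycopersicum)
builds F-type acylsucroses in the order R4 (ASAT1) -> R3 (ASAT2-F) -> R3'
(ASAT3-F), while S. pennellii runs a *flipped* pathway R4 (ASAT1) -> R2
(ASAT3-P) -> R3 (ASAT2-P), producing P-type acylsucroses with all chains on
the pyranose ring.  The reaction-order reversal is emergent from the
occupancy patterns, not hard-coded.

No kinetics: the study reports no rate constants, so donor preference is a
set, and relative product abundance is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    AcylChain,
    AcylSucrose,
    Branching,
    FURANOSE_POSITIONS,
    RingPosition,
    SugarType,
    classify_type,
    format_annotation,
)

# Canonical acyl-CoA donors.
iC5 = AcylChain(5, Branching.ISO)
aiC5 = AcylChain(5, Branching.ANTEISO)
nC12 = AcylChain(12, Branching.NORMAL)
C2 = AcylChain(2, Branching.NORMAL)

DEFAULT_DONORS = frozenset({iC5, aiC5, nC12})


class DonorNotAllowedError(ValueError):
    """The donor is outside the rule's allowed set (distinct from no-match)."""


@dataclass(frozen=True)
class EnzymeRule:
    """One ASAT activity as an acceptor-pattern -> product-position rewrite.

    ``required_occupied`` positions must carry a chain and ``required_free``
    must not; with ``exact`` the occupied set must equal ``required_occupied``
    exactly.  Matching is defined only for fully placed structures.
    """

    name: str
    required_occupied: frozenset[RingPosition]
    required_free: frozenset[RingPosition]
    product_position: RingPosition
    allowed_donors: frozenset[AcylChain]
    exact: bool = False

    def __post_init__(self) -> None:
        if self.product_position in self.required_occupied:
            raise ValueError("product position cannot be required occupied")

    def matches(self, substrate: AcylSucrose) -> bool:
        if substrate.n_chains and not substrate.placements:
            return False  # composition-only: positions unknown, nothing to match
        occupied = set(substrate.placement_map)
        if self.exact:
            if occupied != set(self.required_occupied):
                return False
        else:
            if not self.required_occupied <= occupied:
                return False
        if occupied & self.required_free:
            return False
        return self.product_position not in occupied

    def apply(self, substrate: AcylSucrose, donor: AcylChain) -> AcylSucrose | None:
        """Product acylsucrose, or None when the acceptor pattern fails."""
        if donor not in self.allowed_donors:
            raise DonorNotAllowedError(
                f"{self.name} does not accept {donor.token}-CoA"
            )
        if not self.matches(substrate):
            return None
        return substrate.with_chain(self.product_position, donor)


def apply_enzyme(
    rule: EnzymeRule, substrate: AcylSucrose, donor: AcylChain
) -> AcylSucrose | None:
    return rule.apply(substrate, donor)


def builtin_rules() -> dict[str, EnzymeRule]:
    """The six canonical ASAT activities of the tomato clade.

    * ASAT1: sucrose -> R4 (short branched C5 donors).
    * ASAT2-F: monoacyl S1:5 (R4) -> R3; R2 must be free, so ASAT4-acetylated
      or R2-acylated substrates are rejected -- the R2-acylated diacyl made
      by ASAT3-P is not an acceptor for any cultivated-tomato enzyme.
    * ASAT3-F: diacyl with R3+R4 -> R3' on the furanose ring; likewise
      requires R2 free.
    * ASAT3-P: monoacyl S1:5 only -> R2 (short donors; long chains are never
      seen at R2).
    * ASAT2-P: diacyl with R2+R4 -> R3.
    * ASAT4: F-type acceptor (R3' occupied) -> R2 acetylation, acetyl-CoA only.
    """
    R = RingPosition
    fur = frozenset(FURANOSE_POSITIONS)
    rules = [
        EnzymeRule(
            "ASAT1",
            required_occupied=frozenset(),
            required_free=frozenset(),
            product_position=R.R4,
            allowed_donors=frozenset({iC5, aiC5}),
            exact=True,
        ),
        EnzymeRule(
            "ASAT2-F",
            required_occupied=frozenset({R.R4}),
            required_free=frozenset({R.R2, R.R3}),
            product_position=R.R3,
            allowed_donors=frozenset({iC5, aiC5, nC12}),
        ),
        EnzymeRule(
            "ASAT3-F",
            required_occupied=frozenset({R.R3, R.R4}),
            required_free=frozenset({R.R2}) | fur,
            product_position=R.R3p,
            allowed_donors=frozenset({iC5, aiC5, nC12}),
        ),
        EnzymeRule(
            "ASAT3-P",
            required_occupied=frozenset({R.R4}),
            required_free=frozenset(),
            product_position=R.R2,
            allowed_donors=frozenset({iC5, aiC5}),
            exact=True,
        ),
        EnzymeRule(
            "ASAT2-P",
            required_occupied=frozenset({R.R2, R.R4}),
            required_free=frozenset({R.R3}),
            product_position=R.R3,
            allowed_donors=frozenset({iC5, aiC5, nC12}),
        ),
        EnzymeRule(
            "ASAT4",
            required_occupied=frozenset({R.R3p}),
            required_free=frozenset({R.R2}),
            product_position=R.R2,
            allowed_donors=frozenset({C2}),
        ),
    ]
    return {r.name: r for r in rules}


def rules_by_name(names: Iterable[str]) -> list[EnzymeRule]:
    table = builtin_rules()
    out = []
    for n in names:
        if n not in table:
            raise KeyError(f"unknown enzyme rule {n!r}; known: {sorted(table)}")
        out.append(table[n])
    return out


@dataclass(frozen=True)
class ActivityProfile:
    """Per-enzyme F/P capability; both true = hybrid, both false = dead."""

    has_F: bool = False
    has_P: bool = False

    @property
    def hybrid(self) -> bool:
        return self.has_F and self.has_P

    @property
    def dead(self) -> bool:
        return not (self.has_F or self.has_P)


@dataclass(frozen=True)
class Edge:
    """Provenance of one biosynthetic step."""

    substrate: AcylSucrose
    rule: str
    donor: AcylChain
    product: AcylSucrose


def _state_key(s: AcylSucrose) -> tuple:
    return (s.n_chains, format_annotation(s))


@dataclass
class SimulationResult:
    reachable: tuple[AcylSucrose, ...]
    terminal: tuple[AcylSucrose, ...]
    dead_ends: tuple[AcylSucrose, ...]
    edges: tuple[Edge, ...]
    phenotype_call: frozenset[SugarType]

    @property
    def products(self) -> tuple[AcylSucrose, ...]:
        """Terminal states expected to accumulate (terminals minus dead ends)."""
        dead = set(self.dead_ends)
        return tuple(t for t in self.terminal if t not in dead)

    def states_frame(self) -> pd.DataFrame:
        dead = set(self.dead_ends)
        term = set(self.terminal)
        return pd.DataFrame(
            {
                "acylsucrose": [format_annotation(s) for s in self.reachable],
                "n_chains": [s.n_chains for s in self.reachable],
                "type": [classify_type(s).value for s in self.reachable],
                "terminal": [s in term for s in self.reachable],
                "dead_end": [s in dead for s in self.reachable],
            }
        )

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substrate": [format_annotation(e.substrate) for e in self.edges],
                "rule": [e.rule for e in self.edges],
                "donor": [e.donor.token for e in self.edges],
                "product": [format_annotation(e.product) for e in self.edges],
            }
        )


class StateSpaceError(RuntimeError):
    pass


def simulate(
    enzymes: Sequence[EnzymeRule],
    donors: Iterable[AcylChain],
    max_steps: int = 6,
    max_states: int = 20000,
) -> SimulationResult:
    """Breadth-first closure from sucrose over all (rule, donor) applications.

    Terminal states have no applicable move.  Terminal mono- and
    di-acylsucroses are flagged as dead ends subject to in-planta
    degradation (acylsucrose hydrolases; silenced-pathway intermediates do
    not accumulate), so the phenotype call is read off the remaining F/P
    terminals.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    donor_set = frozenset(donors)
    seed = AcylSucrose.sucrose()
    reachable: set[AcylSucrose] = {seed}
    edges: list[Edge] = []
    frontier = [seed]
    for _ in range(max_steps):
        next_frontier: list[AcylSucrose] = []
        for state in sorted(frontier, key=_state_key):
            for rule in enzymes:
                for donor in sorted(rule.allowed_donors & donor_set):
                    product = rule.apply(state, donor)
                    if product is None:
                        continue
                    edges.append(Edge(state, rule.name, donor, product))
                    if product not in reachable:
                        reachable.add(product)
                        next_frontier.append(product)
                        if len(reachable) > max_states:
                            raise StateSpaceError(
                                f"state space exceeded {max_states} states"
                            )
        if not next_frontier:
            break
        frontier = next_frontier

    def has_move(state: AcylSucrose) -> bool:
        return any(
            rule.matches(state) and rule.allowed_donors & donor_set
            for rule in enzymes
        )

    ordered = tuple(sorted(reachable, key=_state_key))
    terminal = tuple(s for s in ordered if not has_move(s))
    dead_ends = tuple(s for s in terminal if 1 <= s.n_chains <= 2)
    dead = set(dead_ends)
    phenotype = frozenset(
        t
        for s in terminal
        if s not in dead and s.n_chains
        for t in [classify_type(s)]
        if t in (SugarType.F, SugarType.P)
    )
    return SimulationResult(ordered, terminal, dead_ends, tuple(edges), phenotype)


# Enzyme complements of the two parental pathways.
SL_ENZYMES = ("ASAT1", "ASAT2-F", "ASAT3-F")
SP_ENZYMES = ("ASAT1", "ASAT3-P", "ASAT2-P")


def phenotype_from_profiles(
    asat2: ActivityProfile,
    asat3: ActivityProfile,
    donors: Iterable[AcylChain] = DEFAULT_DONORS,
    max_steps: int = 6,
) -> SimulationResult:
    """Chemotype implied by ASAT2/ASAT3 capability profiles.

    Builds the enzyme complement (ASAT1 plus the F and/or P rule for each
    capable enzyme) and simulates.  The phenotype set is in
    ``result.phenotype_call``; dead-end intermediates (e.g. the F-type
    diacyl in a hybrid-ASAT2 x P-only-ASAT3 plant) are flagged in
    ``result.dead_ends``.
    """
    names = ["ASAT1"]
    if asat2.has_F:
        names.append("ASAT2-F")
    if asat2.has_P:
        names.append("ASAT2-P")
    if asat3.has_F:
        names.append("ASAT3-F")
    if asat3.has_P:
        names.append("ASAT3-P")
    return simulate(rules_by_name(names), donors, max_steps=max_steps)


def load_scenario(config: Mapping) -> tuple[list[EnzymeRule], frozenset[AcylChain], int]:
    """Parse a scenario config: enzyme names, donor tokens, optional max_steps.

    Donor tokens use chain-token syntax (``iC5``, ``aiC5``, ``nC12``, ``nC2``
    or ``C2``).
    """
    from .model import _parse_chain_token  # same grammar as nomenclature chains

    enzymes = rules_by_name(config["enzymes"])
    donors = []
    for tok in config["donors"]:
        chain, pos = _parse_chain_token(tok)
        if pos is not None:
            raise ValueError(f"donor token {tok!r} must not carry a position")
        if chain.branching is Branching.UNSPECIFIED:
            chain = AcylChain(chain.carbons, Branching.NORMAL)
        donors.append(chain)
    return enzymes, frozenset(donors), int(config.get("max_steps", 6))
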