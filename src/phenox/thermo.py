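"""Redox bookkeeping for extracellular electron shuttles.

Phenazines such as phenazine-1-carboxylic acid (PCA) and pyocyanin (PYO)
are two-electron, two-proton redox couples.  Whether a membrane quinone or
a respirable terminal electron acceptor (TEA) can oxidize the reduced
phenazine is, to first order, a question of midpoint potentials: coupling
the oxidation of a more negative couple to the reduction of a more
positive one is favorable at standard conditions.

This module holds the electron tower (a table of half-reactions ordered by
midpoint potential), pairwise reaction potentials and free energies, a
Nernst correction for non-standard pH and redox poise, and two screens:

* :func:`favorable_acceptors` — the purely thermodynamic screen: every
  couple in the tower that sits below (more positive than) the donor.
* :func:`respiratory_drive_screen` — the mechanistic screen for terminal
  electron acceptors: a TEA drives phenazine oxidation through the
  electron transport chain only if some quinone species is both able to
  oxidize the phenazine (thermodynamics) and able to deliver electrons to
  that TEA's reductase (quinone-reductase specificity), and the quinol ->
  TEA step is itself downhill.  This is what distinguishes, e.g., fumarate
  as a driver of PCA oxidation (via menaquinone) from fumarate as a
  non-driver of PYO oxidation (menaquinone is too negative to oxidize PYO
  and the fumarate reductase does not engage ubiquinone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

#: Faraday constant, C per mol of electrons.
FARADAY = 96485.33212
#: Molar gas constant, J / (mol K).
GAS_CONSTANT = 8.314462618


class UnknownCoupleError(KeyError):
    """Raised when a half-reaction name is not present in a table."""


@dataclass(frozen=True)
class HalfReaction:
    """A redox couple: ``oxidized + n_e e- + n_p H+ -> reduced``.

    ``E0_prime`` is the midpoint potential in volts vs. the standard
    hydrogen electrode at the table's reference pH (7 by default).
    """

    name: str
    E0_prime: float
    n_electrons: int = 2
    n_protons: int = 2
    oxidized_label: str = ""
    reduced_label: str = ""

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError(f"{self.name}: n_electrons must be >= 1")
        if self.n_protons < 0:
            raise ValueError(f"{self.name}: n_protons must be >= 0")
        if not math.isfinite(self.E0_prime) or abs(self.E0_prime) >= 2.0:
            raise ValueError(
                f"{self.name}: midpoint potential {self.E0_prime!r} V is not "
                "a plausible biological value (must be finite, |E| < 2 V)"
            )


@dataclass
class PotentialTable:
    """An ordered electron tower of uniquely named half-reactions."""

    reactions: list[HalfReaction] = field(default_factory=list)
    temperature_K: float = 298.15
    reference_pH: float = 7.0

    def __post_init__(self) -> None:
        names = [hr.name for hr in self.reactions]
        if len(set(names)) != len(names):
            raise ValueError("half-reaction names must be unique")

    def __iter__(self):
        return iter(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, name: str) -> bool:
        return any(hr.name == name for hr in self.reactions)

    def get(self, name: str) -> HalfReaction:
        for hr in self.reactions:
            if hr.name == name:
                return hr
        raise UnknownCoupleError(name)

    def names(self) -> list[str]:
        return [hr.name for hr in self.reactions]

    def ordered(self) -> list[HalfReaction]:
        """Couples sorted from most negative (top of tower) down."""
        return sorted(self.reactions, key=lambda hr: hr.E0_prime)

    @classmethod
    def from_records(cls, records: Iterable[Mapping], **meta) -> "PotentialTable":
        return cls([HalfReaction(**dict(r)) for r in records], **meta)

    @classmethod
    def from_yaml(cls, path) -> "PotentialTable":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_records(
            raw["half_reactions"],
            temperature_K=float(raw.get("temperature_K", 298.15)),
            reference_pH=float(raw.get("reference_pH", 7.0)),
        )


def default_table() -> PotentialTable:
    """The shipped electron tower (literature midpoint potentials)."""
    source = resources.files("phenox.data").joinpath("potentials.yaml")
    raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    return PotentialTable.from_records(
        raw["half_reactions"],
        temperature_K=float(raw["temperature_K"]),
        reference_pH=float(raw["reference_pH"]),
    )


def reaction_potential(donor: HalfReaction, acceptor: HalfReaction) -> float:
    """Standard-state potential (V) of coupling donor oxidation to acceptor
    reduction.  Positive means favorable."""
    return acceptor.E0_prime - donor.E0_prime


def gibbs_free_energy(delta_E: float, n_electrons: int) -> float:
    """Standard free energy (J/mol) of an n-electron transfer across
    ``delta_E`` volts: dG = -n F dE."""
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    return -n_electrons * FARADAY * delta_E


def nernst_adjust(
    hr: HalfReaction,
    pH: float = 7.0,
    ratio_red_over_ox: float = 1.0,
    temperature_K: float = 298.15,
) -> float:
    """Midpoint potential corrected for pH and redox poise.

    E = E0' - (ln10 R T n_p / (n_e F)) (pH - 7)
          - (R T / (n_e F)) ln([red]/[ox])

    At pH 7 and a 1:1 redox ratio this returns ``E0_prime`` exactly.
    """
    if ratio_red_over_ox <= 0:
        raise ValueError("ratio_red_over_ox must be positive")
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    rt_over_f = GAS_CONSTANT * temperature_K / FARADAY
    ph_term = math.log(10.0) * rt_over_f * hr.n_protons / hr.n_electrons * (pH - 7.0)
    poise_term = rt_over_f / hr.n_electrons * math.log(ratio_red_over_ox)
    return hr.E0_prime - ph_term - poise_term


def favorable_acceptors(
    table: PotentialTable, donor_name: str
) -> list[tuple[HalfReaction, float]]:
    """All couples that can oxidize the donor at standard conditions.

    Returns ``(acceptor, delta_E)`` pairs with ``delta_E > 0``, sorted by
    descending driving force.  Ties at exactly zero are treated as
    unfavorable.  The donor itself is excluded.
    """
    donor = table.get(donor_name)
    hits = [
        (hr, reaction_potential(donor, hr))
        for hr in table.reactions
        if hr.name != donor_name and reaction_potential(donor, hr) > 0.0
    ]
    hits.sort(key=lambda pair: -pair[1])
    return hits


#: Which quinone species can deliver electrons to each terminal electron
#: acceptor's reductase(s).  Nitrate reductases collectively accept all
#: three quinones; the fumarate, DMSO and TMAO reductases engage only the
#: (demethyl)menaquinones.
DEFAULT_TEA_QUINONE_ACCESS: dict[str, tuple[str, ...]] = {
    "nitrate": ("ubiquinone", "menaquinone", "demethylmenaquinone"),
    "fumarate": ("menaquinone", "demethylmenaquinone"),
    "DMSO": ("menaquinone", "demethylmenaquinone"),
    "TMAO": ("menaquinone", "demethylmenaquinone"),
}


@dataclass(frozen=True)
class DriveVerdict:
    """Outcome of the mechanistic screen for one terminal acceptor."""

    acceptor: str
    can_drive: bool
    routes: tuple[str, ...]  # quinones that carry a fully downhill route


def respiratory_drive_screen(
    table: PotentialTable,
    donor_name: str,
    quinone_access: Mapping[str, tuple[str, ...]] | None = None,
) -> list[DriveVerdict]:
    """Which terminal electron acceptors can drive phenazine oxidation
    through the electron transport chain.

    A TEA qualifies if some quinone q satisfies all three conditions:
    donor -> q is thermodynamically favorable, q -> TEA is favorable, and
    q is accepted by that TEA's reductase.
    """
    access = dict(DEFAULT_TEA_QUINONE_ACCESS if quinone_access is None else quinone_access)
    donor = table.get(donor_name)
    verdicts = []
    for tea_name, quinones in access.items():
        tea = table.get(tea_name)
        routes = tuple(
            q
            for q in quinones
            if q in table
            and reaction_potential(donor, table.get(q)) > 0.0
            and reaction_potential(table.get(q), tea) > 0.0
        )
        verdicts.append(DriveVerdict(tea_name, bool(routes), routes))
    return verdicts
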