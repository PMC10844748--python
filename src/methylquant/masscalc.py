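"""Monoisotopic mass and m/z computation for modified peptides.

Targeted (PRM) quantification of lysine-methylation stoichiometry starts
from theoretical precursor and fragment m/z values for a peptide in each
of its methylation states (me0..me3).  This module owns that arithmetic:
residue-level monoisotopic masses, site-resolved modification deltas,
precursor m/z at arbitrary charge, b/a/y fragment ions (with optional
H3PO4 neutral loss for phosphopeptides), and generation of the four-state
PRM isolation series for a methylatable lysine.

All masses are monoisotopic, in daltons; m/z values are kept at full
precision internally and rounded to two decimals only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ResidueMassTable",
    "ModifiedPeptide",
    "PrmTarget",
    "DEFAULT_TABLE",
    "monoisotopic_mass",
    "mz",
    "prm_series",
    "fragment_mz",
    "parse_mods",
]

# Monoisotopic residue (amino-acid minus water) masses, Da.
_RESIDUE_MASSES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276
CO = 27.994915  # b -> a ion loss
H3PO4 = 97.976896  # phosphate neutral loss

_MOD_DELTAS = {
    "methyl": 14.01565,
    "dimethyl": 28.03130,
    "trimethyl": 42.04695,
    "phospho": 79.96633,
    "carbamidomethyl": 57.02146,
    "acetyl": 42.01057,
    "oxidation": 15.99491,
}

# Short codes used in text mod specs like "K13:me2" or "S10:ph".
_SHORT_CODES = {
    "me1": "methyl",
    "me2": "dimethyl",
    "me3": "trimethyl",
    "ph": "phospho",
    "cam": "carbamidomethyl",
    "ac": "acetyl",
    "ox": "oxidation",
}

_METHYL_CLASS = ("methyl", "dimethyl", "trimethyl")

STATE_LABELS = ("me0", "me1", "me2", "me3")
_STATE_TO_MOD = {"me0": None, "me1": "methyl", "me2": "dimethyl", "me3": "trimethyl"}


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus modification deltas.

    The default instance covers the 20 standard residues and the
    modifications needed for methylation-stoichiometry work; a permissive
    caller may supply extra residue masses (e.g. selenocysteine).
    """

    residue_masses: dict = field(default_factory=lambda: dict(_RESIDUE_MASSES))
    water_mass: float = WATER
    proton_mass: float = PROTON
    mod_deltas: dict = field(default_factory=lambda: dict(_MOD_DELTAS))

    def residue(self, code: str) -> float:
        try:
            return self.residue_masses[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None

    def delta(self, mod_name: str) -> float:
        try:
            return self.mod_deltas[mod_name]
        except KeyError:
            raise KeyError(f"unknown modification {mod_name!r}") from None


DEFAULT_TABLE = ResidueMassTable()


def parse_mods(spec: str) -> list[tuple[int, str]]:
    """Parse a mod string like ``"K13:me2,S10:ph"`` into [(13, 'dimethyl'), ...].

    The leading residue letter is optional documentation; the 1-based
    position and the short code after the colon carry the information.
    """
    mods: list[tuple[int, str]] = []
    spec = spec.strip()
    if not spec:
        return mods
    for token in spec.split(","):
        token = token.strip()
        site, _, code = token.partition(":")
        if not code:
            raise ValueError(f"malformed modification token {token!r}")
        digits = "".join(ch for ch in site if ch.isdigit())
        if not digits:
            raise ValueError(f"no position in modification token {token!r}")
        name = _SHORT_CODES.get(code, code)
        mods.append((int(digits), name))
    return mods


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with site-resolved modifications and a charge.

    ``mods`` is a list of (1-based position, modification name) pairs.
    By default methyl-class modifications are only accepted on lysine and
    phospho only on serine/threonine; ``permissive=True`` disables the
    residue-compatibility check (not the bounds checks).
    """

    sequence: str
    mods: tuple = ()
    charge: int = 1
    permissive: bool = False

    def __init__(self, sequence, mods=(), charge=1, permissive=False, table=None):
        if isinstance(mods, str):
            mods = parse_mods(mods)
        object.__setattr__(self, "sequence", str(sequence))
        object.__setattr__(self, "mods", tuple((int(p), str(m)) for p, m in mods))
        object.__setattr__(self, "charge", int(charge))
        object.__setattr__(self, "permissive", bool(permissive))
        self._validate(table or DEFAULT_TABLE)

    def _validate(self, table: ResidueMassTable) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        for code in self.sequence:
            if code not in table.residue_masses:
                raise KeyError(f"unknown residue code {code!r}")
        methylated: set[int] = set()
        for pos, name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside [1, {len(self.sequence)}]"
                )
            table.delta(name)  # raises on unknown modification
            residue = self.sequence[pos - 1]
            if name in _METHYL_CLASS:
                if pos in methylated:
                    raise ValueError(
                        f"more than one methyl-class modification at position {pos}"
                    )
                methylated.add(pos)
                if residue != "K" and not self.permissive:
                    raise ValueError(
                        f"methyl-class modification on {residue}{pos}; only K allowed"
                    )
            elif name == "phospho" and residue not in "ST" and not self.permissive:
                raise ValueError(
                    f"phospho on {residue}{pos}; only S/T allowed"
                )

    def with_charge(self, charge: int) -> "ModifiedPeptide":
        return ModifiedPeptide(self.sequence, self.mods, charge, self.permissive)


@dataclass(frozen=True)
class PrmTarget:
    """One PRM isolation-list entry: a peptide species and its precursor m/z."""

    peptide: ModifiedPeptide
    state_label: str
    mz: float

    @property
    def mz_display(self) -> float:
        return round(self.mz, 2)


def monoisotopic_mass(peptide: ModifiedPeptide, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    mass = table.water_mass
    for code in peptide.sequence:
        mass += table.residue(code)
    for _, name in peptide.mods:
        mass += table.delta(name)
    return mass


def mz(peptide: ModifiedPeptide, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Precursor m/z = (M + z*proton) / z for the peptide's charge state."""
    z = peptide.charge
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (monoisotopic_mass(peptide, table) + z * table.proton_mass) / z


def prm_series(
    sequence: str,
    site_position: int,
    charge: int,
    *,
    extra_mods: Iterable[tuple[int, str]] = (),
    permissive: bool = False,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[PrmTarget]:
    """The four-state PRM target series (me0..me3) for one lysine site.

    ``site_position`` is 1-based into ``sequence`` and must index a K
    unless ``permissive``.  ``extra_mods`` (e.g. a phospho elsewhere) are
    carried on every state.
    """
    if not 1 <= site_position <= len(sequence):
        raise ValueError(f"site position {site_position} outside sequence")
    if sequence[site_position - 1] != "K" and not permissive:
        raise ValueError(
            f"site {site_position} is {sequence[site_position - 1]!r}, not K"
        )
    extra = tuple(extra_mods)
    targets = []
    for label in STATE_LABELS:
        mod = _STATE_TO_MOD[label]
        mods = extra + ((site_position, mod),) if mod else extra
        pep = ModifiedPeptide(sequence, mods, charge, permissive=permissive)
        targets.append(PrmTarget(pep, label, mz(pep, table)))
    return targets


def _mod_delta_in(peptide: ModifiedPeptide, positions: range, table: ResidueMassTable) -> float:
    return sum(table.delta(name) for pos, name in peptide.mods if pos in positions)


def fragment_mz(
    peptide: ModifiedPeptide,
    ion_type: str,
    index: int,
    charge: int = 1,
    *,
    neutral_loss_h3po4: bool = False,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Monoisotopic m/z of a b/a/y fragment ion.

    ``index`` counts residues from the N terminus (b/a ions) or C terminus
    (y ions), 1 <= index < len(sequence).  Modifications located within the
    fragment are included; ``neutral_loss_h3po4`` subtracts one phosphate
    (-97.9769 Da), the loss commonly annotated '-P' on phosphopeptide
    spectra.
    """
    n = len(peptide.sequence)
    if not 1 <= index < n:
        raise ValueError(f"fragment index {index} outside [1, {n - 1}]")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if ion_type not in ("a", "b", "y"):
        raise ValueError(f"unsupported ion type {ion_type!r}")

    if ion_type in ("a", "b"):
        span = range(1, index + 1)
        residues = peptide.sequence[:index]
        neutral = sum(table.residue(c) for c in residues)
        neutral += _mod_delta_in(peptide, span, table)
        if ion_type == "a":
            neutral -= CO
    else:  # y ion: C-terminal fragment keeps the water
        span = range(n - index + 1, n + 1)
        residues = peptide.sequence[n - index:]
        neutral = sum(table.residue(c) for c in residues) + table.water_mass
        neutral += _mod_delta_in(peptide, span, table)
    if neutral_loss_h3po4:
        neutral -= H3PO4
    return (neutral + charge * table.proton_mass) / charge
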