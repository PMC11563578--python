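"""Elemental-composition mass arithmetic and 2-plex Qlinker mass constants.

All m/z mathematics in the package is routed through this module: monoisotopic
masses are computed from elemental compositions using hard-coded IUPAC/CODATA
atomic masses (sources below), so every derived constant — reporter-ion m/z,
crosslink and monolink deltas, b1+ interference table — is reproducible from
first principles rather than copied from the literature.

The Qlinker reagent pair (C1q2/C2q2) is an amine-reactive, isobaric
bis-NHS-ester built on an iminodipropionic acid scaffold carrying a
2,6-dimethylpiperidine balance/reporter group with a single 13C placed on
either the reporter or the balance arm.  HCD fragmentation releases a
1-imino-2,6-dimethylpiperidin-1-ium reporter cation whose m/z (126 vs 127
channel) identifies the sample of origin.

Atomic mass sources: CODATA 2018 (proton, electron); IUPAC/AME2020 atomic
mass evaluation (isotopic masses), all truncated at >= 9 decimal places.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

__all__ = [
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_C12_DELTA",
    "WATER",
    "ElementComposition",
    "ModificationDelta",
    "ReporterChannel",
    "AMINO_ACID_COMPOSITIONS",
    "AMINO_ACID_MASSES",
    "REPORTER_126",
    "REPORTER_127",
    "DEFAULT_PURITY_COLUMNS",
    "STANDARD_MODIFICATIONS",
    "monoisotopic_mass",
    "ion_mz",
    "peptide_mass",
    "qlinker_deltas",
    "b1_ion_mz",
    "tolerance_window",
    "constants_table",
]

#: Monoisotopic atomic masses in Da. Heavy isotopes are distinct symbols.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.007825032,
    "2H": 2.014101778,
    "C": 12.0,
    "13C": 13.003354835,
    "N": 14.003074004,
    "15N": 15.000108899,
    "O": 15.994914620,
    "18O": 17.999159613,
    "S": 31.972071174,
    "P": 30.973761998,
}

PROTON_MASS = 1.007276467  # Da, CODATA 2018
ELECTRON_MASS = 0.000548580  # Da, CODATA 2018

#: Mass added when one 12C is replaced by 13C.
C13_C12_DELTA = ATOMIC_MASSES["13C"] - ATOMIC_MASSES["C"]

_FORMULA_TOKEN = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


class UnknownElementError(KeyError):
    """Raised when a composition references a symbol not in ATOMIC_MASSES."""


@dataclass(frozen=True)
class ElementComposition:
    """Immutable bag of element counts, heavy isotopes as distinct symbols.

    Construct from a mapping (``ElementComposition({"C": 8, "H": 16, "N": 1})``)
    or a formula string via :meth:`parse` (``"C8H16N"``; isotopes in square
    brackets, ``"C14[13C]H26N2O5"``).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in dict(self.counts).items():
            if sym not in ATOMIC_MASSES:
                raise UnknownElementError(f"unknown element symbol: {sym!r}")
            if n != int(n) or n < 0:
                raise ValueError(f"count for {sym} must be a non-negative integer, got {n}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, formula: str) -> "ElementComposition":
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            pos = m.end()
            sym = m.group(1).strip("[]")
            counts[sym] = counts.get(sym, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        return cls(counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementComposition(merged)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) - n
            if merged[sym] < 0:
                raise ValueError(
                    f"subtraction would give negative count for {sym}"
                )
        return ElementComposition(merged)

    def __mul__(self, k: int) -> "ElementComposition":
        return ElementComposition({s: n * k for s, n in self.counts.items()})

    def substitute(self, old: str, new: str, n: int = 1) -> "ElementComposition":
        """Replace ``n`` atoms of ``old`` by ``new`` (e.g. one 12C by 13C)."""
        return self - ElementComposition({old: n}) + ElementComposition({new: n})

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def formula(self) -> str:
        parts = []
        for sym in sorted(self.counts):
            tag = f"[{sym}]" if sym[0].isdigit() else sym
            n = self.counts[sym]
            parts.append(f"{tag}{n if n > 1 else ''}")
        return "".join(parts)


def monoisotopic_mass(comp: ElementComposition | Mapping[str, int] | str) -> float:
    """Monoisotopic mass in Da of a composition (empty composition -> 0.0)."""
    if isinstance(comp, str):
        comp = ElementComposition.parse(comp)
    elif not isinstance(comp, ElementComposition):
        comp = ElementComposition(comp)
    return sum(ATOMIC_MASSES[sym] * n for sym, n in comp.counts.items())


def ion_mz(
    comp: ElementComposition | str,
    charge: int = 1,
    protonated: bool = True,
) -> float:
    """m/z of an ion formed from ``comp``.

    ``protonated=True`` treats ``comp`` as a neutral species gaining ``charge``
    protons: (M + z*m_p)/z.  ``protonated=False`` treats ``comp`` as the
    intrinsic cation's atom bag, subtracting ``charge`` electron masses:
    (M - z*m_e)/z — the convention for a pre-formed cation such as the
    iminium reporter.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    m = monoisotopic_mass(comp)
    if protonated:
        return (m + charge * PROTON_MASS) / charge
    return (m - charge * ELECTRON_MASS) / charge


WATER = ElementComposition.parse("H2O")

#: Residue (not free amino acid) compositions for the 20 standard residues.
AMINO_ACID_COMPOSITIONS: Dict[str, ElementComposition] = {
    "G": ElementComposition.parse("C2H3NO"),
    "A": ElementComposition.parse("C3H5NO"),
    "S": ElementComposition.parse("C3H5NO2"),
    "P": ElementComposition.parse("C5H7NO"),
    "V": ElementComposition.parse("C5H9NO"),
    "T": ElementComposition.parse("C4H7NO2"),
    "C": ElementComposition.parse("C3H5NOS"),
    "L": ElementComposition.parse("C6H11NO"),
    "I": ElementComposition.parse("C6H11NO"),
    "N": ElementComposition.parse("C4H6N2O2"),
    "D": ElementComposition.parse("C4H5NO3"),
    "Q": ElementComposition.parse("C5H8N2O2"),
    "K": ElementComposition.parse("C6H12N2O"),
    "E": ElementComposition.parse("C5H7NO3"),
    "M": ElementComposition.parse("C5H9NOS"),
    "H": ElementComposition.parse("C6H7N3O"),
    "F": ElementComposition.parse("C9H9NO"),
    "R": ElementComposition.parse("C6H12N4O"),
    "Y": ElementComposition.parse("C9H9NO2"),
    "W": ElementComposition.parse("C11H10N2O"),
}

#: Residue letter -> monoisotopic residue mass (Da), derived from compositions.
AMINO_ACID_MASSES: Dict[str, float] = {
    aa: monoisotopic_mass(c) for aa, c in AMINO_ACID_COMPOSITIONS.items()
}


def peptide_mass(sequence: str, mod_masses: Iterable[float] = ()) -> float:
    """Neutral monoisotopic peptide mass: sum of residues + water + mods."""
    try:
        m = sum(AMINO_ACID_MASSES[aa] for aa in sequence)
    except KeyError as exc:
        raise KeyError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None
    return m + monoisotopic_mass(WATER) + sum(mod_masses)


def b1_ion_mz(residue: str) -> float:
    """m/z of the singly charged b1 fragment of an unmodified N-terminal residue.

    b1+ ions from Leu/Ile (114.09), Asn (115.05) and Asp (116.03) sit just
    below the reporter region; this table documents why reporter channels
    were placed at 126/127 m/z, clear of b1+ and immonium interference.
    """
    if residue not in AMINO_ACID_MASSES:
        raise KeyError(f"unknown residue {residue!r}")
    return AMINO_ACID_MASSES[residue] + PROTON_MASS


def tolerance_window(center: float, tol: float, unit: str = "Da") -> Tuple[float, float]:
    """Inclusive [low, high] m/z window around ``center``.

    ``unit`` is ``"Da"`` (half-width = tol) or ``"ppm"``
    (half-width = center * tol * 1e-6).
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    if unit == "Da":
        half = tol
    elif unit == "ppm":
        half = center * tol * 1e-6
    else:
        raise ValueError(f"unit must be 'Da' or 'ppm', got {unit!r}")
    return (center - half, center + half)


@dataclass(frozen=True)
class ModificationDelta:
    """A named mass modification with site specificity.

    category: "monolink" (dead-end crosslinker, one arm hydrolyzed),
    "crosslink" (bridging two residues) or "standard".
    """

    name: str
    delta_mass: float
    sites: str  # residue letters, optionally with "nterm"/"cterm"
    category: str = "standard"


@dataclass(frozen=True)
class ReporterChannel:
    """One isobaric reporter channel: iminium composition, m/z, purity column.

    ``purity`` = (fraction of this channel's true signal observed in its own
    channel, fraction bleeding into the other channel).  The 126 channel
    bleeds upward mainly through natural 13C; the 127 channel bleeds downward
    through incomplete 13C enrichment (99%).
    """

    label: int
    composition: ElementComposition
    purity: Tuple[float, float]

    @property
    def mz(self) -> float:
        """Theoretical 1+ m/z of the intrinsic iminium cation."""
        return ion_mz(self.composition, charge=1, protonated=False)


# 1-imino-2,6-dimethylpiperidin-1-ium reporter cation. Channel 126 carries no
# 13C (it stays on the balance arm of C1q2); channel 127 carries one 13C.
_REPORTER_BASE = ElementComposition.parse("C8H16N")

#: Purity columns as (own-channel fraction, bleed into the other channel).
DEFAULT_PURITY_COLUMNS = {126: (0.90754, 0.09246), 127: (0.01, 0.90724)}

REPORTER_126 = ReporterChannel(126, _REPORTER_BASE, DEFAULT_PURITY_COLUMNS[126])
REPORTER_127 = ReporterChannel(
    127, _REPORTER_BASE.substitute("C", "13C"), DEFAULT_PURITY_COLUMNS[127]
)


def qlinker_deltas() -> Tuple[ModificationDelta, ModificationDelta]:
    """(crosslink, monolink) modification deltas of the 2-plex Qlinker.

    The reagent is the diacid C15H26N2O5 carrying one 13C. A crosslink forms
    two amide bonds (loses two waters); a monolink forms one amide bond with
    the other NHS arm hydrolyzed (net loss of one water), so
    monolink - crosslink = mass(H2O) exactly.
    """
    diacid = ElementComposition.parse("C14[13C]H26N2O5")
    xl = monoisotopic_mass(diacid) - 2 * monoisotopic_mass(WATER)
    return (
        ModificationDelta("qlinker-crosslink", xl, "K,nterm", "crosslink"),
        ModificationDelta("qlinker-monolink", xl + monoisotopic_mass(WATER), "K,nterm", "monolink"),
    )


#: Standard search modifications used alongside the Qlinker deltas.
STANDARD_MODIFICATIONS = {
    "carbamidomethyl": ModificationDelta(
        "carbamidomethyl", monoisotopic_mass("C2H3NO"), "C"
    ),
    "oxidation": ModificationDelta("oxidation", monoisotopic_mass("O"), "M"),
    "pyro-glu": ModificationDelta("pyro-glu", -monoisotopic_mass(WATER), "E,nterm"),
    "pyro-gln": ModificationDelta("pyro-gln", -monoisotopic_mass("NH3"), "Q,nterm"),
}


def constants_table() -> str:
    """TSV (name, composition, monoisotopic mass or m/z) of exported constants."""
    xl, mono = qlinker_deltas()
    rows = [
        ("proton", "-", PROTON_MASS),
        ("electron", "-", ELECTRON_MASS),
        ("water", WATER.formula(), monoisotopic_mass(WATER)),
        ("reporter_126_mz", REPORTER_126.composition.formula(), REPORTER_126.mz),
        ("reporter_127_mz", REPORTER_127.composition.formula(), REPORTER_127.mz),
        ("qlinker_crosslink_delta", "C14[13C]H26N2O5 - 2 H2O", xl.delta_mass),
        ("qlinker_monolink_delta", "C14[13C]H26N2O5 - H2O", mono.delta_mass),
    ]
    lines = ["name\tcomposition\tmass"]
    lines += [f"{n}\t{c}\t{m:.6f}" for n, c, m in rows]
    return "\n".join(lines) + "\n"
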