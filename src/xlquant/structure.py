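"""Map quantified sites onto 3D structures: distances, restraints, salt bridges.

Amine-reactive crosslinkers with a ~10 Å spacer restrain the Cα atoms of
linked lysines to roughly <= 30 Å (lysine side-chain flexibility included);
a quantified crosslink whose Cα–Cα distance exceeds that bound in every
candidate conformation is suspect.  Reactivity changes of single lysines are
often explained by salt bridges: a lysine NZ engaged with an Asp/Glu
carboxylate oxygen (N–O typically <= 4 Å) is a poor NHS-ester nucleophile,
so breaking the bridge increases monolink/crosslink abundance at that site.

Parsing is delegated to gemmi (PDB and mmCIF); the first model of multi-model
files is used and alternate locations resolve to the highest occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi

from .ident import SiteKey

__all__ = [
    "StructureModel", "ChainMap", "RestraintCheck", "SaltBridge",
    "load_structure", "atom_distance", "check_crosslink", "detect_salt_bridges",
]

#: Default maximum Cα–Cα distance (Å) for a satisfiable lysine–lysine link.
DEFAULT_MAX_CA_CA = 30.0
#: Default N–O cutoff (Å) for calling a salt bridge.
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0

_ACIDIC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


class MissingAtomError(KeyError):
    """Raised when a requested chain/residue/atom is absent from the model."""


@dataclass
class StructureModel:
    """First-model view of a structure with occupancy-resolved atoms."""

    structure_id: str
    _model: gemmi.Model

    def chain(self, chain_id: str) -> gemmi.Chain:
        ch = self._model.find_chain(chain_id)
        if ch is None:
            raise MissingAtomError(f"chain {chain_id!r} not in {self.structure_id}")
        return ch

    def residue(self, chain_id: str, resnum: int) -> gemmi.Residue:
        ch = self.chain(chain_id)
        for res in ch:
            if res.seqid.num == resnum:
                return res
        raise MissingAtomError(
            f"residue {resnum} not in chain {chain_id!r} of {self.structure_id}"
        )

    def atom(self, chain_id: str, resnum: int, atom_name: str) -> gemmi.Atom:
        res = self.residue(chain_id, resnum)
        best = None
        for at in res:
            if at.name == atom_name and (best is None or at.occ > best.occ):
                best = at
        if best is None:
            raise MissingAtomError(
                f"atom {atom_name!r} not in {chain_id}/{resnum} of {self.structure_id}"
            )
        return best

    @property
    def chain_ids(self) -> List[str]:
        return [ch.name for ch in self._model]


#: protein name (as used in SiteKeys) -> candidate chain identifier(s).
ChainMap = Dict[str, Sequence[str]]


def load_structure(path: str | Path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file; multi-model files use model 1 only."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt.lower() == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt.lower() in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0 or all(len(model) == 0 for model in st):
        raise ValueError(f"structure file {path} contains no atoms")
    st.setup_entities()
    return StructureModel(st.name or path.stem, st[0])


def atom_distance(
    model: StructureModel,
    a: Tuple[str, int, str],
    b: Tuple[str, int, str],
) -> float:
    """Euclidean distance (Å) between two (chain, resnum, atom) triples."""
    at_a = model.atom(*a)
    at_b = model.atom(*b)
    return at_a.pos.dist(at_b.pos)


@dataclass(frozen=True)
class RestraintCheck:
    """Cα–Cα restraint verdict for one crosslinked site pair."""

    key: SiteKey
    distance: Optional[float]  # Å; None when unmappable
    max_allowed: float
    verdict: str  # satisfied | violated | unmappable
    detail: str = ""


def _resolve_site(
    model: StructureModel, site: Tuple[str, int], chain_map: ChainMap,
    atom_name: str = "CA",
) -> gemmi.Atom:
    protein, resnum = site
    if protein not in chain_map:
        raise MissingAtomError(f"protein {protein!r} not covered by the chain map")
    chains = chain_map[protein]
    if isinstance(chains, str):
        chains = [chains]
    last_err: Optional[Exception] = None
    for chain_id in chains:
        try:
            return model.atom(chain_id, resnum, atom_name)
        except MissingAtomError as exc:
            last_err = exc
    raise MissingAtomError(str(last_err))


def check_crosslink(
    key: SiteKey,
    model: StructureModel,
    chain_map: ChainMap,
    max_ca_ca: float = DEFAULT_MAX_CA_CA,
) -> RestraintCheck:
    """Cα–Cα distance of a crosslinked pair against the maximum-allowed bound.

    Residues absent from the model (disordered regions are common) yield an
    ``unmappable`` verdict naming the missing piece, never an exception.
    """
    if not key.is_crosslink:
        raise ValueError("restraint checks apply to crosslink site pairs")
    try:
        a = _resolve_site(model, key.sites[0], chain_map)
        b = _resolve_site(model, key.sites[1], chain_map)
    except MissingAtomError as exc:
        return RestraintCheck(key, None, max_ca_ca, "unmappable", str(exc))
    d = a.pos.dist(b.pos)
    verdict = "violated" if d > max_ca_ca else "satisfied"
    return RestraintCheck(key, d, max_ca_ca, verdict)


@dataclass(frozen=True)
class SaltBridge:
    """One lysine-NZ to Asp/Glu carboxylate-oxygen contact."""

    partner: Tuple[str, int, str]  # (chain, resnum, residue name)
    atom_pair: Tuple[str, str]  # (lysine atom, acidic oxygen atom)
    distance: float  # Å


def detect_salt_bridges(
    model: StructureModel,
    lysine: Tuple[str, int],
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> List[SaltBridge]:
    """All Asp OD1/OD2 and Glu OE1/OE2 atoms within ``cutoff`` Å of the
    lysine side-chain nitrogen (NZ), sorted by distance."""
    chain_id, resnum = lysine
    res = model.residue(chain_id, resnum)
    if res.name != "LYS":
        raise ValueError(f"{chain_id}/{resnum} is {res.name}, not LYS")
    nz = model.atom(chain_id, resnum, "NZ")  # MissingAtomError if absent
    bridges: List[SaltBridge] = []
    for chain in model._model:
        for other in chain:
            oxygens = _ACIDIC_OXYGENS.get(other.name)
            if not oxygens:
                continue
            for at in other:
                if at.name in oxygens:
                    d = nz.pos.dist(at.pos)
                    if d <= cutoff:
                        bridges.append(SaltBridge(
                            (chain.name, other.seqid.num, other.name),
                            ("NZ", at.name), d,
                        ))
    bridges.sort(key=lambda b: b.distance)
    return bridges
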