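"""Shared fixtures: small simulated datasets and synthetic structure files.

All structure fixtures are synthetic stand-ins built from hand-placed
coordinates; no deposited coordinates are bundled or downloaded.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Tuple

import pytest

from xlquant.ident import SiteKey
from xlquant.synthetic import SimConfig, SimSite, load_toy_proteome, random_sites, simulate_run


@pytest.fixture(scope="session")
def proteome():
    return load_toy_proteome()


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset: 3 sites x 5 spectra, known ratios, exact recovery."""
    sites = random_sites(3, [-1.0, 0.0, 1.0], n_spectra=5, seed=101)
    cfg = SimConfig(sites=sites, seed=202, n_noise_peaks=0)
    return simulate_run(cfg)


AtomSpec = Tuple[str, int, str, str, Tuple[float, float, float]]
# (chain, resnum, resname, atom name, xyz)


def build_pdb(atoms: Iterable[AtomSpec], nmodels: int = 1) -> str:
    """Serialize hand-placed atoms as minimal PDB text (synthetic fixture)."""
    lines = []
    for model in range(1, nmodels + 1):
        if nmodels > 1:
            lines.append(f"MODEL     {model:4d}")
        serial = 0
        for chain, resnum, resname, atom, (x, y, z) in atoms:
            serial += 1
            element = atom[0]
            shift = 10.0 * (model - 1)  # displace later models
            lines.append(
                f"ATOM  {serial:5d} {atom:^4s}{resname:>4s} {chain}{resnum:4d}    "
                f"{x + shift:8.3f}{y:8.3f}{z:8.3f}  1.00 20.00          {element:>2s}"
            )
        if nmodels > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _lys_with_acid(
    chain: str,
    lys_num: int,
    acid_num: int,
    acid_name: str,
    acid_atom: str,
    no_distance: float,
    ca_ca: float = 6.0,
) -> list:
    """A lysine and an acidic residue with the NZ–O distance set exactly."""
    return [
        (chain, lys_num, "LYS", "N", (0.0, 0.0, 0.0)),
        (chain, lys_num, "LYS", "CA", (1.5, 0.0, 0.0)),
        (chain, lys_num, "LYS", "NZ", (4.0, 2.0, 0.0)),
        (chain, acid_num, acid_name, "CA", (1.5 + ca_ca, 0.0, 0.0)),
        (chain, acid_num, acid_name, acid_atom, (4.0 + no_distance, 2.0, 0.0)),
    ]


@pytest.fixture(scope="session")
def toy_pdb_text() -> str:
    """Two glycines with CA atoms 5 Å apart (3-4-0 offset)."""
    return build_pdb([
        ("A", 1, "GLY", "N", (0.0, 0.0, 0.0)),
        ("A", 1, "GLY", "CA", (0.0, 0.0, 0.0)),
        ("A", 2, "GLY", "N", (3.0, 4.0, 1.0)),
        ("A", 2, "GLY", "CA", (3.0, 4.0, 0.0)),
    ])


@pytest.fixture(scope="session")
def core_polii_like_pdb() -> str:
    """Synthetic stand-in for the core (10-subunit) polymerase geometry:
    the largest-subunit K15 NZ sits 3.8 Å from D1442 OD2 (salt bridge
    formed), and two small-subunit lysines lie within crosslinking range."""
    atoms = _lys_with_acid("A", 15, 1442, "ASP", "OD2", 3.8)
    atoms += [
        ("F", 72, "LYS", "CA", (10.0, 5.0, 3.0)),
        ("F", 72, "LYS", "NZ", (12.0, 6.0, 3.0)),
        ("F", 76, "LYS", "CA", (14.0, 8.0, 2.0)),
        ("F", 76, "LYS", "NZ", (16.0, 9.0, 2.0)),
    ]
    return build_pdb(atoms)


@pytest.fixture(scope="session")
def holo_polii_like_pdb() -> str:
    """Synthetic stand-in for the holo (12-subunit) geometry: the hinge bend
    pulls D1442 away from K15 (NZ–OD2 6.7 Å, salt bridge broken)."""
    atoms = _lys_with_acid("A", 15, 1442, "ASP", "OD2", 6.7)
    atoms += [
        ("F", 72, "LYS", "CA", (10.0, 5.0, 3.0)),
        ("F", 72, "LYS", "NZ", (12.0, 6.0, 3.0)),
        ("F", 76, "LYS", "CA", (14.0, 8.0, 2.0)),
        ("F", 76, "LYS", "NZ", (16.0, 9.0, 2.0)),
    ]
    return build_pdb(atoms)


@pytest.fixture(scope="session")
def mbp_like_pdb() -> str:
    """Synthetic stand-in for the open maltose-binding-protein interface:
    K313 NZ 3.3 Å from E310 OE2 (salt bridge restraining the amine)."""
    return build_pdb(_lys_with_acid("A", 313, 310, "GLU", "OE2", 3.3, ca_ca=5.0))
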