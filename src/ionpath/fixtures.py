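"""Synthetic four-subunit selectivity-filter fixture with settable dihedrals.

Builds a tetramer of short peptides spanning Ser624-Asn629 of the hERG
signature sequence (S-V-G-F-G-N) by internal-coordinate chain extension
(the NeRF construction), so every requested backbone or side-chain
dihedral is reproduced exactly (to floating-point precision, well below
1e-6 degrees) in the generated coordinates.  The settable torsions are
the ones monitored by the filter-folding collective variables:

* psi of Val625 and Gly626       -> N_S2,S3 (8 dihedrals over 4 subunits)
* N-CA-C-O of Phe627             -> N_S1    (4 dihedrals)
* C-CA-CB-OG (chi1) of Ser624    -> N_S4    (4 dihedrals)

Reference angles default to module constants representing an ideally
conductive filter conformation.  They are synthetic stand-ins chosen once
for this package (the only literature-anchored value is the Ser624 chi1
rotamer of about -60 degrees); any other reference structure can be
supplied instead.  Structures are written as standard PDB via biotite and
are readable by mainstream parsers.  Note that the PDB coordinate fields
carry three decimals, so dihedrals recomputed from a written file agree
with the requested values to about 0.05 degrees; the in-memory round trip
is exact.  The similarity variable N_theta is insensitive to this at the
reference point (the half-cosine score is second order in the offset).
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .cv import DihedralParameterization, dihedral

__all__ = [
    "REFERENCE_ANGLES",
    "FixtureStructure",
    "build_filter_fixture",
    "psi_parameterization",
    "phe627_carbonyl_parameterization",
    "ser624_chi1_parameterization",
]

#: Reference torsions (degrees) of the ideally conductive conformation.
#: ser624_chi1 is the gauche-minus rotamer that points the hydroxyl
#: oxygen into the S4 coordination cage.
REFERENCE_ANGLES = {
    "psi_val625": 125.0,
    "psi_gly626": -8.0,
    "phe627_n_ca_c_o": -40.0,
    "ser624_chi1": -60.0,
}

_RESIDUES = (
    (624, "SER"),
    (625, "VAL"),
    (626, "GLY"),
    (627, "PHE"),
    (628, "GLY"),
    (629, "ASN"),
)

# standard backbone geometry (bond lengths in angstrom, angles in degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.530
_B_CB_OG = 1.417
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.5
_A_CA_CB_OG = 110.8
_OMEGA = 180.0
_DEFAULT_PHI = -120.0
_DEFAULT_PSI = 135.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_subunit(torsions: dict) -> list[tuple[int, str, str, str, np.ndarray]]:
    """One chain as a list of (res_id, res_name, atom_name, element, xyz)."""
    atoms: list[tuple[int, str, str, str, np.ndarray]] = []
    coords: dict[tuple[int, str], np.ndarray] = {}

    def put(res_id: int, res_name: str, name: str, xyz: np.ndarray) -> None:
        coords[(res_id, name)] = xyz
        atoms.append((res_id, res_name, name, name[0], xyz))

    # bootstrap the first residue in a canonical local frame
    r0, n0 = _RESIDUES[0]
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    put(r0, n0, "N", N)
    put(r0, n0, "CA", CA)
    put(r0, n0, "C", C)

    for idx, (res_id, res_name) in enumerate(_RESIDUES):
        N = coords[(res_id, "N")]
        CA = coords[(res_id, "CA")]
        C = coords[(res_id, "C")]
        if res_name == "SER":
            chi1 = torsions.get(("chi1", res_id), REFERENCE_ANGLES["ser624_chi1"])
            CB = _place(C, N, CA, _B_CA_CB, _A_N_CA_CB, torsions.get(("cb", res_id), 122.5))
            put(res_id, res_name, "CB", CB)
            OG = _place(C, CA, CB, _B_CB_OG, _A_CA_CB_OG, chi1)
            put(res_id, res_name, "OG", OG)
        psi = torsions.get(("psi", res_id), _DEFAULT_PSI)
        # carbonyl oxygen: N-CA-C-O torsion; defaults to psi - 180
        o_tors = torsions.get(("n_ca_c_o", res_id), psi - 180.0)
        O = _place(N, CA, C, _B_C_O, _A_CA_C_O, o_tors)
        put(res_id, res_name, "O", O)
        if idx == len(_RESIDUES) - 1:
            break
        next_id, next_name = _RESIDUES[idx + 1]
        N2 = _place(N, CA, C, _B_C_N, _A_CA_C_N, psi)
        CA2 = _place(CA, C, N2, _B_N_CA, _A_C_N_CA, _OMEGA)
        phi_t = torsions.get(("phi", next_id), _DEFAULT_PHI)
        C2 = _place(C, N2, CA2, _B_CA_C, _A_N_CA_C, phi_t)
        put(next_id, next_name, "N", N2)
        put(next_id, next_name, "CA", CA2)
        put(next_id, next_name, "C", C2)
    return atoms


_DIHEDRAL_KINDS = {
    "psi": lambda res: (("N", res), ("CA", res), ("C", res), ("N", res + 1)),
    "n_ca_c_o": lambda res: (("N", res), ("CA", res), ("C", res), ("O", res)),
    "chi1": lambda res: (("C", res), ("CA", res), ("CB", res), ("OG", res)),
}


@dataclasses.dataclass
class FixtureStructure:
    """A tetrameric filter fixture wrapping a biotite AtomArray.

    ``coords`` keeps full float64 precision when the structure was built
    in memory (biotite stores float32 internally); structures read back
    from PDB carry the file's three-decimal precision.
    """

    atoms: struc.AtomArray
    _coords64: np.ndarray | None = None

    @property
    def coords(self) -> np.ndarray:
        if self._coords64 is not None:
            return self._coords64
        return np.asarray(self.atoms.coord, dtype=float)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.atoms.chain_id:
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def index_of(self, chain: str, res_id: int, atom_name: str) -> int:
        mask = (
            (self.atoms.chain_id == chain)
            & (self.atoms.res_id == res_id)
            & (self.atoms.atom_name == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            raise KeyError(f"atom {chain}/{res_id}/{atom_name} not uniquely found")
        return int(idx[0])

    def dihedral_quadruple(self, chain: str, res_id: int, kind: str) -> np.ndarray:
        """Atom-index quadruple of a named torsion (psi, n_ca_c_o, chi1)."""
        try:
            spec = _DIHEDRAL_KINDS[kind](res_id)
        except KeyError as exc:
            raise KeyError(f"unknown dihedral kind {kind!r}") from exc
        return np.asarray(
            [self.index_of(chain, r, name) for name, r in spec], dtype=int
        )

    def measure_dihedral(self, chain: str, res_id: int, kind: str) -> float:
        quad = self.dihedral_quadruple(chain, res_id, kind)
        return dihedral(*(self.coords[i] for i in quad))

    def write_pdb(self, path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.atoms)
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path) -> "FixtureStructure":
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
        return cls(arr)


def build_filter_fixture(
    psi_val625: float | None = None,
    psi_gly626: float | None = None,
    phe627_n_ca_c_o: float | None = None,
    ser624_chi1: float | None = None,
    per_subunit: dict[str, dict] | None = None,
    pore_radius: float = 8.0,
) -> FixtureStructure:
    """Build the 4-subunit fixture with the requested torsions.

    Scalar arguments apply to all four subunits (chains A-D); ``None``
    falls back to the reference angles.  ``per_subunit`` may override
    individual chains with mappings like ``{"B": {"psi_val625": 90.0}}``.
    Subunits are rigid-motion copies placed around the pore axis, so the
    torsions are identical in every chain unless overridden.
    """
    base = {
        "psi_val625": REFERENCE_ANGLES["psi_val625"] if psi_val625 is None else psi_val625,
        "psi_gly626": REFERENCE_ANGLES["psi_gly626"] if psi_gly626 is None else psi_gly626,
        "phe627_n_ca_c_o": REFERENCE_ANGLES["phe627_n_ca_c_o"]
        if phe627_n_ca_c_o is None
        else phe627_n_ca_c_o,
        "ser624_chi1": REFERENCE_ANGLES["ser624_chi1"] if ser624_chi1 is None else ser624_chi1,
    }
    chains = ("A", "B", "C", "D")
    rows = []
    for k, chain in enumerate(chains):
        values = dict(base)
        if per_subunit and chain in per_subunit:
            values.update(per_subunit[chain])
        torsions = {
            ("psi", 625): values["psi_val625"],
            ("psi", 626): values["psi_gly626"],
            ("n_ca_c_o", 627): values["phe627_n_ca_c_o"],
            ("chi1", 624): values["ser624_chi1"],
        }
        atoms = _build_subunit(torsions)
        ang = math.radians(90.0 * k)
        R = np.array(
            [
                [math.cos(ang), -math.sin(ang), 0.0],
                [math.sin(ang), math.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shift = R @ np.array([pore_radius, 0.0, 0.0])
        for res_id, res_name, name, element, xyz in atoms:
            rows.append((chain, res_id, res_name, name, element, R @ xyz + shift))
    coords64 = np.asarray([r[5] for r in rows], dtype=float)
    arr = struc.AtomArray(len(rows))
    arr.coord = coords64
    arr.chain_id = np.asarray([r[0] for r in rows])
    arr.res_id = np.asarray([r[1] for r in rows])
    arr.res_name = np.asarray([r[2] for r in rows])
    arr.atom_name = np.asarray([r[3] for r in rows])
    arr.element = np.asarray([r[4] for r in rows])
    arr.hetero = np.zeros(len(rows), dtype=bool)
    return FixtureStructure(arr, coords64)


def _collect(
    fixture: FixtureStructure,
    specs: list[tuple[int, str]],
    references: list[float],
) -> DihedralParameterization:
    quads = []
    refs = []
    for chain in fixture.chains:
        for (res_id, kind), ref in zip(specs, references):
            quads.append(fixture.dihedral_quadruple(chain, res_id, kind))
            refs.append(ref)
    return DihedralParameterization(np.asarray(quads), np.asarray(refs))


def psi_parameterization(
    fixture: FixtureStructure, reference: FixtureStructure | None = None
) -> DihedralParameterization:
    """N_S2,S3: the 8 psi torsions of Val625 and Gly626 over 4 subunits.

    Reference angles are measured from ``reference`` when given,
    otherwise taken from :data:`REFERENCE_ANGLES`.
    """
    if reference is not None:
        refs = [
            reference.measure_dihedral(reference.chains[0], 625, "psi"),
            reference.measure_dihedral(reference.chains[0], 626, "psi"),
        ]
    else:
        refs = [REFERENCE_ANGLES["psi_val625"], REFERENCE_ANGLES["psi_gly626"]]
    return _collect(fixture, [(625, "psi"), (626, "psi")], refs)


def phe627_carbonyl_parameterization(
    fixture: FixtureStructure, reference: FixtureStructure | None = None
) -> DihedralParameterization:
    """N_S1: the N-CA-C-O torsion of Phe627 in each subunit (n = 4)."""
    if reference is not None:
        ref = reference.measure_dihedral(reference.chains[0], 627, "n_ca_c_o")
    else:
        ref = REFERENCE_ANGLES["phe627_n_ca_c_o"]
    return _collect(fixture, [(627, "n_ca_c_o")], [ref])


def ser624_chi1_parameterization(
    fixture: FixtureStructure, reference: FixtureStructure | None = None
) -> DihedralParameterization:
    """N_S4: the C-CA-CB-OG torsion of Ser624 in each subunit (n = 4)."""
    if reference is not None:
        ref = reference.measure_dihedral(reference.chains[0], 624, "chi1")
    else:
        ref = REFERENCE_ANGLES["ser624_chi1"]
    return _collect(fixture, [(624, "chi1")], [ref])
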