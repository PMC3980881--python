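"""Reduced protein model: dihedral search space, geometry, energy, dRMSD.

A peptide of n residues is parameterized purely by torsion angles.  The
backbone carries phi/psi (and optionally omega) per residue; each side chain
is reduced to CB plus one pseudo-atom per rotatable chi torsion, strung out as
a kinematic chain.  Coordinates are built by sequential internal-coordinate
placement (NeRF) from a fixed bond-length/bond-angle table, so the torsions
are the only degrees of freedom.

The energy is an ECEPP-family surrogate with the four classical components:

    E = E_LJ + E_elec + E_torsion + E_hbond

    E_LJ    = sum_pairs A_ij/r^12 - B_ij/r^6        (1-2 and 1-3 excluded)
    E_elec  = sum_pairs 332 q_i q_j / (D r)
    E_tors  = sum_vars (U0/2)(1 + cos(n*theta - theta0))
    E_hbond = sum_{N...O} A'/r^12 - B'/r^10         (replaces LJ on those pairs)

The constants live in a versioned parameter file (data/energy_params.yaml);
absolute energies are not comparable with any full force field, but the
anatomy of the landscape — steric clashes, electrostatics, torsional barriers,
backbone hydrogen bonding — is preserved.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.spatial.distance import pdist, squareform

from .moves import wrap_angle_deg

logger = logging.getLogger("cmqa.protein")

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Rotatable side-chain torsions treated as chi variables, per residue.
#: Terminal rotors (Met epsilon-methyl, Tyr hydroxyl) are counted, which is
#: what makes the classic 5-mer YGGFM come out at 19 variables with phi+psi.
CHI_COUNTS: Dict[str, int] = {
    "G": 0, "A": 0, "P": 0,
    "S": 1, "C": 1, "T": 1, "V": 1,
    "L": 2, "I": 2, "D": 2, "N": 2, "H": 2, "F": 2, "W": 2,
    "Y": 3, "E": 3, "Q": 3,
    "M": 4, "K": 4, "R": 4,
}

BACKBONE_KINDS = ("phi", "psi", "omega")


@dataclass(frozen=True)
class Variable:
    """One dihedral degree of freedom: residue index (0-based) and kind."""

    residue: int
    kind: str  # "phi", "psi", "omega", "chi1", "chi2", ...


@dataclass
class ProteinInstance:
    """A sequence plus its enumerated dihedral variables sigma_1..sigma_m."""

    sequence: str
    variables: List[Variable]

    @property
    def m(self) -> int:
        return len(self.variables)


def enumerate_variables(
    sequence: str,
    angle_set: Sequence[str] = ("phi", "psi", "chi"),
    ends: str = "charged",
) -> ProteinInstance:
    """Enumerate the dihedral variables of a sequence, in a stable order.

    Parameters
    ----------
    sequence : one-letter amino-acid codes.
    angle_set : which torsion kinds are variable, out of {phi, psi, omega,
        chi}.  Omega is between residue i and i+1 (the last residue has none)
        and is held at 180 deg when not listed.
    ends : "charged" keeps phi of residue 1 and psi of the last residue as
        variables (the terminal H/OXT atoms make them well defined, and this
        is the convention under which YGGFM has 19 variables); "free" drops
        them as undefined at bare chain termini.

    Order is per residue: phi, psi, omega, chi1..chi_k.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in VALID_RESIDUES:
            raise ValueError(f"unknown residue code {aa!r} at position {pos}")
    bad = set(angle_set) - {"phi", "psi", "omega", "chi"}
    if bad:
        raise ValueError(f"unknown angle kinds: {sorted(bad)}")
    if ends not in ("charged", "free"):
        raise ValueError(f"ends must be 'charged' or 'free'; got {ends!r}")
    n = len(sequence)
    variables: List[Variable] = []
    for i, aa in enumerate(sequence):
        if "phi" in angle_set and (i > 0 or ends == "charged"):
            variables.append(Variable(i, "phi"))
        if "psi" in angle_set and (i < n - 1 or ends == "charged"):
            variables.append(Variable(i, "psi"))
        if "omega" in angle_set and i < n - 1:
            variables.append(Variable(i, "omega"))
        if "chi" in angle_set:
            for k in range(1, CHI_COUNTS[aa] + 1):
                variables.append(Variable(i, f"chi{k}"))
    return ProteinInstance(sequence=sequence, variables=variables)


# ---------------------------------------------------------------------------
# internal geometry

#: Fixed internal parameters (lengths in Angstrom, angles in degrees).
INTERNAL_GEOMETRY = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,      # peptide bond to the next residue
    ("C", "O"): 1.231,
    ("C", "OXT"): 1.249,
    ("N", "H1"): 1.010,
    ("CA", "CB"): 1.530,
    ("CB", "SC"): 1.530,
    ("SC", "SC"): 1.530,
}
ANGLES = {
    "C_N_CA": 121.7,
    "N_CA_C": 111.2,
    "CA_C_N": 116.2,
    "CA_C_O": 120.8,
    "CA_C_OXT": 117.0,
    "H1_N_CA": 119.0,
    "N_CA_CB": 110.5,
    "CA_CB_SC": 114.0,
    "SC_SC_SC": 114.0,
}
#: Reference torsion C(i)-N-CA-CB placing the beta carbon (L-chirality).
CB_TORSION = -122.6


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral of four points, IUPAC convention, degrees in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return wrap_angle_deg(math.degrees(math.atan2(y, x)))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Place atom D from the frame (a, b, c) so that |CD| = bond,
    angle(b, c, D) = ``angle`` and dihedral(a, b, c, D) = ``torsion``."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m_ = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m_ + d_local[2] * n


@dataclass
class ChainGeometry:
    """Cartesian realization of one conformation.

    Besides coordinates it records the bond list and, for every dihedral
    variable, the quadruple of atom indices that defines it — so the input
    torsions can be re-measured exactly from the built structure.
    """

    coords: np.ndarray                    # (n_atoms, 3), Angstrom
    atom_names: List[str]                 # "N", "CA", "C", "O", "OXT", "H1", "CB", "SC1", ...
    res_index: List[int]                  # 0-based residue of each atom
    bonds: List[Tuple[int, int]]
    torsion_quads: List[Tuple[int, int, int, int]]
    torsion_kinds: List[str]
    torsion_values: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, residue: int, name: str) -> int:
        for i, (r, a) in enumerate(zip(self.res_index, self.atom_names)):
            if r == residue and a == name:
                return i
        raise KeyError(f"no atom {name} in residue {residue}")

    def select(self, name: str = "CA") -> np.ndarray:
        mask = [a == name for a in self.atom_names]
        return self.coords[np.asarray(mask, dtype=bool)]


def build_coordinates(
    instance: ProteinInstance, conformation: np.ndarray
) -> ChainGeometry:
    """Build Cartesian coordinates from torsions by sequential placement.

    Non-variable torsions are held fixed (omega at 180 deg, others at 180 as a
    neutral reference).  The construction is fully deterministic.
    """
    conformation = np.asarray(conformation, dtype=float)
    if conformation.shape != (instance.m,):
        raise ValueError(
            f"conformation has {conformation.shape} angles; instance expects {instance.m}"
        )
    angle_of: Dict[Tuple[int, str], float] = {
        (v.residue, v.kind): wrap_angle_deg(a)
        for v, a in zip(instance.variables, conformation)
    }
    var_index: Dict[Tuple[int, str], int] = {
        (v.residue, v.kind): k for k, v in enumerate(instance.variables)
    }

    def torsion(residue: int, kind: str, default: float = 180.0) -> float:
        return angle_of.get((residue, kind), default)

    seq = instance.sequence
    n = len(seq)
    coords: List[np.ndarray] = []
    names: List[str] = []
    resix: List[int] = []
    bonds: List[Tuple[int, int]] = []
    quads: List[Optional[Tuple[int, int, int, int]]] = [None] * instance.m
    g = INTERNAL_GEOMETRY

    def add(name: str, residue: int, xyz: np.ndarray, bond_to: Optional[int]) -> int:
        coords.append(np.asarray(xyz, dtype=float))
        names.append(name)
        resix.append(residue)
        idx = len(coords) - 1
        if bond_to is not None:
            bonds.append((bond_to, idx))
        return idx

    # seed frame: N1 at origin, CA1 on +x, H1 in the xy-plane
    i_n = add("N", 0, np.zeros(3), None)
    i_ca = add("CA", 0, np.array([g[("N", "CA")], 0.0, 0.0]), i_n)
    h_ang = math.radians(ANGLES["H1_N_CA"])
    i_h = add(
        "H1", 0, g[("N", "H1")] * np.array([math.cos(h_ang), math.sin(h_ang), 0.0]), i_n
    )
    phi1 = torsion(0, "phi")
    i_c = add(
        "C", 0,
        place_atom(coords[i_h], coords[i_n], coords[i_ca],
                   g[("CA", "C")], ANGLES["N_CA_C"], phi1),
        i_ca,
    )
    if (0, "phi") in var_index:
        quads[var_index[(0, "phi")]] = (i_h, i_n, i_ca, i_c)

    prev = {"N": i_n, "CA": i_ca, "C": i_c}
    for i in range(n):
        aa = seq[i]
        i_n, i_ca, i_c = prev["N"], prev["CA"], prev["C"]
        # side chain: CB then one pseudo-atom per chi
        if aa != "G":
            i_cb = add(
                "CB", i,
                place_atom(coords[i_c], coords[i_n], coords[i_ca],
                           g[("CA", "CB")], ANGLES["N_CA_CB"], CB_TORSION),
                i_ca,
            )
            chain = [i_n, i_ca, i_cb]
            for k in range(1, CHI_COUNTS[aa] + 1):
                kind = f"chi{k}"
                bond = g[("CB", "SC")] if k == 1 else g[("SC", "SC")]
                ang = ANGLES["CA_CB_SC"] if k == 1 else ANGLES["SC_SC_SC"]
                i_sc = add(
                    f"SC{k}", i,
                    place_atom(coords[chain[-3]], coords[chain[-2]], coords[chain[-1]],
                               bond, ang, torsion(i, kind, 60.0)),
                    chain[-1],
                )
                if (i, kind) in var_index:
                    quads[var_index[(i, kind)]] = (chain[-3], chain[-2], chain[-1], i_sc)
                chain.append(i_sc)
        psi = torsion(i, "psi")
        if i < n - 1:
            # carbonyl oxygen opposite the next backbone nitrogen
            i_o = add(
                "O", i,
                place_atom(coords[i_n], coords[i_ca], coords[i_c],
                           g[("C", "O")], ANGLES["CA_C_O"], psi + 180.0),
                i_c,
            )
            i_n2 = add(
                "N", i + 1,
                place_atom(coords[i_n], coords[i_ca], coords[i_c],
                           g[("C", "N")], ANGLES["CA_C_N"], psi),
                i_c,
            )
            if (i, "psi") in var_index:
                quads[var_index[(i, "psi")]] = (i_n, i_ca, i_c, i_n2)
            omega = torsion(i, "omega")
            i_ca2 = add(
                "CA", i + 1,
                place_atom(coords[i_ca], coords[i_c], coords[i_n2],
                           g[("N", "CA")], ANGLES["C_N_CA"], omega),
                i_n2,
            )
            if (i, "omega") in var_index:
                quads[var_index[(i, "omega")]] = (i_ca, i_c, i_n2, i_ca2)
            phi2 = torsion(i + 1, "phi")
            i_c2 = add(
                "C", i + 1,
                place_atom(coords[i_c], coords[i_n2], coords[i_ca2],
                           g[("CA", "C")], ANGLES["N_CA_C"], phi2),
                i_ca2,
            )
            if (i + 1, "phi") in var_index:
                quads[var_index[(i + 1, "phi")]] = (i_c, i_n2, i_ca2, i_c2)
            prev = {"N": i_n2, "CA": i_ca2, "C": i_c2}
        else:
            # C-terminus: OXT along psi, carbonyl O opposite
            i_oxt = add(
                "OXT", i,
                place_atom(coords[i_n], coords[i_ca], coords[i_c],
                           g[("C", "OXT")], ANGLES["CA_C_OXT"], psi),
                i_c,
            )
            add(
                "O", i,
                place_atom(coords[i_n], coords[i_ca], coords[i_c],
                           g[("C", "O")], ANGLES["CA_C_O"], psi + 180.0),
                i_c,
            )
            if (i, "psi") in var_index:
                quads[var_index[(i, "psi")]] = (i_n, i_ca, i_c, i_oxt)

    if any(q is None for q in quads):
        missing = [instance.variables[k] for k, q in enumerate(quads) if q is None]
        raise RuntimeError(f"internal error: unplaced torsions {missing}")
    return ChainGeometry(
        coords=np.vstack(coords),
        atom_names=names,
        res_index=resix,
        bonds=bonds,
        torsion_quads=[q for q in quads if q is not None],
        torsion_kinds=[v.kind for v in instance.variables],
        torsion_values=np.array(
            [wrap_angle_deg(a) for a in conformation], dtype=float
        ),
    )


def measure_torsions(geometry: ChainGeometry) -> np.ndarray:
    """Re-measure every variable torsion from the built coordinates."""
    return np.array(
        [
            dihedral_deg(*(geometry.coords[i] for i in quad))
            for quad in geometry.torsion_quads
        ]
    )


# ---------------------------------------------------------------------------
# energy

@dataclass
class EnergyParams:
    """Parameters of the reduced four-component energy surrogate."""

    version: str
    lj: Dict[str, Dict[str, float]]            # class -> {eps, rmin}
    charges: Dict[str, float]                  # class -> partial charge
    dielectric: float
    coulomb_constant: float
    torsion: Dict[str, Dict[str, float]]       # kind -> {u0, n, theta0}
    hbond: Dict[str, float]                    # {a, b}
    clash_radius: float = 1e-6
    clash_penalty: float = 1e6

    @classmethod
    def default(cls) -> "EnergyParams":
        text = resources.files("cmqa").joinpath("data/energy_params.yaml").read_text()
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "EnergyParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


ATOM_CLASS = {"N": "N", "CA": "CA", "C": "C", "O": "O", "OXT": "O", "H1": "H"}


def _atom_class(name: str) -> str:
    if name.startswith("SC"):
        return "SC"
    return ATOM_CLASS.get(name, name)


@dataclass
class EnergyBreakdown:
    total: float
    lj: float
    electrostatic: float
    torsion: float
    hbond: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "total": self.total, "lj": self.lj,
            "electrostatic": self.electrostatic,
            "torsion": self.torsion, "hbond": self.hbond,
        }


def _excluded_pairs(n_atoms: int, bonds: List[Tuple[int, int]]) -> set:
    """1-2 and 1-3 pairs from the bond graph."""
    adj: List[set] = [set() for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    excl = set()
    for a, b in bonds:
        excl.add((min(a, b), max(a, b)))
    for j in range(n_atoms):
        for a in adj[j]:
            for b in adj[j]:
                if a < b:
                    excl.add((a, b))
    return excl


def compute_energy(geometry: ChainGeometry, params: Optional[EnergyParams] = None) -> EnergyBreakdown:
    """Evaluate the reduced energy and its four components.

    Hydrogen-bond (N...O) pairs use the 12-10 term in place of Lennard-Jones;
    1-2/1-3 bonded pairs are excluded from all nonbonded sums.  Coincident
    atoms contribute a large finite clash penalty instead of overflowing.
    """
    if params is None:
        params = EnergyParams.default()
    n = geometry.n_atoms
    classes = [_atom_class(a) for a in geometry.atom_names]
    excl = _excluded_pairs(n, geometry.bonds)

    dmat = squareform(pdist(geometry.coords))
    e_lj = e_el = e_hb = 0.0
    n_clash = 0
    for i in range(n):
        ci = classes[i]
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            cj = classes[j]
            r = dmat[i, j]
            if r < params.clash_radius:
                e_lj += params.clash_penalty
                n_clash += 1
                continue
            qq = params.charges[ci] * params.charges[cj]
            if qq != 0.0:
                e_el += params.coulomb_constant * qq / (params.dielectric * r)
            is_hb = (ci == "N" and cj == "O") or (ci == "O" and cj == "N")
            if is_hb:
                e_hb += params.hbond["a"] / r**12 - params.hbond["b"] / r**10
            else:
                pi, pj = params.lj[ci], params.lj[cj]
                a_i = pi["eps"] * pi["rmin"] ** 12
                b_i = 2.0 * pi["eps"] * pi["rmin"] ** 6
                a_j = pj["eps"] * pj["rmin"] ** 12
                b_j = 2.0 * pj["eps"] * pj["rmin"] ** 6
                a_ij = math.sqrt(a_i * a_j)
                b_ij = math.sqrt(b_i * b_j)
                e_lj += a_ij / r**12 - b_ij / r**6
    if n_clash:
        logger.warning("%d coincident atom pairs; clash penalty applied", n_clash)

    e_tor = 0.0
    for kind, theta in zip(geometry.torsion_kinds, geometry.torsion_values):
        base = "chi" if kind.startswith("chi") else kind
        p = params.torsion[base]
        e_tor += 0.5 * p["u0"] * (
            1.0 + math.cos(math.radians(p["n"] * theta - p["theta0"]))
        )

    total = e_lj + e_el + e_tor + e_hb
    return EnergyBreakdown(total=total, lj=e_lj, electrostatic=e_el,
                           torsion=e_tor, hbond=e_hb)


class ProteinLandscape:
    """Adapter: a protein instance plus energy parameters as a landscape."""

    def __init__(self, instance: ProteinInstance, params: Optional[EnergyParams] = None):
        self.instance = instance
        self.params = params if params is not None else EnergyParams.default()
        self.m = instance.m

    def energy(self, angles: np.ndarray) -> float:
        geom = build_coordinates(self.instance, np.asarray(angles, dtype=float))
        return compute_energy(geom, self.params).total

    def random_conformation(self, rng: np.random.Generator) -> np.ndarray:
        from .moves import random_conformation

        return random_conformation(self.m, rng)


# ---------------------------------------------------------------------------
# dRMSD

def drmsd(a, b, atom_selection: str = "CA") -> float:
    """Distance RMSD between two structures.

    sqrt( (2 / (N(N-1))) * sum_{i<j} (d_ij^A - d_ij^B)^2 ) over the selected
    atoms; superposition-free, hence invariant under rigid motion and
    reflection of either structure.  Accepts ChainGeometry objects or raw
    (N, 3) coordinate arrays.
    """
    xa = a.select(atom_selection) if isinstance(a, ChainGeometry) else np.asarray(a, float)
    xb = b.select(atom_selection) if isinstance(b, ChainGeometry) else np.asarray(b, float)
    if xa.shape != xb.shape or xa.ndim != 2 or xa.shape[1] != 3:
        raise ValueError(f"mismatched structures: {xa.shape} vs {xb.shape}")
    if xa.shape[0] < 3:
        raise ValueError("need at least 3 atoms for dRMSD")
    da, db = pdist(xa), pdist(xb)
    return float(np.sqrt(np.mean((da - db) ** 2)))


# ---------------------------------------------------------------------------
# file formats

def read_fasta(path, record: Optional[str] = None) -> Tuple[str, str]:
    """Read one sequence from a FASTA file (first record unless named)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record]
        if not matches:
            raise ValueError(f"no record {record!r} in {path}")
        rec = matches[0]
    return rec.id, str(rec.seq).upper()


def write_pdb(geometry: ChainGeometry, sequence: str, path) -> None:
    """Write the structure as a PDB file (pseudo side-chain atoms as carbons)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    from Bio.SeqUtils import seq3

    n = geometry.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(geometry.coords, dtype=np.float32)
    atoms.chain_id = np.array(["A"] * n)
    atoms.res_id = np.array([r + 1 for r in geometry.res_index])
    atoms.res_name = np.array(
        [seq3(sequence[r]).upper() for r in geometry.res_index]
    )
    atoms.atom_name = np.array(geometry.atom_names)
    atoms.element = np.array(
        [
            "N" if a == "N" else "O" if a in ("O", "OXT") else "H" if a == "H1" else "C"
            for a in geometry.atom_names
        ]
    )
    atoms.occupancy = np.ones(n)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb_coords(path, atom_name: str = "CA") -> np.ndarray:
    """Read coordinates of one atom type from a PDB file (e.g. a reference)."""
    from biotite.structure.io.pdb import PDBFile

    structure = PDBFile.read(str(path)).get_structure(model=1)
    sel = structure[structure.atom_name == atom_name]
    if sel.array_length() == 0:
        raise ValueError(f"no {atom_name} atoms in {path}")
    return np.asarray(sel.coord, dtype=float)
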