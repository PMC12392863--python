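"""Helical symmetry arithmetic and fibril assembly.

Amyloid fibrils are helical polymers: each symmetry unit is related to the
next by an axial translation (the *rise*, in Å) and a rotation about the
fibril axis (the *twist*, in degrees).  Negative twist denotes a left-handed
helix.  Two derived lengths matter experimentally: the *crossover distance*
(axial length of a full 360° turn, visible in EM as the repeat of the
projected width) and the *half-twist period* (crossover / 2, the apparent
height-modulation period of a twisted fibril lying on a surface, as measured
by AFM).

This module also builds long fibril models from a single monomer by applying
the screw symmetry repeatedly, and computes the optimal superposition RMSD
between two atom sets (Kabsch algorithm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "HelicalParams",
    "AtomicModel",
    "crossover_distance",
    "half_period_nm",
    "compose_symmetry",
    "build_helical_assembly",
    "kabsch_rmsd",
    "principal_axis_to_z",
    "read_structure",
    "write_structure",
]


@dataclass(frozen=True)
class HelicalParams:
    """Screw symmetry of a helical fibril: rise in Å, twist in degrees."""

    rise_A: float
    twist_deg: float

    def __post_init__(self) -> None:
        if not self.rise_A > 0:
            raise ValueError(f"rise_A must be positive, got {self.rise_A}")
        if not -180.0 <= self.twist_deg <= 180.0:
            raise ValueError(
                f"twist_deg must lie in [-180, 180], got {self.twist_deg}"
            )

    @property
    def handedness(self) -> str:
        """'left' for negative twist, 'right' for positive, 'none' for zero."""
        if self.twist_deg < 0:
            return "left"
        if self.twist_deg > 0:
            return "right"
        return "none"


@dataclass
class AtomicModel:
    """A minimal explicit-atom (or pseudo-atom) model.

    coords are in Å.  ``f`` optionally carries per-atom excess scattering
    lengths (electron units) for solution-scattering calculations.
    """

    coords: np.ndarray  # (N, 3) float
    elements: list[str] = field(default_factory=list)
    chain_ids: list[str] = field(default_factory=list)
    residue_ids: list[int] = field(default_factory=list)
    residue_names: list[str] = field(default_factory=list)
    f: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = len(self.coords)
        if n < 1:
            raise ValueError("AtomicModel needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if not self.elements:
            self.elements = ["C"] * n
        if not self.chain_ids:
            self.chain_ids = ["A"] * n
        if not self.residue_ids:
            self.residue_ids = [1] * n
        if not self.residue_names:
            self.residue_names = ["UNK"] * n
        for name, lst in (
            ("elements", self.elements),
            ("chain_ids", self.chain_ids),
            ("residue_ids", self.residue_ids),
            ("residue_names", self.residue_names),
        ):
            if len(lst) != n:
                raise ValueError(f"{name} length {len(lst)} != atom count {n}")
        if self.f is not None:
            self.f = np.asarray(self.f, dtype=float)
            if self.f.shape != (n,):
                raise ValueError("f must be a length-N vector")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


def crossover_distance(p: HelicalParams) -> float:
    """Axial length (Å) of a full 360° turn: rise × 360 / |twist|.

    For the single-layer symmetry (4.8 Å, −2°) this is 864 Å; the
    three-layer symmetry (14.4 Å, −6°) gives the same crossover, as it must.
    """
    if p.twist_deg == 0:
        raise ValueError("zero twist: crossover distance is infinite")
    return p.rise_A * 360.0 / abs(p.twist_deg)


def half_period_nm(p: HelicalParams) -> float:
    """Half-twist period in nm — the height-modulation period seen by AFM.

    A twisted fibril adsorbed on a surface looks the same after rotating
    180°, so its apparent period is crossover / 2.
    """
    return crossover_distance(p) / 2.0 / 10.0


def _wrap_angle(deg: float) -> float:
    """Wrap an angle to [−180, 180)."""
    return float((deg + 180.0) % 360.0 - 180.0)


def compose_symmetry(p: HelicalParams, n_units: int) -> HelicalParams:
    """Symmetry relating unit k to unit k+n: (rise·n, twist·n wrapped).

    Composing the per-layer symmetry three times turns (4.8 Å, −2°) into the
    per-monomer symmetry (14.4 Å, −6°); the crossover distance is invariant.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return HelicalParams(p.rise_A * n_units, _wrap_angle(p.twist_deg * n_units))


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    # positive twist = right-handed rotation about +z viewed from +z
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_helical_assembly(
    monomer: AtomicModel, p: HelicalParams, n_copies: int
) -> AtomicModel:
    """Stack ``n_copies`` of ``monomer`` by the screw symmetry ``p``.

    Copy k is the monomer rotated about z by k·twist and translated by
    k·rise along z.  The fibril axis must already be the z axis of the
    input frame (see :func:`principal_axis_to_z`).  Chain ids are made
    unique by suffixing the copy index.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    blocks = []
    for k in range(n_copies):
        xyz = monomer.coords @ _rot_z(k * p.twist_deg).T
        xyz[:, 2] += k * p.rise_A
        blocks.append(xyz)
    coords = np.vstack(blocks)
    n = monomer.n_atoms
    chain_ids = [
        f"{cid}{k}" if n_copies > 1 else cid
        for k in range(n_copies)
        for cid in monomer.chain_ids
    ]
    return AtomicModel(
        coords=coords,
        elements=monomer.elements * n_copies,
        chain_ids=chain_ids,
        residue_ids=monomer.residue_ids * n_copies,
        residue_names=monomer.residue_names * n_copies,
        f=None if monomer.f is None else np.tile(monomer.f, n_copies),
    )


def _as_coords(x) -> np.ndarray:
    if isinstance(x, AtomicModel):
        return x.coords
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected an (N, 3) coordinate array or AtomicModel")
    return a


def kabsch_rmsd(a, b, pairing: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Minimal RMSD (Å) between two paired atom sets over rigid motions.

    The optimal rotation is obtained from the SVD of the covariance matrix
    with the determinant sign corrected so only proper rotations are used.
    ``pairing`` optionally gives index arrays (ia, ib) selecting matched
    atoms; otherwise atoms are paired in order and the counts must agree.
    """
    P = _as_coords(a)
    Q = _as_coords(b)
    if pairing is not None:
        ia, ib = pairing
        P, Q = P[np.asarray(ia)], Q[np.asarray(ib)]
    if len(P) != len(Q):
        raise ValueError(f"atom counts differ after pairing: {len(P)} vs {len(Q)}")
    if len(P) < 3:
        raise ValueError("need at least 3 paired atoms")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear/degenerate sets have covariance rank < 2: rotation ill-defined
    if min(np.linalg.matrix_rank(Pc, tol=1e-9), np.linalg.matrix_rank(Qc, tol=1e-9)) < 2:
        raise ValueError("degenerate (collinear) point set: superposition undefined")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Qc - Pc @ R.T
    return float(np.sqrt((diff**2).sum() / len(P)))


def principal_axis_to_z(model: AtomicModel) -> AtomicModel:
    """Return a copy rotated so the longest principal axis lies along +z.

    Helper for callers whose monomer frame is arbitrary; assembly assumes
    the fibril axis is z.
    """
    xyz = model.coords - model.coords.mean(axis=0)
    cov = xyz.T @ xyz
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(axis, z))
    if np.isclose(abs(c), 1.0):
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        k = np.cross(axis, z)
        s = np.linalg.norm(k)
        K = np.array(
            [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
        ) / s
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
    out = replace(model)
    out.coords = xyz @ R.T
    return out


# ---------------------------------------------------------------------------
# structure I/O (gemmi)


def read_structure(path: str | Path) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`."""
    import gemmi

    st = gemmi.read_structure(str(path))
    coords, elements, chain_ids, res_ids, res_names = [], [], [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements.append(atom.element.name)
                    chain_ids.append(chain.name)
                    res_ids.append(res.seqid.num)
                    res_names.append(res.name)
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    return AtomicModel(
        coords=np.array(coords),
        elements=elements,
        chain_ids=chain_ids,
        residue_ids=res_ids,
        residue_names=res_names,
    )


def write_structure(model: AtomicModel, path: str | Path) -> None:
    """Write an :class:`AtomicModel` as PDB (.pdb) or mmCIF (.cif).

    PDB chain ids are limited to two characters; assemblies with many copies
    should be written as mmCIF.
    """
    import gemmi

    path = Path(path)
    st = gemmi.Structure()
    st.name = "fapkit"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for i in range(model.n_atoms):
        cid = model.chain_ids[i]
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        ch = chains[cid]
        rid = model.residue_ids[i]
        if len(ch) == 0 or ch[-1].seqid.num != rid:
            res = gemmi.Residue()
            res.name = model.residue_names[i]
            res.seqid = gemmi.SeqId(rid, " ")
            ch.add_residue(res)
        atom = gemmi.Atom()
        atom.name = model.elements[i]
        atom.element = gemmi.Element(model.elements[i])
        x, y, z = model.coords[i]
        atom.pos = gemmi.Position(x, y, z)
        ch[-1].add_atom(atom)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    if path.suffix.lower() == ".pdb":
        if any(len(c) > 2 for c in chains):
            raise ValueError("chain ids too long for PDB; write mmCIF (.cif)")
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
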