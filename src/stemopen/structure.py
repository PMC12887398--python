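"""Structural observables of the 15-mer RNA hairpin.

Three collective variables quantify whether the hairpin stem (residues 1-4
paired with 12-15 of ACGGAAAGACCCCGU) is formed:

* :func:`kabsch_rmsd` — backbone RMSD after least-squares rigid
  superposition (rotation + translation, reflections excluded).
* :func:`coordination_number` — the inter-group contact count
  ``CN = sum_{i in A} sum_{j in B} s(r_ij)`` with the rational switching
  function ``s(r) = [1-((r-d0)/r0)^6] / [1-((r-d0)/r0)^12]`` and cutoff
  r0 = 3.0 A. The function is 1 at contact, 1/2 at r = d0 + r0 (the
  removable singularity's analytic limit), and decays as r^-6.
* :func:`base_pair_distances` — per-stem-pair distances between
  base-centroid pseudo-atoms.

Conformers carry a minimal named-atom representation (backbone atoms plus
one base-centroid pseudo-atom "BC" per residue); they read and write
single- and multi-model PDB through biotite. Coordinates are angstrom,
residue indices 1-based along the 15-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Conformer",
    "CVSeries",
    "BACKBONE_ATOMS",
    "STEM_GROUP_A",
    "STEM_GROUP_B",
    "STEM_PAIRING",
    "RNA15_SEQUENCE",
    "kabsch_superpose",
    "kabsch_rmsd",
    "switching_value",
    "coordination_number",
    "base_pair_distances",
    "compute_cv_series",
    "write_colvar",
    "read_colvar",
]

RNA15_SEQUENCE = "ACGGAAAGACCCCGU"
N_RESIDUES = 15
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
CENTROID_ATOM = "BC"  # base-centroid pseudo-atom
STEM_GROUP_A = frozenset(range(1, 5))
STEM_GROUP_B = frozenset(range(12, 16))
STEM_PAIRING = ((1, 15), (2, 14), (3, 13), (4, 12))


@dataclass
class Conformer:
    """Named-atom coordinates of one 15-mer conformer."""

    atom_names: list[str]
    residue_indices: np.ndarray
    elements: list[str]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if self.residue_indices.shape != (n,) or self.coords.shape != (n, 3):
            raise ValueError("inconsistent atom array lengths")
        if len(self.elements) != n:
            raise ValueError("inconsistent atom array lengths")
        if n and (self.residue_indices.min() < 1 or self.residue_indices.max() > N_RESIDUES):
            raise ValueError(f"residue indices must lie in [1, {N_RESIDUES}]")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.atom_names)

    def select(
        self,
        residues: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(len(self), dtype=bool)
        if residues is not None:
            mask &= np.isin(self.residue_indices, list(residues))
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.fromiter((a in names for a in self.atom_names), bool, len(self))
        return mask

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        return Conformer(
            list(self.atom_names),
            self.residue_indices.copy(),
            list(self.elements),
            self.coords @ rotation.T + translation,
            self.label,
        )

    # --- PDB I/O -----------------------------------------------------------

    def to_atom_array(self) -> struc.AtomArray:
        n = len(self)
        arr = struc.AtomArray(n)
        arr.coord = self.coords.astype(np.float32)
        arr.chain_id = np.full(n, "A")
        arr.res_id = self.residue_indices
        arr.res_name = np.array([RNA15_SEQUENCE[i - 1] for i in self.residue_indices])
        arr.atom_name = np.array(self.atom_names)
        arr.element = np.array(self.elements)
        arr.hetero = np.array([a == CENTROID_ATOM for a in self.atom_names])
        return arr

    @classmethod
    def from_atom_array(cls, arr: struc.AtomArray, label: str = "") -> "Conformer":
        return cls(
            list(arr.atom_name),
            np.asarray(arr.res_id, dtype=int),
            list(arr.element),
            np.asarray(arr.coord, dtype=float),
            label,
        )

    def to_pdb(self, path: str | Path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.to_atom_array())
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path: str | Path, model: int = 1, label: str = "") -> "Conformer":
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=model)
        return cls.from_atom_array(arr, label=label or Path(path).stem)


def write_trajectory_pdb(conformers: Sequence[Conformer], path: str | Path) -> None:
    """Multi-model PDB for a toy trajectory."""
    stack = struc.stack([c.to_atom_array() for c in conformers])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory_pdb(path: str | Path) -> list[Conformer]:
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        return [Conformer.from_atom_array(stack)]
    return [Conformer.from_atom_array(stack[i]) for i in range(stack.stack_depth())]


# --- RMSD -------------------------------------------------------------------


def _matched_coords(
    mobile: Conformer, reference: Conformer, selection: Iterable[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    names = set(selection) if selection is not None else None

    def keyed(conf: Conformer) -> dict[tuple[int, str], np.ndarray]:
        out = {}
        for name, rid, xyz in zip(conf.atom_names, conf.residue_indices, conf.coords):
            if names is None or name in names:
                key = (int(rid), name)
                if key in out:
                    raise ValueError(f"duplicate atom {key} in conformer")
                out[key] = xyz
        return out

    a = keyed(mobile)
    b = keyed(reference)
    if set(a) != set(b):
        raise ValueError(
            "selections do not match one-to-one between mobile and reference "
            f"({len(set(a) ^ set(b))} unpaired atoms)"
        )
    if not a:
        raise ValueError("empty selection")
    keys = sorted(a)
    return np.array([a[k] for k in keys]), np.array([b[k] for k in keys])


def kabsch_superpose(
    mobile_xyz: np.ndarray, reference_xyz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired coordinate sets.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ R.T + t`` best matches the reference in the least-squares
    sense. The determinant sign of the SVD solution is corrected so that
    only proper rotations (no reflections) are returned.
    """
    X = np.asarray(mobile_xyz, float)
    Y = np.asarray(reference_xyz, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    X0 = X - xc
    Y0 = Y - yc
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = X0 @ R.T - Y0
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def kabsch_rmsd(
    mobile: Conformer,
    reference: Conformer,
    selection: Iterable[str] | None = BACKBONE_ATOMS,
) -> float:
    """Backbone (or custom-selection) RMSD after optimal rigid superposition."""
    X, Y = _matched_coords(mobile, reference, selection)
    return kabsch_superpose(X, Y)[2]


# --- Switching-function coordination number ---------------------------------


def switching_value(
    r: float | np.ndarray, d0: float = 0.0, r0: float = 3.0
) -> float | np.ndarray:
    """Rational contact switching function, value in (0, 1].

    s(r) = [1 - x^6] / [1 - x^12] with x = (r - d0)/r0, algebraically equal
    to 1/(1 + x^6) for x != 1 and to the analytic limit 1/2 at x = 1, which
    the simplified form returns without a special case. Distances at or
    inside the contact offset (r <= d0) count as full contacts (s = 1).
    """
    if r0 <= 0:
        raise ValueError(f"r0 must be positive, got {r0}")
    x = (np.asarray(r, dtype=float) - d0) / r0
    x = np.clip(x, 0.0, None)  # r <= d0 -> full contact
    val = 1.0 / (1.0 + x**6)
    if val.ndim == 0:
        return float(val)
    return val


def coordination_number(
    conf: Conformer,
    group_a: Iterable[int] = STEM_GROUP_A,
    group_b: Iterable[int] = STEM_GROUP_B,
    d0: float = 0.0,
    r0: float = 3.0,
    atom_names: Iterable[str] | None = None,
) -> float:
    """Total stem coordination number between two residue groups.

    Sums the switching function over every cross-group atom pair of the
    configured selection (default: all atoms of the residues, i.e. heavy
    backbone atoms plus the base centroid; pass ``atom_names={"BC"}`` for a
    base-only variant). Groups must be disjoint and nonempty.
    """
    ga = set(int(i) for i in group_a)
    gb = set(int(i) for i in group_b)
    if not ga or not gb:
        raise ValueError("groups must be nonempty")
    if ga & gb:
        raise ValueError(f"groups must be disjoint, overlap {sorted(ga & gb)}")
    mask_a = conf.select(residues=ga, atom_names=atom_names)
    mask_b = conf.select(residues=gb, atom_names=atom_names)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("empty atom selection in one of the groups")
    xa = conf.coords[mask_a]
    xb = conf.coords[mask_b]
    diff = xa[:, None, :] - xb[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    return float(np.sum(switching_value(dist, d0=d0, r0=r0)))


def base_pair_distances(
    conf: Conformer,
    pairing: Sequence[tuple[int, int]] = STEM_PAIRING,
    centroid_atom: str = CENTROID_ATOM,
) -> np.ndarray:
    """Distance between base-centroid pseudo-atoms for each stem pair."""
    centroids: dict[int, np.ndarray] = {}
    for name, rid, xyz in zip(conf.atom_names, conf.residue_indices, conf.coords):
        if name == centroid_atom:
            centroids[int(rid)] = xyz
    out = []
    for i, j in pairing:
        if not (1 <= i <= N_RESIDUES and 1 <= j <= N_RESIDUES):
            raise ValueError(f"pair ({i}, {j}) outside residue range 1..{N_RESIDUES}")
        if i not in centroids or j not in centroids:
            raise ValueError(f"missing {centroid_atom} pseudo-atom for pair ({i}, {j})")
        out.append(float(np.linalg.norm(centroids[i] - centroids[j])))
    return np.array(out)


# --- CV series over trajectories --------------------------------------------


@dataclass
class CVSeries:
    """Collective-variable trace over trajectory frames."""

    frames: np.ndarray
    rmsd: np.ndarray
    cn: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.cn = np.asarray(self.cn, dtype=float)
        if not (self.frames.shape == self.rmsd.shape == self.cn.shape):
            raise ValueError("frame, rmsd and cn arrays must have equal length")
        if np.any(self.rmsd < 0) or np.any(self.cn < 0):
            raise ValueError("rmsd and cn must be nonnegative")


def compute_cv_series(
    conformers: Sequence[Conformer],
    reference: Conformer,
    selection: Iterable[str] | None = BACKBONE_ATOMS,
    d0: float = 0.0,
    r0: float = 3.0,
    atom_names: Iterable[str] | None = None,
) -> CVSeries:
    """Evaluate (RMSD-to-reference, stem CN) on every frame."""
    rmsds = [kabsch_rmsd(c, reference, selection=selection) for c in conformers]
    cns = [coordination_number(c, d0=d0, r0=r0, atom_names=atom_names) for c in conformers]
    return CVSeries(np.arange(len(conformers)), np.array(rmsds), np.array(cns))


def write_colvar(series: CVSeries, path: str | Path, dt: float = 1.0) -> None:
    """COLVAR-dialect text: '#! FIELDS time rmsd cn'."""
    with Path(path).open("w") as fh:
        fh.write("#! FIELDS time rmsd cn\n")
        for f, r, c in zip(series.frames, series.rmsd, series.cn):
            fh.write(f"{f * dt:.6f} {r:.6f} {c:.6f}\n")


def read_colvar(path: str | Path) -> CVSeries:
    times, rmsd, cn = [], [], []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            t, r, c = line.split()[:3]
            times.append(float(t))
            rmsd.append(float(r))
            cn.append(float(c))
    return CVSeries(np.arange(len(times)), np.array(rmsd), np.array(cn))
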