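"""Trajectory statistics: superposition, RMSD/RMSF, H-bonds, secondary
structure and inter-segment distances.

All metrics operate on a :class:`Trajectory` — an ordered stack of frames
over a fixed atom table — and a set of named 1-based residue selections.
They apply equally to one-bead-per-residue coarse-grained ensembles and to
all-atom backbones read from multi-model PDB files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ResidueSelection",
    "HBondCriterion",
    "SelectionError",
    "kabsch_superpose",
    "subset_rmsd",
    "rmsf",
    "hbond_occupancy",
    "secondary_structure_fraction",
    "segment_distance",
    "radius_of_gyration",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
]


class SelectionError(ValueError):
    """A residue selection could not be resolved against a trajectory."""


@dataclass(frozen=True)
class ResidueSelection:
    """A named set of 1-based residue ids."""

    name: str
    residue_ids: tuple

    def __post_init__(self):
        ids = tuple(sorted(set(int(i) for i in self.residue_ids)))
        if not ids:
            raise SelectionError(f"selection {self.name!r} is empty")
        object.__setattr__(self, "residue_ids", ids)

    def __len__(self):
        return len(self.residue_ids)


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond test.

    ``max_distance`` (Angstrom) applies between the hydrogen and the
    acceptor by default (``mode='hydrogen'``); ``mode='heavy'`` measures
    from the donor heavy atom instead.  ``min_angle`` is the
    donor–H–acceptor angle in degrees.
    """

    max_distance: float = 3.6
    min_angle: float = 135.0
    acceptor_elements: tuple = ("C", "O", "N", "F", "S")
    mode: str = "hydrogen"

    def __post_init__(self):
        if not self.max_distance > 0:
            raise ValueError("max_distance must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("min_angle must be in (0, 180]")
        if self.mode not in ("hydrogen", "heavy"):
            raise ValueError("mode must be 'hydrogen' or 'heavy'")


class Trajectory:
    """Ordered frames of coordinates over a fixed atom table.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
    residue_ids : int array (n_atoms,)
        1-based residue numbering (BIR2 convention 163..234 for the
        packaged model, but arbitrary ids are accepted).
    residue_names, atom_names, elements : sequence of str, optional
    frame_stride : int
        Number of integrator steps between stored frames (metadata only).
    """

    def __init__(self, coords, residue_ids, residue_names=None,
                 atom_names=None, elements=None, frame_stride: int = 1):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_atoms = coords.shape[1]
        residue_ids = np.asarray(residue_ids, dtype=int)
        if residue_ids.shape != (n_atoms,):
            raise ValueError("residue_ids must match the atom count")
        self.coords = coords
        self.residue_ids = residue_ids
        self.residue_names = list(residue_names) if residue_names is not None \
            else ["ALA"] * n_atoms
        self.atom_names = list(atom_names) if atom_names is not None \
            else ["CA"] * n_atoms
        self.elements = list(elements) if elements is not None \
            else [a[:1] for a in self.atom_names]
        self.frame_stride = int(frame_stride)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self):
        return self.n_frames

    def atom_index(self, residue_id: int, atom_name: str) -> int:
        hits = np.nonzero((self.residue_ids == residue_id)
                          & (np.asarray(self.atom_names) == atom_name))[0]
        if hits.size != 1:
            raise SelectionError(
                f"atom {atom_name!r} of residue {residue_id}: "
                f"{hits.size} matches")
        return int(hits[0])

    def resolve(self, selection, atom_names=None) -> np.ndarray:
        """Atom indices for a selection (ResidueSelection or iterable of ids)."""
        ids = selection.residue_ids if isinstance(selection, ResidueSelection) \
            else tuple(selection)
        name = selection.name if isinstance(selection, ResidueSelection) else "ids"
        mask = np.isin(self.residue_ids, ids)
        if atom_names is not None:
            mask &= np.isin(np.asarray(self.atom_names), atom_names)
        missing = sorted(set(ids) - set(self.residue_ids[mask]))
        if missing:
            raise SelectionError(
                f"selection {name!r}: residues {missing} not present")
        return np.nonzero(mask)[0]

    def slice_frames(self, start=None, stop=None, step=None) -> "Trajectory":
        sl = slice(start, stop, step)
        return Trajectory(self.coords[sl], self.residue_ids,
                          self.residue_names, self.atom_names, self.elements,
                          self.frame_stride * (step or 1))


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(mobile, reference, fit_indices=None):
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(rotation, translation, rmsd_after_fit)`` such that
    ``mobile @ rotation.T + translation`` optimally matches ``reference``
    over the fitted points.  A reflection is excluded by the determinant
    correction.  Degenerate (collinear) fit sets raise ``ValueError``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("mobile and reference must be (n, 3) with equal n")
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    if idx.size < 3:
        raise ValueError("need at least 3 fitted points")
    p = mobile[idx]
    q = reference[idx]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(((moved - q) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def subset_rmsd(traj: Trajectory, reference, fit_selection,
                measure_selection, atom_names=None) -> np.ndarray:
    """Per-frame RMSD over ``measure_selection`` after fitting each frame
    to the reference over ``fit_selection``.

    ``reference`` is an (n_atoms, 3) coordinate set sharing the
    trajectory's atom table (typically the initial structure).
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference must match the trajectory atom table")
    fit_idx = traj.resolve(fit_selection, atom_names)
    meas_idx = traj.resolve(measure_selection, atom_names)
    out = np.empty(traj.n_frames)
    ref_meas = reference[meas_idx]
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coords[f], reference, fit_idx)
        moved = traj.coords[f][meas_idx] @ rot.T + trans
        out[f] = np.sqrt(((moved - ref_meas) ** 2).sum(axis=1).mean())
    return out


def rmsf(traj: Trajectory, selection, fit_selection=None,
         atom_names=None) -> pd.Series:
    """Per-residue RMSF about the mean structure.

    Frames are first superposed on frame 0 over ``fit_selection``
    (default: all atoms), the mean structure is formed, every frame is
    re-superposed on that mean once, and RMSF_i = sqrt(<|r_i - <r_i>|^2>)
    is computed on the selection.  Returns a Series indexed by residue id.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_sel = fit_selection if fit_selection is not None \
        else ResidueSelection("all", tuple(np.unique(traj.residue_ids)))
    fit_idx = traj.resolve(fit_sel, atom_names)
    sel_idx = traj.resolve(selection, atom_names)

    aligned = np.empty_like(traj.coords)
    ref = traj.coords[0]
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coords[f], ref, fit_idx)
        aligned[f] = traj.coords[f] @ rot.T + trans
    mean1 = aligned.mean(axis=0)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(aligned[f], mean1, fit_idx)
        aligned[f] = aligned[f] @ rot.T + trans
    mean2 = aligned.mean(axis=0)
    fluct = np.sqrt(((aligned - mean2) ** 2).sum(axis=2).mean(axis=0))
    return pd.Series(fluct[sel_idx], index=traj.residue_ids[sel_idx],
                     name="rmsf")


# ---------------------------------------------------------------------------
# hydrogen bonds


def hbond_occupancy(traj: Trajectory, donor, acceptor,
                    criterion: HBondCriterion = HBondCriterion(),
                    surrogate_cutoff: float | None = None):
    """Hydrogen-bond occupancy (%) and per-frame presence.

    Two modes:

    * geometric — ``donor`` is ``(residue_id, heavy_atom, hydrogen_atom)``
      and ``acceptor`` is ``(residue_id, atom_name)``; a frame counts when
      the distance (hydrogen-to-acceptor by default) is <= max_distance
      and the donor–H–acceptor angle is >= min_angle.  The acceptor
      element must be one of the allowed set.
    * coarse-grained surrogate — ``donor`` and ``acceptor`` are plain
      residue ids of a one-bead-per-residue ensemble; presence is a pure
      distance test at ``surrogate_cutoff`` (Angstrom), standing in for
      the geometric criterion that bead models cannot express.
    """
    if isinstance(donor, (int, np.integer)):
        if surrogate_cutoff is None:
            raise ValueError("surrogate_cutoff required for bead-pair mode")
        i = traj.resolve((int(donor),))
        j = traj.resolve((int(acceptor),))
        if i.size != 1 or j.size != 1:
            raise SelectionError("bead-pair mode needs one bead per residue")
        dist = np.linalg.norm(traj.coords[:, i[0]] - traj.coords[:, j[0]],
                              axis=1)
        present = dist <= surrogate_cutoff
        return 100.0 * present.mean(), present

    d_res, d_heavy, d_hyd = donor
    a_res, a_name = acceptor
    ai = traj.atom_index(a_res, a_name)
    elem = traj.elements[ai].upper()
    if elem not in tuple(e.upper() for e in criterion.acceptor_elements):
        raise ValueError(
            f"acceptor element {elem!r} outside allowed set "
            f"{criterion.acceptor_elements}")
    di = traj.atom_index(d_res, d_heavy)
    hi = traj.atom_index(d_res, d_hyd)

    h = traj.coords[:, hi]
    d = traj.coords[:, di]
    a = traj.coords[:, ai]
    ref = h if criterion.mode == "hydrogen" else d
    dist = np.linalg.norm(a - ref, axis=1)
    v1 = d - h
    v2 = a - h
    cosang = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    present = (dist <= criterion.max_distance) & (angle >= criterion.min_angle)
    return 100.0 * present.mean(), present


# ---------------------------------------------------------------------------
# secondary structure (virtual C-alpha geometry)

# Window thresholds for the bead/C-alpha classifier.  An ideal alpha-helix
# trace has bend angle ~91 deg and pseudo-dihedral ~+50 deg; an extended
# beta strand ~120 deg / ~180 deg.
HELIX_ANGLE = (75.0, 108.0)
HELIX_DIHEDRAL = (25.0, 100.0)
SHEET_ANGLE = (100.0, 155.0)
SHEET_DIHEDRAL_MIN = 120.0
CHAIN_BREAK_DISTANCE = 4.5


def _angles_dihedrals(coords):
    """Bend angle at each interior bead and pseudo-dihedral i-1..i+2."""
    b = np.diff(coords, axis=1)  # (F, n-1, 3)
    u = b[:, :-1]
    v = b[:, 1:]
    # bend angle at bead i between the vectors to its two neighbours
    cosang = (u * -v).sum(-1) / (np.linalg.norm(u, axis=-1)
                                 * np.linalg.norm(v, axis=-1))
    theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    n1 = np.cross(b[:, :-2], b[:, 1:-1])
    n2 = np.cross(b[:, 1:-1], b[:, 2:])
    m = np.cross(n1, b[:, 1:-1] / np.linalg.norm(b[:, 1:-1], axis=-1,
                                                 keepdims=True))
    x = (n1 * n2).sum(-1)
    y = (m * n2).sum(-1)
    # sign convention: a right-handed alpha-helical trace gives phi ~ +50
    phi = np.degrees(np.arctan2(-y, x))
    return theta, phi


def secondary_structure_fraction(traj: Trajectory,
                                 selection=None) -> pd.DataFrame:
    """Per-residue {helix, sheet, coil} fractions over frames.

    Residues are classified per frame from the local virtual C-alpha
    geometry: the bend angle at the residue and the pseudo-dihedral of the
    four consecutive beads starting one before it.  Chain termini and
    residues flanking a chain break (consecutive-bead distance above
    4.5 Angstrom) are coil.  Fractions sum to 1 per residue.
    """
    order = np.argsort(traj.residue_ids, kind="stable")
    ids = traj.residue_ids[order]
    if len(np.unique(ids)) != len(ids):
        raise ValueError("secondary structure needs one bead per residue")
    if len(ids) < 4:
        raise ValueError("need at least 4 consecutive residues")
    coords = traj.coords[:, order]
    sel_ids = (selection.residue_ids if isinstance(selection, ResidueSelection)
               else tuple(selection) if selection is not None else tuple(ids))

    theta, phi = _angles_dihedrals(coords)
    n = len(ids)
    helix = np.zeros((traj.n_frames, n), dtype=bool)
    sheet = np.zeros((traj.n_frames, n), dtype=bool)
    # residue at position i (1 <= i <= n-3) reads theta[:, i-1], phi[:, i-1]
    th = theta[:, : n - 3]
    ph = phi[:, : n - 3]
    hel = ((th >= HELIX_ANGLE[0]) & (th <= HELIX_ANGLE[1])
           & (ph >= HELIX_DIHEDRAL[0]) & (ph <= HELIX_DIHEDRAL[1]))
    sht = ((th >= SHEET_ANGLE[0]) & (th <= SHEET_ANGLE[1])
           & (np.abs(ph) >= SHEET_DIHEDRAL_MIN))
    helix[:, 1: n - 2] = hel
    sheet[:, 1: n - 2] = sht & ~hel

    gaps = (np.diff(ids) != 1) | (np.linalg.norm(
        np.diff(coords, axis=1), axis=-1) > CHAIN_BREAK_DISTANCE).any(axis=0)
    if gaps.any():
        warnings.warn("chain break detected: flanking residues set to coil",
                      stacklevel=2)
        for k in np.nonzero(gaps)[0]:
            helix[:, max(k - 1, 0): k + 2] = False
            sheet[:, max(k - 1, 0): k + 2] = False

    frac_h = helix.mean(axis=0)
    frac_s = sheet.mean(axis=0)
    df = pd.DataFrame({"helix": frac_h, "sheet": frac_s,
                       "coil": 1.0 - frac_h - frac_s}, index=ids)
    return df.loc[list(sel_ids)]


# ---------------------------------------------------------------------------
# distances


def segment_distance(traj: Trajectory, selection_a, selection_b,
                     atom_names=None) -> np.ndarray:
    """Per-frame distance between the unweighted centroids of two selections."""
    ia = traj.resolve(selection_a, atom_names)
    ib = traj.resolve(selection_b, atom_names)
    ca = traj.coords[:, ia].mean(axis=1)
    cb = traj.coords[:, ib].mean(axis=1)
    return np.linalg.norm(ca - cb, axis=1)


def radius_of_gyration(traj: Trajectory, selection, atom_names=None) -> np.ndarray:
    """Per-frame radius of gyration of a selection (loop-widening metric)."""
    idx = traj.resolve(selection, atom_names)
    sub = traj.coords[:, idx]
    cen = sub.mean(axis=1, keepdims=True)
    return np.sqrt(((sub - cen) ** 2).sum(axis=2).mean(axis=1))


# ---------------------------------------------------------------------------
# PDB / XYZ I/O


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (one MODEL per frame) via Bio.PDB."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("traj")
    for f in range(traj.n_frames):
        sb.init_model(f)
        sb.init_chain("A")
        sb.init_seg("    ")
        last_res = None
        for a in range(traj.n_atoms):
            rid = int(traj.residue_ids[a])
            if rid != last_res:
                sb.init_residue(traj.residue_names[a], " ", rid, " ")
                last_res = rid
            name = traj.atom_names[a]
            sb.init_atom(name, traj.coords[f, a], 0.0, 1.0, " ",
                         name.center(4), element=traj.elements[a])
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def read_pdb_trajectory(path, frame_stride: int = 1) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (atom order from model 0)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {path}")
    atoms0 = [(chain.id, res.id[1], res.resname, atom.get_name(), atom.element)
              for chain in models[0] for res in chain for atom in res]
    coords = np.array([[atom.get_coord()
                        for chain in model for res in chain for atom in res]
                       for model in models], dtype=float)
    if any(coords[k].shape[0] != len(atoms0) for k in range(len(models))):
        raise ValueError("inconsistent atom counts across models")
    return Trajectory(
        coords,
        residue_ids=[a[1] for a in atoms0],
        residue_names=[a[2] for a in atoms0],
        atom_names=[a[3] for a in atoms0],
        elements=[a[4] or a[3][:1] for a in atoms0],
        frame_stride=frame_stride)


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Plain XYZ variant: one block per frame, atom names as symbols."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{traj.atom_names[a]} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz_trajectory(path, template: Trajectory | None = None) -> Trajectory:
    """Read the XYZ variant; residue metadata comes from ``template`` when
    given (XYZ itself carries none), else sequential ids are assigned."""
    frames = []
    names: list = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            block = np.empty((n, 3))
            names = []
            for _ in range(n):
                parts = fh.readline().split()
                names.append(parts[0])
                block[len(names) - 1] = [float(v) for v in parts[1:4]]
            frames.append(block)
    coords = np.array(frames)
    if template is not None:
        if coords.shape[1] != template.n_atoms:
            raise ValueError("template atom count mismatch")
        return Trajectory(coords, template.residue_ids, template.residue_names,
                          template.atom_names, template.elements)
    return Trajectory(coords, np.arange(1, coords.shape[1] + 1),
                      atom_names=names)
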