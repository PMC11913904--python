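"""Structure and trajectory I/O.

Coordinates are Å throughout, frames are 0-indexed, residue numbers follow the
1-based PDB convention.  PDB reading/writing is delegated to biotite; this
module wraps it in the light-weight :class:`FrameCoordinates` container that
the rest of the package operates on, assigns per-atom van-der-Waals radii from
a Bondi table, and provides atom selection, frame iteration with stride, and
rigid-body alignment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ._geometry import kabsch

#: Bondi van-der-Waals radii (Å) for the elements that occur in protein /
#: lipid systems.  Overridable per call; unknown elements fall back to
#: DEFAULT_RADIUS with a warning.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75,
}
DEFAULT_RADIUS = 1.50

#: standard atomic masses for heavy-atom centres of mass
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "CL": 35.45, "FE": 55.845,
}
DEFAULT_MASS = 12.011


@dataclass(eq=False)
class FrameCoordinates:
    """One structure snapshot: coordinates plus per-atom metadata."""

    positions: np.ndarray          # (n, 3) Å
    atom_radius: np.ndarray        # (n,) Å
    atom_name: np.ndarray          # (n,) str
    residue_number: np.ndarray     # (n,) int, 1-based
    residue_name: np.ndarray       # (n,) str
    chain: np.ndarray              # (n,) str
    element: np.ndarray            # (n,) str
    box_lengths: np.ndarray | None = None    # (3,) Å, rectangular box
    frame_index: int = 0
    trajectory_id: str = ""
    #: optional hashable tag identifying the frame geometry; frames carrying
    #: equal keys are guaranteed coordinate-identical, enabling memoised
    #: per-frame analyses on discretely gated ensembles
    geometry_key: object = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.atom_radius = np.asarray(self.atom_radius, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.atom_radius <= 0):
            raise ValueError("atom radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def subset(self, indices: np.ndarray) -> "FrameCoordinates":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            positions=self.positions[idx],
            atom_radius=self.atom_radius[idx],
            atom_name=self.atom_name[idx],
            residue_number=self.residue_number[idx],
            residue_name=self.residue_name[idx],
            chain=self.chain[idx],
            element=self.element[idx],
        )

    def select(self, expression: str) -> "AtomSelection":
        return select_atoms(self, expression)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e.upper(), DEFAULT_MASS)
                         for e in self.element])


@dataclass(eq=False)
class AtomSelection:
    """Sorted atom indices plus the expression that produced them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self):
        self.indices = np.sort(np.asarray(self.indices, dtype=int))

    def __len__(self) -> int:
        return len(self.indices)


_RESID_TOKEN = re.compile(r"^(\d+)(?:-(\d+))?$")


def select_atoms(frame: FrameCoordinates, expression: str) -> AtomSelection:
    """Evaluate a conjunctive selection expression.

    Grammar: clauses joined by ``and``; each clause is one of
    ``chain <id>``, ``name <n1> [n2 ...]``, ``resname <r1> [r2 ...]``,
    ``resid <n>|<a>-<b> [...]``.  Example:
    ``chain A and resid 200-250 and name CA``.
    """
    mask = np.ones(frame.n_atoms, dtype=bool)
    for clause in re.split(r"\s+and\s+", expression.strip()):
        tokens = clause.split()
        if not tokens:
            continue
        key, args = tokens[0].lower(), tokens[1:]
        if not args:
            raise ValueError(f"selection clause '{clause}' has no arguments")
        if key == "chain":
            mask &= np.isin(frame.chain, args)
        elif key == "name":
            mask &= np.isin(frame.atom_name, args)
        elif key == "resname":
            mask &= np.isin(frame.residue_name, args)
        elif key == "resid":
            sub = np.zeros(frame.n_atoms, dtype=bool)
            for tok in args:
                m = _RESID_TOKEN.match(tok)
                if m is None:
                    raise ValueError(f"bad resid token '{tok}'")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                sub |= (frame.residue_number >= lo) & (frame.residue_number <= hi)
            mask &= sub
        else:
            raise ValueError(f"unknown selection keyword '{key}'")
    return AtomSelection(np.nonzero(mask)[0], expression)


def assign_radii(elements: np.ndarray, overrides: dict[str, float] | None = None
                 ) -> np.ndarray:
    table = dict(BONDI_RADII)
    if overrides:
        table.update({k.upper(): float(v) for k, v in overrides.items()})
    radii = np.empty(len(elements))
    unknown = set()
    for i, e in enumerate(elements):
        key = str(e).upper()
        if key in table:
            radii[i] = table[key]
        else:
            radii[i] = table.get("", DEFAULT_RADIUS) if "" in table else DEFAULT_RADIUS
            unknown.add(key)
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: using default radius "
            f"{DEFAULT_RADIUS} Å", stacklevel=2)
    return radii


def _validate_pdb_records(path: str) -> None:
    """Pre-scan ATOM/HETATM records so parse errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}:{lineno}: truncated coordinate record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinate fields in "
                    f"'{line.rstrip()}'") from None


def read_structure(path: str, radius_overrides: dict[str, float] | None = None,
                   radii_from_bfactor: bool = False) -> list[FrameCoordinates]:
    """Read a (multi-model) PDB file into one FrameCoordinates per MODEL.

    Radii come from the Bondi element table unless ``radii_from_bfactor`` is
    set, in which case the B-factor column is interpreted as a per-atom radius
    (the convention this package uses when round-tripping synthetic fixtures).
    """
    _validate_pdb_records(str(path))
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, extra_fields=["b_factor"])
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    box = None
    if stack.box is not None:
        box = np.diagonal(np.asarray(stack.box[0])).copy()
    frames = []
    elements = np.asarray(stack.element, dtype="U4")
    if radii_from_bfactor:
        radii = np.asarray(stack.b_factor[0], dtype=float)
        if np.any(radii <= 0):
            raise ValueError("radii_from_bfactor requires positive B-factors")
    else:
        radii = assign_radii(elements, radius_overrides)
    for m in range(stack.stack_depth()):
        frames.append(FrameCoordinates(
            positions=np.asarray(stack.coord[m], dtype=float),
            atom_radius=radii.copy(),
            atom_name=np.asarray(stack.atom_name, dtype="U6"),
            residue_number=np.asarray(stack.res_id, dtype=int),
            residue_name=np.asarray(stack.res_name, dtype="U5"),
            chain=np.asarray(stack.chain_id, dtype="U4"),
            element=elements,
            box_lengths=box,
            frame_index=m,
        ))
    return frames


def write_structure(path: str, frames: FrameCoordinates | list[FrameCoordinates],
                    radii_as_bfactor: bool = True) -> None:
    """Write one or more frames as a multi-model PDB file."""
    if isinstance(frames, FrameCoordinates):
        frames = [frames]
    first = frames[0]
    n = first.n_atoms
    arrays = []
    for fr in frames:
        if fr.n_atoms != n:
            raise ValueError("all frames must share the atom count")
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(fr.positions, dtype=np.float32)
        arr.chain_id = fr.chain
        arr.res_id = fr.residue_number
        arr.res_name = fr.residue_name
        arr.atom_name = fr.atom_name
        arr.element = fr.element
        arr.set_annotation("b_factor",
                           fr.atom_radius if radii_as_bfactor
                           else np.zeros(n))
        if fr.box_lengths is not None:
            arr.box = np.diag(fr.box_lengths)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


class TrajectoryEnsemble:
    """An ordered collection of frame sequences sharing a frame rate.

    ``trajectories`` holds one list of FrameCoordinates per run; provenance
    labels the starting structure of each run.  Subclasses may generate frames
    lazily as long as they honour this interface.
    """

    def __init__(self, trajectories: list[list[FrameCoordinates]],
                 frame_rate: float, provenance: list[str] | None = None):
        self._trajectories = trajectories
        self.frame_rate = float(frame_rate)
        self.provenance = provenance or [f"traj{i}" for i in range(len(trajectories))]
        for traj in trajectories:
            counts = {f.n_atoms for f in traj}
            if len(counts) > 1:
                raise ValueError("frames within a trajectory must share atom count")

    @property
    def n_trajectories(self) -> int:
        return len(self._trajectories)

    def n_frames(self, i: int) -> int:
        return len(self._trajectories[i])

    def iter_trajectory(self, i: int):
        yield from self._trajectories[i]

    def frames_per_ns(self) -> float:
        return self.frame_rate

    def lag_from_ns(self, lag_ns: float) -> int:
        """Convert a lag time in ns into frames at this ensemble's rate."""
        return max(1, int(round(lag_ns * self.frame_rate)))


def iterate_frames(ensemble: TrajectoryEnsemble, stride: int = 1):
    """Yield every stride-th frame of each trajectory, preserving provenance.

    A stride larger than a trajectory yields that trajectory's first frame
    only.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    for i in range(ensemble.n_trajectories):
        for k, frame in enumerate(ensemble.iter_trajectory(i)):
            if k % stride == 0:
                yield frame


def align_frames(ensemble: TrajectoryEnsemble, reference: FrameCoordinates,
                 selection: AtomSelection) -> TrajectoryEnsemble:
    """Least-squares rigid superposition of each frame onto the reference.

    The rotation/translation is fitted on ``selection`` and applied to all
    atoms of the frame.
    """
    if len(selection) < 3:
        raise ValueError("alignment needs at least 3 selected atoms")
    ref_pts = reference.positions[selection.indices]
    aligned = []
    for i in range(ensemble.n_trajectories):
        traj = []
        for frame in ensemble.iter_trajectory(i):
            rot, trans = kabsch(frame.positions[selection.indices], ref_pts)
            traj.append(replace(frame, positions=frame.positions @ rot.T + trans))
        aligned.append(traj)
    return TrajectoryEnsemble(aligned, ensemble.frame_rate, list(ensemble.provenance))


def merge_frames(a: FrameCoordinates, b: FrameCoordinates) -> FrameCoordinates:
    """Concatenate two frames (e.g. protein + membrane) into one."""
    from dataclasses import replace as _replace
    return _replace(
        a,
        positions=np.vstack([a.positions, b.positions]),
        atom_radius=np.concatenate([a.atom_radius, b.atom_radius]),
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        residue_number=np.concatenate([a.residue_number, b.residue_number]),
        residue_name=np.concatenate([a.residue_name, b.residue_name]),
        chain=np.concatenate([a.chain, b.chain]),
        element=np.concatenate([a.element, b.element]),
        box_lengths=a.box_lengths if a.box_lengths is not None else b.box_lengths,
    )


def selection_rmsd(frame: FrameCoordinates, reference: FrameCoordinates,
                   selection: AtomSelection) -> float:
    d = frame.positions[selection.indices] - reference.positions[selection.indices]
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))
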