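"""Membrane integrity and orientation metrics.

Implements the three geometric observables used to validate a membrane-bound
enzyme simulation: area per lipid (box area divided by lipids per leaflet),
the heme tilt angle relative to the bilayer normal, and the insertion depth of
tunnel bottlenecks below the upper-leaflet nitrogen plane.

Plane fits are total-least-squares (smallest-eigenvector normal of the
centered coordinate covariance), which makes every metric invariant under
rigid rotation of the whole system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import fit_plane
from .io import FrameCoordinates


@dataclass(eq=False)
class MembraneModel:
    """Leaflet membership and marker-atom selections of a bilayer.

    All index arrays refer to atoms of the coordinate frame the model was
    built against (lipids on chain "M" by this package's convention).
    """

    upper_lipids: np.ndarray       # residue numbers
    lower_lipids: np.ndarray
    phosphate_upper: np.ndarray    # atom indices
    phosphate_lower: np.ndarray
    nitrogen_upper: np.ndarray
    nitrogen_lower: np.ndarray
    tail_carbons: np.ndarray
    box_lengths: np.ndarray

    def __post_init__(self):
        overlap = np.intersect1d(self.upper_lipids, self.lower_lipids)
        if len(overlap):
            raise ValueError(f"lipids in both leaflets: {overlap.tolist()}")
        for name in ("phosphate_upper", "phosphate_lower",
                     "nitrogen_upper", "nitrogen_lower", "tail_carbons"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty marker selection: {name}")


def area_per_lipid(frame: FrameCoordinates | None, membrane: MembraneModel
                   ) -> dict[str, float]:
    """Box XY area divided by the lipid count, per leaflet (Å²)."""
    box = frame.box_lengths if (frame is not None and frame.box_lengths is not None) \
        else membrane.box_lengths
    if box is None:
        raise ValueError("box lengths unknown")
    area = float(box[0]) * float(box[1])
    out = {}
    for leaflet, lipids in (("upper", membrane.upper_lipids),
                            ("lower", membrane.lower_lipids)):
        if len(lipids) == 0:
            raise ValueError(f"no lipids in {leaflet} leaflet")
        out[leaflet] = area / len(lipids)
    return out


def heme_tilt_angle(frame: FrameCoordinates, phosphate_indices: np.ndarray,
                    heme_nitrogen_indices: np.ndarray) -> float:
    """Heme tilt relative to the membrane, in degrees.

    The membrane normal is the TLS-plane normal through the phosphate marker
    atoms; the heme normal likewise through the heme nitrogens.  The angle
    between the normals is folded to [0°, 90°] via |dot|, and the tilt is
    90° minus that angle: 90° for a heme lying parallel to the membrane
    plane, 0° for a heme standing perpendicular to it.
    """
    _, n_mem = fit_plane(frame.positions[np.asarray(phosphate_indices, int)])
    _, n_heme = fit_plane(frame.positions[np.asarray(heme_nitrogen_indices, int)])
    cosang = np.clip(abs(float(np.dot(n_mem, n_heme))), 0.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    return 90.0 - angle


@dataclass
class InsertionDepth:
    """Signed distance of a bottleneck to the upper-leaflet nitrogen plane.

    Negative values lie below the plane, toward the bilayer center.
    ``apolar_reference`` is the signed position of the tail-carbon plane on
    the same axis (always negative for a sane bilayer).
    """

    depth: float
    apolar_reference: float


def insertion_depth(frame: FrameCoordinates, bottleneck_residues: list[int],
                    membrane: MembraneModel) -> InsertionDepth:
    """Depth of the bottleneck-residue center of mass below the upper leaflet.

    The plane is fitted to the upper-leaflet nitrogen atoms; its normal is
    oriented away from the bilayer interior (tail carbons), so that points
    inside the membrane get negative depths.
    """
    nitro = frame.positions[membrane.nitrogen_upper]
    centroid, normal = fit_plane(nitro)
    interior = frame.positions[membrane.tail_carbons].mean(axis=0)
    if np.dot(normal, centroid - interior) < 0:
        normal = -normal
    mask = np.isin(frame.residue_number, np.asarray(bottleneck_residues, int))
    if not mask.any():
        raise ValueError(f"bottleneck residues {bottleneck_residues} not in frame")
    masses = frame.masses()[mask]
    heavy = frame.element[mask] != "H"
    pos = frame.positions[mask][heavy]
    m = masses[heavy]
    com = (pos * m[:, None]).sum(axis=0) / m.sum()
    depth = float(np.dot(com - centroid, normal))
    apolar = float(np.dot(interior - centroid, normal))
    return InsertionDepth(depth=depth, apolar_reference=apolar)


def reindex_membrane_model(model: MembraneModel, offset: int) -> MembraneModel:
    """Shift a model's atom indices, e.g. for a merged protein+membrane frame
    where the membrane atoms follow ``offset`` protein atoms."""
    return MembraneModel(
        upper_lipids=model.upper_lipids, lower_lipids=model.lower_lipids,
        phosphate_upper=model.phosphate_upper + offset,
        phosphate_lower=model.phosphate_lower + offset,
        nitrogen_upper=model.nitrogen_upper + offset,
        nitrogen_lower=model.nitrogen_lower + offset,
        tail_carbons=model.tail_carbons + offset,
        box_lengths=model.box_lengths)
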