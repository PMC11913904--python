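"""Per-state analyses of tunnel openness, contacts, flexibility and geometry.

A tunnel counts as *open* in a frame when its bottleneck radius exceeds the
probe floor (0.9 Å default) and as *wide* when it exceeds the van-der-Waals
radius of water (1.7 Å).  A tunnel is labelled closed in a state when even
its ``closed_quantile`` (95th percentile by default) bottleneck stays at or
below the water radius — i.e. the tunnel essentially never opens wider than
a water molecule in that state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import i0, i1

from .clustering import BottleneckSeries
from .io import FrameCoordinates, AtomSelection, select_atoms

#: residue-class map used for reporting bottleneck-residue chemistry
HYDROPHOBICITY_CLASS = {
    "ALA": "hydrophobic", "VAL": "hydrophobic", "LEU": "hydrophobic",
    "ILE": "hydrophobic", "MET": "hydrophobic", "PHE": "hydrophobic",
    "TRP": "hydrophobic", "PRO": "hydrophobic", "GLY": "hydrophobic",
    "SER": "neutral-polar", "THR": "neutral-polar", "CYS": "neutral-polar",
    "TYR": "neutral-polar", "ASN": "neutral-polar", "GLN": "neutral-polar",
    "ASP": "charged", "GLU": "charged", "LYS": "charged",
    "ARG": "charged", "HIS": "charged",
}


@dataclass
class OpennessConfig:
    open_threshold: float = 0.9     # Å, probe floor: open means radius above this
    water_threshold: float = 1.7    # Å, van-der-Waals radius of water
    closed_quantile: float = 0.95

    def __post_init__(self):
        if not 0 < self.open_threshold <= self.water_threshold:
            raise ValueError("need 0 < open_threshold <= water_threshold")
        if not 0 < self.closed_quantile <= 1:
            raise ValueError("closed_quantile must be in (0, 1]")


def _aligned(series: BottleneckSeries, state_labels: list[np.ndarray]
             ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Concatenate state labels and per-type series in trajectory order."""
    counts = [series.frame_counts[t] for t in series.frame_counts]
    if [len(l) for l in state_labels] != counts:
        raise ValueError("state labels and bottleneck series are not "
                         "frame-aligned")
    labels = np.concatenate(state_labels)
    per_type = {t: series.concatenated(t) for t in series.types}
    return labels, per_type


def openness_summary(series: BottleneckSeries, state_labels: list[np.ndarray],
                     config: OpennessConfig = OpennessConfig()) -> pd.DataFrame:
    """Open/wide fractions, radius quantiles and an openness label per
    (state, tunnel type).

    Label rule: *closed* when the ``closed_quantile`` radius is at or below
    the water threshold; *open* when not closed and the tunnel is open in at
    least half the frames; *intermediate* otherwise.
    """
    labels, per_type = _aligned(series, state_labels)
    rows = []
    for s in np.unique(labels):
        mask = labels == s
        if not mask.any():
            warnings.warn(f"state {s} has no frames; omitted", stacklevel=2)
            continue
        for t, values in per_type.items():
            r = values[mask]
            open_frac = float(np.mean(r > config.open_threshold))
            wide_frac = float(np.mean(r > config.water_threshold))
            q = np.quantile(r, [0.05, 0.25, 0.5, 0.75, config.closed_quantile])
            if q[-1] <= config.water_threshold:
                label = "closed"
            elif open_frac >= 0.5:
                label = "open"
            else:
                label = "intermediate"
            rows.append((int(s), t, open_frac, wide_frac,
                         *q, label))
    return pd.DataFrame(rows, columns=[
        "state", "type", "open_fraction", "wide_fraction",
        "q05", "q25", "q50", "q75", "q_closed", "label"])


def co_opening_fractions(a: np.ndarray, b: np.ndarray,
                         threshold: float) -> dict[str, float]:
    """Joint open/closed fractions of two aligned bottleneck series."""
    if len(a) != len(b):
        raise ValueError("series must share the frame index set")
    oa = np.asarray(a) > threshold
    ob = np.asarray(b) > threshold
    n = len(oa)
    return {
        "both_open": float(np.mean(oa & ob)),
        "only_first": float(np.mean(oa & ~ob)),
        "only_second": float(np.mean(~oa & ob)),
        "both_closed": float(np.mean(~oa & ~ob)),
    }


def co_opening(series: BottleneckSeries, state_labels: list[np.ndarray],
               config: OpennessConfig = OpennessConfig()) -> pd.DataFrame:
    """Per state and tunnel-type pair: fraction of frames in which both open,
    both close, or exactly one opens.  Counts are divided by the state's frame
    total, so the four fractions sum to 1 per pair."""
    labels, per_type = _aligned(series, state_labels)
    types = sorted(per_type)
    rows = []
    for s in np.unique(labels):
        mask = labels == s
        for i, ta in enumerate(types):
            for tb in types[i + 1:]:
                f = co_opening_fractions(per_type[ta][mask],
                                         per_type[tb][mask],
                                         config.open_threshold)
                rows.append((int(s), ta, tb, f["both_open"], f["only_first"],
                             f["only_second"], f["both_closed"]))
    return pd.DataFrame(rows, columns=[
        "state", "type_a", "type_b", "both_open", "only_first",
        "only_second", "both_closed"])


def _resolve(frame: FrameCoordinates, sel) -> np.ndarray:
    if isinstance(sel, str):
        sel = select_atoms(frame, sel)
    if isinstance(sel, AtomSelection):
        idx = sel.indices
    else:
        idx = np.asarray(sel, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty selection")
    return idx


def _heavy(frame: FrameCoordinates, idx: np.ndarray) -> np.ndarray:
    return idx[frame.element[idx] != "H"]


def contact_frequencies(frames: list[FrameCoordinates],
                        selection_pairs: list[tuple],
                        cutoff: float = 4.5) -> pd.DataFrame:
    """Fraction of frames in which any heavy-atom pair across the two groups
    lies within ``cutoff`` Å."""
    if not frames:
        raise ValueError("no frames")
    hits = np.zeros(len(selection_pairs), dtype=int)
    for frame in frames:
        for j, (sa, sb) in enumerate(selection_pairs):
            ia = _heavy(frame, _resolve(frame, sa))
            ib = _heavy(frame, _resolve(frame, sb))
            if cutoff <= 0:
                continue
            ta = cKDTree(frame.positions[ia])
            if ta.query_ball_point(frame.positions[ib], cutoff,
                                   return_length=True).sum() > 0:
                hits[j] += 1
    rows = [(str(sa), str(sb), hits[j] / len(frames))
            for j, (sa, sb) in enumerate(selection_pairs)]
    return pd.DataFrame(rows, columns=["selection_a", "selection_b",
                                       "frequency"])


def membrane_contact_series(frames: list[FrameCoordinates],
                            residue_numbers: list[int],
                            lipid_chain: str = "M",
                            search_radius: float = 10.0,
                            cutoff: float = 4.5) -> np.ndarray:
    """Boolean (n_frames, n_residues) membrane-contact matrix.

    Lipid atoms are first restricted to a ``search_radius`` neighborhood of
    the selected residues, then each residue counts as contacting the
    membrane in a frame when any of its heavy atoms lies within ``cutoff`` of
    a neighboring lipid atom.
    """
    residue_numbers = list(residue_numbers)
    out = np.zeros((len(frames), len(residue_numbers)), dtype=bool)
    for fi, frame in enumerate(frames):
        lipid_idx = np.nonzero(frame.chain == lipid_chain)[0]
        sel_idx = np.nonzero(np.isin(frame.residue_number, residue_numbers)
                             & (frame.chain != lipid_chain))[0]
        if len(lipid_idx) == 0 or len(sel_idx) == 0:
            continue
        sel_tree = cKDTree(frame.positions[sel_idx])
        near = sel_tree.query_ball_point(frame.positions[lipid_idx],
                                         search_radius, return_length=True) > 0
        lipid_near = lipid_idx[near]
        if len(lipid_near) == 0:
            continue
        lipid_tree = cKDTree(frame.positions[lipid_near])
        for rj, r in enumerate(residue_numbers):
            ri = sel_idx[frame.residue_number[sel_idx] == r]
            ri = _heavy(frame, ri)
            if len(ri) == 0:
                continue
            n = lipid_tree.query_ball_point(frame.positions[ri], cutoff,
                                            return_length=True)
            out[fi, rj] = n.sum() > 0
    return out


def relative_membrane_interaction_time(contact_series: np.ndarray,
                                       state_labels: np.ndarray,
                                       residue_numbers: list[int]
                                       ) -> pd.DataFrame:
    """Per residue and state: 100 x contact frames / state frames.

    Stacked over k states the percentages sum to at most 100 k (300 % for
    three states means the residue touches the membrane in every frame of
    every state).
    """
    contact_series = np.asarray(contact_series, dtype=bool)
    state_labels = np.asarray(state_labels)
    if len(contact_series) != len(state_labels):
        raise ValueError("contact series and state labels are not aligned")
    rows = []
    for s in np.unique(state_labels):
        mask = state_labels == s
        frac = contact_series[mask].mean(axis=0) * 100.0
        for rj, r in enumerate(residue_numbers):
            rows.append((int(s), int(r), float(frac[rj])))
    return pd.DataFrame(rows, columns=["state", "residue", "percent"])


def plot_membrane_interaction_time(table: pd.DataFrame, path: str) -> None:
    """Stacked bar chart of relative membrane interaction time per residue.

    Bars stack the per-state percentages, so a residue touching the membrane
    in every frame of every one of k states reaches 100 k percent.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    states = sorted(table["state"].unique())
    residues = sorted(table["residue"].unique())
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(residues)), 3.5))
    bottom = np.zeros(len(residues))
    shades = ["#ffffff", "#bbbbbb", "#555555", "#1f77b4", "#ff7f0e"]
    for si, s in enumerate(states):
        sub = table[table["state"] == s].set_index("residue")["percent"]
        vals = np.array([sub.get(r, 0.0) for r in residues])
        ax.bar(range(len(residues)), vals, bottom=bottom,
               color=shades[si % len(shades)], edgecolor="k",
               linewidth=0.4, label=f"state {s}")
        bottom += vals
    ax.set_xticks(range(len(residues)), [str(r) for r in residues],
                  rotation=90, fontsize=7)
    ax.set_ylabel("relative membrane interaction time (%)")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def dihedral_entropy(angles: np.ndarray, convention: str = "histogram",
                     bins: int = 360, kde_kappa: float = 200.0) -> float:
    """Differential entropy (nats) of a circular angle distribution.

    ``histogram``: density histogram on [-pi, pi).  ``kernel``: von Mises
    kernel density with concentration ``kde_kappa``.  Angles are phase-aligned
    to their circular mean before estimation, which makes the estimate exactly
    invariant under adding a constant to all angles.  A uniform sample
    approaches ln(2 pi) ~= 1.8379 nats.
    """
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 2:
        warnings.warn("degenerate (constant) angle series: entropy is -inf",
                      stacklevel=2)
        return -np.inf
    resultant = np.exp(1j * angles).mean()
    theta0 = np.angle(resultant)
    angles = np.mod(angles - theta0 + np.pi, 2 * np.pi) - np.pi
    if np.ptp(angles) < 1e-12:
        warnings.warn("degenerate (constant) angle series: entropy is -inf",
                      stacklevel=2)
        return -np.inf
    if convention == "histogram":
        hist, edges = np.histogram(angles, bins=bins, range=(-np.pi, np.pi),
                                   density=True)
        width = edges[1] - edges[0]
        p = hist[hist > 0]
        return float(-np.sum(p * np.log(p)) * width)
    if convention == "kernel":
        grid = np.linspace(-np.pi, np.pi, bins, endpoint=False)
        dens = np.zeros_like(grid)
        # chunked von Mises kernel sum to bound memory
        norm = 2 * np.pi * i0(kde_kappa) * len(angles)
        for start in range(0, len(angles), 10_000):
            chunk = angles[start:start + 10_000]
            dens += np.exp(kde_kappa * np.cos(grid[:, None] - chunk[None, :])
                           ).sum(axis=1)
        dens /= norm
        width = 2 * np.pi / bins
        p = dens[dens > 0]
        return float(-np.sum(p * np.log(p)) * width)
    raise ValueError(f"unknown convention '{convention}'")


def von_mises_entropy(kappa: float) -> float:
    """Closed-form entropy of the von Mises distribution (nats)."""
    return float(np.log(2 * np.pi * i0(kappa)) - kappa * i1(kappa) / i0(kappa))


@dataclass(eq=False)
class CrystalPCA:
    projections: np.ndarray        # (n_structures, n_components)
    components: np.ndarray
    explained_variance: np.ndarray
    structure_labels: list[str]

    def select_extremes(self, k: int) -> list[int]:
        """Greedy max-min-distance selection of k structures spanning the
        projected space (first pick: farthest from the centroid)."""
        pts = self.projections
        if k >= len(pts):
            return list(range(len(pts)))
        center = pts.mean(axis=0)
        chosen = [int(np.argmax(np.linalg.norm(pts - center, axis=1)))]
        while len(chosen) < k:
            dmin = np.min(np.linalg.norm(
                pts[:, None] - pts[chosen][None], axis=2), axis=1)
            dmin[chosen] = -1
            chosen.append(int(np.argmax(dmin)))
        return chosen


def crystal_pca(structures: list[FrameCoordinates],
                region: tuple[int, int],
                labels: list[str] | None = None) -> CrystalPCA:
    """PCA on the flattened heavy-atom coordinates of a residue region.

    Structures must be pre-aligned on the region and must present identical
    atom counts there (offenders are listed otherwise).
    """
    lo, hi = region
    mats = []
    counts = []
    for st in structures:
        idx = np.nonzero((st.residue_number >= lo) & (st.residue_number <= hi)
                         & (st.element != "H"))[0]
        counts.append(len(idx))
        mats.append(st.positions[idx].ravel())
    if len(set(counts)) > 1:
        offenders = [i for i, c in enumerate(counts) if c != counts[0]]
        raise ValueError(f"region atom counts differ across structures; "
                         f"offending indices {offenders} (counts {counts})")
    x = np.vstack(mats)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2 / max(len(x) - 1, 1)
    proj = u * s
    return CrystalPCA(projections=proj, components=vt,
                      explained_variance=var,
                      structure_labels=labels or
                      [f"structure{i}" for i in range(len(structures))])


def rmsd_per_residue(frames: list[FrameCoordinates],
                     reference: FrameCoordinates) -> pd.DataFrame:
    """Per residue, root-mean-square heavy-atom deviation from the reference,
    averaged over frames.  Assumes prior alignment."""
    heavy = np.nonzero(reference.element != "H")[0]
    residues = np.unique(reference.residue_number[heavy])
    sq = {int(r): [] for r in residues}
    for frame in frames:
        d2 = ((frame.positions[heavy] - reference.positions[heavy]) ** 2
              ).sum(axis=1)
        res = reference.residue_number[heavy]
        for r in residues:
            sq[int(r)].append(d2[res == r])
    rows = [(int(r), float(np.sqrt(np.mean(np.concatenate(sq[int(r)])))))
            for r in residues]
    return pd.DataFrame(rows, columns=["residue", "rmsd_A"])
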