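"""Kinetic state decomposition of a trajectory ensemble.

The stages mirror the standard Markov-state-model workflow: periodic torsion
features are embedded as (cos, sin) pairs, tICA finds the slowest linear
combinations at a lag time, k-means discretises the projected space into
microstates, a transition matrix is estimated at a (possibly different) lag,
implied timescales diagnose Markovianity, and PCCA+ aggregates microstates
into metastable macrostates whose crisp assignment yields the per-frame state
trajectory.

Lag times are always in frames; conversion from ns uses the ensemble's frame
rate (``TrajectoryEnsemble.lag_from_ns``).  Time-lagged pairs never straddle
trajectory boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from ._geometry import dihedral


@dataclass
class StateModelConfig:
    feature_residues: list[int] = field(default_factory=list)
    tica_lag: int = 3500          # frames (70 ns at 50 frames/ns)
    n_microstates: int = 500
    msm_lag: int = 2000           # frames (40 ns at 50 frames/ns)
    n_macrostates: int = 3
    reversible: bool = False
    seed: int = 0
    sample_stride: int = 50

    def __post_init__(self):
        if self.tica_lag < 1 or self.msm_lag < 1:
            raise ValueError("lags must be >= 1 frame")
        if not self.n_microstates >= self.n_macrostates >= 2:
            raise ValueError("need n_microstates >= n_macrostates >= 2")


def featurize_torsions(ensemble, residues: list[int] | None = None
                       ) -> list[np.ndarray]:
    """Periodicity-safe (cos, sin) features of backbone torsions per frame.

    Synthetic gated ensembles emit their angle channels directly; for generic
    ensembles the phi/psi torsions of the listed residues are computed from
    N/CA/C backbone atoms.  Zero-variance channels are dropped with a warning.
    Returns one (n_frames, n_features) matrix per trajectory.
    """
    if hasattr(ensemble, "angle_features"):
        angle_blocks = ensemble.angle_features()
        if residues is not None and hasattr(ensemble, "gate_residues"):
            per_res = angle_blocks[0].shape[1] // len(ensemble.gate_residues)
            cols = []
            for r in residues:
                if r not in ensemble.gate_residues:
                    raise ValueError(f"residue {r} has no emitted angles")
                j = ensemble.gate_residues.index(r)
                cols.extend(range(j * per_res, (j + 1) * per_res))
            angle_blocks = [a[:, cols] for a in angle_blocks]
    else:
        if not residues:
            raise ValueError("residues required for torsion featurization")
        angle_blocks = [_backbone_torsions(ensemble, i, residues)
                        for i in range(ensemble.n_trajectories)]
    feats = [np.hstack([np.cos(a), np.sin(a)]) for a in angle_blocks]
    var = np.var(np.vstack(feats), axis=0)
    keep = var >= 1e-12
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} zero-variance "
                      "feature(s)", stacklevel=2)
        feats = [f[:, keep] for f in feats]
    return feats


def _backbone_torsions(ensemble, traj_index: int, residues: list[int]
                       ) -> np.ndarray:
    rows = []
    for frame in ensemble.iter_trajectory(traj_index):
        atom_of = {}
        for r in set(residues) | {r - 1 for r in residues} | {r + 1 for r in residues}:
            mask = frame.residue_number == r
            for name in ("N", "CA", "C"):
                hit = np.nonzero(mask & (frame.atom_name == name))[0]
                if len(hit):
                    atom_of[(r, name)] = frame.positions[hit[0]]
        angles = []
        for r in residues:
            try:
                phi = dihedral(atom_of[(r - 1, "C")], atom_of[(r, "N")],
                               atom_of[(r, "CA")], atom_of[(r, "C")])
                psi = dihedral(atom_of[(r, "N")], atom_of[(r, "CA")],
                               atom_of[(r, "C")], atom_of[(r + 1, "N")])
            except KeyError:
                raise ValueError(f"residue {r}: backbone atoms for phi/psi "
                                 "not found") from None
            angles.extend([phi, psi])
        rows.append(angles)
    return np.asarray(rows)


@dataclass(eq=False)
class TICAModel:
    mean: np.ndarray
    c0: np.ndarray                 # instantaneous covariance
    ctau: np.ndarray               # symmetrised time-lagged covariance
    eigenvalues: np.ndarray        # descending
    components: np.ndarray         # (n_features, n_components)
    lag: int

    def transform(self, features: list[np.ndarray] | np.ndarray,
                  n_components: int | None = None):
        k = n_components or self.components.shape[1]
        if isinstance(features, np.ndarray):
            return (features - self.mean) @ self.components[:, :k]
        return [(f - self.mean) @ self.components[:, :k] for f in features]


def fit_tica(features: list[np.ndarray], lag: int,
             regularization: float = 1e-6) -> TICAModel:
    """Solve the generalized eigenproblem C_tau v = lambda C_0 v.

    C_tau is the symmetrised time-lagged covariance estimated from pairs that
    stay within one trajectory; C_0 is ridge-regularised before the solve.
    Components come out sorted by eigenvalue, descending, and orthonormal
    under the C_0 metric.
    """
    if isinstance(features, np.ndarray):
        features = [features]
    total = sum(len(f) for f in features)
    if total <= 10 * lag:
        raise ValueError(f"{total} frames is too short for lag {lag} "
                         "(need > 10 x lag)")
    mean = np.vstack(features).mean(axis=0)
    nf = features[0].shape[1]
    c0 = np.zeros((nf, nf))
    ct = np.zeros((nf, nf))
    n0 = nt = 0
    for f in features:
        x = f - mean
        c0 += x.T @ x
        n0 += len(x)
        if len(x) > lag:
            a, b = x[:-lag], x[lag:]
            ct += a.T @ b
            nt += len(a)
    if nt == 0:
        raise ValueError("no time-lagged pairs at this lag")
    c0 /= n0
    ct /= nt
    ct = 0.5 * (ct + ct.T)
    ridge = regularization * np.trace(c0) / nf
    c0r = c0 + ridge * np.eye(nf)
    try:
        vals, vecs = sla.eigh(ct, c0r)
    except sla.LinAlgError as err:
        raise ValueError(f"singular instantaneous covariance: {err}") from None
    order = np.argsort(vals)[::-1]
    return TICAModel(mean=mean, c0=c0, ctau=ct, eigenvalues=vals[order],
                     components=vecs[:, order], lag=lag)


def kmeans_discretize(projected: list[np.ndarray] | np.ndarray, k: int,
                      seed: int = 0) -> list[np.ndarray]:
    """Seeded k-means++ labels, one array per trajectory."""
    if isinstance(projected, np.ndarray):
        projected = [projected]
    stacked = np.vstack(projected)
    if k > len(stacked):
        raise ValueError("k exceeds the number of frames")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                random_state=seed).fit(stacked)
    labels = km.labels_.astype(int)
    out = []
    start = 0
    for p in projected:
        out.append(labels[start:start + len(p)])
        start += len(p)
    return out


@dataclass(eq=False)
class MarkovModel:
    count_matrix: np.ndarray       # (n, n) at lag, full microstate space
    transition_matrix: np.ndarray  # (m, m) over the active set
    active_set: np.ndarray         # microstate ids in the active set
    stationary: np.ndarray         # (m,)
    eigenvalues: np.ndarray        # of the transition matrix, |.| descending
    lag: int
    reversible: bool

    @property
    def n_active(self) -> int:
        return len(self.active_set)


def _count_transitions(labels: list[np.ndarray], lag: int, n: int) -> np.ndarray:
    counts = np.zeros((n, n))
    for lab in labels:
        if len(lab) > lag:
            np.add.at(counts, (lab[:-lag], lab[lag:]), 1.0)
    return counts


def estimate_msm(labels: list[np.ndarray] | np.ndarray, lag: int,
                 reversible: bool = False) -> MarkovModel:
    """Transition matrix from sliding-window counts within trajectories.

    The largest strongly connected set of the count graph is retained (a
    warning lists anything discarded).  The reversible option symmetrises the
    counts, which enforces detailed balance exactly; otherwise plain row
    normalisation is used and the stationary vector comes from the leading
    left eigenvector.
    """
    if isinstance(labels, np.ndarray):
        labels = [labels]
    labels = [np.asarray(l, dtype=int) for l in labels]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = int(max(l.max() for l in labels)) + 1
    counts = _count_transitions(labels, lag, n)
    if counts.sum() == 0:
        raise ValueError("no transition pairs at this lag")
    _, comp = connected_components(csr_matrix(counts > 0),
                                   connection="strong")
    sizes = np.bincount(comp, weights=counts.sum(axis=1) + counts.sum(axis=0))
    active = np.nonzero(comp == np.argmax(sizes))[0]
    visited = np.unique(np.concatenate(labels))
    discarded = np.setdiff1d(visited, active)
    if len(discarded):
        warnings.warn(f"discarding {len(discarded)} microstate(s) outside the "
                      f"largest strongly connected set: {discarded.tolist()}",
                      stacklevel=2)
    c = counts[np.ix_(active, active)]
    if c.sum() == 0:
        raise ValueError("count graph disconnected: no transitions within the "
                         f"largest strongly connected set; discarded "
                         f"{discarded.tolist()}")
    if reversible:
        sym = 0.5 * (c + c.T)
        t = sym / sym.sum(axis=1, keepdims=True)
        pi = sym.sum(axis=1) / sym.sum()
    else:
        t = c / c.sum(axis=1, keepdims=True)
        w, v = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.abs(np.real(v[:, i]))
        pi = pi / pi.sum()
    evals = np.linalg.eigvals(t)
    evals = evals[np.argsort(-np.abs(evals))]
    return MarkovModel(count_matrix=counts, transition_matrix=t,
                       active_set=active, stationary=pi, eigenvalues=evals,
                       lag=lag, reversible=reversible)


def implied_timescales(labels: list[np.ndarray], lags: list[int],
                       n_timescales: int = 5,
                       reversible: bool = False) -> pd.DataFrame:
    """t_i(tau) = -tau / ln|lambda_i| for i >= 2, tabulated per lag.

    Non-positive or unit eigenvalues give NaN (undefined / disconnected).
    """
    rows = []
    for lag in lags:
        model = estimate_msm(labels, lag, reversible=reversible)
        evs = np.real(model.eigenvalues)
        for i in range(1, min(n_timescales + 1, len(evs))):
            lam = evs[i]
            mag = abs(lam)
            if mag <= 0 or mag >= 1.0:
                ts = np.nan
            else:
                ts = -lag / np.log(mag)
            rows.append((lag, i + 1, lam, ts))
    return pd.DataFrame(rows, columns=["lag", "index", "eigenvalue",
                                       "timescale"])


@dataclass(eq=False)
class MacrostateDecomposition:
    memberships: np.ndarray        # (m_active, n_macrostates), rows sum to 1
    crisp_map: np.ndarray          # (n_microstates,), -1 for inactive states
    active_set: np.ndarray
    n_macrostates: int


def pcca(msm: MarkovModel, n_macrostates: int) -> MacrostateDecomposition:
    """Inner-simplex PCCA+ on the dominant right eigenvectors.

    Membership rows are clipped to [0, 1] and renormalised; the crisp map is
    the row argmax (ties resolve to the lower macrostate index).
    """
    if n_macrostates < 2:
        raise ValueError("need at least 2 macrostates")
    if n_macrostates > msm.n_active:
        raise ValueError("more macrostates than active microstates")
    t = msm.transition_matrix
    vals, vecs = np.linalg.eig(t)
    order = np.argsort(-np.real(vals))
    vals = vals[order]
    vecs = vecs[:, order]
    top = vals[:n_macrostates]
    if np.max(np.abs(np.imag(top))) > 1e-8:
        raise ValueError("complex dominant eigenvalues: transition matrix is "
                         "not metastable at this lag")
    if n_macrostates < len(vals):
        gap = np.real(vals[n_macrostates - 1]) - np.real(vals[n_macrostates])
        if gap < 0.02:
            warnings.warn(
                f"weak spectral gap ({gap:.3g}) after {n_macrostates} "
                "eigenvalues; macrostates may be ill-defined", stacklevel=2)
    x = np.real(vecs[:, :n_macrostates])
    x[:, 0] = 1.0

    # inner simplex vertex search
    m = x.shape[0]
    idx = np.zeros(n_macrostates, dtype=int)
    v = x.copy()
    idx[0] = int(np.argmax((v ** 2).sum(axis=1)))
    v = v - v[idx[0]]
    for j in range(1, n_macrostates):
        norms = (v ** 2).sum(axis=1)
        idx[j] = int(np.argmax(norms))
        u = v[idx[j]]
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise ValueError("degenerate eigenvector simplex")
        u = u / nu
        v = v - np.outer(v @ u, u)
    a = np.linalg.inv(x[idx])
    chi = x @ a
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)

    n_total = msm.count_matrix.shape[0]
    crisp = np.full(n_total, -1, dtype=int)
    crisp[msm.active_set] = np.argmax(chi, axis=1)
    return MacrostateDecomposition(memberships=chi, crisp_map=crisp,
                                   active_set=msm.active_set,
                                   n_macrostates=n_macrostates)


def build_state_trajectories(labels: list[np.ndarray],
                             decomposition: MacrostateDecomposition
                             ) -> list[np.ndarray]:
    """Per-frame macrostate labels via the crisp PCCA+ map.

    Frames in microstates outside the active set inherit the previous frame's
    state (or the first defined state, at a trajectory start).
    """
    out = []
    for lab in labels:
        macro = decomposition.crisp_map[np.asarray(lab, dtype=int)]
        if (macro < 0).any():
            defined = np.nonzero(macro >= 0)[0]
            if len(defined) == 0:
                raise ValueError("no frame falls into the active set")
            # forward fill, then backfill the head
            for k in range(1, len(macro)):
                if macro[k] < 0:
                    macro[k] = macro[k - 1]
            first = macro[defined[0]]
            macro[:defined[0]] = first
        out.append(macro)
    return out


@dataclass(eq=False)
class StateSamples:
    """Every stride-th frame of each state's concatenated sequence."""

    frames: dict[int, list[tuple[int, int]]]   # state -> [(traj, frame), ...]
    fractions: dict[int, dict[str, float]]     # state -> provenance fractions
    counts: dict[int, int]                     # state -> frames in the state


def sample_state_frames(state_labels: list[np.ndarray], stride: int,
                        provenance: list[str] | None = None) -> StateSamples:
    if stride < 1:
        raise ValueError("stride must be >= 1")
    provenance = provenance or [f"traj{i}" for i in range(len(state_labels))]
    order = [(i, k) for i, lab in enumerate(state_labels)
             for k in range(len(lab))]
    concat = np.concatenate(state_labels)
    frames: dict[int, list[tuple[int, int]]] = {}
    counts: dict[int, int] = {}
    fractions: dict[int, dict[str, float]] = {}
    for s in np.unique(concat):
        pos = np.nonzero(concat == s)[0]
        counts[int(s)] = len(pos)
        picked = pos[::stride]
        sel = [order[p] for p in picked]
        frames[int(s)] = sel
        total = len(sel)
        frac = {}
        for i, name in enumerate(provenance):
            frac[name] = sum(1 for t, _ in sel if t == i) / total
        fractions[int(s)] = frac
    return StateSamples(frames=frames, fractions=fractions, counts=counts)
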