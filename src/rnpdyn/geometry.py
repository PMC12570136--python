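"""Superposition and geometric trajectory statistics.

All operations take coordinates in nanometres and report nanometres and
degrees.  Superposition uses the Kabsch algorithm (SVD of the weighted
cross-covariance, reflections excluded), the standard least-squares fit
behind RMSD/RMSF analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .selection import Selection
from .topology import Topology
from .trajectory import Frame, Trajectory

__all__ = [
    "SuperpositionResult",
    "SeriesResult",
    "ProfileResult",
    "center_of_mass",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "radius_of_gyration_series",
    "com_distance_series",
    "com_angle_series",
    "min_distance_series",
    "count_clashes",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # applied after rotation, nm
    rmsd: float               # nm

    def transform(self, coordinates: np.ndarray) -> np.ndarray:
        return coordinates @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SeriesResult:
    values: np.ndarray
    unit: str
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.frame_indices):
            raise ValueError("one value per analyzed frame required")
        if not self.unit:
            raise ValueError("unit must be non-empty")


@dataclass(frozen=True)
class ProfileResult:
    values: np.ndarray
    labels: np.ndarray  # residue indices (or atom serials)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("label count must equal value count")


def _require_nonempty(sel: Selection, what: str = "selection") -> np.ndarray:
    if len(sel) == 0:
        raise ValueError(f"empty {what}: {sel.expression!r}")
    return sel.indices


def center_of_mass(frame: Frame, selection: Selection, topology: Topology) -> np.ndarray:
    idx = _require_nonempty(selection)
    masses = topology.masses[idx]
    coords = frame.coordinates[idx]
    return masses @ coords / masses.sum()


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted least-squares rigid superposition of mobile onto reference.

    Returns the proper rotation (det = +1) and translation minimizing the
    weighted RMSD, together with that minimum RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have the same shape")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    w = (
        np.ones(mobile.shape[0])
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    # collinearity check: rank of the centered reference cloud
    if np.linalg.matrix_rank(np.vstack([x, y]), tol=1e-12) < 2:
        raise ValueError("degenerate (collinear) point sets: rotation not unique")

    h = x.T @ (y * w[:, None])
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    fitted = x @ rotation.T + cr
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - reference) ** 2)))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _fitted_coordinates(
    coords: np.ndarray, reference: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Superpose each frame of (n_frames, n_atoms, 3) onto reference."""
    out = np.empty_like(coords)
    for t in range(coords.shape[0]):
        sp = kabsch_superpose(coords[t], reference, weights)
        out[t] = sp.transform(coords[t])
    return out


def rmsd_series(
    trajectory: Trajectory,
    selection: Selection,
    reference_frame_index: int = 0,
    fit: bool = True,
) -> SeriesResult:
    """Per-frame RMSD against a reference frame, optionally after fitting."""
    idx = _require_nonempty(selection)
    n = trajectory.n_frames
    if not -n <= reference_frame_index < n:
        raise IndexError(f"reference frame {reference_frame_index} out of range")
    masses = trajectory.topology.masses[idx]
    w = masses / masses.sum()
    ref = trajectory.frames[reference_frame_index].coordinates[idx]
    values = np.empty(n)
    for t, fr in enumerate(trajectory.frames):
        mob = fr.coordinates[idx]
        if fit:
            values[t] = kabsch_superpose(mob, ref, masses).rmsd
        else:
            values[t] = np.sqrt(np.sum(w[:, None] * (mob - ref) ** 2))
    return SeriesResult(values=values, unit="nm", frame_indices=np.arange(n))


def _analysis_window(n_frames: int, discard: int | tuple[int, int] | None) -> slice:
    if discard is None:
        return slice(0, n_frames)
    if isinstance(discard, int):
        return slice(discard, n_frames)
    start, stop = discard
    return slice(start, stop)


def rmsf_profile(
    trajectory: Trajectory,
    selection: Selection,
    fit: bool = True,
    discard: int | tuple[int, int] | None = None,
) -> ProfileResult:
    """Per-atom root-mean-square fluctuation about the time-average position.

    With fit=True each frame is first superposed onto the first analyzed
    frame, the mean structure of the fitted coordinates is formed, and
    each frame is then superposed onto that mean; fluctuations are
    measured about the post-fit mean (standard essential-dynamics
    practice).
    """
    idx = _require_nonempty(selection)
    window = _analysis_window(trajectory.n_frames, discard)
    coords = trajectory.coordinate_array()[window][:, idx, :]
    if coords.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 analyzed frames")
    masses = trajectory.topology.masses[idx]
    if fit:
        coords = _fitted_coordinates(coords, coords[0], masses)
        coords = _fitted_coordinates(coords, coords.mean(axis=0), masses)
    mean = coords.mean(axis=0)
    msf = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
    labels = np.array(
        [trajectory.topology.atoms[i].residue_index for i in idx], dtype=int
    )
    return ProfileResult(values=np.sqrt(msf), labels=labels)


def radius_of_gyration_series(
    trajectory: Trajectory, selection: Selection
) -> SeriesResult:
    """Mass-weighted radius of gyration per frame (nm)."""
    idx = _require_nonempty(selection)
    masses = trajectory.topology.masses[idx]
    total = masses.sum()
    values = np.empty(trajectory.n_frames)
    for t, fr in enumerate(trajectory.frames):
        r = fr.coordinates[idx]
        com = masses @ r / total
        values[t] = np.sqrt(masses @ np.sum((r - com) ** 2, axis=1) / total)
    return SeriesResult(
        values=values, unit="nm", frame_indices=np.arange(trajectory.n_frames)
    )


def com_distance_series(
    trajectory: Trajectory, sel_a: Selection, sel_b: Selection
) -> SeriesResult:
    """Per-frame distance between the centers of mass of two selections."""
    _require_nonempty(sel_a)
    _require_nonempty(sel_b)
    top = trajectory.topology
    values = np.array(
        [
            np.linalg.norm(
                center_of_mass(fr, sel_a, top) - center_of_mass(fr, sel_b, top)
            )
            for fr in trajectory.frames
        ]
    )
    return SeriesResult(
        values=values, unit="nm", frame_indices=np.arange(trajectory.n_frames)
    )


def com_angle_series(
    trajectory: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    sel_c: Selection,
) -> SeriesResult:
    """Per-frame angle (degrees) at COM(B) between COM(A) and COM(C).

    The vertex is the middle selection; the angle lies in [0, 180].
    """
    for s in (sel_a, sel_b, sel_c):
        _require_nonempty(s)
    top = trajectory.topology
    values = np.empty(trajectory.n_frames)
    for t, fr in enumerate(trajectory.frames):
        a = center_of_mass(fr, sel_a, top)
        b = center_of_mass(fr, sel_b, top)
        c = center_of_mass(fr, sel_c, top)
        v1 = a - b
        v2 = c - b
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0.0 or n2 == 0.0:
            raise ValueError(f"frame {t}: coincident centers of mass, angle undefined")
        cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        values[t] = np.degrees(np.arccos(cosang))
    return SeriesResult(
        values=values, unit="degrees", frame_indices=np.arange(trajectory.n_frames)
    )


def min_distance_series(
    trajectory: Trajectory, sel_a: Selection, sel_b: Selection
) -> SeriesResult:
    """Per-frame minimum pairwise atom distance between two selections.

    Self-pairs (the same atom appearing in both selections) are excluded,
    so overlapping selections report the closest distinct-atom pair.
    """
    ia = _require_nonempty(sel_a)
    ib = _require_nonempty(sel_b)
    same = ia[:, None] == ib[None, :]
    values = np.empty(trajectory.n_frames)
    for t, fr in enumerate(trajectory.frames):
        d = cdist(fr.coordinates[ia], fr.coordinates[ib])
        d[same] = np.inf
        values[t] = d.min()
    return SeriesResult(
        values=values, unit="nm", frame_indices=np.arange(trajectory.n_frames)
    )


def count_clashes(
    frame: Frame, topology: Topology, threshold: float = 0.22
) -> int:
    """Number of heavy-atom pairs closer than threshold (nm).

    Pairs within the same residue and covalently bonded pairs are
    excluded; each unordered pair counts once.
    """
    if threshold <= 0:
        raise ValueError("clash threshold must be positive")
    heavy = np.array(
        [i for i, a in enumerate(topology.atoms) if a.element.upper() != "H"],
        dtype=int,
    )
    if len(heavy) < 2:
        return 0
    res_keys = topology.residue_key_per_atom()
    coords = frame.coordinates[heavy]
    d = cdist(coords, coords)
    count = 0
    for p in range(len(heavy)):
        for q in range(p + 1, len(heavy)):
            i, j = int(heavy[p]), int(heavy[q])
            if res_keys[i] == res_keys[j]:
                continue
            if (min(i, j), max(i, j)) in topology.covalent_pairs:
                continue
            if d[p, q] < threshold:
                count += 1
    return count
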