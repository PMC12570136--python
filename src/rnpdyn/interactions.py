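"""Protein-RNA interface interactions: hydrogen bonds, contacts, stacking.

Hydrogen bonds use the donor-acceptor distance / hydrogen-donor-acceptor
angle criterion (defaults: D-A < 0.30 nm, angle < 30 deg, both strict).
Pi-pi stacking uses aromatic ring centroid distance (< 0.55 nm) and the
angle between least-squares ring-plane normals folded to [0, 90] deg
(<= 40 deg).  Contact persistence uses minimum heavy-atom cross-distance
per residue pair.  Occupancies are exact rational counts over the
analyzed frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import _analysis_window
from .selection import Selection
from .topology import Topology
from .trajectory import Frame, Trajectory

__all__ = [
    "HBond",
    "OccupancyTable",
    "RingSpec",
    "StackingPair",
    "StackingCriteria",
    "DEFAULT_RING_SPEC",
    "assign_donors_acceptors",
    "detect_hbonds_frame",
    "hbond_occupancy",
    "contact_frequency",
    "ring_geometry",
    "detect_stacking_frame",
    "stacking_occupancy",
]


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    present: np.ndarray | None = None  # per-frame flags

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.donor, self.hydrogen, self.acceptor)


@dataclass
class OccupancyTable:
    occupancies: dict  # interaction key -> fraction in [0, 1]
    n_frames: int

    def filtered(self, cutoff: float) -> "OccupancyTable":
        kept = {k: v for k, v in self.occupancies.items() if v >= cutoff}
        return OccupancyTable(occupancies=kept, n_frames=self.n_frames)


@dataclass(frozen=True)
class StackingCriteria:
    d_cut: float = 0.55        # ring centroid distance cutoff, nm
    alpha_cut: float = 40.0    # inter-plane angle cutoff, degrees
    occupancy_cut: float = 0.40

    def __post_init__(self) -> None:
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if not 0 < self.alpha_cut <= 90:
            raise ValueError("alpha_cut must be in (0, 90] degrees")
        if not 0 <= self.occupancy_cut <= 1:
            raise ValueError("occupancy_cut must be in [0, 1]")


@dataclass
class StackingPair:
    protein_residue: tuple[str, int]
    nucleic_residue: tuple[str, int]
    present: np.ndarray
    occupancy: float


@dataclass
class RingSpec:
    """residue_name -> ordered ring atom names used for centroid and plane."""

    rings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for resname, names in self.rings.items():
            if len(names) < 3:
                raise ValueError(f"ring for {resname} needs >= 3 atom names")


# Default ring atoms.  The aromatic side-chain subset CG/CE1/CE2/CZ covers
# Tyr/Phe/His-like six-membered rings; the pyrimidine subset N1/C2/N3/C5
# covers uracil/cytosine-like bases (C2 completes the published N1/N3/C5
# trio).  User-overridable per residue name.
DEFAULT_RING_SPEC = RingSpec(
    rings={
        "TYR": ["CG", "CE1", "CE2", "CZ"],
        "PHE": ["CG", "CE1", "CE2", "CZ"],
        "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
        "TRP": ["CG", "CD1", "CD2", "NE1", "CE2"],
        "U": ["N1", "C2", "N3", "C5"],
        "C": ["N1", "C2", "N3", "C5"],
        "A": ["N1", "C2", "N3", "C5"],
        "G": ["N1", "C2", "N3", "C5"],
    }
)

_POLAR_ELEMENTS = {"N", "O"}


def assign_donors_acceptors(
    topology: Topology, reference: Frame | None = None
) -> tuple[list[tuple[int, int]], list[int]]:
    """Identify donor (D, H) pairs and acceptor atoms.

    Donors are N/O atoms with at least one covalently attached hydrogen;
    acceptors are all N/O atoms.  Attachment comes from the topology's
    covalent pairs or, failing that, is inferred from a reference frame
    as X-H distances below 0.12 nm.
    """
    atoms = topology.atoms
    hydrogens = [i for i, a in enumerate(atoms) if a.element.upper() == "H"]
    polar = [i for i, a in enumerate(atoms) if a.element.upper() in _POLAR_ELEMENTS]
    if not hydrogens:
        raise ValueError(
            "topology has no hydrogens: hydrogen-bond analysis needs protonated input"
        )
    donors: list[tuple[int, int]] = []
    if topology.covalent_pairs:
        for i, j in sorted(topology.covalent_pairs):
            a, b = atoms[i], atoms[j]
            if a.element.upper() in _POLAR_ELEMENTS and b.element.upper() == "H":
                donors.append((i, j))
            elif b.element.upper() in _POLAR_ELEMENTS and a.element.upper() == "H":
                donors.append((j, i))
    elif reference is not None:
        coords = reference.coordinates
        d = cdist(coords[polar], coords[hydrogens])
        for pi, di in enumerate(polar):
            for hi, h in enumerate(hydrogens):
                if d[pi, hi] < 0.12:
                    donors.append((di, h))
    else:
        raise ValueError(
            "need covalent pairs or a reference frame to attach hydrogens to donors"
        )
    return donors, polar


def detect_hbonds_frame(
    frame: Frame,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    topology: Topology,
    dist_cut: float = 0.30,
    angle_cut: float = 30.0,
) -> list[HBond]:
    """Hydrogen bonds in one frame.

    A bond exists iff |D-A| < dist_cut and the angle at D between D->H and
    D->A is < angle_cut (both strict), with D and A in different residues.
    """
    if dist_cut <= 0 or angle_cut <= 0:
        raise ValueError("cutoffs must be positive")
    coords = frame.coordinates
    res_keys = topology.residue_key_per_atom()
    hits: list[HBond] = []
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx == d_idx or res_keys[a_idx] == res_keys[d_idx]:
                continue
            da = coords[a_idx] - coords[d_idx]
            dist = np.linalg.norm(da)
            if dist >= dist_cut or dist == 0.0:
                continue
            dh = coords[h_idx] - coords[d_idx]
            nh = np.linalg.norm(dh)
            if nh == 0.0:
                continue
            cosang = np.clip(dh @ da / (nh * dist), -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) < angle_cut:
                hits.append(HBond(donor=d_idx, hydrogen=h_idx, acceptor=a_idx))
    return hits


def hbond_occupancy(
    trajectory: Trajectory,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    dist_cut: float = 0.30,
    angle_cut: float = 30.0,
    discard: int | tuple[int, int] | None = None,
    occupancy_cut: float = 0.20,
) -> tuple[OccupancyTable, OccupancyTable]:
    """Per-(D,H,A) occupancy over analyzed frames (unfiltered, filtered).

    The filtered view keeps occupancies >= occupancy_cut.  Pairs never
    formed are absent from both tables.
    """
    window = _analysis_window(trajectory.n_frames, discard)
    frames = trajectory.frames[window]
    if not frames:
        raise ValueError("empty analysis window")
    counts: dict[tuple[int, int, int], int] = {}
    for fr in frames:
        for hit in detect_hbonds_frame(
            fr, donors, acceptors, trajectory.topology, dist_cut, angle_cut
        ):
            counts[hit.key] = counts.get(hit.key, 0) + 1
    n = len(frames)
    table = OccupancyTable(
        occupancies={k: c / n for k, c in counts.items()}, n_frames=n
    )
    return table, table.filtered(occupancy_cut)


def contact_frequency(
    trajectory: Trajectory,
    group_a: Selection,
    group_b: Selection,
    topology: Topology | None = None,
    contact_dist: float = 0.45,
    persistence_cut: float = 0.50,
    discard: int | tuple[int, int] | None = None,
) -> tuple[dict, dict]:
    """Residue-pair contact frequencies (all pairs, persistent pairs).

    A residue pair is in contact in a frame iff the minimum heavy-atom
    cross-distance is below contact_dist; pairs with frequency >=
    persistence_cut form the persistent (reported) table.
    """
    top = topology or trajectory.topology
    ia, ib = group_a.indices, group_b.indices
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("contact groups must be non-empty")
    heavy_a = np.array([i for i in ia if top.atoms[i].element.upper() != "H"])
    heavy_b = np.array([i for i in ib if top.atoms[i].element.upper() != "H"])
    res_keys = top.residue_key_per_atom()
    key_a = [res_keys[i] for i in heavy_a]
    key_b = [res_keys[i] for i in heavy_b]
    window = _analysis_window(trajectory.n_frames, discard)
    frames = trajectory.frames[window]
    if not frames:
        raise ValueError("empty analysis window")
    counts: dict[tuple, int] = {}
    for fr in frames:
        d = cdist(fr.coordinates[heavy_a], fr.coordinates[heavy_b])
        in_contact = set()
        close = np.argwhere(d < contact_dist)
        for p, q in close:
            ka, kb = key_a[p], key_b[q]
            if ka != kb:
                in_contact.add((ka, kb))
        for pair in in_contact:
            counts[pair] = counts.get(pair, 0) + 1
    n = len(frames)
    freqs = {k: c / n for k, c in counts.items()}
    persistent = {k: v for k, v in freqs.items() if v >= persistence_cut}
    return freqs, persistent


def ring_geometry(
    frame: Frame,
    topology: Topology,
    residue_key: tuple[str, int],
    ringspec: RingSpec = DEFAULT_RING_SPEC,
) -> tuple[np.ndarray, np.ndarray]:
    """Ring centroid (nm) and unit plane normal for one residue.

    The centroid is the unweighted mean of the resolvable ring atoms; the
    normal is the least-squares plane normal (direction of smallest
    variance, via SVD of the centered ring coordinates).
    """
    chain, resid = residue_key
    res = next(
        (
            r
            for r in topology.residues
            if r.chain_id == chain and r.residue_index == resid
        ),
        None,
    )
    if res is None:
        raise KeyError(f"no residue {resid} in chain {chain!r}")
    names = ringspec.rings.get(res.residue_name)
    if names is None:
        raise ValueError(f"no ring definition for residue name {res.residue_name!r}")
    idx = [
        i
        for i in res.atom_indices
        if topology.atoms[i].name in names
    ]
    if len(idx) < 3:
        raise ValueError(
            f"ring undefined for {res.residue_name}{resid} (chain {chain}): "
            f"only {len(idx)} of {len(names)} ring atoms resolvable"
        )
    pts = frame.coordinates[idx]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[-1]
    return centroid, normal / np.linalg.norm(normal)


def detect_stacking_frame(
    frame: Frame,
    topology: Topology,
    protein_rings: list[tuple[str, int]],
    nucleic_rings: list[tuple[str, int]],
    criteria: StackingCriteria = StackingCriteria(),
    ringspec: RingSpec = DEFAULT_RING_SPEC,
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Stacked ring pairs in one frame.

    A pair stacks iff the centroid distance is < d_cut (strict) and the
    angle between plane normals, folded to [0, 90] deg, is <= alpha_cut.
    """
    hits = []
    geo_p = [
        (key, *ring_geometry(frame, topology, key, ringspec)) for key in protein_rings
    ]
    geo_n = [
        (key, *ring_geometry(frame, topology, key, ringspec)) for key in nucleic_rings
    ]
    for kp, cp, np_ in geo_p:
        for kn, cn, nn in geo_n:
            if np.linalg.norm(cp - cn) >= criteria.d_cut:
                continue
            cosang = np.clip(abs(np_ @ nn), 0.0, 1.0)
            alpha = np.degrees(np.arccos(cosang))
            if alpha <= criteria.alpha_cut:
                hits.append((kp, kn))
    return hits


def stacking_occupancy(
    trajectory: Trajectory,
    protein_rings: list[tuple[str, int]],
    nucleic_rings: list[tuple[str, int]],
    criteria: StackingCriteria = StackingCriteria(),
    ringspec: RingSpec = DEFAULT_RING_SPEC,
    discard: int | tuple[int, int] | None = None,
) -> tuple[list[StackingPair], list[StackingPair]]:
    """Per-pair stacking occupancy (all observed pairs, filtered pairs)."""
    window = _analysis_window(trajectory.n_frames, discard)
    frames = trajectory.frames[window]
    if not frames:
        raise ValueError("empty analysis window")
    n = len(frames)
    flags: dict[tuple, np.ndarray] = {}
    for t, fr in enumerate(frames):
        for kp, kn in detect_stacking_frame(
            fr, trajectory.topology, protein_rings, nucleic_rings, criteria, ringspec
        ):
            flags.setdefault((kp, kn), np.zeros(n, dtype=bool))[t] = True
    pairs = [
        StackingPair(
            protein_residue=kp,
            nucleic_residue=kn,
            present=mask,
            occupancy=float(mask.sum()) / n,
        )
        for (kp, kn), mask in flags.items()
    ]
    kept = [p for p in pairs if p.occupancy >= criteria.occupancy_cut]
    return pairs, kept
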