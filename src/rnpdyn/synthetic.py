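"""Synthetic topologies and trajectories with planted, exactly-known structure.

Every analysis stage in this package is validated against ensembles whose
statistics are known by construction: per-atom Gaussian fluctuations with
a prescribed correlation structure, interaction events (hydrogen bonds,
ring stacking) switched on/off at exact per-frame occupancies, and rigid
domain motions realizing prescribed center-of-mass distance and angle
distributions.  Randomness comes from numpy's PCG64 generator with an
explicit seed; identical configurations yield bit-identical output.

Event masks are deterministic stratified assignments (exactly
round(occupancy * n_frames) "on" frames, spread evenly), not Bernoulli
draws, so occupancy recovery tests are exact rational counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import AtomRecord, Topology, polymer_class_of, ELEMENT_MASSES
from .trajectory import Frame, Trajectory

__all__ = [
    "FluctuationSpec",
    "EventPlan",
    "GeneratorConfig",
    "build_toy_complex",
    "generate_fluctuating_trajectory",
    "plant_hbond_events",
    "plant_stacking_events",
    "generate_domain_motion",
    "event_mask",
]


@dataclass
class FluctuationSpec:
    """Per-atom isotropic sigmas (nm) plus pairwise correlation blocks.

    Each block is (atom indices A, atom indices B, target correlation);
    the implied atom-level correlation matrix must be positive
    semidefinite, validated at build time.
    """

    sigmas: np.ndarray
    correlation_blocks: list[tuple[list[int], list[int], float]] = field(
        default_factory=list
    )

    def correlation_matrix(self, n_atoms: int) -> np.ndarray:
        corr = np.eye(n_atoms)
        for set_a, set_b, rho in self.correlation_blocks:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation {rho} outside [-1, 1]")
            for i in set_a:
                for j in set_b:
                    if i != j:
                        corr[i, j] = corr[j, i] = rho
        evals = np.linalg.eigvalsh(corr)
        if evals.min() < -1e-8:
            raise ValueError(
                f"correlation blocks imply a non-PSD matrix "
                f"(min eigenvalue {evals.min():.3e})"
            )
        return corr


@dataclass(frozen=True)
class EventPlan:
    """Target occupancy and the on/off geometry toggled per frame."""

    occupancy: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_frames: int = 100
    frame_spacing: float = 1.0  # ps


def event_mask(n_frames: int, occupancy: float) -> np.ndarray:
    """Deterministic stratified on/off mask with exactly round(occ*n) on-frames."""
    count = int(round(occupancy * n_frames))
    mask = np.zeros(n_frames, dtype=bool)
    if count > 0:
        mask[(np.arange(count) * n_frames) // count] = True
    return mask


# ---------------------------------------------------------------------------
# Toy complex construction
# ---------------------------------------------------------------------------

_TOY_PROTEIN_CYCLE = ["ALA", "SER", "TYR", "LYS"]  # every 3rd pattern has a ring

# Minimal atom sets: backbone N (with amide H), CA, C, O everywhere, plus
# side chains giving each analysis something to chew on: SER has a
# hydroxyl donor, TYR a six-membered aromatic ring.
_SIDECHAINS = {
    "ALA": [("CB", "C")],
    "LYS": [("CB", "C"), ("NZ", "N"), ("HZ1", "H")],
    "SER": [("CB", "C"), ("OG", "O"), ("HG", "H")],
    "TYR": [
        ("CB", "C"),
        ("CG", "C"),
        ("CD1", "C"),
        ("CD2", "C"),
        ("CE1", "C"),
        ("CE2", "C"),
        ("CZ", "C"),
        ("OH", "O"),
        ("HH", "H"),
    ],
}

_RNA_ATOMS = [
    ("P", "P"),
    ("C1'", "C"),
    ("N1", "N"),
    ("C2", "C"),
    ("O2", "O"),
    ("N3", "N"),
    ("H3", "H"),
    ("C4", "C"),
    ("O4", "O"),
    ("C5", "C"),
    ("C6", "C"),
]

_RING_NAMES_PROTEIN = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]  # hexagon order
_RING_NAMES_RNA = ["N1", "C2", "N3", "C4", "C5", "C6"]


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = 0.139) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(normal @ seed_vec) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed_vec)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.arange(6) * np.pi / 3.0
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def build_toy_complex(
    n_protein_res: int, n_rna_nt: int, seed: int = 0
) -> tuple[Topology, Frame]:
    """A small protein-RNA complex with rings, donors, and two chains.

    The protein chain (A) follows an extended curve with 0.38 nm residue
    spacing and cycles through Ala/Ser/Tyr/Lys-like residues, so it always
    contains hydroxyl donors and at least one aromatic ring when
    n_protein_res >= 3.  The RNA chain (B) carries uracil-like bases with
    planar N1/C2/N3/C4/C5/C6 rings.  Deterministic for a fixed seed.
    """
    if n_protein_res < 2 or n_rna_nt < 1:
        raise ValueError("need n_protein_res >= 2 and n_rna_nt >= 1")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    covalent: set[tuple[int, int]] = set()
    serial = 0

    def add_atom(name, element, resname, resid, chain, pos) -> int:
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                mass=ELEMENT_MASSES.get(element.upper(), 1.0),
                residue_name=resname,
                residue_index=resid,
                chain_id=chain,
                polymer_class=polymer_class_of(resname),
            )
        )
        coords.append(np.asarray(pos, dtype=float))
        return len(atoms) - 1

    # --- protein chain A along a gentle helix-like curve
    for r in range(n_protein_res):
        resname = _TOY_PROTEIN_CYCLE[r % len(_TOY_PROTEIN_CYCLE)]
        resid = r + 1
        base = np.array(
            [0.38 * r, 0.15 * np.sin(0.6 * r), 0.15 * np.cos(0.6 * r)]
        )
        jitter = rng.normal(0.0, 0.005, size=3)
        n_i = add_atom("N", "N", resname, resid, "A", base + jitter)
        h_i = add_atom("H", "H", resname, resid, "A", coords[-1] + [0.0, 0.10, 0.0])
        covalent.add((n_i, h_i))
        ca_i = add_atom("CA", "C", resname, resid, "A", base + [0.12, 0.0, 0.05])
        covalent.add((n_i, ca_i))
        c_i = add_atom("C", "C", resname, resid, "A", base + [0.24, 0.05, 0.0])
        covalent.add((ca_i, c_i))
        o_i = add_atom("O", "O", resname, resid, "A", base + [0.24, 0.17, 0.0])
        covalent.add((c_i, o_i))
        side_anchor = coords[ca_i] + np.array([0.0, -0.15, 0.10])
        if resname == "TYR":
            cb_i = add_atom("CB", "C", resname, resid, "A", side_anchor)
            covalent.add((ca_i, cb_i))
            ring_center = side_anchor + np.array([0.0, -0.25, 0.0])
            ring_normal = np.array([0.0, 0.0, 1.0])
            ring = _hexagon(ring_center, ring_normal)
            prev = cb_i
            for name, pos in zip(_RING_NAMES_PROTEIN, ring):
                i = add_atom(name, "C", resname, resid, "A", pos)
                covalent.add((prev, i))
                prev = i
            oh_i = add_atom(
                "OH", "O", resname, resid, "A", ring_center + [0.0, -0.25, 0.0]
            )
            covalent.add((prev, oh_i))
            hh_i = add_atom(
                "HH", "H", resname, resid, "A", coords[oh_i] + [0.0, -0.097, 0.0]
            )
            covalent.add((oh_i, hh_i))
        else:
            prev = ca_i
            offset = 0.0
            for name, element in _SIDECHAINS[resname]:
                # hydrogens sit 0.10 nm from their parent (covalent X-H)
                offset += 0.10 if element == "H" else 0.14
                pos = side_anchor + np.array([0.0, -offset, 0.0])
                i = add_atom(name, element, resname, resid, "A", pos)
                covalent.add((prev, i))
                prev = i

    # --- RNA chain B offset from the protein
    rna_offset = np.array([0.0, 1.5, 0.0])
    for r in range(n_rna_nt):
        resid = r + 1
        base = rna_offset + np.array(
            [0.45 * r, 0.1 * np.sin(0.5 * r), 0.1 * np.cos(0.5 * r)]
        )
        ring_center = base + np.array([0.0, 0.35, 0.0])
        ring = _hexagon(ring_center, np.array([0.0, 0.0, 1.0]))
        ring_pos = dict(zip(_RING_NAMES_RNA, ring))
        first_of_res: dict[str, int] = {}
        for name, element in _RNA_ATOMS:
            if name in ring_pos:
                pos = ring_pos[name]
            elif name == "P":
                pos = base
            elif name == "C1'":
                pos = base + np.array([0.0, 0.2, 0.0])
            elif name in ("O2", "H3", "O4"):
                # exocyclic atoms point outward from the ring center
                parent = {"O2": "C2", "H3": "N3", "O4": "C4"}[name]
                outward = ring_pos[parent] - ring_center
                outward /= np.linalg.norm(outward)
                bond = 0.10 if name == "H3" else 0.125
                pos = ring_pos[parent] + bond * outward
            else:
                pos = base
            first_of_res[name] = add_atom(name, element, "U", resid, "B", pos)
        # covalent wiring sufficient for donor/acceptor and clash exclusion
        covalent.add((first_of_res["P"], first_of_res["C1'"]))
        covalent.add((first_of_res["C1'"], first_of_res["N1"]))
        ring_cycle = _RING_NAMES_RNA + ["N1"]
        for a, b in zip(ring_cycle, ring_cycle[1:]):
            covalent.add(
                (min(first_of_res[a], first_of_res[b]), max(first_of_res[a], first_of_res[b]))
            )
        covalent.add((first_of_res["C2"], first_of_res["O2"]))
        covalent.add((first_of_res["N3"], first_of_res["H3"]))
        covalent.add((first_of_res["C4"], first_of_res["O4"]))

    topology = Topology(atoms=atoms, covalent_pairs=covalent)
    return topology, Frame(np.array(coords))


# ---------------------------------------------------------------------------
# Fluctuating trajectories
# ---------------------------------------------------------------------------

def generate_fluctuating_trajectory(
    reference: Frame,
    spec: FluctuationSpec,
    config: GeneratorConfig,
    topology: Topology | None = None,
    rigid_motion: bool = False,
) -> Trajectory | list[Frame]:
    """Reference + correlated Gaussian displacements realizing the spec.

    Displacements are isotropic per atom: each Cartesian axis carries an
    independent sample of the atom-level correlation structure scaled by
    the per-atom sigma, so the displacement-vector correlation between
    atoms i and j equals the planted entry.  With rigid_motion=True every
    frame additionally receives a random global roto-translation, which
    exercises superposition-based analyses.
    """
    n_atoms = reference.coordinates.shape[0]
    sigmas = np.asarray(spec.sigmas, dtype=float)
    if sigmas.shape != (n_atoms,):
        raise ValueError("spec.sigmas must have one entry per atom")
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be >= 0")
    corr = spec.correlation_matrix(n_atoms)
    evals, evecs = np.linalg.eigh(corr)
    factor = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    rng = np.random.default_rng(config.seed)
    # independent stream for rigid motion: toggling it must not change the
    # planted displacements, only compose a transform on top of them
    rng_rigid = np.random.default_rng([config.seed, 1])
    frames: list[Frame] = []
    for t in range(config.n_frames):
        z = rng.standard_normal((n_atoms, 3))
        disp = (factor @ z) * sigmas[:, None]
        coords = reference.coordinates + disp
        if rigid_motion:
            coords = _random_rigid(rng_rigid, coords)
        frames.append(Frame(coords, time=t * config.frame_spacing))
    if topology is not None:
        return Trajectory(topology, frames)
    return frames


def _random_rigid(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.normal(0.0, 1.0, size=3)
    return coords @ q.T + shift


# ---------------------------------------------------------------------------
# Planted interaction events
# ---------------------------------------------------------------------------

def plant_hbond_events(
    trajectory: Trajectory,
    donor: int,
    hydrogen: int,
    acceptor: int,
    plan: EventPlan,
    on_distance: float = 0.28,
    off_distance: float = 0.40,
    angle_deg: float = 10.0,
) -> Trajectory:
    """Overwrite a D/H/A triplet so the bond exists at an exact occupancy.

    On-frames realize (on_distance, angle_deg); off-frames the same angle
    at off_distance (outside the default 0.30 nm criterion).
    """
    n_atoms = trajectory.topology.n_atoms
    for idx in (donor, hydrogen, acceptor):
        if not 0 <= idx < n_atoms:
            raise IndexError(f"atom index {idx} out of range")
    mask = event_mask(trajectory.n_frames, plan.occupancy)
    theta = np.radians(angle_deg)
    frames = []
    for t, fr in enumerate(trajectory.frames):
        coords = fr.coordinates.copy()
        d_pos = coords[donor]
        dist = on_distance if mask[t] else off_distance
        coords[acceptor] = d_pos + np.array([dist, 0.0, 0.0])
        coords[hydrogen] = d_pos + 0.10 * np.array(
            [np.cos(theta), np.sin(theta), 0.0]
        )
        frames.append(Frame(coords, time=fr.time, box=fr.box))
    return Trajectory(trajectory.topology, frames)


def plant_stacking_events(
    trajectory: Trajectory,
    protein_residue: tuple[str, int],
    nucleic_residue: tuple[str, int],
    plan: EventPlan,
    on_distance: float = 0.35,
    off_distance: float = 0.80,
) -> Trajectory:
    """Place a base ring parallel to a protein ring at an exact occupancy.

    On-frames put the ring centroids on_distance apart along the protein
    ring normal with parallel planes; off-frames use off_distance.
    """
    top = trajectory.topology

    def ring_atoms(key: tuple[str, int], names: list[str]) -> list[int]:
        chain, resid = key
        res = next(
            (
                r
                for r in top.residues
                if r.chain_id == chain and r.residue_index == resid
            ),
            None,
        )
        if res is None:
            raise KeyError(f"no residue {resid} in chain {chain!r}")
        idx = [i for i in res.atom_indices if top.atoms[i].name in names]
        if len(idx) < 3:
            raise ValueError(f"ring undefined for residue {key}")
        return idx

    p_idx = ring_atoms(protein_residue, _RING_NAMES_PROTEIN)
    n_idx = ring_atoms(nucleic_residue, _RING_NAMES_RNA)
    mask = event_mask(trajectory.n_frames, plan.occupancy)
    frames = []
    for t, fr in enumerate(trajectory.frames):
        coords = fr.coordinates.copy()
        p_pts = coords[p_idx]
        centroid = p_pts.mean(axis=0)
        _, _, vt = np.linalg.svd(p_pts - centroid)
        normal = vt[-1]
        dist = on_distance if mask[t] else off_distance
        target_center = centroid + dist * normal
        coords[n_idx] = _hexagon(target_center, normal)[: len(n_idx)]
        frames.append(Frame(coords, time=fr.time, box=fr.box))
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# Planted domain motion
# ---------------------------------------------------------------------------

def _sample_mixture(
    rng: np.random.Generator, modes: list[tuple[float, float, float]], n: int
) -> np.ndarray:
    """Sample a Gaussian mixture given (mean, sigma, weight) modes."""
    means = np.array([m[0] for m in modes])
    sigmas = np.array([m[1] for m in modes])
    weights = np.array([m[2] for m in modes], dtype=float)
    weights = weights / weights.sum()
    which = rng.choice(len(modes), size=n, p=weights)
    return rng.normal(means[which], sigmas[which])


def generate_domain_motion(
    reference: Frame,
    topology: Topology,
    domain_a: np.ndarray,
    domain_b: np.ndarray,
    domain_c: np.ndarray,
    dist_ab_modes: list[tuple[float, float, float]],
    dist_bc_modes: list[tuple[float, float, float]],
    angle_modes: list[tuple[float, float, float]],
    config: GeneratorConfig = GeneratorConfig(),
) -> Trajectory:
    """Rigid-body domain placement realizing COM distance/angle mixtures.

    Domain B stays put; per frame, domains A and C are rigidly translated
    so that COM distances |AB|, |BC| and the angle A-B-C (at B, degrees)
    are draws from the given Gaussian mixtures.  Mixture modes are
    (mean, sigma, weight) tuples.
    """
    masses = topology.masses
    for name, idx in (("A", domain_a), ("B", domain_b), ("C", domain_c)):
        if len(idx) == 0:
            raise ValueError(f"domain {name} selection is empty")
    for modes, what in (
        (dist_ab_modes, "distance"),
        (dist_bc_modes, "distance"),
        (angle_modes, "angle"),
    ):
        for mean, sigma, weight in modes:
            if sigma < 0 or weight <= 0:
                raise ValueError(f"bad {what} mode ({mean}, {sigma}, {weight})")
            if what == "distance" and mean <= 0:
                raise ValueError(f"infeasible geometry: {what} mean {mean} <= 0")
            if what == "angle" and not 0 < mean < 180:
                raise ValueError(f"infeasible geometry: angle mean {mean} outside (0, 180)")

    def com(idx: np.ndarray, coords: np.ndarray) -> np.ndarray:
        m = masses[idx]
        return m @ coords[idx] / m.sum()

    rng = np.random.default_rng(config.seed)
    d_ab = np.abs(_sample_mixture(rng, dist_ab_modes, config.n_frames))
    d_bc = np.abs(_sample_mixture(rng, dist_bc_modes, config.n_frames))
    theta = np.clip(_sample_mixture(rng, angle_modes, config.n_frames), 1e-6, 180 - 1e-6)

    ref = reference.coordinates
    com_b = com(domain_b, ref)
    frames = []
    for t in range(config.n_frames):
        coords = ref.copy()
        target_a = com_b + np.array([d_ab[t], 0.0, 0.0])
        ang = np.radians(theta[t])
        target_c = com_b + d_bc[t] * np.array([np.cos(ang), np.sin(ang), 0.0])
        coords[domain_a] += target_a - com(domain_a, ref)
        coords[domain_c] += target_c - com(domain_c, ref)
        frames.append(Frame(coords, time=t * config.frame_spacing))
    return Trajectory(topology, frames)
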