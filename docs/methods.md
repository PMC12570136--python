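# Methods

This note documents the models and procedures implemented in `rnpdyn`,
the defaults they ship with, and the design choices made where more than
one convention is in common use.

## Units and coordinate handling

All internal coordinates are nanometres and times picoseconds (the
GROMACS convention, which also matches the units in which the standard
interaction cutoffs are quoted). PDB files are converted at the I/O
boundary (Å ÷ 10 on read, × 10 on write); the plain-text XYZ dialect
(`n_atoms / time=<ps> / name x y z` per frame) is stored in nm directly.
Residue indices are kept verbatim from the source file — no renumbering —
so author-numbered domain windows (e.g. RRM1 = residues 20–98 in HuR)
apply without translation. Periodic-boundary minimum-image corrections
are deliberately out of scope: inputs are assumed to be whole, re-imaged
molecules, as is standard for post-processed analysis ensembles.

## Superposition and fluctuation statistics

Rigid-body fitting uses the Kabsch algorithm: SVD of the weighted
cross-covariance matrix with the determinant correction that excludes
reflections. Weights default to atomic masses for trajectory statistics.
Degenerate (collinear) point sets are rejected rather than silently
fitted, since the rotation is not unique there.

RMSF uses the mean structure as reference in two steps: every frame is
first fitted to the first analyzed frame, the mean of the fitted
coordinates is formed, each frame is then fitted to that mean, and
fluctuations are measured about the post-fit mean. This is standard
essential-dynamics practice; a `fit=False` mode measures raw
fluctuations for cases where frames are already aligned (and is what the
closed-form recovery checks use, since fitting re-absorbs six degrees of
freedom and biases per-atom fluctuations low by a factor
≈ sqrt(1 − 6/3N) on small selections). Whether an upstream tool's RMSF
used a first-frame or mean-structure reference is often unknowable from
its output; both behaviours are reachable through the flags.

## Interdomain geometry

COM distances are Euclidean distances between mass-weighted centroids.
The three-domain angle is measured at the COM of the *middle* selection
(for HuR: the angle at RRM2 between RRM1 and RRM3), in [0°, 180°];
the convention had to be fixed because a three-COM angle is ambiguous,
and the middle-domain vertex is the physically meaningful hinge choice.
Coincident COMs raise an undefined-angle error rather than returning 0.

## GROMOS clustering

Daura's greedy neighbor-count algorithm on a pairwise (optionally
superposed) RMSD matrix: count neighbors within the cutoff, take the
conformation with the most neighbors as a centroid, remove it and its
neighbors as one cluster, repeat. Two choices the original description
leaves open are fixed and documented: the neighbor test is strict
(`< cutoff`), and neighbor-count ties break toward the lowest
conformation index. Cluster ids are 1-based in order of decreasing size.
Typical cutoffs are 0.31 nm for model-convergence checks and 0.60 nm for
trajectory conformational states.

## Essential dynamics and cross-correlation

PCA diagonalizes the covariance of flattened Cartesian coordinates
(1/N normalization) after superposition onto the first analyzed frame;
eigenpairs are sorted by decreasing eigenvalue, and variance fractions
are eigenvalue/trace. Projections are centered coordinates dotted with
eigenvectors, so the variance of PC-k projections equals eigenvalue k by
construction. PC1/PC2 densities are computed on rectangular bins
normalized to a maximum of 1; hexagonal binning is treated as a
presentation-only choice.

The DCCM normalizes displacement covariances per atom pair:
`C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`, with displacements
taken about the post-fit mean after superposition onto the first
analyzed frame (a `fit=False` mode skips superposition for pre-aligned
input). Atoms whose positional variance is below 1e-18 nm² are treated
as static: their rows and columns are set to 0 (diagonal 1) and a
warning is emitted, since a 0/0 correlation is undefined.

## Interaction criteria

* **Hydrogen bonds**: donor–acceptor distance strictly < 0.30 nm *and*
  hydrogen–donor–acceptor angle strictly < 30°, donor and acceptor in
  different residues. Donors are N/O atoms with a covalently attached
  hydrogen (from explicit covalent pairs, or inferred as X–H pairs
  closer than 0.12 nm in a reference frame); acceptors are all N/O.
  Unprotonated topologies raise an explicit error.
* **Contacts**: a residue pair is in contact when the minimum
  heavy-atom cross-distance is < 0.45 nm (this cutoff is a package
  default — no single literature value exists — and is configurable and
  echoed in output); pairs are reported as persistent at ≥ 50 % of
  analyzed frames.
* **π–π stacking**: ring centroid distance strictly < 0.55 nm and the
  angle between least-squares ring-plane normals, folded to [0°, 90°]
  so antiparallel normals count as stacked, ≤ 40°. The default ring
  definitions use the published atom subsets (CG/CE1/CE2/CZ for
  aromatic side chains; N1/C2/N3/C5 for pyrimidine bases, where C2
  completes the published N1/N3/C5 trio) and are user-overridable via
  `RingSpec`. Note that an asymmetric atom subset shifts the centroid
  off the geometric ring center by up to ~0.06 nm; the full-ring spec
  is available when exact ring-center geometry matters. A stacking
  distance printed as "5.5 nm" in common protocols is interpreted here
  as 0.55 nm (5.5 Å): 5.5 nm is physically meaningless for base
  stacking, 5.5 Å is the standard literature cutoff; the value actually
  used is logged in every output header.
* **Occupancies** are exact rational counts (present frames / analyzed
  frames) over the post-discard window, filtered *inclusively*
  (≥ cutoff) at 20 % for hydrogen bonds, 50 % for contact persistence,
  and 40 % for stacking.

The boundary semantics — strict `<` for the geometric criteria (matching
"shorter than" / "less than" phrasing), inclusive `≥` for the occupancy
filters — are part of the tested contract.

## Synthetic data: what it emulates and what it does not

The generator produces systems whose statistics are known exactly:

* `build_toy_complex` — a two-chain protein/RNA topology with backbone,
  hydroxyl donors, a tyrosine-like aromatic ring, and uracil-like base
  rings, placed on a smooth curve with 0.38 nm Cα spacing (protein) and
  0.45 nm base spacing (RNA). It is deterministic per seed.
* `generate_fluctuating_trajectory` — reference + correlated Gaussian
  displacements. Each Cartesian axis carries an independent draw from an
  atom-level correlation matrix (validated positive semidefinite) scaled
  by per-atom σ, so the displacement-vector correlation between two
  atoms equals the planted entry and the per-atom RMSF tends to σ√3.
  Optional per-frame random rigid motion exercises superposition.
* `plant_hbond_events` / `plant_stacking_events` — overwrite a
  donor/hydrogen/acceptor triplet (0.28 nm, 10° on; 0.40 nm off) or
  place a base ring parallel to a protein ring (0.35 nm on; 0.80 nm
  off). On-frames are a deterministic stratified mask with exactly
  `round(occupancy × n_frames)` members, so recovered occupancies are
  exact rationals, not Bernoulli estimates.
* `generate_domain_motion` — rigid-body translation of three domains
  realizing Gaussian-mixture distributions over the two COM distances
  and the vertex angle.

Randomness uses numpy's seeded PCG64 generator throughout; identical
configurations give bit-identical trajectories.

What the generator does **not** emulate: force-field energetics,
bonded geometry beyond rough bond lengths, solvent, periodicity,
anharmonic or diffusive dynamics, and sequence-accurate HuR/RNA
structure. Passing recovery tests therefore demonstrates the
*correctness of the statistical machinery* — that each estimator
recovers what was planted — not that any particular biological system
behaves a given way.

## Problem sizes and tolerances

Validation runs use desk-scale problems chosen so sampling error is
well below the planted signals: 5000 frames for closed-form fluctuation,
correlation, and variance-fraction recovery (Monte-Carlo standard errors
≈ 1–2 %), 1000 frames for exact occupancy checks, 3000 frames for
distance/angle mode recovery, and 1000 random small fixtures per
detector-vs-oracle equivalence check. Exact arithmetic (sequence
lengths, charges, ion counts, occupancy rationals, cluster memberships)
is asserted exactly; stochastic recoveries are asserted within three
standard errors of their closed forms.

## Sequence and charge accounting

The pH-7 standard scheme charges Asp/Glu −1, Lys/Arg +1, His 0, and
treats free zwitterionic termini as net zero; RNA with a 5′-OH terminus
carries −1 per phosphodiester linkage (length − 1). This matches common
MD system-preparation defaults and makes counter-ion arithmetic
checkable: the 27-nt IL-3 ARE carries −26 e and full-length HuR −6 e,
so the solvated complex takes 32 Na⁺. The HuR net charge ships as a
documented reference constant (`refdata.HUR_NET_CHARGE_PH7`); supply the
full UniProt sequence to `formal_charge` to recompute it from first
principles. Published ion counts for related coarse-grained systems
(e.g. 7 Na⁺) imply a different protein charge under that force field's
conventions; the package exposes the arithmetic and does not attempt to
reconcile such differences. Alternative protonation schemes are accepted
through the scheme tag and raise an explicit error when unknown.

## Known limitations

* No periodic-boundary handling; pre-image your trajectories.
* H-bond detection requires explicit hydrogens (by design — inferring
  protons is a preparation step, not an analysis step).
* The selection mini-language covers names, residue ranges, residue
  names, chains, polymer classes, and heavy atoms with boolean algebra,
  but not distance-based or index-based selections.
* Clash counting excludes same-residue and explicitly covalent pairs
  only; 1–3/1–4 bonded neighbors across residues count as clashes if
  within the threshold (0.22 nm default, configurable), which matches
  its use as a model-quality screen rather than a force-field exclusion
  list.
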