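"""Membrane trajectory observables.

Operates on a :class:`Trajectory` (frames of Cartesian coordinates with an
orthorhombic box) and a :class:`Topology` (per-atom names, residues, group
labels, partial charges, Lennard-Jones parameters, masses, and explicit
heavy-atom→hydrogen parent links).  Implemented observables:

- signed z-separation distributions between a probe group and the nearest
  lipid molecules (re-selected each frame by center-of-mass distance),
- hydrogen-bond time fractions per chemical group, counting multiplicity,
- deuterium order parameters SCD(k) = ⟨(3cos²θ_CH − 1)/2⟩ per acyl carbon,
- acyl-chain tilt-angle distributions against the bilayer normal (+z),
- pairwise Coulomb + Lennard-Jones interaction energies between a probe and
  the molecules found inside a cutoff sphere, under the minimum-image
  convention.

Coordinates are in Å, charges in e, energies in kcal mol⁻¹; atom indices are
0-based internally and 1-based in error messages and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Trajectory",
    "DistanceDistribution",
    "HBondReport",
    "OrderProfile",
    "TiltDistribution",
    "EnergyTrace",
    "z_distance_distribution",
    "hbond_time_fractions",
    "scd_profile",
    "tilt_distribution",
    "pairwise_interaction_energy",
    "COULOMB_CONSTANT",
]

# Coulomb constant in kcal·Å·mol⁻¹·e⁻², consistent with Amber-family fields
COULOMB_CONSTANT = 332.0636

TOPOLOGY_COLUMNS = [
    "name",
    "resname",
    "resid",
    "group",
    "charge_e",
    "sigma_A",
    "epsilon_kcal",
    "mass_amu",
    "parent",
]


@dataclass
class Topology:
    """Per-atom static description of the system.

    ``atoms`` is a DataFrame with columns ``name, resname, resid, group,
    charge_e, sigma_A, epsilon_kcal, mass_amu, parent`` where ``parent`` is
    the 0-based index of the bonded heavy atom for hydrogens and −1
    otherwise.  ``selections`` maps selection names to 0-based atom indices.
    """

    atoms: pd.DataFrame
    selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"topology table is missing columns {missing}")
        self.atoms = self.atoms.reset_index(drop=True)
        num = self.atoms[["charge_e", "sigma_A", "epsilon_kcal", "mass_amu"]].to_numpy(float)
        if not np.all(np.isfinite(num[:, 0])):
            raise ValueError("partial charges must be finite")
        if np.any(num[:, 1] < 0) or np.any(num[:, 2] < 0):
            raise ValueError("LJ sigma and epsilon must be non-negative")
        if np.any(num[:, 3] <= 0):
            raise ValueError("masses must be positive")
        parent = self.atoms["parent"].to_numpy(int)
        if np.any(parent >= self.n_atoms) or np.any(parent < -1):
            raise ValueError("parent indices out of range")
        self.selections = {
            k: np.asarray(v, dtype=int) for k, v in self.selections.items()
        }
        for name, idx in self.selections.items():
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
                raise ValueError(f"selection {name!r} references atoms out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return self.atoms["mass_amu"].to_numpy(float)

    @property
    def charges(self) -> np.ndarray:
        return self.atoms["charge_e"].to_numpy(float)

    def select(self, selection) -> np.ndarray:
        """Resolve a selection name or an index sequence to atom indices."""
        if isinstance(selection, str):
            try:
                idx = self.selections[selection]
            except KeyError:
                raise KeyError(
                    f"unknown selection {selection!r}; available: {sorted(self.selections)}"
                ) from None
        else:
            idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise ValueError("empty selection")
        return idx

    def hydrogens_of(self, index: int) -> np.ndarray:
        """Hydrogens bonded to heavy atom ``index`` via the parent links."""
        parent = self.atoms["parent"].to_numpy(int)
        return np.nonzero(parent == index)[0]


@dataclass
class Trajectory:
    """Multi-frame coordinates with a per-frame orthorhombic box.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å, ``box`` shape
    (n_frames, 3) in Å; ``times`` (ns) is optional.
    """

    coordinates: np.ndarray
    box: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        self.box = np.asarray(self.box, float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.coordinates.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.times is not None:
            self.times = np.asarray(self.times, float)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class DistanceDistribution:
    """Histogram density of signed z-separations (Å)."""

    bin_edges: np.ndarray  # Å
    density: np.ndarray  # Å⁻¹, integrates to 1
    samples: np.ndarray | None = None  # per-frame separations, kept for stats

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.density = np.asarray(self.density, float)
        if self.density.size != self.bin_edges.size - 1:
            raise ValueError("density must have one entry per bin")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        integral = float(np.sum(self.density * np.diff(self.bin_edges)))
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(f"density integrates to {integral!r}, not 1")

    @property
    def mean(self) -> float:
        if self.samples is not None:
            return float(np.mean(self.samples))
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(np.sum(mid * self.density * np.diff(self.bin_edges)))


@dataclass
class HBondReport:
    """Per-group hydrogen-bonding time fractions, counting multiplicity.

    A group engaged in one persistent bond scores 1.0; a second bond present
    in half the frames raises it to 1.5, so values above one are meaningful.
    ``donor_fractions``/``acceptor_fractions`` split the same counts by role.
    """

    fractions: dict[str, float]
    donor_fractions: dict[str, float]
    acceptor_fractions: dict[str, float]
    n_frames: int

    def __post_init__(self):
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("time fractions must be non-negative")


@dataclass
class OrderProfile:
    """Deuterium order parameter per acyl carbon index."""

    carbon_index: np.ndarray  # chain position labels (from atom-name suffixes)
    scd: np.ndarray  # in [−0.5, 1]

    def __post_init__(self):
        self.carbon_index = np.asarray(self.carbon_index, int)
        self.scd = np.asarray(self.scd, float)
        if self.carbon_index.shape != self.scd.shape:
            raise ValueError("carbon_index and scd must have equal length")
        if np.any((self.scd < -0.5 - 1e-9) | (self.scd > 1.0 + 1e-9)):
            raise ValueError("SCD values must lie in [-0.5, 1]")


@dataclass
class TiltDistribution:
    """Histogram density of chain tilt angles against +z (degrees)."""

    bin_edges: np.ndarray  # degrees
    density: np.ndarray  # deg⁻¹, integrates to 1
    folded: bool = False
    samples: np.ndarray | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.density = np.asarray(self.density, float)
        if self.density.size != self.bin_edges.size - 1:
            raise ValueError("density must have one entry per bin")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        integral = float(np.sum(self.density * np.diff(self.bin_edges)))
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(f"density integrates to {integral!r}, not 1")

    @property
    def mean(self) -> float:
        if self.samples is not None:
            return float(np.mean(self.samples))
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(np.sum(mid * self.density * np.diff(self.bin_edges)))


@dataclass
class EnergyTrace:
    """Per-frame nonbonded interaction energies, kcal mol⁻¹."""

    electrostatic: np.ndarray
    van_der_waals: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.electrostatic = np.asarray(self.electrostatic, float)
        self.van_der_waals = np.asarray(self.van_der_waals, float)
        if self.electrostatic.shape != self.van_der_waals.shape:
            raise ValueError("energy series must have equal length")
        if not (
            np.all(np.isfinite(self.electrostatic))
            and np.all(np.isfinite(self.van_der_waals))
        ):
            raise ValueError("energies must be finite")


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return delta - box * np.round(delta / box)


def _center_of_mass(coords: np.ndarray, masses: np.ndarray, idx: np.ndarray) -> np.ndarray:
    m = masses[idx]
    return (coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def z_distance_distribution(
    traj: Trajectory,
    topo: Topology,
    probe_selection,
    reference_selection,
    bin_width: float = 1.0,
    n_closest_molecules: int | None = 6,
) -> DistanceDistribution:
    """Signed z-separation between a probe group and the nearest lipids.

    Per frame, the mass-weighted center of the probe selection is compared
    with the center of the ``n_closest_molecules`` reference molecules
    (grouped by residue id, re-ranked every frame by minimum-image
    center-of-mass distance; ``None`` uses the whole reference selection).
    The signed separation z_probe − z_reference is histogrammed and
    normalized to a probability density.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    probe = topo.select(probe_selection)
    ref = topo.select(reference_selection)
    masses = topo.masses
    resids = topo.atoms["resid"].to_numpy(int)
    ref_groups = [ref[resids[ref] == r] for r in np.unique(resids[ref])]
    samples = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        box = traj.box[f]
        com_probe = _center_of_mass(coords, masses, probe)
        coms = np.array([_center_of_mass(coords, masses, g) for g in ref_groups])
        if n_closest_molecules is not None and n_closest_molecules < len(ref_groups):
            d = np.linalg.norm(minimum_image(coms - com_probe, box), axis=1)
            keep = np.argsort(d, kind="stable")[:n_closest_molecules]
            ref_atoms = np.concatenate([ref_groups[i] for i in keep])
        else:
            ref_atoms = ref
        com_ref = _center_of_mass(coords, masses, ref_atoms)
        dz = com_probe[2] - com_ref[2]
        samples[f] = dz - box[2] * np.round(dz / box[2])
    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(samples, bins=edges, density=True)
    return DistanceDistribution(bin_edges=edges, density=density, samples=samples)


def hbond_time_fractions(
    traj: Trajectory,
    topo: Topology,
    donors,
    acceptors,
    d_max: float = 3.5,
    angle_min: float = 135.0,
) -> HBondReport:
    """Per-group hydrogen-bond time fractions.

    A hydrogen bond exists in a frame when the donor-heavy–acceptor
    minimum-image distance is ≤ ``d_max`` Å and the D–H···A angle (at the
    hydrogen) is ≥ ``angle_min`` degrees.  Each bond increments the donor
    atom's group and the acceptor atom's group; fractions are total counts
    divided by the number of frames, so multiple simultaneous bonds push a
    group's fraction above one.
    """
    donor_idx = topo.select(donors)
    acceptor_idx = topo.select(acceptors)
    groups = [str(g) for g in topo.atoms["group"]]
    dh_pairs = []  # (donor heavy, hydrogen)
    for d in donor_idx:
        hyds = topo.hydrogens_of(int(d))
        if hyds.size == 0:
            raise ValueError(
                f"donor atom {int(d) + 1} ({topo.atoms.at[int(d), 'name']}) has no bonded hydrogen"
            )
        dh_pairs.extend((int(d), int(h)) for h in hyds)
    cos_min = np.cos(np.radians(angle_min))
    donor_counts: dict[str, float] = {}
    acceptor_counts: dict[str, float] = {}
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        box = traj.box[f]
        for d, h in dh_pairs:
            da = minimum_image(coords[acceptor_idx] - coords[d], box)
            dist = np.linalg.norm(da, axis=1)
            hd = minimum_image(coords[d] - coords[h], box)
            ha = minimum_image(coords[acceptor_idx] - coords[h], box)
            # angle at H between H→D and H→A; linear D–H···A gives 180°,
            # and angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
            cosang = (ha @ hd) / (np.linalg.norm(ha, axis=1) * np.linalg.norm(hd) + 1e-300)
            bonded = (dist <= d_max) & (cosang <= cos_min)
            bonded &= acceptor_idx != d  # a donor never accepts from itself
            for a in acceptor_idx[bonded]:
                donor_counts[groups[d]] = donor_counts.get(groups[d], 0.0) + 1.0
                acceptor_counts[groups[a]] = acceptor_counts.get(groups[a], 0.0) + 1.0
    nf = float(traj.n_frames)
    donor_fr = {k: v / nf for k, v in donor_counts.items()}
    acceptor_fr = {k: v / nf for k, v in acceptor_counts.items()}
    combined: dict[str, float] = {}
    for src in (donor_fr, acceptor_fr):
        for k, v in src.items():
            combined[k] = combined.get(k, 0.0) + v
    return HBondReport(
        fractions=combined,
        donor_fractions=donor_fr,
        acceptor_fractions=acceptor_fr,
        n_frames=traj.n_frames,
    )


def _name_suffix_number(name: str) -> int | None:
    digits = "".join(ch for ch in name if ch.isdigit())
    return int(digits) if digits else None


def _reconstruct_ch_directions(c_prev, c_k, c_next):
    """Ideal tetrahedral C–H unit vectors of a CH₂ from its carbon neighbors."""
    u = c_next - c_prev
    u /= np.linalg.norm(u)
    v = (c_prev - c_k) + (c_next - c_k)
    v /= np.linalg.norm(v)
    v -= u * (u @ v)  # orthogonalize against the chain direction
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    half = np.radians(0.5 * 109.471)
    h1 = -v * np.cos(half) + w * np.sin(half)
    h2 = -v * np.cos(half) - w * np.sin(half)
    return h1, h2


def scd_profile(
    traj: Trajectory,
    topo: Topology,
    chain_selection,
    normal_axis: int = 2,
    reconstruct_h: bool = False,
    absolute: bool = False,
) -> OrderProfile:
    """Deuterium order parameter per acyl carbon.

    SCD(k) = ⟨(3 cos²θ_CH − 1)/2⟩ averaged over lipids, frames and the C–H
    bonds of carbon k, with θ_CH measured against the bilayer normal
    (``normal_axis``, z by default).  Carbon positions are read from the
    numeric suffix of the atom names (C2, C3, …) within each residue of the
    selection.  Carbons without bonded hydrogens raise an error unless
    ``reconstruct_h`` is set, in which case interior carbons get ideal
    tetrahedral CH₂ directions rebuilt from their carbon neighbors (terminal
    carbons are then skipped).  ``absolute`` reports |SCD|.
    """
    sel = topo.select(chain_selection)
    names = topo.atoms["name"].to_numpy(str)
    resids = topo.atoms["resid"].to_numpy(int)
    carbons = [i for i in sel if names[i].upper().startswith("C")]
    if not carbons:
        raise ValueError("chain selection contains no carbon atoms")
    # (resid, chain position) -> atom index
    by_res: dict[int, list[tuple[int, int]]] = {}
    for i in carbons:
        k = _name_suffix_number(names[i])
        if k is None:
            raise ValueError(f"carbon atom {i + 1} ({names[i]}) has no numeric suffix")
        by_res.setdefault(resids[i], []).append((k, i))
    positions = sorted({k for pairs in by_res.values() for k, _ in pairs})
    sums: dict[int, float] = {k: 0.0 for k in positions}
    counts: dict[int, int] = {k: 0 for k in positions}
    axis = normal_axis
    for res, pairs in by_res.items():
        pairs.sort()
        pos_to_atom = dict(pairs)
        for k, i in pairs:
            hyds = topo.hydrogens_of(i)
            if hyds.size == 0 and not reconstruct_h:
                raise ValueError(
                    f"carbon atom {i + 1} ({names[i]}) has no bonded hydrogens; "
                    "set reconstruct_h=True for ideal tetrahedral reconstruction"
                )
            if hyds.size > 0:
                vec = traj.coordinates[:, hyds, :] - traj.coordinates[:, [i], :]
                cos = vec[..., axis] / np.linalg.norm(vec, axis=-1)
                vals = 0.5 * (3.0 * cos**2 - 1.0)
                sums[k] += float(vals.sum())
                counts[k] += vals.size
            else:
                prev_i = pos_to_atom.get(k - 1)
                next_i = pos_to_atom.get(k + 1)
                if prev_i is None or next_i is None:
                    continue  # terminal carbon: no reconstruction possible
                for f in range(traj.n_frames):
                    c = traj.coordinates[f]
                    h1, h2 = _reconstruct_ch_directions(c[prev_i], c[i], c[next_i])
                    for h in (h1, h2):
                        sums[k] += 0.5 * (3.0 * h[axis] ** 2 - 1.0)
                        counts[k] += 1
    kept = [k for k in positions if counts[k] > 0]
    scd = np.array([sums[k] / counts[k] for k in kept])
    if absolute:
        scd = np.abs(scd)
    return OrderProfile(carbon_index=np.array(kept, int), scd=scd)


def tilt_distribution(
    traj: Trajectory,
    topo: Topology,
    chain_selection,
    fold: bool = False,
    bin_width: float = 2.0,
) -> TiltDistribution:
    """Distribution of acyl-chain tilt angles against the +z normal.

    The chain vector runs from the first to the last tail carbon (by
    atom-name numeric suffix) of each residue in the selection.  Unfolded
    angles span [0, 180]° and show both leaflets (lower-leaflet chains point
    against +z); ``fold`` maps θ → min(θ, 180 − θ).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sel = topo.select(chain_selection)
    names = topo.atoms["name"].to_numpy(str)
    resids = topo.atoms["resid"].to_numpy(int)
    carbons = [i for i in sel if names[i].upper().startswith("C")]
    by_res: dict[int, list[tuple[int, int]]] = {}
    for i in carbons:
        k = _name_suffix_number(names[i])
        if k is None:
            raise ValueError(f"carbon atom {i + 1} ({names[i]}) has no numeric suffix")
        by_res.setdefault(resids[i], []).append((k, i))
    chains = []
    for res, pairs in by_res.items():
        if len(pairs) < 2:
            raise ValueError(f"residue {res} has fewer than 2 chain atoms")
        pairs.sort()
        chains.append((pairs[0][1], pairs[-1][1]))
    first = np.array([a for a, _ in chains])
    last = np.array([b for _, b in chains])
    vec = traj.coordinates[:, last, :] - traj.coordinates[:, first, :]
    norm = np.linalg.norm(vec, axis=-1)
    if np.any(norm == 0):
        raise ValueError("degenerate zero-length chain vector")
    theta = np.degrees(np.arccos(np.clip(vec[..., 2] / norm, -1.0, 1.0))).ravel()
    if fold:
        theta = np.minimum(theta, 180.0 - theta)
        top = 90.0
    else:
        top = 180.0
    edges = np.arange(0.0, top + 0.5 * bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, top)
    density, edges = np.histogram(theta, bins=edges, density=True)
    return TiltDistribution(bin_edges=edges, density=density, folded=fold, samples=theta)


def pairwise_interaction_energy(
    traj: Trajectory,
    topo: Topology,
    selection_a,
    selection_b,
    cutoff: float = 12.0,
) -> EnergyTrace:
    """Coulomb + Lennard-Jones energy between a probe and nearby molecules.

    Per frame, every molecule (residue) of ``selection_b`` with any atom
    within ``cutoff`` Å of any atom of ``selection_a`` (minimum image) is
    retained, and the full pair sum between ``selection_a`` and those
    molecules' atoms is evaluated:

        E_elec = Σ 332.0636 q_i q_j / r_ij
        E_vdw  = Σ 4 ε_ij [(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶]

    with Lorentz–Berthelot combination (σ_ij arithmetic, ε_ij geometric).
    Intra-selection pairs are never computed; the two selections are assumed
    disjoint.
    """
    a = topo.select(selection_a)
    b = topo.select(selection_b)
    charges = topo.charges
    sigma = topo.atoms["sigma_A"].to_numpy(float)
    epsilon = topo.atoms["epsilon_kcal"].to_numpy(float)
    both = np.concatenate([a, b])
    bad = both[~np.isfinite(charges[both] + sigma[both] + epsilon[both])]
    if bad.size:
        raise ValueError(
            f"missing nonbonded parameters for atom(s) {sorted((bad + 1).tolist())}"
        )
    resids = topo.atoms["resid"].to_numpy(int)
    b_groups = [b[resids[b] == r] for r in np.unique(resids[b])]
    sig_ij_all = 0.5 * (sigma[a][:, None] + sigma[b][None, :])
    eps_ij_all = np.sqrt(epsilon[a][:, None] * epsilon[b][None, :])
    q_ij_all = charges[a][:, None] * charges[b][None, :]
    # map b atom index -> column in the (a, b) matrices
    col = {int(j): jj for jj, j in enumerate(b)}
    elec = np.zeros(traj.n_frames)
    vdw = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        box = traj.box[f]
        delta = minimum_image(coords[b][None, :, :] - coords[a][:, None, :], box)
        dist = np.linalg.norm(delta, axis=-1)
        cols = []
        for g in b_groups:
            gc = [col[int(j)] for j in g]
            if dist[:, gc].min() <= cutoff:
                cols.extend(gc)
        if not cols:
            continue
        cols = np.asarray(cols, int)
        r = dist[:, cols]
        elec[f] = COULOMB_CONSTANT * float(np.sum(q_ij_all[:, cols] / r))
        sr6 = (sig_ij_all[:, cols] / r) ** 6
        vdw[f] = float(np.sum(4.0 * eps_ij_all[:, cols] * (sr6**2 - sr6)))
    times = traj.times.copy() if traj.times is not None else None
    return EnergyTrace(electrostatic=elec, van_der_waals=vdw, times=times)
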