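"""Seeded synthetic-data generators with known ground truth.

Each generator emulates the statistical structure of one experimental input
class — two-phase compression isotherms with an LE/LC plateau, pseudo-first-
order insertion traces, polarized ATR spectra built from band parameters and
dipole-orientation-dependent p/s intensities, capacitance-derived impedance
sweeps, and idealized bilayer trajectories — and returns the data object
together with a machine-readable truth record, so every analysis stage has a
recovery test without any experimental raw data.  Trajectories use ideal
tetrahedral geometry, not a force field; they validate observable code, not
physics.

All randomness flows through one ``numpy.random.default_rng(seed)`` per call;
the same parameters and seed reproduce the output exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atr import OpticalConfig, PolarizedSpectrum, interface_field_intensities, pseudo_voigt
from .eis import ImpedanceSweep
from .monolayer import InsertionTrace, Isotherm
from .trajectory import Topology, Trajectory

__all__ = [
    "gen_isotherm",
    "gen_insertion_traces",
    "gen_polarized_spectra",
    "gen_eis_sweep",
    "gen_bilayer_trajectory",
    "DEFAULT_CH_BANDS",
]

MAGIC_ANGLE = float(np.degrees(np.arccos(np.sqrt(1.0 / 3.0))))  # 54.7356°


# ---------------------------------------------------------------------------
# Langmuir monolayer


def gen_isotherm(
    seed: int = 0,
    moduli: tuple[float, float, float] = (100.0, 5.0, 200.0),
    plateau_pressure: float = 20.0,
    plateau_width: float = 1.0,
    pi_start: float = 0.5,
    pi_max: float = 45.0,
    n_points: int = 400,
    area_start: float = 100.0,
    area_shift: float = 0.0,
    noise_sigma: float = 0.05,
    temperature: float = 24.0,
    label: str = "synthetic two-phase isotherm",
):
    """Piecewise constant-modulus compression isotherm.

    A(π) = A_i exp(−(π − π_i)/C_i) over contiguous π-segments — a
    liquid-expanded branch, a low-modulus transition plateau of width
    ``plateau_width`` centered at ``plateau_pressure``, and a condensed
    branch — continuous at the joins.  ``area_shift`` adds a rigid molecular-
    area offset (a solute-present film); Gaussian noise of ``noise_sigma``
    lands on the pressure channel.  Pass a single-element ``moduli`` (or a
    zero-width plateau) for a one-phase film.
    """
    moduli = tuple(float(c) for c in np.atleast_1d(moduli))
    if any(c <= 0 for c in moduli):
        raise ValueError("segment moduli must be positive")
    if plateau_width < 0:
        raise ValueError("plateau width must be non-negative")
    if len(moduli) == 3:
        b1 = plateau_pressure - 0.5 * plateau_width
        b2 = plateau_pressure + 0.5 * plateau_width
        if not (pi_start < b1 < b2 < pi_max) and plateau_width > 0:
            raise ValueError("plateau must lie strictly inside (pi_start, pi_max)")
        bounds = [pi_start, b1, b2, pi_max]
    elif len(moduli) == 1:
        bounds = [pi_start, pi_max]
    else:
        raise ValueError("moduli must have 1 (single-phase) or 3 (two-phase) entries")
    rng = np.random.default_rng(seed)
    pi = np.linspace(pi_start, pi_max, n_points)
    area = np.empty_like(pi)
    a_join = area_start
    for (lo, hi), c in zip(zip(bounds[:-1], bounds[1:]), moduli):
        seg = (pi >= lo) & (pi <= hi)
        area[seg] = a_join * np.exp(-(pi[seg] - lo) / c)
        a_join = a_join * np.exp(-(hi - lo) / c)
    area = area + area_shift
    if np.any(area <= 0):
        raise ValueError("area_shift drives molecular areas non-positive")
    pi_noisy = pi + rng.normal(0.0, noise_sigma, size=pi.shape)
    order = np.argsort(area)[::-1]  # compression direction: decreasing area
    iso = Isotherm(
        area_per_molecule=area[order],
        surface_pressure=pi_noisy[order],
        temperature=temperature,
        label=label,
    )
    truth = {
        "kind": "isotherm",
        "seed": seed,
        "moduli_mN_m": list(moduli),
        "segment_bounds_mN_m": bounds,
        "plateau_pressure_mN_m": plateau_pressure if len(moduli) == 3 else None,
        "plateau_width_mN_m": plateau_width if len(moduli) == 3 else None,
        "area_start_A2": area_start,
        "area_shift_A2": area_shift,
        "noise_sigma_mN_m": noise_sigma,
    }
    return iso, truth


def gen_insertion_traces(
    seed: int = 0,
    pi0_values=(10.0, 15.0, 20.0, 25.0, 30.0),
    slope: float = -0.2,
    intercept: float = 10.5,
    beta: float = 0.01,
    duration: float = 600.0,
    n_points: int = 600,
    noise_sigma: float = 0.05,
):
    """Pseudo-first-order insertion traces with Δπ_max linear in π₀.

    Δπ(t) = Δπ_max(π₀)(1 − e^{−βt}) with Δπ_max(π₀) = slope·π₀ + intercept,
    plus Gaussian noise.  The truth record carries the exclusion pressure
    −intercept/slope implied by the line.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    traces = []
    dpi_max_true = []
    for pi0 in pi0_values:
        dmax = slope * pi0 + intercept
        dpi_max_true.append(dmax)
        y = dmax * (1.0 - np.exp(-beta * t)) + rng.normal(0.0, noise_sigma, size=t.shape)
        y[0] = 0.0  # injection instant defines the baseline
        traces.append(InsertionTrace(time=t, delta_pi=y, pi_zero=float(pi0)))
    truth = {
        "kind": "insertion",
        "seed": seed,
        "slope": slope,
        "intercept_mN_m": intercept,
        "beta_per_s": beta,
        "exclusion_pressure_mN_m": -intercept / slope if slope < 0 else None,
        "delta_pi_max_mN_m": dpi_max_true,
        "pi0_mN_m": list(pi0_values),
        "noise_sigma_mN_m": noise_sigma,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# Polarized ATR spectra

# Six-band CH-stretch fixture: methylene stretches carry the oriented TDMs,
# methyl/Fermi bands sit at the magic angle (isotropic dichroism).
DEFAULT_CH_BANDS = (
    {"center": 2850.0, "fwhm": 10.0, "frac": 0.3, "strength": 0.010, "theta_dip": 67.0},
    {"center": 2873.0, "fwhm": 12.0, "frac": 0.3, "strength": 0.0035, "theta_dip": MAGIC_ANGLE},
    {"center": 2898.0, "fwhm": 14.0, "frac": 0.3, "strength": 0.0025, "theta_dip": MAGIC_ANGLE},
    {"center": 2921.0, "fwhm": 14.0, "frac": 0.3, "strength": 0.013, "theta_dip": 62.0},
    {"center": 2936.0, "fwhm": 14.0, "frac": 0.3, "strength": 0.004, "theta_dip": MAGIC_ANGLE},
    {"center": 2958.0, "fwhm": 12.0, "frac": 0.3, "strength": 0.005, "theta_dip": MAGIC_ANGLE},
)


def _mean_cos2(theta_dip: float, orientation_sd: float | None) -> float:
    """⟨cos²θ⟩ for a delta or Gaussian orientation distribution (degrees)."""
    if orientation_sd is None or orientation_sd == 0.0:
        return float(np.cos(np.radians(theta_dip)) ** 2)
    th = np.radians(np.linspace(0.0, 90.0, 2001))
    w = np.exp(-0.5 * ((th - np.radians(theta_dip)) / np.radians(orientation_sd)) ** 2)
    w *= np.sin(th)  # uniaxial solid-angle weight
    return float(np.trapezoid(w * np.cos(th) ** 2, th) / np.trapezoid(w, th))


def gen_polarized_spectra(
    seed: int = 0,
    bands=DEFAULT_CH_BANDS,
    optics: OpticalConfig | None = None,
    grid: tuple[float, float, float] = (2800.0, 3000.0, 0.5),
    baseline_p: tuple[float, ...] = (0.0005, 1e-6),
    baseline_s: tuple[float, ...] = (0.0004, -1e-6),
    noise_sigma: float = 1e-4,
    orientation_sd: float | None = None,
):
    """Forward-model polarized absorbances from band orientations.

    For each band with ⟨c²⟩ = ⟨cos²θ_dip⟩ (a delta orientation by default, a
    Gaussian distribution of width ``orientation_sd`` otherwise) the peak
    heights are

        A_p = K·[Ex²(1−⟨c²⟩)/2 + Ez²⟨c²⟩],   A_s = K·Ey²(1−⟨c²⟩)/2,

    with K the band strength, drawn as pseudo-Voigt line shapes over the
    wavenumber grid, plus a polynomial baseline per polarization and Gaussian
    noise.  The truth record includes each band's dichroic ratio and areas.
    """
    cfg = optics or OpticalConfig(wavenumber=2900.0)
    fields = interface_field_intensities(cfg)
    lo, hi, step = grid
    x = np.arange(lo, hi + 0.5 * step, step)
    rng = np.random.default_rng(seed)
    yp = np.polynomial.polynomial.polyval(x - 0.5 * (lo + hi), baseline_p)
    ys = np.polynomial.polynomial.polyval(x - 0.5 * (lo + hi), baseline_s)
    yp = np.asarray(yp, float).copy()
    ys = np.asarray(ys, float).copy()
    truth_bands = []
    from .atr import pseudo_voigt_area

    for band in bands:
        c, w, f = band["center"], band["fwhm"], band["frac"]
        if not (lo <= c <= hi):
            raise ValueError(f"band center {c} cm^-1 lies outside the grid")
        c2 = _mean_cos2(band["theta_dip"], orientation_sd)
        amp_p = band["strength"] * (fields.ex2 * (1.0 - c2) / 2.0 + fields.ez2 * c2)
        amp_s = band["strength"] * fields.ey2 * (1.0 - c2) / 2.0
        yp += pseudo_voigt(x, amp_p, c, w, f)
        ys += pseudo_voigt(x, amp_s, c, w, f)
        area_p = float(pseudo_voigt_area(amp_p, w, f))
        area_s = float(pseudo_voigt_area(amp_s, w, f))
        truth_bands.append(
            {
                "center_cm1": c,
                "fwhm_cm1": w,
                "frac": f,
                "theta_dip_deg": band["theta_dip"],
                "mean_cos2": c2,
                "amplitude_p": float(amp_p),
                "amplitude_s": float(amp_s),
                "area_p": area_p,
                "area_s": area_s,
                "dichroic_ratio": area_p / area_s,
            }
        )
    yp += rng.normal(0.0, noise_sigma, size=x.shape)
    ys += rng.normal(0.0, noise_sigma, size=x.shape)
    spec = PolarizedSpectrum(wavenumber=x, absorbance_p=yp, absorbance_s=ys)
    truth = {
        "kind": "atr_spectrum",
        "seed": seed,
        "optics": {
            "n1": cfg.n1,
            "n2": cfg.n2,
            "beta_inc_deg": cfg.beta_inc,
            "n_film": cfg.n_film,
        },
        "fields": {"ex2": fields.ex2, "ey2": fields.ey2, "ez2": fields.ez2},
        "orientation_sd_deg": orientation_sd,
        "noise_sigma_AU": noise_sigma,
        "bands": truth_bands,
    }
    return spec, truth


# ---------------------------------------------------------------------------
# Impedance sweeps


def gen_eis_sweep(
    seed: int = 0,
    potentials=None,
    frequency: float = 25.0,
    c_min: float = 1.44,
    e_min: float = -0.6,
    curvature: float = 0.15,
    defect_peak: tuple[float, float, float] | None = None,
    noise_sigma_ohm: float = 1.0,
):
    """Imaginary-impedance sweep from a prescribed C(E) curve.

    C(E) = c_min + curvature·(E − e_min)² [+ Gaussian defect peak
    (amplitude μF cm⁻², center V, width V)], inverted through
    Z″(E) = −1/(2πf·C(E)) with Gaussian noise on Z″.
    """
    pot = (
        np.arange(-1.2, 0.4001, 0.02) if potentials is None else np.asarray(potentials, float)
    )
    c_e = c_min + curvature * (pot - e_min) ** 2
    if defect_peak is not None:
        amp, center, width = defect_peak
        c_e = c_e + amp * np.exp(-0.5 * ((pot - center) / width) ** 2)
    if np.any(c_e <= 0):
        raise ValueError("prescribed C(E) must be positive")
    rng = np.random.default_rng(seed)
    z = -1.0 / (2.0 * np.pi * frequency * c_e * 1e-6)  # μF cm⁻² → F cm⁻²
    z = z + rng.normal(0.0, noise_sigma_ohm, size=z.shape)
    sweep = ImpedanceSweep(potential=pot, frequency=frequency, z_imag=z)
    truth = {
        "kind": "eis_sweep",
        "seed": seed,
        "frequency_Hz": frequency,
        "c_min_uF_cm2": c_min,
        "e_min_V": e_min,
        "curvature_uF_cm2_V2": curvature,
        "defect_peak": list(defect_peak) if defect_peak else None,
        "c_of_E_uF_cm2": c_e.tolist(),
        "noise_sigma_ohm": noise_sigma_ohm,
    }
    return sweep, truth


# ---------------------------------------------------------------------------
# Toy bilayer trajectories

_CC = 1.54  # Å, C–C bond
_CH = 1.09  # Å, C–H bond
_TET = 109.471  # degrees, tetrahedral angle


def _base_chain(n_carbons: int):
    """All-trans zig-zag chain along local +z with ideal tetrahedral CH₂.

    Returns carbon positions (n, 3), hydrogen positions (2n, 3) and the head
    bead position; the first carbon sits at the local origin.  Every C–H
    direction has zero z-component, so a chain along the normal gives
    SCD = −0.5 exactly.
    """
    half = np.radians(0.5 * _TET)
    b = _CC * np.sqrt(2.0 / 3.0)  # rise per carbon, 1.257 Å
    a = 0.5 * _CC * np.sqrt(1.0 / 3.0)  # half lateral offset, 0.4446 Å
    k = np.arange(n_carbons)
    carbons = np.stack([a * (-1.0) ** k, np.zeros(n_carbons), b * k], axis=1)
    hydros = np.empty((2 * n_carbons, 3))
    for i in range(n_carbons):
        u = np.array([0.0, 0.0, 1.0])
        v = np.array([-((-1.0) ** i), 0.0, 0.0])  # bisector of the two C–C bonds
        w = np.cross(u, v)
        h1 = -v * np.cos(half) + w * np.sin(half)
        h2 = -v * np.cos(half) - w * np.sin(half)
        hydros[2 * i] = carbons[i] + _CH * h1
        hydros[2 * i + 1] = carbons[i] + _CH * h2
    head = carbons[-1] + np.array([0.0, 0.0, 1.6])
    return carbons, hydros, head


def _spin(angle: float) -> np.ndarray:
    """Rotation about the local chain axis (+z before tilting)."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation(theta: float, phi: float) -> np.ndarray:
    """R_z(φ)·R_y(θ): local +z maps onto polar angle θ, azimuth φ."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return rz @ ry


def gen_bilayer_trajectory(
    seed: int = 0,
    n_lipids_per_leaflet: int = 8,
    n_carbons: int = 9,
    n_frames: int = 100,
    tilt_mean: float = 33.0,
    tilt_sd: float = 5.0,
    lattice_spacing: float = 10.0,
    z_base: float = 3.0,
    probe_z_dist: tuple = ("gaussian", 15.0, 2.0),
    hbond_periods: tuple[int, ...] = (1, 2),
    overlap_tol: float = 0.5,
):
    """Idealized two-leaflet bilayer with a probe and an H-bond schedule.

    Each lipid is one all-trans zig-zag chain (explicit ideal-tetrahedral
    hydrogens) plus a head bead, placed on a square lattice in two mirrored
    leaflets; its tilt magnitude is redrawn every frame from a reflected
    Gaussian (``tilt_mean``, ``tilt_sd`` degrees) while the tilt direction
    (azimuth) is drawn uniformly per leaflet per frame — chains of one
    leaflet tilt collectively, as in a gel phase, which also keeps
    neighbouring chains parallel and clash-free.  Upper-leaflet chain
    vectors sit near θ and lower-leaflet ones near 180° − θ.
    A rigid hydroxyl probe (ring bead + O–H) floats above the membrane
    center with its z drawn per frame from ``probe_z_dist`` (``("gaussian",
    mean, sd)`` or ``("uniform", lo, hi)``), and one acceptor atom per entry
    of ``hbond_periods`` satisfies the default hydrogen-bond geometry every
    ``period``-th frame (period 1 = every frame), giving the probe OH a
    known bonding time fraction of Σ 1/period.

    ``n_carbons`` must be odd so the first-to-last carbon vector lies exactly
    along the chain director and the tilt truth is exact.
    """
    if n_lipids_per_leaflet < 4:
        raise ValueError("need at least 4 lipids per leaflet")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if n_carbons < 3 or n_carbons % 2 == 0:
        raise ValueError("n_carbons must be odd and >= 3")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_lipids_per_leaflet)))
    sites = [
        (ix * lattice_spacing, iy * lattice_spacing)
        for ix in range(side)
        for iy in range(side)
    ][:n_lipids_per_leaflet]
    carbons0, hydros0, head0 = _base_chain(n_carbons)
    atoms_per_lipid = 3 * n_carbons + 1

    records = []  # topology rows
    n_lipids = 2 * n_lipids_per_leaflet
    for lip in range(n_lipids):
        resid = lip + 1
        base = lip * atoms_per_lipid
        for k in range(n_carbons):
            records.append(
                (f"C{k + 1}", "LIP", resid, "tail", -0.1, 3.4, 0.109, 12.011, -1)
            )
        for k in range(n_carbons):
            ci = base + k
            records.append((f"H{k + 1}A", "LIP", resid, "tail", 0.05, 2.65, 0.0157, 1.008, ci))
            records.append((f"H{k + 1}B", "LIP", resid, "tail", 0.05, 2.65, 0.0157, 1.008, ci))
        records.append(("P", "LIP", resid, "head", -0.4, 3.74, 0.2, 94.97, -1))
    probe_base = n_lipids * atoms_per_lipid
    records.append(("C1", "DOX", n_lipids + 1, "ring", 0.1, 3.4, 0.109, 72.0, -1))
    records.append(("O1", "DOX", n_lipids + 1, "OH", -0.6, 3.07, 0.17, 15.999, -1))
    records.append(("H1", "DOX", n_lipids + 1, "OH", 0.45, 0.0, 0.0, 1.008, probe_base + 1))
    for j in range(len(hbond_periods)):
        records.append(
            (f"OA{j + 1}", "ACP", n_lipids + 2 + j, f"A{j + 1}", -0.5, 3.07, 0.17, 15.999, -1)
        )
    atoms = pd.DataFrame(records, columns=[
        "name", "resname", "resid", "group", "charge_e", "sigma_A", "epsilon_kcal",
        "mass_amu", "parent",
    ])
    n_atoms = len(atoms)

    lipid_atoms = np.arange(n_lipids * atoms_per_lipid)
    chain_atoms = np.concatenate(
        [
            lip * atoms_per_lipid + np.arange(3 * n_carbons)
            for lip in range(n_lipids)
        ]
    )
    selections = {
        "lipids": lipid_atoms,
        "chains": chain_atoms,
        "heads": np.array([lip * atoms_per_lipid + 3 * n_carbons for lip in range(n_lipids)]),
        "probe": np.arange(probe_base, probe_base + 3),
        "probe_ring": np.array([probe_base]),
        "donors": np.array([probe_base + 1]),
        "acceptors": np.arange(probe_base + 3, n_atoms),
    }

    # local-frame lipid template: carbons, then H pairs, then head
    template = np.vstack([carbons0, hydros0, head0])
    lx = ly = side * lattice_spacing
    chain_height = carbons0[-1, 2] + 2.0
    dist_kind = probe_z_dist[0]
    if dist_kind == "gaussian":
        probe_z = rng.normal(probe_z_dist[1], probe_z_dist[2], size=n_frames)
    elif dist_kind == "uniform":
        probe_z = rng.uniform(probe_z_dist[1], probe_z_dist[2], size=n_frames)
    else:
        raise ValueError("probe_z_dist must be ('gaussian', mean, sd) or ('uniform', lo, hi)")
    box_z = 2.0 * (z_base + chain_height + 5.0) + 2.0 * (np.abs(probe_z).max() + 10.0)
    box = np.tile(np.array([lx, ly, box_z]), (n_frames, 1))

    tilts = np.abs(rng.normal(np.radians(tilt_mean), np.radians(tilt_sd), size=(n_frames, n_lipids)))
    # collective tilt azimuth per leaflet per frame (gel-phase chains tilt
    # together; also keeps neighbouring chains parallel, hence clash-free),
    # plus an independent spin of each chain about its own long axis so the
    # C–H bonds sample the azimuth about the director uniformly
    leaflet_azimuths = rng.uniform(0.0, 2.0 * np.pi, size=(n_frames, 2))
    spins = rng.uniform(0.0, 2.0 * np.pi, size=(n_frames, n_lipids))

    coords = np.empty((n_frames, n_atoms, 3))
    probe_xy = np.array([0.5 * lx + 0.5 * lattice_spacing, 0.5 * ly + 0.5 * lattice_spacing])
    psi = np.radians(20.0)
    for f in range(n_frames):
        for lip in range(n_lipids):
            upper = lip < n_lipids_per_leaflet
            x0, y0 = sites[lip % n_lipids_per_leaflet]
            theta = tilts[f, lip] if upper else np.pi - tilts[f, lip]
            rot = _rotation(theta, leaflet_azimuths[f, 0 if upper else 1]) @ _spin(
                spins[f, lip]
            )
            origin = np.array([x0, y0, z_base if upper else -z_base])
            base = lip * atoms_per_lipid
            placed = template @ rot.T
            # topology order: C1..Cn, H1A,H1B..HnA,HnB, P
            coords[f, base : base + n_carbons] = placed[:n_carbons] + origin
            coords[f, base + n_carbons : base + 3 * n_carbons] = (
                placed[n_carbons : 3 * n_carbons] + origin
            )
            coords[f, base + 3 * n_carbons] = placed[-1] + origin
        p = np.array([probe_xy[0], probe_xy[1], probe_z[f]])
        coords[f, probe_base] = p + np.array([-1.5, 0.0, 0.0])  # ring bead
        coords[f, probe_base + 1] = p  # hydroxyl O
        coords[f, probe_base + 2] = p + np.array([0.96, 0.0, 0.0])  # hydroxyl H
        for j, period in enumerate(hbond_periods):
            on = (f % period) == 0
            radius = 2.8 if on else 6.0
            sign = 1.0 if j % 2 == 0 else -1.0
            offset = np.array([radius * np.cos(psi), sign * radius * np.sin(psi), 0.0])
            coords[f, probe_base + 3 + j] = p + offset

    topo = Topology(atoms=atoms, selections=selections)
    _check_overlaps(coords[0], topo, overlap_tol)
    traj = Trajectory(coordinates=coords, box=box, times=np.arange(n_frames, dtype=float))
    expected_oh = float(sum(1.0 / p for p in hbond_periods))
    truth = {
        "kind": "bilayer_traj",
        "seed": seed,
        "n_lipids_per_leaflet": n_lipids_per_leaflet,
        "n_carbons": n_carbons,
        "n_frames": n_frames,
        "tilt_mean_deg": tilt_mean,
        "tilt_sd_deg": tilt_sd,
        "probe_z_dist": list(probe_z_dist),
        "hbond_periods": list(hbond_periods),
        "expected_hbond_fractions": {
            "OH": expected_oh,
            **{f"A{j + 1}": 1.0 / p for j, p in enumerate(hbond_periods)},
        },
        "scd_aligned_value": -0.5,
    }
    return traj, topo, truth


def _check_overlaps(coords: np.ndarray, topo: Topology, tol: float) -> None:
    """Reject placements with inter-residue atom clashes closer than tol."""
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if pairs.size:
        resid = topo.atoms["resid"].to_numpy(int)
        inter = pairs[resid[pairs[:, 0]] != resid[pairs[:, 1]]]
        if inter.size:
            i, j = inter[0]
            raise ValueError(
                f"overlapping placement: atoms {i + 1} and {j + 1} are closer than {tol} Å"
            )
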