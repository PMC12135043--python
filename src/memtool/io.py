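"""Readers and writers for the delimited text formats of the toolkit.

All tabular formats are comma- or tab-delimited text with a named header
line and optional ``#``-prefixed metadata comments (``# key: value``).
Floats are written at ``repr`` precision so regenerated artifacts compare
byte-for-byte.  Trajectories travel as multi-frame PDB (MODEL/ENDMDL with a
CRYST1 box, via MDAnalysis) or extended XYZ with a per-frame ``Lattice=``
comment; topologies as a delimited atom table whose ``parent`` column holds
the 0-based heavy-atom index for each hydrogen (−1 otherwise), with named
atom selections in a YAML sidecar.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atr import BandModel, PolarizedSpectrum
from .eis import ImpedanceSweep
from .monolayer import InsertionTrace, Isotherm
from .trajectory import TOPOLOGY_COLUMNS, Topology, Trajectory

__all__ = [
    "read_isotherm",
    "write_isotherm",
    "read_insertion_trace",
    "write_insertion_trace",
    "read_spectrum",
    "write_spectrum",
    "read_eis_sweep",
    "write_eis_sweep",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_band_seeds",
    "write_truth",
]


def _read_metadata(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    sep = ","
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            if "\t" in line:
                sep = "\t"
            break
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def _fmt(v) -> str:
    return repr(float(v))


def _write_table(path, columns: dict[str, np.ndarray], meta: dict | None = None) -> None:
    buf = _io.StringIO()
    for key, val in (meta or {}).items():
        if val is not None:
            buf.write(f"# {key}: {val}\n")
    names = list(columns)
    buf.write(",".join(names) + "\n")
    arrays = [np.asarray(columns[n]) for n in names]
    for row in zip(*arrays):
        buf.write(",".join(_fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


# -- monolayer ---------------------------------------------------------------


def read_isotherm(path) -> Isotherm:
    meta = _read_metadata(path)
    df = _read_table(path, ["area_A2", "pi_mN_m"])
    return Isotherm(
        area_per_molecule=df["area_A2"].to_numpy(float),
        surface_pressure=df["pi_mN_m"].to_numpy(float),
        temperature=float(meta.get("temperature_C", 24.0)),
        label=meta.get("label", ""),
    )


def write_isotherm(path, iso: Isotherm) -> None:
    _write_table(
        path,
        {"area_A2": iso.area_per_molecule, "pi_mN_m": iso.surface_pressure},
        meta={"temperature_C": iso.temperature, "label": iso.label or None},
    )


def read_insertion_trace(path) -> InsertionTrace:
    meta = _read_metadata(path)
    if "pi_zero_mN_m" not in meta:
        raise ValueError(f"{path}: missing '# pi_zero_mN_m:' metadata comment")
    df = _read_table(path, ["time_s", "dpi_mN_m"])
    return InsertionTrace(
        time=df["time_s"].to_numpy(float),
        delta_pi=df["dpi_mN_m"].to_numpy(float),
        pi_zero=float(meta["pi_zero_mN_m"]),
        label=meta.get("label", ""),
    )


def write_insertion_trace(path, trace: InsertionTrace) -> None:
    _write_table(
        path,
        {"time_s": trace.time, "dpi_mN_m": trace.delta_pi},
        meta={"pi_zero_mN_m": trace.pi_zero, "label": trace.label or None},
    )


# -- spectra -----------------------------------------------------------------


def read_spectrum(path) -> PolarizedSpectrum:
    df = _read_table(path, ["wavenumber_cm1", "abs_p", "abs_s"])
    return PolarizedSpectrum(
        wavenumber=df["wavenumber_cm1"].to_numpy(float),
        absorbance_p=df["abs_p"].to_numpy(float),
        absorbance_s=df["abs_s"].to_numpy(float),
    )


def write_spectrum(path, spec: PolarizedSpectrum) -> None:
    _write_table(
        path,
        {
            "wavenumber_cm1": spec.wavenumber,
            "abs_p": spec.absorbance_p,
            "abs_s": spec.absorbance_s,
        },
    )


def read_band_seeds(path) -> tuple[BandModel, tuple[float, float], int, list[str | None]]:
    """Band-seed config: per-band center/width/mix, fit window, baseline order.

    YAML layout::

        window: [2800, 3000]
        baseline_order: 1
        bands:
          - {center: 2850, fwhm: 10, frac: 0.3, role: sym_ch2}
          - {center: 2921, fwhm: 14, frac: 0.3, role: asym_ch2}

    The optional ``role`` tags (``sym_ch2``/``asym_ch2``) mark the two
    methylene stretches used for the chain-tilt calculation.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    bands = cfg.get("bands")
    if not bands:
        raise ValueError(f"{path}: no bands listed")
    window = tuple(float(v) for v in cfg.get("window", ()))
    if len(window) != 2:
        raise ValueError(f"{path}: 'window' must be [low, high]")
    seeds = BandModel(
        centers=[b["center"] for b in bands],
        fwhms=[b.get("fwhm", 10.0) for b in bands],
        fracs=[b.get("frac", 0.5) for b in bands],
        amplitudes_p=[b.get("amplitude_p", 0.0) for b in bands],
        amplitudes_s=[b.get("amplitude_s", 0.0) for b in bands],
    )
    roles = [b.get("role") for b in bands]
    return seeds, window, int(cfg.get("baseline_order", 1)), roles


# -- impedance ---------------------------------------------------------------


def read_eis_sweep(path) -> ImpedanceSweep:
    df = _read_table(path, ["potential_V", "freq_Hz", "z_imag_ohm_cm2"])
    return ImpedanceSweep(
        potential=df["potential_V"].to_numpy(float),
        frequency=df["freq_Hz"].to_numpy(float),
        z_imag=df["z_imag_ohm_cm2"].to_numpy(float),
    )


def write_eis_sweep(path, sweep: ImpedanceSweep) -> None:
    _write_table(
        path,
        {
            "potential_V": sweep.potential,
            "freq_Hz": sweep.frequency,
            "z_imag_ohm_cm2": sweep.z_imag,
        },
    )


# -- topology ----------------------------------------------------------------


def read_topology(path, selections_path=None) -> Topology:
    df = _read_table(path, ["index"] + TOPOLOGY_COLUMNS)
    df = df.sort_values("index").reset_index(drop=True)
    if not np.array_equal(df["index"].to_numpy(int), np.arange(len(df))):
        raise ValueError(f"{path}: 'index' must be contiguous 0-based")
    selections = {}
    if selections_path is not None:
        raw = yaml.safe_load(Path(selections_path).read_text()) or {}
        selections = {k: np.asarray(v, int) for k, v in raw.items()}
    return Topology(atoms=df[TOPOLOGY_COLUMNS].copy(), selections=selections)


def write_topology(path, topo: Topology, selections_path=None) -> None:
    buf = _io.StringIO()
    buf.write("index," + ",".join(TOPOLOGY_COLUMNS) + "\n")
    for i, row in topo.atoms.iterrows():
        buf.write(
            f"{i},{row['name']},{row['resname']},{int(row['resid'])},{row['group']},"
            f"{_fmt(row['charge_e'])},{_fmt(row['sigma_A'])},{_fmt(row['epsilon_kcal'])},"
            f"{_fmt(row['mass_amu'])},{int(row['parent'])}\n"
        )
    Path(path).write_text(buf.getvalue())
    if selections_path is not None:
        data = {k: [int(i) for i in v] for k, v in topo.selections.items()}
        Path(selections_path).write_text(yaml.safe_dump(data, sort_keys=True))


# -- trajectories ------------------------------------------------------------


def read_trajectory(path, topo: Topology | None = None) -> Trajectory:
    """Read a multi-frame PDB or extended-XYZ trajectory."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return _read_pdb(path)
    if path.suffix.lower() == ".xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported trajectory format: {path.suffix!r} (use .pdb or .xyz)")


def write_trajectory(path, traj: Trajectory, topo: Topology) -> None:
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        _write_pdb(path, traj, topo)
    elif path.suffix.lower() == ".xyz":
        _write_xyz(path, traj, topo)
    else:
        raise ValueError(f"unsupported trajectory format: {path.suffix!r} (use .pdb or .xyz)")


def _read_pdb(path) -> Trajectory:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    frames, boxes = [], []
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float).copy())
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValueError(f"{path}: frame {ts.frame} lacks a CRYST1 box")
        boxes.append(ts.dimensions[:3].astype(float).copy())
    return Trajectory(coordinates=np.array(frames), box=np.array(boxes))


def _write_pdb(path, traj: Trajectory, topo: Topology) -> None:
    # fixed-format writer: CRYST1 inside every MODEL block so per-frame
    # boxes survive a round trip, and byte-identical output for determinism
    names = topo.atoms["name"].tolist()
    resnames = topo.atoms["resname"].tolist()
    resids = topo.atoms["resid"].to_numpy(int)
    elements = [_element_of(n) for n in names]
    with open(path, "w") as fh:
        fh.write("REMARK   1 written by memtool\n")
        for f in range(traj.n_frames):
            lx, ly, lz = traj.box[f]
            fh.write(f"MODEL     {f + 1:4d}\n")
            fh.write(
                f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            for i in range(traj.n_atoms):
                x, y, z = traj.coordinates[f, i]
                fh.write(
                    f"ATOM  {i + 1:5d} {names[i]:<4.4s} {resnames[i]:<3.3s} X"
                    f"{resids[i]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elements[i]:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _write_xyz(path, traj: Trajectory, topo: Topology) -> None:
    elements = [_element_of(n) for n in topo.atoms["name"]]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            lx, ly, lz = traj.box[f]
            fh.write(f"{traj.n_atoms}\n")
            fh.write(
                f'Lattice="{_fmt(lx)} 0.0 0.0 0.0 {_fmt(ly)} 0.0 0.0 0.0 {_fmt(lz)}" '
                f"frame={f}\n"
            )
            for el, (x, y, z) in zip(elements, traj.coordinates[f]):
                fh.write(f"{el} {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")


def _read_xyz(path) -> Trajectory:
    frames, boxes = [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            if 'Lattice="' not in comment:
                raise ValueError(f"{path}: extended-XYZ frame lacks a Lattice box")
            lattice = comment.split('Lattice="', 1)[1].split('"', 1)[0].split()
            vals = [float(v) for v in lattice]
            boxes.append([vals[0], vals[4], vals[8]])
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(v) for v in parts[1:4]]
            frames.append(coords)
    return Trajectory(coordinates=np.array(frames), box=np.array(boxes))


# -- truth records -----------------------------------------------------------


def write_truth(path, truth: dict) -> None:
    Path(path).write_text(yaml.safe_dump(truth, sort_keys=True))
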