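"""Impedance-derived pseudocapacitance of supported membranes.

A bilayer-covered electrode behaves, at a single low frequency, as a series
RC element, so the imaginary impedance component maps to a pseudocapacitance

    C_ps = 1 / (2π f |Z″|).

Since a defect-free bilayer is a parallel-plate dielectric, C ∝ ε/d, the
fractional thickness change of the layer upon adsorption of a solute (at
unchanged dielectric constant) follows from the capacitance ratio alone:

    Δd/d = (C_ref / C_new − 1) · 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImpedanceSweep",
    "CapacitanceCurve",
    "pseudocapacitance_curve",
    "thickness_change_from_capacitance",
]


@dataclass
class ImpedanceSweep:
    """Imaginary impedance vs. potential at fixed (or per-point) frequency.

    ``z_imag`` is in Ω·cm² and negative for a capacitive response;
    potentials are carried through as V vs SCE labels.
    """

    potential: np.ndarray  # V vs SCE
    frequency: np.ndarray  # Hz (scalar broadcast to the grid)
    z_imag: np.ndarray  # Ω·cm²

    def __post_init__(self):
        self.potential = np.atleast_1d(np.asarray(self.potential, float))
        self.z_imag = np.atleast_1d(np.asarray(self.z_imag, float))
        self.frequency = np.broadcast_to(
            np.asarray(self.frequency, float), self.potential.shape
        ).copy()
        if self.potential.shape != self.z_imag.shape:
            raise ValueError("potential and z_imag must have equal length")
        if np.any(self.frequency <= 0):
            raise ValueError("frequencies must be positive")
        if not np.all(np.isfinite(self.z_imag)):
            raise ValueError("z_imag contains non-finite values")


@dataclass
class CapacitanceCurve:
    """Pseudocapacitance vs. potential, μF cm⁻²."""

    potential: np.ndarray  # V vs SCE
    c_ps: np.ndarray  # μF cm⁻²

    def __post_init__(self):
        self.potential = np.atleast_1d(np.asarray(self.potential, float))
        self.c_ps = np.atleast_1d(np.asarray(self.c_ps, float))
        if self.potential.shape != self.c_ps.shape:
            raise ValueError("potential and c_ps must have equal length")
        if np.any(self.c_ps <= 0):
            raise ValueError("pseudocapacitance must be positive")

    @property
    def minimum(self) -> tuple[float, float]:
        """(potential, C_ps) of the curve minimum."""
        i = int(np.argmin(self.c_ps))
        return float(self.potential[i]), float(self.c_ps[i])


def pseudocapacitance_curve(sweep: ImpedanceSweep) -> CapacitanceCurve:
    """Series-RC pseudocapacitance C_ps = 1/(2π f |Z″|), in μF cm⁻²."""
    zero = sweep.z_imag == 0.0
    if np.any(zero):
        bad = sweep.potential[zero]
        raise ValueError(
            f"zero imaginary impedance at potential(s) {bad.tolist()} V; C_ps undefined"
        )
    c_farad = 1.0 / (2.0 * np.pi * sweep.frequency * np.abs(sweep.z_imag))  # F cm⁻²
    return CapacitanceCurve(potential=sweep.potential.copy(), c_ps=c_farad * 1e6)


def thickness_change_from_capacitance(c_ref: float, c_new: float) -> float:
    """Fractional dielectric-thickness change, percent.

    Assumes the dielectric constant is unchanged, so d ∝ 1/C and
    Δd/d = (c_ref/c_new − 1)·100 %.  Positive output means the layer
    thickened (capacitance dropped).
    """
    if c_ref <= 0 or c_new <= 0:
        raise ValueError("capacitances must be positive")
    return (c_ref / c_new - 1.0) * 100.0
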