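"""Archetype energetics: normalization, Boltzmann populations, and the
static/dynamic/implausible disorder classification.

The physical picture: disorder requires alternative conformations of
similar energy — similar on the scale of the molar thermal energy RT at
the crystallization temperature — to be populated when the crystal grows.
Whether the frozen-in conformers can still interconvert in the solid is
then decided by the energy barrier between them: a barrier accessible at
the given temperature means dynamic disorder, an inaccessible one means
static disorder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import (AMBIENT_TEMPERATURE, GAS_CONSTANT,
                        HARTREE_TO_KJ_PER_MOL)


@dataclass
class EnergyRecord:
    """Total energy of one archetype computation, normalized per ASU."""

    archetype_id: int
    total_energy_hartree: float
    n_asu_units: int = 1

    def __post_init__(self) -> None:
        if self.n_asu_units < 1:
            raise ValueError("n_asu_units must be >= 1")

    @property
    def energy_per_asu_kj_mol(self) -> float:
        return normalize_per_asu(self.total_energy_hartree, self.n_asu_units)


@dataclass
class DisorderAssessment:
    """Energy-based verdict on a disordered structure."""

    delta_e: float  # kJ/mol per ASU, minor minus major
    barrier: Optional[float]  # kJ/mol, None if not computed
    temperature: float  # K
    thermal_window: float  # RT, kJ/mol
    predicted_occupancies: list = field(default_factory=list)
    verdict: str = "barrier-unknown"
    # dynamic | static | disorder-unlikely | barrier-unknown


def thermal_energy(temperature: float) -> float:
    """Molar thermal energy RT in kJ/mol (R = 8.314 J mol^-1 K^-1)."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return GAS_CONSTANT * temperature / 1000.0


def normalize_per_asu(total_energy_hartree: float, n_asu_units: int) -> float:
    """Convert a total energy (Hartree) to kJ/mol per ASU content."""
    if n_asu_units < 1:
        raise ValueError("n_asu_units must be >= 1")
    return total_energy_hartree * HARTREE_TO_KJ_PER_MOL / n_asu_units


def boltzmann_occupancies(energies_per_asu: Sequence[float],
                          temperature: float) -> np.ndarray:
    """Boltzmann populations of archetypes from per-ASU energies (kJ/mol).

    At T = 0 all population sits on the minimum-energy archetype(s),
    ties split equally.
    """
    e = np.asarray(energies_per_asu, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two archetype energies")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if temperature == 0:
        lowest = np.isclose(e, e.min())
        return lowest / lowest.sum()
    rt = thermal_energy(temperature)
    w = np.exp(-(e - e.min()) / rt)  # shift for numerical safety
    return w / w.sum()


def check_occupancy_energy_consistency(
        records: Sequence[EnergyRecord],
        experimental_occupancies: Sequence[float],
        tie_band: float = 0.05) -> dict:
    """Does the experimental occupancy ranking match the energy ranking?

    The expected physics is that the majority component is the
    lower-energy archetype.  Near-equal occupancies carry no ranking
    information, so a gap of at most ``tie_band`` is reported as
    "exempt" rather than judged.
    """
    occ = np.asarray(experimental_occupancies, dtype=float)
    if len(records) != occ.size:
        raise ValueError("records and occupancies differ in length")
    if abs(occ.sum() - 1.0) > 0.01:
        raise ValueError(f"occupancies sum to {occ.sum():.3f}, not 1")
    energies = np.array([r.energy_per_asu_kj_mol for r in records])
    gap = float(occ.max() - occ.min())
    if gap <= tie_band:
        verdict = "exempt"
    elif np.array_equal(np.argsort(-occ, kind="stable"),
                        np.argsort(energies, kind="stable")):
        verdict = "consistent"
    else:
        verdict = "inconsistent"
    return {
        "verdict": verdict,
        "occupancy_gap": gap,
        "energies_per_asu": energies.tolist(),
        "occupancies": occ.tolist(),
    }


def classify_disorder(delta_e: float,
                      barrier: Optional[float],
                      temperature: float = AMBIENT_TEMPERATURE,
                      similarity_factor: float = 1.0,
                      crystallization_temperature: float = AMBIENT_TEMPERATURE
                      ) -> DisorderAssessment:
    """Classify disorder from the archetype energy difference and barrier.

    Disorder needs conformers of similar energy during crystallization:
    if |delta_e| exceeds the crystallization-temperature thermal window
    (similarity_factor x RT) by more than a factor of three, disorder is
    flagged as unlikely.  Otherwise the barrier decides: one the thermal
    energy at ``temperature`` can overcome gives dynamic disorder, a
    higher one gives static disorder, and with no barrier supplied the
    verdict stays open.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    window = thermal_energy(temperature)
    cryst_window = similarity_factor * thermal_energy(
        crystallization_temperature)
    occ = boltzmann_occupancies([0.0, abs(delta_e)], temperature)
    if abs(delta_e) > 3.0 * cryst_window:
        verdict = "disorder-unlikely"
    elif barrier is None:
        verdict = "barrier-unknown"
    elif barrier <= window:
        verdict = "dynamic"
    else:
        verdict = "static"
    return DisorderAssessment(
        delta_e=delta_e, barrier=barrier, temperature=temperature,
        thermal_window=window,
        predicted_occupancies=[float(p) for p in occ],
        verdict=verdict)
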