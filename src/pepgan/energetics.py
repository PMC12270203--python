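"""Dissociation-energy bookkeeping for steered-pulling trajectories and
equilibrium binding-affinity arithmetic.

Two accumulators are provided over a pulled center-of-mass trace
``z(t)`` with spring constant ``k``:

* :func:`harmonic_work` — ``sum 1/2 k (z_i - z_{i+1})^2`` over
  consecutive checkpoints (harmonic form);
* :func:`dissociation_energy` — ``sum k (z_i - z_{i+1})``, which
  telescopes to ``k (z_first - z_last)`` and therefore depends only on
  the endpoints.

The two expressions are dimensionally inconsistent with each other
(kJ/(mol nm^2) vs kJ/(mol nm) spring constants); both are kept exactly
as defined, named by their functional form.  The simulation producing
trajectories is out of scope — input is a plain two-column table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PullTrajectory",
    "KineticConstants",
    "harmonic_work",
    "dissociation_energy",
    "kd_from_kinetics",
    "is_weak_binding",
    "WEAK_BINDING_THRESHOLD_KJ",
]

#: dissociation energies below this baseline (kJ/mol) flag weak binders
WEAK_BINDING_THRESHOLD_KJ = 7.0

DEFAULT_SPRING_CONSTANT = 150.0  # kJ/(mol nm) per the pulling protocol


@dataclasses.dataclass(frozen=True)
class PullTrajectory:
    """Center-of-mass z-coordinates (nm) at successive checkpoints."""

    z: tuple[float, ...]
    spring_constant: float = DEFAULT_SPRING_CONSTANT

    def __post_init__(self) -> None:
        if len(self.z) < 2:
            raise ValueError("trajectory needs at least 2 checkpoints")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite coordinate in trajectory")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, spring_constant: float = DEFAULT_SPRING_CONSTANT):
        df = pd.read_csv(path)
        zcol = "z" if "z" in df.columns else df.columns[-1]
        return cls(tuple(df[zcol].astype(float)), spring_constant)


@dataclasses.dataclass(frozen=True)
class KineticConstants:
    """Association (1/(M s)) and dissociation (1/s) rate constants."""

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rate constants must be positive")


def harmonic_work(traj: PullTrajectory) -> float:
    """``sum 1/2 k (z_i - z_{i+1})^2`` over consecutive checkpoints (kJ/mol)."""
    z = np.asarray(traj.z)
    return float(0.5 * traj.spring_constant * np.sum(np.diff(z) ** 2))


def dissociation_energy(traj: PullTrajectory) -> float:
    """``sum k (z_i - z_{i+1})`` — telescopes to ``k (z_first - z_last)`` (kJ/mol).

    Inserting intermediate checkpoints never changes the value.
    """
    return float(traj.spring_constant * (traj.z[0] - traj.z[-1]))


def is_weak_binding(energy_kj: float, threshold: float = WEAK_BINDING_THRESHOLD_KJ) -> bool:
    """Flag dissociation energies below the weak-binding baseline."""
    return energy_kj < threshold


def kd_from_kinetics(k: KineticConstants) -> float:
    """Equilibrium dissociation constant ``Kd = k_off / k_on``, in nM."""
    return k.k_off / k.k_on * 1e9
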