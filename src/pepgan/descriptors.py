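"""Physiochemical descriptor engine: 31 features per peptide.

The registry reconstructs the descriptor panel from sequence alone with
deterministic, desk-scale surrogates standing in for quantum-chemistry
derived quantities (dipole, rotational moments, solvation energy,
volume/area).  The surrogates keep the same physical roles: composition
features are table sums/means; shape features (dipole components,
moments of inertia, radius of gyration) are computed on an idealized
alpha-helical backbone (radius 2.3 A, rise 1.5 A, 100 deg/residue);
diffusion is Stokes-Einstein on a volume-derived hydrodynamic radius.
Externally computed values (e.g. true quantum-chemical features) can be
injected via :func:`import_external_features`.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import tables as T
from .alphabet import AMINO_ACIDS, validate_sequence

__all__ = [
    "DESCRIPTOR_NAMES",
    "DESCRIPTOR_UNITS",
    "compute_descriptors",
    "descriptor_frame",
    "pocket_windows",
    "DescriptorMatrix",
    "robust_scale",
    "import_external_features",
]

#: registry order is fixed; feature-map rows 21..51 follow this order
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "aromatic_fraction",
    "aliphatic_fraction",
    "polar_neutral_fraction",
    "sulfur_fraction",
    "molecular_weight",
    "hydrophobicity",
    "hydrophilicity",
    "helix_fraction",
    "turn_fraction",
    "sheet_fraction",
    "isoelectric_point",
    "net_charge",
    "hbond_donors",
    "hbond_acceptors",
    "recognition_factor_avg",
    "antigenicity_avg",
    "pocket_b_window",
    "pocket_f_window",
    "molecular_volume",
    "molecular_area",
    "radius_of_gyration",
    "diffusion_coefficient",
    "dipole_x",
    "dipole_y",
    "dipole_z",
    "rotation_x",
    "rotation_y",
    "rotation_z",
    "solvation_energy",
    "stiffness",
    "sidechain_entropy",
)

DESCRIPTOR_UNITS: dict[str, str] = {
    "molecular_weight": "Da",
    "isoelectric_point": "pH",
    "molecular_volume": "A^3",
    "molecular_area": "A^2",
    "radius_of_gyration": "A",
    "diffusion_coefficient": "m^2/s",
    "dipole_x": "e*A",
    "dipole_y": "e*A",
    "dipole_z": "e*A",
    "rotation_x": "amu*A^2",
    "rotation_y": "amu*A^2",
    "rotation_z": "amu*A^2",
    "solvation_energy": "kcal/mol",
    "sidechain_entropy": "kcal/mol",
}

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)
assert N_DESCRIPTORS == 31

# idealized alpha-helical backbone geometry
_HELIX_RADIUS = 2.3       # A
_HELIX_RISE = 1.5         # A per residue
_HELIX_TWIST = math.radians(100.0)

_KB = 1.380649e-23        # J/K
_TEMPERATURE = 298.15     # K
_WATER_VISCOSITY = 8.9e-4  # Pa*s

PH = 7.4


def _helix_coords(n: int) -> np.ndarray:
    """(n, 3) coordinates of residue centers on the idealized helix."""
    i = np.arange(n)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TWIST * i),
            _HELIX_RADIUS * np.sin(_HELIX_TWIST * i),
            _HELIX_RISE * i,
        ]
    )


def _residue_charges(sequence: str, ph: float = PH) -> np.ndarray:
    """Henderson-Hasselbalch partial charges per residue, termini folded in."""
    q = np.zeros(len(sequence))
    for i, aa in enumerate(sequence):
        pka = T.SIDECHAIN_PKA.get(aa)
        if pka is None:
            continue
        if aa in ("D", "E", "C", "Y"):
            q[i] += -1.0 / (1.0 + 10.0 ** (pka - ph))
        else:
            q[i] += 1.0 / (1.0 + 10.0 ** (ph - pka))
    q[0] += 1.0 / (1.0 + 10.0 ** (ph - T.NTERM_PKA))
    q[-1] += -1.0 / (1.0 + 10.0 ** (T.CTERM_PKA - ph))
    return q


def _net_charge_at_ph(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge with a fixed pKa table (termini
    pKa independent of the flanking residue identity)."""
    q = 1.0 / (1.0 + 10.0 ** (ph - T.NTERM_PKA))
    q -= 1.0 / (1.0 + 10.0 ** (T.CTERM_PKA - ph))
    for aa, pka in T.SIDECHAIN_PKA.items():
        n = seq.count(aa)
        if not n:
            continue
        if aa in ("D", "E", "C", "Y"):
            q -= n / (1.0 + 10.0 ** (pka - ph))
        else:
            q += n / (1.0 + 10.0 ** (ph - pka))
    return q


def isoelectric_point(seq: str, tol: float = 0.01) -> float:
    """pH where the net charge vanishes, by bisection on (0, 14)."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol / 2.0:
        mid = (lo + hi) / 2.0
        if _net_charge_at_ph(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _mean(scale: dict[str, float], seq: str) -> float:
    return float(np.mean([scale[a] for a in seq]))


def _sum(scale: dict[str, float], seq: str) -> float:
    return float(np.sum([scale[a] for a in seq]))


def pocket_windows(sequence: str) -> tuple[float, float]:
    """Hydrophobic anchor windows for HLA-A*02:01 pockets B and F.

    Pocket B contacts peptide position 2, pocket F position 9; each
    window is the Kyte-Doolittle hydropathy of that anchor residue.
    """
    seq = validate_sequence(sequence, length=9)
    return T.KYTE_DOOLITTLE[seq[1]], T.KYTE_DOOLITTLE[seq[8]]


def compute_descriptors(sequence: str) -> np.ndarray:
    """Return the 31-feature descriptor vector in registry order.

    Deterministic: the same sequence always yields the same vector.
    Composition features are invariant to residue permutation; the
    pocket windows and the helix-geometry surrogates (dipole, rotation,
    radius of gyration) are position-sensitive by construction.
    """
    seq = validate_sequence(sequence)
    n = len(seq)
    pa = ProteinAnalysis(seq)

    counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}
    frac = lambda s: sum(counts[a] for a in s) / n  # noqa: E731

    helix, turn, sheet = pa.secondary_structure_fraction()

    charges = _residue_charges(seq)
    coords = _helix_coords(n)
    masses = np.array([T.RESIDUE_MASS[a] for a in seq])

    # dipole: first moment of the partial charges about the geometric center
    centered = coords - coords.mean(axis=0)
    dipole = charges @ centered

    # rotational surrogates: principal moments of inertia (ascending)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    d = coords - com
    inertia = np.einsum("i,ij->j", masses, d**2).sum() * np.eye(3) - np.einsum(
        "i,ij,ik->jk", masses, d, d
    )
    moments = np.sort(np.linalg.eigvalsh(inertia))

    rg = math.sqrt(float((masses * (d**2).sum(axis=1)).sum() / masses.sum()))

    volume = _sum(T.RESIDUE_VOLUME, seq)  # A^3
    hydro_radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e-10  # m
    diffusion = _KB * _TEMPERATURE / (6.0 * math.pi * _WATER_VISCOSITY * hydro_radius)

    if n == 9:
        pocket_b, pocket_f = pocket_windows(seq)
    else:  # length policy is 9 by default, but the engine stays general
        pocket_b = T.KYTE_DOOLITTLE[seq[1]] if n >= 2 else 0.0
        pocket_f = T.KYTE_DOOLITTLE[seq[-1]]

    values = {
        "aromatic_fraction": frac(T.AROMATIC),
        "aliphatic_fraction": frac(T.ALIPHATIC),
        "polar_neutral_fraction": frac(T.POLAR_NEUTRAL),
        "sulfur_fraction": frac(T.SULFUR),
        "molecular_weight": _sum(T.RESIDUE_MASS, seq) + T.WATER_MASS,
        "hydrophobicity": _mean(T.EISENBERG, seq),
        "hydrophilicity": _mean(T.HOPP_WOODS, seq),
        "helix_fraction": helix,
        "turn_fraction": turn,
        "sheet_fraction": sheet,
        "isoelectric_point": isoelectric_point(seq),
        "net_charge": float(
            sum(counts[a] for a in T.POSITIVE) - sum(counts[a] for a in T.NEGATIVE)
        ),
        "hbond_donors": _sum(T.HBOND_DONORS, seq) + sum(1 for a in seq if a != "P"),
        "hbond_acceptors": _sum(T.HBOND_ACCEPTORS, seq) + n,
        "recognition_factor_avg": _mean(T.FRAGA_RECOGNITION, seq),
        "antigenicity_avg": _mean(T.KOLASKAR_TONGAONKAR, seq),
        "pocket_b_window": pocket_b,
        "pocket_f_window": pocket_f,
        "molecular_volume": volume,
        "molecular_area": _sum(T.MAX_ASA, seq),
        "radius_of_gyration": rg,
        "diffusion_coefficient": diffusion,
        "dipole_x": float(dipole[0]),
        "dipole_y": float(dipole[1]),
        "dipole_z": float(dipole[2]),
        "rotation_x": float(moments[0]),
        "rotation_y": float(moments[1]),
        "rotation_z": float(moments[2]),
        "solvation_energy": _sum(T.WOLFENDEN_SOLVATION, seq),
        "stiffness": 1.0 / _mean(T.VIHINEN_FLEXIBILITY, seq),
        "sidechain_entropy": _sum(T.SIDECHAIN_ENTROPY, seq),
    }
    vec = np.array([values[name] for name in DESCRIPTOR_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"non-finite descriptor for {seq!r}")
    return vec


_CACHE: dict[str, np.ndarray] = {}


def compute_descriptors_cached(sequence: str) -> np.ndarray:
    """Memoized :func:`compute_descriptors` (descriptors are deterministic)."""
    v = _CACHE.get(sequence)
    if v is None:
        v = compute_descriptors(sequence)
        if len(_CACHE) < 500_000:
            _CACHE[sequence] = v
    return v


def descriptor_frame(sequences: Sequence[str], ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Descriptor table (one row per peptide, registry columns)."""
    rows = [compute_descriptors_cached(s) for s in sequences]
    idx = list(ids) if ids is not None else list(range(len(sequences)))
    return pd.DataFrame(np.array(rows), columns=list(DESCRIPTOR_NAMES), index=idx)


class DescriptorMatrix:
    """Descriptor table with robust (median/IQR) scaling state.

    Scaling parameters fitted on the training peptides are reused to
    transform generated peptides — generated data never re-fits them.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        scaled: bool = False,
        center: np.ndarray | None = None,
        scale: np.ndarray | None = None,
        zero_iqr: np.ndarray | None = None,
    ) -> None:
        missing = [c for c in DESCRIPTOR_NAMES if c not in values.columns]
        if missing:
            raise ValueError(f"missing descriptor column(s): {missing}")
        self.values = values[list(DESCRIPTOR_NAMES)].astype(float)
        self.scaled = scaled
        self.center = center
        self.scale = scale
        self.zero_iqr = zero_iqr

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy()

    def transform(self, new: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted scaling to a new descriptor table."""
        if not self.scaled or self.center is None or self.scale is None:
            raise ValueError("matrix is not scaled; call robust_scale first")
        x = new[list(DESCRIPTOR_NAMES)].to_numpy(dtype=float)
        return pd.DataFrame(
            (x - self.center) / self.scale, columns=list(DESCRIPTOR_NAMES), index=new.index
        )

    def transform_vector(self, vec: np.ndarray) -> np.ndarray:
        if not self.scaled or self.center is None or self.scale is None:
            raise ValueError("matrix is not scaled; call robust_scale first")
        return (vec - self.center) / self.scale

    def inverse(self) -> pd.DataFrame:
        """Undo the scaling; ``inverse(scale(X)) == X`` within tolerance."""
        if not self.scaled:
            return self.values.copy()
        return pd.DataFrame(
            self.array * self.scale + self.center,
            columns=list(DESCRIPTOR_NAMES),
            index=self.values.index,
        )


def robust_scale(matrix: DescriptorMatrix | pd.DataFrame) -> DescriptorMatrix:
    """Median/IQR scale each descriptor column: ``(x - median) / IQR``.

    Columns with zero IQR are left unscaled (divide by 1) and flagged in
    ``zero_iqr``; every scaled column has median 0.
    """
    df = matrix.values if isinstance(matrix, DescriptorMatrix) else matrix
    if len(df) < 2:
        raise ValueError("robust scaling needs at least 2 rows")
    x = df[list(DESCRIPTOR_NAMES)].to_numpy(dtype=float)
    center = np.median(x, axis=0)
    q75, q25 = np.percentile(x, [75, 25], axis=0)
    iqr = q75 - q25
    zero = iqr == 0.0
    scale = np.where(zero, 1.0, iqr)
    scaled = pd.DataFrame(
        (x - center) / scale, columns=list(DESCRIPTOR_NAMES), index=df.index
    )
    return DescriptorMatrix(scaled, scaled=True, center=center, scale=scale, zero_iqr=zero)


def import_external_features(path: str | Path, ids: Iterable[str]) -> DescriptorMatrix:
    """Load an externally computed descriptor table (e.g. true QM values).

    The CSV must be keyed by peptide ``id`` and carry all 31 registry
    columns with finite values; every requested id must be present.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("external feature table needs an 'id' column")
    df = df.set_index("id")
    missing_cols = [c for c in DESCRIPTOR_NAMES if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing descriptor column(s): {missing_cols}")
    ids = [str(i) for i in ids]
    df.index = df.index.astype(str)
    missing_ids = [i for i in ids if i not in df.index]
    if missing_ids:
        raise ValueError(f"external table lacks id(s): {missing_ids[:5]}")
    extra_ids = [i for i in df.index if i not in set(ids)]
    if extra_ids:
        raise ValueError(f"external table has unknown id(s): {extra_ids[:5]}")
    sub = df.loc[ids, list(DESCRIPTOR_NAMES)].astype(float)
    if not np.all(np.isfinite(sub.to_numpy())):
        bad = sub.columns[~np.isfinite(sub.to_numpy()).all(axis=0)].tolist()
        raise ValueError(f"non-finite values in column(s): {bad}")
    return DescriptorMatrix(sub)
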