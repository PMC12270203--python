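"""Sequence feature maps: one-hot encodings, the combined 51x9
discriminator input, position weight matrices, and Dirichlet-prior
conserved-sequence sampling.

The combined map stacks the 20x9 one-hot block over 31 descriptor rows;
since the descriptors are peptide-level, each scaled descriptor is tiled
across the 9 position columns (the only construction consistent with
20 + 31 = 51 rows).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, PEPTIDE_LENGTH, validate_sequence
from .descriptors import N_DESCRIPTORS

__all__ = [
    "one_hot",
    "decode_one_hot",
    "build_feature_map",
    "PositionWeightMatrix",
    "build_pwm",
    "sample_conserved",
]


def one_hot(sequence: str) -> np.ndarray:
    """20 x L binary map; exactly one 1 per column, rows in alphabet order."""
    seq = validate_sequence(sequence)
    m = np.zeros((N_AA, len(seq)))
    for j, aa in enumerate(seq):
        m[AA_INDEX[aa], j] = 1.0
    return m


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; argmax per column, alphabetical ties."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != N_AA:
        raise ValueError(f"expected (20, L) matrix, got {matrix.shape}")
    return "".join(AMINO_ACIDS[i] for i in np.argmax(matrix, axis=0))


def build_feature_map(sequence: str, scaled_descriptors: np.ndarray) -> np.ndarray:
    """Combined 51 x 9 map: one-hot block over tiled scaled descriptors."""
    seq = validate_sequence(sequence, length=PEPTIDE_LENGTH)
    vec = np.asarray(scaled_descriptors, dtype=float).ravel()
    if vec.shape[0] != N_DESCRIPTORS:
        raise ValueError(f"expected {N_DESCRIPTORS} descriptors, got {vec.shape[0]}")
    return np.vstack([one_hot(seq), np.tile(vec[:, None], (1, PEPTIDE_LENGTH))])


class PositionWeightMatrix:
    """Per-position residue probabilities of a set of equal-length peptides."""

    def __init__(self, probs: np.ndarray, counts: np.ndarray, pseudocount: float, n_sequences: int):
        self.probs = probs
        self.counts = counts
        self.pseudocount = pseudocount
        self.n_sequences = n_sequences
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs,
            index=list(AMINO_ACIDS),
            columns=[f"pos{j + 1}" for j in range(self.length)],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="residue")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PositionWeightMatrix":
        df = pd.read_csv(path, index_col="residue")
        if list(df.index) != list(AMINO_ACIDS):
            raise ValueError("PWM CSV rows must be the 20 residues in alphabet order")
        probs = df.to_numpy(dtype=float)
        return cls(probs, counts=np.full_like(probs, np.nan), pseudocount=np.nan, n_sequences=0)


def build_pwm(sequences: Sequence[str], pseudocount: float = 0.5) -> PositionWeightMatrix:
    """Count-based PWM: ``p[a,j] = (count(a,j) + c) / (n + 20 c)``.

    Columns are exactly stochastic for any pseudocount ``c >= 0``.
    """
    if len(sequences) == 0:
        raise ValueError("need at least one sequence")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequence lengths {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((N_AA, L))
    for s in sequences:
        seq = validate_sequence(s)
        for j, aa in enumerate(seq):
            counts[AA_INDEX[aa], j] += 1
    n = len(sequences)
    probs = (counts + pseudocount) / (n + N_AA * pseudocount)
    return PositionWeightMatrix(probs, counts, pseudocount, n)


def sample_conserved(
    pwm: PositionWeightMatrix,
    n: int,
    fixed: Mapping[int, str] | None = None,
    seed: int = 0,
    prior: float = 1.0,
) -> list[str]:
    """Sample conserved sequences from a Dirichlet-perturbed PWM.

    Per column ``j``, residue probabilities are drawn once per sequence
    from ``Dirichlet(counts[:, j] + prior)`` (unit prior by default;
    columns perturbed independently), then the residue is sampled from
    that draw.  Residues with zero concentration (possible when
    ``prior = 0``) are excluded from the support, so a column observed
    as pure A stays pure A under a zero prior.  ``fixed`` maps 1-based
    positions to residues held constant, e.g. ``{2: "L", 9: "V"}`` to
    pin the pocket B/F anchors.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if prior < 0:
        raise ValueError("prior must be >= 0")
    fixed = dict(fixed or {})
    for pos, aa in fixed.items():
        if not (1 <= pos <= pwm.length):
            raise ValueError(f"fixed position {pos} outside 1..{pwm.length}")
        if aa not in AA_INDEX:
            raise ValueError(f"fixed residue {aa!r} not canonical")
    if np.any(np.isnan(pwm.counts)):
        alpha = pwm.probs * max(pwm.n_sequences, 1) + prior  # PWM loaded without counts
    else:
        alpha = pwm.counts + prior
    rng = np.random.default_rng(seed)
    aa_arr = np.array(list(AMINO_ACIDS))
    cols = []
    for j in range(pwm.length):
        if (j + 1) in fixed:
            cols.append(np.full(n, fixed[j + 1]))
            continue
        support = alpha[:, j] > 0
        if not support.any():
            raise ValueError(f"column {j + 1} has no residue with positive weight")
        theta = rng.dirichlet(alpha[support, j], size=n)  # one draw per sequence
        u = rng.random(n)
        idx = (theta.cumsum(axis=1) < u[:, None]).sum(axis=1)
        idx = np.clip(idx, 0, support.sum() - 1)
        cols.append(aa_arr[support][idx])
    grid = np.column_stack(cols)
    return ["".join(row) for row in grid]
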