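"""Canonical amino-acid alphabet shared by every module.

The residue ordering is alphabetical by one-letter code and is fixed
package-wide: one-hot rows, PWM rows and CSV exports all use it.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = 20

#: default accepted peptide length (HLA-A*02:01 groove-fitting 9-mers)
PEPTIDE_LENGTH: int = 9


def is_valid_sequence(sequence: str, length: int | None = None) -> bool:
    """True if *sequence* is non-empty, canonical, and (optionally) of fixed length."""
    if not sequence:
        return False
    if length is not None and len(sequence) != length:
        return False
    return all(c in AA_INDEX for c in sequence)


def validate_sequence(sequence: str, length: int | None = None) -> str:
    """Return the upper-cased sequence or raise ``ValueError``."""
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = sorted({c for c in seq if c not in AA_INDEX})
    if bad:
        raise ValueError(f"non-canonical residue(s) {bad} in {seq!r}")
    if length is not None and len(seq) != length:
        raise ValueError(f"expected length {length}, got {len(seq)} for {seq!r}")
    return seq
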