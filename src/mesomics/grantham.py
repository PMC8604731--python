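"""Grantham physicochemical distances between amino acids.

The Grantham (1974) distance combines side-chain composition (c), polarity
(p) and molecular volume (v):

    d(i, j) = rho * sqrt( alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2 )

with alpha=1.833, beta=0.1018, gamma=0.000399 and rho=50.723 chosen so the
mean inter-residue distance is 100. This module computes the matrix from the
formula and reports distances rounded to integers (e.g. Leu/Ile = 5,
Ser/Arg = 109). A handful of entries in the historically distributed table
differ by one or two units from exact recomputation because of rounding in
the original typesetting; the formula is authoritative here.
"""

from __future__ import annotations

import math

_ALPHA = 1.833
_BETA = 0.1018
_GAMMA = 0.000399
_RHO = 50.723

# residue -> (composition, polarity, volume), Grantham 1974 Table 1
_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

STANDARD_RESIDUES = frozenset(_PROPERTIES)


def _raw_distance(a: str, b: str) -> float:
    ca, pa, va = _PROPERTIES[a]
    cb, pb, vb = _PROPERTIES[b]
    return _RHO * math.sqrt(
        _ALPHA * (ca - cb) ** 2 + _BETA * (pa - pb) ** 2 + _GAMMA * (va - vb) ** 2
    )


def _build_matrix() -> dict[tuple[str, str], float]:
    m: dict[tuple[str, str], float] = {}
    for a in _PROPERTIES:
        for b in _PROPERTIES:
            m[(a, b)] = 0.0 if a == b else float(round(_raw_distance(a, b)))
    return m


_MATRIX = _build_matrix()


def grantham_distance(residue_a: str, residue_b: str) -> float:
    """Grantham distance between two standard amino acids (one-letter codes).

    Returns the published integer matrix value; 0 for identical residues.
    Raises ``ValueError`` for non-standard residues.
    """
    a, b = residue_a.upper(), residue_b.upper()
    if a not in _PROPERTIES:
        raise ValueError(f"non-standard residue {residue_a!r}")
    if b not in _PROPERTIES:
        raise ValueError(f"non-standard residue {residue_b!r}")
    return _MATRIX[(a, b)]


def grantham_matrix() -> dict[tuple[str, str], float]:
    """The full 20x20 matrix (symmetric, zero diagonal) as a dict."""
    return dict(_MATRIX)
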