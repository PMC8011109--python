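"""Clamped uniform B-spline bases for positional weighting.

Convolution activations are weighted by a smooth function of the position
relative to the splice site, parameterized per filter as a linear combination
of B-spline basis functions. The basis rows form a partition of unity, so
all-ones coefficients give a constant weight of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasis:
    """B-spline design matrix over positions 1..L relative to a splice site."""

    positions: np.ndarray  # (L,)
    basis: np.ndarray  # (L, B), rows sum to 1

    @property
    def n_basis(self) -> int:
        return self.basis.shape[1]


def spline_basis(length: int, n_basis: int, degree: int) -> SplineBasis:
    """Build a clamped uniform cubic-style B-spline basis over [1, length].

    The knot vector repeats each endpoint ``degree + 1`` times with uniformly
    spaced interior knots, so the basis is clamped (first and last rows are
    unit vectors) and rows sum to one everywhere.
    """
    if n_basis < degree + 1:
        raise ValueError(f"n_basis ({n_basis}) must be at least degree+1 ({degree + 1})")
    if length < n_basis:
        raise ValueError(f"length ({length}) must be at least n_basis ({n_basis})")
    n_interior = n_basis - degree - 1
    knots = np.concatenate(
        [
            np.full(degree + 1, 1.0),
            np.linspace(1.0, float(length), n_interior + 2)[1:-1],
            np.full(degree + 1, float(length)),
        ]
    )
    positions = np.arange(1, length + 1, dtype=float)
    design = BSpline.design_matrix(positions, knots, degree, extrapolate=False).toarray()
    return SplineBasis(positions=positions, basis=design)
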