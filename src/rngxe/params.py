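"""Genetic (co)variance parameters shared across the package.

The reaction norm decomposes an animal's breeding value into an intercept
``a`` (merit at the origin of the environmental gradient) and a slope ``b``
(environmental sensitivity).  Their joint additive (co)variance is a 2x2
matrix

    G = [[sigma2_i, sigma_il],
         [sigma_il, sigma2_l]]

from which the additive variance at any point X of the gradient follows as
``sigma2_a(X) = sigma2_i + X**2 * sigma2_l + 2 * X * sigma_il``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_PSD_RTOL = 1e-9


@dataclass(frozen=True)
class GeneticCovariance:
    """Intercept/slope additive (co)variance matrix.

    Parameters
    ----------
    sigma2_i
        Additive variance of the reaction-norm intercept (trait units squared).
    sigma2_l
        Additive variance of the slope (trait units squared per squared
        environmental unit).
    sigma_il
        Intercept-slope additive covariance.

    The implied 2x2 matrix must be symmetric positive semidefinite.
    """

    sigma2_i: float
    sigma2_l: float
    sigma_il: float = 0.0

    def __post_init__(self) -> None:
        si, sl, c = float(self.sigma2_i), float(self.sigma2_l), float(self.sigma_il)
        if not (np.isfinite(si) and np.isfinite(sl) and np.isfinite(c)):
            raise ValueError("genetic covariance components must be finite")
        if si < 0 or sl < 0:
            raise ValueError(
                f"variances must be non-negative, got sigma2_i={si}, sigma2_l={sl}"
            )
        bound = si * sl
        if c * c > bound + _PSD_RTOL * max(1.0, bound):
            raise ValueError(
                f"sigma_il^2 = {c * c:g} exceeds sigma2_i*sigma2_l = {bound:g}: "
                "matrix is not positive semidefinite"
            )
        object.__setattr__(self, "sigma2_i", si)
        object.__setattr__(self, "sigma2_l", sl)
        object.__setattr__(self, "sigma_il", c)

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_i, self.sigma_il], [self.sigma_il, self.sigma2_l]]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "GeneticCovariance":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2):
            raise ValueError(f"expected a 2x2 matrix, got shape {m.shape}")
        if abs(m[0, 1] - m[1, 0]) > 1e-8 * max(1.0, abs(m[0, 1])):
            raise ValueError("matrix is not symmetric")
        return cls(m[0, 0], m[1, 1], 0.5 * (m[0, 1] + m[1, 0]))

    def sqrt_factor(self) -> np.ndarray:
        """A matrix square root ``L`` with ``L @ L.T == G``.

        Uses an eigendecomposition so that singular (boundary) matrices,
        e.g. ``sigma2_l == 0``, are handled exactly.
        """
        w, v = np.linalg.eigh(self.as_matrix())
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)

    def correlation(self) -> float:
        denom = np.sqrt(self.sigma2_i * self.sigma2_l)
        if denom == 0:
            return np.nan
        return self.sigma_il / denom
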