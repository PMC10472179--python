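"""Restricted (natural) cubic spline basis, Harrell truncated-power form.

For knots t_1 < ... < t_k the basis has k-1 columns: the identity x and, for
j = 1..k-2,

    B_j(x) = [ (x - t_j)_+^3
               - (x - t_{k-1})_+^3 (t_k - t_j) / (t_k - t_{k-1})
               + (x - t_k)_+^3 (t_{k-1} - t_j) / (t_k - t_{k-1}) ] / (t_k - t_1)^2

which is linear beyond the boundary knots. The (t_k - t_1)^2 normalisation
keeps the nonlinear columns on roughly the scale of x.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError


def default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knots at standard quantiles of the observed exposure.

    4 knots -> 5/35/65/95th percentiles; 3 -> 10/50/90; 5 -> 5/27.5/50/72.5/95
    (common epidemiological placements).
    """
    x = np.asarray(x, dtype=float)
    placements = {
        3: (0.10, 0.50, 0.90),
        4: (0.05, 0.35, 0.65, 0.95),
        5: (0.05, 0.275, 0.50, 0.725, 0.95),
    }
    if n_knots not in placements:
        raise DomainError("n_knots must be 3, 4 or 5 for default placement")
    knots = np.quantile(x, placements[n_knots])
    if len(np.unique(knots)) != n_knots:
        raise DomainError("quantile knots are not distinct; supply knots explicitly")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Evaluate the restricted cubic spline basis (n x (k-1) matrix)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise DomainError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise DomainError("knots must be strictly increasing")
    norm = (knots[-1] - knots[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            np.clip(x - tj, 0, None) ** 3
            - np.clip(x - knots[-2], 0, None) ** 3 * (knots[-1] - tj) / (knots[-1] - knots[-2])
            + np.clip(x - knots[-1], 0, None) ** 3 * (knots[-2] - tj) / (knots[-1] - knots[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)
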