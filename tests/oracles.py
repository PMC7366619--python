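"""Independent reference implementations used to validate the package.

These deliberately avoid the package's own fitting code paths: the grid
search enumerates breakpoint triples exhaustively, and the piecewise
least-squares solve is restated here from first principles.
"""

from itertools import combinations, product

import numpy as np


def piecewise_sse(x, y, psi):
    """Least-squares SSE of a continuous 4-segment piecewise-linear model
    with fixed change points, solved directly via the normal equations of
    the hinge basis."""
    psi = np.asarray(psi, dtype=float)
    X = np.column_stack(
        [np.ones_like(x), x] + [np.clip(x - p, 0.0, None) for p in psi]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _admissible(x, psi, min_pts=2):
    """Every segment must hold at least ``min_pts`` data points."""
    edges = np.concatenate(([-np.inf], np.asarray(psi), [np.inf]))
    counts = np.diff(np.searchsorted(x, edges))
    return bool(np.all(counts >= min_pts))


def grid_search_best(x, y):
    """Exhaustive search over admissible triples of observed strain values.

    Returns (best_sse, best_psi, objective_resolution) where the
    resolution is the largest SSE increase over the one-grid-step
    neighborhood of the optimum.
    """
    interior = np.unique(x)[1:-1]
    best_sse, best_idx = np.inf, None
    for tri in combinations(range(interior.size), 3):
        psi = interior[list(tri)]
        if not _admissible(x, psi):
            continue
        sse = piecewise_sse(x, y, psi)
        if sse < best_sse:
            best_sse, best_idx = sse, tri
    resolution = 0.0
    for off in product((-1, 0, 1), repeat=3):
        idx = [best_idx[i] + off[i] for i in range(3)]
        if any(j < 0 or j >= interior.size for j in idx):
            continue
        if not (idx[0] < idx[1] < idx[2]):
            continue
        if not _admissible(x, interior[idx]):
            continue
        sse = piecewise_sse(x, y, interior[idx])
        resolution = max(resolution, sse - best_sse)
    return best_sse, interior[list(best_idx)], resolution


def blatz_stress_reference(lam, alpha, gamma):
    """Direct transcription of the two-parameter constitutive relation."""
    lam = np.asarray(lam, dtype=float)
    return (
        gamma
        / (alpha + 1.0)
        * (
            lam * np.exp(alpha * (lam**2 - 1.0))
            - lam**-2.0 * np.exp(alpha * (1.0 / lam - 1.0))
        )
    )
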