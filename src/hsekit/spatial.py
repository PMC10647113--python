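"""Spatial weights and Moran autocorrelation statistics.

Global Moran's I,

    I = [ sum_ij W_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2 ]
        * [ n / sum_ij W_ij ],

has expectation -1/(n-1) under the permutation null; inference here is by
random relabelling with a fixed seed.  Local Moran's I_i uses centred values
z_i and their spatial lags, with the H-H / H-L / L-L / L-H quadrant given by
the signs of (z_i, lag_i) and conditional-permutation p-values (unit i held
fixed, the remaining values permuted among its neighbours' positions).

Weights are built from symmetric adjacency pair lists or coordinates
(inverse distance), optionally row-standardised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UnknownUnitError, WeightsError
from .panel import EfficiencyPanel

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LocalMoranResult",
    "build_weights",
    "global_moran",
    "local_moran",
    "period_aggregate",
]


@dataclass
class SpatialWeights:
    """Non-negative n x n weights with zero diagonal over labelled units."""

    ids: tuple
    matrix: np.ndarray
    style: str = "binary"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        W = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if W.shape != (n, n):
            raise WeightsError("weight matrix shape does not match ids")
        if (W < 0).any() or np.diag(W).any():
            raise WeightsError("weights must be non-negative with a zero diagonal")
        self.matrix = W

    @property
    def n(self) -> int:
        return len(self.ids)

    def row_standardize(self) -> "SpatialWeights":
        sums = self.matrix.sum(axis=1)
        if (sums == 0).any():
            iso = [self.ids[i] for i in np.nonzero(sums == 0)[0]]
            raise WeightsError(f"cannot row-standardise; isolated units: {iso}")
        return SpatialWeights(self.ids, self.matrix / sums[:, None],
                              "row_standardized", dict(self.meta))

    def aligned(self, ids) -> np.ndarray:
        """Weight matrix reordered to a caller-supplied unit ordering."""
        pos = {u: i for i, u in enumerate(self.ids)}
        try:
            idx = [pos[u] for u in ids]
        except KeyError as err:
            raise UnknownUnitError(f"unit {err.args[0]!r} not in weights") from None
        return self.matrix[np.ix_(idx, idx)]

    def is_connected(self) -> bool:
        """Breadth-first check that the adjacency graph has one component."""
        adj = self.matrix > 0
        seen = np.zeros(self.n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in np.nonzero(adj[i] | adj[:, i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        return bool(seen.all())


def build_weights(adjacency=None, style: str = "row_standardized",
                  ids=None, coordinates=None, allow_isolates: bool = False) -> SpatialWeights:
    """Build weights from a neighbour pair list or point coordinates.

    ``adjacency``: iterable of (unit_a, unit_b) pairs (symmetrised).
    ``coordinates``: {unit: (x, y)} for inverse-distance weights.
    ``style``: 'binary', 'row_standardized' or 'inverse_distance'.
    """
    if coordinates is not None:
        ids = tuple(coordinates)
        pts = np.array([coordinates[u] for u in ids], dtype=float)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        if (d[~np.eye(len(ids), dtype=bool)] == 0).any():
            raise WeightsError("coincident coordinates give infinite weights")
        with np.errstate(divide="ignore"):
            W = 1.0 / d
        np.fill_diagonal(W, 0.0)
        w = SpatialWeights(ids, W, "inverse_distance", {"source": "coordinates"})
        return w.row_standardize() if style == "row_standardized" else w
    if adjacency is None:
        raise DomainError("provide an adjacency pair list or coordinates")
    pairs = list(adjacency)
    if ids is None:
        ids = tuple(sorted({u for p in pairs for u in p}))
    else:
        ids = tuple(ids)
        known = set(ids)
        for a, b in pairs:
            if a not in known or b not in known:
                raise UnknownUnitError(f"pair ({a!r}, {b!r}) references unknown unit")
    if len(ids) < 2:
        raise DomainError("need at least 2 units")
    pos = {u: i for i, u in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for a, b in pairs:
        if a == b:
            raise WeightsError(f"self-neighbour pair for {a!r}")
        W[pos[a], pos[b]] = W[pos[b], pos[a]] = 1.0
    w = SpatialWeights(ids, W, "binary", {"source": "pairs"})
    if not allow_isolates and (W.sum(axis=1) == 0).any():
        iso = [ids[i] for i in np.nonzero(W.sum(axis=1) == 0)[0]]
        raise WeightsError(f"isolated units: {iso}")
    return w.row_standardize() if style == "row_standardized" else w


def _checked_values(values, n_expected: int) -> np.ndarray:
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size != n_expected:
        raise DomainError("values must be a vector matching the weights dimension")
    if np.ptp(y) == 0:
        raise DomainError("values are constant; Moran's I undefined")
    return y


def _moran_stat(y: np.ndarray, W: np.ndarray) -> float:
    z = y - y.mean()
    return float(len(y) / W.sum() * (z @ W @ z) / (z @ z))


@dataclass
class MoranResult:
    I: float
    expected: float
    p_two_sided: float
    p_one_sided: float
    z_score: float
    n_permutations: int
    seed: int


def global_moran(values, weights: SpatialWeights, n_permutations: int = 999,
                 seed: int = 0) -> MoranResult:
    """Global Moran's I with permutation inference.

    p_two_sided = (1 + #{|I_perm| >= |I_obs|}) / (1 + n_perm); the one-sided
    p-value is for positive autocorrelation (I_perm >= I_obs).  The z-score
    uses the permutation mean and SD.
    """
    W = weights.matrix
    y = _checked_values(values, weights.n)
    i_obs = _moran_stat(y, W)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_permutations)
    for b in range(n_permutations):
        sims[b] = _moran_stat(rng.permutation(y), W)
    p_two = (1 + np.sum(np.abs(sims) >= abs(i_obs))) / (1 + n_permutations)
    p_one = (1 + np.sum(sims >= i_obs)) / (1 + n_permutations)
    sd = sims.std(ddof=1)
    z = (i_obs - sims.mean()) / sd if sd > 0 else np.nan
    return MoranResult(I=i_obs, expected=-1.0 / (weights.n - 1),
                       p_two_sided=float(p_two), p_one_sided=float(p_one),
                       z_score=float(z), n_permutations=n_permutations, seed=seed)


@dataclass
class LocalMoranResult:
    table: pd.DataFrame  # unit_id, I_i, quadrant, p_value
    n_permutations: int
    seed: int


def local_moran(values, weights: SpatialWeights, n_permutations: int = 999,
                seed: int = 0) -> LocalMoranResult:
    """Local Moran's I_i = z_i (W z)_i / (sum_k z_k^2 / n) with LISA quadrants.

    Quadrants: HH (z_i > 0, lag > 0), HL (z_i > 0, lag < 0), LL, LH.  Under
    row-standardised weights sum_i I_i / sum_ij W_ij = global I exactly.
    """
    W = weights.matrix
    y = _checked_values(values, weights.n)
    n = weights.n
    z = y - y.mean()
    m2 = (z @ z) / n
    lag = W @ z
    I_i = z * lag / m2
    quad = np.where(z > 0, np.where(lag >= 0, "HH", "HL"),
                    np.where(lag >= 0, "LH", "LL"))
    rng = np.random.default_rng(seed)
    p = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        wi = np.delete(W[i], i)
        sims = np.empty(n_permutations)
        for b in range(n_permutations):
            sims[b] = z[i] * (wi @ rng.permutation(others)) / m2
        p[i] = (1 + np.sum(np.abs(sims) >= abs(I_i[i]))) / (1 + n_permutations)
    table = pd.DataFrame({"unit_id": list(weights.ids), "I_i": I_i,
                          "quadrant": quad, "p_value": p})
    return LocalMoranResult(table=table, n_permutations=n_permutations, seed=seed)


def period_aggregate(panel: EfficiencyPanel, windows) -> pd.DataFrame:
    """Per-unit arithmetic means over year windows (e.g. [(2010, 2012), ...]).

    Returns a units x windows DataFrame with '<start>-<end>' column labels.
    """
    wide = panel.wide()
    out = {}
    for start, end in windows:
        years = [y for y in wide.columns if start <= y <= end]
        if not years:
            raise DomainError(f"window {start}-{end} contains no panel years")
        out[f"{start}-{end}"] = wide[years].mean(axis=1)
    return pd.DataFrame(out)
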