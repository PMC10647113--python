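"""Distribution dynamics of the efficiency panel: KDE and Markov chains.

Kernel density estimation (Gaussian kernel, Silverman rule-of-thumb
bandwidth) describes how the cross-provincial efficiency distribution moves
over time.  The Markov stage discretises efficiency into four quartile
states and estimates the year-to-year transition probability matrix by
maximum likelihood (transition counts over origin totals); the spatial
variant conditions each transition on the quartile state of the origin
year's spatial lag, revealing whether neighbours' efficiency levels pull a
province's own state up or down ("club convergence").

Default state scheme: quartile cut points are computed from the pooled set
of all unit-year values (linear-interpolation percentiles) and the boundary
rule assigns values equal to a cut to the lower state.  A per-year scheme is
available for panels whose scale drifts strongly over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, StateClassificationError, WeightsError
from .panel import EfficiencyPanel
from .spatial import SpatialWeights

__all__ = [
    "KDEResult",
    "StateSequence",
    "TransitionMatrix",
    "SpatialTransitionMatrix",
    "classify_states",
    "kde_curve",
    "silverman_bandwidth",
    "spatial_transition_matrix",
    "transition_matrix",
]

N_STATES = 4
LAG_LABELS = ("I", "II", "III", "IV")


def silverman_bandwidth(values) -> float:
    """Rule-of-thumb bandwidth h = 1.06 min(s, IQR/1.34) n^{-1/5}.

    s is the sample (n-1) standard deviation and the IQR uses
    linear-interpolation percentiles.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("need at least 2 values for a bandwidth")
    s = float(v.std(ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    delta = min(s, iqr / 1.34) if iqr > 0 else s
    if delta == 0:
        raise DomainError("degenerate bandwidth: values are constant")
    return 1.06 * delta * v.size ** (-0.2)


@dataclass
class KDEResult:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    def integral(self) -> float:
        """Trapezoid integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


def kde_curve(values, grid=None, bandwidth: float | None = None,
              n_grid: int = 512, pad: float = 4.0) -> KDEResult:
    """Gaussian kernel density f(x) = (nh)^{-1} sum_i K((X_i - x)/h).

    The default grid spans the data range padded by ``pad`` bandwidths, wide
    enough for the density to integrate to ~1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("empty sample")
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise DomainError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(v.min() - pad * h, v.max() + pad * h, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (v[None, :] - grid[:, None]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * h * np.sqrt(2 * np.pi))
    return KDEResult(grid=grid, density=density, bandwidth=h, n=int(v.size))


@dataclass
class StateSequence:
    """Quartile state (1..4) per unit-year, with the cut points used."""

    data: pd.DataFrame  # unit_id, year, state
    cuts: np.ndarray | dict  # (q25, q50, q75), per-year dict under that scheme
    scheme: str

    def wide(self) -> pd.DataFrame:
        return self.data.pivot(index="unit_id", columns="year", values="state").sort_index()


def _assign(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """State 1 iff v <= q25, 2 iff q25 < v <= q50, 3 iff q50 < v <= q75, else 4."""
    state = np.ones(values.shape, dtype=int)
    for c in cuts:
        state += (values > c).astype(int)
    return state


def _checked_cuts(values: np.ndarray) -> np.ndarray:
    cuts = np.percentile(values, [25, 50, 75])
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise StateClassificationError(
            f"quartile cut points not strictly increasing: {cuts}; "
            "consider the per_year_quartiles scheme")
    return cuts


def classify_states(panel: EfficiencyPanel,
                    scheme: str = "pooled_quartiles") -> StateSequence:
    """Discretise efficiency into four quartile states."""
    df = panel.data
    if df["te"].nunique() < 4:
        raise StateClassificationError("need at least 4 distinct values")
    if scheme == "pooled_quartiles":
        cuts = _checked_cuts(df["te"].to_numpy(dtype=float))
        out = df[["unit_id", "year"]].copy()
        out["state"] = _assign(df["te"].to_numpy(dtype=float), cuts)
        return StateSequence(out, cuts, scheme)
    if scheme == "per_year_quartiles":
        parts, cuts_by_year = [], {}
        for year, g in df.groupby("year"):
            cuts = _checked_cuts(g["te"].to_numpy(dtype=float))
            cuts_by_year[year] = cuts
            p = g[["unit_id", "year"]].copy()
            p["state"] = _assign(g["te"].to_numpy(dtype=float), cuts)
            parts.append(p)
        return StateSequence(pd.concat(parts, ignore_index=True), cuts_by_year, scheme)
    raise DomainError(f"unknown scheme {scheme!r}")


@dataclass
class TransitionMatrix:
    """4x4 transition counts and maximum-likelihood probabilities.

    Rows with zero origin count carry NaN probabilities (undefined, not 0).
    """

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (N_STATES, N_STATES) or (c < 0).any():
            raise DomainError("counts must be a non-negative 4x4 matrix")
        self.counts = c.astype(int)

    @property
    def origin_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.origin_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / totals[:, None]
        p[totals == 0] = np.nan
        return p

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        p = self.probabilities
        if decimals is not None:
            p = np.round(p, decimals)
        df = pd.DataFrame(p, index=list(LAG_LABELS), columns=list(LAG_LABELS))
        df.insert(0, "N", self.origin_totals)
        return df


def transition_matrix(states: StateSequence) -> TransitionMatrix:
    """Tally year-to-year state transitions across all units."""
    wide = states.wide().to_numpy()
    if wide.shape[1] < 2:
        raise DomainError("need at least 2 periods for transitions")
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    orig, dest = wide[:, :-1].ravel(), wide[:, 1:].ravel()
    np.add.at(counts, (orig - 1, dest - 1), 1)
    return TransitionMatrix(counts)


@dataclass
class SpatialTransitionMatrix:
    """One 4x4 transition block per spatial-lag state I..IV."""

    blocks: dict[str, TransitionMatrix]
    lag_cuts: np.ndarray

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        parts = []
        for label in LAG_LABELS:
            f = self.blocks[label].to_frame(decimals)
            f.insert(0, "lag_state", label)
            parts.append(f.reset_index(names="state"))
        return pd.concat(parts, ignore_index=True)


def spatial_transition_matrix(states: StateSequence, panel: EfficiencyPanel,
                              weights: SpatialWeights,
                              lag_cuts: np.ndarray | None = None) -> SpatialTransitionMatrix:
    """Transition tallies conditioned on the origin year's spatial-lag state.

    The spatial lag of unit i in year t is sum_j W_ij te_jt (row-standardised
    weights); it is classified with the same quartile cut points as the
    values themselves unless ``lag_cuts`` overrides them.
    """
    if states.scheme != "pooled_quartiles":
        raise DomainError("spatial conditioning requires pooled cut points")
    wide = panel.wide()
    units = list(wide.index)
    W = weights.aligned(units)
    if (W.sum(axis=1) == 0).any():
        raise WeightsError("a unit has an all-zero weight row; spatial lag undefined")
    lag = W @ wide.to_numpy()                       # (n_units, n_years)
    cuts = states.cuts if lag_cuts is None else np.asarray(lag_cuts, dtype=float)
    lag_state = _assign(lag, cuts)
    sw = states.wide().to_numpy()
    blocks = {}
    for k, label in enumerate(LAG_LABELS, start=1):
        counts = np.zeros((N_STATES, N_STATES), dtype=int)
        mask = lag_state[:, :-1] == k               # condition on origin-year lag
        orig, dest = sw[:, :-1][mask], sw[:, 1:][mask]
        np.add.at(counts, (orig - 1, dest - 1), 1)
        blocks[label] = TransitionMatrix(counts)
    return SpatialTransitionMatrix(blocks, cuts)
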