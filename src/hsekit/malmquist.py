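"""Output-oriented DEA distance functions and the Malmquist TFP index.

The radial output distance of a point (e0, p0) relative to a technology set
S = {(e_j, p_j)} is D = 1/phi*, where phi* solves the envelopment program

    max phi  s.t.  sum_j lambda_j e_j <= e0,
                   sum_j lambda_j p_j >= phi p0,
                   lambda >= 0            (CRS)
                   sum_j lambda_j = 1     (additionally, under VRS).

The adjacent-period Malmquist index is the geometric mean of the two
single-period indices, decomposed multiplicatively into efficiency change
(effch, CRS), technical change (techch), pure efficiency change (pech, VRS)
and scale efficiency change (sech = effch / pech).

DEA needs positive input/output levels; panels carrying logs must be
exponentiated before entering (see ``technology_from_panel``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import gmean

from .errors import DomainError, InfeasibleDistanceError
from .panel import ProvincePanel

__all__ = [
    "TechnologySet",
    "MalmquistResult",
    "malmquist_decompose",
    "malmquist_panel",
    "output_distance",
    "summarize_geomeans",
    "technology_from_panel",
]


@dataclass(frozen=True)
class TechnologySet:
    """One period's observed production possibilities.

    inputs: (n_dmu, n_inputs) and outputs: (n_dmu, n_outputs) positive levels,
    with the same DMU ordering across periods.
    """

    period: object
    inputs: np.ndarray
    outputs: np.ndarray
    dmu_ids: tuple

    def __post_init__(self):
        e = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        p = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        if e.shape[0] != p.shape[0] or e.shape[0] != len(self.dmu_ids):
            raise DomainError("inputs, outputs and dmu_ids must agree on n_dmu")
        if (e <= 0).any() or (p <= 0).any():
            raise DomainError("DEA requires strictly positive input/output levels")
        object.__setattr__(self, "inputs", e)
        object.__setattr__(self, "outputs", p)

    @property
    def n_dmu(self) -> int:
        return len(self.dmu_ids)


def output_distance(dmu_point, technology: TechnologySet, rts: str = "CRS") -> float:
    """Radial output distance D in (0, inf); own-technology points have D <= 1."""
    if rts not in ("CRS", "VRS"):
        raise DomainError("rts must be 'CRS' or 'VRS'")
    e0 = np.atleast_1d(np.asarray(dmu_point[0], dtype=float))
    p0 = np.atleast_1d(np.asarray(dmu_point[1], dtype=float))
    if (e0 <= 0).any() or (p0 <= 0).any():
        raise DomainError("evaluated point must be strictly positive")
    E, P = technology.inputs, technology.outputs
    n = technology.n_dmu
    # variables: [phi, lambda_1..lambda_n]; maximise phi
    c = np.zeros(n + 1)
    c[0] = -1.0
    a_in = np.hstack([np.zeros((E.shape[1], 1)), E.T])          # sum lam e <= e0
    a_out = np.hstack([p0[:, None], -P.T])                      # phi p0 - sum lam p <= 0
    A_ub = np.vstack([a_in, a_out])
    b_ub = np.concatenate([e0, np.zeros(P.shape[1])])
    A_eq = b_eq = None
    if rts == "VRS":
        A_eq = np.hstack([[0.0], np.ones(n)])[None, :]
        b_eq = np.array([1.0])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(None, None)] + [(0, None)] * n, method="highs")
    if res.status == 2:
        raise InfeasibleDistanceError(
            f"output-distance LP infeasible under {rts} against period "
            f"{technology.period!r}", period=technology.period)
    if not res.success:
        raise DomainError(f"LP solver failure: {res.message}")
    phi = -res.fun
    if phi <= 0:
        raise DomainError("non-positive optimal expansion; degenerate data")
    return 1.0 / phi


@dataclass
class MalmquistResult:
    """Per-DMU Malmquist decomposition for one adjacent-period pair."""

    period_from: object
    period_to: object
    table: pd.DataFrame  # columns: dmu, tfpch, techch, effch, pech, sech

    def geomeans(self) -> pd.Series:
        cols = ["techch", "effch", "pech", "sech", "tfpch"]
        ok = self.table.dropna(subset=cols)
        return pd.Series({c: gmean(ok[c]) for c in cols})


def malmquist_decompose(tech_t: TechnologySet, tech_t1: TechnologySet,
                        on_infeasible: str = "nan") -> MalmquistResult:
    """Four CRS distances + two VRS distances per DMU -> index components.

    effch = D^{t+1}(t+1)/D^t(t) (CRS), techch = MI/effch, pech the VRS
    analogue of effch, sech = effch/pech.  Cross-period VRS programs can be
    infeasible; same-period ones (used here) cannot.  ``on_infeasible``:
    'nan' records NaN for the affected DMU with a note, 'raise' propagates.
    """
    if tech_t.dmu_ids != tech_t1.dmu_ids:
        raise DomainError("technology sets must share the same DMU ordering")
    rows, notes = [], []
    for i, dmu in enumerate(tech_t.dmu_ids):
        pt = (tech_t.inputs[i], tech_t.outputs[i])
        pt1 = (tech_t1.inputs[i], tech_t1.outputs[i])
        try:
            d_t_t = output_distance(pt, tech_t, "CRS")
            d_t_t1 = output_distance(pt1, tech_t, "CRS")
            d_t1_t = output_distance(pt, tech_t1, "CRS")
            d_t1_t1 = output_distance(pt1, tech_t1, "CRS")
            v_t = output_distance(pt, tech_t, "VRS")
            v_t1 = output_distance(pt1, tech_t1, "VRS")
        except InfeasibleDistanceError as err:
            if on_infeasible == "raise":
                err.dmu = dmu
                raise
            notes.append(f"{dmu}: {err}")
            rows.append((dmu,) + (np.nan,) * 5)
            continue
        effch = d_t1_t1 / d_t_t
        mi = np.sqrt((d_t_t1 / d_t_t) * (d_t1_t1 / d_t1_t))
        techch = mi / effch
        pech = v_t1 / v_t
        sech = effch / pech
        rows.append((dmu, mi, techch, effch, pech, sech))
    table = pd.DataFrame(rows, columns=["dmu", "tfpch", "techch", "effch", "pech", "sech"])
    result = MalmquistResult(tech_t.period, tech_t1.period, table)
    result.notes = notes
    return result


def technology_from_panel(panel: ProvincePanel, year,
                          outputs: str = "index") -> TechnologySet:
    """Build a period technology from a log panel by exponentiating levels.

    ``outputs='index'`` uses the single aggregated output; ``'raw'`` uses the
    three service outputs when present.
    """
    g = panel.data[panel.data["year"] == year].sort_values("unit_id")
    if g.empty:
        raise DomainError(f"year {year!r} not in panel")
    e = np.exp(g[["ln_labor", "ln_capital"]].to_numpy(dtype=float))
    if outputs == "index":
        p = np.exp(g[["ln_output_index"]].to_numpy(dtype=float))
    elif outputs == "raw":
        p = np.exp(g[["ln_out_visits", "ln_out_discharge", "ln_out_surgery"]]
                   .to_numpy(dtype=float))
    else:
        raise DomainError("outputs must be 'index' or 'raw'")
    return TechnologySet(year, e, p, tuple(g["unit_id"]))


def malmquist_panel(panel: ProvincePanel, outputs: str = "index") -> list[MalmquistResult]:
    """Adjacent-period Malmquist decomposition over the whole panel."""
    years = panel.years
    techs = [technology_from_panel(panel, y, outputs) for y in years]
    return [malmquist_decompose(a, b) for a, b in zip(techs, techs[1:])]


def summarize_geomeans(results: list[MalmquistResult]) -> pd.DataFrame:
    """Per-pair geometric means across DMUs plus an overall geometric-mean row."""
    if not results:
        raise DomainError("need at least one adjacent-period result")
    rows = []
    for r in results:
        s = r.geomeans()
        rows.append({"period": f"{r.period_from}-{r.period_to}", **s.to_dict()})
    out = pd.DataFrame(rows)
    overall = {"period": "geometric mean"}
    for c in ["techch", "effch", "pech", "sech", "tfpch"]:
        overall[c] = gmean(out[c])
    return pd.concat([out, pd.DataFrame([overall])], ignore_index=True)
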