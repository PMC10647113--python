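"""End-to-end orchestration: frontier fit -> efficiency panel -> dynamics/ESDA.

A :class:`PipelineConfig` (built in code or loaded from YAML) names the data
source (a panel CSV, the embedded efficiency fixture, or the synthetic
generator), toggles stages, and records every seed.  ``run_pipeline`` writes
each stage's tables as CSV before the next stage consumes them, plus a JSON
manifest of the configuration and seeds, so a run is reproducible
bit-for-bit from its manifest.  Presentation rounding (3 decimals) is
applied only in the ``*_rounded`` report files; the primary CSVs carry full
precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dynamics, frontier, malmquist, panel as panel_mod, simulate, spatial
from .errors import HsekitError
from .panel import EfficiencyPanel, ProvincePanel

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("hsekit.pipeline")


@dataclass
class PipelineConfig:
    """Validated configuration for a full analysis run."""

    out_dir: str = "hsekit_out"
    seed: int = 0
    # data source: exactly one of panel_csv / synthetic / fixture
    panel_csv: str | None = None
    panel_schema: dict | None = None
    log_transform: bool = False
    synthetic: dict | None = None          # kwargs for FrontierTruth
    use_fixture: bool = False              # start from the embedded TE panel
    # stage toggles
    run_frontier: bool = True
    run_malmquist: bool = True
    run_dynamics: bool = True
    run_esda: bool = True
    # stage options
    frontier_form: str = "cobb_douglas"
    frontier_inefficiency: str = "truncated_normal"
    time_varying: bool = True
    dea_outputs: str = "index"
    markov_scheme: str = "pooled_quartiles"
    kde_years: list = field(default_factory=list)
    adjacency_csv: str | None = None       # unit pair list; default: China map
    esda_windows: list = field(default_factory=lambda: [])
    n_permutations: int = 999

    def validate(self) -> None:
        sources = [self.panel_csv is not None, self.synthetic is not None,
                   self.use_fixture]
        if sum(sources) != 1:
            raise HsekitError(
                "configure exactly one data source: panel_csv, synthetic, or use_fixture")
        if self.use_fixture and (self.run_frontier or self.run_malmquist):
            raise HsekitError(
                "the efficiency fixture has no input/output levels; disable the "
                "frontier and malmquist stages to run dynamics/ESDA on it")
        if self.run_esda and not self.use_fixture and self.adjacency_csv is None \
                and self.synthetic is None and self.panel_csv is not None:
            raise HsekitError("ESDA on a custom panel requires adjacency_csv")


def load_config(path) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise HsekitError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _weights_for(cfg: PipelineConfig, units) -> spatial.SpatialWeights:
    if cfg.adjacency_csv:
        import pandas as pd
        pairs = list(pd.read_csv(cfg.adjacency_csv).itertuples(index=False, name=None))
        return spatial.build_weights(pairs, style="row_standardized", ids=sorted(units))
    if cfg.use_fixture or cfg.panel_csv:
        return spatial.build_weights(panel_mod.load_china_adjacency(),
                                     style="row_standardized")
    return simulate.generate_weights(len(units), "random_contiguity",
                                     style="row_standardized", seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages, writing tables and a manifest to out_dir.

    Returns a manifest dict (also written as manifest.json).  A stage error
    aborts downstream stages; completed outputs are kept and the failure is
    recorded in the manifest.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}, "failure": None}

    prov_panel: ProvincePanel | None = None
    te_panel: EfficiencyPanel | None = None
    try:
        # ----- data stage -----
        if cfg.use_fixture:
            te_panel = panel_mod.load_efficiency_fixture()
            log.info("loaded embedded efficiency fixture: %d rows", len(te_panel.data))
        elif cfg.panel_csv:
            prov_panel = panel_mod.read_panel(cfg.panel_csv, schema=cfg.panel_schema,
                                              log_transform=cfg.log_transform)
            log.info("read panel %s: %d rows", cfg.panel_csv, len(prov_panel.data))
        else:
            truth = simulate.FrontierTruth(**{**cfg.synthetic, "seed": cfg.seed})
            prov_panel, u_true, te_true = simulate.generate_panel(truth)
            te_true.data.to_csv(out / "true_efficiency.csv", index=False)
            manifest["stages"]["simulate"] = {"truth": dataclasses.asdict(truth)}
            log.info("simulated panel: n=%d T=%d", truth.n_units, truth.n_periods)
        if prov_panel is not None:
            if "ln_output_index" not in prov_panel.data.columns:
                lncols = prov_panel.data[["ln_out_visits", "ln_out_discharge",
                                          "ln_out_surgery"]].to_numpy()
                idx, w = panel_mod.build_output_index(lncols)
                prov_panel.data["ln_output_index"] = idx
                prov_panel.output_weights = w
                manifest["stages"]["output_index"] = {"weights": list(map(float, w))}
            panel_mod.write_panel(prov_panel, out / "panel.csv")
            panel_mod.descriptive_stats(prov_panel, by_year=True).to_csv(
                out / "descriptives.csv", index=False)

        # ----- frontier stage -----
        if cfg.run_frontier:
            if prov_panel is None:
                raise HsekitError("frontier stage needs a province panel")
            spec = frontier.FrontierSpec(form=cfg.frontier_form,
                                         inefficiency=cfg.frontier_inefficiency,
                                         time_varying=cfg.time_varying)
            fit = frontier.fit_frontier(prov_panel, spec)
            fit.params_table().to_csv(out / "frontier_params.csv", index=False)
            te_panel = fit.te_panel
            te_panel.data.to_csv(out / "efficiency_panel.csv", index=False)
            te_panel.wide().round(3).to_csv(out / "efficiency_panel_rounded.csv")
            manifest["stages"]["frontier"] = {
                "loglik": fit.loglik, "gamma": fit.gamma, "eta": fit.eta,
                "mu": fit.mu, "sigma_sq": fit.sigma_sq,
                "beta": list(map(float, fit.beta)),
            }
            log.info("frontier fit: loglik=%.3f gamma=%.3f eta=%.4f",
                     fit.loglik, fit.gamma, fit.eta)

        # ----- malmquist stage -----
        if cfg.run_malmquist:
            if prov_panel is None:
                raise HsekitError("malmquist stage needs a province panel")
            results = malmquist.malmquist_panel(prov_panel, outputs=cfg.dea_outputs)
            summary = malmquist.summarize_geomeans(results)
            summary.to_csv(out / "malmquist_summary.csv", index=False)
            summary.round(3).to_csv(out / "malmquist_summary_rounded.csv", index=False)
            per_dmu = [r.table.assign(period=f"{r.period_from}-{r.period_to}")
                       for r in results]
            import pandas as pd
            pd.concat(per_dmu, ignore_index=True).to_csv(
                out / "malmquist_per_dmu.csv", index=False)
            manifest["stages"]["malmquist"] = {
                "overall_tfpch": float(summary["tfpch"].iloc[-1])}

        # ----- dynamics stage -----
        if cfg.run_dynamics:
            if te_panel is None:
                raise HsekitError("dynamics stage needs an efficiency panel")
            years = cfg.kde_years or [te_panel.years[0],
                                      te_panel.years[len(te_panel.years) // 2],
                                      te_panel.years[-1]]
            import pandas as pd
            kde_rows = []
            for y in years:
                vals = te_panel.data.loc[te_panel.data["year"] == y, "te"]
                k = dynamics.kde_curve(vals.to_numpy())
                kde_rows.append(pd.DataFrame({"year": y, "x": k.grid,
                                              "density": k.density}))
            pd.concat(kde_rows, ignore_index=True).to_csv(out / "kde_curves.csv",
                                                          index=False)
            states = dynamics.classify_states(te_panel, scheme=cfg.markov_scheme)
            tm = dynamics.transition_matrix(states)
            tm.to_frame().to_csv(out / "markov_matrix.csv")
            tm.to_frame(decimals=3).to_csv(out / "markov_matrix_rounded.csv")
            manifest["stages"]["dynamics"] = {
                "origin_counts": [int(x) for x in tm.origin_totals],
                "cut_points": [float(c) for c in np.atleast_1d(states.cuts)]
                if states.scheme == "pooled_quartiles" else "per_year",
            }
            if cfg.run_esda or cfg.use_fixture or cfg.adjacency_csv:
                w = _weights_for(cfg, te_panel.units)
                stm = dynamics.spatial_transition_matrix(states, te_panel, w)
                stm.to_frame().to_csv(out / "spatial_markov_matrix.csv", index=False)
                stm.to_frame(decimals=3).to_csv(
                    out / "spatial_markov_matrix_rounded.csv", index=False)

        # ----- ESDA stage -----
        if cfg.run_esda:
            if te_panel is None:
                raise HsekitError("ESDA stage needs an efficiency panel")
            import pandas as pd
            w = _weights_for(cfg, te_panel.units)
            windows = cfg.esda_windows or [(y, y) for y in te_panel.years]
            agg = spatial.period_aggregate(te_panel, windows)
            agg = agg.loc[list(w.ids)]
            rows = []
            lisa_parts = []
            for col in agg.columns:
                res = spatial.global_moran(agg[col].to_numpy(), w,
                                           n_permutations=cfg.n_permutations,
                                           seed=cfg.seed)
                rows.append({"window": col, "moran_i": res.I,
                             "p_value": res.p_one_sided, "z": res.z_score})
                loc = spatial.local_moran(agg[col].to_numpy(), w,
                                          n_permutations=cfg.n_permutations,
                                          seed=cfg.seed)
                lisa_parts.append(loc.table.assign(window=col))
            pd.DataFrame(rows).to_csv(out / "moran_global.csv", index=False)
            pd.concat(lisa_parts, ignore_index=True).to_csv(out / "moran_local.csv",
                                                            index=False)
            manifest["stages"]["esda"] = {"windows": [r["window"] for r in rows]}
    except HsekitError as err:
        manifest["failure"] = str(err)
        log.error("pipeline aborted: %s", err)
        raise
    finally:
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
        log.removeHandler(handler)
        handler.close()
    return manifest
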