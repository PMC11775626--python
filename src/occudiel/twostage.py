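"""Two-stage space-use analysis and spatial projection.

Stage 1 fits a constant-detection occupancy model to each prey species and
collects the per-site posterior-mean space-use probabilities.  Stage 2
feeds those prey psi fields — treated as fixed covariates, standardized
like any other — into the tiger model together with habitat and
anthropogenic-pressure covariates, with tiger detection modelled on
distance to roads and water.  Coefficients whose 95% credible interval
excludes zero are flagged significant (overlap0 = 0).  The fitted per-site
tiger psi is finally projected onto a regular grid by inverse-distance
weighting for mapping.

Stage-1 uncertainty is deliberately not propagated into stage 2 (posterior
means enter as plug-in covariates); ``bootstrap_stage1`` offers a
resampling check of that simplification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .occupancy import OccupancyModel, OccupancyMCMCResults

__all__ = [
    "PreyStageResult",
    "PipelineResult",
    "run_prey_stage",
    "run_tiger_stage",
    "significance",
    "idw_interpolate",
    "idw_map",
    "IDWGrid",
    "run_pipeline",
    "competitor_presence",
]

DEFAULT_MCMC = dict(chains=3, adapt=1000, burnin=1000, iterations=10000)

TIGER_PSI_COLUMNS = ["forest_km2", "human_count", "livestock_count",
                     "psi_blue_bull", "psi_gaur", "psi_wild_pig"]
TIGER_P_COLUMNS = ["dist_road", "dist_water"]
PREY_PSI_COLUMNS = ["human_count", "livestock_count", "dist_road",
                    "dist_settlement", "canopy_pct", "forest_km2",
                    "competitor_presence"]


def competitor_presence(histories: dict, focal: str) -> pd.Series:
    """Per-site indicator that any potentially competing species (all prey
    except the focal one) was detected at least once."""
    others = [h for sp, h in histories.items() if sp != focal]
    if not others:
        raise ValueError("no competitor histories supplied")
    site_ids = others[0].site_ids
    any_det = np.zeros(len(site_ids), dtype=bool)
    for h in others:
        any_det |= h.y.sum(axis=1) > 0
    return pd.Series(any_det.astype(float), index=site_ids,
                     name="competitor_presence")


@dataclass
class PreyStageResult:
    fits: dict                    # species -> OccupancyMCMCResults
    psi_table: pd.DataFrame       # sites x species posterior-mean psi
    summaries: pd.DataFrame       # stacked Table-1-style rows
    skipped: list = field(default_factory=list)


def run_prey_stage(histories: dict, covariates: pd.DataFrame,
                   psi_columns=PREY_PSI_COLUMNS, mcmc: dict | None = None,
                   seed=None, add_competitor: bool = True) -> PreyStageResult:
    """Fit each prey species with site covariates on psi and constant p.

    Species with zero detections cannot inform the model and are skipped
    with an explicit report entry.  Returns the per-site posterior-mean
    psi matrix used as stage-2 covariates.
    """
    mcmc = {**DEFAULT_MCMC, **(mcmc or {})}
    covs = covariates.set_index("site_id") if "site_id" in covariates.columns \
        else covariates.copy()
    fits, skipped, psi_cols, rows = {}, [], {}, []
    ss = np.random.SeedSequence(seed)
    for k, (sp, hist) in enumerate(sorted(histories.items())):
        if hist.y.sum() == 0:
            skipped.append({"species": sp, "reason": "zero detections"})
            continue
        table = covs.copy()
        if add_competitor and "competitor_presence" in psi_columns:
            table["competitor_presence"] = competitor_presence(histories, sp)
        use_cols = [c for c in psi_columns if c in table.columns]
        model = OccupancyModel.from_history(hist, table, psi_columns=use_cols,
                                           p_columns=())
        res = model.sample(seed=np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(k,)), **mcmc)
        fits[sp] = res
        psi_cols[f"psi_{sp}"] = res.predict_psi()["psi_mean"].to_numpy()
        s = res.summary()
        s = s.assign(species=sp)
        rows.append(s)
    psi_table = pd.DataFrame(psi_cols,
                             index=next(iter(histories.values())).site_ids)
    summaries = pd.concat(rows) if rows else pd.DataFrame()
    return PreyStageResult(fits=fits, psi_table=psi_table,
                           summaries=summaries, skipped=skipped)


def run_tiger_stage(history, covariates: pd.DataFrame, prey_psi: pd.DataFrame,
                    psi_columns=TIGER_PSI_COLUMNS, p_columns=TIGER_P_COLUMNS,
                    mcmc: dict | None = None, seed=None,
                    standardize_prey_psi: bool = True) -> OccupancyMCMCResults:
    """Stage-2 tiger fit with prey psi fields as plug-in covariates."""
    mcmc = {**DEFAULT_MCMC, **(mcmc or {})}
    covs = covariates.set_index("site_id") if "site_id" in covariates.columns \
        else covariates.copy()
    table = covs.join(prey_psi, how="left")
    for c in psi_columns:
        if c not in table.columns:
            raise KeyError(
                f"tiger design column {c!r} missing"
                + (f" (prey species {c[4:]!r} has no stage-1 psi)"
                   if c.startswith("psi_") else ""))
    if not standardize_prey_psi:
        # centre only; the raw probability scale is retained
        for c in psi_columns:
            if c.startswith("psi_"):
                table[c] = table[c] - table[c].mean()
    model = OccupancyModel.from_history(history, table,
                                       psi_columns=psi_columns,
                                       p_columns=p_columns)
    return model.sample(seed=seed, **mcmc)


def bootstrap_stage1(history, covariates: pd.DataFrame, prey: PreyStageResult,
                     n_draws: int = 50, psi_columns=TIGER_PSI_COLUMNS,
                     p_columns=TIGER_P_COLUMNS, seed=None) -> pd.DataFrame:
    """Propagate stage-1 uncertainty into the stage-2 coefficients.

    The default pipeline plugs posterior-*mean* prey psi fields into the
    tiger model.  This check instead draws whole prey-psi tables from the
    stage-1 posteriors and refits the tiger model (maximum likelihood, for
    speed) once per draw; the spread of the refitted coefficients shows
    how much the plug-in simplification hides.  Returns one row of
    coefficient estimates per draw.
    """
    from scipy.special import expit as _expit

    rng = np.random.default_rng(seed)
    covs = covariates.set_index("site_id") if "site_id" in covariates.columns \
        else covariates.copy()
    rows = []
    for _ in range(int(n_draws)):
        cols = {}
        for sp, fit in prey.fits.items():
            b = fit.coef_draws["psi"]
            c = rng.integers(b.shape[0])
            k = rng.integers(b.shape[1])
            cols[f"psi_{sp}"] = _expit(fit.model.X @ b[c, k])
        table = covs.join(pd.DataFrame(cols, index=prey.psi_table.index))
        model = OccupancyModel.from_history(
            history, table,
            psi_columns=[c for c in psi_columns if c in table.columns],
            p_columns=[c for c in p_columns if c in table.columns])
        rows.append(model.fit().params)
    return pd.DataFrame(rows).reset_index(drop=True)


def significance(summary: pd.DataFrame) -> pd.Series:
    """Covariate significance by the credible-interval rule.

    A coefficient is significant iff its interval excludes zero
    (overlap0 = 0); an interval touching zero at a bound contains it
    (closed-interval convention) and is not significant.
    """
    return (summary["overlap0"] == 0).rename("significant")


# ---------------------------------------------------------------------------
# inverse-distance-weighted projection


@dataclass
class IDWGrid:
    x: np.ndarray          # cell-centre eastings (ncol,)
    y: np.ndarray          # cell-centre northings (nrow,)
    values: np.ndarray     # (nrow, ncol)
    cell_size: float
    power: float

    def to_ascii(self, path):
        """ESRI ASCII raster (row 0 = north edge)."""
        nrow, ncol = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncol}\nnrows {nrow}\n")
            fh.write(f"xllcorner {self.x[0] - self.cell_size / 2:.3f}\n")
            fh.write(f"yllcorner {self.y[0] - self.cell_size / 2:.3f}\n")
            fh.write(f"cellsize {self.cell_size:.3f}\nNODATA_value -9999\n")
            for row in self.values[::-1]:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "value": self.values.ravel()})


def idw_interpolate(coords, values, query, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted prediction at query points.

    v(s) = sum_i d_i^-power v_i / sum_i d_i^-power; a query coinciding with
    a site returns that site's value exactly.  Being a weighted average,
    outputs lie within [min v, max v].
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if coords.shape[0] == 0:
        raise ValueError("at least one site is required")
    d = np.sqrt(((query[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    out = np.empty(query.shape[0])
    exact = d < 1e-12
    hit = exact.any(axis=1)
    out[hit] = values[np.argmax(exact[hit], axis=1)]
    w = 1.0 / np.maximum(d[~hit], 1e-300) ** power
    out[~hit] = (w * values).sum(axis=1) / w.sum(axis=1)
    return out


def idw_map(coords, values, cell_size: float = 250.0, power: float = 2.0,
            pad: float = 0.0) -> IDWGrid:
    """Project site values onto a regular grid covering the sites."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("at least one site is required")
    x0, x1 = coords[:, 0].min() - pad, coords[:, 0].max() + pad
    y0, y1 = coords[:, 1].min() - pad, coords[:, 1].max() + pad
    xs = np.arange(x0 + cell_size / 2, x1 + cell_size / 2, cell_size)
    ys = np.arange(y0 + cell_size / 2, y1 + cell_size / 2, cell_size)
    xx, yy = np.meshgrid(xs, ys)
    q = np.column_stack([xx.ravel(), yy.ravel()])
    vals = idw_interpolate(coords, values, q, power=power)
    return IDWGrid(x=xs, y=ys, values=vals.reshape(len(ys), len(xs)),
                   cell_size=cell_size, power=power)


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class PipelineResult:
    screen: object
    prey: PreyStageResult
    tiger: OccupancyMCMCResults
    tiger_summary: pd.DataFrame
    psi_sites: pd.DataFrame
    grid: IDWGrid
    report: dict

    def save(self, outdir):
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.prey.summaries.to_csv(out / "table1.csv")
        self.tiger_summary.to_csv(out / "table2.csv")
        self.psi_sites.to_csv(out / "psi_sites.csv", index=False)
        self.grid.to_ascii(out / "psi_grid.asc")
        self.grid.to_frame().to_csv(out / "psi_grid_cells.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=1, default=str)


def run_pipeline(histories: dict, covariates: pd.DataFrame,
                 tiger_species: str = "tiger",
                 screen_columns=("dist_water", "dist_road", "dist_settlement",
                                 "canopy_pct", "forest_km2", "human_count",
                                 "livestock_count"),
                 keep=("forest_km2", "human_count", "livestock_count"),
                 mcmc: dict | None = None, seed=None,
                 cell_size: float = 250.0, power: float = 2.0) -> PipelineResult:
    """Screen covariates, run both stages, and build the psi map."""
    from .screening import screen as screen_fn

    covs = covariates.set_index("site_id") if "site_id" in covariates.columns \
        else covariates.copy()
    # constant columns carry no information and would abort the screen
    usable = [c for c in screen_columns if covs[c].std(ddof=0) > 0]
    constant = sorted(set(screen_columns) - set(usable))
    scr = screen_fn(covs[usable], keep=[k for k in keep if k in usable])
    prey_hist = {sp: h for sp, h in histories.items() if sp != tiger_species}
    prey_cols = [c for c in PREY_PSI_COLUMNS
                 if c == "competitor_presence" or c in scr.retained]
    ss = np.random.SeedSequence(seed)
    prey = run_prey_stage(prey_hist, covariates, psi_columns=prey_cols,
                          mcmc=mcmc, seed=int(ss.generate_state(1)[0] >> 1))
    tiger_psi_cols = [c for c in TIGER_PSI_COLUMNS
                      if c.startswith("psi_") and c in prey.psi_table.columns
                      or (not c.startswith("psi_") and c in scr.retained)]
    tiger = run_tiger_stage(histories[tiger_species], covariates,
                            prey.psi_table, psi_columns=tiger_psi_cols,
                            mcmc=mcmc,
                            seed=np.random.SeedSequence(entropy=ss.entropy,
                                                        spawn_key=(1,)))
    tsum = tiger.summary()
    tsum = tsum.assign(significant=significance(tsum))
    psi_sites = tiger.predict_psi()
    psi_sites.insert(0, "site_id", list(histories[tiger_species].site_ids))
    coords = covs.loc[psi_sites["site_id"], ["x", "y"]].to_numpy()
    grid = idw_map(coords, psi_sites["psi_mean"].to_numpy(),
                   cell_size=cell_size, power=power)
    report = {
        "seed": seed,
        "constant_columns_excluded": constant,
        "screen": scr.to_dict(),
        "prey_skipped": prey.skipped,
        "tiger": tiger.report(),
        "prey_reports": {sp: r.report() for sp, r in prey.fits.items()},
        "grid": {"cell_size": cell_size, "power": power,
                 "shape": list(grid.values.shape)},
    }
    return PipelineResult(screen=scr, prey=prey, tiger=tiger,
                          tiger_summary=tsum, psi_sites=psi_sites,
                          grid=grid, report=report)
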