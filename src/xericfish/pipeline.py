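"""End-to-end orchestration: synthesize -> bin -> climate -> flow -> trends
-> richness models -> trait tests -> ancestral states.

Every stage reads and writes plain CSV/JSON/Newick under the output
directory, so any stage can be re-run in isolation; a JSON manifest records
seeds, row counts, the dropped-record ledger and a checksum per output.
All stage parameters live in :class:`PipelineConfig`, which round-trips
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import assemblage, climate, flow, hexgrid, phylo, synth, traits, trends

__all__ = ["PipelineConfig", "run"]

STAGES = ("synth", "bin", "climate", "flow", "trend",
          "models", "traits", "phylo")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one declarative object.

    Thresholds: ``wet_threshold_mm`` (a day below this is a zero-precip
    day), ``stage_threshold`` (stage above this on a zero-discharge day is
    a flow reversal, not a dry channel), ``log_offset`` (the c in
    log10(q/qbar + c)), ``min_years`` (hexes need this many sampled years
    to enter richness models), ``min_freshwater`` (site-level majority-
    freshwater rule).
    """

    seed: int = 0
    # synthetic-input sizes
    n_hexes: int = 23
    n_years_fish: int = 30
    n_years_hydro: int = 20
    n_years_climate: int = 20
    n_gauge_hexes: int = 8
    n_species_tree: int = 60
    richness_year_slope: float = -0.02
    dry_spell_trend: float = 0.5
    temp_trend: float = 0.05
    # grid and region conventions
    grid_radius: float = 0.1
    hemisphere: str = "north"
    water_year_start_month: int = 10
    water_year_start_day: int = 1
    # thresholds
    wet_threshold_mm: float = 1.0
    stage_threshold: float = 0.02
    log_offset: float = 0.01
    min_years: int = 10
    min_freshwater: float = 0.5
    # Monte-Carlo sizes
    n_perm_cca: int = 199
    n_perm_traits: int = 2000
    n_maps: int = 200
    # optional external inputs (paths); when None the synth stage provides them
    occurrences_path: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    polygons_path: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path):
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    manifest["outputs"][str(path.name)] = {
        "rows": int(len(df)), "sha256": _sha256(path)}


def run(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = hexgrid.HexGrid(circumradius=cfg.grid_radius)
    wy = flow.WaterYear(cfg.water_year_start_month, cfg.water_year_start_day)
    manifest: dict = {"seed": cfg.seed, "outputs": {}, "dropped": {},
                      "stages_run": []}
    rng = np.random.default_rng(cfg.seed)

    occurrences = traits_df = tree = None
    gauge_series: dict[str, pd.DataFrame] = {}
    climate_series: dict[str, pd.DataFrame] = {}

    # ----------------------------------------------------------- synth
    if cfg.stages.get("synth", True):
        ap = synth.AssemblageSimParams(
            n_hexes=cfg.n_hexes, n_years=cfg.n_years_fish,
            richness_year_slope=cfg.richness_year_slope, grid=grid,
            seed=int(rng.integers(2 ** 31)))
        occurrences, truth = synth.gen_assemblage(ap)
        _write(occurrences, out / "inputs" / "occurrences.csv", manifest)
        _write(truth, out / "inputs" / "richness_truth.csv", manifest)

        hex_ids = truth["hexid"].unique()
        for hexid in hex_ids[: cfg.n_gauge_hexes]:
            hp = synth.HydroSimParams(
                n_years=cfg.n_years_hydro, dry_spell_rate_per_year=2.0,
                dry_spell_trend=cfg.dry_spell_trend,
                start_year=ap.start_year + cfg.n_years_fish - cfg.n_years_hydro,
                seed=int(rng.integers(2 ** 31)))
            g = synth.gen_discharge(hp)
            gauge_series[hexid] = g
            _write(g, out / "inputs" / f"gauge_{hexid}.csv", manifest)
        for hexid in hex_ids:
            cp = synth.ClimateSimParams(
                n_years=cfg.n_years_climate, temp_trend=cfg.temp_trend,
                start_year=ap.start_year,
                seed=int(rng.integers(2 ** 31)))
            c = synth.gen_climate(cp)
            climate_series[hexid] = c
            _write(c, out / "inputs" / f"climate_{hexid}.csv", manifest)

        traits_df, tree, tip_states = synth.gen_traits_and_tree(
            n_species=cfg.n_species_tree, q_true=0.3,
            size_effect=1.0, trophic_effect=1.0,
            seed=int(rng.integers(2 ** 31)))
        _write(traits_df, out / "inputs" / "traits.csv", manifest)
        tree_path = out / "inputs" / "tree.nwk"
        tree.write(path=str(tree_path), schema="newick")
        manifest["outputs"]["tree.nwk"] = {"sha256": _sha256(tree_path)}
        manifest["stages_run"].append("synth")

    # external inputs override / supply missing pieces
    if cfg.occurrences_path:
        occurrences = pd.read_csv(cfg.occurrences_path,
                                  dtype={"lat_text": str, "lon_text": str})
    if cfg.traits_path:
        traits_df = pd.read_csv(cfg.traits_path)
    if cfg.tree_path:
        tree = dendropy.Tree.get(path=cfg.tree_path, schema="newick")

    # ------------------------------------------------------------- bin
    binned = None
    if cfg.stages.get("bin", True) and occurrences is not None:
        rec = occurrences.copy()
        if "lat_text" not in rec:
            rec["lat_text"] = rec["lat"].astype(str)
            rec["lon_text"] = rec["lon"].astype(str)
        kept, dropped = hexgrid.filter_precision(rec)
        manifest["dropped"]["precision"] = int(len(dropped))
        if cfg.polygons_path:
            poly = hexgrid.read_polygons(cfg.polygons_path)
            kept, d2 = hexgrid.filter_xeric(kept, poly)
            manifest["dropped"]["outside_habitat"] = int(len(d2))
        if traits_df is not None and "freshwater" in traits_df:
            kept, d3 = hexgrid.filter_freshwater(
                kept, traits_df, min_fraction=cfg.min_freshwater,
                missing="keep")
            manifest["dropped"]["freshwater_rule"] = int(len(d3))
        gauge_pts = pd.DataFrame(
            [dict(gauge=h, lat=la, lon=lo)
             for h, (lo, la) in (
                 (h, hexgrid.hex_centroid(*map(int, h.split("_")), grid))
                 for h in gauge_series)])
        clim_pts = pd.DataFrame(
            [dict(point=h, lat=la, lon=lo)
             for h, (lo, la) in (
                 (h, hexgrid.hex_centroid(*map(int, h.split("_")), grid))
                 for h in climate_series)])
        if gauge_pts.empty:
            gauge_pts = pd.DataFrame(columns=["gauge", "lat", "lon"])
        if clim_pts.empty:
            clim_pts = pd.DataFrame(columns=["point", "lat", "lon"])
        rec_b, gau_b, cli_b, bundles = hexgrid.bin_all(
            kept, gauge_pts, clim_pts, grid)
        binned = rec_b
        _write(rec_b, out / "binned_occurrences.csv", manifest)
        _write(bundles, out / "hex_bundles.csv", manifest)
        manifest["stages_run"].append("bin")

    # --------------------------------------------------------- climate
    climate_metrics = None
    if cfg.stages.get("climate", True) and climate_series:
        precip_rows, temp_rows = [], []
        for hexid, c in climate_series.items():
            pm = climate.annual_precip_metrics(c, cfg.wet_threshold_mm)
            pm.insert(0, "hexid", hexid)
            precip_rows.append(pm)
            tm = climate.seasonal_temp_metrics(c, cfg.hemisphere)
            tm.insert(0, "hexid", hexid)
            temp_rows.append(tm)
        precip_metrics = pd.concat(precip_rows, ignore_index=True)
        temp_metrics = pd.concat(temp_rows, ignore_index=True)
        climate_metrics = (precip_metrics, temp_metrics)
        _write(precip_metrics, out / "precip_metrics.csv", manifest)
        _write(temp_metrics, out / "temp_metrics.csv", manifest)
        manifest["stages_run"].append("climate")

    # ------------------------------------------------------------ flow
    flow_metrics = None
    if cfg.stages.get("flow", True) and gauge_series:
        rows, naa_rows = [], []
        for hexid, g in gauge_series.items():
            flags = flow.dry_day_flags(g, cfg.stage_threshold)
            daily = g.merge(flags, on="date")
            dm = flow.drying_metrics(daily, wy)
            dm.insert(0, "hexid", hexid)
            rows.append(dm)
            dec = flow.seasonal_profile_fft(
                g["discharge"].to_numpy(), cfg.log_offset)
            naa = flow.net_annual_anomaly(dec.anomaly, g["date"], wy)
            naa.insert(0, "hexid", hexid)
            naa_rows.append(naa)
        drying = pd.concat(rows, ignore_index=True)
        naa_all = pd.concat(naa_rows, ignore_index=True)
        flow_metrics = drying.merge(naa_all, on=["hexid", "water_year"],
                                    how="left")
        _write(flow_metrics, out / "flow_metrics.csv", manifest)
        manifest["stages_run"].append("flow")

    # ----------------------------------------------------------- trend
    if cfg.stages.get("trend", True):
        trend_rows = []
        if climate_metrics is not None:
            pm, tm = climate_metrics
            ok = pm.dropna(subset=["total"])
            r = trends.regional_kendall(ok["total"], ok["year"], ok["hexid"])
            trend_rows.append(("annual_precip_total", *r))
            annual_t = (tm.dropna(subset=["mean_temp"])
                        .groupby(["hexid", "year"])["mean_temp"].mean()
                        .reset_index())
            r = trends.regional_kendall(annual_t["mean_temp"],
                                        annual_t["year"], annual_t["hexid"])
            trend_rows.append(("annual_mean_temp", *r))
        if flow_metrics is not None:
            for metric in ("zero_flow_days", "first_day_min_flow",
                           "max_no_flow_duration", "naa"):
                ok = flow_metrics.dropna(subset=[metric])
                if ok["hexid"].nunique() < 2:
                    continue
                r = trends.regional_kendall(ok[metric], ok["water_year"],
                                            ok["hexid"])
                trend_rows.append((metric, *r))
        trend_tab = pd.DataFrame(
            trend_rows, columns=["metric", "S", "var_S", "Z", "p",
                                 "sen_slope", "ci_low", "ci_high"])
        _write(trend_tab, out / "trends.csv", manifest)
        manifest["stages_run"].append("trend")

    # ---------------------------------------------------------- models
    if cfg.stages.get("models", True) and binned is not None:
        matrices, dropped_hex = assemblage.build_matrix(binned, cfg.min_years)
        manifest["dropped"]["short_hex_series"] = len(dropped_hex)
        rich = pd.DataFrame(
            [dict(hexid=h, year=int(y), richness=int(r))
             for h, m in matrices.items()
             for y, r in zip(m.years, m.richness)])
        if len(rich) and rich["hexid"].nunique() >= 2:
            if flow_metrics is not None:
                rich = rich.merge(
                    flow_metrics.rename(columns={"water_year": "year"}),
                    on=["hexid", "year"], how="left")
            flow_terms = [t for t in ("naa", "zero_flow_days",
                                      "first_day_min_flow",
                                      "max_no_flow_duration")
                          if t in rich and rich[t].notna().sum() > 0]
            model_defs = {"null": [], "year": ["year"]}
            for t in flow_terms:
                model_defs[t] = [t]
            if flow_terms:
                model_defs["full"] = ["year"] + flow_terms
            fits = []
            for nm, terms in model_defs.items():
                sub = rich.dropna(subset=terms) if terms else rich
                fits.append(assemblage.fit_poisson_glmm(
                    sub, terms, name=nm))
            tab = assemblage.aic_table(fits)
            _write(tab, out / "model_selection.csv", manifest)
            coef = pd.DataFrame(
                [dict(model=f.name, term=t, beta=b, se=s)
                 for f in fits
                 for t, b, s in zip(["(intercept)"] + f.terms,
                                    f.beta, f.beta_se)])
            _write(coef, out / "model_coefficients.csv", manifest)

            # pooled presence matrix for CCA over hex-years with flow data
            all_species = sorted({s for m in matrices.values()
                                  for s in m.species})
            sp_ix = {s: j for j, s in enumerate(all_species)}
            key = rich.dropna(subset=flow_terms) if flow_terms else rich
            Y = np.zeros((len(key), len(all_species)))
            X = np.zeros((len(key), 1 + len(flow_terms)))
            for i, row in enumerate(key.itertuples()):
                m = matrices[row.hexid]
                yr_ix = int(np.flatnonzero(m.years == row.year)[0])
                for s in np.array(m.species)[m.presence[yr_ix]]:
                    Y[i, sp_ix[s]] = 1.0
                X[i, 0] = row.year
                for j, t in enumerate(flow_terms, start=1):
                    X[i, j] = getattr(row, t)
            if len(key) >= 5:
                res = assemblage.cca(Y, X, n_perm=cfg.n_perm_cca,
                                     seed=int(rng.integers(2 ** 31)))
                cca_tab = pd.DataFrame(dict(
                    axis=np.arange(1, len(res.eigenvalues) + 1)[:5],
                    eigenvalue=res.eigenvalues[:5],
                    p=res.axis_p[:5]))
                cca_tab.attrs = {}
                summary = pd.DataFrame([dict(
                    total_inertia=res.total_inertia,
                    constrained_inertia=res.constrained_inertia,
                    explained_percent=assemblage.explained_fraction(res))])
                _write(summary, out / "cca_summary.csv", manifest)
                _write(cca_tab, out / "cca_axes.csv", manifest)
        manifest["stages_run"].append("models")

    # ---------------------------------------------------------- traits
    if cfg.stages.get("traits", True) and traits_df is not None:
        flags, tallies = traits.concern_flag(traits_df)
        rows = []
        for trait in ("max_length", "trophic_level", "longevity"):
            if trait not in traits_df:
                continue
            vals = traits_df[trait]
            a = vals[flags].dropna()
            b = vals[~flags].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            r = traits.fisher_pitman(a, b, n_perm=cfg.n_perm_traits,
                                     seed=int(rng.integers(2 ** 31)))
            rows.append(dict(trait=trait, z=r.z, p_asymptotic=r.p_asymptotic,
                             p_permutation=r.p_permutation, n_perm=r.n_perm))
        _write(pd.DataFrame(rows), out / "trait_tests.csv", manifest)
        summary = traits.listing_reason_summary(traits_df)
        venn = pd.DataFrame(
            [dict(region="+".join(sorted(k)) or "(none)", count=v)
             for k, v in summary["venn"].items()])
        _write(venn, out / "listing_reason_regions.csv", manifest)
        manifest["listing_summary"] = {
            "n_listed": summary["n_listed"],
            "percents": summary["percents"],
            "fraction_multiple": summary["fraction_multiple"],
            "tallies": tallies,
        }
        manifest["stages_run"].append("traits")

    # ----------------------------------------------------------- phylo
    if cfg.stages.get("phylo", True) and tree is not None \
            and traits_df is not None:
        flags, _ = traits.concern_flag(traits_df)
        tip_states = {s: int(f) for s, f in
                      zip(traits_df["species"], flags)}
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        tip_states = {k: v for k, v in tip_states.items() if k in labels}
        if len(tip_states) >= 3:
            sub = phylo.prune_tree(tree, list(tip_states))
            fit = phylo.fit_mk(sub, tip_states)
            sm = phylo.stochastic_maps(sub, tip_states, fit,
                                       n_maps=cfg.n_maps,
                                       seed=int(rng.integers(2 ** 31)))
            node_tab = sm.table.copy()
            node_tab.insert(0, "q_hat", fit.q)
            _write(node_tab, out / "node_state_probabilities.csv", manifest)
            manifest["mk_fit"] = {"q": fit.q, "loglik": fit.loglik}
        manifest["stages_run"].append("phylo")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return manifest
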