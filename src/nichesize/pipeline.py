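"""Configured, logged, resumable pipeline: synth -> clean -> limits ->
covariates -> fit -> diagnose.

Each stage is a pure function of its declared inputs; a manifest (input and
output hashes, row counts, software version, seed) makes re-runs
bit-identical under the same seed. Logging is JSON-lines with per-stage
counts so cleaning reports can be reconciled against row deltas.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diagnostics as dg
from . import exposure_covariates as cov
from . import formats_io as fio
from . import niche_limits as nl
from . import phylo_mixed_model as pm
from . import trait_cleaning as tc
from .errors import StageError
from .synthetic_world import WorldConfig, generate_world

logger = logging.getLogger(__name__)

STAGES = ["synth", "clean", "limits", "covariates", "fit", "diagnose"]

DEFAULTS = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "world": {},
    "baseline_years": [1961, 1975],
    "mad_k": 5.0,
    "min_count": 100,
    "site_decimals": 4,
    "response": "log10_mass",
    "metric": "mass",
    "include_year": True,
    "slopes": "tpi",
    "stage_map": {}, "sex_map": {},
    "diagnostics": {"n_iter_dw": 200, "n_boot": 49, "n_sim_ppc": 200},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULTS, **user}
    cfg["diagnostics"] = {**DEFAULTS["diagnostics"],
                          **(user.get("diagnostics") or {})}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Runner:
    def __init__(self, config: dict):
        self.cfg = config
        self.out = Path(config["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {"version": __version__, "seed": config["seed"],
                         "stages": {}}
        self.logpath = self.out / "pipeline_log.jsonl"

    def path(self, name: str) -> Path:
        return self.out / name

    def log(self, stage: str, **fields):
        rec = {"stage": stage, **fields}
        with open(self.logpath, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    def record(self, stage: str, inputs: list, outputs: list, **counts):
        self.manifest["stages"][stage] = {
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in outputs},
            "counts": counts,
        }
        self.log(stage, **counts)

    def need(self, stage: str, *paths: Path) -> None:
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise StageError(stage, f"missing required input(s): {missing}")

    # -- stages -------------------------------------------------------------

    def synth(self):
        wc = WorldConfig(seed=self.cfg["seed"], **self.cfg["world"])
        world = generate_world(wc)
        outs = []
        for name in ("tmax", "ppt", "pet", "cropland", "pasture", "urban",
                     "realm"):
            p = self.path(f"{name}.nc")
            fio.write_climate_cube(world.cubes[name], p)
            outs.append(p)
        p = self.path("ranges.csv")
        fio.write_range_masks(world.masks, world.cubes["tmax"], p)
        outs.append(p)
        p = self.path("tree.nwk")
        fio.write_tree(world.tree, p)
        outs.append(p)
        p = self.path("synonyms.csv")
        fio.write_synonyms(world.synonyms, p)
        outs.append(p)
        p = self.path("observations.csv")
        fio.write_observations(world.observations, p)
        outs.append(p)
        self.record("synth", [], outs, n_observations=len(world.observations),
                    n_species=wc.n_species)

    def clean(self):
        src = self.path("observations.csv")
        self.need("clean", src, self.path("synonyms.csv"))
        table = fio.read_observations(src)
        syn = fio.read_synonyms(self.path("synonyms.csv"))
        cleaned, rep = tc.clean_pre_covariates(
            table, syn, self.cfg["stage_map"], self.cfg["sex_map"],
            self.cfg["site_decimals"])
        out = self.path("cleaned_pre.csv")
        fio.write_observations(cleaned, out)
        repp = self.path("cleaning_report_pre.json")
        with open(repp, "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2, sort_keys=True)
        self.record("clean", [src], [out, repp],
                    n_input=rep.n_input, n_output=rep.n_output,
                    removed=rep.total_removed)

    def limits(self):
        ins = [self.path(f"{n}.nc") for n in ("tmax", "ppt", "pet")]
        rng = self.path("ranges.csv")
        self.need("limits", *ins, rng)
        tmax = fio.read_climate_cube(ins[0])
        ppt = fio.read_climate_cube(ins[1])
        pet = fio.read_climate_cube(ins[2])
        masks = fio.read_range_masks(rng, tmax)
        ai = nl.compute_ai(ppt, pet)
        base = tuple(self.cfg["baseline_years"])
        lim = pd.concat([nl.derive_limits_table(tmax, masks, base),
                         nl.derive_limits_table(ai, masks, base)],
                        ignore_index=True)
        aip = self.path("ai.nc")
        fio.write_climate_cube(ai, aip)
        out = self.path("limits.csv")
        nl.write_limits(lim, out)
        self.record("limits", ins + [rng], [out, aip],
                    n_limit_rows=len(lim),
                    ai_upper_adjusted_fraction=nl.adjusted_upper_fraction(lim))

    def covariates(self):
        src = self.path("cleaned_pre.csv")
        ins = [src, self.path("limits.csv"), self.path("tmax.nc"),
               self.path("ai.nc"), self.path("cropland.nc"),
               self.path("pasture.nc"), self.path("urban.nc"),
               self.path("realm.nc")]
        self.need("covariates", *ins)
        table = pd.read_csv(src)
        lim = nl.read_limits(self.path("limits.csv"))
        table = cov.attach_climate_indices(
            table, fio.read_climate_cube(self.path("tmax.nc")),
            fio.read_climate_cube(self.path("ai.nc")), lim)
        table = cov.attach_landuse(
            table, fio.read_climate_cube(self.path("cropland.nc")),
            fio.read_climate_cube(self.path("pasture.nc")),
            fio.read_climate_cube(self.path("urban.nc")))
        table = cov.attach_realm(
            table, fio.read_climate_cube(self.path("realm.nc")))
        out = self.path("with_covariates.csv")
        table.to_csv(out, index=False)
        self.record("covariates", ins, [out], n_rows=len(table))

    def fit(self):
        src = self.path("with_covariates.csv")
        self.need("fit", src, self.path("tree.nwk"))
        table = pd.read_csv(src)
        metric = self.cfg["metric"]
        table, rep = tc.clean_post_covariates(
            table, metric, self.cfg["mad_k"], self.cfg["min_count"])
        repp = self.path("cleaning_report_post.json")
        with open(repp, "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2, sort_keys=True)
        zcols = [self.cfg["response"], "tpi", "api", "alu", "ulu", "year"]
        zed, means, sds = cov.zscore_columns(table, zcols)
        zed = cov.add_interactions(zed, [("tpi", "api"), ("tpi", "alu"),
                                         ("tpi", "ulu")])
        zed.to_csv(self.path("model_table.csv"), index=False)
        tree = fio.read_tree(self.path("tree.nwk"))
        species = sorted(zed["species_id"].unique())
        C = pm.phylo_correlation(tree, species)
        spec = pm.ModelSpec(response=self.cfg["response"],
                            include_year=self.cfg["include_year"],
                            slope_predictors=(
                                ("tpi",) if self.cfg["slopes"] == "tpi"
                                else tuple(self.cfg["slopes"])))
        design = pm.assemble(zed, spec, C)
        fit_res = pm.fit(design)
        outj = self.path("model_fit.json")
        fit_res.to_json(outj)
        resid = pd.DataFrame({"row": design.index,
                              "fitted": fit_res.fitted,
                              "residual": fit_res.residuals})
        outr = self.path("residuals.csv")
        resid.to_csv(outr, index=False)
        self.record("fit", [src], [outj, outr, repp],
                    n_modelled=design.n, n_dropped=design.n_dropped,
                    n_cleaned_rows=rep.n_output,
                    partial_r2=pm.partial_r2(fit_res))

    def diagnose(self):
        ins = [self.path("model_table.csv"), self.path("model_fit.json"),
               self.path("tree.nwk")]
        self.need("diagnose", *ins)
        table = pd.read_csv(self.path("model_table.csv"))
        tree = fio.read_tree(self.path("tree.nwk"))
        species = sorted(table["species_id"].unique())
        C = pm.phylo_correlation(tree, species)
        spec = pm.ModelSpec(response=self.cfg["response"],
                            include_year=self.cfg["include_year"])
        design = pm.assemble(table, spec, C)
        fit_res = pm.fit(design)  # deterministic re-fit from the table
        d = self.cfg["diagnostics"]
        report = dg.run_all(fit_res, design, table, seed=self.cfg["seed"],
                            n_iter_dw=d["n_iter_dw"], n_boot=d["n_boot"],
                            n_sim_ppc=d["n_sim_ppc"])
        out = self.path("diagnostics.json")
        report.to_json(out)
        self.record("diagnose", ins, [out],
                    dw_fraction_nonsignificant=
                    report.dw_global["fraction_nonsignificant"],
                    influence_fraction=report.influence["fraction"])


def run(config: dict, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order; returns the manifest."""
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise StageError(bad[0], "unknown stage")
    runner = _Runner(config)
    if runner.logpath.exists():
        runner.logpath.unlink()
    for s in STAGES:
        if s in stages:
            logger.info("running stage %s", s)
            getattr(runner, s)()
    mpath = runner.path("manifest.json")
    with open(mpath, "w") as fh:
        json.dump(runner.manifest, fh, indent=2, sort_keys=True)
    return runner.manifest
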