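"""Configuration-driven orchestration of the full analysis chain.

simulate/ingest -> derived phenotypes -> trajectory clusters -> growth NLME
-> heritability table -> linkage scan -> reports.  Every run is a pure
function of (config, seed): reports are written as TSV/JSON plus a manifest
recording the config hash, seed and package version, so identical configs
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth import LogisticGrowthME, fit_quality
from .linkage import genome_scan, ibd_from_descent, power_simulation
from .pedigree import Pedigree, household_matrix, kinship_matrix
from .phenotypes import (adult_trait_table, assign_diet_exposure,
                         inverse_normal_transform, regress_out_age)
from .simulate import SimConfig, adult_phenotyped_ids, gene_drop, simulate_colony
from .trajectories import TrajectoryKMeans
from .varcomp import (CovariateDesign, PolygenicModel, LiabilityThresholdModel,
                      lrt_variance_component, screen_covariates)

log = logging.getLogger("pedigrowth")

STAGES = ("simulate", "phenotypes", "cluster", "growth", "varcomp", "linkage", "power")


class PipelineConfigError(ValueError):
    """Schema violation in a pipeline configuration."""


@dataclass
class PipelineConfig:
    """Pipeline settings: exactly one of (input paths | simulate block)."""

    outdir: str = "pedigrowth_out"
    seed: int = 0
    # data source
    pedigree_csv: str | None = None
    phenotype_csv: str | None = None
    diet_timeline: list | None = None  # [{"diet","start","end"}, ...]
    simulate: dict | None = None  # SimConfig overrides
    # analysis toggles
    stages: tuple = ("phenotypes", "cluster", "growth", "varcomp")
    # thresholds
    adult_age: float = 5.0
    min_measures: int = 6
    chronic_run: int = 3
    obesity_percentile: float = 80.0
    obesity_fixed_cm: float | None = None  # set to use the fixed 40.5 cut-off
    suggestive_lod: float = 1.9
    significant_lod: float = 3.3
    alpha: float = 0.05
    grid_step_years: float = 1.0
    k_range: tuple = (2, 6)
    n_starts: int = 20
    scan_step_cm: float = 5.0
    power_reps: int = 100
    power_h2_total: float = 0.65
    power_h2q: float = 0.17

    def validate(self) -> None:
        has_paths = self.pedigree_csv is not None or self.phenotype_csv is not None
        if has_paths and self.simulate is not None:
            raise PipelineConfigError(
                "config must set either input paths or a simulate block, not both")
        if not has_paths and self.simulate is None:
            raise PipelineConfigError("config needs input paths or a simulate block")
        if has_paths and (self.pedigree_csv is None or self.phenotype_csv is None):
            raise PipelineConfigError("both pedigree_csv and phenotype_csv are required")
        for name in ("adult_age", "min_measures", "chronic_run", "suggestive_lod",
                     "significant_lod", "alpha", "grid_step_years", "scan_step_cm"):
            if getattr(self, name) <= 0:
                raise PipelineConfigError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise PipelineConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_data(config: PipelineConfig):
    if config.simulate is not None:
        sim = SimConfig(**{"seed": config.seed, **config.simulate})
        colony = simulate_colony(sim)
        return colony.pedigree, colony.measurements, colony.diet_timeline, sim
    ped = Pedigree.from_csv(config.pedigree_csv)
    meas = pd.read_csv(config.phenotype_csv)
    meas["pregnant"] = meas["pregnant"].astype(bool)
    return ped, meas, config.diet_timeline, None


def _growth_cohort(measurements: pd.DataFrame) -> pd.DataFrame:
    """Birth-to-adulthood subjects: first measured young, observed past the
    mid-growth ages; only their trajectories carry growth signal."""
    first = measurements.groupby("id")["age"].min()
    last = measurements.groupby("id")["age"].max()
    ids = first[first <= 2.0].index.intersection(last[last >= 4.0].index)
    return measurements[measurements["id"].isin(ids)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a dict of output paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs: dict[str, str] = {}
    log.info("loading data (%s)", "simulate" if config.simulate is not None else "files")
    ped, meas, timeline, sim = _load_data(config)
    sex_of = {i.id: i.sex for i in ped.individuals}
    meas = meas.copy()
    meas["sex"] = meas["id"].map(sex_of)
    if "simulate" in config.stages or config.simulate is not None:
        ped.to_csv(outdir / "pedigree.csv")
        meas.drop(columns=["sex"]).to_csv(outdir / "phenotypes.csv", index=False)
        outputs["pedigree"] = str(outdir / "pedigree.csv")
        outputs["phenotypes"] = str(outdir / "phenotypes.csv")

    adult = clusters = None
    varcomp_rows = []
    growth_json = {}
    subject_params = None

    if "phenotypes" in config.stages:
        log.info("stage phenotypes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adult = adult_trait_table(meas, adult_age=config.adult_age,
                                      wc_threshold=config.obesity_fixed_cm)
        adult["sex"] = adult["id"].map(sex_of)
        if timeline:
            id_era = [iv for iv in timeline if iv["diet"] == "ID"]
            if id_era:
                interval = (date.fromisoformat(id_era[0]["start"]),
                            date.fromisoformat(id_era[-1]["end"]))
                expo = assign_diet_exposure(ped, interval)
                adult["maternal_diet"] = adult["id"].map(
                    lambda i: expo[i].maternal_diet_gestation)
                adult["id_intro"] = adult["id"].map(lambda i: expo[i].id_intro_period)
        adult.to_csv(outdir / "adult_traits.tsv", sep="\t", index=False)
        outputs["adult_traits"] = str(outdir / "adult_traits.tsv")

    if "cluster" in config.stages:
        log.info("stage cluster (per sex)")
        cohort = _growth_cohort(meas)
        frames = []
        for sex in ("F", "M"):
            sub = cohort[cohort["sex"] == sex]
            res = TrajectoryKMeans(sub, grid_step=config.grid_step_years,
                                   min_measures=config.min_measures,
                                   k_range=range(config.k_range[0], config.k_range[1] + 1),
                                   n_starts=config.n_starts).fit(seed=config.seed)
            frame = res.assignment.to_frame()
            frame["sex"] = sex
            frames.append(frame)
            log.info("  %s: %s", sex, res.summary().splitlines()[0])
        clusters = pd.concat(frames, ignore_index=True)
        clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        outputs["clusters"] = str(outdir / "clusters.tsv")

    if "growth" in config.stages:
        if clusters is None:
            raise PipelineConfigError("growth stage requires the cluster stage")
        log.info("stage growth (NLME per sex x cluster)")
        cohort = _growth_cohort(meas)
        tables = []
        for (sex, cl), grp in clusters.groupby(["sex", "cluster"]):
            sub = cohort[cohort["id"].isin(grp["id"]) & ~cohort["pregnant"].astype(bool)]
            data = sub.rename(columns={"bw": "value"})[["id", "age", "value"]]
            counts = data.groupby("id").size()
            data = data[data["id"].isin(counts[counts >= config.min_measures].index)]
            if data["id"].nunique() < 10:
                log.warning("  group (%s, %s): too few subjects, skipped", sex, cl)
                continue
            fit = LogisticGrowthME(data, group=(sex, int(cl)),
                                   min_measures=config.min_measures).fit()
            r_dev, r_life = fit_quality(fit)
            log.info("  (%s, %s): theta1=%.2f midpoint=%.2f r_dev=%.3f",
                     sex, cl, fit.fixed.theta1, fit.fixed.midpoint, r_dev)
            growth_json[f"{sex}_{cl}"] = {**fit.to_json_dict(),
                                          "r_dev": r_dev, "r_life": r_life}
            tab = fit.subject_table()
            tab["sex"], tab["cluster"] = sex, int(cl)
            tables.append(tab)
        if tables:
            subject_params = pd.concat(tables, ignore_index=True)
            subject_params.to_csv(outdir / "growth_subject_params.tsv", sep="\t", index=False)
            outputs["growth_subject_params"] = str(outdir / "growth_subject_params.tsv")
        (outdir / "growth_fits.json").write_text(json.dumps(growth_json, indent=1))
        outputs["growth_fits"] = str(outdir / "growth_fits.json")

    if "varcomp" in config.stages:
        if adult is None:
            raise PipelineConfigError("varcomp stage requires the phenotypes stage")
        log.info("stage varcomp")
        traits = {"mean_bw": adult, "mean_bmi": adult, "mean_crl": adult}
        if subject_params is not None:
            sp = subject_params.drop_duplicates("id").set_index("id")
            traits["growth_theta1"] = sp.reset_index().rename(
                columns={"theta1": "growth_theta1"})
        for trait, table in traits.items():
            row = _fit_trait_h2(trait, table, ped, config)
            if row is not None:
                varcomp_rows.append(row)
        if (adult["chronic_obese"].astype(bool).mean() >= 0.02
                and adult["chronic_obese"].astype(bool).nunique() == 2):
            row = _fit_chronic_obesity(adult, ped)
            varcomp_rows.append(row)
        rep = pd.DataFrame(varcomp_rows)
        rep.to_csv(outdir / "heritability.tsv", sep="\t", index=False)
        outputs["heritability"] = str(outdir / "heritability.tsv")

    if "linkage" in config.stages:
        if sim is None:
            raise PipelineConfigError("linkage stage requires simulate mode (oracle IBD)")
        if adult is None:
            raise PipelineConfigError("linkage stage requires the phenotypes stage")
        log.info("stage linkage (oracle IBD, %.0f cM grid)", config.scan_step_cm)
        descent = gene_drop(ped, sim)
        ids = [i for i in adult["id"] if i in descent.records]
        sub = adult.set_index("id").loc[ids]
        y = inverse_normal_transform(
            regress_out_age(sub["mean_bw"].to_numpy(), sub["mean_age"].to_numpy()))
        order, phi_full = kinship_matrix(ped)
        pos = {v: k for k, v in enumerate(order)}
        idx = [pos[i] for i in ids]
        phi = phi_full[np.ix_(idx, idx)]
        X = np.column_stack([np.ones(len(ids)),
                             (sub["sex"] == "M").to_numpy(float)])
        ibd = ibd_from_descent(descent, ids, grid_step=config.scan_step_cm)
        scan = genome_scan(y, X, phi, ibd)
        scan.suggestive, scan.significant = config.suggestive_lod, config.significant_lod
        scan.to_tsv(outdir / "linkage_scan.tsv")
        scan.peaks().to_csv(outdir / "linkage_peaks.tsv", sep="\t", index=False)
        ax = scan.plot()
        ax.figure.savefig(outdir / "linkage_scan.png", dpi=120, bbox_inches="tight")
        outputs["linkage_scan"] = str(outdir / "linkage_scan.tsv")
        outputs["linkage_peaks"] = str(outdir / "linkage_peaks.tsv")
        outputs["linkage_plot"] = str(outdir / "linkage_scan.png")

    if "power" in config.stages:
        if sim is None:
            raise PipelineConfigError("power stage requires simulate mode")
        log.info("stage power (%d reps)", config.power_reps)
        res = power_simulation(sim, h2_total=config.power_h2_total,
                               h2q=config.power_h2q, reps=config.power_reps,
                               seed=config.seed,
                               lod_threshold=config.significant_lod)
        res = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in res.items()}
        (outdir / "power.json").write_text(json.dumps(res, indent=1))
        outputs["power"] = str(outdir / "power.json")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "outputs": outputs,
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    outputs["manifest"] = str(outdir / "manifest.json")
    log.info("done in %.1fs", time.time() - t0)
    return outputs


def _fit_trait_h2(trait: str, table: pd.DataFrame, ped: Pedigree,
                  config: PipelineConfig):
    sub = table.dropna(subset=[trait]).drop_duplicates("id")
    if len(sub) < 30:
        return None
    ids = list(sub["id"])
    y = sub[trait].to_numpy(float)
    if "mean_age" in sub.columns:
        y = regress_out_age(y, sub["mean_age"].to_numpy(float))
    y = inverse_normal_transform(y)
    _, phi = kinship_matrix(ped, ids=ids)
    _, hmat = household_matrix(ped, ids)
    df = pd.DataFrame({"sex": (sub.get("sex", pd.Series("F", index=sub.index)) == "M")
                       .astype(float).to_numpy()}, index=range(len(ids)))
    main = ["sex"]
    if "maternal_diet" in sub.columns:
        df["maternal_diet"] = (sub["maternal_diet"] == "ID").astype(float).to_numpy()
        main.append("maternal_diet")
    design = CovariateDesign.from_dataframe(df, main=main,
                                            interactions=["sex*maternal_diet"]
                                            if len(main) == 2 else [])
    design = screen_covariates(y, design, phi, hmat, alpha=config.alpha)
    full = PolygenicModel(y, design, phi=phi, hmat=hmat).fit()
    # reduced models for the boundary LRTs
    from .varcomp import VarianceComponentModel
    no_g = VarianceComponentModel(y, design, {"household": hmat}).fit()
    no_c = PolygenicModel(y, design, phi=phi).fit()
    return {
        "trait": trait, "n": len(ids),
        "h2": round(full.h2, 4), "se_h2": round(full.se_h2, 4),
        "p_h2": lrt_variance_component(full, no_g),
        "c2": round(full.c2, 4), "se_c2": round(full.se_c2, 4),
        "p_c2": lrt_variance_component(full, no_c),
        "covariates": ",".join(design.names) or "-",
    }


def _fit_chronic_obesity(adult: pd.DataFrame, ped: Pedigree):
    sub = adult.drop_duplicates("id")
    ids = list(sub["id"])
    yb = sub["chronic_obese"].astype(bool).astype(float).to_numpy()
    _, phi = kinship_matrix(ped, ids=ids)
    X = np.column_stack([np.ones(len(ids)), (sub["sex"] == "M").to_numpy(float)])
    fit = LiabilityThresholdModel(yb, X, phi=phi).fit()
    return {"trait": "chronic_obesity", "n": len(ids),
            "h2": round(fit.h2, 4), "se_h2": round(fit.se_h2, 4), "p_h2": fit.p_h2,
            "c2": np.nan, "se_c2": np.nan, "p_c2": np.nan, "covariates": "sex"}
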