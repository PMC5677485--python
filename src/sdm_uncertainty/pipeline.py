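"""End-to-end orchestration of the factorial experiment.

Design: every combination of GCM × covariate hypothesis × collinearity
level × thresholding procedure is one projection configuration (10 × 3 ×
3 × 12 = 1,080 per species at the full design, 28 decision levels); the
performance analysis drops the GCM axis (3 × 3 × 12 = 108 cells, 18
levels).  ``run_all`` executes generate → covariates → fit → project →
performance → attribute → report, writing every table as CSV plus a
manifest with the config hash; a rerun with the same config skips stages
whose outputs already match.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from itertools import product
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import ensemble as ens
from .attribution import (
    deviance_partition_by_species,
    fit_effects_mixed,
    species_influence,
)
from .covariates import COLLINEARITY_LEVELS, HYPOTHESES, CovariateSet
from .metrics import METRICS
from .performance import (
    cv_extrapolation_correlation,
    fit_performance_mixed,
    run_performance_grid,
    summarize_decision_table,
)
from .range_change import rank_frequency, rank_vulnerability, rci
from .synthetic_world import (
    FORECAST,
    HINDCAST,
    WorldConfig,
    generate_climate,
    generate_occurrences,
    perturb_gcm,
)
from .thresholding import PROCEDURES, binary_map, select_all_thresholds

logger = logging.getLogger(__name__)

STAGES = ("generate", "covariates", "fit", "project", "performance", "attribute", "report")


@dataclass(frozen=True)
class RunConfig:
    """Factor levels and world parameters for one experiment."""

    world: WorldConfig = field(default_factory=WorldConfig)
    hypotheses: tuple[str, ...] = HYPOTHESES
    collinearity_levels: tuple[str, ...] = COLLINEARITY_LEVELS
    thresholds: tuple[str, ...] = PROCEDURES
    n_cv_splits: int = 10
    optimize_on: str = "train"
    rci_delta: float = 0.01
    preset: str = "custom"

    def __post_init__(self) -> None:
        for name in ("hypotheses", "collinearity_levels", "thresholds"):
            if not getattr(self, name):
                raise ValueError(f"factor list {name} is empty")

    @classmethod
    def toy(cls, seed: int = 0) -> "RunConfig":
        """CI-speed preset: 2 × 2 × 2 × 2 factorial on a small world."""
        return cls(
            world=WorldConfig(n_sites=20, n_years=22, n_species=3, n_gcms=2, seed=seed),
            hypotheses=("temporal", "hydrological"),
            collinearity_levels=("all", "vif10"),
            thresholds=("TSS", "Fixed"),
            n_cv_splits=3,
            preset="toy",
        )

    @classmethod
    def full_factorial(cls, seed: int = 0, n_species: int = 6, n_sites: int = 50) -> "RunConfig":
        """Full 10 × 3 × 3 × 12 factorial (1,080 cells/species, 28 levels)."""
        return cls(
            world=WorldConfig(
                n_sites=n_sites, n_years=39, n_species=n_species, n_gcms=10, seed=seed
            ),
            preset="full",
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, world=replace(self.world, seed=seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["world"].pop("species_response", None)
        return d


def enumerate_design(config: RunConfig) -> tuple[list[tuple[str, str, str, str]], int]:
    """All (gcm, hypothesis, collinearity, threshold) tuples, plus the
    count of decision levels (sum of the four factors' level counts)."""
    gcms = config.world.gcm_names()
    tuples = list(
        product(gcms, config.hypotheses, config.collinearity_levels, config.thresholds)
    )
    n_levels = (
        len(gcms)
        + len(config.hypotheses)
        + len(config.collinearity_levels)
        + len(config.thresholds)
    )
    return tuples, n_levels


def config_hash(config: RunConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, seed: int | None = None, preset: str | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file and/or a named preset."""
    if preset and path:
        raise ValueError("give either a preset or a config file, not both")
    if preset:
        factory = {"toy": RunConfig.toy, "full": RunConfig.full_factorial}[preset]
        cfg = factory(seed=seed if seed is not None else 0)
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    world_kwargs = raw.pop("world", {})
    if "gcm_deltas" in world_kwargs and world_kwargs["gcm_deltas"] is not None:
        world_kwargs["gcm_deltas"] = tuple(tuple(x) for x in world_kwargs["gcm_deltas"])
    if "breeding_months" in world_kwargs:
        world_kwargs["breeding_months"] = tuple(world_kwargs["breeding_months"])
    for key in ("hypotheses", "collinearity_levels", "thresholds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(world=WorldConfig(**world_kwargs), **raw)
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg


# ---------------------------------------------------------------------------
# range-change projection grid

def run_range_change_grid(
    panel: pd.DataFrame,
    occ: pd.DataFrame,
    covsets: dict[tuple[str, str], CovariateSet],
    config: RunConfig,
    models: dict | None = None,
) -> pd.DataFrame:
    """RCI for every (species, gcm, covariate set, threshold) combination.

    Ensembles are trained on all observed years; thresholds are selected
    on the training predictions; each pseudo-GCM contributes a hindcast
    and forecast site-level prediction whose thresholded ranges give RCI.
    Configurations with an empty hindcast range are skipped with a log
    entry.
    """
    world = config.world
    years = sorted(occ["year"].unique())
    full_split = ens.SplitPlan("full", tuple(int(y) for y in years), ())
    gcms = world.gcm_names()

    # scenario covariates depend only on (hypothesis, scenario, member);
    # projection years are systematically thinned to at most ~16 per scenario
    # before the per-site probability averaging
    stride = max(1, world.n_years // 16)
    scen_cache: dict[tuple[str, str, str], pd.DataFrame] = {}
    for hyp in config.hypotheses:
        kwargs = (
            {
                "capacity": world.bucket_capacity_mm,
                "reference_stats": covsets[(hyp, config.collinearity_levels[0])].standardization,
            }
            if hyp == "hydrological"
            else {"breeding_months": world.breeding_months}
            if hyp == "temporal"
            else {}
        )
        for scenario in (HINDCAST, FORECAST):
            for member in gcms:
                full = cov.derive(hyp, panel, scenario=scenario, member=member, **kwargs)
                mat = full.matrix
                keep = np.sort(mat.index.get_level_values("year").unique())[::stride]
                scen_cache[(hyp, scenario, member)] = mat[
                    mat.index.get_level_values("year").isin(keep)
                ]

    rows: list[dict] = []
    species_list = sorted(occ["species"].unique())
    for species in species_list:
        for key, covset in covsets.items():
            hyp, level = key
            if models is not None and (species, key) in models:
                model = models[(species, key)]
            else:
                model = ens.fit_ensemble(occ, species, covset, full_split, seed=world.seed)
            X_tr, y_tr = ens.training_frame(occ, species, covset, years)
            p_tr = ens.predict_ensemble(model, X_tr)
            specs = select_all_thresholds(p_tr, y_tr, config.thresholds)
            for member in gcms:
                # probability of occurrence per site = mean of the per-year
                # predictions (thresholded afterwards, once per procedure)
                mh = scen_cache[(hyp, HINDCAST, member)]
                mf = scen_cache[(hyp, FORECAST, member)]
                ph = (
                    pd.Series(
                        ens.predict_ensemble(model, mh),
                        index=mh.index.get_level_values("site"),
                    )
                    .groupby(level=0)
                    .mean()
                    .to_numpy()
                )
                pf = (
                    pd.Series(
                        ens.predict_ensemble(model, mf),
                        index=mf.index.get_level_values("site"),
                    )
                    .groupby(level=0)
                    .mean()
                    .to_numpy()
                )
                for proc in config.thresholds:
                    hmap = binary_map(ph, specs[proc])
                    fmap = binary_map(pf, specs[proc])
                    hr, fr = int(hmap.sum()), int(fmap.sum())
                    if hr == 0:
                        logger.warning(
                            "empty hindcast range (%s, %s, %s/%s, %s); record skipped",
                            species, member, hyp, level, proc,
                        )
                        continue
                    rows.append(
                        {
                            "species": species,
                            "gcm": member,
                            "hypothesis": hyp,
                            "collinearity": level,
                            "threshold": proc,
                            "hindcast_range": hr,
                            "forecast_range": fr,
                            "rci": rci(hmap, fmap),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# staged runner

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


class Runner:
    """Stage-by-stage executor with config-hash resumability."""

    def __init__(self, config: RunConfig, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash(config)
        self._manifest_path = self.outdir / "manifest.json"
        self.manifest = self._load_manifest()
        self._cache: dict[str, object] = {}

    def _load_manifest(self) -> dict:
        if self._manifest_path.exists():
            m = json.loads(self._manifest_path.read_text())
            if m.get("config_hash") == self.hash:
                return m
        return {"config_hash": self.hash, "seed": self.config.world.seed, "stages": {}}

    def _save_manifest(self) -> None:
        self._manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    def _stage_done(self, stage: str) -> bool:
        files = self.manifest["stages"].get(stage, {}).get("files", [])
        return bool(files) and all((self.outdir / f).exists() for f in files)

    def _record(self, stage: str, files: list[str]) -> None:
        digests = {}
        for f in files:
            digests[f] = hashlib.sha256((self.outdir / f).read_bytes()).hexdigest()[:16]
        self.manifest["stages"][stage] = {"files": files, "sha256": digests}
        self._save_manifest()

    # -- stages -----------------------------------------------------------
    def generate(self):
        if "panel" not in self._cache:
            # generation is cheap and deterministic: always rebuild in memory,
            # skip only the disk writes on resume
            obs = generate_climate(self.config.world)
            panel = perturb_gcm(obs, self.config.world)
            occ = generate_occurrences(obs, self.config.world)
            if not self._stage_done("generate"):
                _write_csv(panel, self.outdir / "climate.csv")
                _write_csv(occ.panel, self.outdir / "occurrence.csv")
                _write_csv(occ.truth, self.outdir / "species_truth.csv")
                self._record("generate", ["climate.csv", "occurrence.csv", "species_truth.csv"])
            self._cache["panel"], self._cache["occ"] = panel, occ
        return self._cache["panel"], self._cache["occ"]

    def covariates(self):
        if "covsets" not in self._cache:
            panel, _ = self.generate()
            grid = cov.build_covariate_grid(
                panel,
                self.config.world,
                hypotheses=self.config.hypotheses,
                levels=self.config.collinearity_levels,
            )
            if not self._stage_done("covariates"):
                files = []
                for (hyp, level), cs in grid.items():
                    stem = f"covariates_{hyp}_{level}"
                    cs.matrix.reset_index().to_csv(self.outdir / f"{stem}.csv", index=False)
                    (self.outdir / f"{stem}.json").write_text(
                        json.dumps(
                            {
                                "hypothesis": hyp,
                                "collinearity_level": level,
                                "vif_report": {
                                    k: (None if np.isinf(v) else v)
                                    for k, v in cs.vif_report.items()
                                },
                                "removal_log": cs.removal_log,
                            },
                            indent=2,
                        )
                    )
                    files += [f"{stem}.csv", f"{stem}.json"]
                self._record("covariates", files)
            self._cache["covsets"] = grid
        return self._cache["covsets"]

    def fit(self):
        """Fit the per-(species, covariate set) full-data ensembles."""
        if "models" not in self._cache:
            _, occ = self.generate()
            covsets = self.covariates()
            path = self.outdir / "models.joblib"
            if self._stage_done("fit") and path.exists():
                self._cache["models"] = joblib.load(path)
            else:
                years = sorted(occ.panel["year"].unique())
                split = ens.SplitPlan("full", tuple(int(y) for y in years), ())
                models = {}
                for species in sorted(occ.panel["species"].unique()):
                    for key, cs in covsets.items():
                        models[(species, key)] = ens.fit_ensemble(
                            occ.panel, species, cs, split, seed=self.config.world.seed
                        )
                joblib.dump(models, path)
                (self.outdir / "models.json").write_text(
                    json.dumps(
                        {f"{sp}|{k[0]}|{k[1]}": m.describe() for (sp, k), m in models.items()},
                        indent=2,
                    )
                )
                self._record("fit", ["models.json"])
                self._cache["models"] = models
        return self._cache["models"]

    def project(self) -> pd.DataFrame:
        if "rci" not in self._cache:
            if self._stage_done("project"):
                self._cache["rci"] = pd.read_csv(self.outdir / "rci.csv")
            else:
                panel, occ = self.generate()
                covsets = self.covariates()
                models = self.fit()
                records = run_range_change_grid(
                    panel, occ.panel, covsets, self.config, models=models
                )
                _write_csv(records, self.outdir / "rci.csv")
                self._record("project", ["rci.csv"])
                self._cache["rci"] = records
        return self._cache["rci"]

    def performance(self) -> pd.DataFrame:
        if "performance" not in self._cache:
            if self._stage_done("performance"):
                self._cache["performance"] = pd.read_csv(self.outdir / "performance.csv")
            else:
                _, occ = self.generate()
                covsets = self.covariates()
                extrap = ens.make_extrapolation_split(occ.panel)
                cv = ens.make_cv_splits(
                    occ.panel, n_splits=self.config.n_cv_splits, seed=self.config.world.seed
                )
                records = run_performance_grid(
                    occ.panel,
                    covsets,
                    extrap,
                    cv,
                    seed=self.config.world.seed,
                    procedures=self.config.thresholds,
                    optimize_on=self.config.optimize_on,
                )
                _write_csv(records, self.outdir / "performance.csv")
                self._record("performance", ["performance.csv"])
                self._cache["performance"] = records
        return self._cache["performance"]

    def attribute(self):
        if "attribution" not in self._cache:
            records = self.project()
            attribution = deviance_partition_by_species(
                records, delta=self.config.rci_delta, on_incomplete="skip"
            )
            effects, info = fit_effects_mixed(records, delta=self.config.rci_delta)
            _write_csv(attribution, self.outdir / "attribution.csv")
            _write_csv(effects, self.outdir / "rci_effects.csv")
            self._record("attribute", ["attribution.csv", "rci_effects.csv"])
            self._cache["attribution"] = (attribution, effects, info)
        return self._cache["attribution"]

    def report(self) -> dict:
        records = self.project()
        perf = self.performance()
        attribution, rci_effects, _ = self.attribute()
        ranks = rank_vulnerability(records, on_missing="drop")
        freq = rank_frequency(ranks)
        corr = pd.DataFrame(
            [vars(cv_extrapolation_correlation(perf, m)) for m in METRICS]
        )
        tss_eff = fit_performance_mixed(perf, "tss")
        prev_eff = fit_performance_mixed(perf, "prevalence_match")
        decisions = summarize_decision_table(rci_effects, tss_eff, prev_eff)
        if records["species"].nunique() >= 3:
            influence = species_influence(records, delta=self.config.rci_delta)
        else:
            influence = pd.DataFrame(
                columns=["species", "max_abs_coefficient_change", "n_bin_changes"]
            )
        freq.reset_index().to_csv(self.outdir / "rank_frequency.csv", index=False)
        _write_csv(corr, self.outdir / "cv_extrapolation_correlation.csv")
        _write_csv(tss_eff, self.outdir / "performance_effects_tss.csv")
        _write_csv(prev_eff, self.outdir / "performance_effects_prevalence.csv")
        _write_csv(decisions, self.outdir / "decision_table.csv")
        _write_csv(influence, self.outdir / "species_influence.csv")
        self._record(
            "report",
            [
                "rank_frequency.csv",
                "cv_extrapolation_correlation.csv",
                "performance_effects_tss.csv",
                "performance_effects_prevalence.csv",
                "decision_table.csv",
                "species_influence.csv",
            ],
        )
        return {
            "attribution": attribution,
            "rci_effects": rci_effects,
            "rank_frequency": freq,
            "correlation": corr,
            "decision_table": decisions,
            "species_influence": influence,
        }


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage; returns the artifact directory."""
    runner = Runner(config, outdir)
    for stage in STAGES:
        try:
            getattr(runner, stage)()
        except Exception as exc:
            partial = runner.manifest
            partial["failed_stage"] = stage
            runner._save_manifest()
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return runner.outdir
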