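"""End-to-end analysis pipeline.

Orchestrates the full chain: synthetic-study generation (optional) ->
perceptual-noise fit -> per-observer MLDS fits -> population-model fits
-> TCC variant fits -> AIC comparison -> correlation / attenuation
report.  Each stage reads and writes plain CSV/JSON in an output
directory and is cached by a hash of its configuration and inputs, so
re-running with an identical config is a no-op and always reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import neural_resource as nr
from . import stats as st
from . import tcc
from .feature_space import FEATURE_SPACES, circ_diff, to_analysis_space
from .scaling import (build_similarity_function, filter_quad_trials, fit_mlds,
                      fit_perceptual_noise_sd)
from .synthetic import StudyConfig, generate_study

log = logging.getLogger("simrecall")

__all__ = ["PipelineConfig", "run_all", "add_analysis_errors"]

TASK_FILES = {"quad": "quad.csv", "wm": "wm.csv",
              "perceptual": "perceptual.csv", "latents": "latents.csv"}


def add_analysis_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``error`` column (analysis radians) to a report-task table."""
    out = trials.copy()
    errors = np.empty(len(out))
    for feat, g in out.groupby("feature"):
        space = FEATURE_SPACES[feat]
        errors[out.index.get_indexer(g.index)] = circ_diff(
            to_analysis_space(g["response_deg"].to_numpy(), space),
            to_analysis_space(g["target_deg"].to_numpy(), space))
    out["error"] = errors
    return out


class PipelineConfig:
    """Structured configuration (YAML) for the pipeline.

    Two sections: ``study`` mirrors :class:`simrecall.synthetic.StudyConfig`
    and ``fit`` holds fitter settings (Monte-Carlo samples, quadrature
    nodes, bootstrap replicates).
    """

    def __init__(self, study: dict | None = None, fit: dict | None = None):
        self.study = dict(study or {})
        self.fit = {
            "nr_mc_samples": 5000,
            "nr_final_mc_samples": 20_000,
            "nr_gamma_grid": None,   # [lo, hi, n] geometric, or None for default
            "nr_kappa_grid": None,
            "tcc_quad_nodes": tcc.QUAD_NODES_FIT,
            "tcc_shape_stride": 1,   # subsample the printed shape grids
            "replicates": 100,
            "seed": 0,
        }
        self.fit.update(fit or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw.get("study"), raw.get("fit"))

    def study_config(self) -> StudyConfig:
        return StudyConfig(**self.study)

    def digest(self, *parts) -> str:
        payload = json.dumps([self.study, self.fit, *map(str, parts)],
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cached(outdir: Path, name: str, key: str):
    """Return the cached file path if its stored hash matches ``key``."""
    target = outdir / name
    hash_file = outdir / f"{name}.hash"
    if target.exists() and hash_file.exists() and hash_file.read_text() == key:
        log.info("stage %s: cached", name)
        return target
    return None


def _store(outdir: Path, name: str, key: str) -> None:
    (outdir / f"{name}.hash").write_text(key)


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    key = config.digest("simulate")
    paths = {k: outdir / v for k, v in TASK_FILES.items()}
    if all(_cached(outdir, v, key) for v in TASK_FILES.values()):
        return paths
    tables = generate_study(config.study_config())
    for k, path in paths.items():
        tables[k].to_csv(path, index=False)
        _store(outdir, TASK_FILES[k], key)
    log.info("simulated study: %s", {k: len(v) for k, v in tables.items()})
    return paths


def stage_fit_perceptual(config: PipelineConfig, outdir: Path) -> Path:
    out, key = outdir / "perceptual_sd.json", config.digest("perceptual")
    if _cached(outdir, out.name, key):
        return out
    trials = add_analysis_errors(
        pd.read_csv(outdir / TASK_FILES["perceptual"]))
    trials = trials[trials["practice"] == 0]
    result = {}
    for feat, g in trials.groupby("feature"):
        fit = fit_perceptual_noise_sd(g["error"].to_numpy())
        result[feat] = asdict(fit)
        log.info("perceptual %s: sd=%.4f (n=%d)", feat, fit.sd, fit.n_used)
    out.write_text(json.dumps(result, indent=2))
    _store(outdir, out.name, key)
    return out


def _perceptual_sds(outdir: Path) -> dict[str, float]:
    raw = json.loads((outdir / "perceptual_sd.json").read_text())
    return {feat: rec["sd"] for feat, rec in raw.items()}


def stage_fit_mlds(config: PipelineConfig, outdir: Path) -> Path:
    out, key = outdir / "mlds_fits.csv", config.digest("mlds")
    if _cached(outdir, out.name, key):
        return out
    quad = pd.read_csv(outdir / TASK_FILES["quad"])
    sds = _perceptual_sds(outdir)
    rows = []
    for (oid, feat), g in quad.groupby(["observer_id", "feature"]):
        fit = fit_mlds(g, sds[feat])
        rows.append({"observer_id": oid, "feature": feat, "tau": fit.tau,
                     "sigma": fit.sigma, "loglik": fit.log_likelihood,
                     "n_trials": fit.n_trials, "converged": fit.converged})
    pd.DataFrame(rows).to_csv(out, index=False)
    _store(outdir, out.name, key)
    return out


def _wm_errors(outdir: Path) -> pd.DataFrame:
    wm = add_analysis_errors(pd.read_csv(outdir / TASK_FILES["wm"]))
    return wm[wm["practice"] == 0]


def stage_fit_nr(config: PipelineConfig, outdir: Path) -> Path:
    out, key = outdir / "nr_fits.csv", config.digest("nr")
    if _cached(outdir, out.name, key):
        return out
    wm = _wm_errors(outdir)
    fc = config.fit
    grids = {}
    for key, name in (("nr_gamma_grid", "gamma_grid"),
                      ("nr_kappa_grid", "kappa_grid")):
        if fc.get(key):
            lo, hi, n = fc[key]
            grids[name] = np.geomspace(lo, hi, int(n))
    rows = []
    for (oid, feat), g in wm.groupby(["observer_id", "feature"]):
        fit = nr.fit_neural_resource(
            g, mc_samples=fc["nr_mc_samples"],
            final_mc_samples=fc["nr_final_mc_samples"],
            seed=fc["seed"] + 12345, **grids)
        if not fit.converged:
            log.warning("NR fit %s/%s: convergence flag not set", oid, feat)
        rows.append({"observer_id": oid, "feature": feat, "r_max": fit.r_max,
                     "width": fit.width, "gamma": fit.gamma,
                     "kappa": fit.kappa, "loglik": fit.log_likelihood,
                     "aic": fit.aic, "converged": fit.converged})
    pd.DataFrame(rows).to_csv(out, index=False)
    _store(outdir, out.name, key)
    return out


def stage_fit_tcc(config: PipelineConfig, outdir: Path, variant: str) -> Path:
    out = outdir / f"tcc_fits_{variant}.csv"
    key = config.digest("tcc", variant)
    if _cached(outdir, out.name, key):
        return out
    wm = _wm_errors(outdir)
    nodes = config.fit["tcc_quad_nodes"]
    stride = max(int(config.fit.get("tcc_shape_stride", 1)), 1)
    exp_grid = tcc.EXPONENT_GRID[::stride]
    vm_grid = tcc.VM_SD_GRID[::stride]
    sds = _perceptual_sds(outdir)
    mlds = None
    if variant == "empirical":
        mlds_path = outdir / "mlds_fits.csv"
        if not mlds_path.exists():
            raise FileNotFoundError(
                "empirical TCC needs MLDS fits (quad task missing?)")
        mlds = pd.read_csv(mlds_path).set_index(["observer_id", "feature"])
    rows = []
    for (oid, feat), g in wm.groupby(["observer_id", "feature"]):
        if variant == "empirical":
            try:
                tau = mlds.loc[(oid, feat), "tau"]
            except KeyError:
                log.warning("no MLDS fit for %s/%s; observer skipped", oid, feat)
                continue
            omega = build_similarity_function(float(tau), sds[feat])
            fit = tcc.fit_empirical_tcc(g, omega, quad_nodes=nodes)
        elif variant == "synthetic":
            fit = tcc.fit_synthetic_tcc(g, sds[feat], quad_nodes=nodes,
                                        exponent_grid=exp_grid)
        elif variant == "vonmises":
            fit = tcc.fit_vonmises_tcc(g, quad_nodes=nodes, sd_grid=vm_grid)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        d = fit.params.d_prime_by_setsize
        rows.append({"observer_id": oid, "feature": feat, "variant": variant,
                     "d3": d.get(3, np.nan), "d6": d.get(6, np.nan),
                     "shape_param": fit.params.shape_param,
                     "loglik": fit.log_likelihood, "aic": fit.aic})
    pd.DataFrame(rows).to_csv(out, index=False)
    _store(outdir, out.name, key)
    return out


def stage_compare(config: PipelineConfig, outdir: Path) -> Path:
    """Group mean per-observer AIC differences between model pairs."""
    out, key = outdir / "delta_aic.csv", config.digest("compare")
    if _cached(outdir, out.name, key):
        return out
    tables = {"nr": pd.read_csv(outdir / "nr_fits.csv")}
    for v in ("empirical", "synthetic", "vonmises"):
        path = outdir / f"tcc_fits_{v}.csv"
        if path.exists():
            tables[v] = pd.read_csv(path)
    pairs = [("empirical", "nr"), ("empirical", "synthetic"),
             ("synthetic", "vonmises")]
    rows = []
    for a, b in pairs:
        if a not in tables or b not in tables:
            continue
        merged = tables[a].merge(tables[b], on=["observer_id", "feature"],
                                 suffixes=("_a", "_b"))
        for feat, g in merged.groupby("feature"):
            rows.append({"feature": feat, "model_a": a, "model_b": b,
                         "mean_delta_aic": st.delta_aic(g["aic_a"], g["aic_b"]),
                         "n": len(g)})
    pd.DataFrame(rows).to_csv(out, index=False)
    _store(outdir, out.name, key)
    return out


def _reliability_fits(config, outdir, quad, wm, feat, sds, rng):
    """Bootstrap reliabilities of the empirical and synthetic exponents."""
    replicates = config.fit["replicates"]
    nodes = config.fit["tcc_quad_nodes"]
    stride = max(int(config.fit.get("tcc_shape_stride", 1)), 1)
    quad_by_obs = {oid: g for oid, g in quad.groupby("observer_id")}
    wm_by_obs = {oid: g for oid, g in wm.groupby("observer_id")}
    r_emp = st.bootstrap_reliability(
        quad_by_obs, lambda t: fit_mlds(t, sds[feat]).tau,
        n_replicates=replicates, seed=rng)
    r_syn = st.bootstrap_reliability(
        wm_by_obs,
        lambda t: tcc.fit_synthetic_tcc(
            t, sds[feat], quad_nodes=nodes,
            exponent_grid=tcc.EXPONENT_GRID[::stride]).params.shape_param,
        n_replicates=replicates, seed=rng)
    return r_emp, r_syn


def stage_stats(config: PipelineConfig, outdir: Path) -> Path:
    """Correlation / attenuation report for empirical vs synthetic exponents.

    Observers missing from either task are dropped from the cross-task
    correlations (their single-task fits remain in the fit tables).
    """
    out, key = outdir / "correlations.json", config.digest("stats")
    if _cached(outdir, out.name, key):
        return out
    mlds = pd.read_csv(outdir / "mlds_fits.csv")
    syn = pd.read_csv(outdir / "tcc_fits_synthetic.csv")
    merged = mlds.merge(syn, on=["observer_id", "feature"],
                        suffixes=("_mlds", "_syn"))
    dropped = set(mlds.observer_id) ^ set(syn.observer_id)
    if dropped:
        log.warning("dropped from correlations (missing in one task): %s",
                    sorted(dropped))
    quad = filter_quad_trials(pd.read_csv(outdir / TASK_FILES["quad"]))
    wm = _wm_errors(outdir)
    sds = _perceptual_sds(outdir)
    rng = np.random.default_rng(config.fit["seed"] + 777)
    report: dict[str, dict] = {"per_feature": {}}
    pooled_x, pooled_y = {}, {}
    for feat, g in merged.groupby("feature"):
        x = g["tau"].to_numpy()
        y = g["shape_param"].to_numpy()
        rep = st.pearson_r(x, y)
        entry = {"r": rep.r, "n": rep.n}
        if config.fit["replicates"] > 0:
            r_emp, r_syn = _reliability_fits(
                config, outdir, quad[quad.feature == feat],
                wm[wm.feature == feat], feat, sds, rng)
            corrected = st.corrected_correlation(rep.r, r_emp, r_syn, rep.n)
            entry.update({"reliability_empirical": r_emp,
                          "reliability_synthetic": r_syn,
                          "r_corrected": corrected.r_corrected,
                          "corrected_out_of_range":
                              corrected.corrected_out_of_range})
        report["per_feature"][feat] = entry
        pooled_x[feat], pooled_y[feat] = x, y
    if len(pooled_x) >= 2:
        # standardize within feature with a joint outlier mask, keeping pairs
        bx, by = [], []
        for feat in pooled_x:
            x, y = pooled_x[feat], pooled_y[feat]
            mask = (st.iterative_outlier_mask(x)
                    & st.iterative_outlier_mask(y))
            if mask.sum() >= 3:
                bx.append((x[mask] - x[mask].mean()) / x[mask].std())
                by.append((y[mask] - y[mask].mean()) / y[mask].std())
        rep = st.pearson_r(np.concatenate(bx), np.concatenate(by),
                           remove_outliers=False)
        report["pooled"] = {"r": rep.r, "n": rep.n}
    # sigma vs amplitude: the shared-variability association
    sig = merged
    if len(sig) >= 4:
        for col in ("d3", "d6"):
            rep = st.pearson_r(sig["sigma"].to_numpy(),
                               sig[col].to_numpy())
            report[f"sigma_vs_{col}"] = {"r": rep.r, "n": rep.n}
    out.write_text(json.dumps(report, indent=2))
    _store(outdir, out.name, key)
    return out


def run_all(config: PipelineConfig, outdir: str | Path,
            variants: tuple[str, ...] = ("empirical", "synthetic", "vonmises"),
            simulate: bool = True) -> dict[str, Path]:
    """Run every stage in dependency order; returns the output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Path] = {}
    if simulate:
        results.update(stage_simulate(config, outdir))
    results["perceptual"] = stage_fit_perceptual(config, outdir)
    results["mlds"] = stage_fit_mlds(config, outdir)
    results["nr"] = stage_fit_nr(config, outdir)
    for v in variants:
        results[f"tcc_{v}"] = stage_fit_tcc(config, outdir, v)
    results["compare"] = stage_compare(config, outdir)
    if "synthetic" in variants:
        results["stats"] = stage_stats(config, outdir)
    return results
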