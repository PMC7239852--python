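"""Stage orchestration: FCSS -> pathway statistics -> fitness -> environment.

``run_all`` drives the full analysis from input tables to a report bundle;
randomness (only the bootstrap stage uses any) flows from one run-level
seed.  Stage failures abort with a stage-scoped message but retain the
partial outputs already written.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import env_response, fcss_screen, repro_stats, tables

log = logging.getLogger("aposcape")

__all__ = ["RunConfig", "StageFailure", "run_all"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: Path
    ovules: Path | None = None
    seeds: Path | None = None
    histograms: Path | None = None
    env: Path | None = None
    rng_seed: int = 0
    basis: str = "competing_only"
    maternal_reference_channel: float = 200.0
    bootstrap_replicates: int = 1000
    run_fcss: bool = True
    run_repro: bool = True
    run_env: bool = True
    round_digits: int = 3

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("ovules", "seeds", "histograms", "env"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} table not found: {p}")


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs", name, timings[name])
                raise StageFailure(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, timings[name])

    return _Timer()


def run_all(cfg: RunConfig) -> dict:
    """Execute all enabled stages in order and write the report bundle.

    Writes ``seeds_from_fcss.tsv`` (when histograms are given),
    ``repro_summary.tsv``, ``fit.json`` and ``report.md`` under
    ``cfg.out_dir``.  Returns a dict with the in-memory results.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {"seed": cfg.rng_seed}

    seeds_path = cfg.seeds
    if cfg.run_fcss and cfg.histograms is not None:
        with _stage("fcss", timings):
            long = pd.read_csv(cfg.histograms)
            hists = fcss_screen.histograms_from_long_table(
                long, cfg.maternal_reference_channel
            )
            by_pop: dict[str, list] = {}
            for h in hists:
                pop = h.seed_id.split("-")[0] if "-" in h.seed_id else "all"
                by_pop.setdefault(pop, []).append(fcss_screen.classify_histogram(h))
            counts = [
                fcss_screen.tabulate_population(cls, population_id=pop)
                for pop, cls in sorted(by_pop.items())
            ]
            from .synthetic_data import seeds_to_frame

            seed_df = seeds_to_frame(counts)
            tables.write_table(seed_df, out / "seeds_from_fcss.tsv")
            results["fcss_seed_counts"] = seed_df
            if seeds_path is None:
                seeds_path = out / "seeds_from_fcss.tsv"

    summary = None
    if cfg.run_repro:
        if cfg.ovules is None or seeds_path is None:
            raise StageFailure(
                "repro",
                ValueError("repro stage needs ovule and seed tables (was fcss disabled?)"),
            )
        with _stage("repro", timings):
            report = tables.validate_tables({"ovules": cfg.ovules, "seeds": seeds_path})
            if not report.ok:
                raise ValueError(str(report))
            ovules = tables.read_table(cfg.ovules)
            seeds = tables.read_table(seeds_path)
            summary = repro_stats.summarize_table(ovules, seeds, basis=cfg.basis)
            tables.write_table(summary, out / "repro_summary.tsv")
            results["repro_summary"] = summary

    if cfg.run_env and cfg.env is not None:
        if summary is None:
            raise StageFailure(
                "envmodel",
                ValueError("envmodel needs the repro summary (was the repro stage disabled?)"),
            )
        with _stage("envmodel", timings):
            env = tables.read_table(cfg.env)
            props = summary.rename(
                columns={"obs_seed_sexual": "sexual", "obs_seed_apomictic": "apomictic"}
            )[["population_id", "sexual", "apomictic"]]
            screen = env_response.pearson_screen(env, props, stage="seed")
            merged = env.merge(props, on="population_id")
            fit = env_response.fit_response(merged["mdr"], merged["sexual"])
            boot = env_response.bootstrap_gradient(
                merged["mdr"],
                merged["sexual"],
                fit=fit,
                B=cfg.bootstrap_replicates,
                rng_seed=np.random.default_rng(cfg.rng_seed),
            )
            fit_payload = {
                "params": {
                    "s_lo": fit.s_lo, "s_hi": fit.s_hi, "k": fit.k, "x0": fit.x0,
                },
                "rss": fit.rss,
                "n": fit.n,
                "k_identified": fit.k_identified,
                "bootstrap": {
                    "B": cfg.bootstrap_replicates,
                    "ci_k": list(boot.ci_k),
                    "p_k": boot.p_k,
                },
            }
            (out / "fit.json").write_text(json.dumps(fit_payload, indent=2))
            tables.write_table(screen, out / "covariate_screen.tsv")
            results["screen"] = screen
            results["fit"] = fit

    with _stage("report", timings):
        _write_report(out, results, timings, cfg)
    results["timings"] = timings
    return results


def _fmt(x: float, nd: int) -> str:
    return f"{repro_stats.round_half_up(x, nd):.{nd}f}"


def _write_report(out: Path, results: dict, timings: dict, cfg: RunConfig) -> None:
    lines = ["# Reproductive pathway analysis report", ""]
    lines.append(f"Run seed: {cfg.rng_seed}")
    summary = results.get("repro_summary")
    if summary is not None:
        lines += [
            "",
            "## Pathway proportions and efficiency per population",
            "",
            "| population | exp. sexual | obs. sexual | exp. apo | obs. apo | chi2 | p | eff. sexual | eff. apo |",
            "|---|---|---|---|---|---|---|---|---|",
        ]
        nd = cfg.round_digits
        for r in summary.itertuples():
            lines.append(
                f"| {r.population_id} | {_fmt(r.exp_seed_sexual, nd)} | "
                f"{_fmt(r.obs_seed_sexual, nd)} | {_fmt(r.exp_seed_apomictic, nd)} | "
                f"{_fmt(r.obs_seed_apomictic, nd)} | {_fmt(r.chi2, nd)} | "
                f"{_fmt(r.p_value, nd)} | {_fmt(r.efficiency_sexual, nd)} | "
                f"{_fmt(r.efficiency_apomictic, nd)} |"
            )
    fit = results.get("fit")
    if fit is not None:
        lines += [
            "",
            "## Environmental response (sexual proportion vs MDR)",
            "",
            f"S(x) = {fit.s_lo:.3f} + ({fit.s_hi:.3f} - {fit.s_lo:.3f}) / (1 + exp(-{fit.k:.3f} (x - {fit.x0:.2f})))",
            f"RSS = {fit.rss:.5f} on n = {fit.n} populations",
        ]
        if fit.bootstrap is not None:
            lines.append(
                f"bootstrap 95% CI for k: [{fit.bootstrap.ci_k[0]:.3f}, "
                f"{fit.bootstrap.ci_k[1]:.3f}], p = {fit.bootstrap.p_k:.4f}"
            )
    lines += ["", "## Stage timings (s)", ""]
    for stage, t in timings.items():
        lines.append(f"- {stage}: {t:.2f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
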