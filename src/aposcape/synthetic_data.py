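"""Synthetic data with the statistical structure of a facultative-apomict survey.

Generates every input the pipeline consumes — ovule embryo-sac class counts,
seed-origin counts, single-seed flow-cytometry histograms, environmental
covariate tables and fitness measurements — from an explicit generative
model whose parameters mirror the field-study design:

* three sampled individuals per population, ~17 scored ovules per
  individual, ~75 screened seeds per population;
* ovule classes (MES-only / AES-only / mixed / aborted) drawn from a
  multinomial whose default simplex reproduces mean reproductive potentials
  of roughly 0.49 (sexual) and 0.79 (apomictic) with ~2% aborted ovules;
* within-ovule competition: a mixed ovule yields an apomictic seed with
  probability ``omega`` (0.5 is the independence null; larger values model
  apomixis dominance), and each pathway forms a seed with success
  probability ``sigma``;
* an MDR gradient on which the sexual seed proportion follows a bounded
  logistic with additive Gaussian noise, plus independent decoy covariates;
* FCSS histograms with embryo/endosperm Gaussian peaks at the C-values
  diagnostic of each seed origin, Poisson channel noise and a debris floor;
* spikelet weighings, inflorescence counts and germination trials around
  cytotype-level fecundity/germinability truths.

Every generator is deterministic given ``SimConfig.rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .env_response import bounded_logistic
from .fcss_screen import SeedHistogram
from .repro_stats import OvuleCounts, SeedCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_ovule_seed_tables",
    "gen_env_gradient",
    "gen_fcss_dataset",
    "gen_fitness_dataset",
    "simulate_seed_formation",
    "ovules_to_frame",
    "seeds_to_frame",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generative model (defaults = study conditions)."""

    n_populations: int = 20
    individuals_per_pop: int = 3
    ovules_per_individual: int = 17
    seeds_per_pop: int = 75
    # (p_mes_only, p_aes_only, p_mixed, p_aborted); defaults chosen so the
    # implied mean potentials are ~0.49 sexual and ~0.79 apomictic.
    class_probs: tuple[float, float, float, float] = (0.186, 0.495, 0.299, 0.020)
    multi_aes_prob: float = 0.40
    competition_omega: float = 0.5  # P(mixed ovule resolves apomictic); 0.5 = null
    success_probs: tuple[float, float] = (0.8, 0.8)  # (sigma_sexual, sigma_apomictic)
    response_params: tuple[float, float, float, float] = (0.05, 0.45, 1.2, 12.5)
    mdr_range: tuple[float, float] = (11.0, 15.0)
    noise_sd: float = 0.05
    fcss_cv: float = 0.03
    fcss_particles: int = 5000
    fcss_channels: int = 1024
    maternal_reference_channel: float = 200.0
    # (fecundity, germinability) truth per cytotype
    fitness_truth: tuple[tuple[str, float, float], ...] = (
        ("2x", 0.37, 0.739),
        ("4x", 0.17, 0.791),
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        probs = list(self.class_probs) + [
            self.multi_aes_prob,
            self.competition_omega,
            *self.success_probs,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    class_probs: tuple[float, float, float, float]
    omega: float
    success_probs: tuple[float, float]
    expected_seed_sexual: dict[str, float] = field(default_factory=dict)
    seed_labels: dict[str, str] = field(default_factory=dict)
    response_params: tuple[float, float, float, float] | None = None
    population_mdr: dict[str, float] = field(default_factory=dict)
    fitness: dict[str, tuple[float, float]] = field(default_factory=dict)


def simulate_seed_formation(
    counts: OvuleCounts,
    omega: float,
    success_probs: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw (sexual, apomictic) seed counts from one set of ovule classes.

    MES-only ovules form a sexual seed with probability sigma_sexual;
    AES-only ovules form an apomictic seed with sigma_apomictic; a mixed
    ovule resolves apomictically with probability omega * sigma_apomictic,
    otherwise sexually with (1 - omega) * sigma_sexual.  Aborted ovules
    yield nothing.
    """
    sig_s, sig_a = success_probs
    n_sex = rng.binomial(counts.n_mes_only, sig_s)
    n_apo = rng.binomial(counts.n_aes_only, sig_a)
    # each mixed ovule: apomictic seed w.p. omega*sig_a, sexual seed w.p.
    # (1-omega)*sig_s, otherwise no seed
    p_apo = omega * sig_a
    p_sex = (1.0 - omega) * sig_s
    mixed_apo, mixed_sex, _ = rng.multinomial(
        counts.n_mixed, [p_apo, p_sex, 1.0 - p_apo - p_sex]
    )
    return int(n_sex + mixed_sex), int(n_apo + mixed_apo)


def gen_ovule_seed_tables(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[OvuleCounts], list[SeedCounts], SimTruth]:
    """Per-individual ovule class counts and per-population seed counts."""
    rng = cfg.rng() if rng is None else rng
    truth = SimTruth(
        class_probs=cfg.class_probs, omega=cfg.competition_omega,
        success_probs=cfg.success_probs,
    )
    ovules: list[OvuleCounts] = []
    seeds: list[SeedCounts] = []
    for p in range(cfg.n_populations):
        pop = f"P{p:03d}"
        pop_sex = pop_apo = 0
        pop_mes = pop_aes = pop_mixed = pop_total = 0
        for i in range(cfg.individuals_per_pop):
            mes, aes, mixed, aborted = rng.multinomial(
                cfg.ovules_per_individual, cfg.class_probs
            )
            multi = rng.binomial(aes + mixed, cfg.multi_aes_prob)
            oc = OvuleCounts(
                population_id=pop,
                individual_id=f"{pop}-i{i}",
                n_mes_only=int(mes),
                n_aes_only=int(aes),
                n_mixed=int(mixed),
                n_multi_aes=int(multi),
                n_aborted=int(aborted),
            )
            ovules.append(oc)
            ns, na = simulate_seed_formation(
                oc, cfg.competition_omega, cfg.success_probs, rng
            )
            pop_sex += ns
            pop_apo += na
            pop_mes += mes
            pop_aes += aes
            pop_mixed += mixed
            pop_total += cfg.ovules_per_individual
        formed = pop_sex + pop_apo
        if formed > cfg.seeds_per_pop:
            # subsample without replacement to the screening depth
            kept_sex = int(rng.hypergeometric(pop_sex, pop_apo, cfg.seeds_per_pop))
            kept_apo = cfg.seeds_per_pop - kept_sex
        else:
            kept_sex, kept_apo = pop_sex, pop_apo
        seeds.append(
            SeedCounts(population_id=pop, n_sexual=kept_sex, n_apomictic=kept_apo)
        )
        if pop_mes + pop_aes + pop_mixed > 0:
            truth.expected_seed_sexual[pop] = (pop_mes + 0.5 * pop_mixed) / pop_total
    return ovules, seeds, truth


def gen_env_gradient(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """MDR gradient, decoy covariates and noisy logistic sexual proportions.

    Returns (env table, proportions table, truth).  Proportions are clipped
    to (0.001, 0.999) so the inverse-link GLM stays defined.
    """
    rng = cfg.rng() if rng is None else rng
    pops = [f"P{p:03d}" for p in range(cfg.n_populations)]
    mdr = rng.uniform(*cfg.mdr_range, size=cfg.n_populations)
    s = bounded_logistic(mdr, *cfg.response_params)
    s = np.clip(s + rng.normal(0.0, cfg.noise_sd, cfg.n_populations), 0.001, 0.999)
    env = pd.DataFrame(
        {
            "population_id": pops,
            "mdr": mdr,
            # independent decoys with bioclim-like scales
            "annual_mean_temp": rng.normal(21.0, 2.0, cfg.n_populations),
            "temp_seasonality": rng.normal(350.0, 60.0, cfg.n_populations),
            "precip_driest_quarter": rng.normal(120.0, 40.0, cfg.n_populations),
            "precip_coldest_quarter": rng.normal(150.0, 50.0, cfg.n_populations),
            "uvb_radiation": rng.normal(4500.0, 500.0, cfg.n_populations),
            "cloud_cover": rng.normal(55.0, 8.0, cfg.n_populations),
        }
    )
    props = pd.DataFrame(
        {"population_id": pops, "sexual": s, "apomictic": 1.0 - s}
    )
    truth = SimTruth(
        class_probs=cfg.class_probs,
        omega=cfg.competition_omega,
        success_probs=cfg.success_probs,
        response_params=cfg.response_params,
        population_mdr=dict(zip(pops, mdr)),
    )
    return env, props, truth


_LABEL_C_VALUES = {"sexual": (2.0, 3.0), "apomictic": (2.0, 5.0), "biii": (3.0, 5.0)}


def gen_fcss_dataset(
    cfg: SimConfig,
    labels: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[list[SeedHistogram], SimTruth]:
    """Single-seed histograms with embryo + endosperm Gaussian peaks.

    Embryo/endosperm C-value pairs per label: sexual (2C, 3C), apomictic
    (2C, 5C), BIII (3C, 5C).  Peak positions scale with the maternal 2C
    reference channel; per-channel counts get Poisson noise and a 1% uniform
    debris floor.
    """
    rng = cfg.rng() if rng is None else rng
    bad = set(labels) - set(_LABEL_C_VALUES)
    if bad:
        raise ValueError(f"unknown seed labels: {sorted(bad)}")
    hists = []
    truth = SimTruth(
        class_probs=cfg.class_probs, omega=cfg.competition_omega,
        success_probs=cfg.success_probs,
    )
    grid = np.arange(cfg.fcss_channels, dtype=float)
    for j, label in enumerate(labels):
        seed_id = f"seed{j:04d}"
        c_emb, c_end = _LABEL_C_VALUES[label]
        n_emb = int(round(cfg.fcss_particles * 0.55))
        n_end = int(round(cfg.fcss_particles * 0.44))
        n_debris = cfg.fcss_particles - n_emb - n_end
        expected = np.zeros(cfg.fcss_channels)
        for c, n in ((c_emb, n_emb), (c_end, n_end)):
            mu = c / 2.0 * cfg.maternal_reference_channel
            sd = cfg.fcss_cv * mu
            expected += n * np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        expected[30:400] += max(n_debris, 0) / 370.0
        channels = rng.poisson(expected).astype(float)
        hists.append(
            SeedHistogram(
                seed_id=seed_id,
                channels=channels,
                maternal_reference_channel=cfg.maternal_reference_channel,
            )
        )
        truth.seed_labels[seed_id] = label
    return hists, truth


def gen_fitness_dataset(
    cfg: SimConfig,
    individuals_per_cytotype: int = 12,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Spikelet weighings, germination trials and inflorescence counts.

    Full/empty spikelet counts are binomial around the cytotype fecundity
    truth; hundred-spikelet weights are lognormal around per-spikelet
    masses (full spikelets heavier than empty ones); germination is
    binomial around the germinability truth.  Returns
    (weighings, germination, inflorescences, truth).
    """
    rng = cfg.rng() if rng is None else rng
    truth = SimTruth(
        class_probs=cfg.class_probs, omega=cfg.competition_omega,
        success_probs=cfg.success_probs,
        fitness={c: (f, g) for c, f, g in cfg.fitness_truth},
    )
    w_rows, g_rows, i_rows = [], [], []
    mass = {"full": 0.0025, "empty": 0.0008}  # grams per spikelet
    for cytotype, fec, germ in cfg.fitness_truth:
        for i in range(individuals_per_cytotype):
            ind = f"{cytotype}-ind{i:02d}"
            n_infl = int(rng.poisson(32) + 1)
            i_rows.append(
                {
                    "individual_id": ind,
                    "cytotype": cytotype,
                    "n_inflorescences": n_infl,
                }
            )
            for b in range(3):  # three bagged inflorescences per individual
                infl = f"{ind}-b{b}"
                n_spik = int(rng.lognormal(math.log(4500.0), 0.15))
                n_full = int(rng.binomial(n_spik, fec))
                n_empty = n_spik - n_full
                for group, count in (("full", n_full), ("empty", n_empty)):
                    if count == 0:
                        continue
                    m = mass[group]
                    hundred = tuple(100.0 * m * rng.lognormal(0.0, 0.03) for _ in range(3))
                    w_rows.append(
                        {
                            "individual_id": ind,
                            "inflorescence_id": infl,
                            "group": group,
                            "w100_a": hundred[0],
                            "w100_b": hundred[1],
                            "w100_c": hundred[2],
                            "total_weight": count * m,
                        }
                    )
            n_sown = 30
            g_rows.append(
                {
                    "individual_id": ind,
                    "n_sown": n_sown,
                    "n_germinated": int(rng.binomial(n_sown, germ)),
                    "horizon_days": 60,
                }
            )
    return (
        pd.DataFrame(w_rows),
        pd.DataFrame(g_rows),
        pd.DataFrame(i_rows),
        truth,
    )


def ovules_to_frame(ovules: Sequence[OvuleCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population_id": [o.population_id for o in ovules],
            "individual_id": [o.individual_id or "" for o in ovules],
            "season": [o.season for o in ovules],
            "n_mes_only": [o.n_mes_only for o in ovules],
            "n_aes_only": [o.n_aes_only for o in ovules],
            "n_mixed": [o.n_mixed for o in ovules],
            "n_multi_aes": [o.n_multi_aes for o in ovules],
            "n_aborted": [o.n_aborted for o in ovules],
        }
    )


def seeds_to_frame(seeds: Sequence[SeedCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population_id": [s.population_id for s in seeds],
            "individual_id": [s.individual_id or "" for s in seeds],
            "season": [s.season for s in seeds],
            "n_sexual": [s.n_sexual for s in seeds],
            "n_apomictic": [s.n_apomictic for s in seeds],
            "n_biii": [s.n_biii for s in seeds],
            "n_unclassified": [s.n_unclassified for s in seeds],
        }
    )
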