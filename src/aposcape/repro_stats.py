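"""Reproductive-pathway statistics for facultative apomicts.

In a facultative aposporous plant every ovule can initiate a meiotic
(sexual) embryo sac (MES), an aposporous (apomictic) embryo sac (AES), both,
or abort.  This module quantifies, per population:

* **reproductive potentials** — the fraction of ovules carrying each
  pathway's embryo sac (mixed ovules count for both, so potentials may sum
  to more than 1);
* **observed proportions** at ovule or seed stage;
* **expected seed proportions** under the independence null (each embryo
  sac develops independently and has the same probability of forming a
  seed, so a mixed ovule is credited half to each pathway);
* **pathway efficiencies** — observed over expected seed proportions:
  values above 1 mean a pathway over-performs its ovule-stage
  representation;
* stage, season and goodness-of-fit tests around those quantities.

Counts are carried in small frozen dataclasses (:class:`OvuleCounts`,
:class:`SeedCounts`) that validate their invariants on construction, and
population summaries aggregate pooled counts across individuals by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OvuleCounts",
    "SeedCounts",
    "ReproSummary",
    "StageComparison",
    "NoClassifiableError",
    "observed_proportions",
    "reproductive_potentials",
    "expected_seed_proportions",
    "pathway_efficiency",
    "chi2_goodness_of_fit",
    "exact_goodness_of_fit_p",
    "stage_shift_test",
    "parameter_correlations",
    "season_compare",
    "pool_counts",
    "summarize_population",
    "summarize_table",
    "round_half_up",
]

Basis = Literal["competing_only", "shared_credit"]


class NoClassifiableError(ValueError):
    """Raised when no classifiable ovules or seeds are available."""


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, mirroring printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# count containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OvuleCounts:
    """Ovule embryo-sac class counts for one individual or population.

    ``n_mes_only`` / ``n_aes_only`` are ovules carrying only meiotic /
    only aposporous sacs, ``n_mixed`` carries both, ``n_multi_aes`` is the
    subset of AES-bearing ovules with two or more AES, and ``n_aborted``
    covers aborted or absent embryo sacs.
    """

    population_id: str
    n_mes_only: int
    n_aes_only: int
    n_mixed: int
    n_multi_aes: int = 0
    n_aborted: int = 0
    individual_id: str | None = None
    season: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("n_mes_only", "n_aes_only", "n_mixed", "n_multi_aes", "n_aborted"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.n_multi_aes > self.n_aes_only + self.n_mixed:
            raise ValueError(
                "n_multi_aes cannot exceed the number of AES-bearing ovules "
                f"({self.n_multi_aes} > {self.n_aes_only + self.n_mixed})"
            )
        if self.n_total < 1:
            raise ValueError("at least one ovule is required")

    # naming: *_only counts exclude mixed ovules, *_any include them.
    @property
    def nm_only(self) -> int:
        return self.n_mes_only

    @property
    def na_only(self) -> int:
        return self.n_aes_only

    @property
    def nm_any(self) -> int:
        return self.n_mes_only + self.n_mixed

    @property
    def na_any(self) -> int:
        return self.n_aes_only + self.n_mixed

    @property
    def n_total(self) -> int:
        return self.n_mes_only + self.n_aes_only + self.n_mixed + self.n_aborted


@dataclass(frozen=True)
class SeedCounts:
    """Seed reproductive-origin counts for one individual or population."""

    population_id: str
    n_sexual: int
    n_apomictic: int
    n_biii: int = 0
    n_unclassified: int = 0
    individual_id: str | None = None
    season: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("n_sexual", "n_apomictic", "n_biii", "n_unclassified"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")

    @property
    def n_classified(self) -> int:
        """Seeds entering the sexual-vs-apomictic analysis denominator."""
        return self.n_sexual + self.n_apomictic


@dataclass(frozen=True)
class StageComparison:
    """Result of a two-list comparison (paired/Welch t or chi-squared)."""

    statistic: float
    df: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class ReproSummary:
    """All pathway statistics for one population (sexual, apomictic pairs)."""

    population_id: str
    potentials: tuple[float, float]
    obs_ovule_props: tuple[float, float]
    obs_seed_props: tuple[float, float]
    exp_seed_props: tuple[float, float]
    efficiency: tuple[float, float]
    chi2: float
    p_value: float
    n_ovules: int
    n_seeds: int


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def pool_counts(counts: Sequence[OvuleCounts] | Sequence[SeedCounts]):
    """Sum per-individual counts into one population-level record.

    Population statistics default to pooled counts rather than means of
    individual proportions, because per-population samples are small
    (typically three individuals).
    """
    if not counts:
        raise ValueError("nothing to pool")
    first = counts[0]
    pops = {c.population_id for c in counts}
    pop = counts[0].population_id if len(pops) == 1 else "+".join(sorted(pops))
    if isinstance(first, OvuleCounts):
        return OvuleCounts(
            population_id=pop,
            n_mes_only=sum(c.n_mes_only for c in counts),
            n_aes_only=sum(c.n_aes_only for c in counts),
            n_mixed=sum(c.n_mixed for c in counts),
            n_multi_aes=sum(c.n_multi_aes for c in counts),
            n_aborted=sum(c.n_aborted for c in counts),
            season=first.season if len({c.season for c in counts}) == 1 else "unknown",
        )
    return SeedCounts(
        population_id=pop,
        n_sexual=sum(c.n_sexual for c in counts),
        n_apomictic=sum(c.n_apomictic for c in counts),
        n_biii=sum(c.n_biii for c in counts),
        n_unclassified=sum(c.n_unclassified for c in counts),
        season=first.season if len({c.season for c in counts}) == 1 else "unknown",
    )


# ---------------------------------------------------------------------------
# proportions, potentials, efficiency
# ---------------------------------------------------------------------------


def observed_proportions(
    counts: OvuleCounts | SeedCounts, basis: Basis = "competing_only"
) -> tuple[float, float]:
    """Observed (sexual, apomictic) proportions at ovule or seed stage.

    For ovules, ``basis="competing_only"`` uses nm_any/(nm_any + na_any)
    (each pathway counted wherever its sac occurs), while
    ``basis="shared_credit"`` splits mixed ovules evenly:
    (nm_only + 0.5 nma) / (nm_only + na_only + nma).  Seed counts have a
    single natural basis, sexual / (sexual + apomictic).
    """
    if isinstance(counts, SeedCounts):
        denom = counts.n_classified
        if denom == 0:
            raise NoClassifiableError(
                f"no classifiable seeds for population {counts.population_id!r}"
            )
        p = counts.n_sexual / denom
        return (p, 1.0 - p)

    if basis == "competing_only":
        denom = counts.nm_any + counts.na_any
        if denom == 0:
            raise NoClassifiableError(
                f"no classifiable ovules for population {counts.population_id!r}"
            )
        p = counts.nm_any / denom
    elif basis == "shared_credit":
        denom = counts.nm_only + counts.na_only + counts.n_mixed
        if denom == 0:
            raise NoClassifiableError(
                f"no classifiable ovules for population {counts.population_id!r}"
            )
        p = (counts.nm_only + 0.5 * counts.n_mixed) / denom
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown basis {basis!r}")
    return (p, 1.0 - p)


def reproductive_potentials(counts: OvuleCounts) -> tuple[float, float]:
    """(sexual, apomictic) reproductive potentials, nm_any/nt and na_any/nt.

    Each is the fraction of ovules carrying that pathway's embryo sac.
    Mixed ovules count toward both, so the pair may sum to more than 1;
    aborted ovules dilute both.
    """
    nt = counts.n_total
    return (counts.nm_any / nt, counts.na_any / nt)


def expected_seed_proportions(counts: OvuleCounts) -> tuple[float, float]:
    """Expected (sexual, apomictic) seed proportions under the independence null.

    Assuming both sac types develop independently and form seeds with equal
    probability, a mixed ovule contributes half to each pathway:
    ((nm_only + 0.5 nma)/nt, (na_only + 0.5 nma)/nt).  The pair sums to
    1 − n_aborted/nt.
    """
    nt = counts.n_total
    half = 0.5 * counts.n_mixed
    return ((counts.nm_only + half) / nt, (counts.na_only + half) / nt)


def pathway_efficiency(
    observed: tuple[float, float], expected: tuple[float, float]
) -> tuple[float, float]:
    """Componentwise observed/expected ratio; NaN where expected is zero.

    Efficiency 1 means a pathway converts its expected share into seeds
    exactly; below 1 it under-performs, above 1 it out-competes.
    """
    out = []
    for obs, exp in zip(observed, expected):
        if exp > 0:
            out.append(obs / exp)
        else:
            if obs > 0:
                warnings.warn(
                    "efficiency undefined: observed > 0 with expected = 0",
                    stacklevel=2,
                )
            out.append(float("nan"))
    return (out[0], out[1])


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def chi2_goodness_of_fit(
    observed_counts: tuple[int, int], expected_props: tuple[float, float]
) -> tuple[float, float]:
    """Pearson chi-squared goodness of fit for a two-class table, df = 1.

    ``expected_props`` are renormalized over the two competing classes; no
    continuity correction is applied.  Returns (chi2, upper-tail p).
    """
    n = sum(observed_counts)
    if n < 1:
        raise NoClassifiableError("total count must be >= 1")
    total_p = sum(expected_props)
    if total_p <= 0:
        raise ValueError("expected proportions must have positive sum")
    exp = np.asarray([n * p / total_p for p in expected_props], dtype=float)
    if np.any(exp == 0):
        raise ValueError("expected count of zero; chi-squared undefined")
    obs = np.asarray(observed_counts, dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def exact_goodness_of_fit_p(
    observed_counts: tuple[int, int], expected_props: tuple[float, float]
) -> float:
    """Exact two-class goodness-of-fit tail probability by enumeration.

    Enumerates all ``(k, n-k)`` tables under the binomial null and sums the
    probability of outcomes whose Pearson statistic is at least as large as
    the observed one.  Independent small-n reference for
    :func:`chi2_goodness_of_fit`.
    """
    n = sum(observed_counts)
    if n < 1:
        raise NoClassifiableError("total count must be >= 1")
    p0 = expected_props[0] / sum(expected_props)
    ks = np.arange(n + 1)
    e = np.array([n * p0, n * (1 - p0)])
    chi_all = (ks - e[0]) ** 2 / e[0] + ((n - ks) - e[1]) ** 2 / e[1]
    chi_obs = (observed_counts[0] - e[0]) ** 2 / e[0] + (
        observed_counts[1] - e[1]
    ) ** 2 / e[1]
    pmf = stats.binom.pmf(ks, n, p0)
    return float(pmf[chi_all >= chi_obs - 1e-12].sum())


def stage_shift_test(
    ovule_props: Sequence[float],
    seed_props: Sequence[float],
    paired: bool = True,
) -> StageComparison:
    """Compare per-population pathway proportions between ovule and seed stage.

    Paired Student t across populations by default (df = n−1); Welch t with
    Satterthwaite df otherwise.  Two-sided p.
    """
    a = np.asarray(ovule_props, dtype=float)
    b = np.asarray(seed_props, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length lists")
        if len(a) < 2:
            raise ValueError("need at least two populations")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return StageComparison(0.0, len(a) - 1.0, 1.0, "paired_t")
            warnings.warn(
                "zero variance of paired differences with nonzero mean; p -> 0",
                stacklevel=2,
            )
            return StageComparison(math.inf, len(a) - 1.0, 0.0, "paired_t")
        res = stats.ttest_rel(a, b)
        return StageComparison(float(res.statistic), len(a) - 1.0, float(res.pvalue), "paired_t")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two populations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return StageComparison(float(res.statistic), float(res.df), float(res.pvalue), "welch_t")


def parameter_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p for a per-population parameter matrix.

    Zero-variance columns yield NaN (undefined, not zero).  Requires at
    least three populations of finite values.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least three populations")
    cols = list(num.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    valid = {c for c in cols if num[c].std(ddof=1) > 0}
    for c in cols:
        if c in valid:
            r.loc[c, c], p.loc[c, c] = 1.0, 0.0
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            if ci in valid and cj in valid:
                res = stats.pearsonr(num[ci], num[cj])
                r.loc[ci, cj] = r.loc[cj, ci] = float(res.statistic)
                p.loc[ci, cj] = p.loc[cj, ci] = float(res.pvalue)
    return r, p


def season_compare(
    early: Sequence[OvuleCounts] | Sequence[SeedCounts],
    late: Sequence[OvuleCounts] | Sequence[SeedCounts],
    basis: Basis = "competing_only",
    statistic: Literal["welch_t", "chi2_homogeneity"] = "welch_t",
) -> StageComparison:
    """Compare sexual-pathway representation between collection seasons.

    Default is a Welch two-sample t on per-population sexual proportions
    (fractional Satterthwaite df).  ``chi2_homogeneity`` instead tests
    pooled sexual/apomictic counts for homogeneity across seasons in a
    2x2 table (df = 1, no continuity correction).
    """
    if len(early) < 2 or len(late) < 2:
        raise ValueError("each season needs at least two populations")
    if statistic == "welch_t":
        pe = [observed_proportions(c, basis)[0] for c in early]
        pl = [observed_proportions(c, basis)[0] for c in late]
        res = stats.ttest_ind(pe, pl, equal_var=False)
        return StageComparison(
            float(res.statistic), float(res.df), float(res.pvalue), "welch_t"
        )
    if statistic == "chi2_homogeneity":
        def _pair(counts):
            if isinstance(counts[0], SeedCounts):
                return (
                    sum(c.n_sexual for c in counts),
                    sum(c.n_apomictic for c in counts),
                )
            return (sum(c.nm_any for c in counts), sum(c.na_any for c in counts))

        table = np.array([_pair(early), _pair(late)], dtype=float)
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        return StageComparison(float(chi2), float(df), float(p), "chi2_homogeneity")
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------


def summarize_population(
    ovules: OvuleCounts | Sequence[OvuleCounts],
    seeds: SeedCounts | Sequence[SeedCounts],
    basis: Basis = "competing_only",
) -> ReproSummary:
    """Full pathway summary for one population from (pooled) counts.

    The chi-squared term tests observed seed counts against the expected
    seed proportions (renormalized over the two competing classes).
    By construction obs_seed_props = efficiency * exp_seed_props.
    """
    if not isinstance(ovules, OvuleCounts):
        ovules = pool_counts(list(ovules))
    if not isinstance(seeds, SeedCounts):
        seeds = pool_counts(list(seeds))
    potentials = reproductive_potentials(ovules)
    obs_ov = observed_proportions(ovules, basis)
    obs_seed = observed_proportions(seeds)
    exp_seed = expected_seed_proportions(ovules)
    eff = pathway_efficiency(obs_seed, exp_seed)
    chi2, p = chi2_goodness_of_fit((seeds.n_sexual, seeds.n_apomictic), exp_seed)
    return ReproSummary(
        population_id=ovules.population_id,
        potentials=potentials,
        obs_ovule_props=obs_ov,
        obs_seed_props=obs_seed,
        exp_seed_props=exp_seed,
        efficiency=eff,
        chi2=chi2,
        p_value=p,
        n_ovules=ovules.n_total,
        n_seeds=seeds.n_classified,
    )


def summarize_table(
    ovules: pd.DataFrame,
    seeds: pd.DataFrame,
    basis: Basis = "competing_only",
    aggregation: Literal["pooled", "mean_of_individuals"] = "pooled",
) -> pd.DataFrame:
    """Per-population summaries from long-format ovule and seed tables.

    Expects the ``ovules.tsv`` / ``seeds.tsv`` column layout.  ``pooled``
    (default) sums counts across individuals before computing statistics;
    ``mean_of_individuals`` averages per-individual proportions, with the
    chi-squared still computed on pooled counts.
    """
    rows = []
    pops = sorted(set(ovules["population_id"]) & set(seeds["population_id"]))
    for pop in pops:
        ov_rows = [
            OvuleCounts(
                population_id=pop,
                n_mes_only=int(r.n_mes_only),
                n_aes_only=int(r.n_aes_only),
                n_mixed=int(r.n_mixed),
                n_multi_aes=int(getattr(r, "n_multi_aes", 0)),
                n_aborted=int(getattr(r, "n_aborted", 0)),
                individual_id=str(getattr(r, "individual_id", "")),
                season=str(getattr(r, "season", "unknown")),
            )
            for r in ovules[ovules["population_id"] == pop].itertuples()
        ]
        sd_rows = [
            SeedCounts(
                population_id=pop,
                n_sexual=int(r.n_sexual),
                n_apomictic=int(r.n_apomictic),
                n_biii=int(getattr(r, "n_biii", 0)),
                n_unclassified=int(getattr(r, "n_unclassified", 0)),
                individual_id=str(getattr(r, "individual_id", "")),
                season=str(getattr(r, "season", "unknown")),
            )
            for r in seeds[seeds["population_id"] == pop].itertuples()
        ]
        summary = summarize_population(ov_rows, sd_rows, basis)
        if aggregation == "mean_of_individuals":
            ov_props = [
                observed_proportions(c, basis)[0]
                for c in ov_rows
                if c.nm_any + c.na_any > 0
            ]
            sd_props = [
                observed_proportions(c)[0] for c in sd_rows if c.n_classified > 0
            ]
            summary = replace(
                summary,
                obs_ovule_props=(np.mean(ov_props), 1 - np.mean(ov_props)),
                obs_seed_props=(np.mean(sd_props), 1 - np.mean(sd_props)),
            )
        rows.append(
            {
                "population_id": pop,
                "potential_sexual": summary.potentials[0],
                "potential_apomictic": summary.potentials[1],
                "obs_ovule_sexual": summary.obs_ovule_props[0],
                "obs_ovule_apomictic": summary.obs_ovule_props[1],
                "obs_seed_sexual": summary.obs_seed_props[0],
                "obs_seed_apomictic": summary.obs_seed_props[1],
                "exp_seed_sexual": summary.exp_seed_props[0],
                "exp_seed_apomictic": summary.exp_seed_props[1],
                "efficiency_sexual": summary.efficiency[0],
                "efficiency_apomictic": summary.efficiency[1],
                "chi2": summary.chi2,
                "p_value": summary.p_value,
                "n_ovules": summary.n_ovules,
                "n_seeds": summary.n_seeds,
            }
        )
    return pd.DataFrame(rows)
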