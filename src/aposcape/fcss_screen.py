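"""Flow cytometry seed screen (FCSS): single-seed histogram classification.

A mature grass seed contains two tissues whose nuclei differ in DNA content:
the embryo and the endosperm.  Their relative-fluorescence peak positions
identify the seed's reproductive origin.  For a tetraploid pseudogamous
aposporous plant with maternal 2C embryos:

* sexual seed — reduced egg fertilized by a reduced sperm: embryo 2C,
  endosperm 3C (ratio 1.5);
* apomictic seed — unreduced parthenogenetic egg, fertilized central cell
  with two unreduced polar nuclei: embryo 2C, endosperm 5C (ratio 2.5);
* BIII seed — fertilization of an *unreduced* egg: embryo ploidy rises to
  1.5x the maternal level.

Quality gates follow cytometric practice for this assay: at least 3000
particles per histogram and a maximum coefficient of variation of 5% per
retained peak; anything failing the gates is reported as unclassified.

Histograms are consumed as plain channel-count vectors (long-format CSV);
vendor FCS binaries are out of scope, but any converter producing
``seed_id, channel, count`` rows can feed this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .repro_stats import SeedCounts

__all__ = [
    "SeedHistogram",
    "PeakCall",
    "SeedClass",
    "find_peaks",
    "qc_gate",
    "classify_seed",
    "classify_histogram",
    "tabulate_population",
    "histograms_from_long_table",
    "MIN_PARTICLES",
    "MAX_PEAK_CV",
]

MIN_PARTICLES = 3000
MAX_PEAK_CV = 0.05
#: ratio windows: sexual 3C/2C = 1.5, apomictic 5C/2C = 2.5.  Widths chosen
#: to accommodate 5%-CV peak location error while staying disjoint.
SEXUAL_RATIO_WINDOW = (1.5, 0.15)
APOMICTIC_RATIO_WINDOW = (2.5, 0.25)
EMBRYO_C_TOLERANCE = 0.3
DEBRIS_FLOOR = 20  # channels below this are instrument debris; ignored
SMOOTH_WIDTH = 5  # moving-average width (channels) for peak detection


@dataclass(frozen=True)
class SeedHistogram:
    """Relative-fluorescence histogram of one seed."""

    seed_id: str
    channels: np.ndarray  # per-channel particle counts
    maternal_reference_channel: float  # expected channel of the maternal 2C peak

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if np.any(ch < 0):
            raise ValueError("channel counts must be nonnegative")
        object.__setattr__(self, "channels", ch)

    @property
    def n_particles(self) -> int:
        return int(self.channels.sum())


@dataclass(frozen=True)
class PeakCall:
    """A fitted histogram peak in channel and C-value units."""

    mean_channel: float
    cv: float
    particle_count: int
    c_value: float


@dataclass(frozen=True)
class SeedClass:
    """Classification of one seed from its embryo/endosperm peak pair."""

    seed_id: str
    label: str  # sexual | apomictic | biii | unclassified
    embryo_c: float = float("nan")
    endosperm_c: float = float("nan")
    ratio: float = float("nan")
    qc_pass: bool = False
    reason: str = ""


def _moment_fit(raw: np.ndarray, center: float) -> tuple[float, float]:
    """Weighted mean/sd of channel positions, iterated on a +-3 sigma window."""
    mean, sigma = float(center), max(3.0, 0.02 * max(center, 1.0))
    for _ in range(4):
        lo = max(int(mean - 3 * sigma), 0)
        hi = min(int(mean + 3 * sigma) + 1, len(raw))
        w = raw[lo:hi]
        if w.sum() <= 0:
            break
        x = np.arange(lo, hi, dtype=float)
        mean = float(np.average(x, weights=w))
        var = float(np.average((x - mean) ** 2, weights=w))
        sigma = max(np.sqrt(var), 1e-6)
    return mean, sigma


def _gaussian_ls_fit(raw: np.ndarray, mean0: float, sigma0: float) -> tuple[float, float]:
    """Local least-squares Gaussian + constant-baseline fit on a +-3 sigma window.

    The baseline term absorbs debris counts under the peak that would
    otherwise inflate moment-based width estimates; falls back to the
    moment estimates when the fit does not converge.
    """
    lo = max(int(mean0 - 3 * sigma0), 0)
    hi = min(int(mean0 + 3 * sigma0) + 1, len(raw))
    x = np.arange(lo, hi, dtype=float)
    w = raw[lo:hi]
    if len(x) < 6 or w.sum() <= 0:
        return mean0, sigma0

    def model(x, amp, mu, sd, base):
        return base + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            model,
            x,
            w,
            p0=[float(w.max()), mean0, sigma0, 0.0],
            sigma=np.sqrt(w + 1.0),  # Poisson counting error per channel
            bounds=([0.0, lo, 0.3 * sigma0, 0.0], [np.inf, hi, 3.0 * sigma0, np.inf]),
            maxfev=2000,
        )
    except Exception:
        return mean0, sigma0
    return float(popt[1]), float(popt[2])


def find_peaks(
    hist: SeedHistogram,
    min_peak_fraction: float = 0.05,
    smooth_width: int = SMOOTH_WIDTH,
    debris_floor: int = DEBRIS_FLOOR,
) -> list[PeakCall]:
    """Detect and fit histogram peaks, sorted by mean channel.

    A moving-average-smoothed histogram is scanned for local maxima; each
    candidate is refined by iterated moment estimation on a +-3 sigma window of
    the raw counts.  Peaks whose integrated count falls below
    ``min_peak_fraction`` of the total are dropped, as are near-duplicate
    maxima landing within 2 sigma of a larger peak.
    """
    if hist.n_particles < 1:
        return []
    if not 0 < min_peak_fraction < 1:
        raise ValueError("min_peak_fraction must be in (0, 1)")
    raw = hist.channels.copy()
    raw[:debris_floor] = 0.0
    total = raw.sum()
    if total <= 0:
        return []
    kernel = np.ones(smooth_width) / smooth_width
    # edge-replicated padding so the boundaries create no spurious maxima
    padded = np.pad(raw, smooth_width, mode="edge")
    smooth = np.convolve(padded, kernel, mode="same")[smooth_width:-smooth_width]
    # prominence keeps shot noise on the floor from spawning candidates
    idx, props = signal.find_peaks(smooth, prominence=0.5 * smooth.max() * min_peak_fraction)
    if len(idx) == 0:
        return []
    order = np.argsort(smooth[idx])[::-1]
    calls: list[PeakCall] = []
    for i in order:
        center = idx[i]
        mean, sigma = _moment_fit(raw, center)
        mean, sigma = _gaussian_ls_fit(raw, mean, sigma)
        if any(abs(mean - c.mean_channel) < 2 * max(sigma, c.cv * c.mean_channel) for c in calls):
            continue
        lo = max(int(mean - 3 * sigma), 0)
        hi = min(int(mean + 3 * sigma) + 1, len(raw))
        count = int(raw[lo:hi].sum())
        if count < min_peak_fraction * total:
            continue
        calls.append(
            PeakCall(
                mean_channel=mean,
                cv=sigma / mean if mean > 0 else float("inf"),
                particle_count=count,
                c_value=2.0 * mean / hist.maternal_reference_channel,
            )
        )
    return sorted(calls, key=lambda c: c.mean_channel)


def qc_gate(peaks: Sequence[PeakCall], n_particles: int) -> bool:
    """True iff >=3000 particles, >=2 peaks, and every peak CV <= 5%.

    CVs are compared at the 0.1% precision cytometry software reports, so
    an estimate of 5.04% passes and 5.06% fails.
    """
    return (
        n_particles >= MIN_PARTICLES
        and len(peaks) >= 2
        and all(round(p.cv, 3) <= MAX_PEAK_CV for p in peaks)
    )


def classify_seed(
    peaks: Sequence[PeakCall],
    maternal_c: float = 2.0,
    seed_id: str = "",
) -> SeedClass:
    """Assign a reproductive origin from embryo/endosperm peak C-values.

    The embryo is the lowest-C of the two largest peaks, the endosperm the
    next.  Sexual: endosperm/embryo ratio within 1.5 +- 0.15 and embryo near
    the maternal C-level; apomictic: ratio within 2.5 +- 0.25 with maternal
    embryo; BIII: embryo near 1.5x maternal (fertilized unreduced egg).
    """
    if len(peaks) < 2:
        return SeedClass(seed_id, "unclassified", reason="fewer than two peaks")
    major = sorted(peaks, key=lambda p: p.particle_count, reverse=True)[:2]
    embryo, endosperm = sorted(major, key=lambda p: p.c_value)
    ratio = endosperm.c_value / embryo.c_value
    maternal_embryo = abs(embryo.c_value - maternal_c) <= EMBRYO_C_TOLERANCE
    label = "unclassified"
    reason = "peak ratio outside all windows"
    if maternal_embryo and abs(ratio - SEXUAL_RATIO_WINDOW[0]) <= SEXUAL_RATIO_WINDOW[1]:
        label, reason = "sexual", ""
    elif maternal_embryo and abs(ratio - APOMICTIC_RATIO_WINDOW[0]) <= APOMICTIC_RATIO_WINDOW[1]:
        label, reason = "apomictic", ""
    elif abs(embryo.c_value - 1.5 * maternal_c) <= EMBRYO_C_TOLERANCE:
        label, reason = "biii", ""
    return SeedClass(
        seed_id=seed_id,
        label=label,
        embryo_c=embryo.c_value,
        endosperm_c=endosperm.c_value,
        ratio=ratio,
        qc_pass=True,
        reason=reason,
    )


def classify_histogram(
    hist: SeedHistogram,
    maternal_c: float = 2.0,
    min_peak_fraction: float = 0.05,
) -> SeedClass:
    """Full per-seed pipeline: peak detection, QC gate, classification."""
    peaks = find_peaks(hist, min_peak_fraction=min_peak_fraction)
    if not qc_gate(peaks, hist.n_particles):
        return SeedClass(hist.seed_id, "unclassified", qc_pass=False, reason="failed QC gate")
    return classify_seed(peaks, maternal_c=maternal_c, seed_id=hist.seed_id)


def tabulate_population(
    classes: Iterable[SeedClass], population_id: str = "", season: str = "unknown"
) -> SeedCounts:
    """Count seed classifications into a :class:`SeedCounts` record.

    QC failures land in ``n_unclassified``.
    """
    tally = {"sexual": 0, "apomictic": 0, "biii": 0, "unclassified": 0}
    for c in classes:
        tally[c.label] += 1
    return SeedCounts(
        population_id=population_id,
        n_sexual=tally["sexual"],
        n_apomictic=tally["apomictic"],
        n_biii=tally["biii"],
        n_unclassified=tally["unclassified"],
        season=season,
    )


def histograms_from_long_table(
    table: pd.DataFrame,
    maternal_reference_channel: float,
    n_channels: int = 1024,
) -> list[SeedHistogram]:
    """Build :class:`SeedHistogram` objects from a long-format table.

    Expects columns ``seed_id, channel, count``; missing channels are zero.
    """
    out = []
    for seed_id, grp in table.groupby("seed_id", sort=True):
        ch = np.zeros(n_channels)
        idx = grp["channel"].to_numpy(dtype=int)
        if np.any((idx < 0) | (idx >= n_channels)):
            raise ValueError(f"seed {seed_id!r}: channel index out of range")
        ch[idx] = grp["count"].to_numpy(dtype=float)
        out.append(
            SeedHistogram(
                seed_id=str(seed_id),
                channels=ch,
                maternal_reference_channel=maternal_reference_channel,
            )
        )
    return out
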