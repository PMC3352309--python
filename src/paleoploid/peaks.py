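"""Ks age distributions: binning, mode detection, clock conversion.

Ks values are binned at 0.01 Ks units (left-closed, right-open bins) for
reporting. Modes are found on a Gaussian kernel density estimate with a
fixed bandwidth in Ks units; a peak is a local density maximum whose
prominence is at least a fraction of the global density maximum. A
background of duplicate loss decaying from Ks = 0 shows up as a boundary
maximum, which is reported separately and never counts as a duplication
or speciation mode. A secondary mode must be separated from the primary
by at least twice the bandwidth.

Ks converts to absolute time through a clock-like synonymous substitution
rate r (default 3.51e-9 substitutions per synonymous site per year). The
default convention is T = Ks / r, which treats the pairwise Ks as the
per-lineage divergence; the textbook alternative T = Ks / (2r) for
symmetric pairwise divergence is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.stats import gaussian_kde


@dataclass(frozen=True)
class ClockRate:
    """Synonymous substitution rate per site per year."""

    rate: float = 3.51e-9
    convention: str = "direct"  # "direct": T = Ks/r; "halved": T = Ks/(2r)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.convention not in ("direct", "halved"):
            raise ValueError(f"unknown convention {self.convention!r}")


DEFAULT_CLOCK = ClockRate()


@dataclass(frozen=True)
class Peak:
    """A detected density mode."""

    location: float  # Ks
    density: float
    prominence: float
    boundary: bool = False  # density maximum at Ks = 0, not a true mode


@dataclass
class KsDistribution:
    """Binned Ks values with detected modes."""

    values: list[float]
    bin_width: float = 0.01
    max_ks: float = 2.0
    kind: str = "paralog-event"  # or "ortholog"
    counts: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    n_excluded: int = 0
    peaks: list[Peak] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.values or self.counts.sum() == 0


def _bin_index(value: float, width: float) -> int:
    """Left-closed right-open bin index, robust to float division noise."""
    idx = int(math.floor(value / width))
    if value >= (idx + 1) * width:
        idx += 1
    elif value < idx * width:
        idx -= 1
    return idx


def make_histogram(
    values: Sequence[float],
    bin_width: float = 0.01,
    max_ks: float = 2.0,
    kind: str = "paralog-event",
) -> KsDistribution:
    """Bin Ks values into [k·w, (k+1)·w) bins over [0, max_ks).

    Values >= max_ks are excluded from the counts and tallied in
    ``n_excluded``; negative values are rejected.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = [float(v) for v in values]
    if any(v < 0 for v in vals):
        raise ValueError("Ks values must be non-negative")
    n_bins = _bin_index(max_ks, bin_width)
    counts = np.zeros(n_bins, dtype=int)
    excluded = 0
    for v in vals:
        idx = _bin_index(v, bin_width)
        if 0 <= idx < n_bins:
            counts[idx] += 1
        else:
            excluded += 1
    return KsDistribution(
        values=vals,
        bin_width=bin_width,
        max_ks=max_ks,
        kind=kind,
        counts=counts,
        n_excluded=excluded,
    )


def detect_peaks(
    dist: KsDistribution,
    bandwidth: float | None = 0.01,
    min_prominence_frac: float = 0.05,
    min_values: int = 50,
    grid_step: float | None = None,
) -> list[Peak]:
    """Gaussian-KDE modes of the distribution, ordered by density.

    Peaks are interior local maxima with prominence >=
    ``min_prominence_frac`` times the global density maximum. A monotone
    pile-up against Ks = 0 (duplicate-loss background) is reported as a
    ``boundary`` peak. Requires >= ``min_values`` in-range values.

    ``bandwidth`` is in Ks units; the 0.01 default resolves modes down to
    a few bin widths apart (needed for very recent duplication bursts).
    ``bandwidth=None`` uses Scott's rule, the right choice for a smooth
    unimodal sample where a fixed narrow kernel would undersmooth and
    jitter the mode location.
    """
    vals = np.asarray([v for v in dist.values if v < dist.max_ks], dtype=float)
    if vals.size < min_values:
        raise ValueError(
            f"too few Ks values for mode detection ({vals.size} < {min_values})"
        )
    sd = vals.std(ddof=1)
    if sd == 0:  # degenerate: all values identical
        peaks = [Peak(float(vals[0]), float("inf"), float("inf"))]
        dist.peaks = peaks
        return peaks
    if bandwidth is None:
        kde = gaussian_kde(vals)  # Scott's rule
        bandwidth = float(kde.factor * sd)
    else:
        kde = gaussian_kde(vals, bw_method=bandwidth / sd)
    step = grid_step if grid_step is not None else bandwidth / 5.0
    grid = np.arange(0.0, dist.max_ks + step / 2, step)
    density = kde(grid)
    top = float(density.max())
    idx, props = _scipy_find_peaks(density, prominence=min_prominence_frac * top)
    peaks = [
        Peak(float(grid[i]), float(density[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    # boundary pile-up at 0: left edge above every interior peak's shoulder
    if density[0] >= density[1] and all(not np.isclose(p.location, 0.0) for p in peaks):
        peaks.append(Peak(float(grid[0]), float(density[0]), float(density[0]), boundary=True))
    peaks.sort(key=lambda p: -p.density)
    dist.peaks = peaks
    return peaks


def primary_mode(dist: KsDistribution) -> Peak | None:
    """Highest-density interior mode (boundary pile-ups excluded)."""
    for p in dist.peaks:
        if not p.boundary:
            return p
    return None


def secondary_mode(dist: KsDistribution, bandwidth: float = 0.01) -> Peak | None:
    """Second interior mode, if separated from the primary by >= 2×bandwidth."""
    interior = [p for p in dist.peaks if not p.boundary]
    if len(interior) < 2:
        return None
    primary = interior[0]
    for p in interior[1:]:
        if abs(p.location - primary.location) >= 2 * bandwidth:
            return p
    return None


def duplication_mode(
    dist: KsDistribution,
    bandwidth: float = 0.01,
    min_mass_frac: float = 0.10,
) -> Peak | None:
    """The duplication mode of a paralog-event distribution, if any.

    A genome duplication deposits a large burst of events at one age, so a
    qualifying mode must both be an interior KDE mode clear of the
    boundary (location >= 2×bandwidth) and concentrate a material share of
    all events: at least ``min_mass_frac`` of the in-range values within
    ±2×bandwidth of the mode. The mass requirement rejects the sampling
    wiggles that a sparse, decaying duplicate-loss background produces
    under a narrow kernel. Returns the strongest qualifying mode or None.
    """
    vals = np.asarray([v for v in dist.values if v < dist.max_ks], dtype=float)
    if vals.size == 0:
        return None
    for p in dist.peaks:
        if p.boundary or p.location < 2 * bandwidth:
            continue
        mass = np.mean(np.abs(vals - p.location) <= 2 * bandwidth)
        if mass >= min_mass_frac:
            return p
    return None


def has_duplication_signal(
    dist: KsDistribution, bandwidth: float = 0.01, min_mass_frac: float = 0.10
) -> bool:
    """Whether a paralog-event distribution shows a duplication mode."""
    return duplication_mode(dist, bandwidth, min_mass_frac) is not None


def ks_to_time(ks: float, clock: ClockRate = DEFAULT_CLOCK) -> float:
    """Years corresponding to a Ks value under the clock convention."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    divisor = clock.rate if clock.convention == "direct" else 2.0 * clock.rate
    return ks / divisor


def ks_to_mya(ks: float, clock: ClockRate = DEFAULT_CLOCK) -> float:
    return ks_to_time(ks, clock) / 1e6
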