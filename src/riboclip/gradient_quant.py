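"""Quantification of gradient absorbance traces, dilution-series blot
intensities, and peptide-level protein ratios."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class DegenerateTraceError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class GradientTrace:
    """A254 absorbance sampled along gradient depth."""

    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        absb = np.asarray(self.absorbance, dtype=float)
        if pos.shape != absb.shape or pos.size < 10:
            raise ValueError("positions/absorbance must match and hold >= 10 points")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", absb)

    def resampled_uniform(self) -> "GradientTrace":
        """Linear-interpolated copy on a uniform grid of the same size."""
        dx = np.diff(self.positions)
        if np.allclose(dx, dx[0]):
            return self
        grid = np.linspace(self.positions[0], self.positions[-1], self.positions.size)
        return GradientTrace(grid, np.interp(grid, self.positions, self.absorbance))


@dataclass(frozen=True)
class GradientBoundaries:
    mode: str  # polysome_monosome | monosome_subunit
    free_rnp_end: float | None = None
    s40_start: float | None = None
    s60_end: float | None = None
    s80_start: float | None = None
    s80_end: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("polysome_monosome", "monosome_subunit"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "polysome_monosome":
            if self.s80_start is None or self.s80_end is None:
                raise ValueError("polysome_monosome mode needs s80_start and s80_end")
            if self.s80_end <= self.s80_start:
                raise ValueError("boundaries out of order")
        else:
            if None in (self.s40_start, self.s60_end, self.s80_end):
                raise ValueError("monosome_subunit mode needs s40_start, s60_end, s80_end")
            if not (self.s40_start < self.s60_end < self.s80_end):
                raise ValueError("boundaries out of order")


def _left_riemann(trace: GradientTrace, baseline: float, lo: float, hi: float) -> float:
    """Left-endpoint Riemann sum of (absorbance - baseline) over [lo, hi)."""
    t = trace.resampled_uniform()
    if lo < t.positions[0] or hi > t.positions[-1]:
        raise ValueError(f"window [{lo}, {hi}] outside trace range")
    dx = t.positions[1] - t.positions[0]
    mask = (t.positions >= lo) & (t.positions < hi)
    return float(np.sum(t.absorbance[mask] - baseline) * dx)


def polysome_monosome_ratio(trace: GradientTrace, boundaries: GradientBoundaries) -> float:
    """Polysome area (80S_end to trace end) over monosome area
    (80S_start to 80S_end), both above a baseline set to the global
    minimum excluding the free-RNP region."""
    if boundaries.mode != "polysome_monosome":
        raise ValueError("boundaries must be in polysome_monosome mode")
    t = trace.resampled_uniform()
    if boundaries.free_rnp_end is not None:
        mask = t.positions >= boundaries.free_rnp_end
        if not mask.any():
            raise ValueError("free-RNP region covers the whole trace")
        baseline = float(t.absorbance[mask].min())
    else:
        baseline = float(t.absorbance.min())
    mono = _left_riemann(t, baseline, boundaries.s80_start, boundaries.s80_end)
    poly = _left_riemann(t, baseline, boundaries.s80_end, float(t.positions[-1]))
    if mono <= 0:
        raise DegenerateTraceError("non-positive monosome area")
    return poly / mono


def monosome_subunit_ratio(trace: GradientTrace, boundaries: GradientBoundaries) -> float:
    """Monosome area (60S_end to 80S_end) over subunit area (40S_start
    to 60S_end) above the global-minimum baseline."""
    if boundaries.mode != "monosome_subunit":
        raise ValueError("boundaries must be in monosome_subunit mode")
    t = trace.resampled_uniform()
    baseline = float(t.absorbance.min())
    subunit = _left_riemann(t, baseline, boundaries.s40_start, boundaries.s60_end)
    mono = _left_riemann(t, baseline, boundaries.s60_end, boundaries.s80_end)
    if subunit <= 0:
        raise DegenerateTraceError("non-positive subunit area")
    return mono / subunit


@dataclass(frozen=True)
class DilutionSeries:
    """Ordered (dilution factor, band intensity) pairs for one epitope."""

    dilutions: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.dilutions) != len(self.intensities):
            raise ValueError("dilutions and intensities must align")
        if len(self.dilutions) < 3:
            raise InsufficientDataError("need at least 3 points")


def dilution_slope(series: DilutionSeries) -> tuple[float, float]:
    """Slope of the best linear fit over 3 or 4 consecutive points.

    "Best" is the window with the highest r-squared; ties prefer the
    larger window, then the earlier one.  Returns (slope, r2).
    """
    x = np.asarray(series.dilutions, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    best: tuple[float, int, int] | None = None  # (r2, window size, -start)
    best_slope = 0.0
    for size in (3, 4):
        for start in range(0, len(x) - size + 1):
            res = stats.linregress(x[start:start + size], y[start:start + size])
            r2 = float(res.rvalue) ** 2
            key = (r2, size, -start)
            if best is None or key > best:
                best = key
                best_slope = float(res.slope)
    assert best is not None
    return best_slope, best[0]


def abundance_ratio(numerator: DilutionSeries, denominator: DilutionSeries) -> float:
    """Ratio of best-window dilution slopes (epitope abundance ratio)."""
    num, _ = dilution_slope(numerator)
    den, _ = dilution_slope(denominator)
    if den == 0:
        raise DegenerateTraceError("zero denominator slope")
    return num / den


def protein_ratio(peptide_ratios: Mapping[str, Mapping[int, Sequence[float]]],
                  flip_replicates: Sequence[int] = ()) -> dict[str, dict[int, float]]:
    """Per-replicate median over distinct peptide ratios for each protein.

    Replicates listed in ``flip_replicates`` had their isotope labels
    swapped; their ratios are inverted before aggregation.
    """
    flip = set(flip_replicates)
    out: dict[str, dict[int, float]] = {}
    for protein, reps in peptide_ratios.items():
        medians: dict[int, float] = {}
        for rep, ratios in reps.items():
            vals = [1.0 / r if rep in flip else r for r in ratios if r > 0]
            if not vals:
                continue
            medians[rep] = float(np.median(vals))
        if medians:
            out[protein] = medians
    return out


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_trace_tsv(path: str | Path) -> GradientTrace:
    data = np.loadtxt(path, delimiter="\t", comments="#")
    return GradientTrace(data[:, 0], data[:, 1])


def write_trace_tsv(trace: GradientTrace, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([trace.positions, trace.absorbance]),
               delimiter="\t", fmt="%.8g")


def read_dilution_series_tsv(path: str | Path) -> DilutionSeries:
    data = np.loadtxt(path, delimiter="\t", comments="#")
    return DilutionSeries(tuple(data[:, 0]), tuple(data[:, 1]))
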