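"""Optical quality control: MTF and degree-of-sharpness measurements.

The modulation transfer function (MTF) of an imaging chain is measured from
resolution charts: per chart region at spatial frequency f (lp/mm) the
transmitted modulation is ``(I_max - I_min) / (I_max + I_min)`` of the
region's averaged profile.  MTF50 and MTF10 are the frequencies where the
modulation falls to 0.5 and 0.1, found by linear interpolation between the
bracketing samples.  The degree of sharpness (DS) of a concentric-circle
chart is the finest circle group whose modulation still exceeds a visibility
threshold.  Group summaries (e.g. deep-blue bands vs the rest) are plain
arithmetic means of the per-band readouts.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .phantom import ChartImage, ChartRegion

__all__ = [
    "ModulationMeasurement",
    "MtfReport",
    "QcSummary",
    "measure_modulation",
    "mtf_crossings",
    "degree_of_sharpness",
    "summarize",
    "write_reports_csv",
]


@dataclass(frozen=True)
class ModulationMeasurement:
    frequency_lpmm: float
    modulation: float


@dataclass
class MtfReport:
    """MTF readout for one illumination band (or ``"white"``)."""

    band_label: str
    frequencies: tuple[float, ...]
    modulation: tuple[float, ...]
    mtf50: float
    mtf10: float
    mtf50_censored: bool = False  # True: level not bracketed, value is a lower bound
    mtf10_censored: bool = False


@dataclass
class QcSummary:
    reports: dict[str, MtfReport]
    #: group name -> {"mtf50": mean, "mtf10": mean}
    group_averages: dict[str, dict[str, float]]

    def formatted(self) -> dict[str, dict[str, float]]:
        """Group averages rounded to 2 decimals for display."""
        return {
            g: {k: round(v, 2) for k, v in d.items()} for g, d in self.group_averages.items()
        }


def _region_profile(image: np.ndarray, region: ChartRegion) -> np.ndarray:
    """Averaged 1D profile of a chart region, trimmed away from blur-contaminated edges."""
    if region.annulus is not None:
        cy, cx, r_in, r_out = region.annulus
        yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
        rad = np.hypot(yy - cy, xx - cx)
        margin = min(2.0, 0.2 * (r_out - r_in))
        mask = (rad >= r_in + margin) & (rad < r_out - margin)
        return image[mask].ravel()
    r0, r1 = region.rows
    c0, c1 = region.cols
    row_trim = max(2, (r1 - r0) // 4)
    col_trim = max(2, (c1 - c0) // 10)
    block = image[r0 + row_trim : r1 - row_trim, c0 + col_trim : c1 - col_trim]
    return block.mean(axis=0)


def measure_modulation(
    chart: ChartImage | np.ndarray, regions: tuple[ChartRegion, ...] | None = None
) -> list[ModulationMeasurement]:
    """Measure per-region modulation of an annotated chart.

    Line-bar regions are row-averaged into a horizontal profile; circle-chart
    annuli use all annulus pixels.  A region without oscillation (flat
    profile) is flagged and reported with modulation 0.
    """
    if isinstance(chart, ChartImage):
        image = chart.image
        regions = chart.regions if regions is None else regions
    else:
        image = np.asarray(chart, dtype=float)
        if regions is None:
            raise ParameterError("regions annotation required for a bare image")
    out = []
    for region in regions:
        profile = _region_profile(image, region)
        hi, lo = float(profile.max()), float(profile.min())
        if hi - lo < 1e-9 or hi + lo <= 0:
            warnings.warn(
                f"region at {region.frequency_lpmm:g} lp/mm shows no oscillation",
                stacklevel=2,
            )
            modulation = 0.0
        else:
            modulation = (hi - lo) / (hi + lo)
        out.append(ModulationMeasurement(region.frequency_lpmm, modulation))
    return out


def _interp_crossing(freqs: np.ndarray, mods: np.ndarray, level: float) -> tuple[float, bool]:
    """Frequency where the (isotonic) modulation curve crosses `level`."""
    below = mods <= level
    if not below.any():
        return float(freqs[-1]), True  # beyond the measured range; lower bound
    j = int(np.argmax(below))
    if j == 0:
        return float(freqs[0]), False
    f0, f1 = freqs[j - 1], freqs[j]
    m0, m1 = mods[j - 1], mods[j]
    if m0 == m1:
        return float(f1), False
    return float(f0 + (m0 - level) / (m0 - m1) * (f1 - f0)), False


def mtf_crossings(
    pairs, band_label: str = ""
) -> MtfReport:
    """MTF50/MTF10 from (frequency, modulation) pairs by linear interpolation.

    Pairs are sorted by frequency and cleaned to a non-increasing curve
    (running minimum) before the crossings are located.  A level that is not
    bracketed is reported as censored, with the last measured frequency as a
    lower bound.
    """
    items = [
        (p.frequency_lpmm, p.modulation) if isinstance(p, ModulationMeasurement) else tuple(p)
        for p in pairs
    ]
    if len(items) < 2:
        raise ParameterError("need at least 2 frequency samples")
    items.sort(key=lambda fm: fm[0])
    freqs = np.array([f for f, _ in items], dtype=float)
    mods = np.minimum.accumulate(np.array([m for _, m in items], dtype=float))
    mtf50, c50 = _interp_crossing(freqs, mods, 0.5)
    mtf10, c10 = _interp_crossing(freqs, mods, 0.1)
    return MtfReport(
        band_label=band_label,
        frequencies=tuple(freqs),
        modulation=tuple(mods),
        mtf50=mtf50,
        mtf10=mtf10,
        mtf50_censored=c50,
        mtf10_censored=c10,
    )


def degree_of_sharpness(
    chart: ChartImage | np.ndarray,
    regions: tuple[ChartRegion, ...] | None = None,
    visibility_threshold: float = 0.1,
) -> float:
    """Finest circle-chart frequency (lp/mm) whose modulation is still visible.

    Returns 0 with a warning when no group exceeds the threshold.
    """
    measurements = measure_modulation(chart, regions)
    visible = [m.frequency_lpmm for m in measurements if m.modulation > visibility_threshold]
    if not visible:
        warnings.warn("no circle group visible above threshold", stacklevel=2)
        return 0.0
    return max(visible)


def summarize(
    reports: dict[str, MtfReport] | list[MtfReport],
    groups: dict[str, tuple[str, ...]],
) -> QcSummary:
    """Arithmetic group means of MTF50/MTF10 over named band groups."""
    if isinstance(reports, list):
        reports = {r.band_label: r for r in reports}
    averages: dict[str, dict[str, float]] = {}
    for name, members in groups.items():
        if not members:
            raise ParameterError(f"group {name!r} is empty")
        missing = [m for m in members if str(m) not in reports]
        if missing:
            raise ParameterError(f"group {name!r}: no report for {missing}")
        sel = [reports[str(m)] for m in members]
        averages[name] = {
            "mtf50": float(np.mean([r.mtf50 for r in sel])),
            "mtf10": float(np.mean([r.mtf10 for r in sel])),
        }
    return QcSummary(reports=dict(reports), group_averages=averages)


def write_reports_csv(summary: QcSummary, csv_path, json_path=None) -> None:
    """Write per-band MTF readouts as CSV and (optionally) group averages as JSON."""
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["band", "mtf50_lpmm", "mtf10_lpmm", "mtf50_censored", "mtf10_censored"])
        for label, r in summary.reports.items():
            writer.writerow([label, f"{r.mtf50:.4f}", f"{r.mtf10:.4f}",
                             int(r.mtf50_censored), int(r.mtf10_censored)])
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary.formatted(), indent=2))
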