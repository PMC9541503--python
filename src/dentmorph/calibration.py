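"""Radiocarbon calibration against an IntCal-format curve with HPD intervals.

A conventional radiocarbon age ``age +/- sigma`` (14C yr BP) is mapped to a
posterior over calendar age theta on a 1-year grid:

    p(theta) ∝ exp(-(age - mu(theta))^2 / (2 (sigma^2 + sigma_c(theta)^2)))
                / sqrt(sigma^2 + sigma_c(theta)^2)

where ``mu`` and ``sigma_c`` are the calibration curve's 14C age and 1-sigma
error, linearly interpolated from the curve tabulation.  Highest posterior
density (HPD) regions are accumulated in descending density order to the
requested coverage (1-sigma 68.27% and 2-sigma 95.45% by default) and reported
as [older, younger] cal BP bounds rounded to 10 years, the granularity of
published date tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadiocarbonDate",
    "CalibrationCurve",
    "CalibrationResult",
    "read_curve",
    "calibrate",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = (0.6827, 0.9545)


class CurveParseError(ValueError):
    pass


class CalibrationRangeError(ValueError):
    pass


@dataclass(frozen=True)
class RadiocarbonDate:
    lab_code: str
    age_14c: float  # conventional 14C years BP
    sigma: float  # 1-sigma error, years

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Tabulated curve: calendar grid, 14C age mu, curve error sigma (all years)."""

    cal_bp: np.ndarray
    mu: np.ndarray
    sigma_curve: np.ndarray
    name: str = "curve"

    def __post_init__(self) -> None:
        cal = np.asarray(self.cal_bp, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sc = np.asarray(self.sigma_curve, dtype=float)
        if not (len(cal) == len(mu) == len(sc)):
            raise CurveParseError("curve columns must have equal length")
        d = np.diff(cal)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise CurveParseError("cal BP grid must be strictly monotone")
        if np.any(sc <= 0):
            raise CurveParseError("curve sigma must be positive")
        if d[0] < 0:  # store ascending
            cal, mu, sc = cal[::-1], mu[::-1], sc[::-1]
        object.__setattr__(self, "cal_bp", cal)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma_curve", sc)

    def interpolate(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (np.interp(grid, self.cal_bp, self.mu),
                np.interp(grid, self.cal_bp, self.sigma_curve))


@dataclass(frozen=True)
class CalibrationResult:
    date: RadiocarbonDate
    grid: np.ndarray  # calendar ages, 1-year step, ascending
    density: np.ndarray  # posterior mass per grid point, sums to 1
    hpd_ranges: dict  # level -> list of [older, younger] cal BP, rounded to 10
    levels: tuple[float, ...]
    curve_name: str = "curve"

    def summary_rows(self) -> list[dict]:
        rows = []
        for level in self.levels:
            for older, younger in self.hpd_ranges[level]:
                rows.append({"lab_code": self.date.lab_code, "age_14c": self.date.age_14c,
                             "sigma": self.date.sigma, "level": level,
                             "from_cal_bp": older, "to_cal_bp": younger})
        return rows


def read_curve(path, name: str | None = None) -> CalibrationCurve:
    """Parse an IntCal-dialect text curve.

    Header lines starting with '#' (or '%') are skipped; data rows are comma or
    whitespace separated with columns (cal BP, 14C age BP, 1-sigma error, ...);
    any extra columns are ignored.
    """
    cal, mu, sc = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("%"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise CurveParseError(f"line {lineno}: expected >= 3 columns")
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise CurveParseError(f"line {lineno}: non-numeric field") from exc
            cal.append(vals[0])
            mu.append(vals[1])
            sc.append(vals[2])
    if len(cal) < 2:
        raise CurveParseError("curve needs at least 2 rows")
    return CalibrationCurve(cal_bp=np.array(cal), mu=np.array(mu),
                            sigma_curve=np.array(sc),
                            name=name or str(path))


def calibrate(date: RadiocarbonDate, curve: CalibrationCurve,
              levels: tuple[float, ...] = DEFAULT_LEVELS,
              round_to: int = 10) -> CalibrationResult:
    """Calibrate one date on a 1-year grid and extract HPD ranges.

    Raises
    ------
    CalibrationRangeError
        If the 14C age lies outside the curve's tabulated 14C range.
    """
    if not (curve.mu.min() - 5 * date.sigma <= date.age_14c <= curve.mu.max() + 5 * date.sigma):
        raise CalibrationRangeError(
            f"{date.age_14c} BP outside curve 14C range "
            f"[{curve.mu.min():.0f}, {curve.mu.max():.0f}]")
    grid = np.arange(np.ceil(curve.cal_bp.min()), np.floor(curve.cal_bp.max()) + 1.0)
    mu, sc = curve.interpolate(grid)
    var = date.sigma ** 2 + sc ** 2
    log_d = -0.5 * (date.age_14c - mu) ** 2 / var - 0.5 * np.log(var)
    log_d -= log_d.max()
    density = np.exp(log_d)
    density /= density.sum()
    hpd = {level: _hpd_ranges(grid, density, level, round_to) for level in levels}
    return CalibrationResult(date=date, grid=grid, density=density, hpd_ranges=hpd,
                             levels=tuple(levels), curve_name=curve.name)


def _hpd_ranges(grid: np.ndarray, density: np.ndarray, level: float,
                round_to: int) -> list[list[float]]:
    """Descending-density accumulation to ``level``; contiguous runs merged."""
    order = np.argsort(density)[::-1]
    cum = np.cumsum(density[order])
    n_in = int(np.searchsorted(cum, level) + 1)
    included = np.zeros(grid.size, dtype=bool)
    included[order[:n_in]] = True
    ranges: list[list[float]] = []
    idx = np.flatnonzero(included)
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            ranges.append([grid[prev], grid[start]])
            start = i
        prev = i
    ranges.append([grid[prev], grid[start]])
    # [older, younger] with cal BP ages: older = larger
    out = []
    for hi, lo in ranges:
        older, younger = max(hi, lo), min(hi, lo)
        if round_to:
            older = round(older / round_to) * round_to
            younger = round(younger / round_to) * round_to
        out.append([float(older), float(younger)])
    out.sort(key=lambda r: -r[0])
    return out
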