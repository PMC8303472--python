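"""Evaluation statistics: acquisition stability and expert agreement.

Two questions are answered here.  First, how stable is the normalized
calcium intensity across repeated acquisitions of the same patient under
different scanner settings (population SD of the per-acquisition values —
the dispersion of a fixed, fully observed set of acquisitions, hence
divisor n).  Second, how well does the white-pixel count agree with expert
planimetry of the same valves (Pearson product-moment correlation with the
two-sided t-test on r, t = r sqrt(n-2) / sqrt(1 - r^2)).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image import ValidationError

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "population_sd",
    "pearson",
    "acquisition_stability",
    "load_table1_stability",
    "load_table2_validation",
    "plot_agreement",
]


@dataclass(frozen=True)
class PairedSeries:
    """Per-patient (white-pixel count, planimetry area in cm^2) pairs."""

    labels: tuple[str, ...]
    x: np.ndarray  # white-pixel counts
    y: np.ndarray  # planimetry areas, cm^2

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(self.labels) == len(x) == len(y)):
            raise ValidationError("labels, x and y must have equal length")
        if len(x) < 3:
            raise ValidationError("need at least 3 pairs")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedSeries":
        """Read columns id, white_pixels, planimetry_cm2 from a CSV file."""
        df = pd.read_csv(path)
        missing = {"id", "white_pixels", "planimetry_cm2"} - set(df.columns)
        if missing:
            raise ValidationError(f"CSV missing columns: {sorted(missing)}")
        return cls(labels=tuple(df["id"].astype(str)),
                   x=df["white_pixels"].to_numpy(),
                   y=df["planimetry_cm2"].to_numpy())

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class AgreementResult:
    pearson_r: float
    r_squared: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"pearson_r": self.pearson_r, "r_squared": self.r_squared,
                "p_value": self.p_value, "n": self.n}


def population_sd(values, sample: bool = False) -> float:
    """Standard deviation with divisor n (``sample=True`` switches to n-1)."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("cannot take the SD of an empty list")
    if sample and arr.size < 2:
        raise ValidationError("sample SD needs at least 2 values")
    return float(np.std(arr, ddof=1 if sample else 0))


def pearson(series: PairedSeries) -> AgreementResult:
    """Product-moment correlation with the two-sided t-test p-value."""
    if np.ptp(series.x) == 0 or np.ptp(series.y) == 0:
        raise ValidationError("correlation undefined for a constant series")
    r, p = sps.pearsonr(series.x, series.y)
    return AgreementResult(pearson_r=float(r), r_squared=float(r) ** 2,
                           p_value=float(p), n=series.n)


def acquisition_stability(reports, statistic: str = "mean",
                          sample: bool = False) -> float:
    """Population SD of the normalized mean (or median) across acquisitions.

    ``reports`` may be CalciumReport objects or plain numbers.  Used to
    compare dark-ROI placements and the mean-vs-median summary choice: the
    smaller the SD, the more setting-invariant the normalization.
    """
    if statistic not in ("mean", "median"):
        raise ValidationError("statistic must be 'mean' or 'median'")
    values = []
    for rep in reports:
        if hasattr(rep, "normalized_mean"):
            v = rep.normalized_mean if statistic == "mean" else rep.normalized_median
            if v is None:
                raise ValidationError(
                    "cannot include an empty-mask report in a stability estimate")
        else:
            v = float(rep)
        values.append(v)
    if len(values) < 2:
        raise ValidationError("stability needs at least 2 reports")
    return population_sd(values, sample=sample)


def _data_path(name: str):
    return importlib.resources.files("echocalc.data").joinpath(name)


def load_table1_stability() -> pd.DataFrame:
    """Packaged fixture: 24 normalized mean/median values, 3 patients."""
    with importlib.resources.as_file(_data_path("table1_stability.csv")) as p:
        return pd.read_csv(p)


def load_table2_validation() -> pd.DataFrame:
    """Packaged fixture: 12-patient validation set (counts vs planimetry)."""
    with importlib.resources.as_file(_data_path("table2_validation.csv")) as p:
        return pd.read_csv(p)


def plot_agreement(series: PairedSeries, result: AgreementResult,
                   path: str | Path) -> None:
    """Scatter of planimetry (y) against white-pixel count (x) with LS line."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111)
    ax.scatter(series.x, series.y, color="tab:blue", zorder=3)
    slope, intercept = np.polyfit(series.x, series.y, 1)
    xs = np.linspace(series.x.min(), series.x.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="tab:red",
            label=f"r = {result.pearson_r:.2f}, n = {result.n}")
    ax.set_xlabel("Number of white pixels")
    ax.set_ylabel("Planimetry area (cm$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
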