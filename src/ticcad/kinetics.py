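"""Time-intensity-curve kinetics.

A lesion's enhancement trajectory is summarized by six semi-quantitative
parameters computed from the signal intensities :math:`SI_0` (pre-contrast)
through :math:`SI_{T-1}`:

* ``si_slope`` — late-phase slope
  :math:`100\\,(SI_{tail} - SI_{mean})/SI_{mean}` where
  :math:`SI_{mean} = (SI_1 + SI_2)/2` is the mean of the first two
  post-contrast phases and :math:`SI_{tail}` the last phase;
* ``msi`` — maximum slope of increase, the largest consecutive-phase
  difference :math:`\\max_i (SI_{i+1} - SI_i)` over :math:`i = 0..T-2`
  (the pre-to-first-post step included), in signal units;
* ``e_initial`` — initial enhancement :math:`100\\,(SI_1 - SI_0)/SI_0`;
* ``e_peak`` — peak enhancement :math:`100\\,(SI_{peak} - SI_0)/SI_0`, the
  peak searched over post-contrast phases only;
* ``eser`` — early signal enhancement ratio
  :math:`100\\,(SI_1 - SI_0)/(SI_2 - SI_0)`;
* ``sep`` — second enhancement percentage :math:`100\\,(SI_2 - SI_0)/SI_0`.

The late slope drives the standard three-way curve typing: persistent
enhancement (type I, slope >= +10%), plateau (type II, between -10% and
+10%), washout (type III, slope <= -10%), with both named bounds inclusive
at their own type.  Division guards yield NaN rather than raising;
region-level aggregation skips NaN per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .errors import FormatError
from .io import DceSeries, MaskImage

PARAM_NAMES = ("si_slope", "msi", "e_initial", "e_peak", "eser", "sep")

#: inclusive classification bounds on the late slope, in percent
SLOPE_LOWER_DEFAULT = -10.0
SLOPE_UPPER_DEFAULT = 10.0


@dataclass
class TimeCurve:
    """One signal-intensity trajectory (region mean or single pixel)."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 4:
            raise FormatError("curve needs at least 4 time points")
        if self.values.shape != self.times.shape:
            raise FormatError("curve values and times must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("curve contains non-finite values")

    @property
    def si_0(self) -> float:
        return float(self.values[0])

    @property
    def si_mean(self) -> float:
        """Mean of the first two post-contrast phases."""
        return float((self.values[1] + self.values[2]) / 2.0)

    @property
    def si_tail(self) -> float:
        return float(self.values[-1])

    @property
    def si_peak(self) -> float:
        """Maximum over post-contrast phases (baseline is not a candidate)."""
        return float(np.max(self.values[1:]))

    @property
    def peak_index(self) -> int:
        """Phase index of the (first) post-contrast peak."""
        return int(np.argmax(self.values[1:]) + 1)


@dataclass
class KineticParams:
    """The six semi-quantitative parameters plus the curve type.

    ``tic_type`` is ``"I"``, ``"II"``, ``"III"`` or ``None`` when the late
    slope is undefined.
    """

    si_slope: float
    msi: float
    e_initial: float
    e_peak: float
    eser: float
    sep: float
    tic_type: str | None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def si_slope(curve: TimeCurve) -> float:
    """Late-phase slope in percent; NaN when the early mean is zero."""
    m = curve.si_mean
    if m == 0:
        return math.nan
    return 100.0 * (curve.si_tail - m) / m


def classify_tic(
    slope: float,
    lower: float = SLOPE_LOWER_DEFAULT,
    upper: float = SLOPE_UPPER_DEFAULT,
) -> str | None:
    """Three-way curve typing from the late slope (bounds inclusive).

    Type I (persistent) iff ``slope >= upper``; type III (washout) iff
    ``slope <= lower``; type II (plateau) strictly in between.  Returns
    ``None`` for NaN input.
    """
    if slope is None or math.isnan(slope):
        return None
    if slope >= upper:
        return "I"
    if slope <= lower:
        return "III"
    return "II"


def msi(curve: TimeCurve) -> float:
    """Maximum consecutive-phase increase, in signal units (can be negative)."""
    return float(np.max(np.diff(curve.values)))


def e_initial(curve: TimeCurve) -> float:
    if curve.si_0 <= 0:
        return math.nan
    return 100.0 * (curve.values[1] - curve.si_0) / curve.si_0


def e_peak(curve: TimeCurve) -> float:
    if curve.si_0 <= 0:
        return math.nan
    return 100.0 * (curve.si_peak - curve.si_0) / curve.si_0


def eser(curve: TimeCurve) -> float:
    denom = curve.values[2] - curve.si_0
    if denom == 0:
        return math.nan
    return 100.0 * (curve.values[1] - curve.si_0) / denom


def sep(curve: TimeCurve) -> float:
    if curve.si_0 <= 0:
        return math.nan
    return 100.0 * (curve.values[2] - curve.si_0) / curve.si_0


def compute_params(
    curve: TimeCurve,
    slope_lower: float = SLOPE_LOWER_DEFAULT,
    slope_upper: float = SLOPE_UPPER_DEFAULT,
) -> KineticParams:
    """All six parameters plus the curve type; NaN-tolerant."""
    s = si_slope(curve)
    return KineticParams(
        si_slope=s,
        msi=msi(curve),
        e_initial=e_initial(curve),
        e_peak=e_peak(curve),
        eser=eser(curve),
        sep=sep(curve),
        tic_type=classify_tic(s, slope_lower, slope_upper),
    )


def extract_mean_curve(series: DceSeries, mask: MaskImage) -> TimeCurve:
    """Average the per-pixel curves over a mask."""
    if mask.data.shape != series.shape:
        raise FormatError("mask shape does not match series")
    if not mask.data.any():
        raise FormatError("cannot extract a curve from an empty mask")
    values = series.data[:, mask.data].mean(axis=1)
    return TimeCurve(values=values, times=series.times)


@dataclass
class ParametricMapSet:
    """Per-pixel parameter maps over a lesion plus their region means.

    ``maps`` holds one H×W float array per parameter with NaN outside the
    lesion and at pixels where the parameter is undefined.  ``region_means``
    averages each parameter over its defined pixels independently; its
    ``tic_type`` is the classification of the mean per-pixel slope.
    """

    maps: dict[str, np.ndarray]
    region_means: KineticParams
    lesion: MaskImage


def pixelwise_maps(
    series: DceSeries,
    lesion: MaskImage,
    slope_lower: float = SLOPE_LOWER_DEFAULT,
    slope_upper: float = SLOPE_UPPER_DEFAULT,
) -> ParametricMapSet:
    """Compute the six parameters for every lesion pixel.

    This is the region pathway: each pixel's curve is reduced to parameters
    first and the lesion mean is taken afterwards, which in general differs
    from parameters of the mean curve on heterogeneous lesions.
    """
    if lesion.data.shape != series.shape:
        raise FormatError("lesion mask shape does not match series")
    if not lesion.data.any():
        raise FormatError("lesion mask is empty")
    v = series.data[:, lesion.data]  # (T, n_pixels)
    si0 = v[0]
    si1, si2 = v[1], v[2]
    early_mean = (si1 + si2) / 2.0
    tail = v[-1]
    peak = v[1:].max(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope_px = np.where(early_mean != 0, 100.0 * (tail - early_mean) / early_mean, np.nan)
        ei_px = np.where(si0 > 0, 100.0 * (si1 - si0) / si0, np.nan)
        ep_px = np.where(si0 > 0, 100.0 * (peak - si0) / si0, np.nan)
        eser_px = np.where(si2 != si0, 100.0 * (si1 - si0) / (si2 - si0), np.nan)
        sep_px = np.where(si0 > 0, 100.0 * (si2 - si0) / si0, np.nan)
    msi_px = np.diff(v, axis=0).max(axis=0)

    per_pixel = {
        "si_slope": slope_px,
        "msi": msi_px,
        "e_initial": ei_px,
        "e_peak": ep_px,
        "eser": eser_px,
        "sep": sep_px,
    }
    h, w = series.shape
    maps = {}
    means = {}
    for name, vals in per_pixel.items():
        m = np.full((h, w), np.nan)
        m[lesion.data] = vals
        maps[name] = m
        defined = vals[np.isfinite(vals)]
        means[name] = float(defined.mean()) if defined.size else math.nan
    region = KineticParams(
        tic_type=classify_tic(means["si_slope"], slope_lower, slope_upper), **means
    )
    return ParametricMapSet(maps=maps, region_means=region, lesion=lesion)
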