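"""Digital DCE-MRI phantom: seeded synthetic cases and cohorts.

The generator emulates a single-slice breast protocol — one pre-contrast
acquisition plus eight post-contrast phases at 80 s spacing — with one
elliptical mass-like lesion on a mildly, slowly enhancing background.

Lesion kinetics are piecewise linear: baseline :math:`S_0` at t=0, a linear
wash-in to :math:`S_0(1+\\text{wash\\_in\\_fraction})` at ``t_peak``, then a
linear late segment whose slope is calibrated analytically so that the
late-phase slope statistic of the *sampled* curve equals a requested target
exactly.  This makes every downstream parameter closed-form invertible,
which is why linear segments are used rather than a pharmacokinetic model:
the curve-type classification only constrains the sampled values.

Within a curve archetype the late-slope target is drawn from a
class-conditional band — malignant lesions wash out faster than benign ones
of the same type — reflecting that the continuous slope carries diagnostic
information beyond the coarse I/II/III label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import FormatError
from .io import DceSeries, MaskImage, RoiPolygon
from .kinetics import TimeCurve, classify_tic, si_slope
from .evaluation import BENIGN, MALIGNANT

DEFAULT_TIMES = 80.0 * np.arange(9)

#: per-class archetype probabilities (I, II, III)
DEFAULT_MIX = {
    BENIGN: (0.75, 0.20, 0.05),
    MALIGNANT: (0.15, 0.35, 0.50),
}

#: late-slope target bands (percent), class-conditional within archetype:
#: malignant lesions sit at the washout-ward end of each type's range
SLOPE_BANDS = {
    (BENIGN, "I"): (20.0, 45.0),
    (BENIGN, "II"): (-5.0, 9.0),
    (BENIGN, "III"): (-20.0, -10.0),
    (MALIGNANT, "I"): (10.0, 25.0),
    (MALIGNANT, "II"): (-9.0, 5.0),
    (MALIGNANT, "III"): (-45.0, -15.0),
}

#: wash-in fraction range (peak enhancement as a fraction of baseline)
WASH_IN_RANGE = (0.7, 1.3)


@dataclass
class LesionKineticSpec:
    """Noise-free kinetic prescription for one lesion.

    ``late_slope_target`` is the late-phase slope (percent) the sampled
    curve must attain exactly; it must be consistent with ``archetype``
    under the ±10 typing rule.
    """

    archetype: str
    late_slope_target: float
    baseline: float = 100.0
    wash_in_fraction: float = 1.0
    t_peak: float = 80.0

    def __post_init__(self) -> None:
        if self.archetype not in ("I", "II", "III"):
            raise FormatError(f"archetype must be I/II/III, got {self.archetype!r}")
        if self.baseline <= 0:
            raise FormatError("baseline must be positive")
        if classify_tic(self.late_slope_target) != self.archetype:
            raise FormatError(
                f"late_slope_target {self.late_slope_target} classifies as "
                f"{classify_tic(self.late_slope_target)}, not {self.archetype}"
            )


@dataclass
class PhantomSpec:
    """Geometry and noise for one simulated case.

    ``center``/``semi_axes``/``theta`` may be left ``None`` to be drawn at
    simulation time (semi-axes uniform in 3–12 px, any orientation, center
    placed so the lesion keeps a ≥4 px margin).  ``sigma`` is the noise
    standard deviation as a fraction of the lesion baseline; ``jitter`` the
    half-width of the per-pixel multiplicative lesion inhomogeneity.
    """

    shape: tuple[int, int] = (64, 64)
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] | None = None
    theta: float | None = None
    background_baseline: float = 100.0
    background_fraction: float = 0.2
    noise: str = "gaussian"
    sigma: float = 0.05
    jitter: float = 0.05
    times: np.ndarray = None

    def __post_init__(self) -> None:
        if self.times is None:
            self.times = DEFAULT_TIMES.copy()
        self.times = np.asarray(self.times, dtype=float)
        if self.sigma < 0 or self.jitter < 0:
            raise FormatError("sigma and jitter must be non-negative")
        if self.noise not in ("gaussian", "rician"):
            raise FormatError("noise must be 'gaussian' or 'rician'")


@dataclass
class SimulatedCase:
    """One phantom case with its ground truth."""

    series: DceSeries
    lesion_mask: MaskImage
    roi: RoiPolygon
    label: str
    archetype: str
    pspec: PhantomSpec
    kspec: LesionKineticSpec


def kinetic_curve(spec: LesionKineticSpec, times: np.ndarray = None) -> TimeCurve:
    """Noise-free lesion curve sampled at ``times``.

    The late segment's slope ``m`` is solved from the linear calibration
    equation tail = (1 + target/100) · mean(post1, post2), every sample
    being affine in ``m``.
    """
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    if len(times) < 4:
        raise FormatError("need at least 4 sample times")
    tp = spec.t_peak
    if not 0 < tp < times[-1]:
        raise FormatError(f"t_peak {tp} must lie strictly inside (0, {times[-1]})")
    s0 = spec.baseline
    sp = s0 * (1.0 + spec.wash_in_fraction)
    a = np.where(times <= tp, s0 + (sp - s0) * times / tp, sp)
    b = np.maximum(times - tp, 0.0)
    r = spec.late_slope_target / 100.0
    # solve a[-1] + m b[-1] = (1+r) * (a1+a2 + m (b1+b2)) / 2
    num = (1.0 + r) * (a[1] + a[2]) / 2.0 - a[-1]
    den = b[-1] - (1.0 + r) * (b[1] + b[2]) / 2.0
    if abs(den) < 1e-12:
        raise FormatError("infeasible calibration: no late segment to adjust")
    m = num / den
    return TimeCurve(values=a + m * b, times=times)


def background_curve(pspec: PhantomSpec) -> np.ndarray:
    """Mild linear background enhancement up to ``background_fraction``."""
    t = pspec.times
    return pspec.background_baseline * (1.0 + pspec.background_fraction * t / t[-1])


def _resolve_geometry(pspec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    h, w = pspec.shape
    axes = pspec.semi_axes
    if axes is None:
        axes = tuple(rng.uniform(3.0, 12.0, size=2))
    margin = max(axes) + 4.0
    if 2 * margin >= min(h, w):
        raise FormatError("lesion does not fit inside the image with a 4-px margin")
    center = pspec.center
    if center is None:
        center = (
            float(rng.uniform(margin, h - 1 - margin)),
            float(rng.uniform(margin, w - 1 - margin)),
        )
    theta = pspec.theta
    if theta is None:
        theta = float(rng.uniform(0.0, math.pi))
    return replace(pspec, center=center, semi_axes=tuple(map(float, axes)), theta=theta)


def _ellipse_mask(shape, center, semi_axes, theta, grow: float = 0.0) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    a, b = semi_axes[0] + grow, semi_axes[1] + grow
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def ellipse_roi_polygon(pspec: PhantomSpec, grow: float = 4.0, n_vertices: int = 32) -> RoiPolygon:
    """Polygonal ROI tracing the truth ellipse grown by ``grow`` pixels."""
    a, b = pspec.semi_axes
    theta = pspec.theta
    cr, cc = pspec.center
    phi = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    u = (a + grow) * np.cos(phi)
    v = (b + grow) * np.sin(phi)
    r = cr + u * math.cos(theta) - v * math.sin(theta)
    c = cc + u * math.sin(theta) + v * math.cos(theta)
    h, w = pspec.shape
    verts = np.column_stack([np.clip(r, 0, h - 1), np.clip(c, 0, w - 1)])
    return RoiPolygon(verts)


def simulate_case(
    pspec: PhantomSpec,
    kspec: LesionKineticSpec,
    seed: int,
    label: str | None = None,
    case_id: str = "",
) -> SimulatedCase:
    """Render one case: background + jittered lesion curve + noise.

    Deterministic for a fixed seed; the draw order is geometry, per-pixel
    jitter, then noise, so changing ``sigma`` alone never changes the truth
    mask or labels.
    """
    rng = np.random.default_rng(seed)
    pspec = _resolve_geometry(pspec, rng)
    h, w = pspec.shape
    times = pspec.times
    lesion = _ellipse_mask(pspec.shape, pspec.center, pspec.semi_axes, pspec.theta)
    curve = kinetic_curve(kspec, times)
    bg = background_curve(pspec)
    data = np.broadcast_to(bg[:, None, None], (len(times), h, w)).copy()
    n_lesion = int(lesion.sum())
    delta = rng.uniform(-pspec.jitter, pspec.jitter, size=n_lesion)
    data[:, lesion] = curve.values[:, None] * (1.0 + delta[None, :])
    if pspec.sigma > 0:
        scale = pspec.sigma * kspec.baseline
        if pspec.noise == "gaussian":
            data = data + rng.normal(0.0, scale, size=data.shape)
        else:  # rician magnitude noise
            n1 = rng.normal(0.0, scale, size=data.shape)
            n2 = rng.normal(0.0, scale, size=data.shape)
            data = np.sqrt((data + n1) ** 2 + n2**2)
    series = DceSeries(data=data, times=times, case_id=case_id)
    if label is None:
        label = BENIGN if kspec.archetype == "I" else MALIGNANT
    return SimulatedCase(
        series=series,
        lesion_mask=MaskImage(lesion, kind="lesion"),
        roi=ellipse_roi_polygon(pspec),
        label=label,
        archetype=kspec.archetype,
        pspec=pspec,
        kspec=kspec,
    )


def simulate_cohort(
    n_benign: int,
    n_malignant: int,
    mix: dict | None = None,
    seed: int = 0,
    pspec: PhantomSpec | None = None,
) -> list[SimulatedCase]:
    """Simulate an independent seeded case list for a two-class cohort.

    ``mix`` maps each class to (P(I), P(II), P(III)); per-case seeds are
    drawn up front from one root generator so cases are reproducible and
    order-independent of downstream consumption.
    """
    if n_benign < 1 or n_malignant < 1:
        raise FormatError("need at least one case per class")
    mix = DEFAULT_MIX if mix is None else mix
    for label, probs in mix.items():
        if abs(sum(probs) - 1.0) > 1e-9:
            raise FormatError(f"archetype mix for {label} does not sum to 1")
    base = pspec or PhantomSpec()
    rng = np.random.default_rng(seed)
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant
    case_seeds = rng.integers(0, 2**31, size=len(labels))
    archetypes = []
    kspecs = []
    for label in labels:
        arch = ("I", "II", "III")[rng.choice(3, p=mix[label])]
        lo, hi = SLOPE_BANDS[(label, arch)]
        target = float(rng.uniform(lo, hi))
        wash_in = float(rng.uniform(*WASH_IN_RANGE))
        archetypes.append(arch)
        kspecs.append(
            LesionKineticSpec(
                archetype=arch,
                late_slope_target=target,
                baseline=base.background_baseline,
                wash_in_fraction=wash_in,
            )
        )
    cases = []
    for i, (label, arch, ks) in enumerate(zip(labels, archetypes, kspecs)):
        cases.append(
            simulate_case(
                base,
                ks,
                seed=int(case_seeds[i]),
                label=label,
                case_id=f"case{i:04d}",
            )
        )
    return cases
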