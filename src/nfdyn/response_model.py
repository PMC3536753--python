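"""Phenomenological ground-truth model of single-cell NF-κB nuclear localization.

The measured quantity throughout the package is the relative nuclear
localization of a p65 fluorescent reporter: mean nuclear intensity divided by
the pre-stimulus mean cytoplasmic intensity.  This module generates plausible
single-cell time courses of that quantity, together with the population
structure observed for different LPS preparations: a Hill-shaped fraction of
responding cells versus concentration, lognormal cell-to-cell heterogeneity,
a mixture of transient / persistent / secondary-activation responder classes,
and a soluble-TNF-receptor (sTNFRII) modifier that suppresses the persistent
class.

The single-cell trace is a gamma-shaped pulse plus an optional saturating
plateau (persistent cells) and an optional delayed secondary activation::

    I(t) = b                                              for t < 0
    I(t) = b + A * (t/tau)^s * exp(s * (1 - t/tau))       primary pulse
             + P * (1 - exp(-t / tau_p))                  plateau
             + A2 * r(t - t2) * exp(-(t - t2) / lam)      secondary, t >= t2

where ``r(u) = 1 - exp(-u / 5 min)`` is a fast rise keeping the trace
continuous at the secondary onset.  The primary pulse attains its maximum
``b + A`` exactly at ``t = tau`` whenever ``P = A2 = 0``; the shape parameter
``s`` controls the width at half maximum independently of ``tau``.

Three preparation presets (Sigma, EB, UP) ship with the package; their central
parameters encode the cross-preparation population statistics reported for
these LPS sources (relative peak amplitudes, time-to-peak ratios and series,
peak-width ratios, and potency windows).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "ResponderClass",
    "PulseParams",
    "HeterogeneityParams",
    "DoseModel",
    "ClassEffects",
    "StnfrModifier",
    "PreparationPreset",
    "SimulatedCell",
    "pulse_value",
    "pulse_width_at_half_max",
    "solve_shape_for_width",
    "activation_probability",
    "sample_cell",
    "sample_population",
    "load_presets",
    "default_presets",
    "default_time_grid",
]

#: Rise time (minutes) of the fast saturation that makes the secondary
#: activation term continuous at its onset.
SECONDARY_RISE_MIN = 5.0

PRESET_SCHEMA_VERSION = 1


class ResponderClass(str, enum.Enum):
    INACTIVE = "inactive"
    TRANSIENT = "transient"
    PERSISTENT = "persistent"
    SECONDARY = "secondary"


@dataclass(frozen=True)
class PulseParams:
    """Parameters of one cell's normalized nuclear-localization time course.

    All times are minutes, all intensities dimensionless (normalized to the
    pre-stimulus cytoplasmic mean).
    """

    baseline: float
    amplitude: float
    time_to_peak: float
    shape: float
    plateau_amp: float = 0.0
    plateau_rise: float = 150.0
    secondary_amp: float = 0.0
    secondary_time: float = 0.0
    secondary_decay: float = 60.0
    responder_class: ResponderClass = ResponderClass.TRANSIENT

    def __post_init__(self) -> None:
        if not (self.baseline >= 0 and np.isfinite(self.baseline)):
            raise ValueError(f"baseline must be finite and >= 0, got {self.baseline}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.time_to_peak > 0:
            raise ValueError(f"time_to_peak must be > 0, got {self.time_to_peak}")
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if self.plateau_amp < 0 or self.secondary_amp < 0:
            raise ValueError("plateau_amp and secondary_amp must be >= 0")
        if not self.plateau_rise > 0 or not self.secondary_decay > 0:
            raise ValueError("plateau_rise and secondary_decay must be > 0")
        if self.responder_class is ResponderClass.INACTIVE and (
            self.amplitude != 0 or self.plateau_amp != 0 or self.secondary_amp != 0
        ):
            raise ValueError("inactive cells must have A = P = A2 = 0")


@dataclass(frozen=True)
class HeterogeneityParams:
    """Lognormal cell-to-cell variability and responder-class mixture.

    CVs are coefficients of variation of mean-preserving lognormal factors
    applied to the central amplitude, time-to-peak, and baseline.  ``class_mix``
    gives the probabilities of the transient / persistent / secondary classes
    among *active* cells and must sum to 1.
    """

    cv_amplitude: float = 0.25
    cv_time_to_peak: float = 0.25
    cv_baseline: float = 0.05
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"transient": 0.5, "persistent": 0.5, "secondary": 0.0}
    )

    def __post_init__(self) -> None:
        for name in ("cv_amplitude", "cv_time_to_peak", "cv_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mix = dict(self.class_mix)
        unknown = set(mix) - {"transient", "persistent", "secondary"}
        if unknown:
            raise ValueError(f"unknown responder classes in class_mix: {sorted(unknown)}")
        probs = np.array([mix.get(k, 0.0) for k in ("transient", "persistent", "secondary")])
        if np.any(probs < 0) or np.any(probs > 1) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix must be probabilities summing to 1, got {mix}")
        object.__setattr__(self, "class_mix", mix)


@dataclass(frozen=True)
class DoseModel:
    """Hill-shaped fraction of activated cells versus ligand concentration."""

    pmax: float
    K: float  # half-activation concentration, µg/mL
    h: float  # Hill coefficient

    def __post_init__(self) -> None:
        if not 0.0 <= self.pmax <= 1.0:
            raise ValueError(f"pmax must be in [0, 1], got {self.pmax}")
        if not self.K > 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not self.h > 0:
            raise ValueError(f"Hill coefficient must be > 0, got {self.h}")


@dataclass(frozen=True)
class ClassEffects:
    """How responder classes modify the central pulse when a cell is sampled.

    Persistent cells gain a plateau ``P = plateau_frac * A`` rising with time
    constant ``plateau_rise``; secondary-activation cells gain a delayed pulse
    of amplitude ``secondary_frac * A`` starting ``secondary_delay`` minutes
    after the primary peak and decaying with ``secondary_decay``.
    """

    plateau_frac: float = 0.2
    plateau_rise: float = 150.0
    secondary_frac: float = 0.8
    secondary_delay: float = 180.0
    secondary_decay: float = 60.0


@dataclass(frozen=True)
class StnfrModifier:
    """Effect of soluble TNF receptor (paracrine TNF blocking) on sampling.

    Multiplies the persistent-class probability (renormalized afterwards) and
    the plateau amplitude of cells that still come out persistent.
    """

    persistent_prob_factor: float = 0.1
    plateau_amp_factor: float = 0.2


@dataclass(frozen=True)
class AnchoredCurve:
    """Piecewise log-linear interpolation of a parameter vs concentration.

    Anchors are (concentration µg/mL, value) pairs; interpolation is linear in
    log10(concentration), flat beyond the outermost anchors.
    """

    anchors: tuple[tuple[float, float], ...]

    def __call__(self, conc: float) -> float:
        pts = sorted(self.anchors)
        if len(pts) == 1 or conc <= 0:
            return pts[0][1] if len(pts) == 1 else pts[0][1]
        xs = np.log10([p[0] for p in pts])
        ys = [p[1] for p in pts]
        return float(np.interp(np.log10(conc), xs, ys))


@dataclass(frozen=True)
class PreparationPreset:
    """An LPS preparation: dose–response, central pulse vs concentration,
    heterogeneity, and sTNFRII modifier."""

    name: str
    dose_model: DoseModel
    baseline: float
    amplitude: AnchoredCurve
    time_to_peak: AnchoredCurve
    peak_width: AnchoredCurve
    heterogeneity: HeterogeneityParams
    class_effects: ClassEffects = ClassEffects()
    stnfr_modifier: StnfrModifier = StnfrModifier()

    def central_pulse(self, conc: float) -> PulseParams:
        """Central (noise-free) pulse parameters at a given concentration."""
        tau = self.time_to_peak(conc)
        width = self.peak_width(conc)
        s = solve_shape_for_width(tau, width)
        return PulseParams(
            baseline=self.baseline,
            amplitude=self.amplitude(conc),
            time_to_peak=tau,
            shape=s,
        )

    def pulse_table(self, concentrations: Sequence[float]) -> dict[float, PulseParams]:
        """Mapping concentration -> central PulseParams on a given grid."""
        return {c: self.central_pulse(c) for c in concentrations}


@dataclass
class SimulatedCell:
    """One sampled cell: ground-truth parameters, trace, features, geometry.

    ``true_features`` is filled by the trace-featurization code so that the
    generator and the measurement share a single definition of peak amplitude,
    time-to-peak and width.  Motion path and nucleus geometry are assigned when
    the cell is placed into a movie.
    """

    cell_id: int
    responder_class: ResponderClass
    params: PulseParams
    time_grid: np.ndarray  # minutes relative to stimulation
    true_trace: np.ndarray
    true_features: "object | None" = None  # features.TraceFeatures, set lazily
    path: np.ndarray | None = None  # (T, 2) centroid row/col per frame
    semi_axes: tuple[float, float] | None = None  # (a, b) pixels
    orientation: float | None = None  # radians

    @property
    def active(self) -> bool:
        return self.responder_class is not ResponderClass.INACTIVE


# ---------------------------------------------------------------------------
# Trace model analytics


def pulse_value(params: PulseParams, t) -> np.ndarray | float:
    """Evaluate the normalized nuclear-localization model at time(s) ``t``.

    ``t`` is minutes relative to stimulation and may be negative (pre-stimulus,
    where the trace equals the baseline).  Continuous in ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    out = np.full(t_arr.shape, params.baseline, dtype=float)
    pos = t_arr >= 0
    if np.any(pos):
        tp = t_arr[pos]
        x = tp / params.time_to_peak
        # log-space evaluation avoids overflow of x**s for large s
        with np.errstate(divide="ignore", invalid="ignore"):
            logg = params.shape * (np.log(x) + 1.0 - x)
        g = np.where(x > 0, np.exp(logg), 0.0)
        v = params.baseline + params.amplitude * g
        v = v + params.plateau_amp * (1.0 - np.exp(-tp / params.plateau_rise))
        if params.secondary_amp > 0:
            u = tp - params.secondary_time
            u = np.maximum(u, 0.0)
            rise = 1.0 - np.exp(-u / SECONDARY_RISE_MIN)
            v = v + params.secondary_amp * rise * np.exp(-u / params.secondary_decay)
        out[pos] = v
    return out if np.ndim(t) else float(out)


def pulse_width_at_half_max(tau: float, s: float) -> float:
    """Analytic width at half maximum of the pure pulse (P = A2 = 0).

    The pulse crosses half of its maximum at ``t = tau * x`` where
    ``ln x + 1 - x = -ln 2 / s``; the two roots come from the two real
    branches of the Lambert W function, and the width scales linearly in tau.
    """
    if not (tau > 0 and s > 0):
        raise ValueError("tau and s must be > 0")
    c = -math.log(2.0) / s
    z = -math.exp(c - 1.0)
    x_lo = -lambertw(z, 0).real
    x_hi = -lambertw(z, -1).real
    return tau * (x_hi - x_lo)


_SHAPE_LO, _SHAPE_HI = 1e-4, 1e6


def solve_shape_for_width(tau: float, target_width: float) -> float:
    """Find the shape ``s`` giving a pure pulse the requested half-max width.

    Width is monotone decreasing in ``s`` at fixed ``tau``; the root is
    bracketed and solved by bisection to within 0.1 min.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if not target_width > 0:
        raise ValueError("target_width must be > 0")
    w_lo = pulse_width_at_half_max(tau, _SHAPE_HI)  # narrowest
    w_hi = pulse_width_at_half_max(tau, _SHAPE_LO)  # widest
    if not (w_lo <= target_width <= w_hi):
        raise ValueError(
            f"target_width {target_width:g} min not achievable at tau={tau:g}; "
            f"feasible range is [{w_lo:.3g}, {w_hi:.3g}] min"
        )
    return float(
        brentq(
            lambda s: pulse_width_at_half_max(tau, s) - target_width,
            _SHAPE_LO,
            _SHAPE_HI,
            xtol=1e-10,
            rtol=1e-12,
            maxiter=200,
        )
    )


def activation_probability(dose: DoseModel, conc: float) -> float:
    """Hill activation probability pmax * c^h / (c^h + K^h); 0 at c = 0."""
    if not np.isfinite(conc) or conc < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {conc}")
    if conc == 0:
        return 0.0
    # evaluate via the ratio (K/c)^h for numerical stability over nine decades
    return dose.pmax / (1.0 + (dose.K / conc) ** dose.h)


# ---------------------------------------------------------------------------
# Sampling


def default_time_grid(
    n_frames: int = 120, dt: float = 5.0, stim_frame: int = 3
) -> np.ndarray:
    """Movie acquisition times in minutes relative to stimulation."""
    return (np.arange(n_frames) - stim_frame) * dt


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplicative factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def sample_cell(
    preset: PreparationPreset,
    conc: float,
    stnfr: bool,
    rng: np.random.Generator | int,
    time_grid: np.ndarray | None = None,
    cell_id: int = 0,
) -> SimulatedCell:
    """Draw one cell's ground truth at a given concentration.

    The activity draw is Bernoulli with the preset's Hill probability; active
    cells draw a responder class from the heterogeneity mixture (persistent
    probability multiplied by the sTNFRII factor and renormalized when
    ``stnfr`` is on), then lognormally perturb the central amplitude,
    time-to-peak and baseline.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if time_grid is None:
        time_grid = default_time_grid()
    time_grid = np.asarray(time_grid, dtype=float)

    het = preset.heterogeneity
    eff = preset.class_effects
    p_act = activation_probability(preset.dose_model, conc)
    active = rng.random() < p_act

    central = preset.central_pulse(conc)
    b = central.baseline * _lognormal_factor(rng, het.cv_baseline)

    if not active:
        params = PulseParams(
            baseline=b,
            amplitude=0.0,
            time_to_peak=central.time_to_peak,
            shape=central.shape,
            responder_class=ResponderClass.INACTIVE,
        )
        cls = ResponderClass.INACTIVE
    else:
        mix = dict(het.class_mix)
        if stnfr:
            mix["persistent"] = mix.get("persistent", 0.0) * preset.stnfr_modifier.persistent_prob_factor
            total = sum(mix.values())
            if total == 0:
                mix = {"transient": 1.0, "persistent": 0.0, "secondary": 0.0}
            else:
                mix = {k: v / total for k, v in mix.items()}
        names = ("transient", "persistent", "secondary")
        probs = np.array([mix.get(k, 0.0) for k in names])
        cls = ResponderClass(names[rng.choice(len(names), p=probs / probs.sum())])

        A = central.amplitude * _lognormal_factor(rng, het.cv_amplitude)
        tau = central.time_to_peak * _lognormal_factor(rng, het.cv_time_to_peak)
        kwargs: dict = {}
        if cls is ResponderClass.PERSISTENT:
            plateau = eff.plateau_frac * A
            if stnfr:
                plateau *= preset.stnfr_modifier.plateau_amp_factor
            kwargs.update(plateau_amp=plateau, plateau_rise=eff.plateau_rise)
        elif cls is ResponderClass.SECONDARY:
            kwargs.update(
                secondary_amp=eff.secondary_frac * A,
                secondary_time=tau + eff.secondary_delay,
                secondary_decay=eff.secondary_decay,
            )
        params = PulseParams(
            baseline=b,
            amplitude=A,
            time_to_peak=tau,
            shape=central.shape,
            responder_class=cls,
            **kwargs,
        )

    trace = pulse_value(params, time_grid)
    cell = SimulatedCell(
        cell_id=cell_id,
        responder_class=cls,
        params=params,
        time_grid=time_grid,
        true_trace=np.asarray(trace, dtype=float),
    )
    _attach_true_features(cell)
    return cell


def _attach_true_features(cell: SimulatedCell) -> None:
    """Compute true features from the true trace via the measurement code."""
    from . import features as _features  # deferred: features imports nothing from here

    trace = _features.Trace(
        track_id=cell.cell_id,
        time=cell.time_grid,
        values=cell.true_trace,
        valid=np.ones_like(cell.true_trace, dtype=bool),
    )
    if cell.active:
        feats = _features.peak_features(trace)
        feats = replace(
            feats,
            active=True,
            n_secondary=_features.count_secondary_peaks(trace),
        )
    else:
        feats = _features.TraceFeatures(
            active=False,
            baseline=float(np.mean(cell.true_trace[cell.time_grid < 0])),
            peak_amp=float("nan"),
            time_to_peak=float("nan"),
            peak_width=float("nan"),
            width_censored=False,
            n_secondary=0,
        )
    cell.true_features = feats


def sample_population(
    preset: PreparationPreset,
    conc: float,
    stnfr: bool,
    n_cells: int,
    rng: np.random.Generator | int,
    time_grid: np.ndarray | None = None,
) -> list[SimulatedCell]:
    """Draw ``n_cells`` independent cells for one experimental condition."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return [
        sample_cell(preset, conc, stnfr, rng, time_grid=time_grid, cell_id=i)
        for i in range(n_cells)
    ]


# ---------------------------------------------------------------------------
# Shipped presets


def _curve_from_config(node) -> AnchoredCurve:
    if isinstance(node, (int, float)):
        return AnchoredCurve(anchors=((1.0, float(node)),))
    return AnchoredCurve(anchors=tuple((float(c), float(v)) for c, v in node))


def load_presets(path=None) -> dict[str, PreparationPreset]:
    """Load preparation presets from YAML (the packaged file by default)."""
    if path is None:
        text = resources.files("nfdyn").joinpath("presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if cfg.get("schema_version") != PRESET_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported preset schema version {cfg.get('schema_version')!r}; "
            f"expected {PRESET_SCHEMA_VERSION}"
        )
    presets: dict[str, PreparationPreset] = {}
    for name, node in cfg["presets"].items():
        presets[name] = PreparationPreset(
            name=name,
            dose_model=DoseModel(**node["dose_model"]),
            baseline=float(node["baseline"]),
            amplitude=_curve_from_config(node["amplitude"]),
            time_to_peak=_curve_from_config(node["time_to_peak"]),
            peak_width=_curve_from_config(node["peak_width"]),
            heterogeneity=HeterogeneityParams(**node.get("heterogeneity", {})),
            class_effects=ClassEffects(**node.get("class_effects", {})),
            stnfr_modifier=StnfrModifier(**node.get("stnfr_modifier", {})),
        )
    return presets


_DEFAULT_PRESETS: dict[str, PreparationPreset] | None = None


def default_presets() -> dict[str, PreparationPreset]:
    """The three shipped LPS preparation presets (Sigma, EB, UP), cached."""
    global _DEFAULT_PRESETS
    if _DEFAULT_PRESETS is None:
        _DEFAULT_PRESETS = load_presets()
    return _DEFAULT_PRESETS
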