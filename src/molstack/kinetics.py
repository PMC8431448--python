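"""Aggregation-kinetics curve fitting and inhibition-potency statistics.

ThT-style fluorescence traces are fitted with a four-parameter logistic,

    F(t) = baseline + amplitude / (1 + exp(-rate * (t - t_half))),

from which the lag time follows as ``t_half - 2/rate``. Inhibition potency
of a compound at a dose is summarised by the *relative concentration*:
the dose (mM) divided by the percent inhibition of the endpoint signal,
i.e. the millimolar concentration needed per 1% inhibition — lower values
mean a more potent inhibitor. Percent inhibition is read at a fixed
endpoint (default 1000 min) on baseline-subtracted, replicate-averaged
curves; negative values (signal above control) flag aggregation
accelerators, for which the relative concentration is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import MolstackError


@dataclass
class KineticCurve:
    """One fluorescence time series for one well/condition."""

    times: np.ndarray          # minutes, strictly increasing
    signal: np.ndarray         # fluorescence, arbitrary units
    compound: str = ""
    concentration: float = 0.0  # mM
    replicate_id: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise MolstackError("times and signal must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise MolstackError("times must be strictly increasing")

    @property
    def label(self) -> tuple[str, float]:
        return (self.compound, self.concentration)


def logistic(t, baseline, amplitude, rate, t_half):
    return baseline + amplitude / (1.0 + np.exp(-rate * (t - t_half)))


@dataclass
class SigmoidFit:
    baseline: float
    amplitude: float
    rate: float           # 1/min
    t_half: float         # min
    lag_time: float | None  # min; None when undefined (flat curve, bad fit)
    rss: float
    converged: bool
    message: str = ""

    def __call__(self, t):
        return logistic(np.asarray(t, dtype=float), self.baseline,
                        self.amplitude, self.rate, self.t_half)


def fit_sigmoid(curve: KineticCurve, model: str = "logistic") -> SigmoidFit:
    """Least-squares sigmoid fit of one curve.

    ``model`` is ``"logistic"`` (default) or ``"gompertz"``. Non-convergence
    is reported in the returned record (``converged=False`` with the
    initial-guess residual), never raised.
    """
    if curve.times.size < 6:
        raise MolstackError("sigmoid fit needs >= 6 time points")
    t, y = curve.times, curve.signal
    span = float(y.max() - y.min())
    t_range = float(t[-1] - t[0])
    p0 = [float(y.min()), max(span, 1e-6), 4.0 / max(t_range / 4.0, 1e-6),
          float(t[np.argmin(np.abs(y - (y.min() + span / 2.0)))])]
    if model == "gompertz":
        def func(tt, baseline, amplitude, rate, t_half):
            return baseline + amplitude * np.exp(-np.exp(-rate * (tt - t_half)))
    elif model == "logistic":
        func = logistic
    else:
        raise MolstackError(f"unknown sigmoid model {model!r}")
    bounds = ([-np.inf, 0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(func, t, y, p0=p0, bounds=bounds, maxfev=20000)
        converged, message = True, ""
    except (RuntimeError, ValueError) as exc:
        popt, converged, message = p0, False, str(exc)
    baseline, amplitude, rate, t_half = (float(v) for v in popt)
    rss = float(np.sum((y - func(t, *popt)) ** 2))
    flat = amplitude < 0.01 * max(span, 1e-12) or amplitude < 1e-9
    lag = None if (flat or not converged) else t_half - 2.0 / rate
    return SigmoidFit(baseline=baseline, amplitude=amplitude, rate=rate,
                      t_half=t_half, lag_time=lag, rss=rss,
                      converged=converged, message=message)


def _baseline_value(curve: KineticCurve, mode: str) -> float:
    if mode == "first":
        return float(curve.signal[0])
    if mode == "fit":
        fit = fit_sigmoid(curve)
        return fit.baseline if fit.converged else float(curve.signal[0])
    if mode == "none":
        return 0.0
    raise MolstackError(f"unknown baseline mode {mode!r}")


def endpoint_signal(curve: KineticCurve, endpoint: float,
                    baseline: str = "fit") -> float:
    """Baseline-subtracted signal at the endpoint, linearly interpolated
    between the two bracketing samples."""
    if not curve.times[0] <= endpoint <= curve.times[-1]:
        raise MolstackError(
            f"endpoint {endpoint} min outside curve span "
            f"[{curve.times[0]}, {curve.times[-1]}]")
    value = float(np.interp(endpoint, curve.times, curve.signal))
    return value - _baseline_value(curve, baseline)


def percent_inhibition(treated: KineticCurve, control: KineticCurve,
                       endpoint: float = 1000.0, baseline: str = "fit") -> float:
    """100 × (1 − treated/control) at the endpoint, both baseline-subtracted.

    Negative values mean the treated signal exceeds the control —
    aggregation acceleration, not inhibition.
    """
    control_value = endpoint_signal(control, endpoint, baseline)
    treated_value = endpoint_signal(treated, endpoint, baseline)
    # a flat control leaves only numerical residue after baseline subtraction
    scale = max(float(np.ptp(control.signal)), 1.0)
    if control_value <= 1e-6 * scale:
        raise MolstackError(
            f"control endpoint signal {control_value:g} <= 0 after baseline "
            "subtraction; inhibition undefined")
    return 100.0 * (1.0 - treated_value / control_value)


@dataclass(frozen=True)
class PotencyResult:
    """Relative concentration: mM of compound per 1% endpoint inhibition."""

    compound: str
    concentration: float          # mM
    percent_inhibition: float     # at endpoint
    relative_concentration: float | None  # mM per 1% inhibition; None if not an inhibitor
    endpoint: float               # minutes
    inhibition_sd: float | None = None

    @property
    def is_inhibitor(self) -> bool:
        return self.relative_concentration is not None


def relative_concentration(concentration: float, inhibition: float) -> float | None:
    """Dose (mM) per 1% inhibition; ``None`` flags a non-inhibitor."""
    if concentration <= 0:
        raise MolstackError("concentration must be > 0")
    if inhibition <= 0:
        return None
    return concentration / inhibition


def _average_curve(curves: list[KineticCurve]) -> KineticCurve:
    times = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, times):
            raise MolstackError("replicates must share one time grid to be averaged")
    return KineticCurve(times=times,
                        signal=np.mean([c.signal for c in curves], axis=0),
                        compound=curves[0].compound,
                        concentration=curves[0].concentration)


def group_by_label(curves: list[KineticCurve]) -> dict[tuple[str, float], list[KineticCurve]]:
    groups: dict[tuple[str, float], list[KineticCurve]] = {}
    for c in curves:
        groups.setdefault(c.label, []).append(c)
    return groups


def potency_table(curves: list[KineticCurve], control_label: str = "control",
                  endpoint: float = 1000.0, baseline: str = "fit") -> list[PotencyResult]:
    """Per (compound, dose) potency vs the replicate-averaged control.

    Replicates are averaged before the endpoint read; the spread of
    per-replicate inhibition values is reported as ``inhibition_sd``.
    """
    groups = group_by_label(curves)
    control_groups = [g for (name, _), g in groups.items() if name == control_label]
    if not control_groups:
        raise MolstackError(f"no control curves labelled {control_label!r}")
    control = _average_curve([c for g in control_groups for c in g])
    results = []
    for (name, dose), group in sorted(groups.items()):
        if name == control_label:
            continue
        mean_inh = percent_inhibition(_average_curve(group), control,
                                      endpoint=endpoint, baseline=baseline)
        per_rep = [percent_inhibition(c, control, endpoint=endpoint, baseline=baseline)
                   for c in group]
        results.append(PotencyResult(
            compound=name, concentration=dose, percent_inhibition=mean_inh,
            relative_concentration=(relative_concentration(dose, mean_inh)
                                    if dose > 0 else None),
            endpoint=endpoint,
            inhibition_sd=float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else None,
        ))
    return results


def dose_response(curves: list[KineticCurve], control_label: str = "control",
                  endpoint: float = 1000.0, baseline: str = "fit") -> pd.DataFrame:
    """Compound × dose matrix of endpoint percent inhibition vs control.

    Positive entries mean rescue/inhibition, negative mean acceleration
    (or toxicity in growth read-outs). Ready for heat-map plotting.
    """
    table = potency_table(curves, control_label=control_label,
                          endpoint=endpoint, baseline=baseline)
    if not table:
        raise MolstackError("no treated curves to tabulate")
    frame = pd.DataFrame(
        [{"compound": r.compound, "dose_mM": r.concentration,
          "percent_inhibition": r.percent_inhibition} for r in table])
    return frame.pivot_table(index="compound", columns="dose_mM",
                             values="percent_inhibition", aggfunc="mean")


def read_curves_csv(path) -> list[KineticCurve]:
    """Read curves from long-form CSV: time_min, signal, compound, dose_mM, replicate."""
    frame = pd.read_csv(path)
    required = {"time_min", "signal", "compound", "dose_mM", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise MolstackError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for (compound, dose, rep), sub in frame.groupby(
            ["compound", "dose_mM", "replicate"], sort=True):
        sub = sub.sort_values("time_min")
        curves.append(KineticCurve(times=sub["time_min"].to_numpy(),
                                   signal=sub["signal"].to_numpy(),
                                   compound=str(compound),
                                   concentration=float(dose),
                                   replicate_id=int(rep)))
    return curves


def write_curves_csv(curves: list[KineticCurve], path) -> None:
    rows = []
    for c in curves:
        for t, s in zip(c.times, c.signal):
            rows.append({"time_min": t, "signal": s, "compound": c.compound,
                         "dose_mM": c.concentration, "replicate": c.replicate_id})
    pd.DataFrame(rows).to_csv(path, index=False)
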