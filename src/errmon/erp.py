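"""ERP quantification: condition averages, peak measures, AUC, difference scores.

Components and their measurement conventions:

=====  ========  ========  ==============  =========
name   lock      polarity  window (ms)     electrode
=====  ========  ========  ==============  =========
N2     stimulus  negative  [200, 350]      FCz
P3     stimulus  positive  [350, 500]      FCz
Ne     response  negative  [0, 150]        FCz
CRN    response  negative  [0, 150]        FCz
Pe     response  positive  [150, 300]      Cz
Pc     response  positive  [150, 300]      Cz
=====  ========  ========  ==============  =========

Peaks are the global extremum of the subject's condition-average waveform
inside the closed window (ties resolved to the earliest sample); latency is
reported at sample resolution.  The area under the curve integrates the
signed waveform (trapezoidal rule) over the same window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import EpochSet

__all__ = [
    "COMPONENT_DEFS",
    "Erp",
    "ErpMeasure",
    "condition_average",
    "peak_measure",
    "area_under_curve",
    "measure_component",
    "peak_to_peak",
    "delta_score",
]

#: component -> (lock, polarity, window, electrode, condition category)
COMPONENT_DEFS = {
    "N2": ("stimulus", "negative", (200.0, 350.0), "FCz", None),
    "P3": ("stimulus", "positive", (350.0, 500.0), "FCz", None),
    "Ne": ("response", "negative", (0.0, 150.0), "FCz", "detected_error"),
    "CRN": ("response", "negative", (0.0, 150.0), "FCz", "correct_go"),
    "Pe": ("response", "positive", (150.0, 300.0), "Cz", "detected_error"),
    "Pc": ("response", "positive", (150.0, 300.0), "Cz", "correct_go"),
}

#: components measuring the same family, for difference/peak-to-peak scores
FAMILY = {"N2": "N2", "P3": "P3", "Ne": "ern", "CRN": "ern", "Pe": "pe", "Pc": "pe"}


@dataclass
class Erp:
    """A condition-average waveform (channels x samples)."""

    condition: str
    data: np.ndarray
    times: np.ndarray
    n_epochs: int
    channel_labels: list[str]
    units: str


@dataclass
class ErpMeasure:
    component: str
    condition: str
    electrode: str
    window: tuple[float, float]
    peak_amplitude: float
    peak_latency: float
    auc: float = np.nan
    units: str = "uV"


def condition_average(ep: EpochSet, label: str) -> Erp:
    """Pointwise mean over kept epochs with the given response category."""
    mask = ep.kept & np.array([l == label for l in ep.labels])
    if not mask.any():
        raise ValueError(f"no kept epochs labeled {label!r}")
    return Erp(label, ep.data[mask].mean(axis=0), ep.times.copy(),
               int(mask.sum()), list(ep.channel_labels), ep.units)


def _window_slice(erp: Erp, electrode: str, window: tuple[float, float]):
    if electrode not in erp.channel_labels:
        raise ValueError(f"electrode {electrode!r} not present")
    lo, hi = window
    if lo < erp.times[0] or hi > erp.times[-1]:
        raise ValueError(f"window {window} outside epoch time axis")
    mask = (erp.times >= lo) & (erp.times <= hi)   # closed interval
    wave = erp.data[erp.channel_labels.index(electrode)][mask]
    return wave, erp.times[mask]


def peak_measure(erp: Erp, electrode: str, window: tuple[float, float],
                 polarity: str) -> tuple[float, float]:
    """(amplitude, latency) of the most negative/positive peak in the window."""
    wave, times = _window_slice(erp, electrode, window)
    if polarity == "negative":
        k = int(np.argmin(wave))      # argmin/argmax take the earliest tie
    elif polarity == "positive":
        k = int(np.argmax(wave))
    else:
        raise ValueError(f"polarity must be negative|positive, got {polarity!r}")
    return float(wave[k]), float(times[k])


def area_under_curve(erp: Erp, electrode: str,
                     window: tuple[float, float]) -> float:
    """Signed trapezoidal integral over the closed window (units x ms)."""
    wave, times = _window_slice(erp, electrode, window)
    return float(np.trapezoid(wave, times))


def measure_component(erp: Erp, component: str,
                      electrode: str | None = None,
                      window: tuple[float, float] | None = None) -> ErpMeasure:
    """Standard peak + AUC measurement for a named component."""
    if component not in COMPONENT_DEFS:
        raise ValueError(f"unknown component {component!r}")
    _, polarity, def_window, def_electrode, _ = COMPONENT_DEFS[component]
    electrode = electrode or def_electrode
    window = window or def_window
    amp, lat = peak_measure(erp, electrode, window, polarity)
    auc = area_under_curve(erp, electrode, window)
    return ErpMeasure(component, erp.condition, electrode, window,
                      amp, lat, auc, erp.units)


def peak_to_peak(neg: ErpMeasure, pos: ErpMeasure) -> tuple[float, float]:
    """Positive-peak minus negative-peak (amplitude, latency) build-up."""
    if neg.component not in ("Ne", "CRN") or pos.component not in ("Pe", "Pc"):
        raise ValueError("peak_to_peak expects (Ne|CRN, Pe|Pc)")
    if neg.condition != pos.condition:
        raise ValueError("peak_to_peak requires measures from the same condition")
    return (pos.peak_amplitude - neg.peak_amplitude,
            pos.peak_latency - neg.peak_latency)


def delta_score(a: ErpMeasure, b: ErpMeasure, quantity: str = "peak_amplitude") -> float:
    """a - b on the requested field, for within-family condition contrasts.

    E.g. dNe/ERN amplitude = Ne(errors) - CRN(correct responses).
    """
    if FAMILY.get(a.component) != FAMILY.get(b.component):
        raise ValueError(f"components {a.component}/{b.component} are not "
                         "from the same family")
    if quantity not in ("peak_amplitude", "peak_latency", "auc"):
        raise ValueError(f"unknown quantity {quantity!r}")
    return float(getattr(a, quantity) - getattr(b, quantity))
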