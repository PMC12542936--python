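"""Amperometric ROS/RNS sensing: calibration, depletion kinetics, detection.

The sensor is a platinum tip biased at 0.85 V whose oxidation current is
linear in analyte concentration.  Once the probe is inside a cell the cell
behaves as a sealed chamber holding a fixed amount of ROS/RNS: electrode
consumption obeys ``V dC/dt = -A C`` with current ``i = A C`` (up to the
calibration constant), giving

    i(t) = baseline + i0 * exp(-t / tau),      tau = V / A,

so fitting (i0, tau) to a measured decay yields the initial concentration
through the calibration slope and a cell-volume estimate ``V = A * tau``
in sensitivity-scaled (arbitrary) volume units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "CurrentTrace",
    "SensorCalibration",
    "DepletionFit",
    "PenetrationEvent",
    "calibration_current",
    "simulate_depletion_trace",
    "fit_depletion",
    "detect_penetration",
    "detect_mitochondrion",
    "filter_trace",
    "correlate_current_fluorescence",
]

DEFAULT_SAMPLE_RATE = 1000.0  # Hz
DEFAULT_CUTOFF = 50.0         # Hz low-pass
DEFAULT_TAU = 12.0            # s, average depletion time constant


class FitError(RuntimeError):
    pass


@dataclass
class CurrentTrace:
    """Uniformly sampled amperometric signal (pA) with optional position."""

    current: np.ndarray                   # pA
    sample_rate: float = DEFAULT_SAMPLE_RATE
    position: Optional[np.ndarray] = None  # um, synchronized
    annotations: list = field(default_factory=list)  # (time_s, label)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != self.current.shape:
                raise ValueError("position channel must match current length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.current)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.current) / self.sample_rate

    def annotation_time(self, label: str) -> Optional[float]:
        for t, lab in self.annotations:
            if lab == label:
                return t
        return None

    # -- delimited text I/O ------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        cols = [self.times, self.current]
        header = "# sample_rate %g\n" % self.sample_rate
        for t, lab in self.annotations:
            header += "# annotation %g %s\n" % (t, lab)
        header += "time_s\tcurrent_pA"
        if self.position is not None:
            cols.append(self.position)
            header += "\tposition_um"
        np.savetxt(path, np.column_stack(cols), delimiter="\t",
                   header=header, comments="")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CurrentTrace":
        path = Path(path)
        rate = DEFAULT_SAMPLE_RATE
        annotations = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# sample_rate"):
                    rate = float(line.split()[2])
                elif line.startswith("# annotation"):
                    parts = line.split(maxsplit=3)
                    annotations.append((float(parts[2]), parts[3].strip()))
                elif not line.startswith("#"):
                    break
        df = pd.read_csv(path, sep="\t", comment="#")
        position = df["position_um"].to_numpy() if "position_um" in df else None
        return cls(current=df["current_pA"].to_numpy(), sample_rate=rate,
                   position=position, annotations=annotations)


@dataclass(frozen=True)
class SensorCalibration:
    """Linear amperometric calibration with analyte selectivity weights."""

    slope: float = 20.0                  # pA per mM
    intercept: float = 0.0               # pA
    bias_voltage: float = 0.85           # V
    selectivity_weights: Mapping[str, float] = field(
        default_factory=lambda: {"h2o2": 1.0, "na": 0.01, "k": 0.01})

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.selectivity_weights.get("h2o2", 1.0) != 1.0:
            raise ValueError("primary analyte (h2o2) weight must be 1")


@dataclass
class DepletionFit:
    i0: float                        # pA
    tau: float                       # s
    baseline: float                  # pA
    c0: float                        # mM, via calibration slope
    volume_estimate: float           # arbitrary volume units, A * tau
    rss: float                       # pA^2

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")


@dataclass
class PenetrationEvent:
    detected: bool
    t_insert: Optional[float] = None       # s
    t_withdraw: Optional[float] = None     # s
    insertion_deformation: float = 0.0     # um
    withdrawal_deformation: float = 0.0    # um

    def __post_init__(self) -> None:
        if (self.t_insert is not None and self.t_withdraw is not None
                and not self.t_insert < self.t_withdraw):
            raise ValueError("t_insert must precede t_withdraw")
        if self.insertion_deformation < 0 or self.withdrawal_deformation < 0:
            raise ValueError("deformations must be >= 0")


def calibration_current(cal: SensorCalibration,
                        concentration: Union[float, Mapping[str, float]]) -> float:
    """Sensor current (pA) for a concentration or analyte->mM mapping.

    Mixed analytes superpose with their selectivity weights; a bare float
    is the primary analyte.
    """
    if isinstance(concentration, Mapping):
        total = 0.0
        for analyte, c in concentration.items():
            if c < 0:
                raise ValueError("concentration must be >= 0")
            total += cal.selectivity_weights.get(analyte, 0.0) * c
    else:
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        total = float(concentration)
    return cal.slope * total + cal.intercept


def simulate_depletion_trace(i0: float, tau: float = DEFAULT_TAU,
                             baseline: float = 0.0, window: float = 60.0,
                             noise_sd: float = 0.0, seed: int = 0,
                             sample_rate: float = DEFAULT_SAMPLE_RATE) -> CurrentTrace:
    """Sealed-chamber depletion decay ``baseline + i0 exp(-t/tau)`` + noise."""
    if window <= 0:
        raise ValueError("window must be > 0")
    n = int(round(window * sample_rate))
    t = np.arange(n) / sample_rate
    i = baseline + i0 * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=n)
    return CurrentTrace(current=i, sample_rate=sample_rate)


def _exp_model(t, i0, tau, baseline):
    return baseline + i0 * np.exp(-t / tau)


def fit_depletion(trace: CurrentTrace, window: Optional[float] = None,
                  sensitivity: float = 1.0, slope: float = 1.0) -> DepletionFit:
    """Nonlinear least-squares fit of the exponential depletion decay.

    ``c0 = i0 / slope`` converts the fitted amplitude to a concentration;
    ``volume_estimate = sensitivity * tau`` is in sensitivity-scaled units.
    """
    t = trace.times
    i = trace.current
    if window is not None:
        mask = t <= window
        t, i = t[mask], i[mask]
    if len(t) < 100:
        raise FitError("window must contain at least 100 samples")

    baseline0 = float(np.min(i))
    i0_guess = max(float(i[0] - baseline0), 1e-6)
    # crude tau guess from the 1/e crossing
    target = baseline0 + i0_guess / math.e
    below = np.nonzero(i <= target)[0]
    tau0 = float(t[below[0]]) if len(below) and t[below[0]] > 0 else max(t[-1] / 3.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, t, i, p0=(i0_guess, tau0, baseline0),
            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"depletion fit did not converge: {exc}") from exc
    i0, tau, baseline = (float(v) for v in popt)
    if tau <= 0 or i0 <= 0:
        raise FitError(f"rejected fit: i0={i0:.3g} pA, tau={tau:.3g} s")
    resid = i - _exp_model(t, *popt)
    return DepletionFit(i0=i0, tau=tau, baseline=baseline, c0=i0 / slope,
                        volume_estimate=sensitivity * tau,
                        rss=float(resid @ resid))


def filter_trace(trace: CurrentTrace, cutoff: float = DEFAULT_CUTOFF) -> CurrentTrace:
    """Zero-phase (forward-backward) Butterworth low-pass; DC gain 1."""
    nyq = trace.sample_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError("cutoff must be in (0, sample_rate/2)")
    b, a = signal.butter(4, cutoff / nyq)
    smoothed = signal.filtfilt(b, a, trace.current)
    return CurrentTrace(current=smoothed, sample_rate=trace.sample_rate,
                        position=trace.position, annotations=list(trace.annotations))


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_penetration(trace: CurrentTrace, k: float = 6.0,
                       t_contact: Optional[float] = None) -> PenetrationEvent:
    """Locate the membrane-penetration current spike and deformations.

    Insertion: first sample where the median-filtered derivative exceeds
    ``k`` times its MAD-scaled noise level.  Withdrawal: the later downward
    spike after which the current returns to within 2 noise-SD of the
    pre-insertion baseline.  Deformations need the synchronized position
    channel; the contact time comes from ``t_contact`` or a ``contact``
    annotation.
    """
    i = signal.medfilt(trace.current, kernel_size=5)
    # step-matched derivative: difference of trailing/leading window means
    w = max(3, int(round(0.01 * trace.sample_rate)))
    if len(i) < 3 * w:
        return PenetrationEvent(detected=False)
    c = np.cumsum(np.concatenate(([0.0], i)))
    lead = (c[2 * w:] - c[w:-w]) / w     # mean of i[j : j+w]
    trail = (c[w:-w] - c[:-2 * w]) / w   # mean of i[j-w : j]
    d = lead - trail                     # indexed by j = w .. len-w
    sigma = 1.4826 * _mad(d)
    if sigma <= 0:
        sigma = float(np.std(d)) or np.inf
    above = np.nonzero(d > k * sigma)[0]
    if len(above) == 0:
        return PenetrationEvent(detected=False)
    j0 = int(above[0])
    # refine to the sharpest rise inside the crossing neighbourhood
    j_peak = j0 + int(np.argmax(d[j0:j0 + 2 * w]))
    idx_in = j_peak + w
    t_insert = idx_in / trace.sample_rate

    pre = trace.current[:max(idx_in - 5, 1)]
    baseline = float(np.median(pre))
    noise_sd = float(np.std(pre)) if len(pre) > 1 else sigma

    # withdrawal: sustained return to baseline after the insertion spike
    t_withdraw = None
    post = i[idx_in:]
    back = np.nonzero(post <= baseline + 2.0 * max(noise_sd, sigma))[0]
    # require it to stay down for 10 samples
    for j in back:
        if j + 10 <= len(post) and np.all(post[j:j + 10] <= baseline + 4.0 * max(noise_sd, sigma)):
            t_withdraw = (idx_in + j) / trace.sample_rate
            break

    ins_def = 0.0
    wd_def = 0.0
    if trace.position is not None:
        tc = t_contact if t_contact is not None else trace.annotation_time("contact")
        if tc is not None:
            jc = min(int(round(tc * trace.sample_rate)), len(trace.position) - 1)
            ins_def = abs(float(trace.position[idx_in] - trace.position[jc]))
        tw_start = trace.annotation_time("withdraw_start")
        if t_withdraw is not None and tw_start is not None:
            j0 = min(int(round(tw_start * trace.sample_rate)), len(trace.position) - 1)
            j1 = min(int(round(t_withdraw * trace.sample_rate)), len(trace.position) - 1)
            wd_def = abs(float(trace.position[j1] - trace.position[j0]))

    if t_withdraw is not None and not t_insert < t_withdraw:
        t_withdraw = None
    return PenetrationEvent(detected=True, t_insert=t_insert, t_withdraw=t_withdraw,
                            insertion_deformation=ins_def,
                            withdrawal_deformation=wd_def)


def detect_mitochondrion(trace: CurrentTrace, threshold: float = 8.0,
                         debounce: float = 0.05,
                         cutoff: Optional[float] = DEFAULT_CUTOFF):
    """Threshold detector on the baseline-subtracted, low-pass current.

    Returns ``(detected, t_detect)``.  The current must exceed ``threshold``
    (pA) continuously for at least ``debounce`` seconds; ``t_detect`` is the
    first crossing of a sufficiently long excursion.  The trace is assumed
    baseline-corrected by the caller.
    """
    i = trace.current
    if cutoff is not None and len(i) > 15:
        i = filter_trace(trace, cutoff).current
    above = i > threshold
    need = max(1, int(round(debounce * trace.sample_rate)))
    run = 0
    start = None
    for j, flag in enumerate(above):
        if flag:
            if run == 0:
                start = j
            run += 1
            if run >= need:
                return True, start / trace.sample_rate
        else:
            run = 0
    return False, None


def correlate_current_fluorescence(pairs: Sequence) -> dict:
    """Pearson r between paired currents and fluorescence, with Fisher CI."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (current, fluorescence)")
    n = len(arr)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        se = 1.0 / math.sqrt(n - 3)
        zc = stats.norm.ppf(0.975)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return {"r": float(r), "p": float(p), "ci95": (float(lo), float(hi)), "n": n}
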