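"""Trial windowing, signal preprocessing and the four dependent indicators.

Each crossing trial yields two subjective-assessment indicators computed
from the 20 Hz potentiometer trace — ``iSA``, the area under the assessed
risk curve (its dynamics), and ``mSA``, its maximum — and two
skin-conductance indicators computed from the phasic electrodermal signal —
``nSCR``, the number of skin conductance responses in the trial window, and
``mSCR``, the largest response amplitude.  The window opens when the
pedestrian begins to cross and closes 3 s after the pedestrian has passed,
to absorb the latency between a stimulus and its electrodermal response.

Before model fitting the subjective indicators are skewness-corrected
(iSA -> iSA^(1/2), mSA -> mSA^(1/3)) and standardised within participant;
the SCR indicators are rescaled per participant without centering, which
preserves the nonnegativity and the exact zeros that the compound
Poisson-gamma law requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SignalTrace",
    "SCREvent",
    "TrialWindow",
    "TransformSpec",
    "DEFAULT_SCR_THRESHOLD",
    "SA_COLUMNS",
    "SCR_COLUMNS",
    "preprocess_eda",
    "detect_scrs",
    "compute_isa",
    "compute_msa",
    "count_and_max_scr",
    "apply_transforms",
    "IndicatorTransformer",
]

#: Minimum trough-to-peak amplitude (microsiemens) for a retained SCR.
#: Thresholds as high as 5 uS are sometimes quoted for this protocol but
#: lie outside the physiological range of phasic responses (typical
#: thresholds are 0.01-0.05 uS); the default is 0.05 uS, configurable.
DEFAULT_SCR_THRESHOLD = 0.05

SA_COLUMNS = ("iSA", "mSA")
SCR_COLUMNS = ("nSCR", "mSCR")
_SA_POWERS = {"iSA": 0.5, "mSA": 1.0 / 3.0}


@dataclass
class SignalTrace:
    """A uniformly sampled signal: timestamps (s), values, rate (Hz)."""

    t: np.ndarray
    v: np.ndarray
    rate: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("timestamps and values must align")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class SCREvent:
    """One skin conductance response: onset (s) and amplitude (uS)."""

    onset: float
    amplitude: float

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("SCR amplitude must be positive")


@dataclass(frozen=True)
class TrialWindow:
    """Closed interval [start, end]: crossing onset to pass time + 3 s."""

    start: float
    end: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("window end must exceed its start")

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


@dataclass
class TransformSpec:
    """Normalising transforms applied to the raw indicator table."""

    isa_power: float = 0.5
    msa_power: float = 1.0 / 3.0
    standardize: bool = True     # center/scale subjective indicators
    scr_scale: bool = True       # rescale (not center) SCR indicators

    def __post_init__(self):
        for p in (self.isa_power, self.msa_power):
            if not 0 < p <= 1:
                raise ValueError("transform exponents must lie in (0, 1]")


def preprocess_eda(trace: SignalTrace, out_rate: float = 50.0) -> SignalTrace:
    """Condition a raw conductance trace for SCR extraction.

    Applies, in order: resampling to ``out_rate`` (linear interpolation),
    a centered 1-s moving median, and a 1-Hz zero-phase low-pass filter
    (4th-order Butterworth, forward-backward).  Constants pass through
    unchanged; sub-sample spikes are removed by the median stage and
    residual high-frequency noise by the low-pass stage.
    """
    if trace.rate < out_rate:
        raise ValueError(f"input rate must be >= {out_rate} Hz")
    if trace.duration < 1.0:
        raise ValueError("trace must span at least 1 s")
    t_new = trace.t[0] + np.arange(
        int(np.floor(trace.duration * out_rate)) + 1
    ) / out_rate
    v = np.interp(t_new, trace.t, trace.v)
    win = int(round(out_rate))
    win += 1 - win % 2  # centered window needs an odd length
    v = ndimage.median_filter(v, size=win, mode="nearest")
    sos = signal.butter(4, 1.0, btype="low", fs=out_rate, output="sos")
    v = signal.sosfiltfilt(sos, v)
    return SignalTrace(t=t_new, v=v, rate=out_rate)


def detect_scrs(
    trace: SignalTrace, amplitude_threshold: float = DEFAULT_SCR_THRESHOLD
) -> list[SCREvent]:
    """Detect SCRs as trough-to-peak excursions above a threshold.

    Each local maximum of the phasic trace is paired with the preceding
    local minimum; excursions of at least ``amplitude_threshold`` become
    events with the trough time as onset and the trough-to-peak difference
    as amplitude.  Events are returned sorted by onset.
    """
    v = trace.v
    if v.size < 3:
        return []
    d = np.sign(np.diff(v))
    # carry the previous slope through flat stretches
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    turns = np.diff(d)
    peaks = np.where(turns < 0)[0] + 1
    troughs = np.where(turns > 0)[0] + 1
    events = []
    for pk in peaks:
        prior = troughs[troughs < pk]
        tr = int(prior[-1]) if prior.size else 0
        amp = float(v[pk] - v[tr])
        if amp >= amplitude_threshold:
            events.append(SCREvent(onset=float(trace.t[tr]), amplitude=amp))
    events.sort(key=lambda e: e.onset)
    return events


def _window_slice(trace: SignalTrace, window: TrialWindow):
    mask = (trace.t >= window.start) & (trace.t <= window.end)
    if not np.any(mask):
        raise ValueError("trial window does not overlap the trace")
    return mask


def compute_isa(trace: SignalTrace, window: TrialWindow) -> float:
    """Area under the assessed-risk curve over the trial window.

    Trapezoidal rule on the in-window samples, with the window boundaries
    added by linear interpolation so piecewise-linear traces integrate
    exactly.
    """
    mask = _window_slice(trace, window)
    lo = max(window.start, float(trace.t[0]))
    hi = min(window.end, float(trace.t[-1]))
    t = trace.t[mask]
    v = trace.v[mask]
    if t[0] > lo:
        t = np.insert(t, 0, lo)
        v = np.insert(v, 0, np.interp(lo, trace.t, trace.v))
    if t[-1] < hi:
        t = np.append(t, hi)
        v = np.append(v, np.interp(hi, trace.t, trace.v))
    return float(np.trapezoid(v, t))


def compute_msa(trace: SignalTrace, window: TrialWindow) -> float:
    """Maximum assessed risk over the trial window."""
    mask = _window_slice(trace, window)
    return float(np.max(trace.v[mask]))


def count_and_max_scr(
    events: list[SCREvent], window: TrialWindow
) -> tuple[int, float]:
    """(nSCR, mSCR) for one trial: in-window count and largest amplitude.

    The window is closed on both ends; an event exactly at the pass time
    + 3 s boundary is counted.  With no in-window events the pair (0, 0.0)
    is returned.
    """
    amps = [e.amplitude for e in events if window.contains(e.onset)]
    if not amps:
        return 0, 0.0
    return len(amps), float(max(amps))


def apply_transforms(
    table: pd.DataFrame,
    spec: TransformSpec | None = None,
    participant_col: str = "participant_id",
    collision_col: str = "is_collision",
) -> pd.DataFrame:
    """Skewness-correct and per-participant normalise an indicator table.

    Subjective indicators present among ``iSA``/``mSA`` are raised to their
    corrective power and then centered and scaled to unit variance within
    participant; SCR indicators among ``nSCR``/``mSCR`` are divided by the
    participant's mean over nonzero values (no centering, so zeros and
    nonnegativity survive).  Collision trials are excluded from every
    normalising statistic but are transformed with the same constants.
    Participants with zero variance in a subjective indicator keep a unit
    scale and trigger a warning.
    """
    if spec is None:
        spec = TransformSpec()
    out = table.copy()
    collision = (
        out[collision_col].to_numpy(dtype=bool)
        if collision_col in out
        else np.zeros(len(out), dtype=bool)
    )
    groups = out.groupby(participant_col, sort=False).indices
    for pid, idx in groups.items():
        keep = idx[~collision[idx]]
        if keep.size < 2:
            raise ValueError(
                f"participant {pid!r} has fewer than 2 non-collision trials"
            )
        for col in SA_COLUMNS:
            if col not in out:
                continue
            power = spec.isa_power if col == "iSA" else spec.msa_power
            vals = out[col].to_numpy(dtype=float)
            if np.any(vals[idx] < 0):
                raise ValueError(f"{col} must be nonnegative on the raw scale")
            tv = vals[idx] ** power
            if spec.standardize:
                ref = tv[~collision[idx]]
                m, s = float(np.mean(ref)), float(np.std(ref, ddof=1))
                if s < 1e-12:
                    warnings.warn(
                        f"participant {pid!r} has zero variance in {col}; "
                        "scale left at 1"
                    )
                    s = 1.0
                tv = (tv - m) / s
            out.loc[out.index[idx], col] = tv
        for col in SCR_COLUMNS:
            if col not in out or not spec.scr_scale:
                continue
            vals = out[col].to_numpy(dtype=float)[idx]
            ref = vals[~collision[idx]]
            nz = ref[ref > 0]
            scale = float(np.mean(nz)) if nz.size else 1.0
            out.loc[out.index[idx], col] = vals / scale
    return out


class IndicatorTransformer(TransformerMixin, BaseEstimator):
    """scikit-learn wrapper around :func:`apply_transforms`.

    Stateless between fit and transform (the normalising statistics are
    per-participant and recomputed from the table being transformed, which
    is the only sound choice for within-participant standardisation).
    """

    def __init__(self, spec: TransformSpec | None = None,
                 participant_col: str = "participant_id",
                 collision_col: str = "is_collision"):
        self.spec = spec
        self.participant_col = participant_col
        self.collision_col = collision_col

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("IndicatorTransformer expects a DataFrame")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return apply_transforms(
            X,
            spec=self.spec,
            participant_col=self.participant_col,
            collision_col=self.collision_col,
        )
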