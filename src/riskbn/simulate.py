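"""Synthetic data generator for the crossing-risk pipeline.

No raw data from the driving-simulator study are public, so every
downstream stage is exercised on data simulated from an explicit ground
truth that mirrors the reported effect structure:

* a transformed subjective indicator that is Gaussian around a cell mean
  determined by a small set of parent factors (``Margin`` and ``Order``
  for the dynamics pair; ``Margin``, ``Order`` and ``Orientation`` for the
  maxima pair), plus a per-participant additive offset;
* a skin-conductance indicator drawn from a compound Poisson-gamma law
  whose log-mean is linear in the standardised subjective indicator
  (default slopes 0.14 for the dynamics pair and 0.2 for the maxima pair),
  times a per-participant multiplicative scale.

Cell means are expressed on the per-participant standardised scale.  For
that scale to be self-consistent the residual standard deviation defaults
to sqrt(1 - Var(cell means)), so the within-participant variance of the
transformed indicator is 1 and standardisation leaves the planted
contrasts intact.  Both sources of participant heterogeneity are exactly
the ones the standardisation stage removes, so that stage is exercised
nontrivially.

Random streams are split per participant and per trial from the master
seed with ``numpy.random.SeedSequence``, so any subset of the data is
reproducible on its own.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .design import FACTOR_NAMES, build_fractional_design, make_trial_plan
from .indicators import SCREvent, SignalTrace
from .tweedie import sample_tweedie, to_compound_poisson

__all__ = [
    "GroundTruth",
    "TrialTiming",
    "PAIR_COLUMNS",
    "default_ground_truth",
    "sample_compound_poisson_gamma",
    "simulate_indicator_pairs",
    "simulate_indicator_table",
    "simulate_sa_trace",
    "simulate_scr_events",
    "simulate_trace_tables",
]

#: Indicator column names per pair: (subjective, SCR).
PAIR_COLUMNS = {"dynamics": ("iSA", "nSCR"), "maxima": ("mSA", "mSCR")}

_COLLISION_Z = 3.0  # planted saturated response for scripted collisions


@dataclass
class GroundTruth:
    """Generative configuration for one indicator pair.

    ``sa_cell_means`` maps level-label tuples of ``sa_parents`` to the mean
    of the transformed subjective indicator on the standardised scale.
    ``sa_sd`` is the residual SD on that scale; ``None`` selects the
    self-consistent value sqrt(1 - Var(cell means)).  The SCR indicator
    follows Tw_p(mu, phi) with log mu = scr_intercept + scr_slope * z where
    z is the standardised subjective value.
    """

    pair: str
    sa_parents: tuple[str, ...]
    sa_cell_means: dict[tuple[str, ...], float]
    scr_slope: float
    scr_intercept: float = 0.3
    scr_phi: float = 1.0
    scr_p: float = 1.5
    sa_sd: float | None = None
    participant_sd: float = 0.5
    scr_participant_log_sd: float = 0.3
    sa_shift: float = 5.0        # raw-scale offset on the transformed scale
    trace_noise: float = 0.1     # lognormal jitter of trace peak height

    def __post_init__(self):
        if self.pair not in PAIR_COLUMNS:
            raise ValueError(f"unknown indicator pair {self.pair!r}")
        if not 1.0 < self.scr_p < 2.0:
            raise ValueError("scr_p must lie strictly in (1, 2)")
        if self.scr_phi <= 0:
            raise ValueError("scr_phi must be positive")
        if self.sa_sd is not None and self.sa_sd <= 0:
            raise ValueError("sa_sd must be positive")
        self.sa_parents = tuple(self.sa_parents)
        self.sa_cell_means = {
            tuple(k): float(v) for k, v in self.sa_cell_means.items()
        }

    @property
    def columns(self) -> tuple[str, str]:
        return PAIR_COLUMNS[self.pair]

    @property
    def cell_variance(self) -> float:
        m = np.array(list(self.sa_cell_means.values()))
        return float(np.mean((m - m.mean()) ** 2))

    @property
    def sa_sd_effective(self) -> float:
        if self.sa_sd is not None:
            return self.sa_sd
        return float(np.sqrt(max(1.0 - self.cell_variance, 0.04)))

    def cell_mean(self, levels: dict[str, str]) -> float:
        key = tuple(levels[p] for p in self.sa_parents)
        return self.sa_cell_means[key]

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sa_parents"] = list(self.sa_parents)
        d["sa_cell_means"] = {
            "|".join(k): v for k, v in self.sa_cell_means.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["sa_parents"] = tuple(d["sa_parents"])
        d["sa_cell_means"] = {
            tuple(k.split("|")): float(v)
            for k, v in d["sa_cell_means"].items()
        }
        return cls(**d)


def default_ground_truth(pair: str, null: bool = False) -> GroundTruth:
    """Packaged generative configuration for one indicator pair.

    The dynamics configuration plants an Order contrast of 0.98 at the
    1.5 m margin and 0.72 at the 2.5 m margin with a log-link SCR slope of
    0.14; the maxima configuration plants Order contrasts of 1.0 (pedestrian
    walking away) and 0.23 (facing) at either margin with slope 0.2.
    ``null=True`` zeroes every effect (flat cell means, zero slope) while
    keeping the noise structure, for specificity checks.
    """
    if pair == "dynamics":
        cells = {
            ("1.5 m", "First"): 0.70,
            ("1.5 m", "Second"): -0.28,
            ("2.5 m", "First"): 0.15,
            ("2.5 m", "Second"): -0.57,
        }
        gt = GroundTruth(
            pair="dynamics",
            sa_parents=("Margin", "Order"),
            sa_cell_means=cells,
            scr_slope=0.14,
        )
    elif pair == "maxima":
        cells = {
            ("1.5 m", "First", "Back"): 0.9,
            ("1.5 m", "Second", "Back"): -0.1,
            ("1.5 m", "First", "Face"): 0.515,
            ("1.5 m", "Second", "Face"): 0.285,
            ("2.5 m", "First", "Back"): 0.1,
            ("2.5 m", "Second", "Back"): -0.9,
            ("2.5 m", "First", "Face"): -0.285,
            ("2.5 m", "Second", "Face"): -0.515,
        }
        gt = GroundTruth(
            pair="maxima",
            sa_parents=("Margin", "Order", "Orientation"),
            sa_cell_means=cells,
            scr_slope=0.2,
        )
    else:
        raise ValueError(f"unknown indicator pair {pair!r}")
    if null:
        gt.sa_cell_means = {k: 0.0 for k in gt.sa_cell_means}
        gt.scr_slope = 0.0
        gt.sa_sd = 1.0
    return gt



def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)

def sample_compound_poisson_gamma(mu, phi, p, n=None, seed=None):
    """Draw ``n`` compound Poisson-gamma variates (see :mod:`.tweedie`)."""
    if n is not None and n < 1:
        raise ValueError("n must be >= 1")
    return sample_tweedie(mu, phi, p, size=n, rng=seed)


def simulate_indicator_pairs(
    ground_truth: GroundTruth, n: int, seed=None
) -> pd.DataFrame:
    """Draw (standardised subjective, SCR) indicator pairs directly.

    The subjective value is standard normal; the SCR indicator follows the
    ground truth's log-link law.  This is the cleanest input for slope
    recovery, bypassing the factorial layer entirely.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    mu = np.exp(ground_truth.scr_intercept + ground_truth.scr_slope * z)
    y = sample_tweedie(mu, ground_truth.scr_phi, ground_truth.scr_p, rng=rng)
    sa_col, scr_col = ground_truth.columns
    return pd.DataFrame({sa_col: z, scr_col: y})


def simulate_indicator_table(
    design: np.ndarray | None,
    n_participants: int,
    ground_truth: GroundTruth,
    seed=None,
    collisions: bool = True,
) -> pd.DataFrame:
    """Simulate a raw-scale per-trial indicator table.

    For each participant the design is shuffled into a trial plan (with the
    four scripted collision trials when ``collisions`` is set) and each
    trial yields one row: participant, rank, collision flag, the seven
    factor labels and the pair's two indicators on the raw scale.  The raw
    subjective value is the transformed-scale Gaussian draw (shifted by
    ``sa_shift`` plus the participant offset) raised back through the
    inverse skewness correction; the raw SCR value is the participant's
    multiplicative scale times the compound Poisson-gamma draw.  Collision
    trials carry a saturated planted response and are meant to be excluded
    from modelling.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if design is None:
        design = build_fractional_design()
    sa_col, scr_col = ground_truth.columns
    inv_power = 2.0 if sa_col == "iSA" else 3.0
    sd = ground_truth.sa_sd_effective
    ss = _as_seedseq(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_participants)):
        plan_ss, person_ss, trials_ss = child.spawn(3)
        prng = np.random.default_rng(person_ss)
        pid = f"P{i + 1:02d}"
        offset = prng.normal(0.0, ground_truth.participant_sd)
        scr_scale = float(
            np.exp(prng.normal(0.0, ground_truth.scr_participant_log_sd))
        )
        plan = make_trial_plan(design, participant_id=pid, seed=plan_ss)
        if not collisions:
            plan = plan[~plan.is_collision].reset_index(drop=True)
        trial_streams = trials_ss.spawn(len(plan))
        for (_, trial), t_ss in zip(plan.iterrows(), trial_streams):
            rng = np.random.default_rng(t_ss)
            if trial.is_collision:
                z = _COLLISION_Z
            else:
                levels = {f: trial[f] for f in FACTOR_NAMES}
                z = ground_truth.cell_mean(levels) + rng.normal(0.0, sd)
            transformed = ground_truth.sa_shift + offset + z
            sa_raw = max(transformed, 0.05) ** inv_power
            mu = float(
                np.exp(
                    ground_truth.scr_intercept + ground_truth.scr_slope * z
                )
            )
            y = sample_tweedie(
                mu, ground_truth.scr_phi, ground_truth.scr_p, rng=rng
            )
            rows.append(
                {
                    "participant_id": pid,
                    "rank": int(trial["rank"]),
                    "is_collision": bool(trial.is_collision),
                    **{f: trial[f] for f in FACTOR_NAMES},
                    sa_col: sa_raw,
                    scr_col: scr_scale * y,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialTiming:
    """Timeline of one crossing trial (seconds from trial start)."""

    duration: float = 20.0
    cross_start: float = 4.0   # pedestrian begins to cross
    pass_time: float = 10.0    # closest approach / pedestrian has passed
    sa_rate: float = 20.0

    def __post_init__(self):
        if not 0 <= self.cross_start < self.pass_time:
            raise ValueError("need 0 <= cross_start < pass_time")
        if self.pass_time + 3.0 > self.duration:
            raise ValueError("trial must extend 3 s past the pass time")

    @property
    def window(self) -> tuple[float, float]:
        return self.cross_start, self.pass_time + 3.0


def simulate_sa_trace(
    condition: dict[str, str] | float,
    ground_truth: GroundTruth,
    participant_offset: float = 0.0,
    trial_timing: TrialTiming = TrialTiming(),
    seed=None,
) -> SignalTrace:
    """Simulate a 20 Hz subjective-assessment trace for one trial.

    The template is a raised-cosine bump peaking at the pass time with
    compact support inside the interaction window; its height maps the
    condition's standardised mean (plus the participant offset) through a
    logistic squash into (0, 1), so peak height and area are monotone in
    the planted mean.  With ``trace_noise`` = 0 and zero offset the trace
    is deterministic.  ``condition`` may be a level dict or directly a
    standardised mean.
    """
    if trial_timing.duration < 10.0:
        raise ValueError("trial window must span at least 10 s")
    m = (
        float(condition)
        if np.isscalar(condition)
        else ground_truth.cell_mean(condition)
    )
    rng = np.random.default_rng(seed)
    height = 1.0 / (1.0 + np.exp(-0.8 * (m + participant_offset)))
    height = 0.05 + 0.9 * height
    if ground_truth.trace_noise > 0:
        height *= float(
            np.exp(rng.normal(0.0, ground_truth.trace_noise))
        )
    n = int(trial_timing.duration * trial_timing.sa_rate) + 1
    t = np.arange(n) / trial_timing.sa_rate
    center = trial_timing.pass_time
    half_width = min(
        center - trial_timing.cross_start, trial_timing.duration - center
    )
    v = np.zeros(n)
    inside = np.abs(t - center) < half_width
    v[inside] = height * np.cos(
        np.pi * (t[inside] - center) / (2.0 * half_width)
    ) ** 2
    return SignalTrace(t=t, v=np.clip(v, 0.0, 1.0), rate=trial_timing.sa_rate)


def simulate_scr_events(
    z: float,
    ground_truth: GroundTruth,
    trial_timing: TrialTiming = TrialTiming(),
    seed=None,
) -> list[SCREvent]:
    """Simulate the trial's SCR events for a standardised subjective value.

    The event count is Poisson with the rate implied by the ground truth's
    compound Poisson-gamma law at mu = exp(intercept + slope * z), and
    amplitudes are the matching gamma draws, so windowed indicator
    statistics reproduce the indicator-level law (in particular the
    zero-response probability exp(-lambda)).  Onsets are uniform on the
    closed trial window [cross start, pass time + 3 s].
    """
    rng = np.random.default_rng(seed)
    mu = float(np.exp(ground_truth.scr_intercept + ground_truth.scr_slope * z))
    lam, shape, scale = to_compound_poisson(
        mu, ground_truth.scr_phi, ground_truth.scr_p
    )
    n = rng.poisson(lam)
    if n == 0:
        return []
    lo, hi = trial_timing.window
    onsets = np.sort(rng.uniform(lo, hi, size=n))
    amps = rng.gamma(shape, scale, size=n)
    return [
        SCREvent(onset=float(o), amplitude=float(max(a, 1e-12)))
        for o, a in zip(onsets, amps)
    ]


def simulate_trace_tables(
    design: np.ndarray | None,
    n_participants: int,
    ground_truth: GroundTruth,
    seed=None,
    trial_timing: TrialTiming = TrialTiming(),
):
    """Simulate signal-level data: trial plans, SA traces and SCR events.

    Returns ``(plan, traces, events)`` DataFrames in long format.  Each
    trial draws one standardised subjective value z from the ground truth;
    the 20 Hz subjective trace peaks at a height monotone in z and the SCR
    events follow the compound Poisson-gamma law at mu(z).  Collision
    trials get a saturated z.  Streams split per participant and trial as
    in :func:`simulate_indicator_table`.
    """
    if design is None:
        design = build_fractional_design()
    ss = _as_seedseq(seed)
    plans, trace_rows, event_rows = [], [], []
    for i, child in enumerate(ss.spawn(n_participants)):
        plan_ss, person_ss, trials_ss = child.spawn(3)
        prng = np.random.default_rng(person_ss)
        pid = f"P{i + 1:02d}"
        offset = prng.normal(0.0, ground_truth.participant_sd)
        plan = make_trial_plan(design, participant_id=pid, seed=plan_ss)
        plans.append(plan)
        sd = ground_truth.sa_sd_effective
        for (_, trial), t_ss in zip(plan.iterrows(), trials_ss.spawn(len(plan))):
            z_ss, ev_ss = t_ss.spawn(2)
            rng = np.random.default_rng(z_ss)
            if trial.is_collision:
                z = _COLLISION_Z
            else:
                levels = {f: trial[f] for f in FACTOR_NAMES}
                z = ground_truth.cell_mean(levels) + rng.normal(0.0, sd)
            trace = simulate_sa_trace(
                z, ground_truth, participant_offset=offset,
                trial_timing=trial_timing, seed=rng,
            )
            trace_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "rank": int(trial["rank"]),
                        "t": trace.t,
                        "value": trace.v,
                    }
                )
            )
            for ev in simulate_scr_events(
                z, ground_truth, trial_timing=trial_timing, seed=ev_ss
            ):
                event_rows.append(
                    {
                        "participant_id": pid,
                        "rank": int(trial["rank"]),
                        "onset": ev.onset,
                        "amplitude": ev.amplitude,
                    }
                )
    traces = pd.concat(trace_rows, ignore_index=True)
    events = pd.DataFrame(
        event_rows, columns=["participant_id", "rank", "onset", "amplitude"]
    )
    return pd.concat(plans, ignore_index=True), traces, events
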