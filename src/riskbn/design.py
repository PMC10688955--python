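"""Fractional factorial bookkeeping for the pedestrian-crossing experiment.

Seven two-level factors describe how a virtual pedestrian crosses the path
of the passenger's vehicle: where the pedestrian starts (``Side``,
``Orientation``), how the two move relative to each other (``vSpeed``,
``pSpeed``, ``Angle``), and their relative position at close proximity
(``Order``, ``Margin``).  A full 2^7 factorial would need 128 trials per
participant; instead a 2^(7-2) regular fraction of 32 runs is used, chosen
with resolution-IV generators so that the design stays balanced through
third-order interactions.  Four scripted collision trials are inserted at
fixed ranks to keep participants convinced that collisions can happen; they
are flagged and excluded from all model fitting.

Sign coding convention: the first-listed level of each factor is coded -1,
the second +1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "FACTORS",
    "FACTOR_NAMES",
    "DEFAULT_GENERATORS",
    "COLLISION_RANKS",
    "COLLISION_ANNOTATION",
    "DesignError",
    "build_fractional_design",
    "check_balance",
    "make_trial_plan",
    "design_to_frame",
    "frame_to_signs",
]


class DesignError(ValueError):
    """Raised when a requested design violates its structural contract."""


@dataclass(frozen=True)
class FactorSpec:
    """One manipulated two-level factor; ``level_low`` is coded -1."""

    name: str
    level_low: str
    level_high: str

    def label(self, sign: int) -> str:
        return self.level_high if sign > 0 else self.level_low

    def sign(self, label: str) -> int:
        if label == self.level_low:
            return -1
        if label == self.level_high:
            return 1
        raise DesignError(f"unknown level {label!r} for factor {self.name}")


#: The seven manipulated factors and their levels.
FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("Side", "Left", "Right"),
    FactorSpec("Orientation", "Face", "Back"),
    FactorSpec("vSpeed", "20 kph", "30 kph"),
    FactorSpec("pSpeed", "5.5 kph", "7 kph"),
    FactorSpec("Angle", "pi/6", "pi/3"),
    FactorSpec("Order", "First", "Second"),
    FactorSpec("Margin", "1.5 m", "2.5 m"),
)
FACTOR_NAMES: tuple[str, ...] = tuple(f.name for f in FACTORS)
_FACTOR_BY_NAME = {f.name: f for f in FACTORS}

#: Minimum-aberration resolution-IV generator pair for the 2^(7-2) fraction:
#: F = ABCD and G = ABDE in conventional letter notation (A..E are the five
#: base factors, i.e. the first five columns).
DEFAULT_GENERATORS: tuple[str, ...] = ("ABCD", "ABDE")

#: 1-based ranks at which scripted collision trials are inserted.
COLLISION_RANKS: tuple[int, ...] = (7, 14, 21, 28)

#: Speeds recorded for the collision trials.
COLLISION_ANNOTATION = {"vSpeed": "30 kph", "pSpeed": "7.5 kph"}

_LETTERS = "ABCDEFGHIJ"


def _generator_columns(word: str, n_base: int) -> list[int]:
    cols = []
    for ch in word.upper():
        idx = _LETTERS.find(ch)
        if idx < 0 or idx >= n_base:
            raise DesignError(
                f"generator {word!r} uses letter {ch!r} outside the "
                f"{n_base} base factors"
            )
        cols.append(idx)
    if len(set(cols)) != len(cols):
        raise DesignError(f"generator {word!r} repeats a base factor")
    return cols


def build_fractional_design(
    n_factors: int = 7,
    generators: Sequence[str] = DEFAULT_GENERATORS,
) -> np.ndarray:
    """Build a regular two-level fractional factorial design.

    Parameters
    ----------
    n_factors:
        Total number of factors (base factors plus one per generator).
    generators:
        Defining words, each a product of distinct base-factor letters
        (``A`` is the first column).  An empty sequence gives the full
        2^``n_factors`` factorial.

    Returns
    -------
    ndarray of shape (2^(n_factors - len(generators)), n_factors)
        Rows of -1/+1 levels.

    Raises
    ------
    DesignError
        If the generators produce duplicate runs or a design that is not
        balanced through third-order interactions (resolution < IV).
    """
    n_gen = len(generators)
    n_base = n_factors - n_gen
    if n_base < 1:
        raise DesignError("more generators than factors")
    base = np.array(
        list(itertools.product((-1, 1), repeat=n_base)), dtype=np.int8
    )
    cols = [base[:, i] for i in range(n_base)]
    for word in generators:
        idx = _generator_columns(word, n_base)
        cols.append(np.prod([base[:, i] for i in idx], axis=0).astype(np.int8))
    design = np.column_stack(cols)

    if len(np.unique(design, axis=0)) != design.shape[0]:
        raise DesignError("generators yield duplicate runs")
    bad = check_balance(design, order=min(3, n_factors))
    if bad:
        names = ", ".join("*".join(str(i) for i in cols_) for cols_ in bad[:5])
        raise DesignError(
            "design is not balanced through third-order interactions "
            f"(resolution < IV); unbalanced columns: {names}"
        )
    return design


def check_balance(design: np.ndarray, order: int) -> list[tuple[int, ...]]:
    """Return the interaction columns up to ``order`` whose sum is nonzero.

    An empty list means the design is balanced through the requested
    interaction order.  Columns are reported as tuples of 0-based factor
    indices.
    """
    design = np.asarray(design)
    k = design.shape[1]
    if not 1 <= order <= k:
        raise DesignError(f"order must be in [1, {k}], got {order}")
    bad: list[tuple[int, ...]] = []
    for size in range(1, order + 1):
        for combo in itertools.combinations(range(k), size):
            col = np.prod(design[:, combo], axis=1)
            if int(col.sum()) != 0:
                bad.append(combo)
    return bad


def design_to_frame(
    design: np.ndarray, factors: Sequence[FactorSpec] = FACTORS
) -> pd.DataFrame:
    """Translate a -1/+1 design matrix into factor-level labels."""
    design = np.asarray(design)
    if design.shape[1] != len(factors):
        raise DesignError("design width does not match the factor list")
    data = {
        f.name: [f.label(s) for s in design[:, j]]
        for j, f in enumerate(factors)
    }
    return pd.DataFrame(data)


def frame_to_signs(
    frame: pd.DataFrame, factors: Sequence[FactorSpec] = FACTORS
) -> np.ndarray:
    """Inverse of :func:`design_to_frame`."""
    cols = [
        [f.sign(lab) for lab in frame[f.name]] for f in factors
    ]
    return np.column_stack(cols).astype(np.int8)


def make_trial_plan(
    design: np.ndarray,
    participant_id: str,
    seed: int,
    factors: Sequence[FactorSpec] = FACTORS,
) -> pd.DataFrame:
    """Randomise the design for one participant and insert collision trials.

    The 32 factorial runs are shuffled with a seeded uniform permutation and
    the four scripted collision trials are inserted at ranks 7, 14, 21 and
    28 (1-based).  Collision rows carry only the recorded speed annotation
    (vehicle 30 kph, pedestrian 7.5 kph); their other factor columns are
    empty and ``is_collision`` is set.

    Returns a DataFrame with columns ``participant_id``, ``rank``,
    ``is_collision`` and one label column per factor.
    """
    design = np.asarray(design)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(design.shape[0])
    shuffled = design[perm]

    n_total = design.shape[0] + len(COLLISION_RANKS)
    collision_idx = {r - 1 for r in COLLISION_RANKS}
    rows = []
    it = iter(shuffled)
    for i in range(n_total):
        if i in collision_idx:
            labels = {f.name: COLLISION_ANNOTATION.get(f.name, "") for f in factors}
            rows.append(
                {"participant_id": participant_id, "rank": i + 1,
                 "is_collision": True, **labels}
            )
        else:
            run = next(it)
            labels = {f.name: f.label(s) for f, s in zip(factors, run)}
            rows.append(
                {"participant_id": participant_id, "rank": i + 1,
                 "is_collision": False, **labels}
            )
    return pd.DataFrame(rows)
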