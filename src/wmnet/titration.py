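"""Day-1 staircase simulation and psychometric titration.

Before scanning, each participant's working-memory span is titrated with
an adaptive staircase on set size: +1 letter after a correct response,
-2 letters after an error, clamped to the stimulus range [3, 9].  The
per-size accuracies are then fitted with a sigmoid whose asymptotes are
1.0 (floor effect at tiny arrays) and 0.5 (the largest-array anchor),

    acc(s) = 0.5 + 0.5 / (1 + exp(k * (s - m)))

with midpoint ``m`` and slope ``k > 0``.  The *Criterion* is the
continuous set size where the fitted curve crosses 82% accuracy; it
doubles as the subject-level working-memory-ability covariate.  The four
individually titrated difficulty levels are consecutive set sizes: the
two sizes with fitted accuracy immediately above Criterion (Very Easy,
Easy) and the two immediately below (Medium, Hard), so the Very Easy
size is the subject's *Starting Set Size*.

Stabilising conventions used before fitting: observed sizes tested on
fewer than 10 trials enter at 50% accuracy, and peripheral anchors are
appended at sizes 1 and 2 (100%) and 10 and 11 (50%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TitrationError",
    "PsychometricFit",
    "RelativeLevels",
    "sigmoid_accuracy",
    "run_staircase",
    "trace_to_counts",
    "prepare_fit_table",
    "fit_psychometric",
    "derive_levels",
    "titrate_subject",
]

SIZE_FLOOR, SIZE_CEIL = 3, 9
CRITERION_ACCURACY = 0.82
MIN_TRIALS_PER_SIZE = 10
#: (size, accuracy) anchor points appended before every fit.
ANCHORS = ((1, 1.00), (2, 1.00), (10, 0.50), (11, 0.50))

# logit of the criterion on the [0.5, 1] sigmoid: solves
# 0.5 + 0.5/(1+e^x) = 0.82  =>  x = log(0.5625)
_CRIT_X = float(np.log((1.0 - CRITERION_ACCURACY) / (CRITERION_ACCURACY - 0.5)))


class TitrationError(ValueError):
    """Raised for degenerate staircase data or out-of-range fits."""


def sigmoid_accuracy(size, midpoint: float, slope: float):
    """Fitted accuracy family: 1.0 at small sizes, 0.5 asymptote at large."""
    size = np.asarray(size, dtype=float)
    return 0.5 + 0.5 / (1.0 + np.exp(slope * (size - midpoint)))


@dataclass(frozen=True)
class PsychometricFit:
    """Two-parameter sigmoid fit with the derived 82% Criterion."""

    midpoint: float
    slope: float
    criterion_set_size: float

    def accuracy(self, size):
        return sigmoid_accuracy(size, self.midpoint, self.slope)


@dataclass(frozen=True)
class RelativeLevels:
    """The four consecutive titrated set sizes, coded 1-4."""

    starting_set_size: int
    levels: tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.levels is None:
            object.__setattr__(
                self, "levels", tuple(self.starting_set_size + i for i in range(4)))
        if list(self.levels) != list(range(self.levels[0], self.levels[0] + 4)):
            raise TitrationError(f"levels {self.levels} are not consecutive")

    def absolute_size(self, level: int) -> int:
        """Absolute set size for a relative difficulty code 1-4."""
        return self.levels[level - 1]


def run_staircase(
    true_psychometric: Mapping[int, float] | Callable[[int], float],
    n_trials: int,
    rng: np.random.Generator,
    start_size: int = SIZE_FLOOR,
) -> pd.DataFrame:
    """Simulate the adaptive staircase against a known psychometric.

    ``true_psychometric`` maps set size to p(correct).  Returns a frame
    with columns ``trial``, ``set_size`` (the size presented on that
    trial) and ``correct``.
    """
    if n_trials < 1:
        raise TitrationError("n_trials must be >= 1")
    if not SIZE_FLOOR <= start_size <= SIZE_CEIL:
        raise TitrationError(f"start_size {start_size} outside stimulus range")
    p_of = true_psychometric if callable(true_psychometric) else true_psychometric.__getitem__
    size = int(start_size)
    rows = []
    for trial in range(n_trials):
        p = float(p_of(size))
        if not 0.0 <= p <= 1.0:
            raise TitrationError(f"accuracy {p} for size {size} outside [0, 1]")
        correct = bool(rng.random() < p)
        rows.append((trial, size, correct))
        size = size + 1 if correct else size - 2
        size = min(max(size, SIZE_FLOOR), SIZE_CEIL)
    return pd.DataFrame(rows, columns=["trial", "set_size", "correct"])


def trace_to_counts(trace: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a staircase trace to (size, n_trials, n_correct)."""
    g = trace.groupby("set_size")["correct"]
    out = pd.DataFrame({
        "size": g.size().index.to_numpy(),
        "n_trials": g.size().to_numpy(),
        "n_correct": g.sum().to_numpy().astype(int),
    })
    return out


def prepare_fit_table(accuracy_by_size: pd.DataFrame) -> pd.DataFrame:
    """Apply the low-trial-count rule and append the peripheral anchors.

    The largest set sizes are corrected for sparse sampling: an
    observed size with fewer than 10 trials enters the fit at 50%
    accuracy when it lies above every adequately sampled size (the
    staircase rarely visits sizes far above a subject's span, so raw
    accuracies there are noise).  Under-sampled sizes *below* the
    staircase's range keep their raw accuracy; the 100% anchors at
    sizes 1-2 stabilise that end.  Anchor points (1, 1.0), (2, 1.0),
    (10, 0.5), (11, 0.5) are always appended.  Returns a frame with
    (size, accuracy, is_anchor).
    """
    req = {"size", "n_trials", "n_correct"}
    if not req.issubset(accuracy_by_size.columns):
        raise TitrationError(f"fit table needs columns {sorted(req)}")
    obs = accuracy_by_size.copy()
    acc = obs["n_correct"] / obs["n_trials"]
    well = obs.loc[obs["n_trials"] >= MIN_TRIALS_PER_SIZE, "size"]
    top_well = int(well.max()) if len(well) else int(obs["size"].min()) - 1
    sparse_top = (obs["n_trials"] < MIN_TRIALS_PER_SIZE) & (obs["size"] > top_well)
    acc = acc.where(~sparse_top, 0.50)
    rows = [(int(s), float(a), False) for s, a in zip(obs["size"], acc)]
    rows += [(s, a, True) for s, a in ANCHORS]
    return pd.DataFrame(rows, columns=["size", "accuracy", "is_anchor"])


def fit_psychometric(accuracy_by_size: pd.DataFrame) -> PsychometricFit:
    """Unweighted least-squares sigmoid fit of per-size accuracies.

    ``accuracy_by_size`` has columns (size, n_trials, n_correct) for the
    observed staircase sizes; anchors and the low-count rule are applied
    internally.
    """
    if len(accuracy_by_size) < 2:
        raise TitrationError(
            "need observed accuracies for at least 2 set sizes")
    table = prepare_fit_table(accuracy_by_size)
    x = table["size"].to_numpy(float)
    y = table["accuracy"].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign overflow in exp during search
        (midpoint, slope), _ = curve_fit(
            sigmoid_accuracy, x, y,
            p0=(6.0, 1.0), bounds=((0.0, 1e-3), (12.0, 20.0)), maxfev=20000)
    criterion = midpoint + _CRIT_X / slope
    criterion = float(np.clip(criterion, 1.0, 11.0))
    return PsychometricFit(float(midpoint), float(slope), criterion)


def derive_levels(fit: PsychometricFit) -> RelativeLevels:
    """Map a psychometric fit to the four titrated set sizes.

    *Easy* is the set size whose fitted accuracy is immediately above
    Criterion, *Very Easy* the one above that; Medium and Hard follow
    below.  The fitted curve must cross 82% within the stimulus range;
    the starting size is clamped to [3, 6] so all four levels stay
    within [3, 9].
    """
    acc = fit.accuracy(np.arange(SIZE_FLOOR, SIZE_CEIL + 1))
    above = acc > CRITERION_ACCURACY
    if not above[0]:
        raise TitrationError(
            "fitted accuracy is below Criterion over the whole range")
    if above[-1]:
        raise TitrationError(
            "fitted accuracy never drops below Criterion within [3, 9]")
    easy = SIZE_FLOOR + int(np.max(np.nonzero(above)[0]))
    start = min(max(easy - 1, SIZE_FLOOR), SIZE_CEIL - 3)
    return RelativeLevels(starting_set_size=start)


def titrate_subject(
    true_psychometric: Mapping[int, float] | Callable[[int], float],
    rng: np.random.Generator,
    n_trials: int = 150,
    start_size: int = SIZE_FLOOR,
) -> tuple[PsychometricFit, RelativeLevels, pd.DataFrame]:
    """Run staircase, fit the sigmoid and derive levels in one call.

    The 150-trial default mirrors a six-block, 25-trial screening
    session.
    """
    trace = run_staircase(true_psychometric, n_trials, rng, start_size)
    counts = trace_to_counts(trace)
    fit = fit_psychometric(counts)
    return fit, derive_levels(fit), trace
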