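"""Sorting-step counts for letter-array alphabetization.

Manipulation demand in the delayed-recognition alphabetization task is
quantified as the minimum number of discrete reordering moves needed to
alphabetize a random consonant array, minimized over four sorting
algorithms: insertion, selection, and merge variants of each.  Because
people are not known to follow any particular algorithm, the most
efficient of the four counts is taken per array.

Counting rules (each rule counts visible reordering moves, not
comparisons):

* ``insertion`` — scan left to right; a letter costs one step iff it is
  not a running maximum of the prefix (i.e. it must be extracted and
  reinserted into the sorted prefix).  Equivalently ``n`` minus the
  number of left-to-right maxima.
* ``selection`` — one step per executed swap, swapping each
  alphabetically-earliest remaining letter into place; letters already
  in place cost nothing.  Equals ``n`` minus the number of cycles of the
  sorting permutation.
* ``merge_insertion`` / ``merge_selection`` — split the array at
  ``ceil(n/2)``, count steps inside each half with the base rule, then
  merge the two sorted halves; each element taken from the second half
  while the first is non-empty costs one step.

Two closed-form oracles are provided for verification: the minimum
number of transpositions (``n`` minus permutation cycles) and the
minimum number of remove-and-reinsert moves (``n`` minus the longest
increasing subsequence).
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONSONANTS",
    "ALGORITHMS",
    "LetterArrayError",
    "validate_array",
    "count_steps",
    "all_step_counts",
    "min_sorting_steps",
    "oracle_min_steps",
    "generate_array",
    "generate_stimulus_set",
    "steps_table",
]

VOWELS = frozenset("AEIOU")
#: The 21 uppercase consonants used as stimuli (vowels excluded to
#: prevent chunking into pronounceable groups).
CONSONANTS = tuple(c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if c not in VOWELS)

ALGORITHMS = ("insertion", "selection", "merge_insertion", "merge_selection")

MIN_LEN, MAX_LEN = 3, 9


class LetterArrayError(ValueError):
    """Raised for invalid letter arrays or unknown algorithm names."""


def validate_array(letters: Sequence[str] | str, consonants_only: bool = False) -> str:
    """Validate a letter array and return it as an uppercase string.

    Arrays must hold 3-9 distinct uppercase letters.  Step counting
    depends only on the relative alphabetical order, so any letters are
    orderable; with ``consonants_only=True`` (the stimulus invariant)
    vowels are rejected as well.
    """
    s = "".join(letters).upper()
    if not (MIN_LEN <= len(s) <= MAX_LEN):
        raise LetterArrayError(
            f"array length {len(s)} outside [{MIN_LEN}, {MAX_LEN}]: {s!r}")
    if len(set(s)) != len(s):
        raise LetterArrayError(f"array has duplicate letters: {s!r}")
    allowed = set(CONSONANTS) if consonants_only else set(
        "ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    bad = sorted(set(s) - allowed)
    if bad:
        raise LetterArrayError(f"array has invalid letters {bad}: {s!r}")
    return s


def _insertion_steps(seq: Sequence[str]) -> int:
    # n minus the number of left-to-right running maxima.
    steps, prefix_max = 0, ""
    for letter in seq:
        if letter > prefix_max:
            prefix_max = letter
        else:
            steps += 1
    return steps


def _selection_steps(seq: Sequence[str]) -> int:
    # n minus the number of cycles of the sorting permutation.
    target = {letter: i for i, letter in enumerate(sorted(seq))}
    perm = [target[letter] for letter in seq]
    return len(perm) - _n_cycles(perm)


def _n_cycles(perm: Sequence[int]) -> int:
    seen = [False] * len(perm)
    cycles = 0
    for start in range(len(perm)):
        if seen[start]:
            continue
        cycles += 1
        j = start
        while not seen[j]:
            seen[j] = True
            j = perm[j]
    return cycles


def _merge_cost(first: Sequence[str], second: Sequence[str]) -> int:
    # One step per element pulled from the second half while the first
    # half still has elements waiting.
    a, b = sorted(first), sorted(second)
    i = j = cost = 0
    while i < len(a) and j < len(b):
        if b[j] < a[i]:
            cost += 1
            j += 1
        else:
            i += 1
    return cost


def _merge_steps(seq: Sequence[str], base) -> int:
    split = (len(seq) + 1) // 2
    first, second = seq[:split], seq[split:]
    return base(first) + base(second) + _merge_cost(first, second)


_COUNTERS = {
    "insertion": _insertion_steps,
    "selection": _selection_steps,
    "merge_insertion": lambda s: _merge_steps(s, _insertion_steps),
    "merge_selection": lambda s: _merge_steps(s, _selection_steps),
}


def count_steps(array: Sequence[str] | str, algorithm: str) -> int:
    """Number of reordering steps to alphabetize ``array`` under one rule."""
    s = validate_array(array)
    try:
        counter = _COUNTERS[algorithm]
    except KeyError:
        raise LetterArrayError(
            f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
        ) from None
    return counter(s)


def all_step_counts(array: Sequence[str] | str) -> dict[str, int]:
    """Step counts for all four algorithms."""
    s = validate_array(array)
    return {name: _COUNTERS[name](s) for name in ALGORITHMS}


def min_sorting_steps(array: Sequence[str] | str) -> int:
    """Minimum step count over the four sorting algorithms.

    This is the per-trial manipulation-demand code ("Sorting Steps").
    """
    return min(all_step_counts(array).values())


def oracle_min_steps(array: Sequence[str] | str, primitive: str) -> int:
    """Closed-form minimum move counts, for independent verification.

    ``transposition``: minimum number of pairwise swaps, equal to ``n``
    minus the number of permutation cycles.  ``remove_reinsert``:
    minimum number of remove-and-reinsert moves, equal to ``n`` minus
    the length of the longest increasing subsequence.
    """
    s = validate_array(array)
    if primitive == "transposition":
        return _selection_steps(s)
    if primitive == "remove_reinsert":
        return len(s) - _lis_length(s)
    raise LetterArrayError(f"unknown primitive {primitive!r}")


def _lis_length(seq: Sequence[str]) -> int:
    tails: list[str] = []
    for letter in seq:
        pos = bisect_left(tails, letter)
        if pos == len(tails):
            tails.append(letter)
        else:
            tails[pos] = letter
    return len(tails)


def generate_array(size: int, rng: np.random.Generator) -> str:
    """Draw ``size`` distinct consonants uniformly, in random order."""
    if not (MIN_LEN <= size <= MAX_LEN):
        raise LetterArrayError(f"size {size} outside [{MIN_LEN}, {MAX_LEN}]")
    picks = rng.choice(len(CONSONANTS), size=size, replace=False)
    return "".join(CONSONANTS[i] for i in picks)


def generate_stimulus_set(
    sizes: Iterable[int], per_size: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Stratified stimulus set: ``per_size`` random arrays per set size.

    Returns a tidy frame with columns ``size``, ``array`` and
    ``min_steps`` (recorded at generation time).
    """
    if per_size < 1:
        raise LetterArrayError("per_size must be >= 1")
    rows = []
    for size in sizes:
        for _ in range(per_size):
            arr = generate_array(int(size), rng)
            rows.append((int(size), arr, min_sorting_steps(arr)))
    return pd.DataFrame(rows, columns=["size", "array", "min_steps"])


def steps_table(arrays: Iterable[str]) -> pd.DataFrame:
    """Per-array step counts for every algorithm plus the minimum."""
    rows = []
    for arr in arrays:
        counts = all_step_counts(arr)
        rows.append({"array": validate_array(arr), **{
            f"steps_{k}": v for k, v in counts.items()},
            "min_steps": min(counts.values())})
    return pd.DataFrame(rows)
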