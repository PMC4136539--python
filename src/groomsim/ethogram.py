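"""Ethogram containers and behavioral-sequence statistics.

An ethogram is an ordered record of which mutually exclusive behavior is
being performed at each timestep.  Everything downstream of the simulator
(and everything upstream of it in real experiments, where ethograms come
from manually scored video) works on this one representation, so the
statistics here accept either an :class:`Ethogram` or any plain sequence of
label strings.

The statistics are bout-based: a *bout* is a maximal run of consecutive
timesteps with the same label, bout frequency counts bout starts, marginal
probability is the fraction of total bouts carried by each behavior, and
transition probabilities are the row-normalized counts of bout-to-bout
label changes (self-transitions are impossible by bout maximality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import groupby
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "Ethogram",
    "Bout",
    "TransitionMatrix",
    "find_bouts",
    "bout_frequency",
    "marginal_probability",
    "cohort_marginal_probability",
    "transition_probabilities",
    "change_from_control",
]


@dataclass(frozen=True)
class Ethogram:
    """Label-per-timestep record of one subject's behavior.

    Parameters
    ----------
    labels
        Ordered behavior labels, one per timestep.  Must be nonempty.
    timestep
        Duration of one step in seconds; simulator iterations use 1.0.
    subject_id
        Optional identifier of the fly or simulated run.
    """

    labels: Tuple[str, ...]
    timestep: float = 1.0
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) == 0:
            raise ValueError("an ethogram must contain at least one timestep")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def vocabulary(self) -> Tuple[str, ...]:
        """Distinct labels in order of first appearance."""
        return tuple(dict.fromkeys(self.labels))


class Bout(NamedTuple):
    """Maximal run of one behavior: label, 1-based start timestep, length."""

    label: str
    start: int
    length: int


@dataclass
class TransitionMatrix:
    """First-order bout-to-bout transition counts and probabilities.

    ``probabilities`` rows are counts rows divided by their row sum; a label
    with no outgoing transitions (it only ever ends the record) keeps an
    all-zero row and is listed in ``terminal_labels`` rather than being
    renormalized.  ``min_display`` is a display threshold for graph export
    only and never alters the matrix itself.
    """

    labels: Tuple[str, ...]
    counts: pd.DataFrame
    probabilities: pd.DataFrame
    terminal_labels: Tuple[str, ...] = ()
    min_display: Optional[float] = None
    unit: str = "bout"


def _as_labels(ethogram: Union[Ethogram, Sequence[str]]) -> Tuple[str, ...]:
    if isinstance(ethogram, Ethogram):
        return ethogram.labels
    labels = tuple(str(x) for x in ethogram)
    if len(labels) == 0:
        raise ValueError("empty ethogram")
    return labels


def find_bouts(ethogram: Union[Ethogram, Sequence[str]]) -> List[Bout]:
    """Run-length encode an ethogram into maximal bouts.

    Concatenating the returned runs reconstructs the input exactly, and
    consecutive bouts always carry different labels.
    """
    labels = _as_labels(ethogram)
    bouts: List[Bout] = []
    start = 1
    for label, run in groupby(labels):
        n = sum(1 for _ in run)
        bouts.append(Bout(label, start, n))
        start += n
    return bouts


def bout_frequency(
    ethogram: Union[Ethogram, Sequence[str]],
    interval: Optional[int] = None,
    vocabulary: Optional[Sequence[str]] = None,
) -> Union[pd.Series, pd.DataFrame]:
    """Count bout starts per behavior, optionally binned into time intervals.

    Parameters
    ----------
    ethogram
        Ethogram or label sequence.
    interval
        If given, the number of timesteps per bin; a bout is assigned to the
        bin containing its start timestep only.  Returns a DataFrame indexed
        by 1-based interval number with one column per label.
    vocabulary
        Labels to report (missing ones get count 0).  Defaults to the labels
        present, in order of first appearance.
    """
    bouts = find_bouts(ethogram)
    if vocabulary is None:
        vocabulary = tuple(dict.fromkeys(b.label for b in bouts))
    if interval is None:
        counts = pd.Series(0, index=list(vocabulary), dtype=int, name="bouts")
        for b in bouts:
            if b.label in counts.index:
                counts[b.label] += 1
        return counts
    if interval <= 0:
        raise ValueError("interval length must be positive")
    n_bins = (len(_as_labels(ethogram)) - 1) // interval + 1
    table = pd.DataFrame(
        0, index=pd.RangeIndex(1, n_bins + 1, name="interval"), columns=list(vocabulary), dtype=int
    )
    for b in bouts:
        if b.label in table.columns:
            table.loc[(b.start - 1) // interval + 1, b.label] += 1
    return table


def marginal_probability(
    ethogram: Union[Ethogram, Sequence[str]], exact: bool = False
) -> Union[pd.Series, Dict[str, Fraction]]:
    """Fraction of total bouts carried by each behavior.

    With ``exact=True`` returns :class:`fractions.Fraction` values, whose sum
    is exactly 1; otherwise a float Series.
    """
    counts = bout_frequency(ethogram)
    total = int(counts.sum())
    fracs = {label: Fraction(int(c), total) for label, c in counts.items()}
    if exact:
        return fracs
    return pd.Series({k: float(v) for k, v in fracs.items()}, name="marginal_probability")


def cohort_marginal_probability(ethograms: Iterable[Union[Ethogram, Sequence[str]]]) -> pd.Series:
    """Mean of per-subject bout fractions across a cohort of ethograms."""
    per_subject = [marginal_probability(e) for e in ethograms]
    if not per_subject:
        raise ValueError("empty cohort")
    table = pd.DataFrame(per_subject).fillna(0.0)
    return table.mean(axis=0).rename("marginal_probability")


def transition_probabilities(
    ethogram: Union[Ethogram, Sequence[str]],
    min_display: Optional[float] = None,
    unit: str = "bout",
) -> TransitionMatrix:
    """Estimate the first-order transition matrix of an ethogram.

    ``unit="bout"`` (default) counts transitions between consecutive bouts,
    so the diagonal is identically zero; ``unit="timestep"`` counts
    consecutive raw timesteps, including self-transitions.  Each populated
    probability row sums to 1; rows for terminal labels stay all-zero and are
    flagged in ``terminal_labels``.
    """
    if unit not in ("bout", "timestep"):
        raise ValueError(f"unknown transition unit {unit!r}")
    if unit == "bout":
        seq = [b.label for b in find_bouts(ethogram)]
        if len(seq) < 2:
            raise ValueError("transition analysis needs at least 2 bouts")
    else:
        seq = list(_as_labels(ethogram))
        if len(seq) < 2:
            raise ValueError("transition analysis needs at least 2 timesteps")
    labels = tuple(dict.fromkeys(seq))
    counts = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for a, b in zip(seq[:-1], seq[1:]):
        counts.loc[a, b] += 1
    row_sums = counts.sum(axis=1)
    probs = counts.astype(float)
    populated = row_sums > 0
    probs.loc[populated] = probs.loc[populated].div(row_sums[populated], axis=0)
    terminal = tuple(row_sums.index[~populated])
    return TransitionMatrix(
        labels=labels,
        counts=counts,
        probabilities=probs,
        terminal_labels=terminal,
        min_display=min_display,
        unit=unit,
    )


def change_from_control(
    experimental: Union[pd.Series, Dict[str, float]],
    control: Union[pd.Series, Dict[str, float]],
) -> pd.Series:
    """Elementwise experimental minus control per behavior label.

    Positive values mean an increase over control.  The two tables must
    cover exactly the same label vocabulary.
    """
    exp = pd.Series(experimental, dtype=float)
    ctrl = pd.Series(control, dtype=float)
    if set(exp.index) != set(ctrl.index):
        missing = set(exp.index).symmetric_difference(ctrl.index)
        raise ValueError(f"label vocabularies differ: {sorted(missing)}")
    return (exp - ctrl.reindex(exp.index)).rename("change_from_control")
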