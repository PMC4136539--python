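"""Synthetic inputs with known ground truth for every pipeline stage.

The study's raw inputs — grooming videos and dissected-body-part
photographs — cannot be redistributed, so every consumer in this package is
exercised against generated data whose generating parameters are known:
Markov-chain ethograms with a known transition matrix, binary dust-image
stacks with a known per-pixel dust probability, decay time series with a
known half-clearance time, and the canonical simulator scenario configs.

All generators are seed-deterministic and return (or take) their ground
truth explicitly so estimator-recovery tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dustmaps import DustImage
from .ethogram import Ethogram
from .model import FLAT, SGM, UIM, ModelConfig

__all__ = [
    "MarkovEthogramSample",
    "generate_markov_ethogram",
    "generate_dust_image_stack",
    "generate_decay_series",
    "scenario_configs",
]


@dataclass
class MarkovEthogramSample:
    """A generated ethogram together with its generating ground truth."""

    ethogram: Ethogram
    transition_probabilities: pd.DataFrame
    bout_labels: Tuple[str, ...]
    bout_counts: pd.Series


def _validate_transition_matrix(P: np.ndarray) -> None:
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < 0):
        raise ValueError("P must be nonnegative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P rows must sum to 1")
    if np.any(np.diag(P) != 0):
        raise ValueError("P must have a zero diagonal (bouts cannot self-transition)")


def generate_markov_ethogram(
    P: Union[np.ndarray, pd.DataFrame],
    n_bouts: int,
    dwell: Union[float, Dict[str, float]] = 1.0,
    labels: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    start: Optional[str] = None,
) -> MarkovEthogramSample:
    """Sample an ethogram of ``n_bouts`` maximal runs from a label chain.

    Bout labels follow the zero-diagonal row-stochastic matrix ``P``; bout
    lengths are geometric with the given per-label mean ``dwell`` (the
    memoryless minimal assumption consistent with first-order transition
    analysis).  The chain starts at ``start`` (default: the first label).
    """
    if isinstance(P, pd.DataFrame):
        if labels is None:
            labels = list(P.index)
        P = P.to_numpy(dtype=float)
    else:
        P = np.asarray(P, dtype=float)
    _validate_transition_matrix(P)
    n_labels = P.shape[0]
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(n_labels)]
    labels = [str(x) for x in labels]
    if len(labels) != n_labels:
        raise ValueError("labels length must match P")
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    dwell_by_label = (
        {lab: float(dwell) for lab in labels} if np.isscalar(dwell) else {k: float(v) for k, v in dwell.items()}
    )
    for lab in labels:
        if dwell_by_label.get(lab, 0) < 1:
            raise ValueError(f"mean dwell for {lab!r} must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    state = labels.index(start) if start is not None else 0
    bout_labels: List[str] = []
    steps: List[str] = []
    for _ in range(n_bouts):
        lab = labels[state]
        bout_labels.append(lab)
        length = int(rng.geometric(1.0 / dwell_by_label[lab]))
        steps.extend([lab] * length)
        state = int(rng.choice(n_labels, p=P[state]))
    counts = pd.Series(bout_labels).value_counts().reindex(labels, fill_value=0)
    return MarkovEthogramSample(
        ethogram=Ethogram(tuple(steps), subject_id="synthetic-markov"),
        transition_probabilities=pd.DataFrame(P, index=labels, columns=labels),
        bout_labels=tuple(bout_labels),
        bout_counts=counts.rename("bouts"),
    )


def generate_dust_image_stack(
    p_map: np.ndarray,
    n_subjects: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    body_part: str = "head",
    time_min: float = 0.0,
) -> List[DustImage]:
    """Binary image stack with independent per-pixel dust probability ``p_map``.

    ``p_map`` is the exact groomogram expectation of the returned stack.
    """
    p_map = np.asarray(p_map, dtype=float)
    if p_map.ndim != 2:
        raise ValueError("p_map must be 2-D")
    if np.any(p_map < 0) or np.any(p_map > 1):
        raise ValueError("p_map values must lie in [0, 1]")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return [
        DustImage(
            (rng.random(p_map.shape) < p_map).astype(np.uint8),
            body_part=body_part,
            subject_id=f"synthetic-{i + 1}",
            time_min=time_min,
        )
        for i in range(n_subjects)
    ]


def generate_decay_series(
    f0: float = 1.0,
    t50_true: float = 7.0,
    model: str = "exponential",
    noise_sd: float = 0.0,
    timepoints: Sequence[float] = (0, 1, 2, 5, 10, 15, 25, 35),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    sigmoid_slope: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Noisy decay time series with known half-clearance time ``t50_true``.

    ``exponential`` uses f0 * exp(-ln2 * t / t50); ``sigmoidal`` uses the
    4-parameter logistic with floor 0, ceiling f0 and midpoint t50 (so the
    curve crosses f0/2 exactly at t50 in both families).  Additive Gaussian
    noise is clipped to [0, 1].
    """
    if t50_true <= 0:
        raise ValueError("t50_true must be positive")
    times = np.asarray(timepoints, dtype=float)
    if model == "exponential":
        values = f0 * np.exp(-np.log(2.0) * times / t50_true)
    elif model == "sigmoidal":
        values = f0 / (1.0 + (times / t50_true) ** sigmoid_slope)
    else:
        raise ValueError("model must be 'exponential' or 'sigmoidal'")
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, size=times.shape), 0.0, 1.0)
    return times, values


def scenario_configs() -> Dict[str, ModelConfig]:
    """The six canonical simulator scenarios, with fixed seeds.

    * ``flat`` — equal dust sensitivities, no inhibition: unordered
      grooming in which only the initial dust noise picks the winner.
    * ``sensory_gain`` — strictly decreasing sensory weights impose the
      hierarchy.
    * ``inhibition`` — unidirectional lateral inhibition (each module
      suppresses all its subordinates) imposes the hierarchy.
    * ``constitutive_clean`` — one module clamped fully dirty with no dust
      anywhere else: continual cleaning of that body part alone.
    * ``constitutive_dusted`` — the same clamp with full-body dust under
      inhibition: superior modules clean, inferior ones are never selected.
    * ``leg_rubbing`` — four body modules plus two leg pairs that accumulate
      dust while body parts are cleaned; the legs' high sensory gain lets
      them win once dirty enough, producing cyclic body/leg alternation.
    """
    return {
        "flat": ModelConfig(mode=FLAT, n_modules=5, n_iterations=200, seed=11),
        "sensory_gain": ModelConfig(mode=SGM, n_modules=5, n_iterations=400, seed=12),
        "inhibition": ModelConfig(mode=UIM, n_modules=5, n_iterations=400, seed=13),
        "constitutive_clean": ModelConfig(
            mode=UIM,
            n_modules=5,
            dust_base=0.0,
            dust_noise=0.0,
            clamped_modules=frozenset({3}),
            clamp_value=1.0,
            n_iterations=200,
            seed=14,
        ),
        "constitutive_dusted": ModelConfig(
            mode=UIM,
            n_modules=5,
            clamped_modules=frozenset({3}),
            n_iterations=400,
            seed=15,
        ),
        "leg_rubbing": ModelConfig(
            mode=UIM,
            inhibition_weight=-1.0,
            n_modules=4,
            dust_removal=0.02,
            legs_enabled=True,
            leg_gain=4.0,
            leg_threshold=0.8,
            leg_increment=0.05,
            leg_dust_removal=0.05,
            anterior_boundary=3,
            n_iterations=700,
            seed=16,
        ),
    }
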