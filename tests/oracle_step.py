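"""Independent straight-line re-implementation of one simulator iteration.

Written in plain Python loops, deliberately sharing no code with
``groomsim.model``, so that replaying a run step by step provides an
independent check of the simulator's per-iteration state.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from groomsim.model import FRONT_LEG_RUB, HIND_LEG_RUB, ModelConfig


def oracle_step(
    cfg: ModelConfig,
    dust: List[float],
    prev_activation: List[float],
    leg_dust: List[float],
):
    """One iteration: returns (winner, activation, new_dust, new_leg_dust).

    ``winner`` is a 1-based module index or a leg label; ``prev_activation``
    matters only for the literal recurrence.
    """
    n = cfg.n_modules
    d = [float(x) for x in dust]

    if cfg.mode == "sgm":
        ws = [float(x) for x in cfg.resolved_sensory_weights]
        a = [d[k] * ws[k] for k in range(n)]
    elif cfg.mode == "uim":
        w = cfg.resolved_inhibition_weight
        src = d if cfg.uim_recurrence == "stateless" else [float(x) for x in prev_activation]
        a = [src[j] + w * sum(src[:j]) for j in range(n)]
    else:
        a = d[:]

    body_max = a[0]
    body_arg = 0
    for k in range(1, n):
        if a[k] > body_max:
            body_max = a[k]
            body_arg = k

    winner = body_arg + 1
    if cfg.legs_enabled:
        al = [cfg.leg_gain * x for x in leg_dust]
        if al[0] >= cfg.leg_threshold and al[0] > body_max and al[0] > al[1]:
            winner = FRONT_LEG_RUB
        elif al[1] >= cfg.leg_threshold and al[1] > body_max and al[1] > al[0]:
            winner = HIND_LEG_RUB

    dl = [float(x) for x in leg_dust]
    if winner == FRONT_LEG_RUB:
        dl[0] = max(0.0, dl[0] - cfg.leg_dust_removal)
    elif winner == HIND_LEG_RUB:
        dl[1] = max(0.0, dl[1] - cfg.leg_dust_removal)
    else:
        d[winner - 1] = max(0.0, d[winner - 1] - cfg.dust_removal)
        if cfg.legs_enabled:
            pair = 0 if winner <= cfg.anterior_boundary else 1
            dl[pair] += cfg.leg_increment
    for k in cfg.clamped_modules:
        d[k - 1] = cfg.resolved_clamp_value
    return winner, a, d, dl


def random_config(rng: np.random.Generator, max_modules: int = 6) -> ModelConfig:
    """A random small but valid simulator configuration."""
    n = int(rng.integers(1, max_modules + 1))
    mode = str(rng.choice(["flat", "sgm", "uim"]))
    clamped = frozenset(
        int(k) for k in range(1, n + 1) if rng.random() < 0.15
    )
    kwargs = dict(
        mode=mode,
        n_modules=n,
        dust_base=float(rng.uniform(0.5, 0.95)),
        dust_noise=float(rng.uniform(0.0, 0.1)),
        dust_removal=float(rng.uniform(0.02, 0.2)),
        n_iterations=int(rng.integers(10, 80)),
        seed=int(rng.integers(0, 2**31 - 1)),
        clamped_modules=clamped,
    )
    if mode == "uim":
        kwargs["inhibition_weight"] = float(-rng.uniform(0.1, 1.0))
        kwargs["uim_recurrence"] = str(rng.choice(["stateless", "literal"]))
    if mode == "sgm":
        gaps = rng.uniform(0.1, 0.5, size=n)
        ws = 1.0 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])[::-1]
        kwargs["sensory_weights"] = tuple(float(x) for x in ws)
    if rng.random() < 0.4:
        kwargs.update(
            legs_enabled=True,
            leg_gain=float(rng.uniform(1.0, 5.0)),
            leg_threshold=float(rng.uniform(0.3, 1.0)),
            leg_increment=float(rng.uniform(0.01, 0.1)),
            leg_dust_removal=float(rng.uniform(0.01, 0.1)),
            anterior_boundary=int(rng.integers(0, n + 1)),
        )
    return ModelConfig(**kwargs)
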