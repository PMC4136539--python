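"""Winner-take-all simulator of the grooming suppression hierarchy.

Dust-coated flies clean their body parts in a stereotyped priority order
(eyes > antennae > abdomen > wings > thorax).  The simulator reproduces this
with three layers:

* a **sensory layer** — each of ``N`` body-cleaning modules is driven by the
  amount of dust ``d`` on its body part, initialized to ``dust_base + r``
  with ``r ~ U[0, dust_noise]``;
* a **hierarchical layer** — either a *sensory gain model* (``sgm``), where
  activation is ``a = d * w_s`` with strictly decreasing per-module weights
  ``w_s``, or a *unidirectional inhibition model* (``uim``), where
  ``a = d @ W`` with an upper-triangular matrix of equal negative weights so
  every module inhibits all its subordinates.  The ``flat`` control uses
  unit weights and no inhibition;
* a **winner-take-all layer** — only the module with maximal activation acts
  each iteration, removing a constant amount of dust ``dr`` from its body
  part, which lowers its own drive and lets the sequence progress.

Constitutive activation (the in-silico analog of thermogenetic neuronal
activation) clamps a module's dust at a maximum after every iteration.
Optional leg rubbing adds two leg pairs that accumulate dust while body
parts are cleaned and join the same competition once dirty enough,
producing the cyclic body-clean/leg-rub alternation seen in real flies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .ethogram import Ethogram

__all__ = [
    "FLAT",
    "SGM",
    "UIM",
    "MODES",
    "FRONT_LEG_RUB",
    "HIND_LEG_RUB",
    "LEG_LABELS",
    "BODY_PARTS",
    "ModelConfig",
    "build_weight_matrix",
    "init_dust",
    "activation_sgm",
    "activation_uim",
    "select_winner",
    "remove_dust",
    "update_legs",
    "GroomingModel",
    "SimulationResult",
    "simulate",
]

FLAT = "flat"
SGM = "sgm"
UIM = "uim"
MODES = (FLAT, SGM, UIM)

FRONT_LEG_RUB = "front_leg_rub"
HIND_LEG_RUB = "hind_leg_rub"
LEG_LABELS = (FRONT_LEG_RUB, HIND_LEG_RUB)

#: Body parts in hierarchy order for the canonical five-module runs.
BODY_PARTS = ("eye", "antenna", "abdomen", "wing", "thorax")

#: A winner is a 1-based body-module index or a leg-pair label.
Winner = Union[int, str]


@dataclass(frozen=True)
class ModelConfig:
    """All simulator parameters.

    Module indices are 1-based throughout (module 1 is the hierarchically
    superior one).  ``sensory_weights`` and ``inhibition_weight`` default per
    mode: all ones / 0 for ``flat``, linearly spaced from 2.0 down to 1.0 /
    0 for ``sgm`` (so weight gaps dominate the dust noise), all ones / -0.5
    for ``uim``.

    ``uim_recurrence`` selects between the default ``stateless`` update,
    which recomputes activation from current dust every iteration
    (``a = d @ W``) so that cleaning lowers a module's activation, and the
    ``literal`` recurrence ``a <- a @ W`` seeded with the initial dust, in
    which dust feeds in only through the initial condition (kept for
    comparison; it diverges and never reflects cleaning).
    """

    mode: str = FLAT
    n_modules: int = 5
    sensory_weights: Optional[Tuple[float, ...]] = None
    inhibition_weight: Optional[float] = None
    dust_base: float = 0.9
    dust_noise: float = 0.1
    dust_removal: float = 0.05
    n_iterations: int = 200
    seed: int = 0
    clamped_modules: FrozenSet[int] = frozenset()
    clamp_value: Optional[float] = None
    initial_dust: Optional[Tuple[float, ...]] = None
    uim_recurrence: str = "stateless"
    legs_enabled: bool = False
    leg_increment: float = 0.05
    leg_threshold: float = 0.8
    leg_dust_removal: float = 0.05
    leg_gain: float = 1.0
    anterior_boundary: int = 3
    module_labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.uim_recurrence not in ("stateless", "literal"):
            raise ValueError("uim_recurrence must be 'stateless' or 'literal'")
        if self.dust_removal <= 0:
            raise ValueError("dust_removal must be positive")
        if self.dust_noise < 0:
            raise ValueError("dust_noise must be nonnegative")
        if self.leg_increment < 0 or self.leg_gain < 0:
            raise ValueError("leg_increment and leg_gain must be nonnegative")
        if self.legs_enabled and self.leg_dust_removal <= 0:
            raise ValueError("leg_dust_removal must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

        object.__setattr__(self, "clamped_modules", frozenset(int(k) for k in self.clamped_modules))
        if not self.clamped_modules <= set(range(1, self.n_modules + 1)):
            raise ValueError("clamped_modules must be a subset of {1..n_modules}")

        if self.sensory_weights is not None:
            ws = tuple(float(w) for w in self.sensory_weights)
            object.__setattr__(self, "sensory_weights", ws)
            if len(ws) != self.n_modules:
                raise ValueError("sensory_weights must have length n_modules")
            if any(w <= 0 for w in ws):
                raise ValueError("sensory_weights must be positive")
            if self.mode == SGM and self.n_modules > 1 and not all(
                a > b for a, b in zip(ws, ws[1:])
            ):
                raise ValueError("sgm sensory_weights must be strictly decreasing")
            if self.mode == FLAT and any(w != 1.0 for w in ws):
                raise ValueError("flat mode requires unit sensory weights")
        if self.inhibition_weight is not None:
            if self.inhibition_weight > 0:
                raise ValueError("inhibition_weight must be nonpositive")
            if self.mode in (FLAT, SGM) and self.inhibition_weight != 0:
                raise ValueError(f"{self.mode} mode requires inhibition_weight = 0")
        if self.initial_dust is not None:
            d0 = tuple(float(x) for x in self.initial_dust)
            object.__setattr__(self, "initial_dust", d0)
            if len(d0) != self.n_modules:
                raise ValueError("initial_dust must have length n_modules")
            if any(x < 0 for x in d0):
                raise ValueError("initial_dust entries must be nonnegative")
        if self.module_labels is not None:
            labels = tuple(str(x) for x in self.module_labels)
            object.__setattr__(self, "module_labels", labels)
            if len(labels) != self.n_modules or len(set(labels)) != self.n_modules:
                raise ValueError("module_labels must be n_modules unique strings")
            if set(labels) & set(LEG_LABELS):
                raise ValueError("module_labels may not collide with leg labels")

    # ---- resolved parameters -------------------------------------------

    @property
    def resolved_sensory_weights(self) -> np.ndarray:
        if self.sensory_weights is not None:
            return np.asarray(self.sensory_weights, dtype=float)
        if self.mode == SGM:
            return np.linspace(2.0, 1.0, self.n_modules)
        return np.ones(self.n_modules)

    @property
    def resolved_inhibition_weight(self) -> float:
        if self.inhibition_weight is not None:
            return float(self.inhibition_weight)
        return -0.5 if self.mode == UIM else 0.0

    @property
    def resolved_clamp_value(self) -> float:
        if self.clamp_value is not None:
            return float(self.clamp_value)
        return self.dust_base + self.dust_noise

    @property
    def labels(self) -> Tuple[str, ...]:
        """Per-module ethogram labels, ``module_k`` unless overridden."""
        if self.module_labels is not None:
            return self.module_labels
        return tuple(f"module_{k}" for k in range(1, self.n_modules + 1))

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)


def build_weight_matrix(n_modules: int, inhibition_weight: float) -> np.ndarray:
    """N x N matrix with unit diagonal and the inhibition weight on the
    strict upper triangle (module k inhibits every module j > k)."""
    W = np.eye(n_modules)
    iu = np.triu_indices(n_modules, k=1)
    W[iu] = inhibition_weight
    return W


def init_dust(config: ModelConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the initial dust vector ``dust_base + r``, ``r ~ U[0, dust_noise]``.

    Noise is drawn once here, module 1..N in order, and never again during a
    run.  ``config.initial_dust``, when set, bypasses the random draw.
    Clamped modules are set to the clamp value.
    """
    if config.initial_dust is not None:
        d = np.array(config.initial_dust, dtype=float)
    else:
        r = rng.uniform(0.0, config.dust_noise, size=config.n_modules) if config.dust_noise > 0 else np.zeros(config.n_modules)
        d = config.dust_base + r
    for k in config.clamped_modules:
        d[k - 1] = config.resolved_clamp_value
    return d


def activation_sgm(dust: np.ndarray, sensory_weights: np.ndarray) -> np.ndarray:
    """Sensory-gain activation: elementwise ``a_k = d_k * w_s_k``."""
    dust = np.asarray(dust, dtype=float)
    sensory_weights = np.asarray(sensory_weights, dtype=float)
    if dust.shape != sensory_weights.shape:
        raise ValueError("dust and sensory_weights must have the same length")
    return dust * sensory_weights


def activation_uim(
    dust: np.ndarray,
    prev_activation: Optional[np.ndarray],
    W: np.ndarray,
    recurrence: str = "stateless",
) -> np.ndarray:
    """Unidirectional-inhibition activation.

    ``stateless`` (default): ``a = d @ W``, i.e. each module's activation is
    its own dust minus ``|w|`` times the dust of every superior module, so
    cleaning feeds back into suppression each iteration.  ``literal``:
    ``a = prev_activation @ W``, the printed recurrence in which dust enters
    only through the initial condition.
    """
    dust = np.asarray(dust, dtype=float)
    if W.shape != (dust.size, dust.size):
        raise ValueError("weight matrix dimensions do not match the dust vector")
    if recurrence == "stateless":
        return dust @ W
    if recurrence == "literal":
        if prev_activation is None:
            raise ValueError("literal recurrence needs the previous activation")
        prev = np.asarray(prev_activation, dtype=float)
        if prev.shape != dust.shape:
            raise ValueError("previous activation has the wrong length")
        return prev @ W
    raise ValueError(f"unknown recurrence {recurrence!r}")


def select_winner(
    activation: np.ndarray,
    leg_activation: Optional[np.ndarray] = None,
    leg_threshold: float = np.inf,
    legs_enabled: bool = False,
) -> Tuple[Winner, np.ndarray]:
    """Winner-take-all selection of the behavior executed this iteration.

    A leg pair wins only if its activation (i) crosses the stationary
    threshold, (ii) exceeds the activation of every body module, and
    (iii) exceeds the other pair — so leg rubbing stays inside the same
    competitive hierarchy.  Otherwise the body module with maximal
    activation wins, ties broken toward the lowest (hierarchically superior)
    index.  Returns the winner (1-based module index or leg label) and the
    one-hot body selection vector ``e`` (all zeros when a leg pair wins).
    """
    activation = np.asarray(activation, dtype=float)
    if activation.size == 0:
        raise ValueError("empty activation vector")
    e = np.zeros(activation.size)
    if legs_enabled and leg_activation is not None:
        al = np.asarray(leg_activation, dtype=float)
        body_max = float(activation.max())
        for p in (0, 1):
            other = al[1 - p]
            if al[p] >= leg_threshold and al[p] > body_max and al[p] > other:
                return LEG_LABELS[p], e
    idx = int(np.argmax(activation))  # argmax returns the first (lowest-index) maximum
    e[idx] = 1.0
    return idx + 1, e


def remove_dust(
    dust: np.ndarray,
    winner: int,
    dr: float,
    clamped: FrozenSet[int] = frozenset(),
    clamp_value: float = 1.0,
) -> np.ndarray:
    """Subtract ``dr`` from the winning module's dust, floored at zero, then
    re-apply the constitutive clamp."""
    d = np.array(dust, dtype=float)
    if not 1 <= winner <= d.size:
        raise IndexError(f"winner index {winner} out of range 1..{d.size}")
    d[winner - 1] = max(0.0, d[winner - 1] - dr)
    for k in clamped:
        d[k - 1] = clamp_value
    return d


def update_legs(leg_dust: np.ndarray, winner: Winner, config: ModelConfig) -> np.ndarray:
    """Advance the two leg pairs' dust after an iteration.

    A body-module win transfers ``leg_increment`` of dust onto the pair that
    cleaned it: the front pair for module indices at or below
    ``anterior_boundary``, the hind pair otherwise.  A leg-pair win removes
    ``leg_dust_removal`` from that pair, floored at zero.
    """
    dl = np.array(leg_dust, dtype=float)
    if winner == FRONT_LEG_RUB:
        dl[0] = max(0.0, dl[0] - config.leg_dust_removal)
    elif winner == HIND_LEG_RUB:
        dl[1] = max(0.0, dl[1] - config.leg_dust_removal)
    else:
        pair = 0 if int(winner) <= config.anterior_boundary else 1
        dl[pair] += config.leg_increment
    return dl


@dataclass
class SimulationResult:
    """Full state trajectory of one simulated grooming run.

    ``dust`` and ``activation`` are (n_iterations, N) arrays holding the
    post-update dust and the activation used for selection at each
    iteration; ``leg_dust``/``leg_activation`` are (n_iterations, 2) when
    legs are enabled, else None.  ``winners`` holds the raw winner per
    iteration (1-based module index or leg label); the ethogram carries the
    corresponding label strings.
    """

    config: ModelConfig
    ethogram: Ethogram
    winners: Tuple[Winner, ...]
    initial_dust: np.ndarray
    dust: np.ndarray
    activation: np.ndarray
    leg_dust: Optional[np.ndarray] = None
    leg_activation: Optional[np.ndarray] = None

    # ---- tabular views --------------------------------------------------

    @property
    def iterations(self) -> pd.RangeIndex:
        return pd.RangeIndex(1, self.config.n_iterations + 1, name="iteration")

    @property
    def dust_trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(self.dust, index=self.iterations, columns=list(self.config.labels))

    @property
    def activation_trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(self.activation, index=self.iterations, columns=list(self.config.labels))

    @property
    def leg_trajectory(self) -> Optional[pd.DataFrame]:
        if self.leg_dust is None:
            return None
        return pd.DataFrame(self.leg_dust, index=self.iterations, columns=list(LEG_LABELS))

    # ---- summaries ------------------------------------------------------

    def first_selection(self) -> pd.Series:
        """1-based iteration of each label's first selection (NaN if never)."""
        firsts = {}
        for label in list(self.config.labels) + (list(LEG_LABELS) if self.config.legs_enabled else []):
            try:
                firsts[label] = self.ethogram.labels.index(label) + 1
            except ValueError:
                firsts[label] = np.nan
        return pd.Series(firsts, name="first_selection")

    def final_dust(self) -> pd.Series:
        return pd.Series(self.dust[-1], index=list(self.config.labels), name="final_dust")

    def selection_counts(self) -> pd.Series:
        labels = list(self.config.labels) + (list(LEG_LABELS) if self.config.legs_enabled else [])
        counts = pd.Series(0, index=labels, dtype=int, name="selections")
        for lab in self.ethogram.labels:
            counts[lab] += 1
        return counts

    def selection_shares(self) -> pd.Series:
        counts = self.selection_counts()
        return (counts / counts.sum()).rename("selection_share")

    def time_to_clean(self) -> Optional[int]:
        """First iteration at which every unclamped module's dust is zero."""
        unclamped = [k - 1 for k in range(1, self.config.n_modules + 1)
                     if k not in self.config.clamped_modules]
        if not unclamped:
            return None
        done = np.all(self.dust[:, unclamped] <= 1e-12, axis=1)
        hits = np.flatnonzero(done)
        return int(hits[0]) + 1 if hits.size else None

    def summary(self) -> str:
        """Human-readable run summary (config echo plus per-module table)."""
        cfg = self.config
        lines = [
            "Grooming simulation results",
            "=" * 64,
            f"mode: {cfg.mode}    modules: {cfg.n_modules}    iterations: {cfg.n_iterations}",
            f"seed: {cfg.seed}    dr: {cfg.dust_removal}    legs: {cfg.legs_enabled}",
            f"clamped: {sorted(cfg.clamped_modules) or 'none'}",
            "-" * 64,
        ]
        table = pd.DataFrame(
            {
                "weight": self.config.resolved_sensory_weights,
                "initial_dust": self.initial_dust,
                "final_dust": self.dust[-1],
                "selections": self.selection_counts().reindex(list(cfg.labels)).to_numpy(),
                "first_selection": self.first_selection().reindex(list(cfg.labels)).to_numpy(),
            },
            index=list(cfg.labels),
        )
        lines.append(table.to_string(float_format=lambda x: f"{x:.4f}"))
        if cfg.legs_enabled:
            counts = self.selection_counts()
            lines.append("-" * 64)
            lines.append(
                f"leg rubs: front={counts[FRONT_LEG_RUB]} hind={counts[HIND_LEG_RUB]}"
            )
        ttc = self.time_to_clean()
        lines.append("-" * 64)
        lines.append(f"all unclamped dust removed at iteration: {ttc}")
        return "\n".join(lines)


class GroomingModel:
    """Three-layer grooming simulator bound to a :class:`ModelConfig`.

    The model object is cheap to construct; :meth:`simulate` runs the
    configured number of iterations and returns a :class:`SimulationResult`.
    Identical configs with identical seeds produce identical results.
    """

    def __init__(self, config: ModelConfig):
        self.config = config

    @classmethod
    def from_scenario(cls, name: str) -> "GroomingModel":
        from .synthetic import scenario_configs

        configs = scenario_configs()
        if name not in configs:
            raise KeyError(f"unknown scenario {name!r}; available: {sorted(configs)}")
        return cls(configs[name])

    def simulate(self, seed: Optional[int] = None) -> SimulationResult:
        cfg = self.config if seed is None else self.config.replace(seed=seed)
        rng = np.random.default_rng(cfg.seed)
        N = cfg.n_modules
        ws = cfg.resolved_sensory_weights
        W = build_weight_matrix(N, cfg.resolved_inhibition_weight)
        clamp = cfg.resolved_clamp_value

        d = init_dust(cfg, rng)
        d0 = d.copy()
        a_prev = d0.copy()  # seed of the literal recurrence
        dl = np.zeros(2)

        winners: list = []
        labels: list = []
        dust_hist = np.empty((cfg.n_iterations, N))
        act_hist = np.empty((cfg.n_iterations, N))
        leg_hist = np.empty((cfg.n_iterations, 2)) if cfg.legs_enabled else None
        leg_act_hist = np.empty((cfg.n_iterations, 2)) if cfg.legs_enabled else None

        for i in range(cfg.n_iterations):
            if cfg.mode == SGM:
                a = activation_sgm(d, ws)
            elif cfg.mode == UIM:
                a = activation_uim(d, a_prev, W, cfg.uim_recurrence)
                a_prev = a
            else:
                a = d.copy()
            al = cfg.leg_gain * dl
            winner, _ = select_winner(a, al, cfg.leg_threshold, cfg.legs_enabled)
            if isinstance(winner, int):
                d = remove_dust(d, winner, cfg.dust_removal, cfg.clamped_modules, clamp)
                labels.append(cfg.labels[winner - 1])
            else:
                labels.append(winner)
            if cfg.legs_enabled:
                dl = update_legs(dl, winner, cfg)
                leg_hist[i] = dl
                leg_act_hist[i] = al
            winners.append(winner)
            dust_hist[i] = d
            act_hist[i] = a

        return SimulationResult(
            config=cfg,
            ethogram=Ethogram(tuple(labels), timestep=1.0, subject_id=f"sim-seed-{cfg.seed}"),
            winners=tuple(winners),
            initial_dust=d0,
            dust=dust_hist,
            activation=act_hist,
            leg_dust=leg_hist,
            leg_activation=leg_act_hist,
        )


def simulate(config: ModelConfig) -> SimulationResult:
    """Functional entry point: run one grooming simulation."""
    return GroomingModel(config).simulate()
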