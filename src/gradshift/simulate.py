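"""Synthetic per-ant conditioning and test data.

Emulates the study conditions: four aldehyde stimuli at carbon-chain
positions 6-9; absolute conditioning (one rewarded CS+, six CS+ and six
blank trials) versus differential conditioning (CS+ rewarded, CS- punished,
two carbons apart, six trials each, interleaved in the pseudo-random
ABBABAABABBA order); and a 15-min test with all four odours. Each ant's
test response at position x is Bernoulli with probability given by the
gradient model: G_sigma for absolute groups, G_sigma * (1 - G_sigma') for
differential groups (multiplicative interaction), so every analysis stage
can be exercised end to end without the original records.

Real ants lapse: they responded to the CS- at a low but nonzero rate
(about 3%), whereas the pure multiplicative model forces p(CS-) = 0. An
optional floor ``epsilon`` mixes p <- epsilon + (1 - epsilon) * p; the
default 0 keeps the generative model exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GradientModel
from .stimuli import (
    ALDEHYDES,
    ExperimentDesign,
    PER_ANT_COLUMNS,
    ResponseTable,
    write_per_ant,
    write_responses,
)

__all__ = [
    "SimulationConfig",
    "TRIAL_PATTERN",
    "PAPER_EXPERIMENTS",
    "simulate_test_responses",
    "simulate_acquisition",
    "make_paper_fixture",
]

#: Pseudo-random CS+/other interleaving used during training (A = CS+,
#: B = blank or CS-).
TRIAL_PATTERN = "ABBABAABABBA"

#: The four study experiments: (label, CS+ position, CS- position,
#: n absolute group, n differential group, generating sigma, sigma').
#: Group sizes are the study's; the widths are the fitted gradient widths
#: used as ground truth for the fixture.
PAPER_EXPERIMENTS = (
    ("hexanal+/octanal-", 6, 8, 29, 38, 1.606, 1.071),
    ("heptanal+/nonanal-", 7, 9, 30, 40, 1.736, 1.403),
    ("octanal+/hexanal-", 8, 6, 30, 41, 1.682, 1.492),
    ("nonanal+/heptanal-", 9, 7, 28, 41, 1.730, 0.732),
)

TEST_POSITIONS = (6, 7, 8, 9)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate one conditioning group.

    ``asymptote_plus``/``asymptote_minus`` are the acquisition-curve ceilings
    (probability of responding on late CS+ / CS- or blank trials);
    ``learning_rate`` is the per-trial gain. ``epsilon`` is the lapse floor
    mixed into every response probability. ``heterogeneity`` optionally
    names (alpha, beta) of a Beta-distributed per-ant response scale; off by
    default (i.i.d. ants), and beyond the study's assumptions.
    """

    design: ExperimentDesign
    true_sigma: float
    true_sigma_prime: float | None = None
    interaction: str = "multiplicative"
    asymptote_plus: float = 1.0
    asymptote_minus: float = 0.03
    learning_rate: float = 0.5
    n_trials_per_cs: int = 6
    epsilon: float = 0.0
    heterogeneity: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("asymptote_plus", "asymptote_minus", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.design.protocol == "differential" and self.true_sigma_prime is None:
            raise ValueError("differential simulation needs true_sigma_prime")

    def gradient_model(self) -> GradientModel:
        if self.design.protocol == "absolute":
            return GradientModel(sigma=self.true_sigma, center_plus=self.design.cs_plus,
                                 interaction="none")
        return GradientModel(
            sigma=self.true_sigma,
            sigma_prime=self.true_sigma_prime,
            center_plus=self.design.cs_plus,
            center_minus=self.design.cs_minus,
            interaction=self.interaction,
        )


def _with_floor(p: np.ndarray, epsilon: float) -> np.ndarray:
    return epsilon + (1.0 - epsilon) * p


def _ant_scales(config: SimulationConfig, rng) -> np.ndarray:
    n = config.design.n_ants
    if config.heterogeneity is None:
        return np.ones(n)
    a, b = config.heterogeneity
    return rng.beta(a, b, size=n)


def simulate_test_responses(config: SimulationConfig, rng=None):
    """Draw per-ant Bernoulli test responses from the gradient model.

    Returns ``(ResponseTable, per_ant_frame)`` where the table aggregates
    responder counts per test position and the frame holds one row per ant x
    test odour in the per-ant CSV schema. Reproducible from ``config.seed``
    (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.gradient_model()
    positions = np.asarray(config.design.test_positions, dtype=float)
    p = model.response(positions) / 100.0
    p = _with_floor(p, config.epsilon)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("response probabilities outside [0, 1]")

    scales = _ant_scales(config, rng)
    draws = rng.random((config.design.n_ants, len(positions))) < scales[:, None] * p[None, :]
    draws = draws.astype(int)

    table = ResponseTable(
        positions=config.design.test_positions,
        n_tested=(config.design.n_ants,) * len(positions),
        n_responders=tuple(int(v) for v in draws.sum(axis=0)),
    )
    records = []
    for ant in range(config.design.n_ants):
        for j, pos in enumerate(config.design.test_positions):
            records.append(
                {
                    "experiment_id": config.design.experiment_id,
                    "protocol": config.design.protocol,
                    "ant_id": f"{config.design.protocol}-{ant:03d}",
                    "phase": "test",
                    "trial_index": "",
                    "stimulus_role": "test",
                    "test_carbon": int(pos),
                    "response": int(draws[ant, j]),
                }
            )
    return table, pd.DataFrame(records, columns=PER_ANT_COLUMNS)


def simulate_acquisition(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Draw per-ant, per-trial binary responses along the training phase.

    The response probability on the t-th CS+ trial (t = 1..6) is
    ``asymptote_plus * (1 - (1 - learning_rate)**t)`` and analogously toward
    ``asymptote_minus`` on CS- trials; blank trials (absolute protocol) sit
    at the lapse floor. Trials follow the pseudo-random ABBABAABABBA
    interleaving. Returns per-ant rows in the per-ant CSV schema
    (phase="trial").
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = config.design
    other_role = "CSminus" if design.protocol == "differential" else "blank"
    records = []
    for ant in range(design.n_ants):
        t_plus = t_other = 0
        for trial_index, symbol in enumerate(TRIAL_PATTERN, start=1):
            if symbol == "A":
                t_plus += 1
                p = config.asymptote_plus * (1 - (1 - config.learning_rate) ** t_plus)
                role = "CSplus"
            else:
                t_other += 1
                if design.protocol == "differential":
                    p = config.asymptote_minus * (1 - (1 - config.learning_rate) ** t_other)
                else:
                    p = config.epsilon
                role = other_role
            p = _with_floor(p, config.epsilon) if role == "CSplus" else p
            records.append(
                {
                    "experiment_id": design.experiment_id,
                    "protocol": design.protocol,
                    "ant_id": f"{design.protocol}-{ant:03d}",
                    "phase": "trial",
                    "trial_index": trial_index,
                    "stimulus_role": role,
                    "test_carbon": "",
                    "response": int(rng.random() < p),
                }
            )
    return pd.DataFrame(records, columns=PER_ANT_COLUMNS)


def _paper_designs(label, cs_plus, cs_minus, n_abs, n_diff):
    absolute = ExperimentDesign(
        experiment_id=label, protocol="absolute", cs_plus=cs_plus,
        test_positions=TEST_POSITIONS, n_ants=n_abs,
    )
    differential = ExperimentDesign(
        experiment_id=label, protocol="differential", cs_plus=cs_plus, cs_minus=cs_minus,
        test_positions=TEST_POSITIONS, n_ants=n_diff,
    )
    return absolute, differential


def make_paper_fixture(seed: int, out_dir=None, include_acquisition: bool = True,
                       epsilon: float = 0.0):
    """Simulate all four study designs with the fitted widths as ground truth.

    Returns a dict with ``records`` (list of (design, ResponseTable), 8
    groups = 32 aggregate rows), ``per_ant`` (long-format frame covering the
    test phase and, optionally, acquisition trials) and ``configs``. If
    ``out_dir`` is given, writes ``responses.csv`` (aggregate schema) and
    ``per_ant.csv`` there.
    """
    rng = np.random.default_rng(seed)
    records, frames, configs = [], [], []
    for label, cs_plus, cs_minus, n_abs, n_diff, sigma, sigma_prime in PAPER_EXPERIMENTS:
        absolute, differential = _paper_designs(label, cs_plus, cs_minus, n_abs, n_diff)
        for design in (absolute, differential):
            config = SimulationConfig(
                design=design,
                true_sigma=sigma,
                true_sigma_prime=sigma_prime if design.protocol == "differential" else None,
                # late-trial response levels observed in the study: near 100%
                # for absolute CS+, about 74% for differential CS+
                asymptote_plus=1.0 if design.protocol == "absolute" else 0.74,
                epsilon=epsilon,
                seed=seed,
            )
            table, test_frame = simulate_test_responses(config, rng=rng)
            records.append((design, table))
            frames.append(test_frame)
            if include_acquisition:
                frames.append(simulate_acquisition(config, rng=rng))
            configs.append(config)

    per_ant = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_responses(records, out_dir / "responses.csv")
        write_per_ant(per_ant, out_dir / "per_ant.csv")
    return {"records": records, "per_ant": per_ant, "configs": configs}
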