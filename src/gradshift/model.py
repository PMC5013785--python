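"""Gaussian excitatory/inhibitory generalization gradients and their combination.

The excitatory gradient G_sigma is a Gaussian of unit height centred on the
CS+ and is read as the probability of responding to a stimulus; the
inhibitory gradient G_sigma' is centred on the CS- and read as the
probability of being inhibited from responding. Under the multiplicative
model the overall probability of responding after differential conditioning
is G_sigma * (1 - G_sigma'): respond AND not be inhibited, the two events
taken as independent. Additive variants (clipped difference of the two
gradients, optionally with a free inhibitory amplitude) are provided as
reconstructions of the classical superposition account for comparison.

Internally all gradients live on [0, 1]; the percentage scale (amplitude
100) is applied only at the interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "GradientModel",
    "INTERACTIONS",
    "gaussian_gradient",
    "combined_response",
    "alternative_response",
    "peak_location",
    "area_shift",
    "observed_area_shift",
]

INTERACTIONS = ("multiplicative", "additive_clipped", "additive_free_amplitude", "none")

#: Fixed height of both gradients on the percentage scale.
AMPLITUDE = 100.0


def gaussian_gradient(x, center, sigma):
    """Unit-height Gaussian gradient exp(-(x-center)^2 / (2 sigma^2)).

    Returns a response fraction in [0, 1]; multiply by the amplitude (100)
    for the percentage scale. Symmetric about ``center`` with maximum 1
    there. ``sigma`` is the gradient width in carbon units and must be > 0.
    """
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - center) ** 2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GradientModel:
    """Parameters of the excitatory/inhibitory gradient pair.

    Parameters
    ----------
    sigma : float
        Standard deviation (carbon units) of the excitatory gradient,
        centred on the CS+.
    center_plus : float
        CS+ carbon position.
    sigma_prime, center_minus : float, optional
        Width and centre (CS- position) of the inhibitory gradient; absent
        for the absolute-only model (``interaction="none"``).
    amplitude : float
        Gradient height on the percentage scale, fixed at 100.
    interaction : str
        One of ``multiplicative`` (the primary model), ``additive_clipped``,
        ``additive_free_amplitude`` or ``none``.
    inhibitory_amplitude : float, optional
        The free inhibitory height A' in [0, 100]; only used by
        ``additive_free_amplitude``.
    """

    sigma: float
    center_plus: float
    sigma_prime: float | None = None
    center_minus: float | None = None
    amplitude: float = AMPLITUDE
    interaction: str = "multiplicative"
    inhibitory_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.interaction not in INTERACTIONS:
            raise ValueError(f"unknown interaction {self.interaction!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if (self.interaction == "none") != (self.center_minus is None):
            raise ValueError("center_minus must be present iff interaction != 'none'")
        if self.interaction != "none":
            if self.sigma_prime is None or self.sigma_prime <= 0:
                raise ValueError("sigma_prime must be > 0 for an inhibitory gradient")
        if self.interaction == "additive_free_amplitude":
            a = self.inhibitory_amplitude
            if a is None or not (0.0 <= a <= AMPLITUDE):
                raise ValueError("inhibitory_amplitude must lie in [0, 100]")

    # -- response functions -------------------------------------------------

    def excitatory(self, x):
        """Excitatory gradient on [0, 1]."""
        return gaussian_gradient(x, self.center_plus, self.sigma)

    def inhibitory(self, x):
        """Inhibitory gradient on [0, 1]; zero for the absolute-only model."""
        if self.interaction == "none":
            return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
        return gaussian_gradient(x, self.center_minus, self.sigma_prime)

    def response(self, x):
        """Predicted response percentage in [0, 100] at carbon position(s) x."""
        if self.interaction == "none":
            return self.amplitude * self.excitatory(x)
        if self.interaction == "multiplicative":
            return combined_response(x, self)
        return alternative_response(x, self)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "sigma": self.sigma,
            "sigma_prime": self.sigma_prime,
            "center_plus": self.center_plus,
            "center_minus": self.center_minus,
            "amplitude": self.amplitude,
            "interaction": self.interaction,
        }
        if self.interaction == "additive_free_amplitude":
            payload["inhibitory_amplitude"] = self.inhibitory_amplitude
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GradientModel":
        payload = json.loads(text)
        return cls(**payload)


def combined_response(x, model: GradientModel):
    """Multiplicative response 100 * G_sigma(x) * (1 - G_sigma'(x)), in %.

    Exactly 0 at the CS- (where the inhibition probability is 1) and never
    above the excitatory gradient alone.
    """
    if model.interaction != "multiplicative":
        raise ValueError(f"combined_response requires the multiplicative model, got {model.interaction!r}")
    if model.center_minus is None:
        raise ValueError("multiplicative model needs a CS- centre")
    g = model.excitatory(x)
    g_prime = model.inhibitory(x)
    return model.amplitude * g * (1.0 - g_prime)


def alternative_response(x, model: GradientModel):
    """Additive interaction variants, in %.

    ``additive_clipped``: clip(100*G_sigma - 100*G_sigma', 0, 100).
    ``additive_free_amplitude``: clip(100*G_sigma - A'*G_sigma', 0, 100)
    with the inhibitory height A' a free parameter in [0, 100].
    """
    if model.interaction not in ("additive_clipped", "additive_free_amplitude"):
        raise ValueError(f"alternative_response got interaction {model.interaction!r}")
    g = model.excitatory(x)
    g_prime = model.inhibitory(x)
    if model.interaction == "additive_clipped":
        a_prime = model.amplitude
    else:
        a_prime = model.inhibitory_amplitude
    return np.clip(model.amplitude * g - a_prime * g_prime, 0.0, model.amplitude)


def peak_location(model: GradientModel, window: float = 4.0, step: float = 0.001,
                  return_flag: bool = False):
    """Position of the combined gradient's maximum near the CS+.

    Dense grid search (default step 0.001 carbons on
    [center_plus - window, center_plus + window]) followed by bounded local
    refinement. For ``interaction="none"`` the peak is the CS+ exactly. A
    plateau of grid maxima is broken toward the CS+ and flagged.

    With ``return_flag=True`` returns ``(location, plateau_flag)``.
    """
    if model.interaction == "none":
        loc = float(model.center_plus)
        return (loc, False) if return_flag else loc

    grid = np.arange(model.center_plus - window, model.center_plus + window + step / 2, step)
    values = np.asarray(model.response(grid))
    vmax = values.max()
    at_max = np.flatnonzero(values >= vmax - 1e-12 * max(vmax, 1.0))
    plateau = len(at_max) > 1
    # tie-break toward the CS+
    best = at_max[np.argmin(np.abs(grid[at_max] - model.center_plus))]
    x0 = grid[best]

    lo = max(grid[0], x0 - step)
    hi = min(grid[-1], x0 + step)
    res = minimize_scalar(lambda x: -float(model.response(x)), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    loc = float(res.x) if -res.fun >= vmax else float(x0)
    if plateau:
        loc = float(x0)
    return (loc, plateau) if return_flag else loc


def _shift_sides(center_plus, center_minus, positions):
    positions = [float(p) for p in positions]
    away = [p for p in positions if (p - center_plus) * (center_plus - center_minus) > 0]
    toward = [p for p in positions if (p - center_plus) * (center_plus - center_minus) < 0]
    if not away or not toward:
        raise ValueError("test positions must span both sides of the CS+")
    return away, toward


def area_shift(model: GradientModel, test_positions) -> float:
    """Signed area-shift score (percentage points) of the predicted gradient.

    Sum of predicted responses at test positions on the side of the CS+
    opposite the CS-, minus the sum on the CS- side; the CS+ itself is
    excluded. Positive values mean responding is elevated away from the CS-,
    the area-shift signature of differential conditioning.
    """
    if model.interaction == "none" or model.center_minus is None:
        # no CS-: orient sides arbitrarily (above CS+ counts as "away");
        # a symmetric Gaussian then scores exactly 0 on symmetric positions
        reference = model.center_plus - 1.0
    else:
        reference = model.center_minus
    away, toward = _shift_sides(model.center_plus, reference, test_positions)
    return float(np.sum(model.response(np.array(away))) - np.sum(model.response(np.array(toward))))


def observed_area_shift(table, design) -> float:
    """Observed-data area-shift score from a ResponseTable, same contract.

    Uses measured response percentages instead of model predictions.
    """
    if design.cs_minus is None:
        raise ValueError("observed_area_shift needs a differential design")
    away, toward = _shift_sides(design.cs_plus, design.cs_minus, table.positions)
    return float(
        sum(table.pct_at(int(p)) for p in away) - sum(table.pct_at(int(p)) for p in toward)
    )
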