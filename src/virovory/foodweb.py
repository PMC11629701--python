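"""Three-compartment virus-bacteria-grazer food-web ODE model.

The model tracks free viruses (V, ml^-1), heterotrophic bacteria
(B, ml^-1) and a phagotrophic protist grazer (G, ml^-1):

    dV/dt = S_v - phi_gv*G*V - phi_bv*B*V - delta_v*V
    dB/dt = mu_b*B + eps_bv*phi_bv*B*V - phi_gb*G*B - delta_b*B**2
    dG/dt = eps_gb*phi_gb*G*B + eps_gv*phi_gv*G*V - delta_g*G**2

Viruses are supplied at a constant rate ``S_v`` and removed by grazer
virovory, bacterial consumption and first-order abiotic decay; consumption
follows mass-action (encounter-rate) kinetics.  Bacteria grow
exponentially, gain biomass from consumed virions with efficiency
``eps_bv``, and are lost to grazing and a quadratic mortality closure.
Grazers gain from bacterivory and virovory with efficiencies ``eps_gb``
and ``eps_gv`` and are closed with quadratic mortality.

A simulated filtration experiment spins the full model up to equilibrium,
instantaneously removes the size classes excluded by the filter, cuts off
the virus supply (``S_v = 0``), and integrates forward, mirroring dark
bottle incubations of size-fractionated seawater spiked with virions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FoodwebParameters",
    "FoodwebState",
    "Trajectory",
    "TreatmentSpec",
    "EquilibriumError",
    "IntegrationError",
    "DEFAULT_OUTPUT_TIMES",
    "DEFAULT_SPINUP_STATE",
    "derivatives",
    "integrate",
    "run_to_equilibrium",
    "simulate_treatment",
    "removal_fraction",
]

#: Experimental sampling grid (days): 0 h, 12 h, 24 h, 48 h, 4 d, 8 d.
DEFAULT_OUTPUT_TIMES: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)

_RATE_FIELDS = (
    "S_v",
    "phi_gv",
    "phi_bv",
    "phi_gb",
    "mu_b",
    "delta_v",
    "delta_b",
    "delta_g",
)
_EFFICIENCY_FIELDS = ("eps_gb", "eps_gv", "eps_bv")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to complete an integration."""


class EquilibriumError(RuntimeError):
    """Raised when equilibrium is not reached within ``max_days``.

    Carries the last state reached as ``last_state``.
    """

    def __init__(self, message: str, last_state: "FoodwebState"):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class FoodwebParameters:
    """Rate and efficiency parameters of the food-web model.

    Units: ``S_v`` virus ml^-1 day^-1; ``phi_gv``/``phi_gb`` ml grazer^-1
    day^-1; ``phi_bv`` ml bacteria^-1 day^-1; ``mu_b`` and ``delta_v``
    day^-1; ``delta_b`` ml bacteria^-1 day^-1; ``delta_g`` ml grazer^-1
    day^-1 (quadratic closure); efficiencies dimensionless in [0, 1].
    """

    S_v: float = 5e7
    phi_gv: float = 1e-3
    phi_bv: float = 1e-6
    phi_gb: float = 1e-3
    mu_b: float = 0.8
    delta_v: float = 0.1
    delta_b: float = 1e-6
    delta_g: float = 0.1
    eps_gb: float = 0.1
    eps_gv: float = 1e-6
    eps_bv: float = 1e-3

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be a finite non-negative rate, got {value}")
        for name in _EFFICIENCY_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(f"efficiency {name!r} must lie in [0, 1], got {value}")

    @classmethod
    def table1_defaults(cls) -> "FoodwebParameters":
        """Reference parameter set used for the simulated bottle experiments."""
        return cls()

    def replace(self, **changes: float) -> "FoodwebParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FoodwebParameters":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class FoodwebState:
    """Concentrations (ml^-1) of viruses, bacteria and grazers."""

    V: float
    B: float
    G: float

    def __post_init__(self) -> None:
        for name in ("V", "B", "G"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"state component {name!r} must be finite and >= 0, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.B, self.G], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FoodwebState":
        return cls(float(y[0]), float(y[1]), float(y[2]))


#: Spin-up initial condition (configurable; equilibrium results do not
#: depend on it).
DEFAULT_SPINUP_STATE = FoodwebState(V=1e6, B=1e5, G=1e2)


@dataclass(frozen=True)
class Trajectory:
    """Model solution sampled at ``times`` (days, starting at 0)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 3) columns V, B, G
    params: FoodwebParameters

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.ndim != 1 or states.shape != (times.size, 3):
            raise ValueError("states must have shape (len(times), 3)")
        if times.size and (times[0] < 0 or np.any(np.diff(times) <= 0)):
            raise ValueError("times must be strictly increasing and start at >= 0")

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def B(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def G(self) -> np.ndarray:
        return self.states[:, 2]

    def state_at(self, index: int) -> FoodwebState:
        return FoodwebState.from_array(self.states[index])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_days": self.times,
                "V_per_ml": self.V,
                "B_per_ml": self.B,
                "G_per_ml": self.G,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class TreatmentSpec:
    """A simulated filtration treatment.

    ``filtration`` selects the pore-size class: ``"lt100"`` (< 100 um,
    full community), ``"lt1p2"`` (< 1.2 um, grazers removed) or
    ``"lt0p1"`` (< 0.1 um, bacteria and grazers removed).  ``supply_cut``
    sets S_v = 0 at t = 0, emulating the loss of in-situ virus production
    inside a closed bottle.  ``retention`` optionally leaves a fraction of
    a removed compartment behind (imperfect filtration).
    """

    filtration: str = "lt100"
    supply_cut: bool = True
    duration: float = 8.0
    output_times: tuple[float, ...] = DEFAULT_OUTPUT_TIMES
    retention: float = 0.0

    _REMOVES = {"lt100": (), "lt1p2": ("G",), "lt0p1": ("B", "G")}

    def __post_init__(self) -> None:
        if self.filtration not in self._REMOVES:
            raise ValueError(
                f"filtration must be one of {sorted(self._REMOVES)}, got {self.filtration!r}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.retention < 1.0:
            raise ValueError("retention must lie in [0, 1)")

    def apply_filtration(self, state: FoodwebState) -> FoodwebState:
        kept = {"V": state.V, "B": state.B, "G": state.G}
        for name in self._REMOVES[self.filtration]:
            kept[name] *= self.retention
        return FoodwebState(**kept)


def _rhs(y: np.ndarray, p: FoodwebParameters) -> np.ndarray:
    V, B, G = y
    dV = p.S_v - p.phi_gv * G * V - p.phi_bv * B * V - p.delta_v * V
    dB = p.mu_b * B + p.eps_bv * p.phi_bv * B * V - p.phi_gb * G * B - p.delta_b * B * B
    dG = p.eps_gb * p.phi_gb * G * B + p.eps_gv * p.phi_gv * G * V - p.delta_g * G * G
    return np.array([dV, dB, dG])


def derivatives(
    state: FoodwebState, params: FoodwebParameters
) -> tuple[float, float, float]:
    """Instantaneous rates of change (dV/dt, dB/dt, dG/dt) in ml^-1 day^-1."""
    dV, dB, dG = _rhs(state.as_array(), params)
    return float(dV), float(dB), float(dG)


def integrate(
    initial: FoodwebState,
    params: FoodwebParameters,
    duration: float,
    output_times: Sequence[float] | None = None,
    rtol: float = 1e-10,
) -> Trajectory:
    """Integrate the model from ``initial`` for ``duration`` days.

    Uses an adaptive stiff-capable solver (LSODA).  Transient negative
    excursions below 1e-12 of the compartment scale are clipped to zero;
    larger negatives or solver failure raise :class:`IntegrationError`.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if output_times is None:
        t_eval = np.linspace(0.0, duration, 201)
    else:
        t_eval = np.asarray(output_times, dtype=float)
        if t_eval.size == 0 or t_eval.min() < 0 or t_eval.max() > duration:
            raise ValueError("output_times must be non-empty and lie within [0, duration]")
    scale = max(initial.V, initial.B, initial.G, 1.0)
    sol = solve_ivp(
        lambda t, y: _rhs(y, params),
        (0.0, float(duration)),
        initial.as_array(),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-12 * scale,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    states = sol.y.T.copy()
    if np.any(~np.isfinite(states)):
        raise IntegrationError("ODE integration produced non-finite values")
    floor = -1e-12 * scale
    if np.any(states < floor):
        worst = states.min()
        raise IntegrationError(
            f"integration produced a negative concentration ({worst:g} ml^-1)"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=t_eval, states=states, params=params)


def run_to_equilibrium(
    initial: FoodwebState | None = None,
    params: FoodwebParameters | None = None,
    tol: float = 1e-9,
    max_days: float = 5000.0,
    chunk_days: float = 250.0,
) -> tuple[FoodwebState, float]:
    """Integrate until the relative derivative norm falls below ``tol``.

    The criterion is ``max_i |dy_i/dt| / max(y_i, 1) < tol``, i.e. each
    compartment changes by less than ``tol`` of itself (or of 1 ml^-1 for
    near-empty compartments) per day.  Returns ``(state, days_elapsed)``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if initial is None:
        initial = DEFAULT_SPINUP_STATE
    if params is None:
        params = FoodwebParameters.table1_defaults()

    def rel_norm(y: np.ndarray) -> float:
        dy = _rhs(y, params)
        return float(np.max(np.abs(dy) / np.maximum(y, 1.0)))

    y = initial.as_array()
    elapsed = 0.0
    while elapsed < max_days:
        if rel_norm(y) < tol:
            return FoodwebState.from_array(y), elapsed
        step = min(chunk_days, max_days - elapsed)
        traj = integrate(FoodwebState.from_array(y), params, step, output_times=[step])
        y = traj.states[-1]
        elapsed += step
    if rel_norm(y) < tol:
        return FoodwebState.from_array(y), elapsed
    raise EquilibriumError(
        f"no equilibrium within {max_days} days (relative derivative norm "
        f"{rel_norm(y):.3e} >= tol {tol:.3e})",
        FoodwebState.from_array(y),
    )


def simulate_treatment(
    spec: TreatmentSpec,
    params: FoodwebParameters | None = None,
    spinup_initial: FoodwebState | None = None,
) -> Trajectory:
    """Simulate one filtration treatment of a bottle incubation.

    Steps: (1) spin the full model up to equilibrium, (2) apply the
    filtration cut, (3) zero the virus supply if ``spec.supply_cut``,
    (4) integrate for ``spec.duration`` days on ``spec.output_times``.
    """
    if params is None:
        params = FoodwebParameters.table1_defaults()
    equilibrium, _ = run_to_equilibrium(spinup_initial, params)
    start = spec.apply_filtration(equilibrium)
    run_params = params.replace(S_v=0.0) if spec.supply_cut else params
    times = spec.output_times
    if times[0] != 0.0:
        times = (0.0,) + tuple(times)
    return integrate(start, run_params, spec.duration, output_times=times)


def removal_fraction(trajectory: Trajectory) -> np.ndarray:
    """Fraction of the initial virus pool removed, 1 - V(t)/V(0), per output time."""
    v0 = trajectory.V[0]
    if v0 <= 0:
        raise ValueError("initial virus concentration is zero; removal undefined")
    return 1.0 - trajectory.V / v0
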