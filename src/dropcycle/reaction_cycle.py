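"""Well-mixed kinetics of the carbodiimide-fueled peptide activation cycle.

The cycle couples five species: the fuel EDC (``F``), the diacid peptide
precursor (``P``), the O-acylisourea intermediate (``I``), the transient
cationic anhydride product (``A``) and the urea waste EDU (``W``).  Fuel is
consumed irreversibly, either by direct hydrolysis or by activating the
precursor; the intermediate partitions between productive anhydride
formation and futile hydrolysis; the anhydride hydrolyzes back to the
precursor.  Two linear conservation laws follow from this wiring and are
enforced on every integration:

    P + I + A = P0          (peptide backbone)
    F + I + W = F0          (carbodiimide)

All concentrations are in mM and all times in minutes.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "ExperimentConfig",
    "CycleState",
    "TimeCourse",
    "IntegrationError",
    "derivatives",
    "integrate",
    "peak_anhydride",
    "threshold_times",
    "depletion_time",
    "load_defaults",
]

#: Relative tolerance on the two conservation laws accepted in a TimeCourse.
CONSERVATION_RTOL = 1e-6


def load_defaults() -> dict:
    """Return the packaged default parameter set as a plain dict."""
    with importlib.resources.files("dropcycle.data").joinpath("defaults.json").open() as fh:
        return json.load(fh)


class IntegrationError(RuntimeError):
    """ODE solver failure, carrying the solver's diagnostic message."""


@dataclass(frozen=True)
class RateConstants:
    """The five rate parameters of the fuel-driven cycle.

    Parameters
    ----------
    k0 : float
        Direct fuel hydrolysis, first order (1/min).
    k1 : float
        Precursor activation by fuel, second order (1/mM/min).
    k2 : float
        O-acylisourea -> anhydride conversion, first order (1/min).
    k3 : float
        O-acylisourea hydrolysis back to precursor, first order (1/min).
    k4 : float
        Anhydride hydrolysis (deactivation), first order (1/min).
    """

    k0: float
    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name}={v!r} must be finite and >= 0")

    @classmethod
    def default(cls) -> "RateConstants":
        """Packaged constants, calibrated against the macroscopic observables
        of the standard reaction conditions (see docs/methods.md)."""
        return cls(**load_defaults()["rate_constants"])

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RateConstants":
        return cls(*map(float, values))

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2, self.k3, self.k4])

    def replace(self, **kwargs: float) -> "RateConstants":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ExperimentConfig:
    """Initial composition of a fueled reaction.

    ``P0`` is the precursor, ``F0`` the fuel, ``U0`` the RNA concentration in
    uridine monomer units; all mM.  Standard conditions are 23 mM precursor,
    4.1 mM poly-U in 200 mM MES at pH 5.3, 25 degC.
    """

    F0: float
    P0: float = 23.0
    U0: float = 4.1
    buffer: str = "200 mM MES pH 5.3"
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        for name in ("F0", "P0", "U0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class CycleState:
    """Concentrations of the five species at one instant (mM, minutes)."""

    t: float
    F: float
    P: float
    I: float
    A: float
    W: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be >= 0")
        for name in "FPIAW":
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.F, self.P, self.I, self.A, self.W])


def derivatives(state: CycleState, k: RateConstants) -> np.ndarray:
    """Rate-of-change vector (dF, dP, dI, dA, dW) in mM/min.

    Raises ``ValueError`` if any concentration in ``state`` is negative
    (enforced by ``CycleState`` itself; re-checked here for raw inputs).
    """
    F, P, I, A = state.F, state.P, state.I, state.A
    if min(F, P, I, A, state.W) < 0:
        raise ValueError("negative concentration")
    act = k.k1 * F * P
    dF = -k.k0 * F - act
    dP = -act + k.k3 * I + k.k4 * A
    dI = act - (k.k2 + k.k3) * I
    dA = k.k2 * I - k.k4 * A
    dW = k.k0 * F + (k.k2 + k.k3) * I
    return np.array([dF, dP, dI, dA, dW])


def _rhs(t: float, y: np.ndarray, k: RateConstants) -> list[float]:
    F, P, I, A, W = y
    act = k.k1 * F * P
    return [
        -k.k0 * F - act,
        -act + k.k3 * I + k.k4 * A,
        act - (k.k2 + k.k3) * I,
        k.k2 * I - k.k4 * A,
        k.k0 * F + (k.k2 + k.k3) * I,
    ]


class TimeCourse:
    """Integrated concentrations of the cycle on a regular output grid.

    Thin wrapper around a ``(t, F, P, I, A, W)`` table that enforces the two
    conservation laws and strictly increasing times, and carries a provenance
    record (config, rate constants, solver settings).
    """

    COLUMNS = ("time_min", "F_mM", "P_mM", "I_mM", "A_mM", "W_mM")

    def __init__(self, t: np.ndarray, y: np.ndarray, provenance: dict | None = None):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.shape != (5, t.size):
            raise ValueError("y must have shape (5, len(t))")
        if t.size == 0:
            raise ValueError("empty time course")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        self.t = t
        self.F, self.P, self.I, self.A, self.W = y
        self.provenance = provenance or {}
        self._validate_conservation()

    def _validate_conservation(self) -> None:
        prov = self.provenance
        P0 = prov.get("P0", self.P[0] + self.I[0] + self.A[0])
        F0 = prov.get("F0", self.F[0] + self.I[0] + self.W[0])
        scale_P = max(abs(P0), 1e-12)
        scale_F = max(abs(F0), 1e-12)
        err_P = np.max(np.abs(self.P + self.I + self.A - P0)) / scale_P
        err_F = np.max(np.abs(self.F + self.I + self.W - F0)) / scale_F
        if err_P > CONSERVATION_RTOL or err_F > CONSERVATION_RTOL:
            raise IntegrationError(
                f"conservation violated: peptide rel err {err_P:.3g}, "
                f"carbodiimide rel err {err_F:.3g} (tolerance {CONSERVATION_RTOL:g})"
            )

    def __len__(self) -> int:
        return self.t.size

    def __iter__(self) -> Iterator[CycleState]:
        clip = lambda v: max(float(v), 0.0)
        for i in range(self.t.size):
            yield CycleState(
                t=float(self.t[i]),
                F=clip(self.F[i]),
                P=clip(self.P[i]),
                I=clip(self.I[i]),
                A=clip(self.A[i]),
                W=clip(self.W[i]),
            )

    def state_at(self, t: float) -> CycleState:
        """Linearly interpolated state at time ``t`` (within the grid span)."""
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t} outside integration span")
        vals = [max(float(np.interp(t, self.t, arr)), 0.0) for arr in (self.F, self.P, self.I, self.A, self.W)]
        return CycleState(float(t), *vals)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.t,
                "F_mM": self.F,
                "P_mM": self.P,
                "I_mM": self.I,
                "A_mM": self.A,
                "W_mM": self.W,
            }
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the table; provenance goes to ``<path>.json`` unless disabled."""
        self.as_dataframe().to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            with open(f"{path}.json", "w") as fh:
                json.dump(self.provenance, fh, indent=1, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        df = pd.read_csv(path)
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        y = df[list(cls.COLUMNS[1:])].to_numpy().T
        try:
            with open(f"{path}.json") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {}
        return cls(df["time_min"].to_numpy(), y, prov)

    def plot(self, ax=None):
        """Concentration traces against time (fuel on a secondary axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.A, label="anhydride (A)", color="crimson")
        ax.plot(self.t, self.I, label="intermediate (I)", color="gray")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (mM)")
        ax2 = ax.twinx()
        ax2.plot(self.t, self.F, label="fuel (F)", color="steelblue", ls="--")
        ax2.set_ylabel("fuel (mM)")
        ax.legend(loc="upper right")
        return ax


def integrate(
    config: ExperimentConfig,
    k: RateConstants,
    t_end: float,
    output_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> TimeCourse:
    """Integrate the cycle from fuel addition to ``t_end`` minutes.

    Uses an adaptive stiff-capable solver (LSODA); the output grid is regular
    with spacing ``output_step``.  Raises :class:`IntegrationError` when the
    solver fails or a conservation law is violated beyond 1e-6 relative.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if output_step <= 0:
        raise ValueError("output_step must be > 0")
    t_eval = np.arange(0.0, t_end + output_step * 1e-9, output_step)
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    y0 = [config.F0, config.P0, 0.0, 0.0, 0.0]
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_end)),
        y0,
        args=(k,),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    provenance = {
        "F0": config.F0,
        "P0": config.P0,
        "U0": config.U0,
        "buffer": config.buffer,
        "temperature_C": config.temperature_C,
        "rate_constants": dataclasses.asdict(k),
        "solver": {"method": "LSODA", "rtol": rtol, "atol": atol, "output_step": output_step},
    }
    return TimeCourse(sol.t, sol.y, provenance)


def peak_anhydride(tc: TimeCourse) -> tuple[float, float]:
    """Earliest time and value of the anhydride maximum over the output grid."""
    i = int(np.argmax(tc.A))
    return float(tc.t[i]), float(tc.A[i])


def _cross(t0: float, t1: float, a0: float, a1: float, level: float) -> float:
    """Linear interpolation of the time where a segment crosses ``level``."""
    if a1 == a0:
        return t0
    return t0 + (level - a0) / (a1 - a0) * (t1 - t0)


def threshold_times(tc: TimeCourse, A_crit: float) -> tuple[float | None, float | None]:
    """First up-crossing and first post-peak down-crossing of ``A_crit``.

    Returns ``(t_on, t_off)``; either is ``None`` when the trace never
    reaches (resp. never clears) the threshold.  Crossing times are linearly
    interpolated between output points.
    """
    if A_crit <= 0:
        raise ValueError("A_crit must be > 0")
    A, t = tc.A, tc.t
    above = np.nonzero(A >= A_crit)[0]
    if above.size == 0:
        return None, None
    i_on = above[0]
    t_on = t[i_on] if i_on == 0 else _cross(t[i_on - 1], t[i_on], A[i_on - 1], A[i_on], A_crit)
    i_peak = int(np.argmax(A))
    below = np.nonzero(A[i_peak:] < A_crit)[0]
    if below.size == 0:
        return float(t_on), None
    j = i_peak + below[0]
    t_off = _cross(t[j - 1], t[j], A[j - 1], A[j], A_crit)
    return float(t_on), float(t_off)


def depletion_time(tc: TimeCourse, detection_limit: float = 0.1) -> float | None:
    """Earliest time after which both fuel and anhydride stay below the limit.

    Mirrors the HPLC notion of the species being "absent": the default limit
    of 0.1 mM plays the role of the detection limit.  Returns ``None`` when
    either species still exceeds the limit at the end of the trace.
    """
    if detection_limit <= 0:
        raise ValueError("detection_limit must be > 0")
    t = tc.t
    times = []
    for arr in (tc.F, tc.A):
        over = np.nonzero(arr >= detection_limit)[0]
        if over.size == 0:
            times.append(float(t[0]))
            continue
        j = over[-1]
        if j == t.size - 1:
            return None
        times.append(_cross(t[j], t[j + 1], arr[j], arr[j + 1], detection_limit))
    return float(max(times))
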