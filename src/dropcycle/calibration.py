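"""Model calibration: rate constants from HPLC data, quench-delay correction,
and the one-site binding fit for ITC isotherms.

Both fitting problems follow the Model/Results pattern: a model object is
built from data, its ``fit()`` returns a results object carrying the point
estimates, standard errors and approximate confidence intervals derived from
the Gauss-Newton covariance at the optimum, plus a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .reaction_cycle import (
    CycleState,
    ExperimentConfig,
    RateConstants,
    TimeCourse,
    integrate,
)

__all__ = [
    "HPLCMeasurement",
    "read_hplc_csv",
    "write_hplc_csv",
    "KineticModel",
    "KineticFitResults",
    "fit_rate_constants",
    "quench_correction",
    "BindingModel",
    "ITCIsotherm",
    "ITCModel",
    "ITCFitResults",
    "fit_binding_isotherm",
    "itc_heats",
]

_SPECIES = ("fuel", "anhydride", "precursor")
_SPECIES_COLUMN = {"fuel": "F", "anhydride": "A", "precursor": "P"}
_PARAM_NAMES = ("k0", "k1", "k2", "k3", "k4")

#: Default delay between filtration and benzylamine quench when unrecorded,
#: the midpoint of the typical 15-25 s range.
DEFAULT_QUENCH_DELAY_S = 20.0


@dataclass(frozen=True)
class HPLCMeasurement:
    """One HPLC concentration reading.

    ``quench_delay_s`` is the time elapsed between filtration and benzylamine
    quench and must be present exactly when ``is_filtrate`` is set; the
    anhydride is quantified via its benzylamine mono-amide (1:1).
    """

    t: float
    species: str
    concentration: float
    is_filtrate: bool = False
    quench_delay_s: float | None = None

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise ValueError(f"species must be one of {_SPECIES}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.is_filtrate and self.quench_delay_s is None:
            object.__setattr__(self, "quench_delay_s", DEFAULT_QUENCH_DELAY_S)
        if not self.is_filtrate and self.quench_delay_s is not None:
            raise ValueError("quench_delay_s only applies to filtrate samples")


def read_hplc_csv(path) -> list[HPLCMeasurement]:
    """Read ``time_min,species,conc_mM,is_filtrate,quench_delay_s`` rows."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        delay = getattr(row, "quench_delay_s", None)
        if delay is not None and pd.isna(delay):
            delay = None
        out.append(
            HPLCMeasurement(
                t=float(row.time_min),
                species=str(row.species),
                concentration=float(row.conc_mM),
                is_filtrate=bool(getattr(row, "is_filtrate", False)),
                quench_delay_s=delay,
            )
        )
    return out


def write_hplc_csv(measurements: list[HPLCMeasurement], path) -> None:
    pd.DataFrame(
        [
            {
                "time_min": m.t,
                "species": m.species,
                "conc_mM": m.concentration,
                "is_filtrate": m.is_filtrate,
                "quench_delay_s": m.quench_delay_s,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)


class KineticFitResults:
    """Estimates and diagnostics of a rate-constant fit."""

    def __init__(
        self,
        model: "KineticModel",
        params: RateConstants,
        cov: np.ndarray,
        rss: float,
        nfev: int,
        success: bool,
        message: str,
        nonidentifiable: tuple[str, ...],
    ):
        self.model = model
        self.params = params
        self.cov = cov
        self.rss = rss
        self.nfev = nfev
        self.success = success
        self.message = message
        self.nonidentifiable = nonidentifiable
        with np.errstate(invalid="ignore"):
            self.bse = np.sqrt(np.diag(cov))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals from the Gauss-Newton covariance."""
        z = stats.norm.ppf(1 - alpha / 2)
        est = self.params.as_array()
        return pd.DataFrame(
            {"lower": est - z * self.bse, "upper": est + z * self.bse},
            index=list(_PARAM_NAMES),
        )

    def predict(self, t_end: float | None = None, output_step: float = 0.1) -> TimeCourse:
        t_end = t_end or max(m.t for m in self.model.data) * 1.05
        return integrate(self.model.config, self.params, t_end, output_step)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Kinetic rate-constant fit (weighted least squares)",
            f"  observations: {len(self.model.data)}   RSS: {self.rss:.6g}",
            f"  converged: {self.success} ({self.message}); nfev={self.nfev}",
            f"  weighting: {self.model.weighting}",
            f"{'param':>6} {'estimate':>12} {'std err':>12} {'[0.025':>12} {'0.975]':>12}",
        ]
        for i, name in enumerate(_PARAM_NAMES):
            flag = "  (non-identifiable)" if name in self.nonidentifiable else ""
            lines.append(
                f"{name:>6} {self.params.as_array()[i]:>12.5g} {self.bse[i]:>12.3g} "
                f"{ci['lower'].iloc[i]:>12.3g} {ci['upper'].iloc[i]:>12.3g}{flag}"
            )
        return "\n".join(lines)


class KineticModel:
    """Least-squares calibration of the cycle's rate constants to HPLC data.

    The loss is relative (proportional-error) by default because the fuel
    (tens of mM) and anhydride (sub-mM) spans differ by orders of magnitude;
    absolute weighting is available via ``weighting="absolute"``.  Only
    unfiltered measurements are accepted: filtrate data must first be
    corrected with :func:`quench_correction`.
    """

    def __init__(
        self,
        data: list[HPLCMeasurement],
        config: ExperimentConfig,
        weighting: str = "relative",
    ):
        if weighting not in ("relative", "absolute"):
            raise ValueError("weighting must be 'relative' or 'absolute'")
        if any(m.is_filtrate for m in data):
            raise ValueError("KineticModel expects unfiltered measurements only")
        species = {m.species for m in data}
        counts = {s: sum(1 for m in data if m.species == s) for s in species}
        if len(species) < 2 or any(c < 4 for c in counts.values()):
            warnings.warn(
                "under-determined data: need >= 2 species with >= 4 time points each",
                stacklevel=2,
            )
        self.data = sorted(data, key=lambda m: (m.t, m.species))
        self.config = config
        self.weighting = weighting
        self._t = np.array([m.t for m in self.data])
        self._obs = np.array([m.concentration for m in self.data])
        self._cols = [_SPECIES_COLUMN[m.species] for m in self.data]
        # per-species scale for relative weighting, floored to avoid blow-up
        scale = {}
        for s in species:
            vals = [m.concentration for m in data if m.species == s]
            scale[s] = max(np.max(vals) * 0.02, 1e-6)
        self._floor = np.array([scale[m.species] for m in self.data])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ExperimentConfig, **kw) -> "KineticModel":
        ms = [
            HPLCMeasurement(t=float(r.time_min), species=str(r.species), concentration=float(r.conc_mM))
            for r in df.itertuples(index=False)
        ]
        return cls(ms, config, **kw)

    def _predict(self, k: RateConstants) -> np.ndarray:
        from scipy.integrate import solve_ivp

        from .reaction_cycle import _rhs

        t_grid = np.unique(self._t[self._t > 0])
        sol = solve_ivp(
            _rhs,
            (0.0, float(t_grid[-1])),
            [self.config.F0, self.config.P0, 0.0, 0.0, 0.0],
            args=(k,),
            method="LSODA",
            t_eval=t_grid,
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed during fit: {sol.message}")
        idx = {"F": 0, "P": 1, "I": 2, "A": 3, "W": 4}
        at = {t: j for j, t in enumerate(t_grid)}
        init = {"F": self.config.F0, "P": self.config.P0, "I": 0.0, "A": 0.0, "W": 0.0}
        out = np.empty_like(self._obs)
        for i, (t, col) in enumerate(zip(self._t, self._cols)):
            out[i] = init[col] if t == 0 else sol.y[idx[col], at[t]]
        return out

    def _residuals(self, log_k: np.ndarray) -> np.ndarray:
        pred = self._predict(RateConstants.from_array(np.exp(log_k)))
        if self.weighting == "relative":
            return (pred - self._obs) / (np.abs(self._obs) + self._floor)
        return pred - self._obs

    def fit(self, start: RateConstants | None = None, xtol: float = 1e-12) -> KineticFitResults:
        """Minimize the weighted least squares in log-parameter space.

        Positivity of the constants is guaranteed by the log transform; the
        fit is deterministic given the same starting guess.
        """
        start = start or RateConstants.default()
        x0 = np.log(np.maximum(start.as_array(), 1e-12))
        res = least_squares(self._residuals, x0, xtol=xtol, ftol=1e-14, gtol=1e-14, max_nfev=400)
        if not res.success:
            raise RuntimeError(f"kinetic fit did not converge: {res.message}")
        k_hat = RateConstants.from_array(np.exp(res.x))
        # identifiability: near-zero Jacobian columns (log scale) carry no signal
        col_norm = np.linalg.norm(res.jac, axis=0)
        ref = max(col_norm.max(), 1e-30)
        flagged = tuple(n for n, c in zip(_PARAM_NAMES, col_norm) if c < 1e-6 * ref)
        dof = max(len(self._obs) - len(x0), 1)
        rss = float(2 * res.cost)
        jtj = res.jac.T @ res.jac
        try:
            cov_log = np.linalg.pinv(jtj) * rss / dof
        except np.linalg.LinAlgError:
            cov_log = np.full((5, 5), np.nan)
        # delta method: var(k) = k^2 var(log k)
        kk = np.outer(k_hat.as_array(), k_hat.as_array())
        cov = cov_log * kk
        if flagged:
            warnings.warn(f"non-identifiable rate constants: {flagged}", stacklevel=2)
        return KineticFitResults(
            model=self,
            params=k_hat,
            cov=cov,
            rss=rss,
            nfev=res.nfev,
            success=res.success,
            message=res.status and str(res.message) or "",
            nonidentifiable=flagged,
        )


def fit_rate_constants(
    data: list[HPLCMeasurement],
    config: ExperimentConfig,
    initial_guess: RateConstants | None = None,
    weighting: str = "relative",
) -> KineticFitResults:
    """Convenience wrapper: build a :class:`KineticModel` and fit it."""
    return KineticModel(data, config, weighting=weighting).fit(start=initial_guess)


def quench_correction(
    measured_A: float,
    filtrate_state: CycleState,
    delay_s: float,
    k: RateConstants,
) -> float:
    """Remove the anhydride produced in the filtrate between filtration and quench.

    Fuel and precursor keep reacting in the filtrate during the handling
    delay, so the quenched mono-amide overstates the anhydride present at
    filtration time.  The correction integrates the cycle over the delay
    starting from the filtrate composition and subtracts the net anhydride
    change; the result is floored at zero with a warning if the correction
    exceeds the measurement.
    """
    if delay_s < 0:
        raise ValueError("delay_s must be >= 0")
    if measured_A < 0:
        raise ValueError("measured_A must be >= 0")
    if delay_s == 0:
        return float(measured_A)
    cfg = ExperimentConfig(F0=filtrate_state.F, P0=filtrate_state.P)
    # start from the filtrate composition, including its anhydride (for k4 loss)
    from scipy.integrate import solve_ivp

    from .reaction_cycle import _rhs

    y0 = [filtrate_state.F, filtrate_state.P, filtrate_state.I, filtrate_state.A, 0.0]
    delay_min = delay_s / 60.0
    sol = solve_ivp(_rhs, (0.0, delay_min), y0, args=(k,), method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"quench-correction integration failed: {sol.message}")
    delta_A = float(sol.y[3, -1] - filtrate_state.A)
    corrected = measured_A - delta_A
    if corrected < 0:
        warnings.warn(
            "quench correction exceeds the measurement; corrected value floored at 0",
            stacklevel=2,
        )
        corrected = 0.0
    return float(corrected)


# ---------------------------------------------------------------------------
# ITC one-site binding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingModel:
    """One-site binding parameters: ``Kd`` (mM), ``dH`` (kJ per mole of bound
    peptide) and stoichiometry ``n`` (sites per RNA monomer unit)."""

    Kd: float
    dH: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")


@dataclass(frozen=True)
class ITCIsotherm:
    """Geometry and blank-subtracted heats of a titration.

    The peptide sits in the syringe and titrates into the RNA-filled cell.
    ``heats_uJ`` are per-injection integrated heats in microjoules.
    """

    cell_volume_uL: float
    cell_rna_mM: float
    syringe_peptide_mM: float
    inj_volumes_uL: np.ndarray
    heats_uJ: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.inj_volumes_uL, dtype=float)
        q = np.asarray(self.heats_uJ, dtype=float)
        if self.cell_volume_uL <= 0 or np.any(v <= 0):
            raise ValueError("volumes must be > 0")
        if v.shape != q.shape or v.ndim != 1:
            raise ValueError("inj_volumes_uL and heats_uJ must be matching 1-D arrays")
        object.__setattr__(self, "inj_volumes_uL", v)
        object.__setattr__(self, "heats_uJ", q)

    @classmethod
    def design(
        cls,
        n_injections: int = 26,
        injection_volume_uL: float = 1.5,
        cell_volume_uL: float = 250.0,
        cell_rna_mM: float = 1.1,
        syringe_peptide_mM: float = 38.0,
    ) -> "ITCIsotherm":
        """Injection schedule with zero heats (for generators and tests)."""
        return cls(
            cell_volume_uL=cell_volume_uL,
            cell_rna_mM=cell_rna_mM,
            syringe_peptide_mM=syringe_peptide_mM,
            inj_volumes_uL=np.full(n_injections, injection_volume_uL),
            heats_uJ=np.zeros(n_injections),
        )

    def with_heats(self, heats_uJ: np.ndarray) -> "ITCIsotherm":
        return dataclasses.replace(self, heats_uJ=np.asarray(heats_uJ, dtype=float))


def _cell_concentrations(iso: ITCIsotherm) -> tuple[np.ndarray, np.ndarray]:
    """Total RNA-monomer and peptide concentrations in the cell after each
    injection, under the perfusion (constant-volume displacement) model."""
    cum = np.cumsum(iso.inj_volumes_uL) / iso.cell_volume_uL
    dil = np.exp(-cum)
    M = iso.cell_rna_mM * dil
    X = iso.syringe_peptide_mM * (1 - dil)
    return M, X


def itc_heats(binding: BindingModel, iso: ITCIsotherm) -> np.ndarray:
    """Per-injection heats (uJ) of the one-site isotherm.

    Bound peptide in the cell follows the single-site quadratic; the
    incremental heat accounts for the bound material displaced by each
    injection.  mM * uL * kJ/mol conveniently equals uJ.
    """
    M, X = _cell_concentrations(iso)
    s = binding.n * M + X + binding.Kd
    MX = 0.5 * (s - np.sqrt(s**2 - 4 * binding.n * M * X))
    Q = MX * binding.dH * iso.cell_volume_uL
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dv = iso.inj_volumes_uL / iso.cell_volume_uL
    return Q - Qprev + dv * 0.5 * (Q + Qprev)


class ITCFitResults:
    """Estimates and diagnostics of a one-site ITC fit."""

    def __init__(
        self,
        model: "ITCModel",
        binding: BindingModel,
        cov: np.ndarray,
        rss: float,
        success: bool,
        message: str,
        flags: tuple[str, ...],
    ):
        self.model = model
        self.binding = binding
        self.cov = cov
        self.rss = rss
        self.success = success
        self.message = message
        self.flags = flags
        with np.errstate(invalid="ignore"):
            self.bse = np.sqrt(np.diag(cov))

    @property
    def c_value(self) -> float:
        """Wiseman c = n * [sites] / Kd at the start of the titration."""
        return self.binding.n * self.model.isotherm.cell_rna_mM / self.binding.Kd

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        est = np.array([self.binding.Kd, self.binding.dH, self.binding.n])
        return pd.DataFrame(
            {"lower": est - z * self.bse, "upper": est + z * self.bse},
            index=["Kd", "dH", "n"],
        )

    def predict(self) -> np.ndarray:
        return itc_heats(self.binding, self.model.isotherm)

    def summary(self) -> str:
        ci = self.conf_int()
        est = [self.binding.Kd, self.binding.dH, self.binding.n]
        units = ["mM", "kJ/mol", ""]
        lines = [
            "One-site ITC binding fit",
            f"  injections used: {self.model.n_used}   RSS: {self.rss:.6g} uJ^2",
            f"  c-value: {self.c_value:.3g}" + ("   flags: " + ", ".join(self.flags) if self.flags else ""),
            f"{'param':>6} {'estimate':>12} {'std err':>12} {'[0.025':>12} {'0.975]':>12}",
        ]
        for i, name in enumerate(["Kd", "dH", "n"]):
            lines.append(
                f"{name:>6} {est[i]:>12.5g} {self.bse[i]:>12.3g} "
                f"{ci['lower'].iloc[i]:>12.3g} {ci['upper'].iloc[i]:>12.3g} {units[i]}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        M, X = _cell_concentrations(self.model.isotherm)
        ratio = X / M
        ax.plot(ratio, self.model.isotherm.heats_uJ, "o", label="data")
        ax.plot(ratio, self.predict(), "-", label="one-site fit")
        ax.set_xlabel("molar ratio peptide : RNA monomer")
        ax.set_ylabel("injection heat (uJ)")
        ax.legend()
        return ax


class ITCModel:
    """One-site (Wiseman) fit of an ITC isotherm by least squares on heats.

    The first injection is excluded by default (partial delivery during
    equilibration is common practice).  A low Wiseman c-value (< 1) does not
    abort the fit but flags wide, poorly determined intervals.
    """

    def __init__(self, isotherm: ITCIsotherm, skip_first: bool = True):
        if isotherm.inj_volumes_uL.size < 10:
            raise ValueError("need >= 10 injections")
        self.isotherm = isotherm
        self.skip_first = skip_first
        self._use = np.ones(isotherm.inj_volumes_uL.size, dtype=bool)
        if skip_first:
            self._use[0] = False
        self.n_used = int(self._use.sum())

    def _start(self) -> np.ndarray:
        q = self.isotherm.heats_uJ[self._use]
        # total heat ~ dH * V0 * bound_final; assume ~1/3 of sites filled at low c
        bound_guess = max(self.isotherm.cell_rna_mM / 3, 1e-6)
        dH0 = np.sum(q) / (self.isotherm.cell_volume_uL * bound_guess)
        if dH0 == 0:
            dH0 = 1.0
        Kd0 = max(self.isotherm.cell_rna_mM, 0.1)
        return np.array([np.log(Kd0), dH0, 0.0])  # (log Kd, dH, log n)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        binding = BindingModel(Kd=float(np.exp(theta[0])), dH=float(theta[1]), n=float(np.exp(theta[2])))
        return (itc_heats(binding, self.isotherm) - self.isotherm.heats_uJ)[self._use]

    def fit(self, start: BindingModel | None = None) -> ITCFitResults:
        q = self.isotherm.heats_uJ[self._use]
        flags: list[str] = []
        if np.allclose(q, 0.0, atol=1e-12):
            flags.append("unidentifiable: all heats zero")
            binding = BindingModel(Kd=1.0, dH=0.0, n=1.0)
            cov = np.full((3, 3), np.inf)
            return ITCFitResults(self, binding, cov, 0.0, False, "degenerate data", tuple(flags))
        if start is not None:
            theta0 = np.array([np.log(start.Kd), start.dH, np.log(start.n)])
        else:
            theta0 = self._start()
        res = least_squares(self._residuals, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        binding = BindingModel(Kd=float(np.exp(res.x[0])), dH=float(res.x[1]), n=float(np.exp(res.x[2])))
        rss = float(2 * res.cost)
        dof = max(self.n_used - 3, 1)
        try:
            cov_t = np.linalg.pinv(res.jac.T @ res.jac) * rss / dof
        except np.linalg.LinAlgError:
            cov_t = np.full((3, 3), np.nan)
        # delta method back to (Kd, dH, n)
        g = np.diag([binding.Kd, 1.0, binding.n])
        cov = g @ cov_t @ g
        c = binding.n * self.isotherm.cell_rna_mM / binding.Kd
        if c < 1:
            flags.append("low c-value: stoichiometry and Kd weakly identified")
        return ITCFitResults(self, binding, cov, rss, bool(res.success), str(res.message), tuple(flags))


def fit_binding_isotherm(isotherm: ITCIsotherm, skip_first: bool = True) -> ITCFitResults:
    """Convenience wrapper: build an :class:`ITCModel` and fit it."""
    return ITCModel(isotherm, skip_first=skip_first).fit()
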