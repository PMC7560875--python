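"""Phase behavior of the fueled coacervate system.

Covers the critical coacervation concentration (the minimal anhydride level
that sustains droplets, ~0.9 mM under standard conditions), the empirical
(fuel, RNA) regime map with its three regimes (no droplets / dynamic /
metastable), two-phase mass balances with partition-derived in-droplet
concentrations, cation:anion charge ratios, and turbidity lifetimes.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .reaction_cycle import (
    ExperimentConfig,
    RateConstants,
    TimeCourse,
    integrate,
    load_defaults,
    peak_anhydride,
)

__all__ = [
    "PhaseBoundaries",
    "RegimeLabel",
    "MassBalanceResult",
    "ChargeModel",
    "TurbidityTrace",
    "critical_concentration",
    "fuel_threshold_scan",
    "classify_regime",
    "mass_balance",
    "charge_ratio",
    "turbidity_lifetime",
]


class RegimeLabel(str, enum.Enum):
    """Closed vocabulary of droplet regimes."""

    NO_DROPLETS = "no_droplets"
    DYNAMIC = "dynamic"
    METASTABLE = "metastable"


@dataclass(frozen=True)
class PhaseBoundaries:
    """Empirical boundaries of the (fuel, RNA) regime map.

    ``A_crit`` is the critical coacervation concentration; ``fuel_lower`` is
    the RNA-independent fuel threshold below which no droplets form;
    ``metastable_anchors`` are (RNA mM, fuel mM) points of the dynamic ->
    metastable boundary, linearly interpolated and clamped outside.
    """

    A_crit: float = 0.9
    fuel_lower: float = 7.5
    metastable_anchors: tuple[tuple[float, float], ...] = ((1.4, 25.0), (4.1, 40.0))

    def __post_init__(self) -> None:
        if self.A_crit <= 0:
            raise ValueError("A_crit must be > 0")
        if any(f <= self.fuel_lower for _, f in self.metastable_anchors):
            raise ValueError("metastable boundary must lie above the lower fuel threshold")

    @classmethod
    def default(cls) -> "PhaseBoundaries":
        d = load_defaults()["phase"]
        return cls(
            A_crit=d["A_crit_mM"],
            fuel_lower=d["fuel_lower_mM"],
            metastable_anchors=tuple(tuple(a) for a in d["metastable_anchors"]),
        )

    def metastable_fuel(self, U0: float) -> float:
        """Fuel level of the dynamic->metastable boundary at RNA ``U0`` (mM)."""
        anchors = sorted(self.metastable_anchors)
        rna = [a[0] for a in anchors]
        fuel = [a[1] for a in anchors]
        return float(np.interp(U0, rna, fuel))  # np.interp clamps outside


@dataclass(frozen=True)
class ChargeModel:
    """Signed charges entering the cation:anion ratio.

    The anhydride product carries +3, the precursor +1 and each RNA uridine
    monomer -1.  The precursor is excluded from the ratio by default: only
    the product's charges are counted against the RNA's.
    """

    product: int = 3
    precursor: int = 1
    rna_monomer: int = -1
    include_precursor: bool = False


@dataclass(frozen=True)
class MassBalanceResult:
    """Two-phase split of one species, whole-sample basis concentrations in mM.

    ``droplet_mM`` is the amount sequestered in the droplet phase expressed on
    the whole-sample basis; ``in_droplet_M`` the local concentration inside
    the droplets in molar.
    """

    species: str
    total_mM: float
    outer_mM: float
    droplet_mM: float
    volume_fraction: float
    in_droplet_M: float

    def __post_init__(self) -> None:
        recon = self.outer_mM * (1 - self.volume_fraction) + self.in_droplet_M * self.volume_fraction * 1000.0
        if abs(recon - self.total_mM) > 1e-6 * max(abs(self.total_mM), 1e-9):
            raise ValueError("mass balance does not close")


@dataclass(frozen=True)
class TurbidityTrace:
    """Blank-subtracted absorbance at 600 nm against time (minutes, a.u.)."""

    t: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("t and absorbance must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "absorbance", a)


def critical_concentration(
    threshold_fuel: float,
    config: ExperimentConfig | None = None,
    k: RateConstants | None = None,
    t_end: float = 30.0,
) -> float:
    """Peak anhydride reached at the turbidity-onset fuel concentration.

    The turbidity threshold observed in fuel titrations (7.5 mM fuel under
    standard conditions) is converted into a critical anhydride concentration
    by integrating the cycle at that fuel level and reading off the peak.
    """
    if threshold_fuel < 0:
        raise ValueError("threshold_fuel must be >= 0")
    if threshold_fuel == 0:
        return 0.0
    config = (config or ExperimentConfig(F0=threshold_fuel)).replace(F0=threshold_fuel)
    k = k or RateConstants.default()
    return peak_anhydride(integrate(config, k, t_end))[1]


def fuel_threshold_scan(
    config: ExperimentConfig,
    k: RateConstants,
    A_crit: float = 0.9,
    resolution: float = 0.5,
    fuel_max: float = 100.0,
    t_end: float = 30.0,
) -> float | None:
    """Smallest fuel concentration (on a grid of ``resolution``) whose peak
    anhydride reaches ``A_crit``.

    A coarse geometric bracketing is refined by bisection down to
    ``resolution``; the result is snapped up to the grid.  Returns ``None``
    when the threshold is not reached within ``fuel_max``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")

    def peak(f0: float) -> float:
        if f0 <= 0:
            return 0.0
        return peak_anhydride(integrate(config.replace(F0=f0), k, t_end))[1]

    if A_crit <= 0:
        return resolution  # grid minimum: any fuel at all exceeds a zero threshold
    lo, hi = 0.0, None
    f = max(resolution, fuel_max / 16)
    while f <= fuel_max * (1 + 1e-12):
        if peak(f) >= A_crit:
            hi = f
            break
        lo = f
        f *= 2
    if hi is None:
        if lo < fuel_max and peak(fuel_max) >= A_crit:
            lo, hi = lo, fuel_max
        else:
            return None
    while hi - lo > resolution / 4:
        mid = 0.5 * (lo + hi)
        if peak(mid) >= A_crit:
            hi = mid
        else:
            lo = mid
    return float(np.ceil(hi / resolution - 1e-9) * resolution)


def classify_regime(F0: float, U0: float, boundaries: PhaseBoundaries | None = None) -> RegimeLabel:
    """Label a (fuel, RNA) condition as no_droplets / dynamic / metastable."""
    if F0 < 0 or U0 < 0:
        raise ValueError("F0 and U0 must be >= 0")
    b = boundaries or PhaseBoundaries.default()
    if F0 <= b.fuel_lower:
        return RegimeLabel.NO_DROPLETS
    if F0 >= b.metastable_fuel(U0):
        return RegimeLabel.METASTABLE
    return RegimeLabel.DYNAMIC


def mass_balance(
    total: float,
    filtrate: float,
    droplet_volume_fraction: float,
    species: str = "anhydride",
) -> MassBalanceResult:
    """Split a species between the droplet phase and the outer phase.

    ``total`` is the whole-sample concentration, ``filtrate`` the outer-phase
    concentration measured after removing the droplets, and
    ``droplet_volume_fraction`` the centrifugation-measured volume fraction of
    the droplet phase.  The droplet amount (sample basis) is
    ``total - filtrate * (1 - volume_fraction)``; noisy measurements with
    ``filtrate > total`` clamp the droplet amount to zero with a warning.
    """
    if not (0 < droplet_volume_fraction < 1):
        raise ValueError("droplet_volume_fraction must lie in (0, 1)")
    if total < 0 or filtrate < 0:
        raise ValueError("concentrations must be >= 0")
    droplet = total - filtrate * (1 - droplet_volume_fraction)
    outer = filtrate
    if droplet < 0:
        warnings.warn(
            f"filtrate ({filtrate} mM) exceeds total ({total} mM); "
            "droplet amount clamped to zero",
            stacklevel=2,
        )
        droplet = 0.0
        outer = total / (1 - droplet_volume_fraction)
    in_droplet_M = droplet / droplet_volume_fraction / 1000.0
    return MassBalanceResult(
        species=species,
        total_mM=float(total),
        outer_mM=float(outer),
        droplet_mM=float(droplet),
        volume_fraction=float(droplet_volume_fraction),
        in_droplet_M=float(in_droplet_M),
    )


def charge_ratio(
    product_in_droplets: float,
    rna_in_droplets: float,
    charges: ChargeModel | None = None,
    precursor_in_droplets: float = 0.0,
) -> float:
    """Cation:anion charge ratio inside the droplet phase.

    Both inputs are droplet-phase amounts on the whole-sample basis (mM).
    Under the default :class:`ChargeModel` only the +3 product counts against
    the -1-per-monomer RNA; set ``include_precursor`` to add the precursor's
    +1 contribution.
    """
    charges = charges or ChargeModel()
    if rna_in_droplets <= 0:
        raise ValueError("rna_in_droplets must be > 0")
    if product_in_droplets < 0:
        raise ValueError("product_in_droplets must be >= 0")
    cations = charges.product * product_in_droplets
    if charges.include_precursor:
        cations += charges.precursor * precursor_in_droplets
    anions = abs(charges.rna_monomer) * rna_in_droplets
    return float(cations / anions)


def turbidity_lifetime(trace: TurbidityTrace, cutoff: float = 0.01) -> float | None:
    """Time at which the turbidity last drops below ``cutoff`` after its peak.

    This is the plate-reader lifetime: the time for the blank-subtracted
    absorbance at 600 nm to fall under 0.01 a.u. after fuel addition.
    Returns ``None`` when the trace never exceeds the cutoff (no droplets) or
    never clears it within the trace.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    t, a = trace.t, trace.absorbance
    if np.max(a) <= cutoff:
        return None
    i_peak = int(np.argmax(a))
    after = a[i_peak:]
    above = np.nonzero(after >= cutoff)[0]
    j = i_peak + above[-1]  # last point at/above cutoff following the max
    if j == t.size - 1:
        return None
    frac = (a[j] - cutoff) / (a[j] - a[j + 1])
    return float(t[j] + frac * (t[j + 1] - t[j]))
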