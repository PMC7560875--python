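"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of (truth, design, seed): identical inputs
give identical outputs, and every generator returns enough ground truth to
score the downstream estimator.  Noise models: multiplicative Gaussian for
HPLC and ITC heats (instrument-proportional), additive Gaussian for
turbidity, Poisson-Gaussian for micrographs.

The coupling of image content to the anhydride concentration (droplet count
and area growing with A(t) above the coacervation threshold) is a synthetic
construction: it emulates the qualitative correlation between product level
and droplet load so that the imaging estimators can be exercised against
ground truth, and is not a mechanistic claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import BindingModel, HPLCMeasurement, ITCIsotherm, itc_heats
from .imaging import MicrographFrame
from .phase_analysis import TurbidityTrace
from .reaction_cycle import ExperimentConfig, RateConstants, TimeCourse, integrate
from .phase_analysis import RegimeLabel

__all__ = [
    "NoiseSpec",
    "TurbidityModel",
    "ImagingDesign",
    "synth_hplc",
    "synth_turbidity",
    "synth_itc",
    "synth_timelapse",
    "synth_frame",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitude and seed for a generator.

    ``rel`` is the relative (multiplicative) noise fraction, ``floor`` an
    additive Gaussian floor in the units of the signal.
    """

    rel: float = 0.0
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel < 0 or self.floor < 0:
            raise ValueError("noise parameters must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TurbidityModel:
    """Map from anhydride concentration to 600-nm absorbance.

    Dynamic droplets scatter in proportion to the anhydride above the
    critical concentration.  Metastable droplets are kinetically arrested:
    once formed, the turbidity holds at its running maximum and collapses
    only after the persistence time.
    """

    scale: float = 0.25
    A_crit: float = 0.9
    persistence_min: float = 76.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.persistence_min < 0:
            raise ValueError("persistence must be >= 0")


@dataclass(frozen=True)
class ImagingDesign:
    """Geometry and optics of a synthetic confocal frame.

    ``count_scale`` converts anhydride excess above ``A_crit`` (mM) into a
    droplet count per frame; radii are drawn uniformly in
    ``[radius_min_px, radius_max_px]``.  ``gain`` is photons per intensity
    unit for the Poisson branch of the noise; ``read_noise`` the Gaussian
    floor in intensity units.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    psf_sigma_px: float = 2.0
    background: float = 200.0
    count_scale: float = 12.0
    radius_min_px: float = 6.0
    radius_max_px: float = 14.0
    A_crit: float = 0.9
    gain: float = 1.0
    read_noise: float = 5.0


def synth_hplc(
    config: ExperimentConfig,
    k: RateConstants,
    sample_times: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
    filtrate: bool = False,
    quench_delay_s: float = 20.0,
    species: tuple[str, ...] = ("fuel", "anhydride", "precursor"),
) -> list[HPLCMeasurement]:
    """HPLC measurements drawn from the kinetic model.

    For filtrate samples, the anhydride value is the model value advanced by
    ``quench_delay_s`` — emulating the product formed in the filtrate between
    filtration and quench — so that the quench correction can be round-trip
    tested.  Noise is multiplicative Gaussian plus an additive floor, clipped
    at zero.
    """
    from scipy.integrate import solve_ivp

    from .reaction_cycle import _rhs

    sample_times = np.asarray(sample_times, dtype=float)
    delay_min = quench_delay_s / 60.0 if filtrate else 0.0
    t_grid = np.unique(np.concatenate([sample_times, sample_times + delay_min]))
    t_grid = t_grid[t_grid > 0]
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_grid[-1]) if t_grid.size else 1e-3),
        [config.F0, config.P0, 0.0, 0.0, 0.0],
        args=(k,),
        method="LSODA",
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    at = {t: j for j, t in enumerate(t_grid)}
    init = {"fuel": config.F0, "anhydride": 0.0, "precursor": config.P0}
    row = {"fuel": 0, "anhydride": 3, "precursor": 1}
    rng = noise.rng()
    out = []
    for t in sample_times:
        for sp in species:
            t_read = t + delay_min if (filtrate and sp == "anhydride") else t
            c = init[sp] if t_read == 0 else float(sol.y[row[sp], at[t_read]])
            c_noisy = c * (1 + noise.rel * rng.standard_normal()) + noise.floor * rng.standard_normal()
            out.append(
                HPLCMeasurement(
                    t=float(t),
                    species=sp,
                    concentration=max(c_noisy, 0.0),
                    is_filtrate=filtrate,
                    quench_delay_s=quench_delay_s if filtrate else None,
                )
            )
    return out


def synth_turbidity(
    tc: TimeCourse,
    model: TurbidityModel = TurbidityModel(),
    noise: NoiseSpec = NoiseSpec(),
    regime: RegimeLabel | str = RegimeLabel.DYNAMIC,
) -> TurbidityTrace:
    """Turbidity trace implied by an anhydride time course.

    Dynamic regime: absorbance tracks ``scale * max(0, A - A_crit)``.
    Metastable regime: after the first crossing above ``A_crit`` the
    absorbance is held at its running maximum (kinetic arrest) and drops to
    zero after the persistence time has elapsed since fuel addition.
    """
    regime = RegimeLabel(regime)
    base = model.scale * np.clip(tc.A - model.A_crit, 0.0, None)
    if regime is RegimeLabel.METASTABLE and np.any(base > 0):
        held = np.maximum.accumulate(base)
        absorb = np.where(tc.t <= model.persistence_min, held, 0.0)
    else:
        absorb = base
    rng = noise.rng()
    absorb = absorb + noise.floor * rng.standard_normal(absorb.size)
    return TurbidityTrace(t=tc.t.copy(), absorbance=absorb)


def synth_itc(
    truth: BindingModel,
    design: ITCIsotherm | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> ITCIsotherm:
    """Synthetic isotherm: one-site heats with dilution accounting plus noise.

    The default design mirrors the study's titration: 26 injections of
    1.5 uL of 38 mM peptide into 250 uL of 1.1 mM RNA monomer.
    """
    design = design or ITCIsotherm.design()
    q = itc_heats(truth, design)
    rng = noise.rng()
    q_noisy = q * (1 + noise.rel * rng.standard_normal(q.size)) + noise.floor * rng.standard_normal(q.size)
    return design.with_heats(q_noisy)


def _place_disks(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    r_min: float,
    r_max: float,
    margin: float = 4.0,
    max_tries: int = 20000,
) -> list[tuple[float, float, float]]:
    """Rejection-sample ``n`` non-overlapping disks (cx, cy, r)."""
    placed: list[tuple[float, float, float]] = []
    h, w = shape
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        r = rng.uniform(r_min, r_max)
        cx = rng.uniform(r + margin, w - r - margin)
        cy = rng.uniform(r + margin, h - r - margin)
        if all((cx - x) ** 2 + (cy - y) ** 2 > (r + rr + 2 * margin) ** 2 for x, y, rr in placed):
            placed.append((cx, cy, r))
    return placed


def synth_frame(
    n_droplets: int,
    K_true: float,
    design: ImagingDesign = ImagingDesign(),
    seed: int = 0,
    time_min: float = 0.0,
) -> tuple[MicrographFrame, pd.DataFrame]:
    """One synthetic frame with ``n_droplets`` non-overlapping droplets.

    Interior intensity is ``K_true`` times the background, blurred with a
    Gaussian PSF and corrupted with Poisson-Gaussian noise.  Returns the
    frame and its ground-truth table (one row per droplet).
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    disks = _place_disks(rng, n_droplets, design.shape, design.radius_min_px, design.radius_max_px)
    img = np.full(design.shape, design.background, dtype=float)
    yy, xx = np.mgrid[0 : design.shape[0], 0 : design.shape[1]]
    for cx, cy, r in disks:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = K_true * design.background
    img = gaussian_filter(img, design.psf_sigma_px)
    photons = rng.poisson(np.clip(img * design.gain, 0, None)).astype(float) / design.gain
    img_noisy = np.clip(photons + design.read_noise * rng.standard_normal(img.shape), 0.0, None)
    frame = MicrographFrame(pixels=img_noisy, pixel_size_um=design.pixel_size_um, time_min=time_min)
    truth = pd.DataFrame(
        [{"time_min": time_min, "cx_px": cx, "cy_px": cy, "radius_px": r, "K_true": K_true} for cx, cy, r in disks]
    )
    return frame, truth


def synth_timelapse(
    tc: TimeCourse,
    frame_times: np.ndarray,
    K_true: float,
    design: ImagingDesign = ImagingDesign(),
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[list[MicrographFrame], pd.DataFrame]:
    """Frame sequence whose droplet load follows the anhydride excess.

    The droplet count at each frame time is
    ``round(count_scale * max(0, A(t) - A_crit))``; frames with no anhydride
    excess are blank (background plus noise only).  Returns the frames and
    the concatenated ground-truth table.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    seeds = np.random.SeedSequence(noise.seed).generate_state(frame_times.size)
    frames: list[MicrographFrame] = []
    truths: list[pd.DataFrame] = []
    for t, s in zip(frame_times, seeds):
        A = float(np.interp(t, tc.t, tc.A))
        n = int(round(design.count_scale * max(0.0, A - design.A_crit)))
        frame, truth = synth_frame(n, K_true, design, seed=int(s), time_min=float(t))
        frames.append(frame)
        truths.append(truth)
    truth_all = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["time_min", "cx_px", "cy_px", "radius_px", "K_true"])
    )
    return frames, truth_all
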