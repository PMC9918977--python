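"""Seeded generators for every input class consumed by the pipeline.

The generators emulate the study conditions rather than arbitrary data:

* protein Amide I absorbance as a sum of Gaussian bands (native and
  gel-complexed GAPDH presets, encoding 45/34/21 % and ~30 % alpha
  respectively), optionally on top of a broad liquid-water background
  (1640 cm^-1, FWHM 120) and a narrow water-vapor line comb;
* carrageenan fingerprint spectra whose component widths encode the chain
  state (helix 10 cm^-1, coil 25 cm^-1, perturbed helix 16 cm^-1 at
  unchanged positions), plus the sulfate band at 1240 cm^-1;
* supernatant A280 mixing series following the hinge model with a
  breakpoint at q* = 0.2 under the study's Beer-Lambert parameters;
* spatially clustered docking-pose clouds with per-cluster energies.

All generators are pure functions of (parameters, seed): spectra carry
additive white noise scaled to peak amplitude, the mixing series carries
multiplicative noise.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .amide1 import BandSet, gel_reference_bands, native_reference_bands
from .complexation import EPSILON_GAPDH_280, GAPDH_TETRAMER_MASS, MixingSeries
from .docking import Pose
from .spectra import FWHM_TO_SIGMA, Spectrum, gaussian

__all__ = [
    "SpectrumPreset",
    "NATIVE_PRESET",
    "GEL_PRESET",
    "PoseCloudSpec",
    "make_protein_spectrum",
    "make_carrageenan_spectrum",
    "make_mixing_series",
    "make_pose_cloud",
    "make_water_reference",
    "make_vapor_reference",
]


@dataclass(frozen=True)
class SpectrumPreset:
    """Recipe for a synthetic protein spectrum."""

    name: str
    bands: BandSet
    noise_sigma: float = 0.0          # fraction of peak amplitude
    background: str = "none"          # none | water_band | water_band_plus_vapor

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.background not in ("none", "water_band", "water_band_plus_vapor"):
            raise ValueError(f"unknown background {self.background!r}")


NATIVE_PRESET = SpectrumPreset("native", native_reference_bands())
GEL_PRESET = SpectrumPreset("gel", gel_reference_bands())
_PRESETS = {"native": NATIVE_PRESET, "gel": GEL_PRESET}

#: Amide II band (N-H bend + C-N stretch): center, FWHM, area relative to
#: total Amide I area — included when the grid reaches below 1500 cm^-1
_AMIDE_II_BAND = (1548.0, 45.0, 0.5)
#: broad liquid-water bending band and its association overtone
_WATER_BANDS = ((1640.0, 120.0, 1.0), (2130.0, 250.0, 0.25))
#: fixed pseudo-random vapor-line positions (30 lines, 1300-1900 cm^-1)
_VAPOR_RNG = np.random.default_rng(20230129)
_VAPOR_LINES = tuple(zip(
    np.sort(_VAPOR_RNG.uniform(1300.0, 1900.0, 30)),
    _VAPOR_RNG.uniform(0.5, 1.5, 30),
))


def _band_sum(x: np.ndarray, bands: BandSet) -> np.ndarray:
    y = np.zeros_like(x)
    for c in bands.components:
        y += gaussian(x, c.center, c.fwhm, c.area)
    return y


def _water_profile(x: np.ndarray) -> np.ndarray:
    """Unit-peak liquid-water profile (bending band + association band)."""
    y = np.zeros_like(x)
    for center, fwhm, rel in _WATER_BANDS:
        y += rel * np.exp(-0.5 * ((x - center) / (fwhm * FWHM_TO_SIGMA)) ** 2)
    return y / y.max() if y.max() > 0 else y


def _vapor_profile(x: np.ndarray) -> np.ndarray:
    """Unit-peak water-vapor comb (narrow lines, FWHM 2 cm^-1)."""
    y = np.zeros_like(x)
    for pos, amp in _VAPOR_LINES:
        y += amp * np.exp(-0.5 * ((x - pos) / (2.0 * FWHM_TO_SIGMA)) ** 2)
    m = y.max()
    return y / m if m > 0 else y


def make_water_reference(grid: np.ndarray | None = None) -> Spectrum:
    """Liquid-water reference spectrum (unit peak) on *grid* (default
    1300-2400 cm^-1 at 1 cm^-1)."""
    x = np.arange(1300.0, 2401.0, 1.0) if grid is None else np.asarray(grid, float)
    return Spectrum(x, _water_profile(x), "liquid water reference")


def make_vapor_reference(grid: np.ndarray | None = None) -> Spectrum:
    """Water-vapor reference spectrum (unit peak) on *grid*."""
    x = np.arange(1300.0, 2401.0, 1.0) if grid is None else np.asarray(grid, float)
    return Spectrum(x, _vapor_profile(x), "water vapor reference")


def make_protein_spectrum(
    preset: SpectrumPreset | str = "native",
    seed: int = 0,
    grid: np.ndarray | None = None,
    *,
    water_scale: float = 2.0,
    vapor_scale: float = 0.05,
    include_amide_ii: bool | None = None,
) -> Spectrum:
    """Synthetic protein Amide I spectrum for a preset.

    With ``background="none"`` the grid spans 1580-1720 cm^-1 and the
    absorbance equals the analytic Gaussian band sum (plus seeded noise).
    With a water/vapor background the grid extends to 1300-2400 cm^-1 so the
    reference-scaling windows (1700-1900 and 2000-2300 cm^-1) are covered;
    the water profile peaks at ``water_scale`` x the Amide I maximum and the
    vapor comb at ``vapor_scale`` x.  An Amide II band is included whenever
    the grid reaches below 1500 cm^-1 (or ``include_amide_ii`` forces it), so
    protein subtraction by Amide II scaling can be exercised.
    """
    if isinstance(preset, str):
        try:
            preset = _PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}") from None
    if grid is None:
        if preset.background == "none":
            x = np.arange(1580.0, 1721.0, 1.0)
        else:
            x = np.arange(1300.0, 2401.0, 1.0)
    else:
        x = np.asarray(grid, dtype=float)
    y = _band_sum(x, preset.bands)
    peak = float(y.max())
    if include_amide_ii is None:
        include_amide_ii = float(x.min()) <= 1500.0
    if include_amide_ii:
        c2, f2, rel2 = _AMIDE_II_BAND
        total = sum(c.area for c in preset.bands.components)
        y = y + gaussian(x, c2, f2, rel2 * total)
    if preset.background in ("water_band", "water_band_plus_vapor"):
        y = y + water_scale * peak * _water_profile(x)
    if preset.background == "water_band_plus_vapor":
        y = y + vapor_scale * peak * _vapor_profile(x)
    if preset.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, preset.noise_sigma * peak, x.size)
    return Spectrum(x, y, f"synthetic {preset.name} GAPDH")


#: fingerprint component centers (cm^-1) and relative areas
_CARRAGEENAN_BANDS = ((1010.0, 1.0), (1040.0, 1.5), (1070.0, 1.2))
_SULFATE_BAND = (1240.0, 40.0, 2.0)
_STATE_FWHM = {"helix": 10.0, "coil": 25.0, "perturbed_helix": 16.0}


def make_carrageenan_spectrum(
    state: str,
    seed: int = 0,
    noise_sigma: float = 0.01,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Synthetic carrageenan spectrum; component width encodes chain state.

    Components sit at 1010/1040/1070 cm^-1 in every state — only their FWHM
    changes (helix 10, coil 25, perturbed helix 16 cm^-1) — and the sulfate
    band at 1240 cm^-1 (FWHM 40) is state-independent.
    """
    if state not in _STATE_FWHM:
        raise ValueError(f"unknown state {state!r}; expected one of {set(_STATE_FWHM)}")
    x = np.arange(900.0, 1801.0, 1.0) if grid is None else np.asarray(grid, float)
    fwhm = _STATE_FWHM[state]
    y = np.zeros_like(x)
    for center, area in _CARRAGEENAN_BANDS:
        y += gaussian(x, center, fwhm, area)
    y += gaussian(x, _SULFATE_BAND[0], _SULFATE_BAND[1], _SULFATE_BAND[2])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma * float(y.max()), x.size)
    return Spectrum(x, y, f"synthetic kappa-carrageenan ({state})")


def make_mixing_series(
    q_star: float = 0.2,
    grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
    *,
    c0: float = 5.0,
    epsilon: float = EPSILON_GAPDH_280,
    path_cm: float = 1.0,
    protein_molar_mass: float = GAPDH_TETRAMER_MASS,
) -> MixingSeries:
    """Supernatant A280 series following ``fraction(q) = min(q/q*, 1)``.

    Defaults reproduce the study conditions: breakpoint at q* = 0.2 on the
    mass-ratio grid 0.1-1.0 (step 0.1), initial protein 5 mg/mL, epsilon
    30.4 mM^-1 cm^-1, 1 cm path.  *noise* is multiplicative (fractional).
    """
    if q_star <= 0:
        raise ValueError("q_star must be > 0")
    q = np.round(np.arange(0.1, 1.01, 0.1), 10) if grid is None else np.asarray(grid, float)
    fraction = np.minimum(q / q_star, 1.0)
    c0_mM = c0 * 1000.0 / protein_molar_mass
    a280 = epsilon * path_cm * c0_mM * (1.0 - fraction)
    if noise > 0:
        rng = np.random.default_rng(seed)
        a280 = a280 * (1.0 + rng.normal(0.0, noise, q.size))
    return MixingSeries(q, np.clip(a280, 0.0, None), path_cm=path_cm, c0=c0,
                        epsilon=epsilon, protein_molar_mass=protein_molar_mass)


@dataclass
class PoseCloudSpec:
    """Recipe for a synthetic docking-pose cloud."""

    cluster_centres: list[tuple[float, float, float]]
    sizes: list[int]
    sigma: float = 3.0                 # isotropic positional spread, Angstrom
    energy_means: list[float] = field(default_factory=list)
    energy_sigma: float = 0.3          # kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.energy_means:
            self.energy_means = [-3.0] * len(self.cluster_centres)
        if not (len(self.cluster_centres) == len(self.sizes) == len(self.energy_means)):
            raise ValueError("cluster_centres, sizes and energy_means must match")
        if any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def make_pose_cloud(spec: PoseCloudSpec) -> list[Pose]:
    """Isotropic Gaussian point clouds of single-atom poses per cluster.

    Warns when two cluster centres are closer than 4 sigma (overlapping
    clouds make the generator truth ambiguous).
    """
    centres = np.asarray(spec.cluster_centres, dtype=float).reshape(-1, 3)
    for i in range(len(centres)):
        for j in range(i + 1, len(centres)):
            if np.linalg.norm(centres[i] - centres[j]) < 4.0 * spec.sigma:
                _warnings.warn(
                    f"cluster centres {i} and {j} closer than 4 sigma; "
                    "clouds overlap", stacklevel=2,
                )
    rng = np.random.default_rng(spec.seed)
    poses: list[Pose] = []
    for centre, size, e_mean in zip(centres, spec.sizes, spec.energy_means):
        xyz = rng.normal(0.0, spec.sigma, (size, 3)) + centre
        energies = rng.normal(e_mean, spec.energy_sigma, size)
        for k in range(size):
            poses.append(Pose(("C",), xyz[k:k + 1], float(energies[k]),
                              disaccharide_map=np.array([1])))
    return poses
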