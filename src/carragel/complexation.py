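"""Protein partitioning across a mixing series and complex stoichiometry.

Mixtures of GAPDH with increasing kappa-carrageenan/protein mass ratio q
co-precipitate as gels; the protein in the sediment is the difference between
the initial amount and what remains in the supernatant (quantified by A280 via
Beer-Lambert with the GAPDH extinction coefficient).  Sedimented fraction
versus q follows a hinge: it rises linearly while polysaccharide is limiting
and saturates at 1 above the stoichiometric ratio q*.  Least-squares fitting
of ``f(q) = min(q / q*, 1)`` recovers q*, and the disaccharides-per-tetramer
count follows from the molar masses: ``round(q* * M_tetramer / M_disaccharide)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "EPSILON_GAPDH_280",
    "GAPDH_TETRAMER_MASS",
    "KAPPA_DISACCHARIDE_MASS",
    "MixingSeries",
    "HingeFit",
    "StoichiometryResult",
    "concentration_from_a280",
    "sediment_fraction",
    "find_stoichiometric_ratio",
    "disaccharides_per_tetramer",
    "stoichiometry",
]

#: molar extinction coefficient of GAPDH at 280 nm, mM^-1 cm^-1
EPSILON_GAPDH_280 = 30.4
#: rabbit-muscle GAPDH homotetramer, g/mol (4 x ~36 kDa chains)
GAPDH_TETRAMER_MASS = 144_000.0
#: kappa-carrageenan disaccharide repeat (free acid), g/mol
KAPPA_DISACCHARIDE_MASS = 386.0


@dataclass
class MixingSeries:
    """Supernatant absorbances over a polysaccharide/protein mass-ratio grid."""

    q: np.ndarray                      # mass ratios, strictly increasing, > 0
    a280: np.ndarray                   # supernatant absorbance at 280 nm
    path_cm: float = 1.0
    c0: float = 5.0                    # initial protein concentration, mg/mL
    epsilon: float = EPSILON_GAPDH_280  # mM^-1 cm^-1
    protein_molar_mass: float = GAPDH_TETRAMER_MASS  # g/mol

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.a280 = np.asarray(self.a280, dtype=float)
        if self.q.size != self.a280.size:
            raise ValueError("q and a280 must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and > 0")
        if np.any(self.a280 < 0):
            raise ValueError("a280 must be >= 0")
        if self.epsilon <= 0 or self.path_cm <= 0 or self.c0 <= 0:
            raise ValueError("epsilon, path_cm and c0 must be > 0")

    @property
    def c0_mM(self) -> float:
        """Initial protein concentration in mM of tetramer."""
        return self.c0 * 1000.0 / self.protein_molar_mass


def concentration_from_a280(a280: float, epsilon: float, path_cm: float) -> float:
    """Beer-Lambert: concentration (mM) from absorbance at 280 nm."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path_cm must be > 0")
    if np.any(np.asarray(a280) < 0):
        raise ValueError("absorbance must be >= 0")
    return a280 / (epsilon * path_cm)


def sediment_fraction(series: MixingSeries, tolerance: float = 0.05) -> np.ndarray:
    """Per-ratio fraction of protein in the sediment, 1 - c_sup / c0.

    Supernatant concentrations exceeding the initial concentration by more
    than *tolerance* (relative) violate mass balance and raise.
    """
    c_sup = concentration_from_a280(series.a280, series.epsilon, series.path_cm)
    c0 = series.c0_mM
    if np.any(c_sup > c0 * (1.0 + tolerance)):
        worst = float(c_sup.max() / c0)
        raise ValueError(
            f"supernatant exceeds initial protein by {100 * (worst - 1):.1f} % "
            "— impossible mass balance"
        )
    return np.clip(1.0 - c_sup / c0, 0.0, 1.0)


@dataclass
class HingeFit:
    """Breakpoint fit of the sedimented-fraction hinge model."""

    q_star: float
    extrapolated: bool
    lower_bound: bool
    sse: float
    warnings: list[str] = field(default_factory=list)


def find_stoichiometric_ratio(series: MixingSeries) -> HingeFit:
    """Least-squares fit of ``fraction(q) = min(q / q*, 1)``.

    Below q* the sedimented protein grows linearly with added polysaccharide;
    above it all protein is in the gel.  Degenerate series (all fractions ~1)
    return q* = min(q) flagged as a lower bound; a q* outside the observed q
    range is flagged extrapolated.
    """
    if series.q.size < 4:
        raise ValueError("need at least 4 mixing ratios spanning the breakpoint")
    f = sediment_fraction(series)
    q = series.q
    warnings: list[str] = []
    if np.any(np.diff(f) < -0.05):
        warnings.append("sediment fraction not monotone beyond noise tolerance")
    if np.all(f >= 0.98):
        return HingeFit(float(q[0]), False, True, 0.0,
                        warnings + ["all protein sedimented: q* <= min(q)"])

    def sse(qs: float) -> float:
        r = np.minimum(q / qs, 1.0) - f
        return float(r @ r)

    candidates = np.linspace(q[0] / 4.0, 2.0 * q[-1], 2049)
    best = candidates[int(np.argmin([sse(c) for c in candidates]))]
    span = candidates[1] - candidates[0]
    res = minimize_scalar(sse, bounds=(best - span, best + span), method="bounded",
                          options={"xatol": 1e-10})
    q_star = float(res.x)
    extrapolated = not (q[0] <= q_star <= q[-1])
    if extrapolated:
        warnings.append("breakpoint outside the observed q range")
    return HingeFit(q_star, extrapolated, False, float(res.fun), warnings)


def disaccharides_per_tetramer(
    q_star: float,
    tetramer_mass: float = GAPDH_TETRAMER_MASS,
    disaccharide_mass: float = KAPPA_DISACCHARIDE_MASS,
) -> int:
    """Disaccharide repeat units bound per protein tetramer at stoichiometry.

    The mass ratio q* converts to a molar ratio through the molar masses:
    q* = 0.2 with the default masses gives round(0.2 * 144000 / 386) = 75.
    """
    if tetramer_mass <= 0 or disaccharide_mass <= 0:
        raise ValueError("molar masses must be > 0")
    if q_star < 0:
        raise ValueError("q_star must be >= 0")
    return round(q_star * tetramer_mass / disaccharide_mass)


@dataclass
class StoichiometryResult:
    q_star: float
    disaccharides_per_tetramer: int
    sediment_fraction: np.ndarray
    extrapolated: bool
    lower_bound: bool
    warnings: list[str]


def stoichiometry(
    series: MixingSeries,
    tetramer_mass: float = GAPDH_TETRAMER_MASS,
    disaccharide_mass: float = KAPPA_DISACCHARIDE_MASS,
) -> StoichiometryResult:
    """Full series analysis: hinge fit plus the molar-ratio conversion."""
    fit = find_stoichiometric_ratio(series)
    return StoichiometryResult(
        q_star=fit.q_star,
        disaccharides_per_tetramer=disaccharides_per_tetramer(
            fit.q_star, tetramer_mass, disaccharide_mass
        ),
        sediment_fraction=sediment_fraction(series),
        extrapolated=fit.extrapolated,
        lower_bound=fit.lower_bound,
        warnings=fit.warnings,
    )
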