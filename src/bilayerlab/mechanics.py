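"""Membrane mechanical moduli.

Two estimators:

* Area compressibility modulus from equilibrium projected-area
  fluctuations in the NpT ensemble,

      K_A = k_B T A_0 / <(A - A_0)^2>,

  reported in mN/m.

* Bending modulus from a buckled membrane held at fixed strain. A
  membrane buckled along x at strain gamma = 1 - Lx/L exerts a force per
  unit length f = -<sigma_xx> * Lz on the box walls; classical Euler
  elastica theory fixes the dimensionless relation f~(gamma) = f L^2 / K_c,
  so K_c = f L^2 / f~(gamma). For the first periodic buckling mode the
  relation is exact in terms of complete elliptic integrals:

      gamma = 2 (1 - E(m)/K(m)),      f~ = 16 K(m)^2,

  with m the elliptic parameter; f~ -> 4 pi^2 (the Euler threshold of the
  periodic mode) as gamma -> 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipe, ellipk

from .constants import (BAR_TO_KJ_PER_MOL_NM3, DEFAULT_TEMPERATURE, KB,
                        KJ_PER_MOL_NM2_TO_MN_PER_M)

__all__ = [
    "AreaSeries",
    "BucklingDataset",
    "MechanicalEstimate",
    "compressibility",
    "elastica_force",
    "elastica_shape",
    "extract_kc",
]


@dataclass
class AreaSeries:
    """Projected membrane area per frame (A = Lx*Ly), nm^2."""

    times: np.ndarray  # ps
    areas: np.ndarray  # nm^2

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1 or self.areas.size < 2:
            raise ValueError("need at least 2 area samples")
        if (self.areas <= 0).any():
            raise ValueError("areas must be positive")

    @property
    def mean_area(self) -> float:
        return float(self.areas.mean())


@dataclass
class BucklingDataset:
    """Stress record of a membrane buckled along x at fixed box.

    ``L`` is the flat-state contour length (nm), ``Lx`` the compressed
    box edge; strain gamma = 1 - Lx/L. ``stress_xx`` is the xx element
    of the stress tensor in bar (compressive stress negative).
    """

    L: float
    Lx: float
    Ly: float
    Lz: float
    stress_xx: np.ndarray  # bar
    times: np.ndarray | None = None  # ps
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.stress_xx = np.asarray(self.stress_xx, dtype=float)
        if self.Lx >= self.L:
            raise ValueError("compressed edge Lx must be shorter than contour length L")
        if not 0.0 < self.strain < 0.5:
            raise ValueError(f"strain {self.strain:.3f} outside (0, 0.5)")

    @property
    def strain(self) -> float:
        return 1.0 - self.Lx / self.L


@dataclass
class MechanicalEstimate:
    value: float
    units: str
    error: float
    method: str

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("estimate must be finite")
        if self.error < 0:
            raise ValueError("error must be non-negative")


def _block_se(x: np.ndarray, estimator, n_blocks: int = 5) -> float:
    """Standard error of ``estimator`` over contiguous blocks of ``x``."""
    n = len(x)
    if n < 2 * n_blocks:
        return float("nan")
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    vals = np.array([estimator(x[a:b]) for a, b in zip(edges, edges[1:])])
    return float(np.std(vals, ddof=1) / np.sqrt(n_blocks))


def compressibility(series: AreaSeries, T: float = DEFAULT_TEMPERATURE) -> MechanicalEstimate:
    """Area compressibility modulus from area fluctuations, in mN/m.

    Uses the population variance of the projected area; the estimator
    depends on moments only, so it is invariant under time-reordering of
    the series. The uncertainty comes from 5-block averaging.
    """
    areas = series.areas
    a0 = areas.mean()
    var = float(np.var(areas))  # ddof=0
    if var == 0.0:
        raise ValueError("rigid input: zero area variance")

    def ka_of(block: np.ndarray) -> float:
        v = float(np.var(block))
        return KB * T * block.mean() / v * KJ_PER_MOL_NM2_TO_MN_PER_M if v > 0 else np.nan

    ka = KB * T * a0 / var * KJ_PER_MOL_NM2_TO_MN_PER_M
    se = _block_se(areas, ka_of)
    return MechanicalEstimate(value=float(ka), units="mN/m",
                              error=0.0 if np.isnan(se) else se,
                              method="area-fluctuation")


# ---------------------------------------------------------------------------
# elastica


def _gamma_of_m(m: float) -> float:
    """Strain of the first periodic buckling mode at elliptic parameter m."""
    return 2.0 * (1.0 - ellipe(m) / ellipk(m))


def elastica_force(strain: float) -> float:
    """Dimensionless buckling force f~ = f L^2 / K_c of the periodic elastica.

    Solves gamma(m) = strain for the elliptic parameter m to 1e-12 and
    returns 16 K(m)^2. Strictly increasing in the strain, with the Euler
    threshold 4 pi^2 as the zero-strain limit.
    """
    if not 0.0 < strain < 0.5:
        raise ValueError(f"strain {strain} outside (0, 0.5)")
    m = brentq(lambda mm: _gamma_of_m(mm) - strain, 1e-15, 0.9999999, xtol=1e-15,
               rtol=8.9e-16)
    return float(16.0 * ellipk(m) ** 2)


def elastica_shape(strain: float, L: float, n_points: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Midplane profile (x(s), z(s)) of the periodic buckle, arclength-sampled.

    The tangent angle obeys the pendulum equation; with psi(0)=0 at an
    inflection point, sin(psi/2) = sqrt(m) sn(lambda s | m) with
    lambda = 4 K(m)/L, integrated here by cumulative quadrature.
    """
    if not 0.0 < strain < 0.5:
        raise ValueError(f"strain {strain} outside (0, 0.5)")
    from scipy.special import ellipj
    m = brentq(lambda mm: _gamma_of_m(mm) - strain, 1e-15, 0.9999999, xtol=1e-15,
               rtol=8.9e-16)
    lam = 4.0 * ellipk(m) / L
    s = np.linspace(0.0, L, n_points)
    sn, cn, dn, _ = ellipj(lam * s, m)
    sin_half = np.sqrt(m) * sn
    psi = 2.0 * np.arcsin(np.clip(sin_half, -1.0, 1.0))
    # x' = cos(psi), z' = sin(psi); cumulative trapezoid along arclength
    from scipy.integrate import cumulative_trapezoid
    x = cumulative_trapezoid(np.cos(psi), s, initial=0.0)
    z = cumulative_trapezoid(np.sin(psi), s, initial=0.0)
    return x, z


def extract_kc(data: BucklingDataset, discard_fraction: float = 0.5,
               report_units: str = "kBT") -> MechanicalEstimate:
    """Bending modulus from the stress record of a buckled membrane.

    The leading ``discard_fraction`` of the stress series is dropped as
    equilibration (the default keeps the trailing half). The mean
    compressive stress gives the force per unit length f = -<sigma_xx>*Lz
    (bar converted to kJ/mol/nm^3), and K_c = f L^2 / f~(gamma), reported
    in units of k_B T at the dataset's temperature.
    """
    gamma = data.strain
    stress = data.stress_xx
    n0 = int(np.floor(discard_fraction * len(stress)))
    tail = stress[n0:]
    if tail.size == 0:
        raise ValueError("no stress samples after equilibration discard")
    if tail.size >= 10:
        t = np.arange(tail.size, dtype=float)
        slope = np.polyfit(t, tail, 1)[0]
        resid = tail - tail.mean()
        se_slope = np.sqrt(np.sum(resid ** 2) / max(tail.size - 2, 1)
                           / np.sum((t - t.mean()) ** 2))
        if se_slope > 0 and abs(slope) > 4.0 * se_slope:
            warnings.warn("stress series appears non-stationary (drift detected)")
    mean_stress = float(tail.mean())

    def kc_of(chunk: np.ndarray) -> float:
        return _kc_from_stress(float(chunk.mean()), data, gamma)

    kc = _kc_from_stress(mean_stress, data, gamma)
    se = _block_se(tail, kc_of)
    kbt = KB * data.temperature
    if report_units == "kBT":
        value, err, units = kc / kbt, (0.0 if np.isnan(se) else se / kbt), "kBT"
    elif report_units == "kJ/mol":
        value, err, units = kc, (0.0 if np.isnan(se) else se), "kJ/mol"
    else:
        raise ValueError(f"unknown report units {report_units!r}")
    return MechanicalEstimate(value=float(value), units=units, error=float(err),
                              method="buckling")


def _kc_from_stress(mean_stress_bar: float, data: BucklingDataset, gamma: float) -> float:
    """K_c in kJ/mol from the mean compressive stress (bar)."""
    sigma = mean_stress_bar * BAR_TO_KJ_PER_MOL_NM3  # kJ/mol/nm^3
    f_per_length = -sigma * data.Lz  # kJ/mol/nm^2 (force per unit length in y)
    return f_per_length * data.L ** 2 / elastica_force(gamma)
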