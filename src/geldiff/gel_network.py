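"""Hindered diffusion in a fibrous hydrogel network.

This module implements the physical models that connect the structure of a
random fiber network (collagen/PEG hydrogel) to the in-gel self-diffusion
coefficient ``D_g`` of a spherical solute of hydrodynamic radius ``R_h``:

* **Ogston–Amsden obstruction theory** — diffusion is slowed purely by
  steric exclusion from the fiber mesh::

      D_g / D_0 = exp{ -(π/4) · ((R_h + R_f) / (r̄ + R_f))² }

  where ``R_f`` is the fiber radius and ``r̄`` the mesh radius, the largest
  sphere radius that on average fits into the network without touching a
  fiber.  For a random straight-fiber network at polymer volume fraction φ
  the mesh radius is ``r̄ = R_f · √(π/φ)``.

  .. note::
     The mesh relation is frequently typeset ambiguously in the hydrogel
     literature.  The form used here, ``r̄ = R_f·√(π/φ)``, is the unique
     power law in ``R_f`` and ``φ`` consistent with the standard numerical
     results for dilute random fiber networks (e.g. r̄ ≈ 14 nm for
     R_f = 1 nm and 140 nm for R_f = 10 nm at φ = 0.016).

* **Clague–Phillips hindered diffusion** — adds hydrodynamic drag from the
  fibers to the obstruction effect::

      D_g / D_0 = (1 + 2α/3)⁻¹ · exp{ -π · φ^(0.174·ln(59.6·R_f/R_s)) },
      α = φ · ((R_s + R_f) / R_f)²

  The pre-exponential factor is the Tsai–Strieder obstruction result; the
  exponential is a regression to hydrodynamic simulations of a sphere in a
  random array of cylindrical fibers.  The regression assumes
  ``R_s < 59.6·R_f``; outside that range a warning is emitted.  ``R_s``
  (the solute radius in this theory) is identified with the hydrodynamic
  radius ``R_h``.

* **Stokes–Einstein free diffusivity** ``D_0 = k_B·T / (6π·η·R_h)``.

On top of the forward models the module provides model-curve generation
``D_g(R_h)``, inversion of a measured diffusivity to a solute radius on the
monotone model curve, and least-squares estimation of the mesh radius from
a panel of diffusion probes with FRAP-measured in-gel diffusivities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import units
from .exceptions import FitError, OutsideModelRangeError, ValidationError

__all__ = [
    "GelComposition",
    "GelNetwork",
    "MediumSpec",
    "ProbeSpec",
    "ModelCurve",
    "MeshFit",
    "MODEL_NAMES",
    "volume_fraction",
    "mesh_radius",
    "stokes_einstein_d0",
    "ogston_amsden_ratio",
    "clague_phillips_ratio",
    "model_curve",
    "invert_radius",
    "estimate_mesh_from_probes",
]

MODEL_NAMES = ("ogston_amsden", "clague_phillips")

#: Validity bound of the Clague–Phillips hydrodynamic regression:
#: the exponent decays only while R_s < CP_VALIDITY_FACTOR · R_f.
CP_VALIDITY_FACTOR = 59.6


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _finite_positive(value: float, name: str) -> None:
    _require(np.isfinite(value) and value > 0, f"{name} must be finite and > 0, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GelComposition:
    """Mass composition of a binary polymer/solvent gel.

    Parameters
    ----------
    polymer_mass_fraction
        Polymer mass per total mass, in [0, 1].
    polymer_density_g_ml
        Dry polymer density, g/mL (collagen ≈ 1.3).
    solvent_density_g_ml
        Solvent density, g/mL (water ≈ 0.997).
    """

    polymer_mass_fraction: float
    polymer_density_g_ml: float = 1.3
    solvent_density_g_ml: float = 0.997

    def __post_init__(self) -> None:
        w = self.polymer_mass_fraction
        _require(np.isfinite(w) and 0.0 <= w <= 1.0,
                 f"polymer_mass_fraction must be in [0, 1], got {w!r}")
        _finite_positive(self.polymer_density_g_ml, "polymer_density_g_ml")
        _finite_positive(self.solvent_density_g_ml, "solvent_density_g_ml")


@dataclass(frozen=True)
class MediumSpec:
    """Solvent conditions entering the Stokes–Einstein relation."""

    temperature_k: float = units.DEFAULT_TEMPERATURE_K
    viscosity_pa_s: float = units.DEFAULT_WATER_VISCOSITY_PA_S
    boltzmann_j_per_k: float = units.BOLTZMANN_J_PER_K

    def __post_init__(self) -> None:
        _finite_positive(self.temperature_k, "temperature_k")
        _finite_positive(self.viscosity_pa_s, "viscosity_pa_s")
        _finite_positive(self.boltzmann_j_per_k, "boltzmann_j_per_k")


@dataclass(frozen=True)
class GelNetwork:
    """Random straight-fiber network: fiber radius, volume fraction, mesh radius.

    ``mesh_radius_nm`` may be given explicitly (e.g. fitted from probe data)
    or derived from ``(fiber_radius_nm, volume_fraction)`` via
    :func:`mesh_radius` using :meth:`from_fiber_and_phi`.
    """

    fiber_radius_nm: float
    volume_fraction: float
    mesh_radius_nm: float

    def __post_init__(self) -> None:
        _finite_positive(self.fiber_radius_nm, "fiber_radius_nm")
        _require(np.isfinite(self.volume_fraction) and 0.0 < self.volume_fraction < 1.0,
                 f"volume_fraction must be in (0, 1), got {self.volume_fraction!r}")
        _finite_positive(self.mesh_radius_nm, "mesh_radius_nm")

    @classmethod
    def from_fiber_and_phi(cls, fiber_radius_nm: float, volume_fraction: float) -> "GelNetwork":
        """Build a network with the mesh radius derived from the mesh relation."""
        return cls(
            fiber_radius_nm=fiber_radius_nm,
            volume_fraction=volume_fraction,
            mesh_radius_nm=mesh_radius(fiber_radius_nm, volume_fraction),
        )


@dataclass(frozen=True)
class ProbeSpec:
    """A diffusion probe: hydrodynamic radius plus measured diffusivities.

    ``d_gel_um2_s`` is the FRAP-measured in-gel self-diffusion coefficient;
    ``d_free_um2_s`` the free-solution value.  Either may be omitted —
    ``d_free`` is then supplied by Stokes–Einstein when needed.
    """

    name: str
    r_h_nm: float
    d_gel_um2_s: float | None = None
    d_free_um2_s: float | None = None

    def __post_init__(self) -> None:
        _finite_positive(self.r_h_nm, "r_h_nm")
        for label, v in (("d_gel_um2_s", self.d_gel_um2_s), ("d_free_um2_s", self.d_free_um2_s)):
            if v is not None:
                _finite_positive(v, label)
        if self.d_gel_um2_s is not None and self.d_free_um2_s is not None:
            _require(self.d_gel_um2_s <= self.d_free_um2_s,
                     f"probe {self.name!r}: d_gel ({self.d_gel_um2_s}) exceeds d_free "
                     f"({self.d_free_um2_s})")


@dataclass(frozen=True)
class ModelCurve:
    """An evaluated model curve D_g(R_h) with its generating parameters."""

    model_name: str
    radius_grid_nm: np.ndarray
    dg_um2_s: np.ndarray
    network: GelNetwork
    medium: MediumSpec

    def __post_init__(self) -> None:
        grid = np.asarray(self.radius_grid_nm, dtype=float)
        vals = np.asarray(self.dg_um2_s, dtype=float)
        object.__setattr__(self, "radius_grid_nm", grid)
        object.__setattr__(self, "dg_um2_s", vals)
        _require(self.model_name in MODEL_NAMES, f"unknown model {self.model_name!r}")
        _require(grid.size > 0, "empty radius grid")
        _require(bool(np.all(np.diff(grid) > 0)), "radius grid must be strictly increasing")
        _require(bool(np.all(vals > 0)), "model diffusivities must be strictly positive")


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def volume_fraction(composition: GelComposition) -> float:
    """Polymer volume fraction from mass fraction and component densities.

    φ = (w/ρ_p) / (w/ρ_p + (1−w)/ρ_s) for polymer mass fraction w; assumes
    ideal (additive-volume) mixing.
    """
    w = composition.polymer_mass_fraction
    vp = w / composition.polymer_density_g_ml
    vs = (1.0 - w) / composition.solvent_density_g_ml
    if vp + vs == 0.0:
        raise ValidationError("degenerate composition: zero total volume")
    return vp / (vp + vs)


def mesh_radius(fiber_radius_nm: float, volume_fraction: float) -> float:
    """Mesh radius r̄ = R_f·√(π/φ) of a random straight-fiber network.

    The largest sphere radius that on average fits into the network without
    touching fibers; strictly increasing in ``R_f``, decreasing in ``φ``.
    """
    _finite_positive(fiber_radius_nm, "fiber_radius_nm")
    _require(np.isfinite(volume_fraction) and 0.0 < volume_fraction < 1.0,
             f"volume_fraction must be in (0, 1), got {volume_fraction!r}")
    return fiber_radius_nm * math.sqrt(math.pi / volume_fraction)


def stokes_einstein_d0(r_h_nm, medium: MediumSpec = MediumSpec()):
    """Free-solution diffusivity D_0 = k_B·T / (6π·η·R_h), in μm²/s.

    Accepts a scalar or array of hydrodynamic radii in nm.
    """
    r = np.asarray(r_h_nm, dtype=float)
    _require(bool(np.all(np.isfinite(r)) and np.all(r > 0)),
             "hydrodynamic radius must be finite and > 0")
    d0_si = (medium.boltzmann_j_per_k * medium.temperature_k
             / (6.0 * math.pi * medium.viscosity_pa_s * units.nm_to_m(1.0) * r))
    out = units.m2_per_s_to_um2_per_s(d0_si)
    return float(out) if np.isscalar(r_h_nm) else out


def ogston_amsden_ratio(r_h_nm, network: GelNetwork):
    """Obstruction-theory diffusivity ratio D_g/D_0 (Ogston–Amsden).

    exp{−(π/4)·((R_h+R_f)/(r̄+R_f))²}; in (0, 1), strictly decreasing in R_h.
    """
    r = np.asarray(r_h_nm, dtype=float)
    _require(bool(np.all(np.isfinite(r)) and np.all(r > 0)),
             "hydrodynamic radius must be finite and > 0")
    ratio = np.exp(-(math.pi / 4.0)
                   * ((r + network.fiber_radius_nm)
                      / (network.mesh_radius_nm + network.fiber_radius_nm)) ** 2)
    return float(ratio) if np.isscalar(r_h_nm) else ratio


def clague_phillips_ratio(r_s_nm, network: GelNetwork):
    """Hindered-diffusion ratio D_g/D_0 (Clague–Phillips).

    (1+2α/3)⁻¹·exp{−π·φ^(0.174·ln(59.6·R_f/R_s))} with
    α = φ·((R_s+R_f)/R_f)².  Uses ``volume_fraction`` and ``fiber_radius``
    of the network; the mesh radius does not enter.  Warns (does not fail)
    when R_s ≥ 59.6·R_f, where the hydrodynamic regression is outside its
    fitted range and the exponent no longer decays.
    """
    r = np.asarray(r_s_nm, dtype=float)
    _require(bool(np.all(np.isfinite(r)) and np.all(r > 0)),
             "solute radius must be finite and > 0")
    rf = network.fiber_radius_nm
    phi = network.volume_fraction
    if np.any(r >= CP_VALIDITY_FACTOR * rf):
        warnings.warn(
            f"Clague–Phillips evaluated at R_s ≥ {CP_VALIDITY_FACTOR}·R_f; the "
            "hydrodynamic regression is outside its validity range there",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha = phi * ((r + rf) / rf) ** 2
    exponent = math.pi * phi ** (0.174 * np.log(CP_VALIDITY_FACTOR * rf / r))
    ratio = np.exp(-exponent) / (1.0 + 2.0 * alpha / 3.0)
    return float(ratio) if np.isscalar(r_s_nm) else ratio


_RATIO_FUNCS = {
    "ogston_amsden": ogston_amsden_ratio,
    "clague_phillips": clague_phillips_ratio,
}


def model_curve(
    model_name: str,
    network: GelNetwork,
    medium: MediumSpec = MediumSpec(),
    radius_grid_nm=None,
) -> ModelCurve:
    """Evaluate D_g(R_h) = D_0(R_h)·ratio(R_h) on a radius grid.

    Default grid: 200 log-spaced radii over [0.5, 500] nm.
    """
    _require(model_name in MODEL_NAMES, f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    if radius_grid_nm is None:
        radius_grid_nm = np.geomspace(0.5, 500.0, 200)
    grid = np.atleast_1d(np.asarray(radius_grid_nm, dtype=float))
    _require(grid.size > 0, "empty radius grid")
    dg = stokes_einstein_d0(grid, medium) * _RATIO_FUNCS[model_name](grid, network)
    return ModelCurve(model_name=model_name, radius_grid_nm=grid, dg_um2_s=dg,
                      network=network, medium=medium)


def invert_radius(
    target_dg_um2_s: float,
    model_name: str,
    network: GelNetwork,
    medium: MediumSpec = MediumSpec(),
    search_interval_nm: tuple[float, float] = (0.1, 1e4),
    rtol: float = 1e-9,
) -> float:
    """Solve D_g(R_h) = target for R_h on the monotone composite curve.

    Brackets the root on a log-spaced scan of the search interval, then
    bisects to relative tolerance ``rtol``.  Deterministic.  Raises
    :class:`OutsideModelRangeError` when no radius in the interval attains
    the target diffusivity.
    """
    _finite_positive(target_dg_um2_s, "target_dg_um2_s")
    lo, hi = search_interval_nm
    _require(0 < lo < hi, "search interval must satisfy 0 < lo < hi")

    def f(r_nm: float) -> float:
        return float(stokes_einstein_d0(r_nm, medium)
                     * _RATIO_FUNCS[model_name](r_nm, network)) - target_dg_um2_s

    scan = np.geomspace(lo, hi, 512)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = (stokes_einstein_d0(scan, medium)
                * _RATIO_FUNCS[model_name](scan, network)) - target_dg_um2_s
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if sign_change.size == 0:
            raise OutsideModelRangeError(
                f"target D_g = {target_dg_um2_s} μm²/s is outside the {model_name} "
                f"model range over [{lo}, {hi}] nm")
        i = int(sign_change[0])
        root = optimize.bisect(f, scan[i], scan[i + 1], rtol=rtol, maxiter=200)
    return float(root)


# ---------------------------------------------------------------------------
# Mesh estimation from probe data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeshFit:
    """Result of fitting the mesh radius to a probe panel.

    Residuals and predictions are in D_g/D_0 ratio space, the quantity the
    obstruction theory predicts; ``poor_fit`` flags an RMS ratio residual
    above 0.05.
    """

    network: GelNetwork
    probe_names: tuple[str, ...]
    observed_ratios: np.ndarray
    predicted_ratios: np.ndarray
    residuals: np.ndarray
    rms_residual: float
    poor_fit: bool
    n_probes: int = field(default=0)


def _single_probe_mesh(r_h_nm: float, rf_nm: float, ratio: float) -> float:
    # closed-form inversion of the Ogston-Amsden ratio for r̄ (one probe)
    if not 0.0 < ratio < 1.0:
        raise FitError(f"observed ratio {ratio!r} outside (0, 1); cannot invert")
    scale = math.sqrt(-4.0 * math.log(ratio) / math.pi)
    mesh = (r_h_nm + rf_nm) / scale - rf_nm
    if mesh <= 0:
        raise FitError(
            f"observed ratio {ratio:.4g} implies a non-physical mesh radius for "
            f"R_h = {r_h_nm} nm, R_f = {rf_nm} nm")
    return mesh


def estimate_mesh_from_probes(
    probes: list[ProbeSpec],
    fiber_radius_nm: float,
    medium: MediumSpec = MediumSpec(),
    volume_fraction: float | None = None,
    poor_fit_rms: float = 0.05,
) -> MeshFit:
    """Least-squares estimate of the mesh radius from measured probe diffusivities.

    For each probe the observed ratio D_g/D_0 is formed (D_0 from the probe
    record, or Stokes–Einstein if absent) and the Ogston–Amsden ratio is
    fitted with r̄ as the single free parameter, minimising squared residuals
    in ratio space so every probe carries equal weight.

    Parameters
    ----------
    probes
        Probe panel; each must carry a measured ``d_gel_um2_s``.
    fiber_radius_nm
        Fiber radius, held fixed (not fitted).
    volume_fraction
        Optional known φ, stored on the returned network for reference; when
        absent, φ is back-computed from the fitted mesh via the mesh relation.
    """
    _finite_positive(fiber_radius_nm, "fiber_radius_nm")
    usable = [p for p in probes if p.d_gel_um2_s is not None]
    if not usable:
        raise ValidationError("need at least one probe with a measured d_gel_um2_s")

    r_h = np.array([p.r_h_nm for p in usable])
    d0 = np.array([p.d_free_um2_s if p.d_free_um2_s is not None
                   else stokes_einstein_d0(p.r_h_nm, medium) for p in usable])
    observed = np.array([p.d_gel_um2_s for p in usable]) / d0
    if np.any(observed >= 1.0):
        warnings.warn("observed D_g/D_0 ≥ 1 for some probes; obstruction model "
                      "cannot reproduce ratios above 1", RuntimeWarning, stacklevel=2)

    # initial guess: median of per-probe closed-form inversions
    singles = []
    for rh_i, ratio_i in zip(r_h, observed):
        try:
            singles.append(_single_probe_mesh(float(rh_i), fiber_radius_nm, float(ratio_i)))
        except FitError:
            continue
    if not singles:
        raise FitError("no probe yields a physical mesh radius; cannot initialise fit")
    mesh0 = float(np.median(singles))

    def resid(log_mesh: np.ndarray) -> np.ndarray:
        mesh = np.exp(log_mesh[0])
        pred = np.exp(-(math.pi / 4.0)
                      * ((r_h + fiber_radius_nm) / (mesh + fiber_radius_nm)) ** 2)
        return pred - observed

    sol = optimize.least_squares(resid, x0=[math.log(mesh0)], method="lm", xtol=1e-14)
    mesh_hat = float(np.exp(sol.x[0]))
    predicted = np.exp(-(math.pi / 4.0)
                       * ((r_h + fiber_radius_nm) / (mesh_hat + fiber_radius_nm)) ** 2)
    residuals = predicted - observed
    rms = float(np.sqrt(np.mean(residuals**2)))

    phi = (volume_fraction if volume_fraction is not None
           else math.pi * (fiber_radius_nm / mesh_hat) ** 2)
    network = GelNetwork(fiber_radius_nm=fiber_radius_nm,
                         volume_fraction=min(max(phi, 1e-12), 1 - 1e-12),
                         mesh_radius_nm=mesh_hat)
    return MeshFit(
        network=network,
        probe_names=tuple(p.name for p in usable),
        observed_ratios=observed,
        predicted_ratios=predicted,
        residuals=residuals,
        rms_residual=rms,
        poor_fit=rms > poor_fit_rms,
        n_probes=len(usable),
    )
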