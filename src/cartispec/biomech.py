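"""Indentation biomechanics: moduli and phase angle from stress-relaxation
and dynamic sinusoidal tests of cartilage, with the finite-thickness
(Hayes) correction.

The test protocol analysed here is: an equilibrium pre-stress of
12.5 kPa to establish contact, four stress-relaxation steps of 5 % of
the remaining thickness each followed by a 15-minute hold, and a
four-cycle 1-Hz sinusoid of 2 % amplitude.  From one such record this
module extracts

* the equilibrium modulus ``E_eq`` -- slope of the least-squares line
  through the per-step equilibrium (plateau) stress-strain points,
* the instantaneous modulus ``E_inst`` -- from the peak force of the
  step whose cumulative strain is closest to 10 %,
* the dynamic modulus ``E_dyn`` and phase angle -- from sinusoidal fits
  of stress and strain at the loading frequency.

Each modulus is converted from the apparent (indentation) stiffness to a
Young's modulus through the flat-punch relation for an elastic layer of
finite thickness bonded to a rigid substrate,

    F = 2 a E w kappa(a/h, nu) / (1 - nu^2),

where ``a`` is the indenter radius, ``h`` the cartilage thickness, ``w``
the indentation depth and ``kappa >= 1`` the Hayes scale factor,
interpolated from a bundled table (see :mod:`cartispec._hayes`).
Poisson's ratio is 0.3 for the equilibrium/instantaneous moduli and 0.5
(incompressible, short-time response) for the dynamic modulus.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator

from .records import MechanicalTest, ModuliResult

NU_EQUILIBRIUM = 0.3
NU_DYNAMIC = 0.5


# ---------------------------------------------------------------------------
# Hayes correction factor
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _load_kappa_table() -> dict[float, PchipInterpolator]:
    """Monotone interpolants kappa(a/h) per tabulated Poisson's ratio."""
    ref = importlib.resources.files("cartispec").joinpath("data/hayes_kappa.csv")
    by_nu: dict[float, list[tuple[float, float]]] = {}
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            by_nu.setdefault(float(row["nu"]), []).append(
                (float(row["a_over_h"]), float(row["kappa"]))
            )
    out = {}
    for nu, pts in by_nu.items():
        pts.sort()
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        out[nu] = PchipInterpolator(x, y)
    return out


def hayes_kappa(a_over_h: float, nu: float) -> float:
    """Finite-thickness scale factor kappa(a/h, nu) for a flat punch.

    Interpolated from the bundled table: shape-preserving (PCHIP) in the
    aspect ratio, linear in Poisson's ratio between tabulated values.
    ``kappa(0, nu) = 1`` is the half-space limit.

    Raises ``ValueError`` outside the tabulated domain a/h in [0, 2],
    nu in [0, 0.5].
    """
    if not 0.0 <= a_over_h <= 2.0:
        raise ValueError(f"a/h = {a_over_h} outside tabulated range [0, 2]")
    if not 0.0 <= nu <= 0.5:
        raise ValueError(f"Poisson's ratio {nu} outside [0, 0.5]")
    table = _load_kappa_table()
    nus = np.array(sorted(table))
    if nu in table:
        return float(table[nu](a_over_h))
    hi = int(np.searchsorted(nus, nu))
    lo = hi - 1
    t = (nu - nus[lo]) / (nus[hi] - nus[lo])
    return float((1 - t) * table[nus[lo]](a_over_h) + t * table[nus[hi]](a_over_h))


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def mean_thickness(points_mm) -> float:
    """Average of three circumferential thickness readings (mm)."""
    pts = np.asarray(points_mm, dtype=float)
    if pts.shape != (3,):
        raise ValueError("expected exactly 3 thickness readings")
    if np.any(pts <= 0):
        raise ValueError("thickness readings must be positive")
    return float(pts.mean())


def _geometry(test: MechanicalTest) -> tuple[float, float]:
    """(indenter radius, thickness) in metres."""
    a_m = 0.5 * test.indenter_diameter_mm * 1e-3
    h_m = test.thickness_mm * 1e-3
    return a_m, h_m


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def prestress_offset(test: MechanicalTest, *, tail_s: float = 10.0) -> tuple[float, float]:
    """Zero-strain reference from the pre-stress equilibrium hold.

    Returns ``(u0_mm, F0_N)``: the displacement origin and the contact
    (pre-stress) force, each averaged over the last ``tail_s`` seconds of
    the pre-stress segment.  If no pre-stress segment is marked, falls
    back to the first sample with a warning.
    """
    u = test.displacement_mm
    f = test.force_N
    t = test.time_s
    if test.markers.prestress is None:
        warnings.warn("no pre-stress segment marked; using first sample as origin",
                      stacklevel=2)
        return float(u[0]), float(f[0])
    i0, i1 = test.markers.prestress
    seg_t = t[i0:i1]
    mask = seg_t >= seg_t[-1] - tail_s
    return float(u[i0:i1][mask].mean()), float(f[i0:i1][mask].mean())


def _step_plateaus(test: MechanicalTest, plateau_s: float,
                   warn_sink: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (displacement, equilibrium force) from the hold tails."""
    if len(test.markers.steps) < 2:
        raise ValueError("need at least 2 relaxation steps for the equilibrium fit")
    u = test.displacement_mm
    f = test.force_N
    t = test.time_s
    u_eq, f_eq = [], []
    for i0, i1 in test.markers.steps:
        seg_t, seg_f, seg_u = t[i0:i1], f[i0:i1], u[i0:i1]
        mask = seg_t >= seg_t[-1] - plateau_s
        tail_t, tail_f = seg_t[mask], seg_f[mask]
        if tail_t.size >= 3:
            slope = np.polyfit(tail_t, tail_f, 1)[0]
            scale = max(abs(tail_f.mean()), 1e-12)
            # relative force drift over the plateau window
            if abs(slope) * (tail_t[-1] - tail_t[0]) / scale > 0.01:
                msg = "equilibrium plateau not reached within hold"
                if warn_sink is not None:
                    warn_sink.append(msg)
                else:
                    warnings.warn(msg, stacklevel=3)
        u_eq.append(seg_u[mask].mean())
        f_eq.append(tail_f.mean())
    return np.array(u_eq), np.array(f_eq)


def _step_peaks(test: MechanicalTest) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (displacement at peak, peak force)."""
    u = test.displacement_mm
    f = test.force_N
    u_pk, f_pk = [], []
    for i0, i1 in test.markers.steps:
        j = i0 + int(np.argmax(f[i0:i1]))
        u_pk.append(u[j])
        f_pk.append(f[j])
    return np.array(u_pk), np.array(f_pk)


# ---------------------------------------------------------------------------
# Moduli
# ---------------------------------------------------------------------------

def equilibrium_modulus(test: MechanicalTest, *, nu: float = NU_EQUILIBRIUM,
                        plateau_s: float = 60.0,
                        warn_sink: list[str] | None = None) -> float:
    """Equilibrium Young's modulus (MPa).

    Stress is nominal (plateau force over the punch face pi a^2) and
    strain is the displacement from the pre-stress origin over the
    thickness.  The least-squares line through the per-step points is
    fitted with an intercept, which absorbs the pre-stress bias; the
    slope is converted by ``E = m pi a (1 - nu^2) / (2 h kappa)``.
    """
    a_m, h_m = _geometry(test)
    kappa = hayes_kappa(a_m / h_m, nu)
    u0_mm, _ = prestress_offset(test)
    u_eq, f_eq = _step_plateaus(test, plateau_s, warn_sink)
    strain = (u_eq - u0_mm) * 1e-3 / h_m
    stress = f_eq / (np.pi * a_m**2)
    m = np.polyfit(strain, stress, 1)[0]
    return m * np.pi * a_m * (1.0 - nu**2) / (2.0 * h_m * kappa) / 1e6


def instantaneous_modulus(test: MechanicalTest, *, nu: float = NU_EQUILIBRIUM,
                          target_strain: float = 0.10,
                          strain_tol: float = 0.03) -> float:
    """Instantaneous Young's modulus (MPa) at ~10 % cumulative strain.

    Uses the step whose cumulative strain at peak is nearest the target
    (step 2 under the 4 x 5 %-of-remaining protocol, cumulative strain
    1 - 0.95^2 = 9.75 %) and inverts the flat-punch relation with the
    pre-stress force subtracted, so a purely elastic record returns the
    equilibrium modulus.
    """
    a_m, h_m = _geometry(test)
    kappa = hayes_kappa(a_m / h_m, nu)
    u0_mm, f0_N = prestress_offset(test)
    u_pk, f_pk = _step_peaks(test)
    strain = (u_pk - u0_mm) * 1e-3 / h_m
    j = int(np.argmin(np.abs(strain - target_strain)))
    if abs(strain[j] - target_strain) > strain_tol:
        raise ValueError(
            f"no step within {target_strain:.0%} +/- {strain_tol:.0%} cumulative strain "
            f"(closest {strain[j]:.2%})"
        )
    w_m = (u_pk[j] - u0_mm) * 1e-3
    return (f_pk[j] - f0_N) * (1.0 - nu**2) / (2.0 * a_m * w_m * kappa) / 1e6


def dynamic_modulus_phase(test: MechanicalTest, *, nu: float = NU_DYNAMIC,
                          freq_hz: float = 1.0, discard_cycles: int = 1,
                          resid_tol: float = 0.2) -> tuple[float, float]:
    """Dynamic modulus (MPa) and phase angle (degrees) at ``freq_hz``.

    Least-squares sinusoid fits ``x(t) = x0 + A sin(2 pi f t) +
    B cos(2 pi f t)`` of force and displacement over the dynamic segment
    (first ``discard_cycles`` cycles dropped as start-up transient).
    The modulus is the Hayes-converted stress/strain amplitude ratio and
    the phase is the lag of stress behind strain wrapped to [0, 90).
    Raises if either relative fit residual (RMS over amplitude) exceeds
    ``resid_tol`` or an amplitude is non-positive.
    """
    if test.markers.dynamic is None:
        raise ValueError("no dynamic segment marked")
    a_m, h_m = _geometry(test)
    kappa = hayes_kappa(a_m / h_m, nu)
    i0, i1 = test.markers.dynamic
    t = test.time_s[i0:i1]
    t = t - t[0]
    keep = t >= discard_cycles / freq_hz
    if (t[keep][-1] - t[keep][0]) * freq_hz < 2.0 - 1e-9:
        raise ValueError("need at least 2 full cycles after discarding the transient")
    w = 2.0 * np.pi * freq_hz
    design = np.column_stack([np.sin(w * t[keep]), np.cos(w * t[keep]),
                              np.ones(keep.sum())])

    def fit(sig):
        coef, *_ = np.linalg.lstsq(design, sig, rcond=None)
        amp = float(np.hypot(coef[0], coef[1]))
        phase = float(np.arctan2(coef[1], coef[0]))  # x = amp*sin(wt + phase)
        resid = sig - design @ coef
        if amp <= 0:
            raise ValueError("zero amplitude in dynamic segment")
        if np.sqrt(np.mean(resid**2)) / amp > resid_tol:
            raise ValueError("dynamic sinusoid fit residual above tolerance")
        return amp, phase

    f_amp, f_phase = fit(test.force_N[i0:i1][keep])
    u_amp, u_phase = fit(test.displacement_mm[i0:i1][keep] * 1e-3)

    e_dyn = f_amp * (1.0 - nu**2) / (2.0 * a_m * u_amp * kappa) / 1e6
    d = f_phase - u_phase
    d = np.arctan2(np.sin(d), np.cos(d))   # wrap to (-pi, pi]
    phase_deg = abs(np.degrees(d))
    if phase_deg >= 90.0:
        phase_deg = 180.0 - phase_deg
    return float(e_dyn), float(phase_deg)


def analyze_test(test: MechanicalTest, *, plateau_s: float = 60.0,
                 freq_hz: float = 1.0) -> ModuliResult:
    """Full inverse analysis of one indentation record."""
    warn_sink: list[str] = []
    e_eq = equilibrium_modulus(test, plateau_s=plateau_s, warn_sink=warn_sink)
    e_inst = instantaneous_modulus(test)
    e_dyn, phase = dynamic_modulus_phase(test, freq_hz=freq_hz)
    return ModuliResult(
        sample_id=test.sample_id,
        E_eq_MPa=e_eq,
        E_inst_MPa=e_inst,
        E_dyn_MPa=e_dyn,
        phase_deg=phase,
        thickness_mm=test.thickness_mm,
        warnings=warn_sink,
    )
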