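"""Synthetic cartilage cohorts: Vis-NIR spectra, indentation tests, labels.

The generator emulates the structure of a cadaver study of knee-joint
articular cartilage: a donor -> site -> sample -> replicate hierarchy
with six anatomical sites, OARSI grades 0-5 drawn per sample, three
replicate single-point spectra per sample and one indentation test per
sample.

Spectra are produced on the two instrument detector grids (Vis detector
350-1100 nm at 0.6 nm, NIR detector 1000-2500 nm at 6.5 nm) and merged
at a 1050 nm cutover.  The generative form is deliberately simple
chemometric plumbing rather than radiative transfer: Gaussian absorption
bands on a low-order polynomial baseline, with

* a grade-dependent additive baseline offset in the visible region
  (400-700 nm), emulating scattering changes as collagen loses
  organisation,
* grade-dependent band depths in the collagen-associated (1000-1400 nm)
  and proteoglycan-associated (1600-1800 nm) regions,
* an additive per-donor random offset over the whole spectrum,
* i.i.d. measurement noise, and high-variance saturation noise in the
  water band (1400-1520 nm) that the preprocessing excises.

Mechanical tests are generated by a quasi-linear viscoelastic forward
model around the protocol: 12.5 kPa pre-stress, four 5 %-of-remaining
stress-relaxation steps with 15-min holds (single-exponential reduced
relaxation per step), then four 1-Hz sinusoid cycles at 2 % amplitude.
The forward parameters are chosen so that the inverse analysis in
:mod:`cartispec.biomech` recovers the ground-truth moduli exactly in the
noiseless case; ground-truth group means default to reported values for
normal / early OA / advanced OA human knee cartilage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomech import hayes_kappa
from .records import (SITES, MechanicalTest, SegmentMarkers, SpectrumRecord,
                      pool_grade)

VIS_RANGE = (350.0, 1100.0)
VIS_STEP = 0.6
NIR_RANGE = (1000.0, 2500.0)
NIR_STEP = 6.5
DEFAULT_CUTOVER_NM = 1050.0


def detector_grids() -> tuple[np.ndarray, np.ndarray]:
    """(vis, nir) wavelength grids of the two-detector instrument."""
    vis = np.arange(VIS_RANGE[0], VIS_RANGE[1] + 1e-9, VIS_STEP)
    nir = np.arange(NIR_RANGE[0], NIR_RANGE[1] + 1e-9, NIR_STEP)
    return vis, nir


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Shape and effect sizes of a synthetic cohort.

    Defaults mirror a 17-donor, 6-site study with 3 samples per site per
    donor and 3 replicate spectra per sample (918 spectra, 306 samples)
    and a grade mix of roughly 38 % normal (OARSI 0-1), 38 % early OA
    (2-3) and 24 % advanced OA (4-5).
    """

    n_donors: int = 17
    sites: tuple[str, ...] = SITES
    samples_per_site_per_donor: int = 3
    replicates_per_sample: int = 3
    grade_distribution: tuple[float, ...] = (0.19, 0.19, 0.19, 0.19, 0.12, 0.12)
    donor_effect_sd: float = 0.02
    class_effect_size: float = 1.0
    noise_sd: float = 0.008
    attenuated_fraction: float = 0.03
    attenuation: float = 0.15
    force_noise_sd_N: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1 or self.samples_per_site_per_donor < 1 \
                or self.replicates_per_sample < 1:
            raise ValueError("all counts must be >= 1")
        if not self.sites:
            raise ValueError("site list must not be empty")
        for s in self.sites:
            if s not in SITES:
                raise ValueError(f"unknown site {s!r}")
        p = np.asarray(self.grade_distribution, dtype=float)
        if p.shape != (6,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("grade_distribution must be 6 non-negative "
                             "probabilities summing to 1")
        if not 0.0 <= self.attenuated_fraction <= 1.0:
            raise ValueError("attenuated_fraction must be in [0, 1]")


@dataclass
class SpectralFeatureModel:
    """Parameters of the generative spectral model (nm / intensity units).

    Per-grade band amplitudes are linear in the grade, so they are
    monotone within each region by construction.
    """

    baseline_coeffs: tuple[float, ...] = (0.45, 0.08, -0.02)
    baseline_offset_region: tuple[float, float] = (400.0, 700.0)
    collagen_region: tuple[float, float] = (1000.0, 1400.0)
    pg_region: tuple[float, float] = (1600.0, 1800.0)
    saturation_region: tuple[float, float] = (1400.0, 1520.0)
    offset_amp_per_grade: float = 0.010
    collagen_centers: tuple[float, ...] = (1156.0, 1210.0, 1350.0)
    collagen_widths: tuple[float, ...] = (25.0, 40.0, 45.0)
    collagen_base_amp: float = 0.080
    collagen_amp_per_grade: float = -0.009
    pg_centers: tuple[float, ...] = (1650.0, 1720.0, 1780.0)
    pg_widths: tuple[float, ...] = (22.0, 30.0, 28.0)
    pg_base_amp: float = 0.060
    pg_amp_per_grade: float = -0.008
    saturation_noise_factor: float = 8.0
    edge_nm: float = 30.0

    def region_amplitude(self, base: float, slope: float, grade: int,
                         signal_scale: float) -> float:
        return max(base + signal_scale * slope * grade, 0.0)


@dataclass
class GroundTruthMechanics:
    """Ground-truth mechanics per pooled OARSI group.

    Group means parameterise normal / early OA / advanced OA knee
    cartilage; donor and within-donor variability act multiplicatively
    (log-normal) on the moduli and additively on phase and thickness.
    """

    E_eq_MPa: dict = field(default_factory=lambda: {
        "normal": 1.29, "early_oa": 0.74, "advanced_oa": 0.164})
    E_inst_MPa: dict = field(default_factory=lambda: {
        "normal": 19.12, "early_oa": 11.57, "advanced_oa": 1.67})
    E_dyn_MPa: dict = field(default_factory=lambda: {
        "normal": 9.42, "early_oa": 5.46, "advanced_oa": 1.517})
    phase_deg: dict = field(default_factory=lambda: {
        "normal": 5.37, "early_oa": 6.12, "advanced_oa": 2.88})
    thickness_mm: dict = field(default_factory=lambda: {
        "normal": 2.37, "early_oa": 2.57, "advanced_oa": 2.27})
    donor_sd_log: float = 0.15
    within_sd_log: float = 0.10
    phase_donor_sd: float = 0.5
    phase_within_sd: float = 0.4
    thickness_donor_sd: float = 0.15
    thickness_within_sd: float = 0.10

    def validate(self) -> None:
        for name in ("E_eq_MPa", "E_inst_MPa", "E_dyn_MPa"):
            vals = getattr(self, name)
            if any(v <= 0 for v in vals.values()):
                raise ValueError(f"{name} means must be positive")
            if not vals["normal"] > vals["early_oa"] > vals["advanced_oa"]:
                raise ValueError(f"{name} means must decrease with severity")


@dataclass
class ProtocolConfig:
    """Indentation protocol parameters."""

    prestress_kpa: float = 12.5
    prestress_hold_s: float = 60.0
    n_steps: int = 4
    step_fraction: float = 0.05      # of remaining thickness per step
    ramp_s: float = 0.5
    relax_s: float = 900.0           # 15-minute hold
    relax_rate_hz: float = 10.0
    tau_s: float = 30.0              # reduced-relaxation time constant
    dyn_cycles: int = 4
    dyn_amp_fraction: float = 0.02   # of remaining thickness
    dyn_freq_hz: float = 1.0
    dyn_rate_hz: float = 100.0


# ---------------------------------------------------------------------------
# Spectrum generation
# ---------------------------------------------------------------------------

def _smooth_window(grid: np.ndarray, lo: float, hi: float, edge: float) -> np.ndarray:
    """Raised-cosine window, 1 inside [lo, hi], 0 outside, soft edges."""
    w = np.zeros_like(grid)
    inside = (grid >= lo) & (grid <= hi)
    w[inside] = 1.0
    left = (grid >= lo - edge) & (grid < lo)
    w[left] = 0.5 * (1 + np.cos(np.pi * (lo - grid[left]) / edge))
    right = (grid > hi) & (grid <= hi + edge)
    w[right] = 0.5 * (1 + np.cos(np.pi * (grid[right] - hi) / edge))
    return w


def clean_spectrum(grid: np.ndarray, grade: int,
                   features: SpectralFeatureModel | None = None,
                   *, signal_scale: float = 1.0) -> np.ndarray:
    """Noise-free spectrum for one grade (no donor effect, no noise)."""
    f = features or SpectralFeatureModel()
    x = grid / 1000.0
    y = np.polynomial.polynomial.polyval(x, f.baseline_coeffs)
    y = y + signal_scale * f.offset_amp_per_grade * grade * _smooth_window(
        grid, *f.baseline_offset_region, f.edge_nm)
    for centers, widths, base, slope in (
            (f.collagen_centers, f.collagen_widths, f.collagen_base_amp,
             f.collagen_amp_per_grade),
            (f.pg_centers, f.pg_widths, f.pg_base_amp, f.pg_amp_per_grade)):
        amp = f.region_amplitude(base, slope, grade, signal_scale)
        for c, w in zip(centers, widths):
            y = y - amp * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return y


def generate_spectrum(grid: np.ndarray, grade: int,
                      features: SpectralFeatureModel | None = None,
                      *, donor_offset: float = 0.0, signal_scale: float = 1.0,
                      noise_sd: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """One noisy spectrum on ``grid`` (either detector grid or merged)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    f = features or SpectralFeatureModel()
    y = clean_spectrum(grid, grade, f, signal_scale=signal_scale) + donor_offset
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=grid.size)
        sat = (grid >= f.saturation_region[0]) & (grid <= f.saturation_region[1])
        if sat.any():
            y[sat] += rng.normal(0.0, f.saturation_noise_factor * noise_sd,
                                 size=int(sat.sum()))
    if not np.all(np.isfinite(y)):
        raise ValueError("generated spectrum contains non-finite values")
    return y


# ---------------------------------------------------------------------------
# Mechanical test generation
# ---------------------------------------------------------------------------

def generate_mechanical_test(moduli, thickness_mm: float, *,
                             indenter_diameter_mm: float = 1.0,
                             protocol: ProtocolConfig | None = None,
                             force_noise_sd: float = 0.0,
                             rng: np.random.Generator | None = None,
                             sample_id: str = "") -> MechanicalTest:
    """Forward-simulate one indentation record.

    ``moduli`` maps ``E_eq_MPa``, ``E_inst_MPa``, ``E_dyn_MPa`` and
    ``phase_deg`` to the ground truth the inverse analysis should
    recover.  The displacement trace follows the commanded protocol; the
    force trace combines a linear equilibrium response, per-step peak
    forces on the instantaneous stiffness line with single-exponential
    relaxation towards equilibrium, and a steady-state sinusoid in the
    dynamic segment.  With ``tau_s == 0`` relaxation is instantaneous
    and step peaks coincide with the equilibrium plateaus.
    """
    if thickness_mm <= 0 or indenter_diameter_mm <= 0:
        raise ValueError("thickness and indenter diameter must be positive")
    p = protocol or ProtocolConfig()
    a = 0.5 * indenter_diameter_mm * 1e-3
    h = thickness_mm * 1e-3
    k03 = hayes_kappa(a / h, 0.3)
    k05 = hayes_kappa(a / h, 0.5)
    e_eq = moduli["E_eq_MPa"] * 1e6
    e_inst = moduli["E_inst_MPa"] * 1e6
    e_dyn = moduli["E_dyn_MPa"] * 1e6
    phase_rad = np.radians(moduli["phase_deg"])

    s_eq = 2.0 * a * e_eq * k03 / (1.0 - 0.3**2)     # N per m of indentation
    s_inst = 2.0 * a * e_inst * k03 / (1.0 - 0.3**2)
    f_pre = p.prestress_kpa * 1e3 * np.pi * a**2
    u_pre = f_pre / s_eq                              # origin (m), from contact

    dt = 1.0 / p.relax_rate_hz
    t_parts, u_parts, f_parts = [], [], []
    cursor_t = 0.0
    n_total = 0

    def extend(tt, uu, ff):
        nonlocal cursor_t, n_total
        t_parts.append(tt)
        u_parts.append(uu)
        f_parts.append(ff)
        cursor_t = tt[-1]
        n_total += tt.size

    # pre-stress equilibrium hold
    n0 = int(round(p.prestress_hold_s * p.relax_rate_hz)) + 1
    tt = np.arange(n0) * dt
    extend(tt, np.full(n0, u_pre), np.full(n0, f_pre))
    prestress_span = (0, n_total)

    # stress-relaxation steps
    step_spans = []
    u_prev, f_prev = 0.0, f_pre                       # u relative to origin
    for k in range(1, p.n_steps + 1):
        start = n_total
        u_k = (1.0 - (1.0 - p.step_fraction) ** k) * h
        f_eq_k = f_pre + s_eq * u_k
        f_pk_k = f_eq_k if p.tau_s == 0 else f_pre + s_inst * u_k
        nr = max(1, int(round(p.ramp_s * p.relax_rate_hz)))
        off = np.arange(1, nr + 1) * dt
        extend(cursor_t + off,
               u_pre + u_prev + (u_k - u_prev) * off / off[-1],
               f_prev + (f_pk_k - f_prev) * off / off[-1])
        nh = int(round(p.relax_s * p.relax_rate_hz))
        off = np.arange(1, nh + 1) * dt
        if p.tau_s > 0:
            fh = f_eq_k + (f_pk_k - f_eq_k) * np.exp(-off / p.tau_s)
        else:
            fh = np.full(nh, f_eq_k)
        extend(cursor_t + off, np.full(nh, u_pre + u_k), fh)
        step_spans.append((start, n_total))
        u_prev, f_prev = u_k, fh[-1]

    # dynamic sinusoid
    start = n_total
    u4 = u_prev
    f_eq4 = f_pre + s_eq * u4
    u_a = p.dyn_amp_fraction * (1.0 - p.step_fraction) ** p.n_steps * h
    f_a = 2.0 * a * e_dyn * k05 * u_a / (1.0 - 0.5**2)
    dtd = 1.0 / p.dyn_rate_hz
    nd = int(round(p.dyn_cycles / p.dyn_freq_hz * p.dyn_rate_hz))
    off = np.arange(1, nd + 1) * dtd
    w = 2.0 * np.pi * p.dyn_freq_hz
    extend(cursor_t + off,
           u_pre + u4 + u_a * np.sin(w * off),
           f_eq4 + f_a * np.sin(w * off + phase_rad))
    dynamic_span = (start, n_total)

    force = np.concatenate(f_parts)
    if force_noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        force = force + rng.normal(0.0, force_noise_sd, size=force.size)

    return MechanicalTest(
        time_s=np.concatenate(t_parts),
        force=force,
        displacement=np.concatenate(u_parts) * 1e3,
        thickness_mm=thickness_mm,
        indenter_diameter_mm=indenter_diameter_mm,
        markers=SegmentMarkers(prestress=prestress_span, steps=step_spans,
                               dynamic=dynamic_span),
        sample_id=sample_id,
        truth={"u_origin_mm": u_pre * 1e3, "F_pre_N": f_pre,
               **{k: float(v) for k, v in moduli.items()}},
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: merged spectra, manifest and mechanics truth."""

    records: list[SpectrumRecord]
    manifest: pd.DataFrame
    mech_truth: pd.DataFrame
    config: CohortConfig
    features: SpectralFeatureModel
    mech: GroundTruthMechanics
    protocol: ProtocolConfig

    def spectra_matrix(self, site: str | None = None
                       ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """(X, wavelengths, meta): one row per measurement."""
        recs = [r for r in self.records if site is None or r.site == site]
        if not recs:
            raise ValueError(f"no spectra for site {site!r}")
        wl = recs[0].wavelengths
        X = np.vstack([r.intensities for r in recs])
        meta = pd.DataFrame({
            "donor_id": [r.donor_id for r in recs],
            "site": [r.site for r in recs],
            "sample_id": [r.sample_id for r in recs],
            "replicate": [r.replicate for r in recs],
            "oarsi_grade": [r.oarsi_grade for r in recs],
        })
        return X, wl, meta

    def mechanical_test(self, sample_id: str) -> MechanicalTest:
        """Realize the indentation record of one sample (deterministic)."""
        row = self.mech_truth.set_index("sample_id").loc[sample_id]
        rng = np.random.default_rng(int(row["mech_seed"]))
        return generate_mechanical_test(
            {k: float(row[k]) for k in
             ("E_eq_MPa", "E_inst_MPa", "E_dyn_MPa", "phase_deg")},
            float(row["thickness_mm"]),
            protocol=self.protocol,
            force_noise_sd=self.config.force_noise_sd_N,
            rng=rng,
            sample_id=sample_id,
        )


def generate_cohort(config: CohortConfig | None = None,
                    features: SpectralFeatureModel | None = None,
                    mech: GroundTruthMechanics | None = None,
                    protocol: ProtocolConfig | None = None,
                    *, cutover_nm: float = DEFAULT_CUTOVER_NM) -> Cohort:
    """Generate a full synthetic cohort.

    Deterministic given ``config.seed``; every sample has exactly
    ``replicates_per_sample`` spectra (merged two-detector grid) and one
    mechanical-test parameter set realisable via
    :meth:`Cohort.mechanical_test`.
    """
    from .preprocess import merge_detectors   # local import: avoids cycle

    config = config or CohortConfig()
    config.validate()
    features = features or SpectralFeatureModel()
    mech = mech or GroundTruthMechanics()
    mech.validate()
    protocol = protocol or ProtocolConfig()

    rng = np.random.default_rng(config.seed)
    vis_grid, nir_grid = detector_grids()

    donor_ids = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    donor_spec_offset = {d: rng.normal(0.0, config.donor_effect_sd)
                         for d in donor_ids}
    donor_mech_z = {d: rng.normal() for d in donor_ids}
    donor_thick_z = {d: rng.normal() for d in donor_ids}
    donor_phase_z = {d: rng.normal() for d in donor_ids}

    grades = np.arange(6)
    p_grade = np.asarray(config.grade_distribution, dtype=float)

    records: list[SpectrumRecord] = []
    man_rows, mech_rows = [], []
    for d in donor_ids:
        for site in config.sites:
            for i in range(config.samples_per_site_per_donor):
                sample_id = f"{d}-{site}-S{i + 1}"
                grade = int(rng.choice(grades, p=p_grade))
                group = pool_grade(grade)
                attenuated = rng.random() < config.attenuated_fraction
                scale = (config.attenuation if attenuated else 1.0) \
                    * config.class_effect_size

                z_w = rng.normal()
                mfac = np.exp(mech.donor_sd_log * donor_mech_z[d]
                              + mech.within_sd_log * z_w)
                thick = max(1.0, mech.thickness_mm[group]
                            + mech.thickness_donor_sd * donor_thick_z[d]
                            + mech.thickness_within_sd * rng.normal())
                phase = float(np.clip(
                    mech.phase_deg[group]
                    + mech.phase_donor_sd * donor_phase_z[d]
                    + mech.phase_within_sd * rng.normal(), 0.2, 80.0))
                mech_seed = int(rng.integers(0, 2**31 - 1))
                mech_rows.append({
                    "sample_id": sample_id,
                    "E_eq_MPa": mech.E_eq_MPa[group] * mfac,
                    "E_inst_MPa": mech.E_inst_MPa[group] * mfac,
                    "E_dyn_MPa": mech.E_dyn_MPa[group] * mfac,
                    "phase_deg": phase,
                    "thickness_mm": thick,
                    "mech_seed": mech_seed,
                })

                for rep in range(1, config.replicates_per_sample + 1):
                    kwargs = dict(donor_offset=donor_spec_offset[d],
                                  signal_scale=scale,
                                  noise_sd=config.noise_sd, rng=rng)
                    vis = SpectrumRecord(
                        vis_grid,
                        generate_spectrum(vis_grid, grade, features, **kwargs),
                        d, site, sample_id, rep, grade)
                    nir = SpectrumRecord(
                        nir_grid,
                        generate_spectrum(nir_grid, grade, features, **kwargs),
                        d, site, sample_id, rep, grade)
                    records.append(merge_detectors(vis, nir, cutover_nm=cutover_nm))

                man_rows.append({"sample_id": sample_id, "donor_id": d,
                                 "site": site, "oarsi_grade": grade,
                                 "group": group, "attenuated": attenuated})

    manifest = pd.DataFrame(man_rows)
    mech_truth = pd.DataFrame(mech_rows)
    return Cohort(records, manifest, mech_truth, config, features, mech, protocol)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_spectra_long(records: list[SpectrumRecord], path) -> None:
    frames = []
    for r in records:
        frames.append(pd.DataFrame({
            "donor_id": r.donor_id, "site": r.site, "sample_id": r.sample_id,
            "replicate": r.replicate, "oarsi_grade": r.oarsi_grade,
            "wavelength_nm": r.wavelengths, "intensity": r.intensities,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_spectra_wide(records: list[SpectrumRecord], path) -> None:
    wl = records[0].wavelengths
    meta = pd.DataFrame({
        "donor_id": [r.donor_id for r in records],
        "site": [r.site for r in records],
        "sample_id": [r.sample_id for r in records],
        "replicate": [r.replicate for r in records],
        "oarsi_grade": [r.oarsi_grade for r in records],
    })
    data = pd.DataFrame(np.vstack([r.intensities for r in records]),
                        columns=[f"{w:.4f}" for w in wl])
    pd.concat([meta, data], axis=1).to_csv(path, index=False)


def read_spectra_wide(path) -> list[SpectrumRecord]:
    df = pd.read_csv(path)
    meta_cols = ["donor_id", "site", "sample_id", "replicate", "oarsi_grade"]
    wl_cols = [c for c in df.columns if c not in meta_cols]
    wl = np.array([float(c) for c in wl_cols])
    out = []
    for _, row in df.iterrows():
        grade = row["oarsi_grade"]
        out.append(SpectrumRecord(
            wl, row[wl_cols].to_numpy(dtype=float), str(row["donor_id"]),
            str(row["site"]), str(row["sample_id"]), int(row["replicate"]),
            None if pd.isna(grade) else int(grade)))
    return out


def write_mechanics(test: MechanicalTest, csv_path, json_path) -> None:
    pd.DataFrame({"time_s": test.time_s,
                  "displacement_mm": test.displacement_mm,
                  "force_N": test.force_N}).to_csv(csv_path, index=False)
    meta = {
        "sample_id": test.sample_id,
        "thickness_mm": test.thickness_mm,
        "indenter_diameter_mm": test.indenter_diameter_mm,
        "markers": {"prestress": test.markers.prestress,
                    "steps": test.markers.steps,
                    "dynamic": test.markers.dynamic},
    }
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_mechanics(csv_path, json_path) -> MechanicalTest:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(json_path).read_text())
    mk = meta["markers"]
    markers = SegmentMarkers(
        prestress=tuple(mk["prestress"]) if mk["prestress"] else None,
        steps=[tuple(s) for s in mk["steps"]],
        dynamic=tuple(mk["dynamic"]) if mk["dynamic"] else None)
    return MechanicalTest(
        time_s=df["time_s"].to_numpy(),
        force=df["force_N"].to_numpy(),
        displacement=df["displacement_mm"].to_numpy(),
        thickness_mm=meta["thickness_mm"],
        indenter_diameter_mm=meta["indenter_diameter_mm"],
        markers=markers, sample_id=meta.get("sample_id", ""))
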