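"""Core data containers shared across the pipeline.

A :class:`SpectrumRecord` is one diffuse-reflectance measurement on a
wavelength grid together with its position in the donor -> site ->
sample -> replicate hierarchy and the histopathological (OARSI) grade of
the sample.  A :class:`MechanicalTest` is one indentation
stress-relaxation + dynamic test with sample geometry and the segment
markers needed by the inverse analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

#: Knee-joint measurement sites: lateral/medial femur, lateral/medial tibia,
#: trochlea and patella.
SITES = ("LF", "MF", "LT", "MT", "TR", "PT")

#: OARSI grade -> pooled severity group.
OARSI_POOLING = {0: "normal", 1: "normal", 2: "early_oa", 3: "early_oa",
                 4: "advanced_oa", 5: "advanced_oa"}

_FORCE_TO_N = {"N": 1.0, "mN": 1e-3, "kN": 1e3}
_LENGTH_TO_MM = {"mm": 1.0, "um": 1e-3, "m": 1e3}


def pool_grade(grade: int) -> str:
    """Map an OARSI grade (0-5) to its pooled group name."""
    try:
        return OARSI_POOLING[int(grade)]
    except (KeyError, ValueError):
        raise ValueError(f"OARSI grade must be an integer in 0..5, got {grade!r}")


@dataclass
class SpectrumRecord:
    """One Vis-NIR measurement: wavelength grid, intensities and metadata."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    donor_id: str
    site: str
    sample_id: str
    replicate: int
    oarsi_grade: int | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.oarsi_grade is not None and not 0 <= int(self.oarsi_grade) <= 5:
            raise ValueError("oarsi_grade must be in 0..5 or None")

    def with_data(self, wavelengths: np.ndarray | None = None,
                  intensities: np.ndarray | None = None) -> "SpectrumRecord":
        """Copy of this record with new spectral data, metadata untouched."""
        return replace(
            self,
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            intensities=self.intensities if intensities is None else intensities,
        )

    @property
    def group(self) -> str | None:
        return None if self.oarsi_grade is None else pool_grade(self.oarsi_grade)


@dataclass
class SegmentMarkers:
    """Index spans (start, stop) delimiting protocol segments of a test.

    ``steps`` spans cover ramp + relaxation hold of each compression step;
    spans are half-open on the stop index.
    """

    prestress: tuple[int, int] | None
    steps: list[tuple[int, int]]
    dynamic: tuple[int, int] | None


@dataclass
class MechanicalTest:
    """Indentation time series with geometry and protocol markers."""

    time_s: np.ndarray
    force: np.ndarray
    displacement: np.ndarray
    thickness_mm: float
    indenter_diameter_mm: float
    markers: SegmentMarkers
    sample_id: str = ""
    force_unit: str = "N"
    displacement_unit: str = "mm"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time_s.size
        if self.force.size != n or self.displacement.size != n:
            raise ValueError("time, force and displacement must have equal length")
        if n > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if self.indenter_diameter_mm <= 0:
            raise ValueError("indenter diameter must be positive")
        if self.force_unit not in _FORCE_TO_N:
            raise ValueError(f"unsupported force unit {self.force_unit!r}")
        if self.displacement_unit not in _LENGTH_TO_MM:
            raise ValueError(f"unsupported displacement unit {self.displacement_unit!r}")

    @property
    def force_N(self) -> np.ndarray:
        return self.force * _FORCE_TO_N[self.force_unit]

    @property
    def displacement_mm(self) -> np.ndarray:
        return self.displacement * _LENGTH_TO_MM[self.displacement_unit]


@dataclass
class ModuliResult:
    """Per-sample indentation outcome in MPa / degrees / mm."""

    sample_id: str
    E_eq_MPa: float
    E_inst_MPa: float
    E_dyn_MPa: float
    phase_deg: float
    thickness_mm: float
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["warnings"] = ";".join(self.warnings)
        return d
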