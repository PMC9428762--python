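"""Core in-memory containers shared across the pipeline.

Units are fixed package-wide and mirror how heel-pad mechanics are
reported in the clinical literature: thickness in mm, force in N,
contact area in cm^2, stress in kPa, strain dimensionless internally
(per cent only at the reporting boundary), strain rate in 1/s, elastic
modulus in kPa and viscous modulus in kPa*s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["StanceRecording", "StressStrainCurve", "HeelPadProperties"]


@dataclass
class StanceRecording:
    """One step's synchronized thickness / force / area streams.

    Attributes
    ----------
    time : array, s
        Uniformly spaced, strictly increasing sample times.
    thickness : array, mm
        Heel-pad thickness (calcaneus base to ground) per frame.
    force : array, N
        Heel-ground contact force per frame; non-negative.
    area : array, cm^2
        Heel contact area per frame.
    frame_rate : float, Hz
    meta : dict
        Free-form provenance (ground-truth parameters for simulated
        recordings, source paths for recordings read from disk).
    warnings : list of str
        Non-fatal issues flagged during generation or reading, e.g.
        model-driven negative stress clipped in the force channel.
    """

    time: np.ndarray
    thickness: np.ndarray
    force: np.ndarray
    area: np.ndarray
    frame_rate: float
    meta: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        n = len(self.time)
        if not (len(self.thickness) == len(self.force) == len(self.area) == n):
            raise ParameterError("all channels must share one frame count")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ParameterError("time must increase uniformly")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if np.any(self.thickness <= 0):
            raise ParameterError("thickness must be positive everywhere")
        if np.any(self.force < -1e-9):
            raise ParameterError("force must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class StressStrainCurve:
    """A stance cycle converted to the stress-strain plane.

    Arrays cover the in-contact window only, from the detected contact
    frame to the last frame above the force threshold.  ``peak_index``
    points at the maximum-strain ("most right") sample; loading is
    ``0..peak_index`` and unloading ``peak_index..end``, sharing the
    peak sample.
    """

    strain: np.ndarray        # dimensionless, compressive positive
    stress: np.ndarray        # kPa
    strain_rate: np.ndarray   # 1/s
    h0: float                 # mm, primary thickness
    contact_index: int        # frame index in the source recording
    peak_index: int           # index into the curve arrays
    frame_rate: float

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.strain_rate = np.asarray(self.strain_rate, dtype=float)
        if not (len(self.strain) == len(self.stress) == len(self.strain_rate)):
            raise ParameterError("curve arrays must share one length")
        if not 0 <= self.peak_index < len(self.strain):
            raise ParameterError("peak_index out of range")

    @property
    def loading(self) -> slice:
        return slice(0, self.peak_index + 1)

    @property
    def unloading(self) -> slice:
        return slice(self.peak_index, len(self.strain))


@dataclass
class HeelPadProperties:
    """The six material properties of one heel, plus fit diagnostics.

    Units follow the clinical reporting convention: mm, per cent, kPa,
    kPa, kPa*s, per cent.
    """

    h0: float            # primary thickness, mm
    peak_strain: float   # %
    peak_stress: float   # kPa
    E: float             # Young's modulus, kPa
    eta: float           # viscous modulus, kPa*s
    edr: float           # energy dissipation ratio, %
    residual_rms: float = float("nan")   # kPa
    nonphysical_eta: bool = False        # fitted eta < 0
    inverted_loop: bool = False          # unloading branch above loading
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "h0_mm": self.h0,
            "peak_strain_pct": self.peak_strain,
            "peak_stress_kPa": self.peak_stress,
            "E_kPa": self.E,
            "eta_kPa_s": self.eta,
            "edr_pct": self.edr,
            "residual_rms_kPa": self.residual_rms,
        }
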