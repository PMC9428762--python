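"""From recorded channels to the stress-strain plane.

The conversion follows the standard in-vivo definitions: the primary
thickness h0 is the thickness at the frame where the heel first carries
measurable force; compressive strain is the thickness deficit relative
to h0; stress is contact force over contact area; and the cycle splits
into a loading branch up to the maximum-strain sample and an unloading
branch after it.
"""

from __future__ import annotations

import numpy as np

from .containers import StanceRecording, StressStrainCurve
from .errors import (
    NoContactError,
    ParameterError,
    SplitError,
)

__all__ = [
    "detect_contact",
    "end_of_contact",
    "primary_thickness",
    "compute_strain",
    "compute_stress",
    "compute_strain_rate",
    "split_cycle",
    "peak_point",
    "curve_from_recording",
    "curve_to_frame",
]

#: Default contact threshold as a fraction of the recording's peak force.
CONTACT_THRESHOLD_FRACTION = 0.01
#: Fraction of the threshold used when refining the crossing back to the
#: onset of sustained force.
REFINE_FLOOR_FRACTION = 0.1


def _resolve_threshold(force: np.ndarray, force_threshold: float | None) -> float:
    if force_threshold is None:
        peak = float(np.max(force))
        if peak <= 0:
            raise NoContactError("force channel carries no load")
        return CONTACT_THRESHOLD_FRACTION * peak
    if force_threshold <= 0:
        raise ParameterError("force_threshold must be positive")
    return float(force_threshold)


def detect_contact(
    rec: StanceRecording,
    force_threshold: float | None = None,
    refine: bool = True,
) -> int:
    """Frame of initial heel-plate contact.

    The detector finds the first frame whose force reaches the
    threshold (default: 1% of the recording's peak force, which keeps
    the crossing robust to force noise around heel strike) and then,
    with ``refine``, walks backwards while the force stays above a low
    floor (10% of the threshold), so that in clean recordings the
    reported frame is the onset of sustained force rather than the
    frame where it first clears the noise band.  The thickness at this
    frame is the strain reference, so landing close to true touch-down
    keeps the primary thickness unbiased.
    """
    thr = _resolve_threshold(rec.force, force_threshold)
    above = np.nonzero(rec.force >= thr)[0]
    if len(above) == 0:
        raise NoContactError(f"no frame reaches the contact threshold {thr:.3g} N")
    idx = int(above[0])
    if refine:
        floor = REFINE_FLOOR_FRACTION * thr
        f = rec.force
        while idx > 0 and (f[idx - 1] >= floor or 0.0 < f[idx - 1] < f[idx]):
            idx -= 1
    return idx


def end_of_contact(
    rec: StanceRecording,
    force_threshold: float | None = None,
    refine: bool = True,
) -> int:
    """Last in-contact frame, mirroring :func:`detect_contact`."""
    thr = _resolve_threshold(rec.force, force_threshold)
    above = np.nonzero(rec.force >= thr)[0]
    if len(above) == 0:
        raise NoContactError(f"no frame reaches the contact threshold {thr:.3g} N")
    idx = int(above[-1])
    if refine:
        floor = REFINE_FLOOR_FRACTION * thr
        f = rec.force
        n = len(f)
        while idx < n - 1 and (f[idx + 1] >= floor or 0.0 < f[idx + 1] < f[idx]):
            idx += 1
    return idx


def primary_thickness(rec: StanceRecording, contact_index: int) -> float:
    """Thickness at the initial-contact frame: the strain reference, mm."""
    if not 0 <= contact_index < rec.n_frames:
        raise ParameterError(f"contact_index {contact_index} out of range")
    return float(rec.thickness[contact_index])


def compute_strain(thickness: np.ndarray, h0: float) -> np.ndarray:
    """Compressive strain (h0 - thickness) / h0, dimensionless.

    Values are deliberately not clamped at zero: noise can push frames
    slightly negative and clamping would bias the least-squares fit.
    """
    if h0 <= 0:
        raise ParameterError(f"h0 must be positive, got {h0}")
    return (h0 - np.asarray(thickness, dtype=float)) / h0


def compute_stress(force: np.ndarray, area: np.ndarray) -> np.ndarray:
    """Contact stress force/area in kPa (10 * N/cm^2).

    Frames with zero area and zero force (pre-contact) report zero
    stress; a positive force on a zero area is inconsistent.
    """
    force = np.asarray(force, dtype=float)
    area = np.asarray(area, dtype=float)
    bad = (area <= 0) & (force > 0)
    if np.any(bad):
        raise ParameterError(
            f"{int(bad.sum())} frames have force > 0 with area <= 0"
        )
    stress = np.zeros_like(force)
    ok = area > 0
    stress[ok] = 10.0 * force[ok] / area[ok]
    return stress


def compute_strain_rate(strain: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference strain rate, 1/s.

    Central differences in the interior (second-order accurate),
    one-sided at the two endpoints.
    """
    strain = np.asarray(strain, dtype=float)
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if len(strain) < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    return np.gradient(strain, dt)


def split_cycle(curve: StressStrainCurve) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the loading and unloading branches (peak shared)."""
    n = len(curve.strain)
    peak = curve.peak_index
    if peak == n - 1:
        raise SplitError("strain is monotone: no unloading branch to split off")
    return np.arange(0, peak + 1), np.arange(peak, n)


def peak_point(curve: StressStrainCurve) -> tuple[float, float]:
    """(peak strain in %, stress at that frame in kPa).

    Both values are read at the maximum-strain ("most right") sample,
    even if the stress maximum happens on a different frame.
    """
    return (
        100.0 * float(curve.strain[curve.peak_index]),
        float(curve.stress[curve.peak_index]),
    )


def curve_from_recording(
    rec: StanceRecording, force_threshold: float | None = None
) -> StressStrainCurve:
    """Full conversion of one recording to a stress-strain cycle.

    The in-contact window runs from the detected contact frame to the
    last frame above the threshold; later swing-phase frames are
    dropped.  Strain ties at the maximum break to the first occurrence.
    """
    contact = detect_contact(rec, force_threshold)
    end = end_of_contact(rec, force_threshold)
    if end - contact < 2:
        raise SplitError("fewer than 3 in-contact frames")
    h0 = primary_thickness(rec, contact)
    sl = slice(contact, end + 1)
    strain = compute_strain(rec.thickness[sl], h0)
    stress = compute_stress(rec.force[sl], rec.area[sl])
    rate = compute_strain_rate(strain, rec.dt)
    peak = int(np.argmax(strain))
    if peak == len(strain) - 1:
        raise SplitError("strain is monotone over the contact window")
    return StressStrainCurve(
        strain=strain,
        stress=stress,
        strain_rate=rate,
        h0=h0,
        contact_index=contact,
        peak_index=peak,
        frame_rate=rec.frame_rate,
    )


def curve_to_frame(curve: StressStrainCurve):
    """Tabular view of a curve (frame, time, strain, stress, rate, phase)."""
    import pandas as pd

    n = len(curve.strain)
    phase = np.where(np.arange(n) <= curve.peak_index, "loading", "unloading")
    phase[curve.peak_index] = "peak"
    return pd.DataFrame(
        {
            "frame": np.arange(n) + curve.contact_index,
            "time_s": (np.arange(n) + curve.contact_index) / curve.frame_rate,
            "strain": curve.strain,
            "stress_kPa": curve.stress,
            "strain_rate_per_s": curve.strain_rate,
            "phase": phase,
        }
    )
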