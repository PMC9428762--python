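"""Kelvin-Voigt fitting and hysteresis energetics.

The constitutive model is linear in its two parameters,

    sigma = E * eps + eta * (eps * deps/dt),

so (E, eta) come from an ordinary least-squares regression of stress on
the two regressors eps and eps*deps/dt, with no intercept (zero strain
carries zero stress by construction).  By default the fit uses the full
loading + unloading cycle: the viscous modulus is identified mainly by
the asymmetry between the two branches, which a loading-only fit would
largely discard.

Energy dissipation is the area enclosed by the hysteresis loop; the
energy dissipation ratio (EDR) normalises it by the area under the
loading branch, i.e. by the energy fed into the pad during compression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HeelPadProperties, StanceRecording, StressStrainCurve
from .errors import (
    DegenerateCurveError,
    HeelpadError,
    StageError,
    UnidentifiableModelError,
)
from .extract import curve_from_recording, peak_point

__all__ = ["fit_kelvin_voigt", "loop_areas", "LoopAreas", "extract_properties",
           "properties_table"]

# Relative condition-number cutoff below which the two regressor columns
# are treated as collinear (e.g. a static compression has eps_dot == 0).
_RANK_RCOND = 1e-10


def fit_kelvin_voigt(
    curve: StressStrainCurve, loading_only: bool = False
) -> tuple[float, float, dict]:
    """Least-squares estimates of (E [kPa], eta [kPa*s]) plus diagnostics.

    A negative eta estimate is permitted (the least-squares solution is
    reported as-is) but flagged as non-physical in the diagnostics.
    """
    sl = curve.loading if loading_only else slice(None)
    eps = curve.strain[sl]
    sigma = curve.stress[sl]
    visc = eps * curve.strain_rate[sl]
    if len(eps) < 3:
        raise UnidentifiableModelError("need at least 3 samples to fit two moduli")
    X = np.column_stack([eps, visc])
    s = np.linalg.svd(X, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < _RANK_RCOND:
        raise UnidentifiableModelError(
            "regressors eps and eps*deps are collinear (is the strain rate zero?)"
        )
    coef, _, _, _ = np.linalg.lstsq(X, sigma, rcond=None)
    E, eta = float(coef[0]), float(coef[1])
    resid = sigma - X @ coef
    diagnostics = {
        "residual_rms": float(np.sqrt(np.mean(resid**2))),
        "condition_number": float(s[0] / s[-1]),
        "n_samples": int(len(eps)),
        "nonphysical_eta": eta < 0,
        "loading_only": loading_only,
    }
    return E, eta, diagnostics


@dataclass(frozen=True)
class LoopAreas:
    """Hysteresis energetics of one cycle (energy densities in kPa)."""

    dissipated: float       # enclosed loop area, >= 0
    loading_area: float     # area under the loading branch
    unloading_area: float   # area under the unloading branch (closed)
    edr: float              # 100 * dissipated / loading_area, %
    signed_area: float      # positive when loading lies above unloading
    inverted: bool          # unloading branch above loading (non-physical)


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Signed polygon area, positive for clockwise traversal in (x, y).

    A hysteresis loop walked loading-first (out along the upper branch,
    back along the lower one) is clockwise, so physical dissipation
    comes out positive.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return -0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def loop_areas(curve: StressStrainCurve) -> LoopAreas:
    """Dissipated energy density, loading-branch energy and EDR.

    ``loading_area`` is the trapezoidal integral of stress over strain
    along the loading branch.  ``unloading_area`` integrates the
    unloading branch (traversed back towards zero strain) closed with
    the chord to the cycle's start point, so that

        loading_area - unloading_area == signed shoelace loop area

    holds exactly on the discrete polygon.  ``dissipated`` is the
    magnitude of that loop area; a loop whose unloading branch lies
    above its loading branch is flagged ``inverted``.
    """
    load = curve.loading
    unload = curve.unloading
    eps_l, sig_l = curve.strain[load], curve.stress[load]
    if len(eps_l) < 2:
        raise DegenerateCurveError("loading branch has fewer than 2 samples")
    # unloading branch walked in decreasing strain, closed back to start
    eps_u = np.concatenate([curve.strain[unload], curve.strain[:1]])
    sig_u = np.concatenate([curve.stress[unload], curve.stress[:1]])

    loading_area = float(np.trapezoid(sig_l, eps_l))
    unloading_area = float(np.trapezoid(sig_u[::-1], eps_u[::-1]))
    if loading_area <= 0:
        raise DegenerateCurveError(
            f"area under the loading branch is {loading_area:.3g} kPa (must be > 0)"
        )
    signed = _shoelace(curve.strain, curve.stress)
    dissipated = abs(signed)
    return LoopAreas(
        dissipated=dissipated,
        loading_area=loading_area,
        unloading_area=unloading_area,
        edr=100.0 * dissipated / loading_area,
        signed_area=signed,
        inverted=signed < 0,
    )


def extract_properties(
    rec: StanceRecording,
    force_threshold: float | None = None,
    loading_only_fit: bool = False,
) -> HeelPadProperties:
    """Run the full per-recording pipeline to the six material properties.

    Contact detection -> primary thickness -> strain/stress/strain rate
    -> cycle split -> peak point -> Kelvin-Voigt fit -> loop energetics.
    Errors from any stage are re-raised with the stage name attached.
    """
    try:
        curve = curve_from_recording(rec, force_threshold)
    except HeelpadError as err:
        raise StageError("extract", err) from err
    try:
        E, eta, diag = fit_kelvin_voigt(curve, loading_only=loading_only_fit)
    except HeelpadError as err:
        raise StageError("kvfit", err) from err
    try:
        areas = loop_areas(curve)
    except HeelpadError as err:
        raise StageError("loop_areas", err) from err
    pk_strain, pk_stress = peak_point(curve)
    return HeelPadProperties(
        h0=curve.h0,
        peak_strain=pk_strain,
        peak_stress=pk_stress,
        E=E,
        eta=eta,
        edr=areas.edr,
        residual_rms=diag["residual_rms"],
        nonphysical_eta=diag["nonphysical_eta"],
        inverted_loop=areas.inverted,
        warnings=list(rec.warnings),
    )


def properties_table(dataset, **kwargs):
    """Extract properties for every cohort member into a tidy table.

    Columns mirror the clinical summary-table layout (one row per
    subject x leg x status) and carry the subject covariates through.
    """
    import pandas as pd

    rows = []
    for m in dataset:
        props = extract_properties(m.recording, **kwargs)
        row = {
            "subject": m.subject,
            "leg": m.leg,
            "group": m.group,
            "status": m.status,
            **props.as_dict(),
        }
        row.update(m.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
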