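"""Forward simulation of stance-phase heel-pad recordings.

The generator plays the measurement chain backwards: given the material
parameters of a heel pad (elastic modulus E, viscous modulus eta,
unloaded thickness h0) and a stance-phase strain trajectory, it produces
the thickness / force / area streams a biplane-fluoroscopy + pressure
plate rig would record at 50 Hz, with additive Gaussian measurement
noise on the two measured channels.  Downstream stages can therefore be
validated against known ground truth without any in-vivo data.

The constitutive model is a modified Kelvin-Voigt element: a linear
spring in parallel with a nonlinear dashpot whose drag grows with
compression,

    sigma(t) = E * eps(t) + eta * eps(t) * deps/dt(t)

with compressive strain and stress taken positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import StanceRecording
from .errors import ParameterError

__all__ = [
    "KVParams",
    "GaitParams",
    "strain_trajectory",
    "strain_rate_trajectory",
    "simulate_stance",
    "PropertyDist",
    "ArmSpec",
    "CohortSpec",
    "CohortMember",
    "CohortDataset",
    "generate_cohort",
    "study_cohort_spec",
    "GROUP_HEALTHY",
    "GROUP_DIABETES",
    "STATUS_TIME_ZERO",
    "STATUS_POST_LOADING",
]

GROUP_HEALTHY = "healthy"
GROUP_DIABETES = "diabetes"
STATUS_TIME_ZERO = "time_zero"
STATUS_POST_LOADING = "post_loading"

# Unit bridge: stress [kPa] * area [cm^2] -> force [N].
KPA_CM2_TO_N = 0.1


@dataclass(frozen=True)
class KVParams:
    """Material parameters of one heel pad."""

    E: float      # elastic (Young's) modulus, kPa
    eta: float    # viscous modulus, kPa*s
    h0: float     # unloaded (primary) thickness, mm

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ParameterError(f"E must be positive, got {self.E}")
        if self.h0 <= 0:
            raise ParameterError(f"h0 must be positive, got {self.h0}")
        if self.eta < 0:
            raise ParameterError(f"eta must be non-negative, got {self.eta}")

    def stress(self, strain: np.ndarray, strain_rate: np.ndarray) -> np.ndarray:
        """Evaluate the constitutive law sigma = E*eps + eta*eps*deps."""
        strain = np.asarray(strain, dtype=float)
        return self.E * strain + self.eta * strain * np.asarray(strain_rate, float)


@dataclass(frozen=True)
class GaitParams:
    """Kinematic and instrumentation parameters of one simulated step.

    ``loading_fraction`` sets the asymmetry of the stance: the strain
    peak sits at ``loading_fraction * stance_duration``, so values below
    0.5 give the faster-loading / slower-unloading shape seen in vivo.
    """

    stance_duration: float = 0.7       # s; stance time at ~1.0 m/s gait
    frame_rate: float = 50.0           # Hz; fluoroscope frame rate
    peak_strain_target: float = 0.52   # fraction of unloaded thickness
    loading_fraction: float = 0.4      # peak position as fraction of stance
    area_peak: float = 40.0            # cm^2, contact area at peak strain
    area_floor_fraction: float = 0.05  # min contact area / area_peak
    noise_sd_thickness: float = 0.0    # mm
    noise_sd_force: float = 0.0        # N
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if self.stance_duration <= 0:
            raise ParameterError("stance_duration must be positive")
        if not 0.0 < self.peak_strain_target < 1.0:
            raise ParameterError(
                f"peak_strain_target must lie in (0, 1), got {self.peak_strain_target}"
            )
        if not 0.0 < self.loading_fraction < 1.0:
            raise ParameterError("loading_fraction must lie in (0, 1)")
        if self.area_peak <= 0:
            raise ParameterError("area_peak must be positive")
        if self.noise_sd_thickness < 0 or self.noise_sd_force < 0:
            raise ParameterError("noise standard deviations must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.stance_duration * self.frame_rate)) + 1

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def _phase_times(gait: GaitParams) -> tuple[float, float, float]:
    """Actual stance end (snapped to the frame grid), peak time, unload time."""
    t_end = (gait.n_frames - 1) / gait.frame_rate
    t_peak = gait.loading_fraction * t_end
    return t_end, t_peak, t_end - t_peak


def strain_trajectory(gait: GaitParams, t: np.ndarray | None = None) -> np.ndarray:
    """Compressive strain over the stance window.

    The default shape is a raised-cosine (Hann) pulse, piecewise in the
    loading and unloading phases so the peak can sit off-centre:

        eps(t) = a * sin^2(pi t / (2 t_p))            t <= t_p
        eps(t) = a * sin^2(pi (T - t) / (2 (T-t_p)))  t >  t_p

    It is zero with zero slope at touch-down and toe-off, rises to the
    peak-strain target exactly once, and has an analytic derivative
    (see :func:`strain_rate_trajectory`).  The gentle quadratic lift-off
    keeps the strain at the first measurable-force frame small, the same
    property that makes contact-frame thickness a usable strain
    reference in real recordings.
    """
    if t is None:
        t = gait.time_grid()
    t = np.asarray(t, dtype=float)
    t_end, t_peak, t_unload = _phase_times(gait)
    a = gait.peak_strain_target
    eps = np.empty_like(t)
    load = t <= t_peak
    eps[load] = a * np.sin(np.pi * t[load] / (2.0 * t_peak)) ** 2
    eps[~load] = a * np.sin(np.pi * (t_end - t[~load]) / (2.0 * t_unload)) ** 2
    return eps


def strain_rate_trajectory(gait: GaitParams, t: np.ndarray | None = None) -> np.ndarray:
    """Analytic time derivative of :func:`strain_trajectory`, 1/s."""
    if t is None:
        t = gait.time_grid()
    t = np.asarray(t, dtype=float)
    t_end, t_peak, t_unload = _phase_times(gait)
    a = gait.peak_strain_target
    rate = np.empty_like(t)
    load = t <= t_peak
    rate[load] = a * (np.pi / (2.0 * t_peak)) * np.sin(np.pi * t[load] / t_peak)
    rate[~load] = -a * (np.pi / (2.0 * t_unload)) * np.sin(
        np.pi * (t_end - t[~load]) / t_unload
    )
    return rate


def max_unloading_strain_rate(gait: GaitParams) -> float:
    """Largest |deps/dt| on the unloading branch (closed form)."""
    t_end, _, t_unload = _phase_times(gait)
    return gait.peak_strain_target * math.pi / (2.0 * t_unload)


def simulate_stance(
    kv: KVParams,
    gait: GaitParams,
    rng: np.random.Generator | None = None,
) -> StanceRecording:
    """Forward-simulate one stance-phase recording.

    Thickness is ``h0 * (1 - eps)`` plus thickness noise; stress follows
    the Kelvin-Voigt law with the analytic strain rate; force is
    ``stress * area`` (kPa * cm^2 -> N) plus force noise.  The contact
    area grows with compression as ``area_peak * sqrt(eps/eps_max)``
    with a small floor so that frames in contact always report a
    positive area.

    If the parameter/trajectory pair drives the model stress negative
    (a very viscous pad unloaded too fast would have to pull on the
    plate), the negative part is clipped to zero in the *force* channel
    only and the recording carries a warning record.
    """
    if rng is None:
        rng = np.random.default_rng(gait.seed)
    t = gait.time_grid()
    eps = strain_trajectory(gait, t)
    rate = strain_rate_trajectory(gait, t)

    thickness = kv.h0 * (1.0 - eps)
    stress = kv.stress(eps, rate)

    area = gait.area_peak * np.sqrt(eps / gait.peak_strain_target)
    area = np.maximum(area, gait.area_floor_fraction * gait.area_peak)

    force = KPA_CM2_TO_N * stress * area
    warnings: list[str] = []
    n_neg = int(np.sum(stress < -1e-12))
    if n_neg:
        warnings.append(
            f"model stress negative on {n_neg} frames; clipped to 0 in force channel"
        )
        force = np.maximum(force, 0.0)

    if gait.noise_sd_thickness > 0:
        thickness = thickness + rng.normal(0.0, gait.noise_sd_thickness, t.shape)
    if gait.noise_sd_force > 0:
        force = force + rng.normal(0.0, gait.noise_sd_force, t.shape)
        force = np.maximum(force, 0.0)  # plate reports no tensile force

    return StanceRecording(
        time=t,
        thickness=thickness,
        force=force,
        area=area,
        frame_rate=gait.frame_rate,
        meta={"true_params": kv, "gait": gait},
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyDist:
    """A truncated-Gaussian population distribution for one property."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")


@dataclass(frozen=True)
class ArmSpec:
    """Population distributions for one (group, status) arm."""

    h0: PropertyDist            # mm
    E: PropertyDist             # kPa
    eta: PropertyDist           # kPa*s
    peak_strain: PropertyDist   # fraction


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    ``arms[group][status]`` holds the population distributions;
    ``n_subjects[group]`` the group sizes.  Each subject contributes
    ``legs_per_subject`` legs whose latent material parameters share a
    within-subject correlation ``leg_correlation``; the two loading
    statuses of one leg share a correlation ``status_correlation`` so
    that paired (time-zero vs post-loading) analyses see realistic
    within-leg coupling.
    """

    arms: dict                                  # group -> status -> ArmSpec
    n_subjects: dict                            # group -> int
    legs_per_subject: int = 2
    leg_correlation: float = 0.7
    # Between-status coupling per property; the defaults are anchored
    # in the published SDs of the time-zero vs post-loading differences
    # (thickness of one leg barely changes between sessions, the moduli
    # decouple more).  A plain float applies to all properties.
    status_correlation: float | dict = field(
        default_factory=lambda: {"h0": 0.97, "E": 0.8, "eta": 0.8,
                                 "peak_strain": 0.9}
    )
    gait: GaitParams = field(
        default_factory=lambda: GaitParams(noise_sd_thickness=0.1, noise_sd_force=2.0)
    )
    covariates: dict = field(default_factory=dict)  # group -> dict of PropertyDist

    def status_rho(self, prop: str) -> float:
        if isinstance(self.status_correlation, dict):
            return self.status_correlation.get(prop, 0.8)
        return float(self.status_correlation)

    def __post_init__(self) -> None:
        for group, n in self.n_subjects.items():
            if n < 2:
                raise ParameterError(f"group '{group}' needs n_subjects >= 2")
        rhos = [self.leg_correlation]
        if isinstance(self.status_correlation, dict):
            rhos.extend(self.status_correlation.values())
        else:
            rhos.append(self.status_correlation)
        for rho in rhos:
            if not 0.0 <= rho <= 1.0:
                raise ParameterError("correlations must lie in [0, 1]")


@dataclass
class CohortMember:
    """One (subject, leg, status) cell: its truth and its recording."""

    subject: str
    leg: str
    group: str
    status: str
    kv: KVParams
    peak_strain_target: float
    recording: StanceRecording
    covariates: dict = field(default_factory=dict)


@dataclass
class CohortDataset:
    members: list

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def select(self, **keys) -> "CohortDataset":
        out = [
            m for m in self.members
            if all(getattr(m, k) == v for k, v in keys.items())
        ]
        return CohortDataset(out)


_MAX_REJECTS = 1000


def _draw_truncated(dist: PropertyDist, latent: float, rng: np.random.Generator) -> float:
    """Map a latent standard-normal draw through the (mean, sd) and
    re-draw the latent if the value falls outside the physical bounds."""
    value = dist.mean + dist.sd * latent
    rejects = 0
    while not (dist.lower <= value <= dist.upper):
        rejects += 1
        if rejects > _MAX_REJECTS:
            raise ParameterError(
                f"truncation rejected >{_MAX_REJECTS} draws for {dist}; "
                "bounds are unreachable from (mean, sd)"
            )
        value = dist.mean + dist.sd * rng.standard_normal()
    return value


_PROPS = ("h0", "E", "eta", "peak_strain")


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortDataset:
    """Draw a full synthetic cohort and simulate every recording.

    Per subject and property a latent factor is drawn; each leg mixes it
    with an own factor at ``leg_correlation``, and each loading status
    mixes the leg factor with a fresh one at ``status_correlation``.
    The resulting latent feeds the status-specific population
    distribution, truncated at physical bounds.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    rho_l = spec.leg_correlation
    for group in sorted(spec.arms):
        statuses = sorted(spec.arms[group])
        cov_dists = spec.covariates.get(group, {})
        for i in range(spec.n_subjects[group]):
            subject = f"{group}_{i + 1:02d}"
            covs = {
                name: _draw_truncated(d, rng.standard_normal(), rng)
                for name, d in sorted(cov_dists.items())
            }
            z_subj = {p: rng.standard_normal() for p in _PROPS}
            for leg_idx in range(spec.legs_per_subject):
                leg = ("left", "right")[leg_idx % 2] if spec.legs_per_subject == 2 \
                    else f"leg{leg_idx + 1}"
                z_leg = {
                    p: math.sqrt(rho_l) * z_subj[p]
                    + math.sqrt(1.0 - rho_l) * rng.standard_normal()
                    for p in _PROPS
                }
                for status in statuses:
                    arm: ArmSpec = spec.arms[group][status]
                    z_status = {
                        p: math.sqrt(spec.status_rho(p)) * z_leg[p]
                        + math.sqrt(1.0 - spec.status_rho(p))
                        * rng.standard_normal()
                        for p in _PROPS
                    }
                    h0 = _draw_truncated(arm.h0, z_status["h0"], rng)
                    E = _draw_truncated(arm.E, z_status["E"], rng)
                    eta = _draw_truncated(arm.eta, z_status["eta"], rng)
                    a = _draw_truncated(arm.peak_strain, z_status["peak_strain"], rng)
                    kv = KVParams(E=E, eta=eta, h0=h0)
                    gait = replace(
                        spec.gait,
                        peak_strain_target=a,
                        seed=None,
                    )
                    rec = simulate_stance(kv, gait, rng=rng)
                    members.append(
                        CohortMember(
                            subject=subject,
                            leg=leg,
                            group=group,
                            status=status,
                            kv=kv,
                            peak_strain_target=a,
                            recording=rec,
                            covariates=dict(covs),
                        )
                    )
    return CohortDataset(members)


def study_cohort_spec(subgroups: bool = False, **overrides) -> CohortSpec:
    """The default two-group, two-status cohort design.

    Population means and SDs follow the published summaries for healthy
    adults and type-2-diabetes patients (20 legs per group): primary
    thickness 14.85+/-2.81 vs 12.25+/-2.34 mm and viscous modulus
    66.59 vs 42.28+/-18.93 kPa*s at time zero, with the corresponding
    post-loading values.  Where a property was reported as median and
    range (non-normal), the median stands in for the mean and a quarter
    of the range for the SD.  With ``subgroups=True`` the diabetes group
    splits into short-course (<10 y) and long-course (>=10 y) halves
    parameterized from the subgroup columns.
    """
    def d(mean, sd, lo=0.0, hi=math.inf):
        return PropertyDist(mean, sd, lo, hi)

    strain_hi = 0.95

    healthy = {
        STATUS_TIME_ZERO: ArmSpec(
            h0=d(14.85, 2.81, lo=5.0),
            E=d(265.50, (306.28 - 154.79) / 4.0, lo=50.0),
            eta=d(66.59, (137.97 - 36.70) / 4.0, lo=0.0),
            peak_strain=d(0.5230, 0.1009, lo=0.05, hi=strain_hi),
        ),
        STATUS_POST_LOADING: ArmSpec(
            h0=d(14.55, 2.74, lo=5.0),
            E=d(236.40, 47.21, lo=50.0),
            eta=d(46.30, 19.99, lo=0.0),
            peak_strain=d(0.5155, (0.7185 - 0.4109) / 4.0, lo=0.05, hi=strain_hi),
        ),
    }
    diabetes = {
        STATUS_TIME_ZERO: ArmSpec(
            h0=d(12.25, 2.34, lo=5.0),
            E=d(214.39, 48.04, lo=50.0),
            eta=d(42.28, 18.93, lo=0.0),
            peak_strain=d(0.6065, 0.1173, lo=0.05, hi=strain_hi),
        ),
        STATUS_POST_LOADING: ArmSpec(
            h0=d(11.95, 2.21, lo=5.0),
            E=d(209.95, 49.04, lo=50.0),
            eta=d(26.45, 16.55, lo=0.0),
            peak_strain=d(0.5861, (0.9292 - 0.4064) / 4.0, lo=0.05, hi=strain_hi),
        ),
    }
    diabetes_a = {
        STATUS_TIME_ZERO: ArmSpec(
            h0=d(12.69, 2.16, lo=5.0),
            E=d(206.50, 43.08, lo=50.0),
            eta=d(36.20, 14.37, lo=0.0),
            peak_strain=d(0.5880, 0.1044, lo=0.05, hi=strain_hi),
        ),
        STATUS_POST_LOADING: ArmSpec(
            h0=d(11.90, 2.13, lo=5.0),
            E=d(204.60, 34.58, lo=50.0),
            eta=d(23.10, 11.12, lo=0.0),
            peak_strain=d(0.5723, 0.0872, lo=0.05, hi=strain_hi),
        ),
    }
    diabetes_b = {
        STATUS_TIME_ZERO: ArmSpec(
            h0=d(12.54, 2.62, lo=5.0),
            E=d(221.30, 53.69, lo=50.0),
            eta=d(47.60, 21.74, lo=0.0),
            peak_strain=d(0.6250, 0.1318, lo=0.05, hi=strain_hi),
        ),
        STATUS_POST_LOADING: ArmSpec(
            h0=d(12.00, 2.40, lo=5.0),
            E=d(215.30, 61.79, lo=50.0),
            eta=d(29.80, 20.72, lo=0.0),
            peak_strain=d(0.5896, (0.9292 - 0.4812) / 4.0, lo=0.05, hi=strain_hi),
        ),
    }

    covariates = {
        GROUP_HEALTHY: {
            "age": PropertyDist(64.4, 3.4, 30.0, 95.0),
            "bmi": PropertyDist(24.1, 2.2, 15.0, 45.0),
        },
        GROUP_DIABETES: {
            "age": PropertyDist(67.8, 4.9, 30.0, 95.0),
            "bmi": PropertyDist(24.7, 3.9, 15.0, 45.0),
            "course_years": PropertyDist(10.5, 6.9, 0.5, 40.0),
        },
    }

    if subgroups:
        arms = {
            GROUP_HEALTHY: healthy,
            "diabetesA": diabetes_a,
            "diabetesB": diabetes_b,
        }
        n_subjects = {GROUP_HEALTHY: 10, "diabetesA": 5, "diabetesB": 5}
        covariates = {
            GROUP_HEALTHY: covariates[GROUP_HEALTHY],
            "diabetesA": {
                "age": PropertyDist(67.6, 3.7, 30.0, 95.0),
                "bmi": PropertyDist(25.4, 3.5, 15.0, 45.0),
                "course_years": PropertyDist(4.8, 2.8, 0.5, 9.9),
            },
            "diabetesB": {
                "age": PropertyDist(69.0, 5.0, 30.0, 95.0),
                "bmi": PropertyDist(25.1, 4.3, 15.0, 45.0),
                "course_years": PropertyDist(16.2, 5.9, 10.0, 40.0),
            },
        }
    else:
        arms = {GROUP_HEALTHY: healthy, GROUP_DIABETES: diabetes}
        n_subjects = {GROUP_HEALTHY: 10, GROUP_DIABETES: 10}

    kwargs = dict(
        arms=arms,
        n_subjects=n_subjects,
        covariates=covariates,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
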