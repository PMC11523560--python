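"""Subject anthropometry and musculoskeletal-model scaling.

Cohorts of synthetic subjects are drawn from truncated normal distributions
of body size, and a generic 7-actuator elbow model (three triceps heads, two
biceps heads, brachialis, brachioradialis) is scaled to each subject:
moment arms scale with stature, maximum isometric forces with body mass.
Only the product ``fmax * moment_arm`` matters for the isometric task
downstream, so this linear scaling is a deliberate simplification of full
musculoskeletal-model scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectStatics",
    "ActuatorParams",
    "ScaledElbowModel",
    "ReferenceAnthropometry",
    "GENERIC_ACTUATORS",
    "REFERENCE",
    "sample_simulated_cohort",
    "sample_recorded_style_cohort",
    "scale_model",
    "cohort_to_csv",
    "cohort_from_csv",
]

FLEXOR_GROUPS = ("BIC", "BRA", "BRD")
GROUP_ORDER = ("BRA", "TRI", "BIC", "BRD")  # channel order used everywhere


@dataclass(frozen=True)
class SubjectStatics:
    """The 7 static per-subject features.

    Units follow measurement convention: height in metres, mass in kg,
    maximum elbow-flexion torque in N·m, segment lengths/widths in cm.
    """

    subject_id: str
    sex: str  # "female" | "male"
    height: float
    mass: float
    mvc_torque: float
    forearm_length: float
    elbow_width: float
    upper_arm_length: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name in ("height", "mass", "mvc_torque", "forearm_length",
                     "elbow_width", "upper_arm_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def numeric_vector(self) -> np.ndarray:
        """Numeric encoding: sex as {0: female, 1: male} plus the 6 measures."""
        return np.array([
            0.0 if self.sex == "female" else 1.0,
            self.height, self.mass, self.mvc_torque,
            self.forearm_length, self.elbow_width, self.upper_arm_length,
        ])


@dataclass(frozen=True)
class ActuatorParams:
    """One muscle-tendon actuator: peak isometric force and signed moment arm.

    Flexors have positive moment arms, the triceps heads negative ones
    (extension action at the elbow).
    """

    name: str
    group: str
    fmax: float       # N
    moment_arm: float  # m, signed

    def __post_init__(self) -> None:
        if self.fmax <= 0:
            raise ValueError("fmax must be > 0")
        if self.group == "TRI" and self.moment_arm >= 0:
            raise ValueError("TRI actuators must have negative moment arms")
        if self.group != "TRI" and self.moment_arm <= 0:
            raise ValueError("flexor actuators must have positive moment arms")

    @property
    def torque_capacity(self) -> float:
        """Signed torque at full activation, fmax * moment_arm (N·m)."""
        return self.fmax * self.moment_arm


@dataclass(frozen=True)
class ScaledElbowModel:
    statics: SubjectStatics
    actuators: tuple[ActuatorParams, ...]

    def __post_init__(self) -> None:
        if len(self.actuators) != 7:
            raise ValueError("an elbow model has exactly 7 actuators")

    @property
    def flexors(self) -> tuple[ActuatorParams, ...]:
        return tuple(a for a in self.actuators if a.group in FLEXOR_GROUPS)

    @property
    def extensors(self) -> tuple[ActuatorParams, ...]:
        return tuple(a for a in self.actuators if a.group == "TRI")

    @property
    def strength_ceiling(self) -> float:
        """Maximum isometric flexion torque, sum of flexor fmax*r (N·m)."""
        return float(sum(a.torque_capacity for a in self.flexors))


# Generic actuator set at the modelled posture (90° elbow flexion, forearm
# supinated).  Values chosen so the reference subject's flexion-strength
# ceiling sits mid-way through the 30-90 N·m target grid (~76 N·m), making
# the upper targets infeasible for smaller subjects.
GENERIC_ACTUATORS: tuple[ActuatorParams, ...] = (
    ActuatorParams("TRI_long", "TRI", 798.5, -0.021),
    ActuatorParams("TRI_lat", "TRI", 624.3, -0.021),
    ActuatorParams("TRI_med", "TRI", 624.3, -0.021),
    ActuatorParams("BIC_long", "BIC", 624.3, 0.035),
    ActuatorParams("BIC_short", "BIC", 435.6, 0.035),
    ActuatorParams("BRA", "BRA", 987.3, 0.025),
    ActuatorParams("BRD", "BRD", 261.3, 0.055),
)


@dataclass(frozen=True)
class ReferenceAnthropometry:
    """Reference population used for both sampling and model scaling.

    Means/SDs default to the recorded-cohort statistics (height 1.70±0.07 m,
    mass 75.1±12.2 kg, MVC 46.9±14.0 N·m, forearm 25.9±1.7 cm, elbow width
    9.5±0.9 cm, upper arm 31.6±2.5 cm) so the simulated and recorded-style
    cohorts share one parameterization.
    """

    height_mean: float = 1.70
    height_sd: float = 0.07
    mass_mean: float = 75.1
    mass_sd: float = 12.2
    mvc_mean: float = 46.9
    mvc_sd: float = 14.0
    forearm_mean: float = 25.9
    forearm_sd: float = 1.7
    elbow_width_mean: float = 9.5
    elbow_width_sd: float = 0.9
    upper_arm_mean: float = 31.6
    upper_arm_sd: float = 2.5
    # fixed fractions of stature used to derive segment sizes for simulated
    # subjects (each equals the reference mean at the reference height)
    derived_noise_sd: float = 0.02  # relative, lognormal-ish jitter

    @property
    def reference_statics(self) -> SubjectStatics:
        return SubjectStatics(
            "reference", "male", self.height_mean, self.mass_mean,
            self.mvc_mean, self.forearm_mean, self.elbow_width_mean,
            self.upper_arm_mean,
        )


REFERENCE = ReferenceAnthropometry()


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo_z: float,
               hi_z: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    return stats.truncnorm.rvs(lo_z, hi_z, loc=mean, scale=sd, size=size,
                               random_state=rng)


def sample_simulated_cohort(n: int, seed: int,
                            ref: ReferenceAnthropometry = REFERENCE,
                            ) -> list[SubjectStatics]:
    """Draw ``n`` synthetic young adults spanning the 5th-95th size percentiles.

    Height and mass are truncated normals (z in [-1.645, 1.645]); sex is a
    fair coin; the remaining statics derive from height/mass via fixed
    allometric ratios with small seeded multiplicative noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(0.95)  # 5th/95th percentile truncation
    heights = _truncnorm(rng, ref.height_mean, ref.height_sd, -z, z, n)
    masses = _truncnorm(rng, ref.mass_mean, ref.mass_sd, -z, z, n)
    sexes = rng.random(n) < 0.5
    noise = rng.normal(0.0, ref.derived_noise_sd, size=(n, 4))
    subjects = []
    for i in range(n):
        h_ratio = heights[i] / ref.height_mean
        m_ratio = masses[i] / ref.mass_mean
        subjects.append(SubjectStatics(
            subject_id=f"sim{i:04d}",
            sex="female" if sexes[i] else "male",
            height=float(heights[i]),
            mass=float(masses[i]),
            mvc_torque=float(ref.mvc_mean * m_ratio * h_ratio
                             * (1 + noise[i, 0])),
            forearm_length=float(ref.forearm_mean * h_ratio * (1 + noise[i, 1])),
            elbow_width=float(ref.elbow_width_mean * h_ratio * (1 + noise[i, 2])),
            upper_arm_length=float(ref.upper_arm_mean * h_ratio
                                   * (1 + noise[i, 3])),
        ))
    return subjects


def sample_recorded_style_cohort(n: int, seed: int,
                                 ref: ReferenceAnthropometry = REFERENCE,
                                 female_fraction: float = 9 / 25,
                                 ) -> list[SubjectStatics]:
    """Draw ``n`` subjects matching the recorded cohort's feature statistics.

    Each feature is an independent truncated normal (±3 SD) at the recorded
    means/SDs; sex is Bernoulli with the recorded 9:16 female:male ratio.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {
        "height": (ref.height_mean, ref.height_sd),
        "mass": (ref.mass_mean, ref.mass_sd),
        "mvc_torque": (ref.mvc_mean, ref.mvc_sd),
        "forearm_length": (ref.forearm_mean, ref.forearm_sd),
        "elbow_width": (ref.elbow_width_mean, ref.elbow_width_sd),
        "upper_arm_length": (ref.upper_arm_mean, ref.upper_arm_sd),
    }
    draws = {k: _truncnorm(rng, m, s, -3, 3, n) for k, (m, s) in cols.items()}
    sexes = rng.random(n) < female_fraction
    return [
        SubjectStatics(
            subject_id=f"rec{i:04d}",
            sex="female" if sexes[i] else "male",
            **{k: float(v[i]) for k, v in draws.items()},
        )
        for i in range(n)
    ]


def scale_model(generic: tuple[ActuatorParams, ...] | list[ActuatorParams],
                statics: SubjectStatics,
                ref: ReferenceAnthropometry = REFERENCE) -> ScaledElbowModel:
    """Scale generic actuators to a subject: r ∝ height, fmax ∝ mass."""
    if len(generic) != 7:
        raise ValueError("generic actuator set must contain 7 actuators")
    h_ratio = statics.height / ref.height_mean
    m_ratio = statics.mass / ref.mass_mean
    scaled = tuple(
        replace(a, fmax=a.fmax * m_ratio, moment_arm=a.moment_arm * h_ratio)
        for a in generic
    )
    return ScaledElbowModel(statics=statics, actuators=scaled)


_CSV_COLUMNS = ["subject_id", "sex", "height_m", "mass_kg", "mvc_Nm",
                "forearm_cm", "elbow_width_cm", "upper_arm_cm"]


def cohort_to_csv(cohort: list[SubjectStatics], path: str | Path) -> None:
    df = pd.DataFrame(
        [[s.subject_id, s.sex, s.height, s.mass, s.mvc_torque,
          s.forearm_length, s.elbow_width, s.upper_arm_length]
         for s in cohort],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> list[SubjectStatics]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [
        SubjectStatics(r.subject_id, r.sex, r.height_m, r.mass_kg, r.mvc_Nm,
                       r.forearm_cm, r.elbow_width_cm, r.upper_arm_cm)
        for r in df.itertuples()
    ]
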