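"""Synthetic plasma-MALDI cohorts with planted structure.

The generator emulates the statistical shape of a binned plasma MALDI
feature matrix from a two-group (weight-gain case vs eutrophic control)
cohort: per-patient replicate spectra over nominal m/z channels, a
log-normal intensity baseline whose scale declines with m/z, a few
dominant near-constant base-peak channels, class-shifted marker
channels, and exactly linearly dependent channel groups. BMI-based WHO
labeling utilities are included so cohort class labels can be derived
the same way a clinical study would assign them.

Noise is split between a patient-level effect shared by a patient's
replicates and an independent replicate-level effect, so replicate
vectors of one patient are correlated — the property that makes
patient-grouped partitioning necessary downstream.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import ConfigError
from .io import NEGATIVE_CLASS, POSITIVE_CLASS, IntensityMatrix

# ---------------------------------------------------------------------------
# BMI and WHO categories
# ---------------------------------------------------------------------------


def compute_bmi(weight: float, height: float) -> float:
    """Body-mass index: weight in kg divided by height in meters squared."""
    if weight <= 0 or height <= 0:
        raise ConfigError(f"weight and height must be positive, got {weight}, {height}")
    return weight / height**2


class WhoCategory(enum.IntEnum):
    """WHO BMI category; ordering reflects increasing BMI."""

    UNDERWEIGHT = 0  # below the eutrophic floor: out-of-study sentinel
    EUTROPHIC = 1
    OVERWEIGHT = 2
    OBESE_I = 3
    OBESE_II = 4
    OBESE_III = 5


def who_category(bmi: float) -> WhoCategory:
    """WHO BMI category with half-open cut points.

    Eutrophic [18, 25), overweight [25, 30), class I obesity [30, 35),
    class II [35, 40), class III >= 40. Below 18 returns the explicit
    UNDERWEIGHT sentinel (out of study), never a silent eutrophic.
    """
    if bmi <= 0:
        raise ConfigError(f"bmi must be positive, got {bmi}")
    if bmi < 18:
        return WhoCategory.UNDERWEIGHT
    if bmi < 25:
        return WhoCategory.EUTROPHIC
    if bmi < 30:
        return WhoCategory.OVERWEIGHT
    if bmi < 35:
        return WhoCategory.OBESE_I
    if bmi < 40:
        return WhoCategory.OBESE_II
    return WhoCategory.OBESE_III


def class_label(bmi: float) -> str:
    """Cohort label for a BMI: overweight or any obesity class is a case."""
    category = who_category(bmi)
    if category is WhoCategory.UNDERWEIGHT:
        raise ConfigError(f"bmi {bmi} is below the eutrophic floor (out of study)")
    return POSITIVE_CLASS if category >= WhoCategory.OVERWEIGHT else NEGATIVE_CLASS


@dataclass(frozen=True)
class SubjectRecord:
    """One enrolled subject with anthropometrics and derived label."""

    patient_id: str
    weight: float  # kg
    height: float  # m
    bmi: float  # kg/m^2
    class_label: str


# ---------------------------------------------------------------------------
# generator specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DependentGroupSpec:
    """A planted dependency group: each member equals coeff * generator."""

    generator: int
    members: tuple[int, ...]
    coefficients: tuple[float, ...]


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal baseline and replicate structure of the spectra.

    ``channel_loc_start``/``channel_loc_end`` give the log-intensity
    trend from the first to the last channel (plasma MALDI intensity
    decays with m/z); ``channel_loc_sd`` is channel-to-channel
    roughness around that trend. ``patient_sigma`` and
    ``replicate_sigma`` are log-space standard deviations of the
    patient-shared and replicate-independent effects. ``base_peak_*``
    configure a few dominant, nearly constant channels that carry the
    per-vector maximum, as matrix-cluster base peaks do in real spectra.

    Both random effects are truncated at ``effect_clip`` standard
    deviations: detector intensities have a bounded dynamic range, and
    an unbounded log-normal tail would let a single outlier dominate a
    channel's upper quantiles.
    """

    channel_loc_start: float = 3.0
    channel_loc_end: float = 0.5
    channel_loc_sd: float = 0.8
    patient_sigma: float = 0.45
    replicate_sigma: float = 0.15
    effect_clip: float = 2.0
    base_peak_channels: tuple[int, ...] = (406, 407, 422, 423)
    base_peak_loc: float = 7.5
    base_peak_noise_factor: float = 0.05
    marker_loc: float = 4.5
    generator_loc: float = 4.0


def _default_markers() -> tuple[tuple[int, float], ...]:
    # Channel indices of m/z 263, 278, 299, 308, 389 at a 250 start:
    # the low-m/z metabolite range where plasma markers live.
    return tuple((mz - 250, 3.0) for mz in (263, 278, 299, 308, 389))


def _default_groups() -> tuple[DependentGroupSpec, ...]:
    coeffs = (0.8, 0.6, 0.45, 0.3)
    return tuple(
        DependentGroupSpec(g, (g + 3, g + 7, g + 11, g + 16), coeffs)
        for g in (500, 520, 540, 560, 580)
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of a synthetic cohort; defaults emulate a
    180-patient study measured in quintuplicate over 1,752 channels."""

    n_per_class: int = 90
    replicates_per_patient: int = 5
    n_channels: int = 1752
    channel_mz_start: int = 250
    marker_channels: tuple[tuple[int, float], ...] = field(default_factory=_default_markers)
    marker_prevalence: float = 0.85
    dependent_groups: tuple[DependentGroupSpec, ...] = field(default_factory=_default_groups)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    dropout_rows: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_per_class, self.replicates_per_patient, self.n_channels) < 1:
            raise ConfigError("cohort dimensions must be positive")
        marker_idx = [c for c, _ in self.marker_channels]
        member_idx = [m for g in self.dependent_groups for m in g.members]
        generator_idx = [g.generator for g in self.dependent_groups]
        special = marker_idx + member_idx + generator_idx + list(
            self.noise_model.base_peak_channels
        )
        if any(not 0 <= c < self.n_channels for c in special):
            raise ConfigError("marker/group/base-peak channel index out of range")
        if len(set(marker_idx)) != len(marker_idx):
            raise ConfigError("duplicate marker channels")
        structural = member_idx + generator_idx
        if len(set(structural)) != len(structural):
            raise ConfigError("dependency groups overlap")
        if set(marker_idx) & set(structural):
            raise ConfigError("marker channels and dependency groups must be disjoint")
        for g in self.dependent_groups:
            if len(g.members) != len(g.coefficients):
                raise ConfigError(f"group at {g.generator}: members/coefficients mismatch")
            if any(c <= 0 for c in g.coefficients):
                raise ConfigError(f"group at {g.generator}: coefficients must be positive")
            if any(m <= g.generator for m in g.members):
                raise ConfigError(
                    f"group at {g.generator}: members must sit above their generator"
                )
        if any(s < 0 for _, s in self.marker_channels):
            raise ConfigError("marker shifts must be >= 0")
        if not 0 < self.marker_prevalence <= 1:
            raise ConfigError("marker_prevalence must lie in (0, 1]")

    def null(self) -> "SyntheticSpec":
        """The same cohort with every marker shift set to zero."""
        import dataclasses

        return dataclasses.replace(
            self, marker_channels=tuple((c, 0.0) for c, _ in self.marker_channels)
        )


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    seed: int
    marker_mz: dict[int, float]  # m/z label -> shift (units of channel scale)
    group_mz: dict[int, tuple[int, ...]]  # generator m/z -> member m/z labels
    dependent_member_mz: tuple[int, ...]
    subjects: list[SubjectRecord]
    spec: SyntheticSpec

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "marker_mz": {str(k): v for k, v in self.marker_mz.items()},
            "group_mz": {str(k): list(v) for k, v in self.group_mz.items()},
            "dependent_member_mz": list(self.dependent_member_mz),
            "subjects": [asdict(s) for s in self.subjects],
            "spec": _spec_dict(self.spec),
        }
        return json.dumps(payload, indent=2)


def _spec_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["marker_channels"] = [list(m) for m in spec.marker_channels]
    d["dependent_groups"] = [asdict(g) for g in spec.dependent_groups]
    return d


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_subjects(rng: np.random.Generator, n_per_class: int) -> list[SubjectRecord]:
    subjects = []
    for label, prefix, bmi_loc, bmi_sd, bmi_lo, bmi_hi in (
        (NEGATIVE_CLASS, "C", 22.3, 2.0, 18.5, 24.8),
        (POSITIVE_CLASS, "P", 33.3, 6.0, 25.1, 55.0),
    ):
        for i in range(n_per_class):
            height = float(np.clip(rng.normal(1.66, 0.09), 1.45, 2.00))
            bmi = float(np.clip(rng.normal(bmi_loc, bmi_sd), bmi_lo, bmi_hi))
            weight = bmi * height**2
            pid = f"{prefix}{i:03d}"
            subjects.append(
                SubjectRecord(pid, weight, height, compute_bmi(weight, height),
                              class_label(compute_bmi(weight, height)))
            )
    return subjects


def generate_cohort(spec: SyntheticSpec) -> tuple[IntensityMatrix, GroundTruth]:
    """Generate a labeled cohort matrix plus its planted ground truth.

    Deterministic given ``spec`` (including its seed). Intensities are
    raw (unnormalized); marker shifts are applied before any per-vector
    normalization so the analysis pipeline, not the generator, performs
    normalization. Dependent member columns are exact scalar multiples
    of their generator column.
    """
    spec.validate()
    nm = spec.noise_model
    rng = np.random.default_rng(spec.seed)

    subjects = _draw_subjects(rng, spec.n_per_class)
    n_patients = len(subjects)
    n_rows = n_patients * spec.replicates_per_patient

    # per-channel log-intensity location: declining trend + roughness,
    # with planted channels pinned to defined "strong peak" baselines
    trend = np.linspace(nm.channel_loc_start, nm.channel_loc_end, spec.n_channels)
    mu = trend + rng.normal(0.0, nm.channel_loc_sd, spec.n_channels)
    for c, _ in spec.marker_channels:
        mu[c] = nm.marker_loc
    for g in spec.dependent_groups:
        mu[g.generator] = nm.generator_loc
    for c in nm.base_peak_channels:
        mu[c] = nm.base_peak_loc

    noise_factor = np.ones(spec.n_channels)
    noise_factor[list(nm.base_peak_channels)] = nm.base_peak_noise_factor

    clip = nm.effect_clip
    patient_effect = np.clip(
        rng.normal(0.0, 1.0, (n_patients, spec.n_channels)), -clip, clip
    )
    replicate_effect = np.clip(
        rng.normal(0.0, 1.0, (n_rows, spec.n_channels)), -clip, clip
    )

    row_patient = np.repeat(np.arange(n_patients), spec.replicates_per_patient)
    log_intensity = (
        mu[None, :]
        + nm.patient_sigma * noise_factor[None, :] * patient_effect[row_patient]
        + nm.replicate_sigma * noise_factor[None, :] * replicate_effect
    )
    values = np.exp(log_intensity)

    # channel baseline scale: std of the channel's own unshifted values,
    # so a planted shift of k is exactly k baseline standard deviations
    channel_scale = values.std(axis=0)

    # markers: a case patient expresses each marker channel independently
    # with probability marker_prevalence (all their replicates follow);
    # controls never express, so the ion is *more prevalent* in cases
    positive_patient = np.array(
        [s.class_label == POSITIVE_CLASS for s in subjects]
    )
    expression = rng.random((n_patients, len(spec.marker_channels)))
    for k, (c, shift) in enumerate(spec.marker_channels):
        expressing = positive_patient & (expression[:, k] < spec.marker_prevalence)
        values[expressing[row_patient], c] += shift * channel_scale[c]

    for g in spec.dependent_groups:
        for member, coeff in zip(g.members, g.coefficients):
            values[:, member] = coeff * values[:, g.generator]

    patient_id = np.array([subjects[p].patient_id for p in row_patient], dtype=object)
    replicate = np.tile(np.arange(1, spec.replicates_per_patient + 1), n_patients)

    if spec.dropout_rows:
        if spec.dropout_rows >= n_rows:
            raise ConfigError("dropout_rows must be smaller than the row count")
        drop = rng.choice(n_rows, size=spec.dropout_rows, replace=False)
        keep = np.setdiff1d(np.arange(n_rows), drop)
        values, patient_id, replicate = values[keep], patient_id[keep], replicate[keep]

    matrix = IntensityMatrix(
        values=values,
        mz=spec.channel_mz_start + np.arange(spec.n_channels),
        patient_id=patient_id,
        replicate=replicate,
        patient_class={s.patient_id: s.class_label for s in subjects},
    )
    mz0 = spec.channel_mz_start
    truth = GroundTruth(
        seed=spec.seed,
        marker_mz={mz0 + c: shift for c, shift in spec.marker_channels},
        group_mz={mz0 + g.generator: tuple(mz0 + m for m in g.members)
                  for g in spec.dependent_groups},
        dependent_member_mz=tuple(
            mz0 + m for g in spec.dependent_groups for m in g.members
        ),
        subjects=subjects,
        spec=spec,
    )
    return matrix, truth
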