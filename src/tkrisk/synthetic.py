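"""Synthetic knee-MRI phantom cohorts.

Generates a fully self-contained stand-in for a prospective knee-OA cohort:
3D intensity volumes with an integer-labeled tissue atlas, visit-level
clinical records (KL grade, OA stratum, TKR event time, KOOS pain, 27
non-imaging variables with missingness), and a case-specific intensity
signal planted in designated tissues so biomarker recovery has a known
ground truth.

The generator emulates the statistical structure of the source cohort, not
knee anatomy: OA-severity-dependent TKR prevalence and class imbalance,
lower KOOS pain in cases than controls, and patient-level KL trajectories
that never regress. Defaults follow the cohort's reported test-split
figures (case rates ~0.4% / 3.9% / 29% in the no / moderate / severe OA
strata; KOOS pain 87.4 +- 16.5 in controls vs 68.7 +- 20.6 in cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TissueSpec",
    "PhantomSpec",
    "TissueAtlas",
    "SubjectRecord",
    "ImagingVolume",
    "NONIMAGING_VARIABLES",
    "generate_atlas",
    "generate_cohort",
    "generate_nonimaging",
    "plant_signal",
    "records_to_frame",
]

Stratum = Literal["none", "moderate", "severe"]

#: Canonical names of the 27 non-imaging variables (clinical, demographic and
#: patient-reported measures screened as TKR risk factors). KOOS pain is one
#: of them and is additionally carried as its own record field for matching.
NONIMAGING_VARIABLES: tuple[str, ...] = (
    "age",
    "comorbidity_score",
    "bmi",
    "arthritis_injections_6mo",
    "education",
    "physician_arthritis_1y",
    "ethnicity",
    "knee_valgus_alignment_deg",
    "income",
    "isometric_leg_strength",
    "nsaid_usage",
    "back_pain_30d",
    "analgesic_usage",
    "difficulty_squatting_7d",
    "systolic_bp",
    "difficulty_kneeling_7d",
    "considering_tkr",
    "baseline_frequent_knee_pain",
    "pase",
    "prior_knee_injury",
    "koos_qol",
    "global_knee_pain_rating",
    "koos_pain",
    "sf12_physical",
    "womac_pain",
    "sf12_mental",
    "womac_disability",
)

# (control mean, case mean, sd) for continuous variables; cases skew toward
# worse function / more pain. Values other than KOOS pain, age and BMI are
# plausible stand-ins: the source study reports only the variable names.
_CONTINUOUS_PARAMS: dict[str, tuple[float, float, float]] = {
    "age": (62.5, 66.3, 9.1),
    "comorbidity_score": (0.6, 1.1, 0.8),
    "bmi": (28.3, 29.6, 4.8),
    "education": (4.0, 3.7, 1.2),
    "ethnicity": (1.2, 1.2, 0.5),
    "knee_valgus_alignment_deg": (-1.0, -2.0, 2.5),
    "income": (5.0, 4.6, 2.0),
    "isometric_leg_strength": (32.0, 27.0, 9.0),
    "systolic_bp": (124.0, 128.0, 15.0),
    "pase": (160.0, 135.0, 60.0),
    "koos_qol": (75.0, 45.0, 20.0),
    "global_knee_pain_rating": (2.0, 5.0, 2.2),
    "sf12_physical": (50.0, 41.0, 9.0),
    "womac_pain": (2.0, 6.5, 3.0),
    "sf12_mental": (54.0, 52.0, 8.5),
    "womac_disability": (7.0, 22.0, 10.0),
}

# (control rate, case rate) for binary items.
_BINARY_PARAMS: dict[str, tuple[float, float]] = {
    "arthritis_injections_6mo": (0.03, 0.15),
    "physician_arthritis_1y": (0.25, 0.70),
    "nsaid_usage": (0.25, 0.55),
    "back_pain_30d": (0.30, 0.45),
    "analgesic_usage": (0.15, 0.40),
    "difficulty_squatting_7d": (0.30, 0.75),
    "difficulty_kneeling_7d": (0.30, 0.75),
    "considering_tkr": (0.02, 0.45),
    "baseline_frequent_knee_pain": (0.35, 0.80),
    "prior_knee_injury": (0.20, 0.35),
}


@dataclass(frozen=True)
class TissueSpec:
    """One labeled anatomic region: an ellipsoid or axis-aligned box."""

    name: str
    geometry: Literal["ellipsoid", "box"]
    center: tuple[int, ...]
    radii: tuple[float, ...]


@dataclass
class PhantomSpec:
    """Everything needed to generate one reproducible synthetic cohort."""

    grid_shape: tuple[int, int, int] = (24, 48, 48)
    tissue_specs: list[TissueSpec] = field(default_factory=list)
    n_patients: int = 50
    visits_per_patient: tuple[int, int] = (1, 3)
    kl_probs: tuple[float, ...] = (0.28, 0.26, 0.20, 0.20, 0.06)
    case_rate_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"none": 0.004, "moderate": 0.039, "severe": 0.29}
    )
    effect_map: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    koos_means: tuple[float, float] = (87.4, 68.7)
    koos_sds: tuple[float, float] = (16.5, 20.6)
    missing_rate: float = 0.05
    tissue_jitter_sd: float = 0.0  # per-visit anatomical intensity variation
    background_intensity: float = 1.0
    # per-tissue base intensity; None -> a default ramp over labels
    tissue_base_intensities: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.kl_probs) != 5:
            raise ValueError("kl_probs must cover KL grades 0-4")
        if abs(sum(self.kl_probs) - 1.0) > 1e-9:
            raise ValueError("kl_probs must sum to 1")
        if any(p < 0 or p > 1 for p in self.kl_probs):
            raise ValueError("kl_probs must lie in [0, 1]")
        for s, p in self.case_rate_by_stratum.items():
            if s not in ("none", "moderate", "severe"):
                raise ValueError(f"unknown stratum {s!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"case rate for {s!r} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        names = [t.name for t in self.tissue_specs]
        if len(names) != len(set(names)):
            raise ValueError("tissue names must be unique")
        for t in self.tissue_specs:
            if any(r <= 0 for r in t.radii):
                raise ValueError(f"tissue {t.name!r} has non-positive radii")
            for c, r, s in zip(t.center, t.radii, self.grid_shape):
                if c - r < -0.5 or c + r > s - 0.5:
                    raise ValueError(
                        f"tissue {t.name!r} does not fit inside grid {self.grid_shape}"
                    )


@dataclass
class TissueAtlas:
    """Integer-labeled grid mapping voxels to named regions; 0 = background."""

    label_grid: np.ndarray
    names: dict[int, str]

    def mask(self, tissue: str) -> np.ndarray:
        for label, name in self.names.items():
            if name == tissue:
                return self.label_grid == label
        raise KeyError(f"unknown tissue {tissue!r}")

    @property
    def tissues(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]


@dataclass
class SubjectRecord:
    """One clinic visit of one patient."""

    patient_id: str
    visit_time: float
    kl_grade: int
    stratum: Stratum
    tkr_time: Optional[float]
    label: Literal["case", "control"]
    nonimaging: dict[str, float]
    koos_pain: float
    split: Optional[Literal["train", "val", "test"]] = None


@dataclass
class ImagingVolume:
    """A 3D (or 2D) intensity grid tied to a subject visit."""

    intensities: np.ndarray
    subject_ref: tuple[str, float]
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)


def stratum_of(kl_grade: int) -> Stratum:
    """OA stratum from KL grade: none (0-1), moderate (2-3), severe (4)."""
    if kl_grade in (0, 1):
        return "none"
    if kl_grade in (2, 3):
        return "moderate"
    if kl_grade == 4:
        return "severe"
    raise ValueError(f"KL grade must be 0-4, got {kl_grade}")


def _region_mask(grid_shape, tissue: TissueSpec) -> np.ndarray:
    coords = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    if tissue.geometry == "ellipsoid":
        acc = np.zeros(grid_shape)
        for ax, (c, r) in enumerate(zip(tissue.center, tissue.radii)):
            acc = acc + ((coords[ax] - c) / r) ** 2
        return acc <= 1.0
    if tissue.geometry == "box":
        mask = np.ones(grid_shape, dtype=bool)
        for ax, (c, r) in enumerate(zip(tissue.center, tissue.radii)):
            mask &= (np.abs(coords[ax] - c) <= r) | np.zeros(grid_shape, dtype=bool)
        return mask
    raise ValueError(f"unknown geometry {tissue.geometry!r}")


def generate_atlas(spec: PhantomSpec) -> TissueAtlas:
    """Build the labeled atlas; one region per tissue spec, regions disjoint.

    Raises if two regions overlap, naming the colliding tissues.
    """
    grid = np.zeros(spec.grid_shape, dtype=np.int32)
    names: dict[int, str] = {}
    for label, tissue in enumerate(spec.tissue_specs, start=1):
        mask = _region_mask(spec.grid_shape, tissue)
        clash = np.unique(grid[mask])
        clash = clash[clash > 0]
        if clash.size:
            other = ", ".join(names[int(c)] for c in clash)
            raise ValueError(
                f"tissue {tissue.name!r} overlaps previously placed region(s): {other}"
            )
        grid[mask] = label
        names[label] = tissue.name
    return TissueAtlas(label_grid=grid, names=names)


def plant_signal(
    volume: ImagingVolume,
    atlas: TissueAtlas,
    effect_map: dict[str, float],
    label: str,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> ImagingVolume:
    """Add the case-specific tissue signal and voxelwise Gaussian noise.

    Cases get each named tissue's additive intensity shift; controls are
    unshifted. Independent noise with sd ``noise_sd`` is added everywhere
    for both labels.
    """
    out = volume.intensities.astype(np.float64).copy()
    if label == "case":
        for tissue, effect in effect_map.items():
            out[atlas.mask(tissue)] += effect  # KeyError-> raised by mask()
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return ImagingVolume(out, volume.subject_ref, volume.spacing)


def generate_nonimaging(
    record: SubjectRecord, spec: PhantomSpec, rng: np.random.Generator
) -> dict[str, float]:
    """Draw the 27 non-imaging values for one record.

    KOOS pain comes from the label's (mean, sd) in ``spec`` clipped to
    [0, 100]; the other continuous variables are label-shifted Gaussians and
    the binary items label-shifted Bernoullis. Each value is then
    independently set missing (NaN) with probability ``spec.missing_rate``.
    """
    is_case = record.label == "case"
    values: dict[str, float] = {}
    for name in NONIMAGING_VARIABLES:
        if name == "koos_pain":
            mean = spec.koos_means[1] if is_case else spec.koos_means[0]
            sd = spec.koos_sds[1] if is_case else spec.koos_sds[0]
            values[name] = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
        elif name in _BINARY_PARAMS:
            p_ctrl, p_case = _BINARY_PARAMS[name]
            values[name] = float(rng.random() < (p_case if is_case else p_ctrl))
        else:
            m_ctrl, m_case, sd = _CONTINUOUS_PARAMS[name]
            values[name] = float(rng.normal(m_case if is_case else m_ctrl, sd))
    if spec.missing_rate > 0:
        for name in NONIMAGING_VARIABLES:
            if rng.random() < spec.missing_rate:
                values[name] = float("nan")
    return values


def _base_anatomy(spec: PhantomSpec, atlas: TissueAtlas) -> np.ndarray:
    # deterministic base anatomy; the default ramp gives each tissue a
    # distinct brightness so quantization has a well-populated range
    base = np.full(spec.grid_shape, spec.background_intensity)
    for label in sorted(atlas.names):
        if spec.tissue_base_intensities is None:
            value = 3.0 + 1.5 * label
        else:
            value = spec.tissue_base_intensities.get(
                atlas.names[label], spec.background_intensity
            )
        base[atlas.label_grid == label] = value
    return base


def generate_cohort(
    spec: PhantomSpec,
) -> tuple[list[SubjectRecord], list[ImagingVolume], TissueAtlas]:
    """Generate the full cohort: records, one volume per visit, and the atlas.

    Per patient: visit times are integer years 0..v-1 (v drawn from
    ``visits_per_patient``); KL grades are iid draws from ``kl_probs``
    sorted ascending, so severity never regresses within a patient. Per
    visit: the case label is Bernoulli with the stratum's rate; cases get
    ``tkr_time = visit_time + U(0.5, 5.0)``, 10% of controls a late event
    ``visit_time + U(5.5, 12)`` and the rest none. Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = generate_atlas(spec)
    base = _base_anatomy(spec, atlas)
    records: list[SubjectRecord] = []
    volumes: list[ImagingVolume] = []
    width = len(str(spec.n_patients))
    for i in range(spec.n_patients):
        pid = f"P{i:0{width}d}"
        lo, hi = spec.visits_per_patient
        n_visits = int(rng.integers(lo, hi + 1))
        kl_grades = np.sort(rng.choice(5, size=n_visits, p=spec.kl_probs))
        for visit, kl in enumerate(kl_grades):
            stratum = stratum_of(int(kl))
            visit_time = float(visit)
            is_case = rng.random() < spec.case_rate_by_stratum[stratum]
            if is_case:
                tkr_time = visit_time + float(rng.uniform(0.5, 5.0))
            elif rng.random() < 0.10:
                tkr_time = visit_time + float(rng.uniform(5.5, 12.0))
            else:
                tkr_time = None
            record = SubjectRecord(
                patient_id=pid,
                visit_time=visit_time,
                kl_grade=int(kl),
                stratum=stratum,
                tkr_time=tkr_time,
                label="case" if is_case else "control",
                nonimaging={},
                koos_pain=float("nan"),
            )
            record.nonimaging = generate_nonimaging(record, spec, rng)
            koos = record.nonimaging["koos_pain"]
            if np.isnan(koos):  # the record-level field is never missing
                mean = spec.koos_means[1] if is_case else spec.koos_means[0]
                sd = spec.koos_sds[1] if is_case else spec.koos_sds[0]
                koos = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
            record.koos_pain = koos
            records.append(record)
            anatomy = base.copy()
            if spec.tissue_jitter_sd > 0:
                # anatomical variability: each tissue's brightness varies
                # per visit around its nominal value
                for label in atlas.names:
                    anatomy[atlas.label_grid == label] += rng.normal(
                        0.0, spec.tissue_jitter_sd
                    )
            vol = ImagingVolume(anatomy, (pid, visit_time))
            volumes.append(
                plant_signal(
                    vol, atlas, spec.effect_map, record.label, rng, spec.noise_sd
                )
            )
    return records, volumes, atlas


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into a visit-level table (one row per visit)."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "visit_time": r.visit_time,
            "kl_grade": r.kl_grade,
            "stratum": r.stratum,
            "tkr_time": r.tkr_time if r.tkr_time is not None else np.nan,
            "label": r.label,
            "koos_pain": r.koos_pain,
            "split": r.split,
        }
        row.update(r.nonimaging)
        rows.append(row)
    return pd.DataFrame(rows)
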