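"""Synthetic study cohorts with the structure of the clinical study.

The emulated study enrols 60 hemophilic-arthropathy patients contributing
146 joints (84 knee, 38 ankle, 10 elbow, 14 hip).  Each joint carries IPSG
soft-tissue grades under three measurement arms — postoperative pathology
(the reference), conventional MRI reading, and MRI reading after Canny-based
contour extraction — plus pre/post radiation-synovectomy synovial volumes
and six-month bleed counts.

Grade bookkeeping is per *assessment* rather than per joint: every lesion
class has its own assessment table whose per-level counts equal the
configured distribution exactly (grades are allocated by seeded permutation,
not sampled).  This lets the default cohort reproduce the source study's
printed count tables verbatim even where those tables do not reconcile with
the joint roster: its effusion table covers 110 of 146 joints (the rest stay
ungraded) and its hemosiderin table holds 148 assessments (two joints are
re-assessed; the extra rows carry a ``repeat`` flag).

The three "groups" are modelled as measurement arms over the same joints,
since the study's per-level comparisons use all joints under each method;
``disjoint_patients=True`` instead partitions patients over arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "VolumeModel",
    "BleedModel",
    "MethodModel",
    "CohortSpec",
    "CohortTable",
    "make_cohort",
    "default_cohort_spec",
    "simulate_volume_pairs",
    "COHORT_COLUMNS",
]

JOINT_TYPES = ("knee", "ankle", "elbow", "hip")
ARMS = ("pathology", "conventional_mri", "canny_mri")
LESIONS = ("effusion", "synovial_hyperplasia", "hemosiderin")

COHORT_COLUMNS = [
    "patient_id", "joint_id", "joint_type", "arm", "repeat",
    "effusion", "synovial_hyperplasia", "hemosiderin",
    "synovial_volume_pre", "synovial_volume_post",
    "bleeds_pre", "bleeds_post", "rs_treated",
]


@dataclass(frozen=True)
class VolumeModel:
    """Lognormal synovial-volume model (mm^3).

    ``post = pre * reduction_factor * eps`` with ``eps`` lognormal, mean 1,
    coefficient of variation ``post_cv``; the reduction factor in (0, 1]
    encodes the post-synovectomy volume decrease multiplicatively.
    """

    pre_mean: float = 45000.0
    pre_cv: float = 0.20
    reduction_factor: float = 0.70
    post_cv: float = 0.20

    def __post_init__(self) -> None:
        if not self.pre_mean > 0:
            raise ValueError("pre_mean must be > 0")
        if not 0 < self.reduction_factor <= 1:
            raise ValueError(
                f"reduction_factor must be in (0, 1], got {self.reduction_factor}"
            )
        if self.pre_cv < 0 or self.post_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass(frozen=True)
class BleedModel:
    """Negative-binomial bleed counts per 6 months, before/after surgery."""

    pre_mean: float = 4.0
    post_mean: float = 1.5
    dispersion: float = 5.0  # NB size; variance = m + m^2/dispersion

    def __post_init__(self) -> None:
        if self.pre_mean < 0 or self.post_mean < 0:
            raise ValueError("bleed means must be >= 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")


@dataclass(frozen=True)
class MethodModel:
    """How a measurement arm's grades relate to pathology.

    kind 'exact': copies pathology.  kind 'confusion': each grade is
    misread with probability ``error_rate`` (one level down; grade 0 is
    overcalled to 1), emulating a reader that blurs adjacent severity
    bands.  kind 'independent': grades drawn i.i.d. from the pathology
    grade distribution, ignoring the joint — the no-association null used
    for test calibration.
    """

    kind: str = "confusion"
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "confusion", "independent"):
            raise ValueError(f"unknown method model kind {self.kind!r}")
        if not 0 <= self.error_rate <= 1:
            raise ValueError(f"error_rate must be in [0, 1], got {self.error_rate}")


@dataclass(frozen=True)
class CohortSpec:
    """Full configuration of a synthetic cohort."""

    joints_per_type: dict = field(
        default_factory=lambda: {"knee": 84, "ankle": 38, "elbow": 10, "hip": 14}
    )
    n_patients: int = 60
    grade_distributions: dict = field(default_factory=dict)
    relaxed_sums: tuple = ()
    volume_model: VolumeModel = field(default_factory=VolumeModel)
    bleed_model: BleedModel = field(default_factory=BleedModel)
    arm_models: dict = field(
        default_factory=lambda: {
            "conventional_mri": MethodModel("confusion", 0.25),
            "canny_mri": MethodModel("confusion", 0.05),
        }
    )
    pathology_sampling: str = "permutation"
    rs_subgroup_size: int = 42
    disjoint_patients: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for jt, n in self.joints_per_type.items():
            if jt not in JOINT_TYPES:
                raise ValueError(f"unknown joint type {jt!r}")
            if n < 0:
                raise ValueError(f"negative joint count for {jt}")
        if self.pathology_sampling not in ("permutation", "multinomial"):
            raise ValueError(
                f"unknown pathology_sampling {self.pathology_sampling!r}"
            )
        n = self.n_joints
        for lesion, dist in self.grade_distributions.items():
            if any(c < 0 for c in dist.values()):
                raise ValueError(f"negative grade count in {lesion}")
            s = sum(dist.values())
            if s != n and lesion not in self.relaxed_sums:
                raise ValueError(
                    f"{lesion} grade counts sum to {s} but the cohort has "
                    f"{n} joints; add {lesion!r} to relaxed_sums to keep the "
                    "counts verbatim anyway"
                )
        if not 0 <= self.rs_subgroup_size <= n:
            raise ValueError("rs_subgroup_size must be within the cohort")

    @property
    def n_joints(self) -> int:
        return sum(self.joints_per_type.values())


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The source study's cohort verbatim.

    146 joints (84/38/10/14); effusion graded (14, 59, 37) at levels
    (0, 1, 2) — level 2 stands for the study's combined 2~3 band;
    synovial hyperplasia (15, 50, 27, 54) and hemosiderin (36, 46, 22, 44)
    at levels (0, 1, 2, 3).  The effusion and hemosiderin tables do not sum
    to 146 in the source (110 and 148); they are kept verbatim with the
    sum check relaxed for those two classes.
    """
    base = dict(
        joints_per_type={"knee": 84, "ankle": 38, "elbow": 10, "hip": 14},
        grade_distributions={
            "effusion": {0: 14, 1: 59, 2: 37},
            "synovial_hyperplasia": {0: 15, 1: 50, 2: 27, 3: 54},
            "hemosiderin": {0: 36, 1: 46, 2: 22, 3: 44},
        },
        relaxed_sums=("effusion", "hemosiderin"),
        seed=seed,
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass(frozen=True)
class CohortTable:
    """A generated cohort: per-joint table plus per-lesion assessments.

    ``joints`` has one row per joint; ``assessments`` one row per graded
    assessment with columns for every arm's grade.
    """

    joints: pd.DataFrame
    assessments: pd.DataFrame
    spec: CohortSpec

    def grade_counts(self, lesion: str, arm: str) -> dict:
        """Per-level grade counts for one lesion class under one arm."""
        sub = self.assessments[self.assessments["lesion"] == lesion]
        vc = sub[arm].value_counts().sort_index()
        return {int(k): int(v) for k, v in vc.items()}

    def arm_grades(self, lesion: str, arm: str) -> np.ndarray:
        sub = self.assessments[self.assessments["lesion"] == lesion]
        return sub[arm].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: one row per (joint, arm), plus repeat-assessment
        rows, with the fixed column set ``COHORT_COLUMNS``."""
        rows = []
        grade_of = {}
        for lesion in LESIONS:
            sub = self.assessments[
                (self.assessments["lesion"] == lesion)
                & (self.assessments["repeat"] == 0)
            ]
            for arm in ARMS:
                grade_of[(lesion, arm)] = dict(zip(sub["joint_id"], sub[arm]))
        for _, j in self.joints.iterrows():
            for arm in ARMS:
                row = {
                    "patient_id": j["patient_id"],
                    "joint_id": j["joint_id"],
                    "joint_type": j["joint_type"],
                    "arm": arm,
                    "repeat": 0,
                    "synovial_volume_pre": j["synovial_volume_pre"],
                    "synovial_volume_post": j["synovial_volume_post"],
                    "bleeds_pre": j["bleeds_pre"],
                    "bleeds_post": j["bleeds_post"],
                    "rs_treated": j["rs_treated"],
                }
                for lesion in LESIONS:
                    row[lesion] = grade_of[(lesion, arm)].get(j["joint_id"], np.nan)
                rows.append(row)
        repeats = self.assessments[self.assessments["repeat"] == 1]
        jindex = self.joints.set_index("joint_id")
        for _, a in repeats.iterrows():
            j = jindex.loc[a["joint_id"]]
            for arm in ARMS:
                row = {
                    "patient_id": j["patient_id"],
                    "joint_id": a["joint_id"],
                    "joint_type": j["joint_type"],
                    "arm": arm,
                    "repeat": 1,
                    "synovial_volume_pre": j["synovial_volume_pre"],
                    "synovial_volume_post": j["synovial_volume_post"],
                    "bleeds_pre": j["bleeds_pre"],
                    "bleeds_post": j["bleeds_post"],
                    "rs_treated": j["rs_treated"],
                }
                for lesion in LESIONS:
                    row[lesion] = a[arm] if a["lesion"] == lesion else np.nan
                rows.append(row)
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    def to_csv(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, spec: Optional[CohortSpec] = None,
                 sep: str = "\t") -> "CohortTable":
        """Rebuild joints and assessments from a written cohort table."""
        frame = pd.read_csv(path, sep=sep)
        missing = set(COHORT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        base = frame[(frame["arm"] == "pathology") & (frame["repeat"] == 0)]
        joints = base[[
            "patient_id", "joint_id", "joint_type",
            "synovial_volume_pre", "synovial_volume_post",
            "bleeds_pre", "bleeds_post", "rs_treated",
        ]].reset_index(drop=True)
        arecs = []
        for lesion in LESIONS:
            for rep in (0, 1):
                sel = frame[(frame["repeat"] == rep) & frame[lesion].notna()]
                if sel.empty:
                    continue
                pivot = sel.pivot_table(
                    index=["joint_id"], columns="arm", values=lesion,
                    aggfunc="first", observed=True,
                ) if rep == 0 else None
                if rep == 0:
                    for jid, r in pivot.iterrows():
                        arecs.append({
                            "lesion": lesion, "joint_id": jid, "repeat": 0,
                            **{arm: int(r[arm]) for arm in ARMS},
                        })
                else:
                    path_rows = sel[sel["arm"] == "pathology"]
                    for _, r in path_rows.iterrows():
                        jid = r["joint_id"]
                        rec = {"lesion": lesion, "joint_id": jid, "repeat": 1}
                        for arm in ARMS:
                            v = sel[(sel["arm"] == arm)
                                    & (sel["joint_id"] == jid)][lesion]
                            rec[arm] = int(v.iloc[0])
                        arecs.append(rec)
        assessments = pd.DataFrame(
            arecs, columns=["lesion", "joint_id", "repeat", *ARMS]
        )
        return cls(joints=joints, assessments=assessments,
                   spec=spec if spec is not None else default_cohort_spec())


def simulate_volume_pairs(
    model: VolumeModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (pre, post) synovial-volume pairs from the lognormal model."""
    s2 = math.log1p(model.pre_cv**2)
    mu = math.log(model.pre_mean) - s2 / 2
    pre = rng.lognormal(mu, math.sqrt(s2), size=n)
    t2 = math.log1p(model.post_cv**2)
    eps = rng.lognormal(-t2 / 2, math.sqrt(t2), size=n)
    post = pre * model.reduction_factor * eps
    return pre, post


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             n: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(n, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def _method_grades(pathology: np.ndarray, model: MethodModel, levels: np.ndarray,
                   probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if model.kind == "exact" or (model.kind == "confusion" and model.error_rate == 0):
        return pathology.copy()
    if model.kind == "independent":
        return rng.choice(levels, size=pathology.size, p=probs)
    out = pathology.copy()
    flip = rng.random(pathology.size) < model.error_rate
    out[flip & (out > 0)] -= 1
    out[flip & (pathology == 0)] = 1
    return out


def make_cohort(spec: CohortSpec) -> CohortTable:
    """Generate the cohort; a pure function of the spec including its seed.

    Per-lesion grade counts equal the spec exactly under permutation
    sampling (the default).  Volumes follow the lognormal model with the
    multiplicative post-surgery reduction; bleed counts are negative
    binomial.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_joints

    joint_type = np.repeat(
        [jt for jt in JOINT_TYPES if jt in spec.joints_per_type],
        [spec.joints_per_type[jt] for jt in JOINT_TYPES if jt in spec.joints_per_type],
    )
    joint_id = np.arange(n)
    patient_id = rng.permutation(np.arange(n) % spec.n_patients)

    pre, post = simulate_volume_pairs(spec.volume_model, n, rng)
    bleeds_pre = _nb_draw(rng, spec.bleed_model.pre_mean, spec.bleed_model.dispersion, n)
    bleeds_post = _nb_draw(rng, spec.bleed_model.post_mean, spec.bleed_model.dispersion, n)
    rs_treated = np.zeros(n, dtype=int)
    rs_treated[rng.choice(n, size=spec.rs_subgroup_size, replace=False)] = 1

    joints = pd.DataFrame({
        "patient_id": patient_id,
        "joint_id": joint_id,
        "joint_type": joint_type,
        "synovial_volume_pre": pre,
        "synovial_volume_post": post,
        "bleeds_pre": bleeds_pre,
        "bleeds_post": bleeds_post,
        "rs_treated": rs_treated,
    })

    arm_assignment = None
    if spec.disjoint_patients:
        perm = rng.permutation(spec.n_patients)
        thirds = np.array_split(perm, 3)
        arm_assignment = {
            arm: set(third) for arm, third in zip(ARMS, thirds)
        }

    arecs = []
    for lesion, dist in spec.grade_distributions.items():
        levels = np.array(sorted(dist))
        counts = np.array([dist[l] for l in levels])
        S = int(counts.sum())
        probs = counts / S if S else counts
        if spec.pathology_sampling == "multinomial" and S:
            grades = rng.choice(levels, size=S, p=probs)
        else:
            grades = rng.permutation(np.repeat(levels, counts))
        order = rng.permutation(n)
        if S <= n:
            assessed = order[:S]
            repeat = np.zeros(S, dtype=int)
        else:
            extra = rng.permutation(n)[: S - n]
            assessed = np.concatenate([order, extra])
            repeat = np.concatenate([np.zeros(n, dtype=int),
                                     np.ones(S - n, dtype=int)])
        rec = pd.DataFrame({
            "lesion": lesion,
            "joint_id": assessed,
            "repeat": repeat,
            "pathology": grades.astype(int),
        })
        for arm in ("conventional_mri", "canny_mri"):
            model = spec.arm_models.get(arm, MethodModel("exact"))
            rec[arm] = _method_grades(
                rec["pathology"].to_numpy(), model, levels, probs, rng
            ).astype(int)
        if arm_assignment is not None:
            pat = joints.set_index("joint_id").loc[rec["joint_id"], "patient_id"]
            for arm in ("pathology", "conventional_mri", "canny_mri"):
                keep = pat.isin(arm_assignment[arm]).to_numpy()
                rec.loc[~keep, arm] = np.nan
        arecs.append(rec)

    assessments = (
        pd.concat(arecs, ignore_index=True)
        if arecs
        else pd.DataFrame(columns=["lesion", "joint_id", "repeat", *ARMS])
    )
    return CohortTable(joints=joints, assessments=assessments, spec=spec)
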