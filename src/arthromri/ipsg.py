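"""IPSG MRI scoring of hemophilic arthropathy.

The International Prophylaxis Study Group (IPSG) additive MRI score grades a
joint on two domains:

* soft tissue — joint effusion/bleeding, synovial hyperplasia and
  hemosiderin deposition, each graded 0 (absent), 1 (small), 2 (medium) or
  3 (large), subtotal 0-9;
* osteochondral — eight binary items covering bone erosion, subchondral
  cystic degeneration and cartilage damage, subtotal 0-8.

The total is the sum of the two subtotals, maximum 17.

The qualitative small/medium/large bands are operationalised here as area
fractions of the joint region with configurable cut points; the defaults
(0.01, 0.05, 0.15) are package conventions for phantom work, not clinical
IPSG definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy import ndimage

__all__ = [
    "IPSGScoreCard",
    "GradeThresholds",
    "total_score",
    "grade_from_fraction",
    "score_from_masks",
    "measure_grades_from_raster",
    "SOFT_TISSUE_ITEMS",
    "OSTEOCHONDRAL_ITEMS",
]

SOFT_TISSUE_ITEMS = ("effusion", "synovial_hyperplasia", "hemosiderin")
OSTEOCHONDRAL_ITEMS = (
    "erosion_any_surface",
    "erosion_ge_half_of_bone",
    "cyst_single",
    "cyst_extensive",
    "cartilage_any_damage",
    "cartilage_ge_half_volume",
    "cartilage_focal_full_thickness",
    "cartilage_full_thickness_ge_half_surface",
)


@dataclass(frozen=True)
class IPSGScoreCard:
    """One joint's IPSG item scores."""

    effusion: int = 0
    synovial_hyperplasia: int = 0
    hemosiderin: int = 0
    erosion_any_surface: int = 0
    erosion_ge_half_of_bone: int = 0
    cyst_single: int = 0
    cyst_extensive: int = 0
    cartilage_any_damage: int = 0
    cartilage_ge_half_volume: int = 0
    cartilage_focal_full_thickness: int = 0
    cartilage_full_thickness_ge_half_surface: int = 0

    def __post_init__(self) -> None:
        for name in SOFT_TISSUE_ITEMS:
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise ValueError(f"{name} must be a grade 0-3, got {v!r}")
        for name in OSTEOCHONDRAL_ITEMS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")

    @classmethod
    def maximum(cls) -> "IPSGScoreCard":
        """The all-maximum card (every graded item 3, every binary item 1)."""
        return cls(3, 3, 3, 1, 1, 1, 1, 1, 1, 1, 1)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def total_score(card: IPSGScoreCard) -> tuple[int, int, int]:
    """Return ``(total, soft_tissue_subtotal, osteochondral_subtotal)``.

    Soft tissue sums the three 0-3 grades (max 9); osteochondral sums the
    eight binary items (max 8); the total tops out at 17.
    """
    soft = sum(getattr(card, name) for name in SOFT_TISSUE_ITEMS)
    osteo = sum(getattr(card, name) for name in OSTEOCHONDRAL_ITEMS)
    return soft + osteo, soft, osteo


@dataclass(frozen=True)
class GradeThresholds:
    """Area-fraction cut points mapping lesion extent to grades 0-3.

    fraction < floor -> 0; [floor, cut1) -> 1; [cut1, cut2) -> 2;
    >= cut2 -> 3.  Fractions are lesion area over joint-region area.
    """

    floor: float = 0.01
    cut1: float = 0.05
    cut2: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.floor < self.cut1 < self.cut2 < 1:
            raise ValueError(
                f"need 0 <= floor < cut1 < cut2 < 1, got "
                f"({self.floor}, {self.cut1}, {self.cut2})"
            )


def grade_from_fraction(
    area_fraction: float, thresholds: GradeThresholds = GradeThresholds()
) -> int:
    """Map a lesion area fraction to a 0-3 grade (half-open bands)."""
    if not 0 <= area_fraction <= 1:
        raise ValueError(f"area fraction must be in [0, 1], got {area_fraction}")
    if area_fraction < thresholds.floor:
        return 0
    if area_fraction < thresholds.cut1:
        return 1
    if area_fraction < thresholds.cut2:
        return 2
    return 3


def _bool(mask) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def _components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))


def score_from_masks(
    masks: dict,
    thresholds: GradeThresholds = GradeThresholds(),
) -> IPSGScoreCard:
    """Score a joint from binary lesion masks.

    ``masks`` maps names to equal-shape binary rasters.  Required:
    ``joint_region`` (nonempty).  Soft-tissue grades come from the area
    fractions of ``effusion``, ``synovium`` and ``hemosiderin`` within the
    joint region.  Osteochondral items come from overlap rules against
    ``bones`` (a list of per-bone masks, or a single ``bone`` mask):

    * erosion touching the one-pixel cortical boundary of any bone scores
      ``erosion_any_surface``; erosion covering >= 50 % of one bone scores
      ``erosion_ge_half_of_bone``;
    * any cyst component scores ``cyst_single``; cysts reaching more than
      two bones or more than 1/3 of a single bone score ``cyst_extensive``;
    * ``cartilage_damage`` overlapping ``cartilage`` scores
      ``cartilage_any_damage``; >= 50 % of the cartilage of one bone scores
      ``cartilage_ge_half_volume``; a damage component bridging the
      cartilage band from the bone side to the exterior is full-thickness,
      scoring the focal item, and the half-surface item when such damage
      covers >= 50 % of a bone's cartilage.
    """
    if "joint_region" not in masks:
        raise ValueError("masks must include 'joint_region'")
    joint = _bool(masks["joint_region"])
    joint_area = int(joint.sum())
    if joint_area == 0:
        raise ValueError("joint region mask is empty")
    shapes = {np.asarray(m).shape for m in masks.values() if not isinstance(m, list)}
    shapes |= {np.asarray(m).shape for v in masks.values() if isinstance(v, list) for m in v}
    if len(shapes) > 1:
        raise ValueError(f"masks have inconsistent shapes: {shapes}")

    def fraction(name: str) -> float:
        if name not in masks:
            return 0.0
        return float(_bool(masks[name]).sum()) / joint_area

    grades = {
        "effusion": grade_from_fraction(min(fraction("effusion"), 1.0), thresholds),
        "synovial_hyperplasia": grade_from_fraction(
            min(fraction("synovium"), 1.0), thresholds
        ),
        "hemosiderin": grade_from_fraction(
            min(fraction("hemosiderin"), 1.0), thresholds
        ),
    }

    if "bones" in masks:
        bones = [_bool(b) for b in masks["bones"]]
    elif "bone" in masks:
        bones = [_bool(masks["bone"])]
    else:
        bones = []

    binaries = dict.fromkeys(OSTEOCHONDRAL_ITEMS, 0)

    erosion = _bool(masks["erosion"]) if "erosion" in masks else None
    if erosion is not None and erosion.any() and bones:
        for bone in bones:
            if not bone.any():
                continue
            boundary = bone & ~ndimage.binary_erosion(bone)
            if (erosion & ndimage.binary_dilation(boundary)).any():
                binaries["erosion_any_surface"] = 1
            if (erosion & bone).sum() >= 0.5 * bone.sum():
                binaries["erosion_ge_half_of_bone"] = 1

    cyst = _bool(masks["cyst"]) if "cyst" in masks else None
    if cyst is not None and cyst.any():
        binaries["cyst_single"] = 1
        if bones:
            touched = sum(1 for b in bones if (cyst & b).any())
            frac_max = max(
                ((cyst & b).sum() / b.sum()) for b in bones if b.any()
            )
            if touched > 2 or frac_max > 1.0 / 3.0:
                binaries["cyst_extensive"] = 1

    cartilage = masks.get("cartilage")
    damage = _bool(masks["cartilage_damage"]) if "cartilage_damage" in masks else None
    if cartilage is not None and damage is not None and damage.any():
        carts = [_bool(c) for c in cartilage] if isinstance(cartilage, list) else [
            _bool(cartilage)
        ]
        union_cart = np.zeros_like(damage)
        for c in carts:
            union_cart |= c
        hit = damage & union_cart
        if hit.any():
            binaries["cartilage_any_damage"] = 1
            for c in carts:
                if c.any() and (damage & c).sum() >= 0.5 * c.sum():
                    binaries["cartilage_ge_half_volume"] = 1
            # full thickness: a damage component inside cartilage that touches
            # both the bone side and the exterior of the cartilage band
            bone_union = np.zeros_like(damage)
            for b in bones:
                bone_union |= b
            exterior = ~(union_cart | bone_union)
            labels, n = _components(hit)
            full = np.zeros_like(hit)
            for i in range(1, n + 1):
                comp = labels == i
                dil = ndimage.binary_dilation(comp)
                if (dil & bone_union).any() and (dil & exterior).any():
                    binaries["cartilage_focal_full_thickness"] = 1
                    full |= comp
            if full.any():
                for c in carts:
                    if c.any() and (full & c).sum() >= 0.5 * c.sum():
                        binaries["cartilage_full_thickness_ge_half_surface"] = 1

    return IPSGScoreCard(**grades, **binaries)


@dataclass(frozen=True)
class IntensityBands:
    """Intensity windows used to segment soft-tissue lesions from a raster.

    Defaults match the phantom renderer's tissue intensities (8-bit):
    hemosiderin near zero, synovium mid-gray, effusion bright fluid.
    """

    hemosiderin_max: float = 30.0
    synovium_low: float = 85.0
    synovium_high: float = 135.0
    effusion_min: float = 215.0


def measure_grades_from_raster(
    pixels: np.ndarray,
    joint_region: np.ndarray,
    thresholds: GradeThresholds = GradeThresholds(),
    bands: IntensityBands = IntensityBands(),
) -> dict:
    """Grade soft-tissue lesions by intensity-band segmentation.

    This is the *measured* pathway (what a reading of the raster yields),
    distinct from scoring ground-truth masks; the two agree on clean
    phantoms and diverge under noise.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    joint = _bool(joint_region)
    area = int(joint.sum())
    if area == 0:
        raise ValueError("joint region mask is empty")
    hemo = joint & (arr <= bands.hemosiderin_max)
    syno = joint & (arr >= bands.synovium_low) & (arr <= bands.synovium_high)
    effu = joint & (arr >= bands.effusion_min)
    return {
        "effusion": grade_from_fraction(effu.sum() / area, thresholds),
        "synovial_hyperplasia": grade_from_fraction(syno.sum() / area, thresholds),
        "hemosiderin": grade_from_fraction(hemo.sum() / area, thresholds),
    }
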