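"""Provisional health-guidance derivation for dissociating metal salts.

A point of departure from an animal study is divided by uncertainty
factors to give a health-guidance-value (HGV) equivalent for the whole
substance.  Because the salt dissociates on oral exposure, the whole-
substance dose partitions into concurrent metal and organic doses by the
composition weight fractions; comparing each component dose against its
reference value (metal MRL, organic POD-derived reference) identifies the
likely driver of toxicity and supports a provisional exposure limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import MissingDataError
from .rounding import round_sig
from .salt_composition import CompositionResult, MetalSpec

__all__ = [
    "PodType",
    "ToxStudy",
    "UncertaintyFactors",
    "Driver",
    "DriverVerdict",
    "LimitRecommendation",
    "AssessmentResult",
    "derive_hgv",
    "partition_dose",
    "determine_driver",
    "recommend_limit",
    "assess_metal_naphthenate",
    "DEFAULT_NAPHTHENATE_REFERENCE",
]

#: Default organic-component reference dose (mg/kg/day): lower bound of the
#: predicted chronic rat POD range (25 mg/kg/day) divided by 10 x 10
#: uncertainty factors.  Override with an experimental value when one exists.
DEFAULT_NAPHTHENATE_REFERENCE = 25.0 / 100.0


class PodType(str, Enum):
    NOAEL = "NOAEL"
    LOAEL = "LOAEL"
    BMDL = "BMDL"


@dataclass(frozen=True)
class ToxStudy:
    substance: str
    pod_type: PodType
    pod: float  # mg/kg/day
    species: str = ""
    endpoint: str = ""
    citation: str = ""

    def __post_init__(self):
        if self.pod <= 0:
            raise ValueError("POD must be positive")


@dataclass(frozen=True)
class UncertaintyFactors:
    """Multiplicative uncertainty factors; each must be >= 1."""

    interspecies: float = 10.0
    intrahuman: float = 10.0
    other: dict = field(default_factory=dict)

    def __post_init__(self):
        for label, f in self.as_dict().items():
            if f < 1:
                raise ValueError(f"uncertainty factor {label} must be >= 1, got {f}")

    def as_dict(self) -> dict:
        return {
            "interspecies": self.interspecies,
            "intrahuman": self.intrahuman,
            **self.other,
        }

    @property
    def product(self) -> float:
        p = 1.0
        for f in self.as_dict().values():
            p *= f
        return p

    @classmethod
    def none(cls) -> "UncertaintyFactors":
        return cls(interspecies=1.0, intrahuman=1.0)


class Driver(str, Enum):
    METAL = "metal"
    NAPHTHENATE = "naphthenate"
    INDETERMINATE = "indeterminate"


def derive_hgv(study: ToxStudy, ufs: UncertaintyFactors) -> float:
    """HGV equivalent: POD divided by the product of uncertainty factors.

    The unrounded value is returned; report at 2 significant figures via
    :func:`uvcbkit.rounding.round_sig`.
    """
    return study.pod / ufs.product


def partition_dose(
    whole_dose: float, composition: CompositionResult
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Split a whole-substance dose into metal and organic dose bounds.

    Both ranges are ordered by acid number, so the metal upper bound pairs
    with the naphthenate lower bound and the pairwise sums reassemble the
    whole dose exactly.
    """
    if whole_dose < 0:
        raise ValueError("dose must be non-negative")
    metal = tuple(whole_dose * f for f in composition.metal_fraction)
    naph = tuple(whole_dose * f for f in composition.naphthenate_fraction)
    return metal, naph


@dataclass(frozen=True)
class DriverVerdict:
    driver: Driver
    fold_metal: float | None
    fold_naphthenate: float | None
    metal_dose: tuple[float, float]
    naphthenate_dose: tuple[float, float]
    equivalence_band: float


def determine_driver(
    metal_dose_range: tuple[float, float],
    metal_mrl: float | None,
    naphthenate_dose_range: tuple[float, float],
    naphthenate_reference: float | None = DEFAULT_NAPHTHENATE_REFERENCE,
    equivalence_band: float = 0.2,
) -> DriverVerdict:
    """Compare fold-exceedances of component doses over their references.

    Folds are computed on dose-range midpoints; the component with the
    larger fold is the predicted driver.  When both folds agree within the
    configurable equivalence band (default +/-20%), or only one reference
    is available, the verdict is the available/indeterminate case.
    """
    if metal_mrl is None and naphthenate_reference is None:
        raise MissingDataError("need at least one reference value")
    fold_metal = None
    fold_naph = None
    if metal_mrl is not None:
        fold_metal = (sum(metal_dose_range) / 2) / metal_mrl
    if naphthenate_reference is not None:
        fold_naph = (sum(naphthenate_dose_range) / 2) / naphthenate_reference
    if fold_metal is None:
        driver = Driver.NAPHTHENATE
    elif fold_naph is None:
        driver = Driver.METAL
    else:
        hi, lo = max(fold_metal, fold_naph), min(fold_metal, fold_naph)
        if lo > 0 and hi / lo <= 1 + equivalence_band:
            driver = Driver.INDETERMINATE
        elif fold_metal > fold_naph:
            driver = Driver.METAL
        else:
            driver = Driver.NAPHTHENATE
    return DriverVerdict(
        driver=driver,
        fold_metal=fold_metal,
        fold_naphthenate=fold_naph,
        metal_dose=tuple(metal_dose_range),
        naphthenate_dose=tuple(naphthenate_dose_range),
        equivalence_band=equivalence_band,
    )


@dataclass(frozen=True)
class LimitRecommendation:
    basis: str  # "metal" or "naphthenate"
    limit: float  # unrounded whole-substance limit, mg/kg/day
    limit_1sf: float
    limit_2sf: float
    narrative: str


def recommend_limit(
    metal: MetalSpec,
    composition: CompositionResult,
    driver: Driver,
    naphthenate_reference: float | None = DEFAULT_NAPHTHENATE_REFERENCE,
    an_bound: str = "lower",
    reference_is_component_dose: bool = False,
) -> LimitRecommendation:
    """Whole-substance exposure limit scaled from the driver's reference.

    For a metal-driven salt the limit is ``metal MRL / metal weight
    fraction`` at the policy-selected acid-number bound (default the lower
    bound, i.e. the smaller metal fraction, giving the more conservative
    scale-up).  For a naphthenate-driven salt the limit is the organic
    reference divided by the organic weight fraction; when the reference
    is itself a component dose already derived from the whole-substance
    HGV (``reference_is_component_dose=True``), the reference is reported
    directly as the limit rather than rescaled.

    Unrounded, 1-significant-figure, and 2-significant-figure values are
    all reported because printed provisional limits in practice do not
    follow a single rounding rule.
    """
    if an_bound not in ("lower", "upper"):
        raise ValueError("an_bound must be 'lower' or 'upper'")
    idx = 0 if an_bound == "lower" else 1
    if driver == Driver.METAL:
        if metal.mrl is None:
            raise MissingDataError(f"metal {metal.symbol} has no MRL")
        fraction = composition.metal_fraction[idx]
        limit = metal.mrl / fraction
        narrative = (
            f"Based on {metal.name or metal.symbol} exposure: metal MRL "
            f"{metal.mrl} mg/kg/day divided by the metal weight fraction "
            f"{fraction:.4f} at acid number "
            f"{getattr(composition.acid_numbers, an_bound)} mg KOH/g."
        )
        basis = "metal"
    elif driver == Driver.NAPHTHENATE:
        if naphthenate_reference is None:
            raise MissingDataError("no naphthenate reference available")
        fraction = composition.naphthenate_fraction[idx]
        if reference_is_component_dose:
            limit = naphthenate_reference
            narrative = (
                f"Based on naphthenates: the organic component dose "
                f"{naphthenate_reference:.4f} mg/kg/day derived from the "
                "whole-substance HGV is adopted directly as the provisional limit."
            )
        else:
            limit = naphthenate_reference / fraction
            narrative = (
                f"Based on naphthenates: organic reference "
                f"{naphthenate_reference} mg/kg/day divided by the naphthenate "
                f"weight fraction {fraction:.4f} at acid number "
                f"{getattr(composition.acid_numbers, an_bound)} mg KOH/g."
            )
        basis = "naphthenate"
    else:
        raise MissingDataError("driver is indeterminate; no limit basis")
    return LimitRecommendation(
        basis=basis,
        limit=limit,
        limit_1sf=round_sig(limit, 1),
        limit_2sf=round_sig(limit, 2),
        narrative=narrative,
    )


@dataclass(frozen=True)
class AssessmentResult:
    """Full per-salt assessment mirroring a summary-table row."""

    metal: MetalSpec
    composition: CompositionResult
    study: ToxStudy | None
    hgv_equivalent: float | None
    metal_dose: tuple[float, float] | None
    naphthenate_dose: tuple[float, float] | None
    verdict: DriverVerdict | None
    recommendation: LimitRecommendation | None

    def to_dict(self) -> dict:
        d = {
            "metal": self.metal.symbol,
            "metal_percent": self.composition.metal_percent(),
            "naphthenate_percent": self.composition.naphthenate_percent(),
            "metal_mrl": self.metal.mrl,
        }
        if self.study is not None:
            d["pod"] = self.study.pod
            d["pod_type"] = self.study.pod_type.value
        if self.hgv_equivalent is not None:
            d["hgv_equivalent"] = round_sig(self.hgv_equivalent, 2)
        if self.metal_dose is not None:
            d["metal_dose"] = tuple(round_sig(x, 2) for x in self.metal_dose)
            d["naphthenate_dose"] = tuple(round_sig(x, 2) for x in self.naphthenate_dose)
        if self.verdict is not None:
            d["driver"] = self.verdict.driver.value
            d["fold_metal"] = self.verdict.fold_metal
            d["fold_naphthenate"] = self.verdict.fold_naphthenate
        if self.recommendation is not None:
            d["limit"] = self.recommendation.limit
            d["limit_1sf"] = self.recommendation.limit_1sf
            d["limit_2sf"] = self.recommendation.limit_2sf
            d["limit_basis"] = self.recommendation.basis
            d["narrative"] = self.recommendation.narrative
        return d


def assess_metal_naphthenate(
    metal: MetalSpec,
    composition: CompositionResult,
    study: ToxStudy | None = None,
    ufs: UncertaintyFactors | None = None,
    whole_dose: float | None = None,
    naphthenate_reference: float | None = DEFAULT_NAPHTHENATE_REFERENCE,
    equivalence_band: float = 0.2,
) -> AssessmentResult:
    """End-to-end assessment of one metal naphthenate.

    When a study is given, the HGV equivalent is derived and its reported
    (2-significant-figure) value is used as the whole-substance dose
    (unless ``whole_dose`` overrides it); the dose is partitioned, the
    driver determined, and a provisional limit derived from the driver's
    reference.  Partitioning the reported rather than the unrounded HGV
    matches standard guidance-value practice, where the published HGV is
    the quantity carried forward.
    """
    ufs = ufs or UncertaintyFactors()
    hgv = derive_hgv(study, ufs) if study is not None else None
    if whole_dose is not None:
        dose = whole_dose
    elif hgv is not None:
        dose = round_sig(hgv, 2)
    else:
        dose = None
    metal_dose = naph_dose = verdict = rec = None
    if dose is not None:
        metal_dose, naph_dose = partition_dose(dose, composition)
        verdict = determine_driver(
            metal_dose,
            metal.mrl,
            naph_dose,
            naphthenate_reference,
            equivalence_band=equivalence_band,
        )
        if verdict.driver == Driver.NAPHTHENATE:
            # adopt the organic component dose at the upper bound as the
            # provisional anchor (experimental whole-substance study scaled
            # by composition), rather than rescaling an external reference
            rec = recommend_limit(
                metal,
                composition,
                verdict.driver,
                naphthenate_reference=max(naph_dose),
                reference_is_component_dose=True,
            )
        elif verdict.driver == Driver.METAL:
            rec = recommend_limit(metal, composition, verdict.driver)
    return AssessmentResult(
        metal=metal,
        composition=composition,
        study=study,
        hgv_equivalent=hgv,
        metal_dose=metal_dose,
        naphthenate_dose=naph_dose,
        verdict=verdict,
        recommendation=rec,
    )
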