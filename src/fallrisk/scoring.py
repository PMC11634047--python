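"""Multifactorial Fall Risk Score (FRS) computation.

The FRS summarises the presence of intrinsic and extrinsic fall-risk factors
on a 0-100 scale: 0 means no catalogued factor is present, 100 means every
catalogued factor is present.  Factors established as strong predictors in
classical inpatient fall-risk instruments (e.g. STRATIFY, Hendrich II,
Downton) carry double weight; the remaining factors carry single weight.
The score is the weighted fraction of present factors:

    FRS = 100 * sum(w_i * present_i) / sum(w_i)

which is the only normalisation consistent with both scale anchors and is
invariant under rescaling all weights by a common positive constant.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Factors assigned double weight (established high-impact predictors).
DOUBLE_WEIGHTED_FACTORS: tuple[str, ...] = (
    "limited_mobility",
    "dizziness",
    "visual_auditory_impairment",
    "medication_use",
    "cognitive_impairment",
    "depression",
    "urge_incontinence",
    "fall_history",
    "restlessness",
)

#: Factors assigned single weight.
SINGLE_WEIGHTED_FACTORS: tuple[str, ...] = (
    "mobility_limiting_comorbidity",
    "foot_disorders",
    "syncope_conditions",
    "fear_of_falling",
    "walking_aid_use",
    "environmental_hazards",
)

#: Gait speed (m/s) below which the gait analysis flags "limited_mobility".
#: Matches the slow-walker cut used in the subgroup analyses.
SLOW_GAIT_CUTOFF = 0.6


class CatalogMismatchError(KeyError):
    """A profile references a factor that is not in the weight catalog."""


class InvalidWeightConfigError(ValueError):
    """The weight configuration is empty or contains invalid weights."""


@dataclass(frozen=True)
class WeightConfig:
    """Catalog of risk factors and their positive weights.

    Parameters
    ----------
    weights
        Mapping from factor name to positive weight.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise InvalidWeightConfigError("factor catalog is empty")
        bad = {k: w for k, w in self.weights.items() if not w > 0}
        if bad:
            raise InvalidWeightConfigError(f"non-positive weights: {bad}")

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.weights)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    @classmethod
    def default(cls) -> "WeightConfig":
        """The default double/single catalog (9 double + 6 single factors)."""
        w: dict[str, float] = {f: 2.0 for f in DOUBLE_WEIGHTED_FACTORS}
        w.update({f: 1.0 for f in SINGLE_WEIGHTED_FACTORS})
        return cls(w)

    @classmethod
    def from_json(cls, source: str | Path) -> "WeightConfig":
        """Load ``{"factors": [{"name": ..., "weight": ...}, ...]}`` from a
        JSON document string or a path to one."""
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        doc = json.loads(text)
        try:
            weights = {f["name"]: float(f["weight"]) for f in doc["factors"]}
        except (KeyError, TypeError) as exc:
            raise InvalidWeightConfigError(f"malformed weight document: {exc}") from exc
        if len(weights) != len(doc["factors"]):
            raise InvalidWeightConfigError("duplicate factor names in document")
        return cls(weights)

    def to_json(self) -> str:
        return json.dumps(
            {"factors": [{"name": k, "weight": w} for k, w in self.weights.items()]},
            indent=2,
        )


@dataclass
class RiskFactorProfile:
    """Presence/absence flags for one assessment, keyed by factor name.

    Flags must be strictly boolean.  ``None`` (unknown) is resolved to absent
    with a warning, mirroring the conservative fallback used when a factor
    cannot be collected for a resident.
    """

    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        resolved: dict[str, bool] = {}
        for name, value in self.flags.items():
            if value is None:
                warnings.warn(
                    f"unknown flag for factor {name!r} treated as absent",
                    stacklevel=3,
                )
                value = False
            if not isinstance(value, (bool,)):
                raise TypeError(f"flag for {name!r} must be boolean, got {value!r}")
            resolved[name] = value
        self.flags = resolved

    @property
    def present(self) -> frozenset[str]:
        return frozenset(k for k, v in self.flags.items() if v)


def profile_from_flags(
    present: Iterable[str], catalog: WeightConfig
) -> RiskFactorProfile:
    """Build a profile with the given factors present, all others absent."""
    present = set(present)
    return RiskFactorProfile({f: f in present for f in catalog.factors})


def apply_gait_rule(
    profile: RiskFactorProfile,
    gait_speed: float,
    cutoff: float = SLOW_GAIT_CUTOFF,
) -> RiskFactorProfile:
    """Flag ``limited_mobility`` when measured gait speed falls below ``cutoff``.

    Gait parameters arrive from the upstream video analysis as a plain speed
    column; this is the default mapping from that measurement into the factor
    catalog and can be replaced by any callable of the same shape.
    """
    flags = dict(profile.flags)
    if gait_speed < cutoff:
        flags["limited_mobility"] = True
    return RiskFactorProfile(flags)


def compute_frs(profile: RiskFactorProfile, weights: WeightConfig) -> float:
    """Score a risk-factor profile on the 0-100 FRS scale.

    Returns ``100 * (weight of present factors) / (total catalog weight)``.

    Raises
    ------
    CatalogMismatchError
        If the profile flags a factor that the catalog does not define.
    """
    unknown = set(profile.flags) - set(weights.factors)
    if unknown:
        raise CatalogMismatchError(
            f"profile factors not in catalog: {sorted(unknown)}"
        )
    present_weight = sum(weights.weights[f] for f in profile.present)
    return 100.0 * present_weight / weights.total_weight
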