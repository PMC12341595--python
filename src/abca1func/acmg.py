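"""ACMG/AMP evidence evaluation and five-tier classification for ABCA1.

Implements the standard evidence-combining tables over criteria weighed as
supporting, moderate, strong, very strong or stand-alone, plus the
gene-specific calibrations used here:

* frequency criteria from the filtering allele frequency
  (BA1 >= 0.005, BS1 >= 0.002, PM2 <= 0.0002);
* the tiered phenotype criterion PP4 from the carrier's HDL-C
  (supporting < 0.5, moderate < 0.3, strong < 0.1 mmol/l or Tangier disease);
* functional-assay evidence PS3 (loss-of-function) / BS3 (functionally
  normal) at the strength permitted by the assay-validation rule — moderate
  when the assay has normal and null controls, replicates and at least 11
  class-1/2/4/5 variant controls, supporting otherwise. A benign criterion
  applied at moderate strength counts as two supporting benign criteria.

Conflict handling: evidence pointing both ways resolves to class 3
(uncertain significance). Concretely, a met benign combination with any
pathogenic criterion on the list — or a met pathogenic combination with any
benign criterion — is treated as contradictory. BA1 is stand-alone and
classifies benign regardless. This reading is what lets a rare, functionally
normal variant carrying PM2 remain class 3 after BS3 is added, instead of
dropping to likely benign on two supporting benign criteria alone.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import CalibrationConfig
from .domains import VariantRecord
from .efflux import LOSS_OF_FUNCTION, NORMAL, UNCERTAIN
from .errors import UnknownCriterionError

# five-tier classes
BENIGN, LIKELY_BENIGN, VUS, LIKELY_PATHOGENIC, PATHOGENIC = 1, 2, 3, 4, 5

CLASS_NAMES = {
    1: "benign",
    2: "likely_benign",
    3: "uncertain_significance",
    4: "likely_pathogenic",
    5: "pathogenic",
}

STAND_ALONE = "stand_alone"
VERY_STRONG = "very_strong"
STRONG = "strong"
MODERATE = "moderate"
SUPPORTING = "supporting"

_STRENGTHS = (STAND_ALONE, VERY_STRONG, STRONG, MODERATE, SUPPORTING)
_BENIGN_STRENGTHS = (STAND_ALONE, STRONG, MODERATE, SUPPORTING)

PATHOGENIC_CODES = tuple(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = tuple(["BA1"] + [f"BS{i}" for i in range(1, 5)]
                     + [f"BP{i}" for i in range(1, 8)])

_NATIVE_STRENGTH = {"PVS": VERY_STRONG, "PS": STRONG, "PM": MODERATE,
                    "PP": SUPPORTING, "BA": STAND_ALONE, "BS": STRONG,
                    "BP": SUPPORTING}

_TOKEN_RE = re.compile(r"^([A-Z]+\d)(?:_([a-z_]+))?$")

ASSERTED = "asserted"
FREQUENCY_RULE = "frequency_rule"
PHENOTYPE_RULE = "phenotype_rule"
FUNCTIONAL_ASSAY = "functional_assay"


def native_strength(code: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _NATIVE_STRENGTH[prefix]
    raise UnknownCriterionError(f"unknown criterion code: {code!r}")


@dataclass(frozen=True)
class CriterionEvidence:
    """One ACMG criterion with its applied strength and provenance."""

    code: str
    strength: str = ""
    source: str = ASSERTED

    def __post_init__(self) -> None:
        if self.code not in PATHOGENIC_CODES and self.code not in BENIGN_CODES:
            raise UnknownCriterionError(f"unknown criterion code: {self.code!r}")
        strength = self.strength or native_strength(self.code)
        object.__setattr__(self, "strength", strength)
        if strength not in _STRENGTHS:
            raise UnknownCriterionError(
                f"unknown strength {strength!r} for {self.code}"
            )
        if self.is_benign and strength not in _BENIGN_STRENGTHS:
            raise UnknownCriterionError(
                f"benign criterion {self.code} cannot carry strength {strength!r}"
            )
        if not self.is_benign and strength == STAND_ALONE:
            raise UnknownCriterionError(
                f"pathogenic criterion {self.code} cannot be stand-alone"
            )

    @property
    def is_benign(self) -> bool:
        return self.code in BENIGN_CODES

    @property
    def token(self) -> str:
        if self.strength == native_strength(self.code):
            return self.code
        return f"{self.code}_{self.strength}"

    @classmethod
    def from_token(cls, token: str, source: str = ASSERTED) -> "CriterionEvidence":
        """Parse a token such as ``PM2``, ``PP4_strong`` or ``BS3_moderate``."""
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise UnknownCriterionError(f"malformed criterion token: {token!r}")
        code, strength = m.groups()
        return cls(code=code, strength=strength or "", source=source)


@dataclass
class ClassificationResult:
    variant: VariantRecord
    criteria_without: tuple[CriterionEvidence, ...] = ()
    criteria_with: tuple[CriterionEvidence, ...] = ()
    class_without_functional: int = VUS
    class_with_functional: int = VUS
    functional_category: str = UNCERTAIN

    @property
    def changed(self) -> bool:
        return self.class_without_functional != self.class_with_functional


def _tally(criteria: Sequence[CriterionEvidence]) -> tuple[Counter, Counter]:
    """Strength tallies for the pathogenic and benign sides.

    A benign criterion at moderate strength counts as two supporting benign
    criteria (the assay-calibration conversion, applied to any benign code).
    """
    path: Counter = Counter()
    benign: Counter = Counter()
    for c in criteria:
        if c.is_benign:
            if c.strength == MODERATE:
                benign[SUPPORTING] += 2
            else:
                benign[c.strength] += 1
        else:
            path[c.strength] += 1
    return path, benign


def _pathogenic_rules(t: Counter) -> Optional[int]:
    vs, s, m, p = t[VERY_STRONG], t[STRONG], t[MODERATE], t[SUPPORTING]
    if vs >= 2:
        return PATHOGENIC
    if vs == 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2):
        return PATHOGENIC
    if s >= 2:
        return PATHOGENIC
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return PATHOGENIC
    if vs == 1 and m == 1:
        return LIKELY_PATHOGENIC
    if s == 1 and 1 <= m <= 2:
        return LIKELY_PATHOGENIC
    if s == 1 and p >= 2:
        return LIKELY_PATHOGENIC
    if m >= 3:
        return LIKELY_PATHOGENIC
    if m == 2 and p >= 2:
        return LIKELY_PATHOGENIC
    if m == 1 and p >= 4:
        return LIKELY_PATHOGENIC
    return None


def _benign_rules(t: Counter) -> Optional[int]:
    if t[STAND_ALONE] >= 1:
        return BENIGN
    if t[STRONG] >= 2:
        return BENIGN
    if t[STRONG] == 1 and t[SUPPORTING] >= 1:
        return LIKELY_BENIGN
    if t[SUPPORTING] >= 2:
        return LIKELY_BENIGN
    return None


def combine(criteria: Iterable[CriterionEvidence]) -> int:
    """Combine evidence into the five-tier class (1–5).

    Duplicate criterion codes are rejected; the result is order-invariant.
    See the module docstring for the conflict-resolution semantics.
    """
    crit = list(criteria)
    codes = [c.code for c in crit]
    dupes = [c for c, n in Counter(codes).items() if n > 1]
    if dupes:
        raise UnknownCriterionError(f"duplicate criterion codes: {sorted(dupes)}")
    path_t, benign_t = _tally(crit)
    path_class = _pathogenic_rules(path_t)
    benign_class = _benign_rules(benign_t)
    has_path = sum(path_t.values()) > 0
    has_benign = sum(benign_t.values()) > 0

    if benign_t[STAND_ALONE] >= 1:
        return BENIGN  # stand-alone frequency evidence
    if path_class is not None and benign_class is not None:
        return VUS
    if path_class is not None:
        return VUS if has_benign else path_class
    if benign_class is not None:
        return VUS if has_path else benign_class
    return VUS


def frequency_criteria(
    faf: Optional[float], config: CalibrationConfig
) -> Optional[CriterionEvidence]:
    """Frequency-based criterion from the filtering allele frequency, if any."""
    if faf is None:
        return None
    if not (0.0 <= faf <= 1.0):
        raise ValueError(f"allele frequency outside [0, 1]: {faf}")
    if faf >= config.freq_ba1:
        return CriterionEvidence("BA1", source=FREQUENCY_RULE)
    if faf >= config.freq_bs1:
        return CriterionEvidence("BS1", source=FREQUENCY_RULE)
    if faf <= config.freq_pm2:
        return CriterionEvidence("PM2", source=FREQUENCY_RULE)
    return None


def phenotype_criterion(
    hdl_c: Optional[float], tangier: bool, config: CalibrationConfig
) -> Optional[CriterionEvidence]:
    """Tiered PP4 from the carrier phenotype; the strictest satisfied tier wins."""
    if hdl_c is not None and hdl_c < 0:
        raise ValueError(f"negative HDL-C: {hdl_c}")
    if tangier or (hdl_c is not None and hdl_c < config.pp4_strong_hdl):
        return CriterionEvidence("PP4", STRONG, source=PHENOTYPE_RULE)
    if hdl_c is not None and hdl_c < config.pp4_moderate_hdl:
        return CriterionEvidence("PP4", MODERATE, source=PHENOTYPE_RULE)
    if hdl_c is not None and hdl_c < config.pp4_supporting_hdl:
        return CriterionEvidence("PP4", SUPPORTING, source=PHENOTYPE_RULE)
    return None


def functional_criterion(
    category: str, assay_valid_strength: str = MODERATE
) -> Optional[CriterionEvidence]:
    """PS3/BS3 evidence implied by the functional category, or None for uncertain."""
    if category == LOSS_OF_FUNCTION:
        return CriterionEvidence("PS3", assay_valid_strength, source=FUNCTIONAL_ASSAY)
    if category == NORMAL:
        return CriterionEvidence("BS3", assay_valid_strength, source=FUNCTIONAL_ASSAY)
    if category == UNCERTAIN:
        return None
    raise ValueError(f"unknown functional category: {category!r}")


def validate_assay(
    n_variant_controls: int,
    has_normal_and_null_controls: bool,
    has_replicates: bool,
    config: CalibrationConfig,
) -> str:
    """Maximum permitted PS3/BS3 strength under the assay-validation rule."""
    if n_variant_controls < 0:
        raise ValueError("control count must be >= 0")
    if (
        has_normal_and_null_controls
        and has_replicates
        and n_variant_controls >= config.min_variant_controls_for_moderate
    ):
        return MODERATE
    return SUPPORTING


def classify_variant(
    variant: VariantRecord,
    category: Optional[str],
    config: CalibrationConfig,
    *,
    assay_valid_strength: str = MODERATE,
) -> ClassificationResult:
    """Classify a variant with and without the functional-assay evidence.

    Criteria are assembled from the asserted list plus the frequency and
    phenotype rules; a derived criterion is skipped when its code is already
    asserted. ``category=None`` behaves like an uncertain assay outcome.
    """
    criteria = list(variant.asserted_criteria)
    asserted_codes = {c.code for c in criteria}
    freq = frequency_criteria(variant.filtering_allele_frequency, config)
    if freq is not None and freq.code not in asserted_codes:
        criteria.append(freq)
    pp4 = phenotype_criterion(variant.hdl_c, variant.tangier_disease, config)
    if pp4 is not None and "PP4" not in asserted_codes:
        criteria.append(pp4)

    without = tuple(criteria)
    class_without = combine(without)

    category = UNCERTAIN if category is None else category
    func = functional_criterion(category, assay_valid_strength)
    with_ = without if func is None else without + (func,)
    class_with = class_without if func is None else combine(with_)

    return ClassificationResult(
        variant=variant,
        criteria_without=without,
        criteria_with=with_,
        class_without_functional=class_without,
        class_with_functional=class_with,
        functional_category=category,
    )


@dataclass
class ReclassificationReport:
    n_variants: int
    n_changed: int
    transitions: dict[str, int] = field(default_factory=dict)
    class_counts_without: dict[int, int] = field(default_factory=dict)
    class_counts_with: dict[int, int] = field(default_factory=dict)


def reclassification_report(
    results: Iterable[ClassificationResult],
) -> ReclassificationReport:
    """Counts of class transitions induced by the functional evidence."""
    results = list(results)
    transitions: Counter = Counter()
    without_counts: Counter = Counter()
    with_counts: Counter = Counter()
    n_changed = 0
    for r in results:
        without_counts[r.class_without_functional] += 1
        with_counts[r.class_with_functional] += 1
        if r.changed:
            n_changed += 1
            transitions[
                f"{r.class_without_functional}->{r.class_with_functional}"
            ] += 1
    return ReclassificationReport(
        n_variants=len(results),
        n_changed=n_changed,
        transitions=dict(sorted(transitions.items())),
        class_counts_without=dict(sorted(without_counts.items())),
        class_counts_with=dict(sorted(with_counts.items())),
    )
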