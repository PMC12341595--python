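"""Cholesterol-efflux quantification from plate fluorescence.

The efflux statistic for one well-set is medium / (medium + lysate) on the
triplicate-averaged BODIPY signals. Two background corrections are applied in
sequence: acceptor-nonspecific leakage (subtract the no-acceptor well-set of
the same construct and experiment) and transporter-nonspecific efflux
(subtract the mock-transfected construct of the same experiment). The
resulting specific efflux is normalized to the same experiment's WT to give a
relative activity in percent of WT; replicate experiments are then summarized
as mean ± SD and compared against WT with the F-test-gated two-sample t-test.

Functional categories follow the gene-calibrated cutoffs: relative efflux
below the loss-of-function threshold (the activity of the p.W590S control) is
``loss_of_function``, above the normal threshold is ``normal``, and the
closed interval between them — both boundaries included — is ``uncertain``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import CalibrationConfig
from .errors import (
    ConfigurationError,
    NormalizationError,
    PairingError,
    UndefinedEffluxError,
)
from .stats import gated_ttest

logger = logging.getLogger(__name__)

WT_ID = "WT"
MOCK_ID = "mock"

ACCEPTOR = "acceptor"
NO_ACCEPTOR = "no_acceptor"
MOCK_TREATMENT = "mock_treatment"
PBA_TREATMENT = "4pba"

LOSS_OF_FUNCTION = "loss_of_function"
UNCERTAIN = "uncertain"
NORMAL = "normal"


@dataclass(frozen=True)
class EffluxMeasurement:
    """One well-set: triplicate medium and lysate fluorescence signals."""

    construct_id: str
    experiment_id: str
    condition: str  # acceptor | no_acceptor
    treatment: str = MOCK_TREATMENT  # mock_treatment | 4pba
    medium_signals: tuple[float, ...] = ()
    lysate_signals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.condition not in (ACCEPTOR, NO_ACCEPTOR):
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.treatment not in (MOCK_TREATMENT, PBA_TREATMENT):
            raise ValueError(f"unknown treatment: {self.treatment!r}")
        for signals, label in ((self.medium_signals, "medium"),
                               (self.lysate_signals, "lysate")):
            if len(signals) == 0:
                raise ValueError(f"{label} signals empty for {self.construct_id}")
            if any(s < 0 for s in signals):
                raise ValueError(f"negative {label} signal for {self.construct_id}")
            if len(signals) != 3:
                logger.warning(
                    "%s/%s: %d %s replicates instead of 3",
                    self.construct_id, self.experiment_id, len(signals), label,
                )


@dataclass
class EffluxResult:
    """Per-construct relative efflux summary across experiments."""

    construct_id: str
    per_experiment: dict[str, float] = field(default_factory=dict)  # % of WT
    mean_relative_efflux: float = float("nan")
    sd: float = float("nan")
    n_experiments: int = 0
    p_value: Optional[float] = None
    category: str = UNCERTAIN


def raw_efflux(
    medium_signals: Sequence[float], lysate_signals: Sequence[float]
) -> float:
    """Efflux fraction mean(medium) / (mean(medium) + mean(lysate))."""
    if len(medium_signals) == 0 or len(lysate_signals) == 0:
        raise UndefinedEffluxError("empty signal triplicate")
    m = float(np.mean(medium_signals))
    l = float(np.mean(lysate_signals))
    if m + l <= 0.0:
        raise UndefinedEffluxError("medium and lysate signals both sum to zero")
    return m / (m + l)


def corrected_efflux(
    acceptor: EffluxMeasurement, no_acceptor: EffluxMeasurement
) -> float:
    """Leakage-corrected efflux: acceptor minus no-acceptor well-set.

    May be negative; values are deliberately not clamped so mock-level
    constructs can sit near zero with symmetric noise.
    """
    if acceptor.condition != ACCEPTOR or no_acceptor.condition != NO_ACCEPTOR:
        raise PairingError("expected one acceptor and one no-acceptor well-set")
    same = (
        acceptor.construct_id == no_acceptor.construct_id
        and acceptor.experiment_id == no_acceptor.experiment_id
        and acceptor.treatment == no_acceptor.treatment
    )
    if not same:
        raise PairingError(
            f"well-sets do not pair: {acceptor.construct_id}/{acceptor.experiment_id}"
            f"/{acceptor.treatment} vs {no_acceptor.construct_id}/"
            f"{no_acceptor.experiment_id}/{no_acceptor.treatment}"
        )
    return raw_efflux(acceptor.medium_signals, acceptor.lysate_signals) - raw_efflux(
        no_acceptor.medium_signals, no_acceptor.lysate_signals
    )


def specific_efflux(construct_corrected: float, mock_corrected: float) -> float:
    """Transporter-specific efflux: corrected construct minus corrected mock."""
    return construct_corrected - mock_corrected


def normalize_to_wt(
    construct: Mapping[str, float], wt: Mapping[str, float]
) -> dict[str, float]:
    """Per-experiment relative efflux in percent of the same experiment's WT.

    Experiments missing either member, or with non-positive WT specific
    efflux, are dropped with a warning; if no experiment survives a
    :class:`NormalizationError` is raised.
    """
    out: dict[str, float] = {}
    for exp, value in construct.items():
        if exp not in wt:
            logger.warning("experiment %s lacks a WT specific efflux; dropped", exp)
            continue
        if wt[exp] <= 0.0:
            logger.warning(
                "experiment %s has non-positive WT specific efflux (%.4g); dropped",
                exp, wt[exp],
            )
            continue
        out[exp] = 100.0 * value / wt[exp]
    if not out:
        raise NormalizationError("no experiment with positive WT specific efflux")
    return out


def compare_to_wt(
    construct_values: Sequence[float],
    wt_values: Sequence[float],
    *,
    variance_test_alpha: float = 0.05,
    tails: str = "two",
    direction: str = "less",
) -> float:
    """F-test-gated t-test p-value of construct vs WT values.

    ``tails="one"`` tests the one-sided alternative given by ``direction``
    ("less" or "greater", referring to the construct relative to WT).
    """
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    alternative = "two-sided" if tails == "two" else direction
    p, _ = gated_ttest(
        construct_values, wt_values,
        variance_alpha=variance_test_alpha, alternative=alternative,
    )
    return p


def categorize(
    mean_relative_efflux: float,
    config: CalibrationConfig,
    *,
    use_alternative: bool = False,
) -> str:
    """Functional category from the mean relative efflux (percent of WT).

    Outer categories are exclusive of their thresholds: a mean exactly at the
    loss-of-function or normal cutoff remains ``uncertain``.
    """
    if math.isnan(mean_relative_efflux):
        raise ValueError("mean relative efflux is NaN")
    lof = (
        config.alternative_lof_threshold if use_alternative else config.lof_threshold
    )
    if mean_relative_efflux < lof:
        return LOSS_OF_FUNCTION
    if mean_relative_efflux > config.normal_threshold:
        return NORMAL
    return UNCERTAIN


def _corrected_by_construct(
    measurements: Iterable[EffluxMeasurement], treatment: str
) -> dict[str, dict[str, float]]:
    """Group well-sets and compute leakage-corrected efflux per construct/experiment."""
    wells: dict[tuple[str, str, str], EffluxMeasurement] = {}
    for m in measurements:
        if m.treatment != treatment:
            continue
        key = (m.construct_id, m.experiment_id, m.condition)
        if key in wells:
            raise ConfigurationError(f"duplicate well-set for {key}")
        wells[key] = m

    corrected: dict[str, dict[str, float]] = {}
    pairs = sorted({(c, e) for c, e, _ in wells})
    for construct, exp in pairs:
        acc = wells.get((construct, exp, ACCEPTOR))
        na = wells.get((construct, exp, NO_ACCEPTOR))
        if acc is None or na is None:
            raise ConfigurationError(
                f"{construct}/{exp}: need both acceptor and no-acceptor well-sets"
            )
        corrected.setdefault(construct, {})[exp] = corrected_efflux(acc, na)
    return corrected


def specific_efflux_by_construct(
    measurements: Iterable[EffluxMeasurement],
    treatment: str = MOCK_TREATMENT,
) -> dict[str, dict[str, float]]:
    """Mock-subtracted specific efflux per construct and experiment."""
    corrected = _corrected_by_construct(measurements, treatment)
    if MOCK_ID not in corrected:
        raise ConfigurationError("no mock-transfected construct in the plate data")
    mock = corrected[MOCK_ID]
    out: dict[str, dict[str, float]] = {}
    for construct, by_exp in corrected.items():
        if construct == MOCK_ID:
            continue
        vals = {}
        for exp, value in by_exp.items():
            if exp not in mock:
                raise ConfigurationError(f"experiment {exp} lacks a mock well-set")
            vals[exp] = specific_efflux(value, mock[exp])
        out[construct] = vals
    return out


def run_efflux_pipeline(
    measurements: Iterable[EffluxMeasurement],
    config: CalibrationConfig,
    *,
    treatment: str = MOCK_TREATMENT,
    use_alternative: bool = False,
) -> list[EffluxResult]:
    """Full plate-to-category pipeline for one treatment arm.

    Returns one :class:`EffluxResult` per non-control construct, in sorted
    construct order (the computation is invariant to input row order). The
    p-value compares the construct's per-experiment specific efflux with WT's
    (two-sided); it is ``None`` when fewer than two shared experiments exist.
    """
    spec = specific_efflux_by_construct(measurements, treatment)
    if WT_ID not in spec:
        raise ConfigurationError("no WT construct in the plate data")
    wt = spec[WT_ID]

    results: list[EffluxResult] = []
    for construct in sorted(spec):
        if construct == WT_ID:
            continue
        rel = normalize_to_wt(spec[construct], wt)
        values = np.array([rel[e] for e in sorted(rel)])
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        shared = sorted(set(spec[construct]) & set(wt))
        p: Optional[float] = None
        if len(shared) >= 2:
            p = compare_to_wt(
                [spec[construct][e] for e in shared],
                [wt[e] for e in shared],
                variance_test_alpha=config.variance_test_alpha,
            )
        results.append(
            EffluxResult(
                construct_id=construct,
                per_experiment=dict(sorted(rel.items())),
                mean_relative_efflux=mean,
                sd=sd,
                n_experiments=values.size,
                p_value=p,
                category=categorize(mean, config, use_alternative=use_alternative),
            )
        )
    return results
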