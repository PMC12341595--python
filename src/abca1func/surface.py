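"""Cell-surface ABCA1 quantification from biotinylation densitometry.

Two readouts per construct and experiment:

* raw surface level — surface band over the β-actin loading band, expressed
  relative to WT's same ratio (×100);
* total-corrected surface level — surface band over the total-ABCA1 band,
  relative to WT (×100). Total ABCA1 serves as its own denominator here, so
  the loading control cancels and is not reapplied.

The corrected readout separates the two mechanisms that deplete surface
protein: a variant whose corrected level remains significantly below WT is
transport deficient, whereas one whose raw level is reduced but whose
corrected level is not is degradation prone. "Reduced" is operationalized as
a one-sided F-test-gated t-test against WT; the published 50 % figure is kept
as a severity flag on the relevant percentage, not as the significance rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .config import CalibrationConfig
from .errors import ConfigurationError, NormalizationError
from .stats import gated_ttest

logger = logging.getLogger(__name__)

WT_ID = "WT"
MOCK_TREATMENT = "mock_treatment"

TRANSPORT_DEFICIENT = "transport_deficient"
DEGRADATION_PRONE = "degradation_prone"
UNAFFECTED = "unaffected"


@dataclass(frozen=True)
class SurfaceMeasurement:
    """Densitometry band intensities for one construct in one experiment."""

    construct_id: str
    experiment_id: str
    treatment: str = MOCK_TREATMENT
    surface_band: float = 0.0
    total_band: float = 0.0
    loading_band: float = 1.0  # β-actin

    def __post_init__(self) -> None:
        if min(self.surface_band, self.total_band) < 0:
            raise ValueError(f"negative band intensity for {self.construct_id}")
        if self.loading_band <= 0:
            raise ValueError(f"loading band must be positive for {self.construct_id}")


@dataclass
class SurfaceResult:
    construct_id: str
    raw_per_experiment: dict[str, float] = field(default_factory=dict)
    corrected_per_experiment: dict[str, float] = field(default_factory=dict)
    raw_surface_pct_of_wt: float = float("nan")
    corrected_surface_pct_of_wt: float = float("nan")
    p_raw: Optional[float] = None
    p_corrected: Optional[float] = None
    mechanism_call: str = UNAFFECTED
    severe: bool = False


def mechanism_call(
    p_raw: Optional[float],
    p_corrected: Optional[float],
    raw_pct: float,
    corrected_pct: float,
    config: CalibrationConfig,
) -> tuple[str, bool]:
    """Mechanism label and severity flag from the two one-sided p-values.

    Transport deficient when corrected surface is significantly below WT;
    degradation prone when only the raw level is; unaffected otherwise. The
    severity flag marks the mechanism's relevant percentage (corrected for
    transport deficiency, raw otherwise) falling below the configured
    surface-deficiency threshold.
    """
    alpha = config.alpha
    if p_corrected is not None and p_corrected < alpha:
        label, relevant = TRANSPORT_DEFICIENT, corrected_pct
    elif p_raw is not None and p_raw < alpha:
        label, relevant = DEGRADATION_PRONE, raw_pct
    else:
        label, relevant = UNAFFECTED, raw_pct
    return label, bool(relevant < config.surface_deficiency_threshold)


def surface_levels(
    measurements: Iterable[SurfaceMeasurement],
    config: CalibrationConfig,
    *,
    treatment: str = MOCK_TREATMENT,
) -> list[SurfaceResult]:
    """Per-construct raw and total-corrected surface levels relative to WT.

    One-sided p-values ("less than WT") are computed on the per-experiment
    band ratios with the F-test-gated machinery; WT itself reports 100/100
    and ``unaffected`` by construction.
    """
    rows: dict[tuple[str, str], SurfaceMeasurement] = {}
    for m in measurements:
        if m.treatment != treatment:
            continue
        key = (m.construct_id, m.experiment_id)
        if key in rows:
            raise ConfigurationError(f"duplicate densitometry row for {key}")
        rows[key] = m

    wt_rows = {e: m for (c, e), m in rows.items() if c == WT_ID}
    if not wt_rows:
        raise ConfigurationError("no WT construct in the densitometry data")
    for exp, m in wt_rows.items():
        if m.surface_band <= 0:
            raise NormalizationError(f"WT surface band is zero in experiment {exp}")

    results: list[SurfaceResult] = []
    for construct in sorted({c for c, _ in rows}):
        raw_pct: dict[str, float] = {}
        corr_pct: dict[str, float] = {}
        raw_ratio: list[float] = []
        corr_ratio: list[float] = []
        wt_raw_ratio: list[float] = []
        wt_corr_ratio: list[float] = []
        for exp in sorted(e for c, e in rows if c == construct):
            if exp not in wt_rows:
                logger.warning("experiment %s lacks a WT row; dropped", exp)
                continue
            m, w = rows[(construct, exp)], wt_rows[exp]
            if m.total_band <= 0 or w.total_band <= 0:
                raise NormalizationError(
                    f"zero total-ABCA1 band in experiment {exp}"
                )
            r = m.surface_band / m.loading_band
            c_ = m.surface_band / m.total_band
            wr = w.surface_band / w.loading_band
            wc = w.surface_band / w.total_band
            raw_pct[exp] = 100.0 * r / wr
            corr_pct[exp] = 100.0 * c_ / wc
            raw_ratio.append(r)
            corr_ratio.append(c_)
            wt_raw_ratio.append(wr)
            wt_corr_ratio.append(wc)
        if not raw_pct:
            raise NormalizationError(f"no usable experiment for {construct}")

        mean_raw = float(np.mean(list(raw_pct.values())))
        mean_corr = float(np.mean(list(corr_pct.values())))
        p_raw = p_corr = None
        if construct != WT_ID and len(raw_ratio) >= 2:
            p_raw, _ = gated_ttest(
                raw_ratio, wt_raw_ratio,
                variance_alpha=config.variance_test_alpha, alternative="less",
            )
            p_corr, _ = gated_ttest(
                corr_ratio, wt_corr_ratio,
                variance_alpha=config.variance_test_alpha, alternative="less",
            )
        if construct == WT_ID:
            label, severe = UNAFFECTED, False
        else:
            label, severe = mechanism_call(p_raw, p_corr, mean_raw, mean_corr, config)
        results.append(
            SurfaceResult(
                construct_id=construct,
                raw_per_experiment=raw_pct,
                corrected_per_experiment=corr_pct,
                raw_surface_pct_of_wt=mean_raw,
                corrected_surface_pct_of_wt=mean_corr,
                p_raw=p_raw,
                p_corrected=p_corr,
                mechanism_call=label,
                severe=severe,
            )
        )
    return results
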