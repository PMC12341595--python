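"""Chemical-chaperone (4-PBA) rescue analysis.

A loss-of-function variant is *rescued* when its cholesterol efflux increases
significantly under 4-PBA treatment (one-tailed F-test-gated t-test versus the
mock-treatment arm). Both arms are normalized to the mock-treated WT of the
same experiment, so a rescued variant's gain is expressed on the same scale as
its baseline deficit.

Variants that are not rescued, yet show a significant one-tailed increase in
cell-surface protein under 4-PBA, and sit in one of the ATP-binding motifs
(Walker A, Walker B or the signature motif) are flagged as suspected
ATPase-deficient: the chaperone delivers more transporter to the membrane, but
the transporter cannot hydrolyse ATP, so efflux stays flat — the phenotype of
the p.K939M / p.K1952M Walker A controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import CalibrationConfig
from .domains import DomainMap, assign_motif, parse_protein_variant
from .efflux import (
    EffluxMeasurement,
    MOCK_TREATMENT,
    PBA_TREATMENT,
    WT_ID,
    normalize_to_wt,
    specific_efflux_by_construct,
)
from .errors import VariantParseError
from .stats import gated_ttest
from .surface import SurfaceMeasurement

logger = logging.getLogger(__name__)


@dataclass
class RescueResult:
    construct_id: str
    efflux_mock_pct: float
    efflux_4pba_pct: float
    p_one_tailed: float
    rescued: bool
    surface_increased: Optional[bool] = None
    motif: Optional[str] = None
    atpase_deficiency_suspected: bool = False


def rescue_test(
    mock_values: Sequence[float],
    pba_values: Sequence[float],
    *,
    alpha: float = 0.05,
    variance_test_alpha: float = 0.05,
) -> tuple[float, bool]:
    """One-tailed test for an efflux increase under 4-PBA.

    Returns ``(p_one_tailed, rescued)`` where rescued requires both a
    significant p-value and a higher 4-PBA mean.
    """
    p, _ = gated_ttest(
        pba_values, mock_values,
        variance_alpha=variance_test_alpha, alternative="greater",
    )
    rescued = p < alpha and float(np.mean(pba_values)) > float(np.mean(mock_values))
    return p, rescued


def flag_atpase_deficiency(
    rescued: bool, surface_increased: bool, motif: Optional[str]
) -> bool:
    """Suspect ATPase deficiency iff not rescued, surface responds to 4-PBA,
    and the variant sits in an ATP-binding motif."""
    return (not rescued) and surface_increased and motif is not None


def _motif_for(construct_id: str, domain_map: DomainMap) -> Optional[str]:
    try:
        _, position, _ = parse_protein_variant(construct_id)
    except VariantParseError:
        return None  # controls such as WT
    hit = assign_motif(position, domain_map)
    return None if hit is None else f"{hit[0]}({hit[1]})"


def analyze_rescue(
    plate_measurements: Iterable[EffluxMeasurement],
    band_measurements: Iterable[SurfaceMeasurement],
    domain_map: DomainMap,
    config: CalibrationConfig,
) -> list[RescueResult]:
    """Full rescue evaluation from two-arm plate and densitometry data.

    Both treatment arms are normalized to the mock-treated WT per experiment.
    ``surface_increased`` is a one-tailed significant increase of the
    surface/loading ratio under 4-PBA; it is ``None`` (and the ATPase flag
    ``False``) when no densitometry rows exist for the construct.
    """
    plate_measurements = list(plate_measurements)
    spec_mock = specific_efflux_by_construct(plate_measurements, MOCK_TREATMENT)
    spec_pba = specific_efflux_by_construct(plate_measurements, PBA_TREATMENT)
    wt_mock = spec_mock[WT_ID]

    bands: dict[tuple[str, str], list[float]] = {}
    for b in band_measurements:
        bands.setdefault((b.construct_id, b.treatment), []).append(
            b.surface_band / b.loading_band
        )

    results: list[RescueResult] = []
    for construct in sorted(set(spec_mock) & set(spec_pba)):
        if construct == WT_ID:
            continue
        rel_mock = normalize_to_wt(spec_mock[construct], wt_mock)
        rel_pba = normalize_to_wt(spec_pba[construct], wt_mock)
        p, rescued = rescue_test(
            list(rel_mock.values()), list(rel_pba.values()),
            alpha=config.alpha, variance_test_alpha=config.variance_test_alpha,
        )
        motif = _motif_for(construct, domain_map)
        surface_increased: Optional[bool] = None
        s_mock = bands.get((construct, MOCK_TREATMENT))
        s_pba = bands.get((construct, PBA_TREATMENT))
        if s_mock and s_pba and len(s_mock) >= 2 and len(s_pba) >= 2:
            p_surf, _ = gated_ttest(
                s_pba, s_mock,
                variance_alpha=config.variance_test_alpha, alternative="greater",
            )
            surface_increased = p_surf < config.alpha and (
                float(np.mean(s_pba)) > float(np.mean(s_mock))
            )
        results.append(
            RescueResult(
                construct_id=construct,
                efflux_mock_pct=float(np.mean(list(rel_mock.values()))),
                efflux_4pba_pct=float(np.mean(list(rel_pba.values()))),
                p_one_tailed=p,
                rescued=rescued,
                surface_increased=surface_increased,
                motif=motif,
                atpase_deficiency_suspected=flag_atpase_deficiency(
                    rescued, bool(surface_increased), motif
                ),
            )
        )
    return results
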