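"""Calibration configuration for the ABCA1 functional-characterization pipeline.

All thresholds used anywhere in the pipeline live here, never hard-coded in the
analysis logic: the efflux category cutoffs (percent of WT), the allele-frequency
cutoffs driving the frequency-based ACMG criteria, the tiered HDL-C cutoffs for
the phenotype criterion PP4, the assay-validation control count, and the scoring
parameters of the NBD1/NBD2 pairwise alignment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError


@dataclass
class CalibrationConfig:
    """Gene-calibrated thresholds for categorization and ACMG evaluation.

    Efflux thresholds are percentages of WT activity. The loss-of-function
    cutoff is the activity of the p.W590S control; the normal cutoff sits
    between the two high-frequency anchor variants p.I883M and p.V2244I.
    The alternative loss-of-function cutoff is the highest efflux observed
    among Tangier-disease-associated variants (p.R2080Q).
    """

    lof_threshold: float = 41.0          # % of WT; below -> loss_of_function
    normal_threshold: float = 80.0       # % of WT; above -> normal
    alternative_lof_threshold: float = 58.0  # % of WT; optional stricter cutoff
    alpha: float = 0.05                  # significance level for all tests
    variance_test_alpha: float = 0.05    # F-test gate between pooled and Welch
    surface_deficiency_threshold: float = 50.0  # % of WT; "severe" flag
    freq_ba1: float = 0.005              # filtering allele frequency, BA1 (>=)
    freq_bs1: float = 0.002              # filtering allele frequency, BS1 (>=)
    freq_pm2: float = 0.0002             # filtering allele frequency, PM2 (<=)
    pp4_supporting_hdl: float = 0.5      # mmol/l HDL-C, PP4 supporting (<)
    pp4_moderate_hdl: float = 0.3        # mmol/l HDL-C, PP4 moderate (<)
    pp4_strong_hdl: float = 0.1          # mmol/l HDL-C, PP4 strong (<)
    min_variant_controls_for_moderate: int = 11  # ClinGen assay-validation rule
    # NBD1/NBD2 alignment (full-protein 1-based inclusive windows)
    nbd1_window: tuple[int, int] = (923, 1121)
    nbd2_window: tuple[int, int] = (1936, 2134)
    gap_open: float = -10.0
    gap_extend: float = -0.5
    substitution_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        self.nbd1_window = tuple(self.nbd1_window)  # type: ignore[assignment]
        self.nbd2_window = tuple(self.nbd2_window)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if not (0 < self.lof_threshold < self.normal_threshold <= 100):
            raise ConfigurationError(
                "need 0 < lof_threshold < normal_threshold <= 100, got "
                f"{self.lof_threshold} / {self.normal_threshold}"
            )
        if not (self.freq_pm2 < self.freq_bs1 < self.freq_ba1):
            raise ConfigurationError(
                "allele-frequency cutoffs must satisfy freq_pm2 < freq_bs1 < freq_ba1"
            )
        if not (self.pp4_strong_hdl < self.pp4_moderate_hdl < self.pp4_supporting_hdl):
            raise ConfigurationError("PP4 HDL-C cutoffs must be strictly decreasing")
        if not (0 < self.alpha < 1 and 0 < self.variance_test_alpha < 1):
            raise ConfigurationError("alpha levels must lie in (0, 1)")
        if self.min_variant_controls_for_moderate < 0:
            raise ConfigurationError("min_variant_controls_for_moderate must be >= 0")
        for name in ("nbd1_window", "nbd2_window"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigurationError(f"{name} must be an increasing 1-based range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nbd1_window"] = list(self.nbd1_window)
        d["nbd2_window"] = list(self.nbd2_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown calibration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationConfig":
        """Load from a JSON file; accepts either a flat object or one with a
        top-level "calibration" section."""
        with open(path) as fh:
            data = json.load(fh)
        if "calibration" in data:
            data = data["calibration"]
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
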