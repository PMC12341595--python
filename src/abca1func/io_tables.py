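"""Tabular input/output, run manifests and the combined end-of-run report.

All tabular interchange uses TSV/CSV with fixed headers, UTF-8, and ``.``
for missing values. Every output directory written by the CLI carries a
single ``manifest.json`` recording the command, configuration hash, input
checksums and seed, so equal inputs provably produce equal outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .acmg import ClassificationResult, CriterionEvidence, reclassification_report
from .config import CalibrationConfig
from .domains import VariantRecord
from .efflux import EffluxMeasurement, EffluxResult
from .errors import JoinError, TableFormatError, UnknownCriterionError
from .rescue import RescueResult
from .surface import SurfaceMeasurement, SurfaceResult

MISSING = "."

VARIANT_COLUMNS = ["variant_p", "variant_c", "faf", "hdl_c", "tangier", "criteria"]
PLATE_COLUMNS = [
    "construct_id", "experiment_id", "condition", "treatment",
    "well_type", "rep1", "rep2", "rep3",
]
BAND_COLUMNS = [
    "construct_id", "experiment_id", "treatment", "surface", "total", "actin",
]


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def _parse_bool(token: str, row: int, col: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", MISSING, ""):
        return False
    raise TableFormatError(f"row {row}, column '{col}': bad boolean '{token}'")


def _parse_float(token, row: int, col: str) -> Optional[float]:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    s = str(token).strip()
    if s in (MISSING, ""):
        return None
    try:
        return float(s)
    except ValueError:
        raise TableFormatError(
            f"row {row}, column '{col}': bad number '{token}'"
        ) from None


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV into records, validating every token.

    Columns: variant_p, variant_c (optional), faf, hdl_c, tangier, criteria
    (semicolon-separated ACMG tokens). Errors name the offending row and
    column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns and c != "variant_c"]
    if missing:
        raise TableFormatError(f"missing column(s): {missing}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        tokens = [t for t in d.get("criteria", "").split(";") if t.strip()]
        try:
            criteria = tuple(CriterionEvidence.from_token(t) for t in tokens)
        except UnknownCriterionError as exc:
            raise TableFormatError(f"row {i}, column 'criteria': {exc}") from exc
        faf = _parse_float(d.get("faf"), i, "faf")
        if faf is not None and not (0.0 <= faf <= 1.0):
            raise TableFormatError(
                f"row {i}, column 'faf': frequency {faf} outside [0, 1]"
            )
        cdna = d.get("variant_c", "").strip() or None
        if cdna == MISSING:
            cdna = None
        try:
            records.append(
                VariantRecord.from_name(
                    d["variant_p"],
                    cdna_change=cdna,
                    filtering_allele_frequency=faf,
                    hdl_c=_parse_float(d.get("hdl_c"), i, "hdl_c"),
                    tangier_disease=_parse_bool(d.get("tangier", ""), i, "tangier"),
                    asserted_criteria=criteria,
                )
            )
        except Exception as exc:
            if isinstance(exc, TableFormatError):
                raise
            raise TableFormatError(
                f"row {i}, column 'variant_p': {exc}"
            ) from exc
    return records


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "variant_p": r.name,
                "variant_c": r.cdna_change or MISSING,
                "faf": MISSING if r.filtering_allele_frequency is None
                else repr(r.filtering_allele_frequency),
                "hdl_c": MISSING if r.hdl_c is None else repr(r.hdl_c),
                "tangier": str(r.tangier_disease).lower(),
                "criteria": ";".join(c.token for c in r.asserted_criteria),
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plate and band tables
# ---------------------------------------------------------------------------

def write_plate_csv(
    measurements: Iterable[EffluxMeasurement], path: str | Path
) -> None:
    rows = []
    for m in measurements:
        for well_type, signals in (("medium", m.medium_signals),
                                   ("lysate", m.lysate_signals)):
            padded = list(signals) + [None] * (3 - len(signals))
            rows.append(
                {
                    "construct_id": m.construct_id,
                    "experiment_id": m.experiment_id,
                    "condition": m.condition,
                    "treatment": m.treatment,
                    "well_type": well_type,
                    "rep1": padded[0], "rep2": padded[1], "rep3": padded[2],
                }
            )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> list[EffluxMeasurement]:
    df = pd.read_csv(path, dtype={"construct_id": str, "experiment_id": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s): {missing}")
    grouped: dict[tuple, dict[str, tuple[float, ...]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        key = (row.construct_id, row.experiment_id, row.condition, row.treatment)
        reps = tuple(
            float(v) for v in (row.rep1, row.rep2, row.rep3) if pd.notna(v)
        )
        if not reps:
            raise TableFormatError(f"row {i}: no replicate signal values")
        if row.well_type not in ("medium", "lysate"):
            raise TableFormatError(
                f"row {i}, column 'well_type': bad value '{row.well_type}'"
            )
        grouped.setdefault(key, {})[row.well_type] = reps
    out = []
    for (construct, exp, condition, treatment), wells in grouped.items():
        if "medium" not in wells or "lysate" not in wells:
            raise TableFormatError(
                f"well-set {construct}/{exp}/{condition}: needs both a medium "
                "and a lysate row"
            )
        out.append(
            EffluxMeasurement(
                construct_id=construct, experiment_id=exp,
                condition=condition, treatment=treatment,
                medium_signals=wells["medium"], lysate_signals=wells["lysate"],
            )
        )
    return out


def write_band_csv(
    measurements: Iterable[SurfaceMeasurement], path: str | Path
) -> None:
    rows = [
        {
            "construct_id": m.construct_id, "experiment_id": m.experiment_id,
            "treatment": m.treatment, "surface": m.surface_band,
            "total": m.total_band, "actin": m.loading_band,
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=BAND_COLUMNS).to_csv(path, index=False)


def read_band_csv(path: str | Path) -> list[SurfaceMeasurement]:
    df = pd.read_csv(path, dtype={"construct_id": str, "experiment_id": str})
    missing = [c for c in BAND_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s): {missing}")
    return [
        SurfaceMeasurement(
            construct_id=r.construct_id, experiment_id=r.experiment_id,
            treatment=r.treatment, surface_band=float(r.surface),
            total_band=float(r.total), loading_band=float(r.actin),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def efflux_results_frame(results: Sequence[EffluxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": r.construct_id,
                "mean_rel_efflux_pct": r.mean_relative_efflux,
                "sd_pct": r.sd,
                "n": r.n_experiments,
                "p_vs_wt": r.p_value,
                "category": r.category,
            }
            for r in results
        ]
    )


def surface_results_frame(results: Sequence[SurfaceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": r.construct_id,
                "raw_surface_pct": r.raw_surface_pct_of_wt,
                "corrected_surface_pct": r.corrected_surface_pct_of_wt,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "mechanism": r.mechanism_call,
                "severe": r.severe,
            }
            for r in results
        ]
    )


def rescue_results_frame(results: Sequence[RescueResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": r.construct_id,
                "efflux_mock_pct": r.efflux_mock_pct,
                "efflux_4pba_pct": r.efflux_4pba_pct,
                "p_one_tailed": r.p_one_tailed,
                "rescued": r.rescued,
                "surface_increased": r.surface_increased,
                "motif": r.motif or MISSING,
                "atpase_deficiency_suspected": r.atpase_deficiency_suspected,
            }
            for r in results
        ]
    )


def classification_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": r.variant.name,
                "criteria_without": ";".join(c.token for c in r.criteria_without),
                "class_without": r.class_without_functional,
                "criteria_with": ";".join(c.token for c in r.criteria_with),
                "class_with": r.class_with_functional,
                "category": r.functional_category,
                "changed": r.changed,
            }
            for r in results
        ]
    )


def full_report(
    classifications: Sequence[ClassificationResult],
    efflux_results: Sequence[EffluxResult] = (),
    surface_results: Sequence[SurfaceResult] = (),
    rescue_results: Sequence[RescueResult] = (),
) -> dict:
    """Assemble the combined per-variant report.

    Returns a dict with a wide per-variant table (``variants``), the class
    transition summary (``transitions``) and the functional category counts
    (``category_counts``). Construct ids present in an optional input but
    absent from the classifications raise a :class:`JoinError` naming the
    orphans.
    """
    if not classifications:
        raise ValueError("at least the classifications must be provided")
    wide = classification_frame(classifications)
    known = set(wide["variant"])

    for frame, label in (
        (efflux_results_frame(list(efflux_results)), "efflux"),
        (surface_results_frame(list(surface_results)), "surface"),
        (rescue_results_frame(list(rescue_results)), "rescue"),
    ):
        if frame.empty:
            continue
        orphans = sorted(set(frame["construct_id"]) - known)
        if orphans:
            raise JoinError(f"{label} results for unknown constructs: {orphans}")
        frame = frame.rename(columns={"construct_id": "variant"})
        wide = wide.merge(frame, on="variant", how="left",
                          suffixes=("", f"_{label}"))

    report = reclassification_report(classifications)
    categories = (
        wide["category"].value_counts().to_dict() if "category" in wide else {}
    )
    return {
        "variants": wide,
        "transitions": dataclasses.asdict(report),
        "category_counts": categories,
    }


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config_hash: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None
    timestamp: str = ""
    version: str = __version__

    @classmethod
    def create(
        cls,
        command: str,
        config: Optional[CalibrationConfig] = None,
        inputs: Sequence[str | Path] = (),
        seed: Optional[int] = None,
    ) -> "RunManifest":
        return cls(
            command=command,
            config_hash=config.digest() if config is not None else "",
            input_checksums={str(p): file_sha256(p) for p in inputs},
            seed=seed,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        )

    def write(self, outdir: str | Path) -> Path:
        path = Path(outdir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
        return path
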