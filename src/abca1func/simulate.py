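"""Synthetic wet-lab inputs with known ground truth.

Emulates every input of the pipeline — plate fluorescence, densitometry
bands, variant annotation tables and protein sequences — so the whole
analysis is testable without any deposited data. The generators are fully
deterministic under a fixed seed (NumPy PCG64 via ``default_rng``).

Plate model. Each construct × experiment × condition well-set draws a total
signal ``T ~ LogNormal(log(scale), jitter)`` shared by its wells; medium and
lysate wells split ``T`` as ``T·f·ε`` and ``T·(1−f)·ε′`` with independent
per-well multiplicative log-normal noise ``ε``. The efflux fraction ``f`` is

* no-acceptor wells: ``leakage``;
* mock acceptor wells: ``leakage + mock_efflux``;
* construct acceptor wells:
  ``leakage + mock_efflux + (activity/100)·(wt_efflux − leakage − mock_efflux)``.

With this parameterization the pipeline's two background subtractions and
WT normalization invert the model exactly at zero noise: the estimated
relative efflux equals the generated activity. Multiplicative noise is used
because the efflux statistic is a ratio, which also makes the per-experiment
scale jitter harmless by construction. Fractions are clipped to [0, 1]
after noise, with clipping events logged.

The default condition set mirrors the study design: four independent
experiments (five for the rescue arm), triplicate wells, WT and mock
controls on every plate. The raw WT efflux fraction (0.30) and leakage
(0.05) are fixture choices — no published raw fractions exist — and are
documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .efflux import (
    ACCEPTOR,
    EffluxMeasurement,
    MOCK_ID,
    MOCK_TREATMENT,
    NO_ACCEPTOR,
    PBA_TREATMENT,
    WT_ID,
)
from .surface import SurfaceMeasurement

logger = logging.getLogger(__name__)

RESCUABLE = "rescuable"
ATPASE_DEFICIENT = "atpase_deficient"
UNAFFECTED_PROFILE = "unaffected"

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _default_activities() -> dict[str, float]:
    # small panel spanning the functional categories
    return {
        "p.V1A": 10.0, "p.V2A": 30.0, "p.V3A": 50.0,
        "p.V4A": 60.0, "p.V5A": 90.0, "p.V6A": 100.0,
    }


@dataclass
class GeneratorSpec:
    """Ground truth and noise model for the synthetic study."""

    seed: int = 0
    n_experiments: int = 4          # five for the rescue design
    activities: dict[str, float] = field(default_factory=_default_activities)
    wt_efflux: float = 0.30         # raw WT acceptor efflux fraction
    leakage: float = 0.05           # no-acceptor efflux fraction
    mock_efflux: float = 0.02       # transporter-independent acceptor efflux
    signal_scale: float = 10000.0   # arbitrary fluorescence units
    well_sigma: float = 0.10        # per-well log-normal sigma
    experiment_jitter_sigma: float = 0.20  # per-well-set total-signal sigma
    surface_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    rescue_profiles: dict[str, str] = field(default_factory=dict)
    rescue_efflux_gain: float = 25.0     # percentage points under 4-PBA
    rescue_surface_factor: float = 1.8   # surface fold-change under 4-PBA

    def __post_init__(self) -> None:
        for name, frac in (("wt_efflux", self.wt_efflux),
                           ("leakage", self.leakage),
                           ("mock_efflux", self.mock_efflux)):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.well_sigma < 0 or self.experiment_jitter_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")
        span = self.wt_efflux - self.leakage - self.mock_efflux
        if span <= 0:
            raise ValueError("wt_efflux must exceed leakage + mock_efflux")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _acceptor_fraction(spec: GeneratorSpec, activity_pct: float) -> float:
    span = spec.wt_efflux - spec.leakage - spec.mock_efflux
    return spec.leakage + spec.mock_efflux + activity_pct / 100.0 * span


def _clip_fraction(f: float, label: str) -> float:
    if not (0.0 <= f <= 1.0):
        logger.info("clipping efflux fraction %.4f for %s", f, label)
        return float(np.clip(f, 0.0, 1.0))
    return f


def _wellset(
    spec: GeneratorSpec,
    rng: np.random.Generator,
    construct: str,
    exp: str,
    condition: str,
    treatment: str,
    f: float,
) -> EffluxMeasurement:
    f = _clip_fraction(f, f"{construct}/{exp}/{condition}")
    total = spec.signal_scale * float(
        np.exp(rng.normal(0.0, spec.experiment_jitter_sigma))
    )
    noise_m = np.exp(rng.normal(0.0, spec.well_sigma, size=3))
    noise_l = np.exp(rng.normal(0.0, spec.well_sigma, size=3))
    return EffluxMeasurement(
        construct_id=construct,
        experiment_id=exp,
        condition=condition,
        treatment=treatment,
        medium_signals=tuple(total * f * noise_m),
        lysate_signals=tuple(total * (1.0 - f) * noise_l),
    )


def generate_plates(
    spec: GeneratorSpec,
    *,
    treatment: str = MOCK_TREATMENT,
    activities: Optional[dict[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[EffluxMeasurement]:
    """Synthetic plate fluorescence for all constructs, WT and mock included."""
    rng = spec.rng() if rng is None else rng
    activities = spec.activities if activities is None else activities
    constructs: list[tuple[str, float]] = [(WT_ID, 100.0), (MOCK_ID, 0.0)]
    constructs += sorted(activities.items())
    measurements: list[EffluxMeasurement] = []
    for i in range(1, spec.n_experiments + 1):
        exp = f"E{i}"
        for construct, activity in constructs:
            if construct == MOCK_ID:
                f_acc = spec.leakage + spec.mock_efflux
            else:
                f_acc = _acceptor_fraction(spec, activity)
            measurements.append(
                _wellset(spec, rng, construct, exp, ACCEPTOR, treatment, f_acc)
            )
            measurements.append(
                _wellset(spec, rng, construct, exp, NO_ACCEPTOR, treatment,
                         spec.leakage)
            )
    return measurements


def generate_bands(
    spec: GeneratorSpec,
    *,
    treatment: str = MOCK_TREATMENT,
    surface_truth: Optional[dict[str, tuple[float, float]]] = None,
    rng: Optional[np.random.Generator] = None,
    wt_surface: float = 500.0,
    wt_total: float = 800.0,
    actin: float = 1000.0,
) -> list[SurfaceMeasurement]:
    """Synthetic densitometry around per-variant (raw %, corrected %) truths.

    WT truth is (100, 100). A variant with truth ``(r, c)`` gets a surface
    band scaled by ``r/100`` and a total band scaled by ``r/c`` relative to
    WT, so the analysis recovers exactly ``(r, c)`` at zero noise.
    """
    rng = spec.rng() if rng is None else rng
    truths = dict(spec.surface_truth if surface_truth is None else surface_truth)
    truths[WT_ID] = (100.0, 100.0)
    out: list[SurfaceMeasurement] = []
    for i in range(1, spec.n_experiments + 1):
        exp = f"E{i}"
        for construct in sorted(truths):
            r, c = truths[construct]
            if c <= 0:
                raise ValueError(f"corrected truth must be positive for {construct}")
            eps = np.exp(rng.normal(0.0, spec.well_sigma, size=3))
            out.append(
                SurfaceMeasurement(
                    construct_id=construct,
                    experiment_id=exp,
                    treatment=treatment,
                    surface_band=wt_surface * r / 100.0 * eps[0],
                    total_band=wt_total * (r / c) * eps[1],
                    loading_band=actin * eps[2],
                )
            )
    return out


def generate_rescue_dataset(
    spec: GeneratorSpec,
) -> tuple[list[EffluxMeasurement], list[SurfaceMeasurement]]:
    """Two-arm (mock / 4-PBA) plates and bands per the rescue profiles.

    ``rescuable`` variants gain ``rescue_efflux_gain`` percentage points of
    efflux and a surface increase under 4-PBA; ``atpase_deficient`` variants
    gain the surface increase but no efflux; ``unaffected`` variants change
    in neither readout.
    """
    rng = spec.rng()
    profiles = spec.rescue_profiles or {
        name: UNAFFECTED_PROFILE for name in spec.activities
    }
    pba_activities = {}
    for name, activity in spec.activities.items():
        gain = spec.rescue_efflux_gain if profiles.get(name) == RESCUABLE else 0.0
        pba_activities[name] = activity + gain

    plates = generate_plates(spec, treatment=MOCK_TREATMENT, rng=rng)
    plates += generate_plates(
        spec, treatment=PBA_TREATMENT, activities=pba_activities, rng=rng
    )

    base_truth = spec.surface_truth or {
        name: (60.0, 90.0) for name in spec.activities
    }
    pba_truth = {}
    for name, (r, c) in base_truth.items():
        factor = (
            spec.rescue_surface_factor
            if profiles.get(name) in (RESCUABLE, ATPASE_DEFICIENT)
            else 1.0
        )
        pba_truth[name] = (r * factor, c)
    bands = generate_bands(spec, treatment=MOCK_TREATMENT,
                           surface_truth=base_truth, rng=rng)
    bands += generate_bands(spec, treatment=PBA_TREATMENT,
                            surface_truth=pba_truth, rng=rng)
    return plates, bands


def generate_variant_table(spec: GeneratorSpec) -> list[dict]:
    """Annotation rows spanning every frequency and phenotype tier.

    Returns dicts with the variant-table columns (variant_p, variant_c, faf,
    hdl_c, tangier, criteria). Deterministic under the spec's seed.
    """
    rng = spec.rng()
    faf_tiers = [0.006, 0.003, 0.0001, 0.001]        # BA1, BS1, PM2, none
    hdl_tiers = [0.45, 0.25, 0.05, None]             # supporting/moderate/strong/none
    rows: list[dict] = []
    names = sorted(spec.activities) or [f"p.V{i}A" for i in range(1, 7)]
    for i, name in enumerate(names):
        rows.append(
            {
                "variant_p": name,
                "variant_c": f"c.{100 + 3 * i}T>C",
                "faf": faf_tiers[i % len(faf_tiers)],
                "hdl_c": hdl_tiers[i % len(hdl_tiers)],
                "tangier": False,
                "criteria": "",
            }
        )
    # guarantee one Tangier carrier regardless of panel size
    rows.append(
        {
            "variant_p": "p.W590S",
            "variant_c": "c.1769G>C",
            "faf": float(rng.uniform(0.0, 1e-5)),
            "hdl_c": None,
            "tangier": True,
            "criteria": "PM2",
        }
    )
    return rows


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return [
        _AA[k] for k in rng.integers(0, len(_AA), size=length)
    ]


def generate_duplicated_domain_sequence(
    length: int = 60,
    divergence: float = 0.0,
    seed: int = 0,
    linker: int = 10,
) -> tuple[str, dict]:
    """Toy protein whose second half is a diverged copy of the first.

    Returns ``(sequence, truth)`` where truth holds the two inclusive 1-based
    windows and the list of conserved (identical) position pairs. With
    ``divergence == 0`` the windows are identical, so alignment yields 100 %
    identity with a constant offset.
    """
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w1 = _random_protein(rng, length)
    w2 = list(w1)
    for i in range(length):
        if rng.random() < divergence:
            choices = [a for a in _AA if a != w2[i]]
            w2[i] = choices[int(rng.integers(0, len(choices)))]
    pad = _random_protein(rng, linker)
    seq = "".join(w1) + "".join(pad) + "".join(w2)
    window1 = (1, length)
    window2 = (length + linker + 1, 2 * length + linker)
    conserved_pairs = [
        (i + 1, length + linker + i + 1)
        for i in range(length)
        if w1[i] == w2[i]
    ]
    return seq, {
        "nbd1_window": window1,
        "nbd2_window": window2,
        "conserved_pairs": conserved_pairs,
    }


# Anchor pairs planted in the synthetic reference protein: the published
# monotone-consistent equivalent positions with their wild-type residues.
REFERENCE_ANCHOR_PAIRS: tuple[tuple[int, int, str], ...] = (
    (939, 1952, "K"),   # Walker A lysine
    (1034, 2046, "S"),
    (1064, 2076, "D"),  # Walker B aspartate
    (1093, 2106, "E"),
    (1107, 2120, "G"),
)

_NBD1_WINDOW = (923, 1121)
_NBD2_WINDOW = (1936, 2134)
_PROTEIN_LENGTH = 2261


def synthetic_reference_protein(
    seed: int = 0, divergence: float = 0.30
) -> tuple[str, list[tuple[int, int, str]]]:
    """Synthetic stand-in for the ABCA1 reference protein.

    This is NOT the NM_005502.4 product: it is a random protein of the same
    length whose NBD2 window is a diverged copy of its NBD1 window,
    constructed so that a global alignment of the windows 923–1121 and
    1936–2134 reproduces the published equivalent-position pairs
    (939↔1952, 1034↔2046, 1064↔2076, 1093↔2106, 1107↔2120) with the
    wild-type residues planted at those positions. The coordinate offsets of
    the pairs (1013/1012/1013) are realized by one single-residue deletion
    and one insertion inside the copied window; anchor neighbourhoods are
    kept identical so the alignment is pinned locally.

    Returns ``(sequence, anchor_pairs)``.
    """
    rng = np.random.default_rng(seed)
    seq = _random_protein(rng, _PROTEIN_LENGTH)

    lo1, hi1 = _NBD1_WINDOW
    s1 = seq[lo1 - 1 : hi1]  # 199 residues, s1[k] is full position 923+k

    # plant wild-type residues at the NBD1 anchor positions
    for pos1, _pos2, aa in REFERENCE_ANCHOR_PAIRS:
        s1[pos1 - lo1] = aa

    # copy with one deletion (index 60) and one insertion (index 155):
    # s2[k] = s1[k]   for k < 60
    # s2[k] = s1[k+1] for 60 <= k < 155   (offset 1012 region)
    # s2[155] = inserted residue (unmatched)
    # s2[k] = s1[k]   for k >= 156        (offset 1013 region)
    s2 = s1[:60] + s1[61:156] + ["W"] + s1[156:]
    assert len(s2) == len(s1)

    # protected indices in s2 (anchor neighbourhoods and indel flanks)
    anchor_idx2 = {pos2 - _NBD2_WINDOW[0] for _p1, pos2, _aa in
                   REFERENCE_ANCHOR_PAIRS}
    protected: set[int] = set()
    for idx in anchor_idx2:
        protected.update(range(idx - 4, idx + 5))
    for idx in (59, 60, 61, 154, 155, 156):
        protected.update(range(idx - 3, idx + 4))

    for k in range(len(s2)):
        if k in protected:
            continue
        if rng.random() < divergence:
            choices = [a for a in _AA if a != s2[k]]
            s2[k] = choices[int(rng.integers(0, len(choices)))]

    lo2, hi2 = _NBD2_WINDOW
    seq[lo1 - 1 : hi1] = s1
    seq[lo2 - 1 : hi2] = s2
    return "".join(seq), [(p1, p2, aa) for p1, p2, aa in REFERENCE_ANCHOR_PAIRS]


def write_fasta(sequence: str, path, header: str = "synthetic_abca1") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")
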