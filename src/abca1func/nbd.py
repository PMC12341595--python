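"""NBD1 ↔ NBD2 alignment and equivalent-position mapping.

The two nucleotide-binding domains of ABCA1 are homologous; aligning their
sequences maps each NBD1 residue to its structural equivalent in NBD2 (and
vice versa), which lets an observed variant in one domain be mirrored into
the other when the residue is conserved. The alignment is a deterministic
global (Needleman–Wunsch) pairwise alignment with a BLOSUM62 scoring matrix
and affine gap penalties, computed over the two inclusive full-protein
windows handed in (defaults 923–1121 and 1936–2134).

Definitions fixed here because they are otherwise ambiguous: *identity* is
the fraction of alignment columns whose residues are identical and
*similarity* the fraction whose substitution score is positive, with gap
columns counted in both denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .config import CalibrationConfig
from .domains import VariantRecord, format_variant


@dataclass(frozen=True)
class PositionPair:
    """One aligned (non-gap) column in full-protein 1-based coordinates."""

    nbd1_pos: int
    nbd2_pos: int
    nbd1_aa: str
    nbd2_aa: str
    conserved: bool  # identical residues


@dataclass
class EquivalenceMap:
    pairs: list[PositionPair] = field(default_factory=list)
    n_columns: int = 0
    percent_identity: float = 0.0
    percent_similarity: float = 0.0
    nbd1_window: tuple[int, int] = (0, 0)
    nbd2_window: tuple[int, int] = (0, 0)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev = (0, 0)
        for p in self.pairs:
            if not (p.nbd1_pos > prev[0] and p.nbd2_pos > prev[1]):
                raise ValueError("aligned pairs must be strictly increasing")
            prev = (p.nbd1_pos, p.nbd2_pos)

    def by_nbd1(self) -> dict[int, PositionPair]:
        return {p.nbd1_pos: p for p in self.pairs}

    def by_nbd2(self) -> dict[int, PositionPair]:
        return {p.nbd2_pos: p for p in self.pairs}


def read_protein_fasta(path) -> str:
    """First record of a FASTA file as an upper-case sequence string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def align_nbds(
    sequence: str,
    nbd1_window: Optional[tuple[int, int]] = None,
    nbd2_window: Optional[tuple[int, int]] = None,
    *,
    config: Optional[CalibrationConfig] = None,
    gap_open: Optional[float] = None,
    gap_extend: Optional[float] = None,
    matrix: Optional[str] = None,
) -> EquivalenceMap:
    """Globally align the two NBD windows of ``sequence``.

    Windows are inclusive 1-based full-protein coordinate ranges; scoring
    parameters default to the calibration config (BLOSUM62, open −10,
    extend −0.5). The first optimal alignment of the deterministic dynamic
    program is used, so repeated calls give identical maps.
    """
    cfg = config or CalibrationConfig()
    nbd1_window = tuple(nbd1_window or cfg.nbd1_window)
    nbd2_window = tuple(nbd2_window or cfg.nbd2_window)
    gap_open = cfg.gap_open if gap_open is None else gap_open
    gap_extend = cfg.gap_extend if gap_extend is None else gap_extend
    matrix_name = matrix or cfg.substitution_matrix

    sequence = sequence.upper()
    for lo, hi in (nbd1_window, nbd2_window):
        if not (1 <= lo <= hi <= len(sequence)):
            raise ValueError(
                f"window {lo}-{hi} outside sequence of length {len(sequence)}"
            )
    s1 = sequence[nbd1_window[0] - 1 : nbd1_window[1]]
    s2 = sequence[nbd2_window[0] - 1 : nbd2_window[1]]

    subs = substitution_matrices.load(matrix_name)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = subs
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(s1, s2)[0]

    pairs: list[PositionPair] = []
    blocks1, blocks2 = alignment.aligned
    for (a0, a1), (b0, b1) in zip(blocks1, blocks2):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            aa1, aa2 = s1[i], s2[j]
            pairs.append(
                PositionPair(
                    nbd1_pos=nbd1_window[0] + i,
                    nbd2_pos=nbd2_window[0] + j,
                    nbd1_aa=aa1,
                    nbd2_aa=aa2,
                    conserved=aa1 == aa2,
                )
            )
    if not pairs:
        raise ValueError("alignment produced no matched columns")

    n_columns = alignment.length
    n_identical = sum(p.conserved for p in pairs)
    n_similar = sum(
        1 for p in pairs if subs[p.nbd1_aa, p.nbd2_aa] > 0
    )
    return EquivalenceMap(
        pairs=pairs,
        n_columns=n_columns,
        percent_identity=100.0 * n_identical / n_columns,
        percent_similarity=100.0 * n_similar / n_columns,
        nbd1_window=nbd1_window,
        nbd2_window=nbd2_window,
        parameters={
            "matrix": matrix_name,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
            "score": float(alignment.score),
        },
    )


def equivalent_variant(
    variant: VariantRecord, emap: EquivalenceMap
) -> Optional[VariantRecord]:
    """Mirror a variant into the opposite NBD at its aligned position.

    Returns the mirrored variant only when the aligned column is conserved
    (identical residues); ``None`` for non-conserved or gapped columns.
    Raises ``ValueError`` when the position lies in neither window or the
    variant's reference residue disagrees with the sequence.
    """
    pos = variant.position
    in1 = emap.nbd1_window[0] <= pos <= emap.nbd1_window[1]
    in2 = emap.nbd2_window[0] <= pos <= emap.nbd2_window[1]
    if not (in1 or in2):
        raise ValueError(
            f"position {pos} lies in neither NBD window "
            f"{emap.nbd1_window} / {emap.nbd2_window}"
        )
    pair = (emap.by_nbd1() if in1 else emap.by_nbd2()).get(pos)
    if pair is None:
        return None  # position sits in a gap column
    seq_aa = pair.nbd1_aa if in1 else pair.nbd2_aa
    if seq_aa != variant.ref_aa:
        raise ValueError(
            f"reference residue mismatch at {pos}: variant says "
            f"{variant.ref_aa}, sequence has {seq_aa}"
        )
    if not pair.conserved:
        return None
    mirrored_pos = pair.nbd2_pos if in1 else pair.nbd1_pos
    return VariantRecord(
        ref_aa=variant.ref_aa, position=mirrored_pos, alt_aa=variant.alt_aa
    )


def domain_similarity(emap: EquivalenceMap) -> tuple[float, float]:
    """(percent identity, percent similarity) of the aligned domains."""
    if not emap.pairs:
        raise ValueError("empty equivalence map")
    return emap.percent_identity, emap.percent_similarity


def proposed_equivalents(
    variants: list[VariantRecord], emap: EquivalenceMap
) -> dict[str, Optional[str]]:
    """Convenience: map variant names to their mirrored names (or None)."""
    out: dict[str, Optional[str]] = {}
    for v in variants:
        mirrored = equivalent_variant(v, emap)
        out[v.name] = None if mirrored is None else format_variant(
            mirrored.ref_aa, mirrored.position, mirrored.alt_aa
        )
    return out
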