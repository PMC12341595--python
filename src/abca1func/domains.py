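"""Variant naming and protein-topology mapping for ABCA1.

Parses protein-level variant names of the ``p.<ref><position><alt>`` form
(1- or 3-letter residue codes, codon numbering per the ABCA1 reference
transcript with the ATG start codon as codon 1) and assigns residue positions
to the transporter's intracellular regions — the two nucleotide-binding
domains (NBD1, NBD2), the regulatory domains (R1, R2) and the four
intracellular coupling helices (IH1–IH4) — and to the three conserved
ATP-binding motifs within each NBD (Walker A, Walker B, signature).

The default :class:`DomainMap` ships as JSON package data containing exactly
the published residue ranges; positions outside every listed range map to the
catch-all label ``"linker/other"``. Extracellular and transmembrane ranges are
deliberately not encoded.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import VariantParseError

OTHER_REGION = "linker/other"
ATP_MOTIFS = ("Walker_A", "Walker_B", "signature")

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")
_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")


def _normalize_aa(token: str, name: str) -> str:
    """Normalize a 1- or 3-letter amino-acid code to 1-letter."""
    if len(token) == 1:
        aa = token.upper()
        if aa not in _AA1:
            raise VariantParseError(f"unknown amino-acid code '{token}' in '{name}'")
        return aa
    if len(token) == 3:
        aa = _AA3TO1.get(token.capitalize())
        if aa is None:
            raise VariantParseError(f"unknown amino-acid code '{token}' in '{name}'")
        return aa
    raise VariantParseError(f"unknown amino-acid code '{token}' in '{name}'")


def parse_protein_variant(name: str) -> tuple[str, int, str]:
    """Parse a ``p.``-style missense variant name into (ref, position, alt).

    Three-letter residue codes are normalized to one-letter; the ``p.``
    prefix is optional. Raises :class:`VariantParseError` on malformed
    strings, unknown residue codes, position 0 or silent (ref == alt)
    substitutions.
    """
    m = _VARIANT_RE.match(name.strip())
    if m is None:
        raise VariantParseError(f"malformed protein variant name: '{name}'")
    ref_tok, pos_str, alt_tok = m.groups()
    if len(ref_tok) == 2 or len(alt_tok) == 2:
        raise VariantParseError(f"malformed protein variant name: '{name}'")
    ref = _normalize_aa(ref_tok, name)
    alt = _normalize_aa(alt_tok, name)
    position = int(pos_str)
    if position < 1:
        raise VariantParseError(f"position must be >= 1 in '{name}'")
    if ref == alt:
        raise VariantParseError(
            f"reference and alternate residue are both '{ref}' in '{name}'"
        )
    return ref, position, alt


def format_variant(ref_aa: str, position: int, alt_aa: str) -> str:
    return f"p.{ref_aa}{position}{alt_aa}"


@dataclass(frozen=True)
class VariantRecord:
    """A missense variant with its clinical annotations.

    ``asserted_criteria`` holds ACMG criterion evidence asserted upstream of
    this package (tuple of :class:`abca1func.acmg.CriterionEvidence`).
    """

    ref_aa: str
    position: int
    alt_aa: str
    cdna_change: Optional[str] = None
    filtering_allele_frequency: Optional[float] = None
    hdl_c: Optional[float] = None
    tangier_disease: bool = False
    asserted_criteria: tuple = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise VariantParseError("ref_aa equals alt_aa")
        faf = self.filtering_allele_frequency
        if faf is not None and not (0.0 <= faf <= 1.0):
            raise VariantParseError(f"allele frequency outside [0, 1]: {faf}")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "VariantRecord":
        ref, pos, alt = parse_protein_variant(name)
        return cls(ref_aa=ref, position=pos, alt_aa=alt, **kwargs)

    @property
    def name(self) -> str:
        return format_variant(self.ref_aa, self.position, self.alt_aa)


@dataclass(frozen=True)
class Range:
    name: str
    start: int
    end: int
    domain: Optional[str] = None  # parent NBD for motifs

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class DomainMap:
    """Inclusive 1-based residue ranges for regions, ATP motifs and latch features."""

    regions: list[Range] = field(default_factory=list)
    motifs: list[Range] = field(default_factory=list)
    features: list[Range] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [r.name for r in self.regions]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        for r in self.regions + self.motifs + self.features:
            if r.start > r.end:
                raise ValueError(f"range {r.name} has start > end")
        for a, b in zip(sorted(self.regions, key=lambda r: r.start),
                        sorted(self.regions, key=lambda r: r.start)[1:]):
            if b.start <= a.end:
                raise ValueError(f"regions {a.name} and {b.name} overlap")
        nbds = {r.name: r for r in self.regions if r.name.startswith("NBD")}
        for m in self.motifs:
            parent = nbds.get(m.domain or "")
            if parent is None or m.start < parent.start or m.end > parent.end:
                raise ValueError(
                    f"motif {m.name}({m.domain}) not contained in its parent NBD"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "DomainMap":
        return cls(
            regions=[Range(r["name"], r["start"], r["end"]) for r in d["regions"]],
            motifs=[
                Range(m["name"], m["start"], m["end"], domain=m["domain"])
                for m in d["motifs"]
            ],
            features=[
                Range(f["name"], f["start"], f["end"])
                for f in d.get("features", [])
            ],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "DomainMap":
        """The shipped map with the published ABCA1 intracellular ranges."""
        text = resources.files("abca1func.data").joinpath("domain_map.json").read_text()
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return {
            "regions": [{"name": r.name, "start": r.start, "end": r.end}
                        for r in self.regions],
            "motifs": [{"name": m.name, "domain": m.domain,
                        "start": m.start, "end": m.end} for m in self.motifs],
            "features": [{"name": f.name, "start": f.start, "end": f.end}
                         for f in self.features],
        }


def assign_region(position: int, domain_map: DomainMap) -> str:
    """Region label containing ``position``; ``"linker/other"`` if none does."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    for region in domain_map.regions:
        if position in region:
            return region.name
    return OTHER_REGION


def assign_motif(position: int, domain_map: DomainMap) -> Optional[tuple[str, str]]:
    """ATP-binding motif containing ``position`` as (motif_name, NBD tag), or None."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    for motif in domain_map.motifs:
        if position in motif:
            return motif.name, motif.domain or ""
    return None


def count_by_region(
    variants: Iterable[VariantRecord], domain_map: DomainMap
) -> dict[str, int]:
    """Count variants per region; every variant counts exactly once.

    Regions without any variant are included with count 0 (as is the
    catch-all ``"linker/other"`` label), so the counts always sum to the
    number of input variants.
    """
    counts: Counter[str] = Counter({r.name: 0 for r in domain_map.regions})
    counts[OTHER_REGION] = 0
    for v in variants:
        counts[assign_region(v.position, domain_map)] += 1
    return dict(counts)
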