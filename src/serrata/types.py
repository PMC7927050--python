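"""Core domain types shared across the pipeline.

All variant coordinates are 1-based inclusive (VCF dialect); callable-region
intervals are 0-based half-open (BED dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "PREDICTOR_TOOLS",
    "IMPACT_CLASSES",
    "TRUNCATING_CONSEQUENCES",
    "AnnotatedVariant",
    "GenotypeCall",
    "PedigreeMember",
    "Pedigree",
    "SignatureCatalog",
    "CandidateGene",
    "classify_allele_pair",
    "impact_class_of",
]

#: The six deleteriousness predictors consumed from VCF INFO tags.
PREDICTOR_TOOLS = ("phylop", "sift", "polyphen", "mutationtaster", "gerp", "lrt")

IMPACT_CLASSES = ("synonymous", "missense", "truncating", "other")

#: Consequence terms collapsed into the "truncating" impact class:
#: nonsense, frameshift and essential-splice (+/-1,2) changes.
TRUNCATING_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_acceptor", "splice_donor"}
)

_KNOWN_CONSEQUENCES = {
    "missense": "missense",
    "synonymous": "synonymous",
    "stop_gained": "truncating",
    "frameshift": "truncating",
    "splice_acceptor": "truncating",
    "splice_donor": "truncating",
    "inframe_deletion": "other",
    "inframe_insertion": "other",
    "intron": "other",
    "utr": "other",
    "intergenic": "other",
    "upstream": "other",
    "downstream": "other",
}


def impact_class_of(consequence: str) -> tuple[str, bool]:
    """Map a raw consequence term to an impact class.

    Returns ``(impact, known)``; unknown terms map to ``other`` with
    ``known=False`` so callers can emit a record-level warning.
    """
    key = consequence.strip().lower()
    if key in _KNOWN_CONSEQUENCES:
        return _KNOWN_CONSEQUENCES[key], True
    return "other", False


def classify_allele_pair(ref: str, alt: str) -> str:
    """Classify a (ref, alt) pair as SNV / insertion / deletion / MNV."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "MNV"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One (record, alt-allele) pair with its consumed annotations.

    ``maf`` is derived: the maximum over the population frequencies that are
    present, 0.0 when the variant is absent from every database.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    impact: str = "other"
    protein_change: str = ""
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    predictor_verdicts: Mapping[str, str] = field(default_factory=dict)
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact!r}")
        for tool in self.predictor_verdicts:
            if tool not in PREDICTOR_TOOLS:
                raise ValueError(f"predictor verdict for unknown tool {tool!r}")
        for db, f in self.pop_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {db} outside [0, 1]")

    @property
    def var_class(self) -> str:
        return classify_allele_pair(self.ref, self.alt)

    @property
    def maf(self) -> float:
        if not self.pop_freqs:
            return 0.0
        return max(self.pop_freqs.values())

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity for cross-family matching: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_flags(self, *flags: str) -> "AnnotatedVariant":
        return replace(self, flags=self.flags | set(flags))


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample genotype with allele depths for one alt allele."""

    sample_id: str
    gt: str  # hom_ref | het | hom_alt | missing
    ref_count: int = 0
    alt_count: int = 0
    depth: int = 0
    depths_available: bool = True

    def __post_init__(self) -> None:
        if self.gt not in ("hom_ref", "het", "hom_alt", "missing"):
            raise ValueError(f"bad genotype {self.gt!r}")
        if min(self.ref_count, self.alt_count, self.depth) < 0:
            raise ValueError("negative read counts")
        if self.depths_available and self.ref_count + self.alt_count > self.depth:
            raise ValueError(
                f"AD {self.ref_count}+{self.alt_count} exceeds DP {self.depth} "
                f"for {self.sample_id}"
            )

    @property
    def aaf(self) -> float:
        """Alternative allele frequency: alt reads / total depth."""
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def carries_alt(self) -> bool:
        return self.gt in ("het", "hom_alt")


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    affected: bool
    sequenced_germline: bool = True
    has_somatic: bool = False
    father: str = "0"
    mother: str = "0"
    sex: int = 0


@dataclass(frozen=True)
class Pedigree:
    family_id: str
    members: tuple[PedigreeMember, ...]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample_id in family {self.family_id}")
        if not any(m.affected and m.sequenced_germline for m in self.members):
            raise ValueError(
                f"family {self.family_id} has no affected sequenced member"
            )

    @property
    def affected_sequenced(self) -> tuple[PedigreeMember, ...]:
        return tuple(
            m for m in self.members if m.affected and m.sequenced_germline
        )

    @property
    def somatic_members(self) -> tuple[PedigreeMember, ...]:
        return tuple(m for m in self.members if m.has_somatic)


class SignatureCatalog:
    """Ordered category labels plus named unit-sum signature profiles."""

    def __init__(
        self,
        categories: Iterable[str],
        signatures: Mapping[str, Iterable[float]],
        scheme: str = "",
    ) -> None:
        import numpy as np

        self.categories: tuple[str, ...] = tuple(categories)
        self.scheme = scheme
        self.signatures: dict[str, "np.ndarray"] = {}
        for name, profile in signatures.items():
            vec = np.asarray(list(profile), dtype=float)
            if vec.shape != (len(self.categories),):
                raise ValueError(
                    f"signature {name}: profile length {vec.size} != "
                    f"{len(self.categories)} categories"
                )
            if (vec < 0).any():
                raise ValueError(f"signature {name}: negative entry")
            total = vec.sum()
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"signature {name}: profile sums to {total:.6g}, not 1"
                )
            self.signatures[name] = vec / total

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.signatures)

    def matrix(self, names: Iterable[str] | None = None):
        """Column-stacked profile matrix (categories x signatures)."""
        import numpy as np

        use = tuple(names) if names is not None else self.names
        return np.column_stack([self.signatures[n] for n in use])

    def subset(self, names: Iterable[str]) -> "SignatureCatalog":
        return SignatureCatalog(
            self.categories,
            {n: self.signatures[n] for n in names},
            scheme=self.scheme,
        )


@dataclass(frozen=True)
class CandidateGene:
    """One gene-level evidence row of the final candidate table."""

    gene: str
    family_id: str
    variant_hgvs: str
    predictor_score: int | None
    max_pop_af: float
    evidence: str  # "G" or "G-S paired analysis"
    selection_criterion: str
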