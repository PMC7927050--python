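"""Three-round germline variant prioritization with family co-segregation.

Round 1: hard filters — population frequency strictly below threshold,
impact restricted to missense/truncating, and for missense a minimum count
of deleterious predictor verdicts (truncating variants pass on impact
alone). Round 2: shared-by-all-affected segregation within the family,
cross-family consistency exclusion, external exclusion list, and removal
of genes in excluded function sets. Round 3: retention of genes in at
least one prioritized function set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .types import AnnotatedVariant, GenotypeCall, Pedigree

__all__ = [
    "FilterConfig",
    "GeneSets",
    "PrioritizedVariant",
    "predictor_score",
    "filter_round1",
    "segregation_filter",
    "cross_family_exclusion",
    "gene_function_prioritize",
    "prioritize_family",
    "prioritize_cohort",
    "CRITERION_LABELS",
]

#: Selection-criterion vocabulary for the candidate table.
CRITERION_LABELS = {
    "cancer": "Involvement in cancer development",
    "senescence": "Senescence candidate",
    "epigenetics": "Epigenetics regulator candidate",
}


@dataclass(frozen=True)
class FilterConfig:
    maf_threshold: float = 0.001
    min_deleterious_votes: int = 3
    retained_impacts: frozenset[str] = frozenset({"missense", "truncating"})
    inheritance: str = "both"  # dominant | recessive | both
    shared_by_all_affected: bool = True
    #: missing genotype in an affected member fails the shared rule
    missing_genotype_fails: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise ValueError("maf_threshold outside [0, 1]")
        if not 0 <= self.min_deleterious_votes <= 6:
            raise ValueError("min_deleterious_votes outside [0, 6]")
        if self.inheritance not in ("dominant", "recessive", "both"):
            raise ValueError(f"bad inheritance {self.inheritance!r}")


@dataclass(frozen=True)
class GeneSets:
    """Declarative stand-in for the study's manual function curation."""

    prioritized: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    excluded: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.all_prioritized & self.all_excluded
        if overlap:
            raise ValueError(
                f"genes in both prioritized and excluded sets: {sorted(overlap)}"
            )

    @property
    def all_prioritized(self) -> frozenset[str]:
        return frozenset(g for gs in self.prioritized.values() for g in gs)

    @property
    def all_excluded(self) -> frozenset[str]:
        return frozenset(g for gs in self.excluded.values() for g in gs)

    def criteria_for(self, gene: str) -> tuple[str, ...]:
        return tuple(
            name for name, genes in self.prioritized.items() if gene in genes
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneSets":
        return cls(
            prioritized={
                k: tuple(v) for k, v in (data.get("prioritized") or {}).items()
            },
            excluded={
                k: tuple(v) for k, v in (data.get("excluded") or {}).items()
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "GeneSets":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def dump(self, path: str | Path) -> None:
        data = {
            "prioritized": {k: list(v) for k, v in self.prioritized.items()},
            "excluded": {k: list(v) for k, v in self.excluded.items()},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass(frozen=True)
class PrioritizedVariant:
    variant: AnnotatedVariant
    family_id: str
    round_reached: int  # 1 | 2 | 3
    predictor_score: int
    inheritance_model: str = ""  # dominant | recessive
    selection_criterion: str = ""

    @property
    def gene(self) -> str:
        return self.variant.gene


def predictor_score(variant: AnnotatedVariant) -> int:
    """Count of tools voting deleterious; unavailable/missing counts 0."""
    return sum(
        1 for v in variant.predictor_verdicts.values() if v == "deleterious"
    )


def filter_round1(
    variants: Iterable[AnnotatedVariant], config: FilterConfig = FilterConfig()
) -> list[AnnotatedVariant]:
    """Hard filters: maf strictly < threshold, retained impact class, and
    for non-truncating impacts at least ``min_deleterious_votes``
    deleterious verdicts. Input order is preserved."""
    out = []
    for v in variants:
        if v.maf >= config.maf_threshold:
            continue
        if v.impact not in config.retained_impacts:
            continue
        if v.impact != "truncating" and predictor_score(v) < config.min_deleterious_votes:
            continue
        out.append(v)
    return out


def segregation_filter(
    variants: Iterable[AnnotatedVariant],
    genotypes: Mapping[tuple, Mapping[str, GenotypeCall]],
    pedigree: Pedigree,
    config: FilterConfig = FilterConfig(),
) -> list[tuple[AnnotatedVariant, str]]:
    """Retain variants shared by all affected sequenced members.

    ``genotypes`` maps variant key -> {sample_id: GenotypeCall}. Under the
    dominant model every affected member must carry the alt allele (het or
    hom_alt); under the recessive model every affected member must be
    hom_alt, or the gene must carry >= 2 distinct retained het variants
    shared by all affected (unphased compound-het surrogate). Returns
    (variant, model) pairs.
    """
    affected = [m.sample_id for m in pedigree.affected_sequenced]
    variants = list(variants)

    def shared(variant: AnnotatedVariant, require: str) -> bool:
        for sid in affected:
            call = genotypes.get(variant.key, {}).get(sid)
            if call is None or call.gt == "missing":
                if config.missing_genotype_fails:
                    return False
                continue
            if require == "carrier" and not call.carries_alt:
                return False
            if require == "hom_alt" and call.gt != "hom_alt":
                return False
            if require == "het" and call.gt != "het":
                return False
        return True

    out: list[tuple[AnnotatedVariant, str]] = []
    dominant_ok = config.inheritance in ("dominant", "both")
    recessive_ok = config.inheritance in ("recessive", "both")

    # unphased compound-het surrogate: genes with >=2 distinct shared hets
    comphet_genes: set[str] = set()
    if recessive_ok:
        shared_hets: dict[str, int] = {}
        for v in variants:
            if v.gene and shared(v, "het"):
                shared_hets[v.gene] = shared_hets.get(v.gene, 0) + 1
        comphet_genes = {g for g, n in shared_hets.items() if n >= 2}

    for v in variants:
        if dominant_ok and shared(v, "carrier"):
            out.append((v, "dominant"))
        elif recessive_ok and (
            shared(v, "hom_alt") or (v.gene in comphet_genes and shared(v, "het"))
        ):
            out.append((v, "recessive"))
    return out


def cross_family_exclusion(
    per_family_retained: Mapping[str, Sequence[tuple[AnnotatedVariant, str]]],
    per_family_genotypes: Mapping[str, Mapping[tuple, Mapping[str, GenotypeCall]]],
    pedigrees: Mapping[str, Pedigree],
    external_exclusion: Iterable[tuple] = (),
    config: FilterConfig = FilterConfig(),
) -> dict[str, list[tuple[AnnotatedVariant, str]]]:
    """Drop variants that segregate inconsistently in another family.

    A variant retained in family A is removed when the identical
    (chrom, pos, ref, alt) is observed in any member of another family
    where it fails the shared-by-all-affected rule, or when it appears on
    the external exclusion list.
    """
    external = {tuple(k) for k in external_exclusion}

    # where is each variant key observed, and does it segregate there?
    observed_in: dict[tuple, set[str]] = {}
    segregates_in: dict[tuple, set[str]] = {}
    for fam, gmap in per_family_genotypes.items():
        ped = pedigrees[fam]
        affected = [m.sample_id for m in ped.affected_sequenced]
        for key, calls in gmap.items():
            carriers = [s for s, c in calls.items() if c.carries_alt]
            if not carriers:
                continue
            observed_in.setdefault(key, set()).add(fam)
            ok = all(
                (c := calls.get(sid)) is not None
                and c.gt != "missing"
                and c.carries_alt
                for sid in affected
            )
            if ok:
                segregates_in.setdefault(key, set()).add(fam)

    out: dict[str, list[tuple[AnnotatedVariant, str]]] = {}
    for fam, retained in per_family_retained.items():
        kept = []
        for v, model in retained:
            if v.key in external:
                continue
            bad = any(
                other != fam and other not in segregates_in.get(v.key, set())
                for other in observed_in.get(v.key, set())
            )
            if not bad:
                kept.append((v, model))
        out[fam] = kept
    return out


def gene_function_prioritize(
    variants: Iterable[PrioritizedVariant],
    gene_sets: GeneSets,
    round: int,
) -> list[PrioritizedVariant]:
    """Round 2 removes excluded-set genes; round 3 keeps prioritized-set
    genes only, attaching the selection criterion."""
    if round not in (2, 3):
        raise ValueError("round must be 2 or 3")
    out = []
    if round == 2:
        excluded = gene_sets.all_excluded
        for pv in variants:
            if pv.gene not in excluded:
                out.append(replace(pv, round_reached=max(pv.round_reached, 2)))
        return out
    for pv in variants:
        criteria = gene_sets.criteria_for(pv.gene)
        if criteria:
            label = " and ".join(
                CRITERION_LABELS.get(c, c) for c in sorted(criteria)
            )
            out.append(
                replace(pv, round_reached=3, selection_criterion=label)
            )
    return out


# ---------------------------------------------------------------------------
# Orchestration helpers
# ---------------------------------------------------------------------------

@dataclass
class FamilyPrioritization:
    family_id: str
    n_input: int
    round1: list[AnnotatedVariant]
    round2: list[PrioritizedVariant]
    round3: list[PrioritizedVariant]

    @property
    def attrition(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "round1": len(self.round1),
            "round2": len(self.round2),
            "round3": len(self.round3),
        }


def prioritize_family(
    variants: Sequence[AnnotatedVariant],
    genotypes: Mapping[tuple, Mapping[str, GenotypeCall]],
    pedigree: Pedigree,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[AnnotatedVariant], list[tuple[AnnotatedVariant, str]]]:
    """Round-1 filters then within-family segregation for one family."""
    r1 = filter_round1(variants, config)
    seg = segregation_filter(r1, genotypes, pedigree, config)
    return r1, seg


def prioritize_cohort(
    per_family_variants: Mapping[str, Sequence[AnnotatedVariant]],
    per_family_genotypes: Mapping[str, Mapping[tuple, Mapping[str, GenotypeCall]]],
    pedigrees: Mapping[str, Pedigree],
    gene_sets: GeneSets,
    config: FilterConfig = FilterConfig(),
    external_exclusion: Iterable[tuple] = (),
) -> dict[str, FamilyPrioritization]:
    """Run the full three-round prioritization across all families."""
    r1: dict[str, list[AnnotatedVariant]] = {}
    seg: dict[str, list[tuple[AnnotatedVariant, str]]] = {}
    for fam, variants in per_family_variants.items():
        r1[fam], seg[fam] = prioritize_family(
            variants, per_family_genotypes[fam], pedigrees[fam], config
        )
    seg = cross_family_exclusion(
        seg, per_family_genotypes, pedigrees, external_exclusion, config
    )
    out: dict[str, FamilyPrioritization] = {}
    for fam in per_family_variants:
        round2_in = [
            PrioritizedVariant(
                variant=v,
                family_id=fam,
                round_reached=1,
                predictor_score=predictor_score(v),
                inheritance_model=model,
            )
            for v, model in seg[fam]
        ]
        round2 = gene_function_prioritize(round2_in, gene_sets, round=2)
        round3 = gene_function_prioritize(round2, gene_sets, round=3)
        out[fam] = FamilyPrioritization(
            family_id=fam,
            n_input=len(per_family_variants[fam]),
            round1=r1[fam],
            round2=round2,
            round3=round3,
        )
    return out
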