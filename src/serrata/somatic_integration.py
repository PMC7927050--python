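"""Paired germline-somatic integration under the two-hit model.

Somatic-sample QC by shared callable footprint, second-hit SNV/indel
detection in germline candidate genes, allelic-imbalance LOH testing at
germline heterozygous sites (exact two-sided binomial against 0.5 with an
effect-size floor and a direction requirement: the germline variant allele
must be the retained one), gene-level aggregation across support sites,
and a panel-of-normals filter for unpaired somatic samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from .intervals import IntervalSet
from .types import AnnotatedVariant, GenotypeCall

__all__ = [
    "SomaticSample",
    "QcResult",
    "LohResult",
    "TwoHitEvidence",
    "paired_qc",
    "second_hit_scan",
    "loh_test",
    "gene_loh_aggregate",
    "unpaired_filter",
    "EVIDENCE_GERMLINE",
    "EVIDENCE_PAIRED",
]

EVIDENCE_GERMLINE = "G"
EVIDENCE_PAIRED = "G-S paired analysis"

#: INFO flag marking somatic-VCF records that are germline het sites
#: re-genotyped in the somatic sample (LOH support), not somatic mutations.
GERMLINE_SITE_FLAG = "GLSITE"


@dataclass
class SomaticSample:
    sample_id: str
    family_id: str
    mutations: list[tuple[AnnotatedVariant, GenotypeCall]]
    callable: IntervalSet
    paired: bool = True
    germline_sample_id: str = ""
    pooled_normal: frozenset[tuple] | None = None
    #: somatic allele depths at germline het sites, for LOH testing
    germline_site_calls: list[tuple[AnnotatedVariant, GenotypeCall]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if not self.paired and self.pooled_normal is None:
            raise ValueError(
                f"{self.sample_id}: unpaired sample requires a pooled-normal panel"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[AnnotatedVariant, Mapping[str, GenotypeCall]]],
        sample_id: str,
        family_id: str,
        callable: IntervalSet,
        paired: bool = True,
        germline_sample_id: str = "",
        pooled_normal: frozenset[tuple] | None = None,
    ) -> "SomaticSample":
        """Split VCF records into somatic mutations vs germline-site calls
        (flagged ``GLSITE``), keeping only callable-region records."""
        mutations = []
        gl_sites = []
        for variant, calls in records:
            call = calls.get(sample_id)
            if call is None:
                continue
            if not callable.contains_vcf_pos(variant.chrom, variant.pos):
                continue
            if GERMLINE_SITE_FLAG in variant.flags:
                gl_sites.append((variant, call))
            else:
                mutations.append((variant, call))
        return cls(
            sample_id=sample_id,
            family_id=family_id,
            mutations=mutations,
            callable=callable,
            paired=paired,
            germline_sample_id=germline_sample_id,
            pooled_normal=pooled_normal,
            germline_site_calls=gl_sites,
        )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcResult:
    sample_id: str
    shared_fraction: float
    passed: bool


def paired_qc(
    germline_callable: IntervalSet,
    somatic_callable: IntervalSet,
    min_shared_fraction: float = 0.70,
    sample_id: str = "",
) -> QcResult:
    """Fraction of the germline callable footprint shared at high coverage
    by the somatic sample; pass iff fraction >= threshold (default 0.70)."""
    total = germline_callable.total_length()
    if total == 0:
        raise ValueError("empty germline callable region set")
    shared = germline_callable.intersect(somatic_callable).total_length()
    fraction = shared / total
    return QcResult(sample_id, fraction, fraction >= min_shared_fraction)


# ---------------------------------------------------------------------------
# LOH testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LohResult:
    gene: str
    chrom: str
    pos: int
    depth: int
    alt_count: int
    aaf: float
    p_value: float
    direction: str  # variant_retained | variant_lost | balanced
    call: bool
    is_candidate_site: bool = True
    skipped: str = ""  # non-empty reason code when the site was untestable


def loh_test(
    germline_variant: AnnotatedVariant,
    germline_call: GenotypeCall,
    somatic_call: GenotypeCall,
    alpha: float = 0.01,
    delta: float = 0.15,
    min_depth: int = 10,
    is_candidate_site: bool = True,
) -> LohResult:
    """Exact two-sided binomial allelic-imbalance test at a germline het
    site.

    Null: somatic alt reads ~ Binomial(depth, 0.5). A positive call needs
    p < alpha, |aaf - 0.5| >= delta, and the imbalance to favor the
    variant allele (wild-type lost) — imbalance toward the reference
    allele contradicts a second hit on the wild-type copy.
    """
    if germline_call.gt != "het":
        raise ValueError("LOH test requires a germline heterozygous site")
    gene = germline_variant.gene
    chrom, pos = germline_variant.chrom, germline_variant.pos
    depth, alt = somatic_call.depth, somatic_call.alt_count
    if depth < min_depth:
        return LohResult(
            gene, chrom, pos, depth, alt, somatic_call.aaf, 1.0,
            "balanced", False, is_candidate_site, skipped="low_depth",
        )
    p = binomtest(alt, depth, 0.5, alternative="two-sided").pvalue
    aaf = alt / depth
    if aaf > 0.5:
        direction = "variant_retained"
    elif aaf < 0.5:
        direction = "variant_lost"
    else:
        direction = "balanced"
    imbalanced = p < alpha and abs(aaf - 0.5) >= delta
    call = imbalanced and direction == "variant_retained"
    return LohResult(
        gene, chrom, pos, depth, alt, aaf, float(p), direction, call,
        is_candidate_site,
    )


def gene_loh_aggregate(results: Sequence[LohResult]) -> bool:
    """Gene-level LOH call from the candidate site plus flanking support.

    True iff the candidate site itself calls true, or at least half
    (ceil(k/2)) of the k testable sites are significantly imbalanced in a
    consistent direction while the candidate site's imbalance favors the
    variant allele.
    """
    testable = [r for r in results if not r.skipped]
    if not testable:
        return False
    candidates = [r for r in testable if r.is_candidate_site]
    if any(r.call for r in candidates):
        return True
    if not candidates or candidates[0].direction != "variant_retained":
        return False
    imbalanced = [
        r
        for r in testable
        if r.p_value < 0.01 and abs(r.aaf - 0.5) >= 0.15
    ]
    # consistency: support sites may retain either haplotype allele, but
    # must agree among themselves
    directions = {r.direction for r in imbalanced}
    k = len(testable)
    needed = -(-k // 2)  # ceil(k/2)
    return len(imbalanced) >= needed and len(directions) == 1


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional multiplicity flag)."""
    from scipy.stats import false_discovery_control

    return list(false_discovery_control(p_values, method="bh"))


# ---------------------------------------------------------------------------
# Second-hit assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoHitEvidence:
    gene: str
    family_id: str
    germline_variant: AnnotatedVariant
    second_hit: str  # somatic_snv | somatic_indel | loh | none
    somatic_variant: AnnotatedVariant | None = None
    somatic_aaf: float = 0.0
    loh_sites: tuple[LohResult, ...] = ()
    tmb_class: str = ""  # caveat column: sample mutational load class

    @property
    def evidence_class(self) -> str:
        return EVIDENCE_PAIRED if self.second_hit != "none" else EVIDENCE_GERMLINE


def second_hit_scan(
    candidates: Sequence,
    sample: SomaticSample,
    aaf_threshold: float = 0.20,
    min_depth: int = 10,
    alpha: float = 0.01,
    delta: float = 0.15,
    require_pathogenic_impact: bool = True,
    germline_genotypes: Mapping[tuple, GenotypeCall] | None = None,
    tmb_class: str = "",
) -> list[TwoHitEvidence]:
    """Assemble two-hit evidence for each germline candidate variant.

    For each candidate's gene, somatic missense/truncating variants with
    depth >= min_depth and AAF >= aaf_threshold count as SNV/indel second
    hits (the germline site itself cannot be its own second hit). When
    germline genotypes are supplied, germline-site somatic depths in the
    gene are LOH-tested and aggregated. One evidence record per candidate;
    an SNV/indel hit takes precedence over LOH in the record's label.
    """
    somatic_by_gene: dict[str, list[tuple[AnnotatedVariant, GenotypeCall]]] = {}
    for variant, call in sample.mutations:
        somatic_by_gene.setdefault(variant.gene, []).append((variant, call))
    gl_by_gene: dict[str, list[tuple[AnnotatedVariant, GenotypeCall]]] = {}
    for variant, call in sample.germline_site_calls:
        gl_by_gene.setdefault(variant.gene, []).append((variant, call))

    out: list[TwoHitEvidence] = []
    for pv in candidates:
        variant = pv.variant
        gene = variant.gene
        hit_variant = None
        hit_call = None
        for sv, sc in somatic_by_gene.get(gene, []):
            if sv.key == variant.key:
                continue  # own germline site
            if require_pathogenic_impact and sv.impact not in (
                "missense", "truncating",
            ):
                continue
            if sc.depth < min_depth or sc.aaf < aaf_threshold:
                continue
            if hit_variant is None or sc.aaf > hit_call.aaf:
                hit_variant, hit_call = sv, sc

        loh_sites: list[LohResult] = []
        loh_call = False
        if germline_genotypes is not None:
            for gv, somatic_call in gl_by_gene.get(gene, []):
                gcall = germline_genotypes.get(gv.key)
                if gcall is None or gcall.gt != "het":
                    continue
                loh_sites.append(
                    loh_test(
                        gv, gcall, somatic_call, alpha=alpha, delta=delta,
                        min_depth=min_depth,
                        is_candidate_site=gv.key == variant.key,
                    )
                )
            if loh_sites:
                loh_call = gene_loh_aggregate(loh_sites)

        if hit_variant is not None:
            kind = (
                "somatic_indel"
                if hit_variant.var_class in ("insertion", "deletion")
                else "somatic_snv"
            )
            out.append(
                TwoHitEvidence(
                    gene, sample.family_id, variant, kind,
                    somatic_variant=hit_variant,
                    somatic_aaf=hit_call.aaf,
                    loh_sites=tuple(loh_sites),
                    tmb_class=tmb_class,
                )
            )
        elif loh_call:
            out.append(
                TwoHitEvidence(
                    gene, sample.family_id, variant, "loh",
                    loh_sites=tuple(loh_sites),
                    tmb_class=tmb_class,
                )
            )
        else:
            out.append(
                TwoHitEvidence(
                    gene, sample.family_id, variant, "none",
                    loh_sites=tuple(loh_sites),
                    tmb_class=tmb_class,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Unpaired analysis
# ---------------------------------------------------------------------------

def unpaired_filter(
    somatic_variants: Iterable[tuple[AnnotatedVariant, GenotypeCall]],
    panel_counts: Mapping[tuple, int],
    max_panel_samples: int = 0,
) -> list[tuple[AnnotatedVariant, GenotypeCall]]:
    """Panel-of-normals filter for unpaired somatic samples.

    Variants seen in more than ``max_panel_samples`` panel samples
    (default 0: any panel observation) are removed as presumed germline
    or artifact.
    """
    return [
        (v, c)
        for v, c in somatic_variants
        if panel_counts.get(v.key, 0) <= max_panel_samples
    ]
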