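"""Synthetic cohorts with known ground truth.

Generates a deterministic pseudo-random reference contig, a gene map of
named intervals on it, declarative gene-function sets, per-family germline
VCFs with one planted causal variant (heterozygous in every affected
member) plus calibrated background noise, and per-sample somatic VCFs
drawn from signature mixtures with planted second-hit SNVs, allelic-
imbalance LOH events, and driver hotspot mutations.

Everything is driven by one integer seed; identical configs and seeds
produce byte-identical on-disk cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import formats_io
from .intervals import IntervalSet
from .mutational_profile import id_classify
from .types import (
    PREDICTOR_TOOLS,
    AnnotatedVariant,
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    SignatureCatalog,
)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

GERMLINE_SITE_FLAG = "GLSITE"

__all__ = [
    "SimConfig",
    "SomaticPlan",
    "FamilyTruth",
    "SomaticTruth",
    "TruthTable",
    "Cohort",
    "make_reference",
    "simulate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SomaticPlan:
    """Per-sample somatic generation plan."""

    family_id: str
    snv_per_mb: float
    indel_per_mb: float
    sbs_weights: Mapping[str, float]
    id_weights: Mapping[str, float]
    second_hit: str = "none"  # none | snv | loh
    qc_fail: bool = False
    unpaired: bool = False
    mean_depth: float = 100.0
    drivers: tuple[tuple[str, str, float], ...] = ()  # (gene, hgvs_p, aaf)

    def __post_init__(self) -> None:
        for weights in (self.sbs_weights, self.id_weights):
            total = sum(weights.values())
            if weights and abs(total - 1.0) > 1e-9:
                raise ValueError(f"signature weights sum to {total}, not 1")
        if self.second_hit not in ("none", "snv", "loh"):
            raise ValueError(f"bad second_hit plan {self.second_hit!r}")


def _default_somatic_plans() -> tuple[SomaticPlan, ...]:
    """Echoes the shape of the study cohort: one sample per family except
    one family with none; one QC-fail; one unpaired; six-plus hypermutated
    with one ultra-hypermutated; MMR-deficiency mixtures in the most
    mutated samples; scattered driver hotspots."""
    clock = {"SBS1": 0.6, "SBS5": 0.4}
    mmr = {"SBS1": 0.3, "SBS5": 0.3, "SBS15": 0.25, "SBS21": 0.15}
    id_clock = {"ID1": 0.6, "ID2": 0.4}
    id_mmr = {"ID1": 0.45, "ID2": 0.45, "ID12": 0.1}
    plans = [
        SomaticPlan("SPS.01", 3.0, 0.4, clock, id_clock,
                    drivers=(("BRAF", "V600E", 0.12),)),
        SomaticPlan("SPS.02", 27.6, 8.4, mmr, id_mmr,
                    drivers=(("BRAF", "V600E", 0.32), ("MSH3", "R100W", 0.05),
                             ("MSH6", "T200M", 0.07))),
        SomaticPlan("SPS.03", 12.0, 1.2, clock, id_clock, second_hit="loh",
                    drivers=(("BRAF", "V600E", 0.08), ("POLE", "S459F", 0.10))),
        SomaticPlan("SPS.04", 2.0, 0.3, clock, id_clock),
        SomaticPlan("SPS.05", 5.0, 0.5, clock, id_clock, qc_fail=True),
        SomaticPlan("SPS.06", 4.0, 0.5, clock, id_clock,
                    drivers=(("BRAF", "V600E", 0.45),)),
        SomaticPlan("SPS.07", 110.0, 100.6, mmr, id_mmr, second_hit="snv",
                    drivers=(("BRAF", "V600E", 0.38), ("MLH1", "R687Q", 0.28),
                             ("POLE", "P286R", 0.12))),
        SomaticPlan("SPS.08", 13.0, 1.5, clock, id_clock,
                    drivers=(("POLE", "V411L", 0.09),)),
        SomaticPlan("SPS.09", 2.0, 0.3, clock, id_clock,
                    drivers=(("BRAF", "V600E", 0.15),)),
        # SPS.10: no somatic sample available
        SomaticPlan("SPS.11", 11.0, 1.1, clock, id_clock),
        SomaticPlan("SPS.12", 3.0, 0.4, clock, id_clock),
        SomaticPlan("SPS.13", 2.5, 0.3, clock, id_clock),
        SomaticPlan("SPS.14", 12.0, 1.4, mmr, id_mmr, second_hit="loh",
                    drivers=(("KRAS", "A146T", 0.25),)),
        SomaticPlan("SPS.15", 3.5, 0.4, clock, id_clock,
                    drivers=(("BRAF", "V600E", 0.30),)),
        SomaticPlan("SPS.16", 89.0, 6.0, mmr, id_mmr, unpaired=True),
    ]
    return tuple(plans)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    #: affected member count per family, cohort-shaped by default
    family_sizes: tuple[int, ...] = (2,) * 8 + (3, 4, 6) + (2,) * 5
    reference_length_mb: float = 2.0
    #: expected count of background variants per family that survive the
    #: round-1 hard filters and segregate in all affected members
    background_survivor_mean: float = 23.5
    #: failing background variants per surviving one
    background_fail_ratio: float = 3.0
    #: fraction of families whose planted causal variant is truncating
    #: (frameshift, predictors unavailable) rather than missense
    truncating_causal_every: int = 4
    germline_mean_depth: float = 60.0
    flanking_het_sites: int = 3
    loh_retained_fraction: float = 0.8
    #: beta-binomial overdispersion for somatic AAF noise (higher = tighter)
    aaf_concentration: float = 60.0
    baseline_aaf: float = 0.45
    somatic_plans: tuple[SomaticPlan, ...] = field(
        default_factory=_default_somatic_plans
    )
    #: number of leaked-germline contaminant records in the unpaired sample
    panel_contaminants: int = 20

    def __post_init__(self) -> None:
        if self.reference_length_mb < 0.5:
            raise ValueError("reference must be at least 0.5 Mb")
        if self.background_survivor_mean < 0 or self.background_fail_ratio < 0:
            raise ValueError("rates must be non-negative")

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(f"SPS.{i + 1:02d}" for i in range(len(self.family_sizes)))


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    family_id: str
    gene: str
    variant: AnnotatedVariant
    hgvs: str
    impact: str
    flanking_het_keys: tuple[tuple, ...] = ()


@dataclass
class SomaticTruth:
    sample_id: str
    family_id: str
    sbs_weights: dict[str, float]
    id_weights: dict[str, float]
    snv_count: int
    indel_count: int
    footprint_mb: float
    second_hit: str
    second_hit_key: tuple | None = None
    loh_site_keys: tuple[tuple, ...] = ()
    qc_fail: bool = False
    unpaired: bool = False
    n_contaminants: int = 0

    @property
    def snv_per_mb(self) -> float:
        return self.snv_count / self.footprint_mb

    @property
    def indel_per_mb(self) -> float:
        return self.indel_count / self.footprint_mb


@dataclass
class TruthTable:
    families: dict[str, FamilyTruth]
    somatic: dict[str, SomaticTruth]
    #: (family_id, gene, kind) for every planted second hit
    second_hits: list[tuple[str, str, str]]


@dataclass
class Cohort:
    """In-memory synthetic cohort; `write_cohort` serializes it."""

    config: SimConfig
    reference: dict[str, str]
    gene_map: dict[str, tuple[str, int, int]]
    gene_sets: "object"  # GeneSets; typed loosely to avoid import cycle
    pedigrees: list[Pedigree]
    germline: dict[str, list]  # family_id -> VcfRecord list
    germline_callable: IntervalSet
    somatic: dict[str, list]  # family_id -> VcfRecord list (single sample)
    somatic_callable: dict[str, IntervalSet]
    panel_counts: dict[tuple, int]
    truth: TruthTable

    @property
    def contigs(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}


# ---------------------------------------------------------------------------
# Reference & gene map
# ---------------------------------------------------------------------------

def make_reference(
    length_mb: float, seed: int, chrom: str = "chr1"
) -> dict[str, str]:
    """Deterministic pseudo-random nucleotide sequence, uniform base
    composition (so every trinucleotide context occurs at desk scale)."""
    if length_mb < 1e-3:
        raise ValueError("reference length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    n = int(round(length_mb * 1_000_000))
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seq = lut[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
    return {chrom: seq}


def write_reference(reference: Mapping[str, str], path: str | Path) -> None:
    """FASTA (wrapped 70 cols) plus a .fai index."""
    path = Path(path)
    with open(path, "w") as fh:
        fai_lines = []
        offset = 0
        for chrom in reference:
            seq = reference[chrom]
            header = f">{chrom}\n"
            fh.write(header)
            offset += len(header)
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
            fai_lines.append(f"{chrom}\t{len(seq)}\t{offset}\t70\t71")
            offset += len(seq) + (len(seq) + 69) // 70
    Path(str(path) + ".fai").write_text("\n".join(fai_lines) + "\n")


def _build_gene_map(
    config: SimConfig, reference: Mapping[str, str]
) -> tuple[dict[str, tuple[str, int, int]], "object"]:
    """Named intervals tiling the reference plus function-set assignment.

    Layout: the ten driver genes first, then one causal gene per family
    (assigned round-robin to the prioritized sets), then excluded-set
    genes, then anonymous background genes.
    """
    from .germline_prioritizer import GeneSets
    from .mutational_profile import DRIVER_GENES

    chrom = next(iter(reference))
    length = len(reference[chrom])
    margin = 200
    n_families = len(config.family_sizes)
    names: list[str] = list(DRIVER_GENES)
    causal = [f"CAUS{i + 1:02d}" for i in range(n_families)]
    names += causal
    excluded = [f"EXCL{i + 1:02d}" for i in range(12)]
    names += excluded
    gene_size = (length - 2 * margin) // max(len(names) + 60, 1)
    n_background = (length - 2 * margin) // gene_size - len(names)
    background = [f"BKG{i + 1:03d}" for i in range(n_background)]
    names += background

    gene_map: dict[str, tuple[str, int, int]] = {}
    pos = margin
    for name in names:
        gene_map[name] = (chrom, pos, pos + gene_size)
        pos += gene_size

    set_names = ("cancer", "senescence", "epigenetics")
    prioritized: dict[str, list[str]] = {s: [] for s in set_names}
    for i, gene in enumerate(causal):
        prioritized[set_names[i % 3]].append(gene)
    # drivers count as cancer genes, mirroring their real-world role
    prioritized["cancer"].extend(DRIVER_GENES)
    gene_sets = GeneSets(
        prioritized={k: tuple(v) for k, v in prioritized.items()},
        excluded={
            "non_cancer_disease": tuple(excluded[:6]),
            "vague_function": tuple(excluded[6:]),
        },
    )
    return gene_map, gene_sets


# ---------------------------------------------------------------------------
# Sequence indexes
# ---------------------------------------------------------------------------

class _RefIndexes:
    """Trinucleotide-context and homopolymer-run indexes over one contig."""

    def __init__(self, chrom: str, seq: str) -> None:
        self.chrom = chrom
        self.seq = seq
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int8)
        for i, b in enumerate(_BASES):
            lut[ord(b)] = i
        c = lut[codes]
        tri = c[:-2] * 16 + c[1:-1] * 4 + c[2:]
        order = np.argsort(tri, kind="stable")
        sorted_tri = tri[order]
        boundaries = np.searchsorted(sorted_tri, np.arange(65))
        self._tri_positions = {
            code: order[boundaries[code] : boundaries[code + 1]] + 1
            for code in range(64)
        }
        # homopolymer runs: (start, length) per canonical base (C/T),
        # complements folded; grouped with numpy for speed
        change = np.nonzero(c[1:] != c[:-1])[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(c)]])
        lengths = (ends - starts).astype(np.int64)
        bases = c[starts].astype(np.int64)
        canon = np.array([3, 1, 1, 3])[bases]  # A,G -> T,C fold
        key = canon * 10 + np.minimum(lengths, 6)
        order = np.argsort(key, kind="stable")
        sk, ss, sl = key[order], starts[order], lengths[order]
        bounds = np.searchsorted(sk, np.arange(key.min(), key.max() + 2))
        self._runs: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
        uniq = np.arange(key.min(), key.max() + 1)
        for u, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
            if hi > lo:
                base = _BASES[int(u) // 10]
                self._runs[(base, int(u) % 10)] = (ss[lo:hi], sl[lo:hi])

    @staticmethod
    def tri_code(tri: str) -> int:
        return (
            _BASES.index(tri[0]) * 16
            + _BASES.index(tri[1]) * 4
            + _BASES.index(tri[2])
        )

    def positions_for_context(self, tri: str) -> np.ndarray:
        """0-based center positions whose trinucleotide equals `tri`."""
        return self._tri_positions[self.tri_code(tri)]

    def runs(self, canonical_base: str, length: int, at_least: bool = False):
        """Runs of `canonical_base` (C/T, complements folded) of exact
        `length`, or of length >= `length` when at_least is set."""
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        if at_least:
            parts = [
                self._runs.get((canonical_base, min(ln, 6)), empty)
                for ln in range(length, 7)
            ]
            return (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
        return self._runs.get((canonical_base, length), empty)


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

class CohortSimulator:
    def __init__(self, config: SimConfig, sbs_catalog=None, id_catalog=None):
        from .resources import load_id_catalog, load_sbs_catalog

        self.config = config
        self.sbs_catalog: SignatureCatalog = sbs_catalog or load_sbs_catalog()
        self.id_catalog: SignatureCatalog = id_catalog or load_id_catalog()
        self.reference = make_reference(config.reference_length_mb, config.seed)
        self.chrom = next(iter(self.reference))
        self.seq = self.reference[self.chrom]
        self._index: _RefIndexes | None = None  # built lazily (somatic only)
        self.gene_map, self.gene_sets = _build_gene_map(config, self.reference)
        margin = 200
        self.germline_callable = IntervalSet(
            [(self.chrom, margin, len(self.seq) - margin)]
        )
        self._used: set[int] = set()

    @property
    def index(self) -> _RefIndexes:
        if self._index is None:
            self._index = _RefIndexes(self.chrom, self.seq)
        return self._index

    # -- small helpers ------------------------------------------------------

    def _base(self, pos0: int) -> str:
        return self.seq[pos0]

    def _alt_base(self, rng, ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return choices[rng.integers(0, 3)]

    def _fresh_pos(self, rng, gene: str | None = None) -> int:
        """Unused 0-based position, optionally inside a gene interval."""
        if gene is not None:
            chrom, start, end = self.gene_map[gene]
            lo, hi = start, end
        else:
            lo, hi = 200, len(self.seq) - 200
        for _ in range(1000):
            pos0 = int(rng.integers(lo, hi))
            if pos0 not in self._used:
                self._used.add(pos0)
                return pos0
        raise RuntimeError("reference exhausted: too many variants requested")

    def _depth_and_ad(self, rng, mean_depth: float, p_alt: float) -> tuple[int, int]:
        depth = max(int(rng.poisson(mean_depth)), 8)
        conc = self.config.aaf_concentration
        p = rng.beta(p_alt * conc, (1 - p_alt) * conc)
        alt = int(rng.binomial(depth, p))
        return depth, alt

    def _het_call(self, rng, sample_id: str, mean_depth: float) -> GenotypeCall:
        depth, alt = self._depth_and_ad(rng, mean_depth, 0.5)
        alt = min(max(alt, 1), depth - 1) if depth > 1 else alt
        return GenotypeCall(sample_id, "het", depth - alt, alt, depth)

    def _hom_ref_call(self, rng, sample_id: str, mean_depth: float) -> GenotypeCall:
        depth = max(int(rng.poisson(mean_depth)), 8)
        return GenotypeCall(sample_id, "hom_ref", depth, 0, depth)

    # -- pedigrees ----------------------------------------------------------

    def build_pedigrees(self) -> list[Pedigree]:
        somatic_fams = {p.family_id for p in self.config.somatic_plans}
        pedigrees = []
        for fam, size in zip(self.config.family_ids, self.config.family_sizes):
            members = tuple(
                PedigreeMember(
                    sample_id=f"{fam}.P{k + 1}",
                    affected=True,
                    has_somatic=(k == 0 and fam in somatic_fams),
                    sex=1 + (k % 2),
                )
                for k in range(size)
            )
            pedigrees.append(Pedigree(fam, members))
        return pedigrees

    # -- germline -----------------------------------------------------------

    def _snv_variant(
        self,
        rng,
        gene: str,
        consequence: str,
        n_deleterious: int | None,
        maf: float,
        hgvs: str = "",
    ) -> AnnotatedVariant:
        pos0 = self._fresh_pos(rng, gene)
        ref = self._base(pos0)
        alt = self._alt_base(rng, ref)
        verdicts: dict[str, str] = {}
        if n_deleterious is None:
            verdicts = {t: "unavailable" for t in PREDICTOR_TOOLS}
        else:
            order = list(PREDICTOR_TOOLS)
            for i, tool in enumerate(order):
                verdicts[tool] = "deleterious" if i < n_deleterious else "tolerated"
        # 6 significant digits: exact VCF float round-trip
        pop = {} if maf == 0 else {"gnomad": float(f"{maf:.6g}")}
        return AnnotatedVariant(
            chrom=self.chrom, pos=pos0 + 1, ref=ref, alt=alt, gene=gene,
            consequence=consequence,
            impact={
                "missense": "missense", "synonymous": "synonymous",
                "stop_gained": "truncating", "frameshift": "truncating",
            }.get(consequence, "other"),
            protein_change=hgvs,
            pop_freqs=pop, predictor_verdicts=verdicts,
        )

    def _frameshift_variant(self, rng, gene: str, hgvs: str = "") -> AnnotatedVariant:
        pos0 = self._fresh_pos(rng, gene)
        ref = self.seq[pos0 : pos0 + 2]
        return AnnotatedVariant(
            chrom=self.chrom, pos=pos0 + 1, ref=ref, alt=ref[0], gene=gene,
            consequence="frameshift", impact="truncating",
            protein_change=hgvs,
            predictor_verdicts={t: "unavailable" for t in PREDICTOR_TOOLS},
        )

    def simulate_family_germline(
        self, pedigree: Pedigree, causal_gene: str, rng
    ) -> tuple[list, FamilyTruth]:
        """Germline records for one family.

        One causal variant het in every affected member; Poisson-many
        background variants that survive the round-1 hard filters and
        segregate; `background_fail_ratio` times as many that each violate
        at least one criterion.
        """
        cfg = self.config
        members = [m.sample_id for m in pedigree.members]
        affected = [m.sample_id for m in pedigree.affected_sequenced]
        fam_index = int(pedigree.family_id.split(".")[-1])
        records = []

        truncating = (
            cfg.truncating_causal_every > 0
            and fam_index % cfg.truncating_causal_every == 0
        )
        if truncating:
            causal = self._frameshift_variant(
                rng, causal_gene, hgvs=f"K{int(rng.integers(100, 900))}fs"
            )
        else:
            aa = "ARNDCQEGHILKMFPSTWYV"
            hgvs = (
                f"{aa[rng.integers(0, 20)]}{int(rng.integers(100, 900))}"
                f"{aa[rng.integers(0, 20)]}"
            )
            causal = self._snv_variant(
                rng, causal_gene, "missense",
                n_deleterious=int(rng.integers(5, 7)),
                maf=0.0 if rng.random() < 0.5 else float(rng.uniform(5e-6, 8e-5)),
                hgvs=hgvs,
            )
        calls = {
            sid: self._het_call(rng, sid, cfg.germline_mean_depth)
            for sid in affected
        }
        records.append((causal, calls))

        # benign common het flankers in the causal gene (LOH support sites)
        flanking_keys = []
        for _ in range(cfg.flanking_het_sites):
            v = self._snv_variant(
                rng, causal_gene, "synonymous", n_deleterious=0,
                maf=float(rng.uniform(0.05, 0.4)),
            )
            calls = {
                sid: self._het_call(rng, sid, cfg.germline_mean_depth)
                for sid in affected
            }
            records.append((v, calls))
            flanking_keys.append(v.key)

        background_genes = [g for g in self.gene_map if g.startswith("BKG")]
        excluded_genes = sorted(self.gene_sets.all_excluded)

        n_pass = int(rng.poisson(cfg.background_survivor_mean))
        for i in range(n_pass):
            # a sprinkle of survivors land in excluded-function genes so
            # round 2 has work to do
            if i % 8 == 0:
                gene = excluded_genes[int(rng.integers(0, len(excluded_genes)))]
            else:
                gene = background_genes[int(rng.integers(0, len(background_genes)))]
            v = self._snv_variant(
                rng, gene, "missense",
                n_deleterious=int(rng.integers(3, 7)),
                maf=0.0 if rng.random() < 0.3 else float(rng.uniform(1e-6, 9e-4)),
            )
            calls = {
                sid: self._het_call(rng, sid, cfg.germline_mean_depth)
                for sid in affected
            }
            records.append((v, calls))

        n_fail = int(round(cfg.background_fail_ratio * n_pass))
        for i in range(n_fail):
            gene = background_genes[int(rng.integers(0, len(background_genes)))]
            mode = int(rng.integers(0, 4))
            if mode == 0:  # too common
                v = self._snv_variant(
                    rng, gene, "missense", n_deleterious=int(rng.integers(3, 7)),
                    maf=float(rng.uniform(1e-3, 0.05)),
                )
            elif mode == 1:  # wrong impact class
                v = self._snv_variant(
                    rng, gene,
                    "synonymous" if rng.random() < 0.5 else "intron",
                    n_deleterious=int(rng.integers(0, 7)),
                    maf=float(rng.uniform(0, 9e-4)),
                )
            elif mode == 2:  # too few deleterious votes
                v = self._snv_variant(
                    rng, gene, "missense", n_deleterious=int(rng.integers(0, 3)),
                    maf=float(rng.uniform(0, 9e-4)),
                )
            else:  # fails the shared-by-all rule
                v = self._snv_variant(
                    rng, gene, "missense", n_deleterious=int(rng.integers(3, 7)),
                    maf=float(rng.uniform(0, 9e-4)),
                )
                carrier = affected[int(rng.integers(0, len(affected)))]
                calls = {}
                for sid in affected:
                    if sid == carrier and len(affected) > 1:
                        calls[sid] = self._het_call(rng, sid, cfg.germline_mean_depth)
                    else:
                        calls[sid] = self._hom_ref_call(
                            rng, sid, cfg.germline_mean_depth
                        )
                records.append((v, calls))
                continue
            calls = {
                sid: (
                    self._het_call(rng, sid, cfg.germline_mean_depth)
                    if rng.random() < 0.6
                    else self._hom_ref_call(rng, sid, cfg.germline_mean_depth)
                )
                for sid in affected
            }
            records.append((v, calls))

        truth = FamilyTruth(
            family_id=pedigree.family_id,
            gene=causal_gene,
            variant=causal,
            hgvs=causal.protein_change,
            impact=causal.impact,
            flanking_het_keys=tuple(flanking_keys),
        )
        return records, truth

    def _plant_cross_family_inconsistency(
        self, germline: dict[str, list], pedigrees: Mapping[str, Pedigree], rng
    ) -> None:
        """One variant that segregates in the first family but is carried
        by only one affected member of the second — the cross-family rule
        must remove it from both."""
        fams = list(germline)
        if len(fams) < 2:
            return
        fam_a, fam_b = fams[0], fams[1]
        gene = "BKG001"
        v = self._snv_variant(rng, gene, "missense", n_deleterious=5, maf=1e-5)
        calls_a = {
            m.sample_id: self._het_call(
                rng, m.sample_id, self.config.germline_mean_depth
            )
            for m in pedigrees[fam_a].affected_sequenced
        }
        germline[fam_a].append((v, calls_a))
        members_b = list(pedigrees[fam_b].affected_sequenced)
        calls_b = {}
        for i, m in enumerate(members_b):
            if i == 0:
                calls_b[m.sample_id] = self._het_call(
                    rng, m.sample_id, self.config.germline_mean_depth
                )
            else:
                calls_b[m.sample_id] = self._hom_ref_call(
                    rng, m.sample_id, self.config.germline_mean_depth
                )
        germline[fam_b].append((v, calls_b))

    # -- somatic ------------------------------------------------------------

    def _mixture_distribution(
        self, catalog: SignatureCatalog, weights: Mapping[str, float]
    ) -> np.ndarray:
        p = np.zeros(len(catalog.categories))
        for name, w in weights.items():
            p += w * catalog.signatures[name]
        return p / p.sum()

    def _place_sbs(
        self, rng, category: str, used: set[int], avoid: frozenset[str] = frozenset()
    ) -> AnnotatedVariant:
        five, rest = category[0], category[2:]
        center, alt = rest[0], rest[2]
        three = rest[4]
        tri = five + center + three
        positions = self.index.positions_for_context(tri)
        for _ in range(200):
            pos0 = int(positions[rng.integers(0, len(positions))])
            if pos0 not in used and self.germline_callable.contains(
                self.chrom, pos0
            ):
                gene = self._gene_at(pos0)
                if gene in avoid:
                    continue
                used.add(pos0)
                return AnnotatedVariant(
                    chrom=self.chrom, pos=pos0 + 1, ref=center, alt=alt,
                    gene=gene, consequence="missense", impact="missense",
                )
        raise RuntimeError(f"no free position for context {tri}")

    def _gene_at(self, pos0: int) -> str:
        # gene intervals tile the reference uniformly; constant-time lookup
        names = self._gene_names_sorted
        starts = self._gene_starts
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i < 0:
            return ""
        name = names[i]
        _, s, e = self.gene_map[name]
        return name if s <= pos0 < e else ""

    @property
    def _gene_names_sorted(self) -> list[str]:
        if not hasattr(self, "_gns"):
            items = sorted(self.gene_map.items(), key=lambda kv: kv[1][1])
            self._gns = [k for k, _ in items]
            self._gst = np.array([v[1] for _, v in items])
        return self._gns

    @property
    def _gene_starts(self) -> np.ndarray:
        self._gene_names_sorted
        return self._gst

    def _place_indel(
        self, rng, category: str, used: set[int],
        avoid: frozenset[str] = frozenset(),
    ) -> AnnotatedVariant | None:
        """Construct an indel whose ID83 classification equals `category`.

        1 bp bins are placed constructively from the homopolymer-run
        index; longer bins by rejection sampling verified against the
        classifier. Returns None when no placement is found."""
        parts = category.split(":")
        size_label, kind, ctx, num = parts[0], parts[1], parts[2], int(parts[3])

        if size_label == "1":
            base = ctx  # canonical C/T; runs index folds complements
            if kind == "Del":
                runs = self.index.runs(base, num + 1, at_least=(num == 5))
            else:
                if num == 0:
                    return self._place_ins_run0(rng, base, used, avoid)
                runs = self.index.runs(base, num, at_least=(num == 5))
            run_starts, run_lengths = runs
            if len(run_starts) == 0:
                return None
            for _ in range(100):
                j = int(rng.integers(0, len(run_starts)))
                start, length = int(run_starts[j]), int(run_lengths[j])
                if kind == "Del":
                    anchor = start - 1
                    if anchor < 1 or anchor in used:
                        continue
                    actual = self.seq[start]
                    ref = self.seq[anchor] + actual
                    alt = self.seq[anchor]
                else:
                    anchor = start + length - 1
                    if anchor < 1 or anchor in used:
                        continue
                    actual = self.seq[start]
                    ref = self.seq[anchor]
                    alt = ref + actual
                if not self.germline_callable.contains(self.chrom, anchor):
                    continue
                if self._gene_at(anchor) in avoid:
                    continue
                used.add(anchor)
                return AnnotatedVariant(
                    chrom=self.chrom, pos=anchor + 1, ref=ref, alt=alt,
                    gene=self._gene_at(anchor), consequence="frameshift",
                    impact="truncating",
                )
            return None

        size = 5 if size_label == "5+" else int(size_label)
        for _ in range(200):
            anchor = int(rng.integers(200, len(self.seq) - 200))
            if anchor in used:
                continue
            if kind == "Del":
                unit = self.seq[anchor + 1 : anchor + 1 + size]
                ref = self.seq[anchor] + unit
                alt = self.seq[anchor]
            else:
                unit = "".join(
                    _BASES[rng.integers(0, 4)] for _ in range(size)
                )
                ref = self.seq[anchor]
                alt = ref + unit
            cand = AnnotatedVariant(
                chrom=self.chrom, pos=anchor + 1, ref=ref, alt=alt,
                gene=self._gene_at(anchor), consequence="frameshift",
                impact="truncating",
            )
            if id_classify(cand, self.reference) == category:
                if cand.gene in avoid:
                    continue
                used.add(anchor)
                return cand
        return None

    def _place_ins_run0(
        self, rng, base: str, used: set[int], avoid: frozenset[str] = frozenset()
    ):
        """1 bp insertion with no adjacent copy of the inserted base."""
        bases = (base, base.translate(_COMPLEMENT))
        for _ in range(200):
            anchor = int(rng.integers(200, len(self.seq) - 200))
            if anchor in used:
                continue
            ins = bases[int(rng.integers(0, 2))]
            if self.seq[anchor] == ins or self.seq[anchor + 1] == ins:
                continue
            if self._gene_at(anchor) in avoid:
                continue
            used.add(anchor)
            return AnnotatedVariant(
                chrom=self.chrom, pos=anchor + 1, ref=self.seq[anchor],
                alt=self.seq[anchor] + ins, gene=self._gene_at(anchor),
                consequence="frameshift", impact="truncating",
            )
        return None

    def simulate_somatic(
        self,
        plan: SomaticPlan,
        pedigree: Pedigree,
        family_truth: FamilyTruth,
        germline_records: Sequence,
        rng,
    ) -> tuple[list, IntervalSet, SomaticTruth]:
        cfg = self.config
        sample_id = f"{plan.family_id}.T"
        chrom = self.chrom

        if plan.qc_fail:
            # truncate the somatic callable footprint to half the germline
            # footprint so the 70% shared-coverage rule fires
            (c, s, e) = next(iter(self.germline_callable))
            callable_set = IntervalSet([(c, s, s + (e - s) // 2)])
        else:
            callable_set = self.germline_callable
        footprint_mb = callable_set.total_length() / 1e6
        # mutations are placed over the germline footprint and filtered to
        # the somatic callable footprint downstream; counts target the
        # somatic footprint so emitted burdens match the plan
        used: set[int] = set()
        avoid = frozenset({family_truth.gene})
        records = []

        p_sbs = self._mixture_distribution(self.sbs_catalog, plan.sbs_weights)
        n_sbs = int(round(plan.snv_per_mb * footprint_mb))
        cat_counts = rng.multinomial(n_sbs, p_sbs)
        for ci in np.nonzero(cat_counts)[0]:
            category = self.sbs_catalog.categories[ci]
            for _ in range(int(cat_counts[ci])):
                v = self._place_sbs(rng, category, used, avoid)
                depth, alt = self._depth_and_ad(
                    rng, plan.mean_depth, cfg.baseline_aaf
                )
                alt = max(alt, 1)
                call = GenotypeCall(sample_id, "het", depth - alt, alt, depth)
                records.append((v, {sample_id: call}))

        p_id = self._mixture_distribution(self.id_catalog, plan.id_weights)
        n_id = int(round(plan.indel_per_mb * footprint_mb))
        n_placed = 0
        while n_placed < n_id:
            ci = int(rng.choice(len(p_id), p=p_id))
            category = self.id_catalog.categories[ci]
            v = self._place_indel(rng, category, used, avoid)
            if v is None:
                continue  # unattainable bin on this reference; redraw
            depth, alt = self._depth_and_ad(rng, plan.mean_depth, cfg.baseline_aaf)
            alt = max(alt, 1)
            call = GenotypeCall(sample_id, "het", depth - alt, alt, depth)
            records.append((v, {sample_id: call}))
            n_placed += 1

        # driver hotspot mutations at planned AAF
        for gene, hgvs, aaf in plan.drivers:
            v = self._snv_variant(rng, gene, "missense", 5, 0.0, hgvs=hgvs)
            depth = max(int(rng.poisson(plan.mean_depth)), 20)
            alt = max(int(round(aaf * depth)), 1)
            call = GenotypeCall(sample_id, "het", depth - alt, alt, depth)
            records.append((v, {sample_id: call}))

        # planted second hit
        second_hit_key = None
        if plan.second_hit == "snv":
            v = self._snv_variant(
                rng, family_truth.gene,
                "stop_gained" if rng.random() < 0.5 else "missense",
                n_deleterious=6, maf=0.0,
            )
            aaf = float(rng.uniform(0.30, 0.50))
            depth = max(int(rng.poisson(plan.mean_depth)), 20)
            alt = max(int(round(aaf * depth)), int(0.25 * depth) + 1)
            call = GenotypeCall(sample_id, "het", depth - alt, alt, depth)
            records.append((v, {sample_id: call}))
            second_hit_key = v.key

        # somatic re-genotyping of germline het sites in the causal gene
        # (LOH support); imbalanced when LOH is planted, balanced otherwise
        loh_keys = []
        causal_keys = {family_truth.variant.key} | set(
            family_truth.flanking_het_keys
        )
        p_alt = (
            cfg.loh_retained_fraction if plan.second_hit == "loh" else 0.5
        )
        for gv, _calls in germline_records:
            if gv.key not in causal_keys:
                continue
            depth = max(int(rng.poisson(plan.mean_depth)), 20)
            alt = int(rng.binomial(depth, p_alt))
            call = GenotypeCall(sample_id, "het", depth - alt, alt, depth)
            records.append(
                (gv.with_flags(GERMLINE_SITE_FLAG), {sample_id: call})
            )
            if plan.second_hit == "loh":
                loh_keys.append(gv.key)

        truth = SomaticTruth(
            sample_id=sample_id,
            family_id=plan.family_id,
            sbs_weights=dict(plan.sbs_weights),
            id_weights=dict(plan.id_weights),
            snv_count=n_sbs + len(plan.drivers)
            + (1 if plan.second_hit == "snv" else 0),
            indel_count=n_id,
            footprint_mb=footprint_mb,
            second_hit=plan.second_hit,
            second_hit_key=second_hit_key,
            loh_site_keys=tuple(loh_keys),
            qc_fail=plan.qc_fail,
            unpaired=plan.unpaired,
        )
        return records, callable_set, truth

    def _contaminate_unpaired(
        self, records: list, truth: SomaticTruth, rng
    ) -> dict[tuple, int]:
        """Leak germline-like variants into the unpaired sample and build
        the pooled-normal panel that removes them."""
        cfg = self.config
        sample_id = truth.sample_id
        panel: dict[tuple, int] = {}
        background_genes = [g for g in self.gene_map if g.startswith("BKG")]
        for i in range(cfg.panel_contaminants):
            gene = background_genes[int(rng.integers(0, len(background_genes)))]
            v = self._snv_variant(rng, gene, "missense", 2, 0.0)
            depth, alt = self._depth_and_ad(rng, 100.0, 0.5)
            alt = max(alt, 1)
            call = GenotypeCall(sample_id, "het", depth - alt, alt, depth)
            records.append((v, {sample_id: call}))
            panel[v.key] = int(rng.integers(1, 20))
        # panel sites not present in the sample
        for _ in range(30):
            pos0 = self._fresh_pos(rng)
            ref = self._base(pos0)
            alt = self._alt_base(rng, ref)
            panel[(self.chrom, pos0 + 1, ref, alt)] = int(rng.integers(1, 20))
        truth.n_contaminants = cfg.panel_contaminants
        return panel

    # -- cohort -------------------------------------------------------------

    def run(self, germline_only: bool = False) -> Cohort:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
        pedigrees = self.build_pedigrees()
        ped_by_id = {p.family_id: p for p in pedigrees}

        germline: dict[str, list] = {}
        family_truths: dict[str, FamilyTruth] = {}
        causal_genes = [f"CAUS{i + 1:02d}" for i in range(len(pedigrees))]
        for ped, gene in zip(pedigrees, causal_genes):
            records, truth = self.simulate_family_germline(ped, gene, rng)
            germline[ped.family_id] = records
            family_truths[ped.family_id] = truth
        self._plant_cross_family_inconsistency(germline, ped_by_id, rng)

        somatic: dict[str, list] = {}
        somatic_callable: dict[str, IntervalSet] = {}
        somatic_truths: dict[str, SomaticTruth] = {}
        panel_counts: dict[tuple, int] = {}
        second_hits: list[tuple[str, str, str]] = []
        for plan in () if germline_only else cfg.somatic_plans:
            ped = ped_by_id[plan.family_id]
            records, callable_set, truth = self.simulate_somatic(
                plan, ped, family_truths[plan.family_id],
                germline[plan.family_id], rng,
            )
            if plan.unpaired:
                panel_counts.update(
                    self._contaminate_unpaired(records, truth, rng)
                )
            somatic[plan.family_id] = records
            somatic_callable[plan.family_id] = callable_set
            somatic_truths[truth.sample_id] = truth
            if plan.second_hit != "none":
                second_hits.append(
                    (plan.family_id, family_truths[plan.family_id].gene,
                     plan.second_hit)
                )

        return Cohort(
            config=cfg,
            reference=self.reference,
            gene_map=self.gene_map,
            gene_sets=self.gene_sets,
            pedigrees=pedigrees,
            germline=germline,
            germline_callable=self.germline_callable,
            somatic=somatic,
            somatic_callable=somatic_callable,
            panel_counts=panel_counts,
            truth=TruthTable(
                families=family_truths,
                somatic=somatic_truths,
                second_hits=second_hits,
            ),
        )


def simulate_cohort(
    config: SimConfig | None = None,
    seed: int | None = None,
    germline_only: bool = False,
    **kwargs,
) -> Cohort:
    """Build an in-memory synthetic cohort (see `write_cohort` for disk)."""
    if config is None:
        config = SimConfig(seed=seed if seed is not None else 0, **kwargs)
    elif seed is not None:
        config = dataclasses.replace(config, seed=seed)
    return CohortSimulator(config).run(germline_only=germline_only)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort in the exact formats `formats_io` reads."""
    outdir = Path(outdir)
    (outdir / "germline").mkdir(parents=True, exist_ok=True)
    (outdir / "somatic").mkdir(parents=True, exist_ok=True)

    write_reference(cohort.reference, outdir / "reference.fa")
    formats_io.write_gene_map(cohort.gene_map, outdir / "genes.tsv")
    cohort.gene_sets.dump(outdir / "gene_sets.yaml")
    formats_io.write_pedigree(cohort.pedigrees, outdir / "cohort.ped")
    formats_io.write_bed(cohort.germline_callable, outdir / "germline_callable.bed")

    for ped in cohort.pedigrees:
        fam = ped.family_id
        formats_io.write_vcf(
            cohort.germline[fam],
            outdir / "germline" / f"{fam}.vcf",
            sample_ids=[m.sample_id for m in ped.members],
            contigs=cohort.contigs,
        )
    for fam in sorted(cohort.somatic):
        sample_id = f"{fam}.T"
        formats_io.write_vcf(
            cohort.somatic[fam],
            outdir / "somatic" / f"{fam}.vcf",
            sample_ids=[sample_id],
            contigs=cohort.contigs,
        )
        formats_io.write_bed(
            cohort.somatic_callable[fam], outdir / "somatic" / f"{fam}.bed"
        )
        if cohort.truth.somatic[sample_id].unpaired:
            # marker consumed by the pipeline: analyze against the panel
            (outdir / "somatic" / f"{fam}.unpaired").write_text("")

    if cohort.panel_counts:
        lines = ["#chrom\tpos\tref\talt\tn_samples"]
        for key in sorted(cohort.panel_counts):
            c, p, r, a = key
            lines.append(f"{c}\t{p}\t{r}\t{a}\t{cohort.panel_counts[key]}")
        (outdir / "panel.tsv").write_text("\n".join(lines) + "\n")

    _write_truth(cohort.truth, outdir)


def _write_truth(truth: TruthTable, outdir: Path) -> None:
    lines = ["#family_id\tgene\tchrom\tpos\tref\talt\timpact\thgvs\tflanking_keys"]
    for fam in sorted(truth.families):
        t = truth.families[fam]
        flank = ",".join(f"{k[0]}:{k[1]}:{k[2]}:{k[3]}" for k in t.flanking_het_keys)
        v = t.variant
        lines.append(
            f"{fam}\t{t.gene}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
            f"\t{t.impact}\t{t.hgvs}\t{flank}"
        )
    (outdir / "truth_families.tsv").write_text("\n".join(lines) + "\n")

    lines = [
        "#sample_id\tfamily_id\tsnv_count\tindel_count\tfootprint_mb"
        "\tsbs_weights\tid_weights\tsecond_hit\tsecond_hit_key"
        "\tloh_sites\tqc_fail\tunpaired\tn_contaminants"
    ]
    for sid in sorted(truth.somatic):
        t = truth.somatic[sid]
        sbs = ",".join(f"{k}:{v:g}" for k, v in sorted(t.sbs_weights.items()))
        idw = ",".join(f"{k}:{v:g}" for k, v in sorted(t.id_weights.items()))
        shk = (
            f"{t.second_hit_key[0]}:{t.second_hit_key[1]}"
            f":{t.second_hit_key[2]}:{t.second_hit_key[3]}"
            if t.second_hit_key
            else "."
        )
        loh = ",".join(f"{k[0]}:{k[1]}" for k in t.loh_site_keys) or "."
        lines.append(
            f"{sid}\t{t.family_id}\t{t.snv_count}\t{t.indel_count}"
            f"\t{t.footprint_mb:.6f}\t{sbs}\t{idw}\t{t.second_hit}\t{shk}"
            f"\t{loh}\t{int(t.qc_fail)}\t{int(t.unpaired)}\t{t.n_contaminants}"
        )
    (outdir / "truth_somatic.tsv").write_text("\n".join(lines) + "\n")

    lines = ["#family_id\tgene\tkind"]
    for fam, gene, kind in truth.second_hits:
        lines.append(f"{fam}\t{gene}\t{kind}")
    (outdir / "truth_second_hits.tsv").write_text("\n".join(lines) + "\n")
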