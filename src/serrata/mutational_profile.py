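"""Per-sample somatic mutational characterization.

Covers mutation-burden metrics with load classes (hypermutated > 10 mut/Mb,
ultra-hypermutated > 100 mut/Mb, strict thresholds), trinucleotide SBS96 and
indel ID83 category classification against a reference sequence, signature
refitting by non-negative least squares with backward pruning, aetiology
flagging, and driver-gene reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .types import AnnotatedVariant, GenotypeCall, SignatureCatalog

__all__ = [
    "SBS96_CATEGORIES",
    "ID83_CATEGORIES",
    "DRIVER_GENES",
    "HOTSPOTS",
    "DEFAULT_AETIOLOGY_FLAGS",
    "CatalogVector",
    "BurdenReport",
    "RefitResult",
    "DriverCall",
    "DriverReport",
    "sbs96_classify",
    "id_classify",
    "build_catalog",
    "compute_burden",
    "refit_signatures",
    "flag_aetiology",
    "driver_report",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: COSMIC-ordered SBS96 labels: substitution-major, then 5' and 3' flank.
SBS96_CATEGORIES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)


def _id83_labels() -> tuple[str, ...]:
    labels: list[str] = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{n}" for n in range(6)]
    for size in ("2", "3", "4", "5+"):
        labels += [f"{size}:Del:R:{n}" for n in range(6)]
    for size in ("2", "3", "4", "5+"):
        labels += [f"{size}:Ins:R:{n}" for n in range(6)]
    for size, max_mh in (("2", 1), ("3", 2), ("4", 3), ("5+", 5)):
        labels += [f"{size}:Del:M:{m}" for m in range(1, max_mh + 1)]
    return tuple(labels)


#: 83 indel categories: type x size x homopolymer/repeat/microhomology
#: context. The bin table is also shipped as ``data/id83_bins.tsv``.
ID83_CATEGORIES: tuple[str, ...] = _id83_labels()

DRIVER_GENES = (
    "BRAF", "KRAS", "POLE", "POLD1",
    "MLH1", "MLH3", "MSH2", "MSH3", "MSH6", "PMS2",
)

#: Exact HGVS-p shorthand hotspot strings per driver gene.
HOTSPOTS: Mapping[str, tuple[str, ...]] = {
    "BRAF": ("V600E",),
    "KRAS": ("G12D", "G12V", "G12C", "G13D", "Q61H", "A146T"),
}

DEFAULT_AETIOLOGY_FLAGS: Mapping[str, tuple[str, ...]] = {
    "clock-like": ("SBS1", "SBS5", "ID1", "ID2"),
    "MMR-deficiency": ("SBS15", "SBS21", "ID1", "ID2"),
    "possible-artifact": ("SBS54",),
}


class ReferenceMismatchError(ValueError):
    """REF allele disagrees with the reference sequence."""


def _seq(reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) from a dict-of-str or pyfaidx-like reference."""
    obj = reference[chrom]
    if isinstance(obj, str):
        return obj[max(start0, 0):end0].upper()
    return str(obj[max(start0, 0):end0]).upper()


def _chrom_len(reference, chrom: str) -> int:
    return len(reference[chrom])


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

def sbs96_classify(mutation: AnnotatedVariant, reference) -> str | None:
    """SBS96 label for an SNV, pyrimidine-normalized.

    Purine-reference mutations are reverse-complemented together with
    their flanks so a mutation and its reverse-complement representation
    share a label. Returns None (unclassifiable) when a flank falls off
    the contig or contains a non-ACGT base.
    """
    if mutation.var_class != "SNV":
        raise ValueError("sbs96_classify requires an SNV")
    pos0 = mutation.pos - 1
    ref_base = _seq(reference, mutation.chrom, pos0, pos0 + 1)
    if ref_base != mutation.ref.upper():
        raise ReferenceMismatchError(
            f"{mutation.chrom}:{mutation.pos} REF {mutation.ref} != "
            f"reference {ref_base}"
        )
    if pos0 == 0 or pos0 + 1 >= _chrom_len(reference, mutation.chrom):
        return None
    tri = _seq(reference, mutation.chrom, pos0 - 1, pos0 + 2)
    alt = mutation.alt.upper()
    if any(b not in "ACGT" for b in tri + alt):
        return None
    if tri[1] in "AG":  # purine center: flip strand
        tri = tri.translate(_COMPLEMENT)[::-1]
        alt = alt.translate(_COMPLEMENT)
    return f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"


# ---------------------------------------------------------------------------
# ID83
# ---------------------------------------------------------------------------

def _indel_event(mutation: AnnotatedVariant) -> tuple[str, int, str] | None:
    """Decompose a VCF-style indel into (kind, pos0_of_event, unit).

    Requires the standard left-anchored representation (ref is a prefix of
    alt or vice versa). Anything else is a complex indel -> None.
    """
    ref, alt = mutation.ref.upper(), mutation.alt.upper()
    if mutation.var_class == "insertion":
        if not alt.startswith(ref):
            return None
        return ("Ins", mutation.pos - 1 + len(ref), alt[len(ref):])
    if mutation.var_class == "deletion":
        if not ref.startswith(alt):
            return None
        return ("Del", mutation.pos - 1 + len(alt), ref[len(alt):])
    return None


def _run_length(reference, chrom: str, pos0: int, base: str, direction: int) -> int:
    """Count consecutive `base` starting at pos0 moving in `direction`."""
    n = 0
    limit = _chrom_len(reference, chrom)
    while 0 <= pos0 < limit and _seq(reference, chrom, pos0, pos0 + 1) == base:
        n += 1
        pos0 += direction
    return n


def _tandem_copies(reference, chrom: str, start0: int, unit: str, skip_first: bool) -> int:
    """Tandem copies of `unit` at start0 (for Del the first copy is the
    deleted one itself, counted via skip_first)."""
    k = len(unit)
    limit = _chrom_len(reference, chrom)
    n = 0
    p = start0
    while p + k <= limit and _seq(reference, chrom, p, p + k) == unit:
        n += 1
        p += k
    # also extend left of the event
    p = start0 - k
    while p >= 0 and _seq(reference, chrom, p, p + k) == unit:
        n += 1
        p -= k
    return n if not skip_first else n  # deleted copy included in scan


def _microhomology(reference, chrom: str, pos0: int, deleted: str) -> int:
    """Longest flanking sequence identity usable for MH-mediated repair:
    max over (prefix of deleted matching sequence right of the deletion,
    suffix of deleted matching sequence left of the deletion)."""
    size = len(deleted)
    limit = _chrom_len(reference, chrom)
    right = 0
    for m in range(size - 1, 0, -1):
        end = pos0 + size + m
        if end <= limit and _seq(reference, chrom, pos0 + size, end) == deleted[:m]:
            right = m
            break
    left = 0
    for m in range(size - 1, 0, -1):
        start = pos0 - m
        if start >= 0 and _seq(reference, chrom, start, pos0) == deleted[size - m:]:
            left = m
            break
    return max(left, right)


def id_classify(mutation: AnnotatedVariant, reference) -> str | None:
    """ID83 label for a pure insertion or deletion.

    1 bp events are binned by the homopolymer run length of the affected
    base (pyrimidine-normalized); >= 2 bp events by tandem-repeat unit
    count, or for non-repeat deletions by microhomology length. Complex
    indels return None (unclassifiable).
    """
    event = _indel_event(mutation)
    if event is None:
        return None
    kind, pos0, unit = event
    size = len(unit)
    if any(b not in "ACGT" for b in unit):
        return None
    chrom = mutation.chrom

    if size == 1:
        base = unit
        if kind == "Del":
            run = (
                1
                + _run_length(reference, chrom, pos0 - 1, base, -1)
                + _run_length(reference, chrom, pos0 + 1, base, +1)
            )
            number = min(run - 1, 5)
        else:
            run = _run_length(reference, chrom, pos0 - 1, base, -1) + _run_length(
                reference, chrom, pos0, base, +1
            )
            number = min(run, 5)
        if base in "AG":
            base = base.translate(_COMPLEMENT)
        return f"1:{kind}:{base}:{number}"

    size_label = str(size) if size < 5 else "5+"
    if kind == "Del":
        copies = _tandem_copies(reference, chrom, pos0, unit, skip_first=True)
        if copies >= 2:
            return f"{size_label}:Del:R:{min(copies - 1, 5)}"
        mh = _microhomology(reference, chrom, pos0, unit)
        if mh >= 1:
            max_mh = 5 if size >= 5 else size - 1
            return f"{size_label}:Del:M:{min(mh, max_mh)}"
        return f"{size_label}:Del:R:0"
    copies = _tandem_copies(reference, chrom, pos0, unit, skip_first=False)
    return f"{size_label}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# Catalog vectors & burden
# ---------------------------------------------------------------------------

@dataclass
class CatalogVector:
    scheme: str  # "SBS96" | "ID"
    counts: np.ndarray
    sample_id: str = ""
    unclassifiable: int = 0
    ignored: int = 0  # mutations of the other class (e.g. indels under SBS96)

    @property
    def categories(self) -> tuple[str, ...]:
        return SBS96_CATEGORIES if self.scheme == "SBS96" else ID83_CATEGORIES

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_catalog(
    mutations: Iterable[AnnotatedVariant],
    reference,
    scheme: str,
    sample_id: str = "",
) -> CatalogVector:
    """Count mutations into SBS96 or ID83 categories.

    Mutations of the other class are ignored (but tallied); context
    failures go to the unclassifiable bucket. classified + unclassifiable
    + ignored equals the input count.
    """
    if scheme not in ("SBS96", "ID"):
        raise ValueError(f"unknown scheme {scheme!r}")
    cats = SBS96_CATEGORIES if scheme == "SBS96" else ID83_CATEGORIES
    index = {c: i for i, c in enumerate(cats)}
    counts = np.zeros(len(cats), dtype=int)
    unclassifiable = 0
    ignored = 0
    for mut in mutations:
        is_snv = mut.var_class == "SNV"
        if scheme == "SBS96":
            if not is_snv:
                ignored += 1
                continue
            label = sbs96_classify(mut, reference)
        else:
            if mut.var_class not in ("insertion", "deletion"):
                ignored += 1
                continue
            label = id_classify(mut, reference)
        if label is None:
            unclassifiable += 1
        else:
            counts[index[label]] += 1
    return CatalogVector(scheme, counts, sample_id, unclassifiable, ignored)


@dataclass(frozen=True)
class BurdenReport:
    sample_id: str
    snv_count: int
    indel_count: int
    footprint_mb: float
    #: combined (SNV+indel) mutations per Mb; classification input.
    tmb: float
    snv_tmb: float
    indel_burden: float
    load_class: str

    @property
    def hypermutated(self) -> bool:
        return self.load_class in ("hypermutated", "ultra_hypermutated")


def classify_load(tmb: float, hyper: float = 10.0, ultra: float = 100.0) -> str:
    """Strict thresholds: exactly 10 is non-hypermutated, exactly 100 is
    hypermutated."""
    if tmb > ultra:
        return "ultra_hypermutated"
    if tmb > hyper:
        return "hypermutated"
    return "non_hypermutated"


def compute_burden(
    mutations: Sequence[AnnotatedVariant],
    footprint_mb: float,
    sample_id: str = "",
) -> BurdenReport:
    if footprint_mb <= 0:
        raise ValueError("callable footprint must be positive")
    snvs = sum(1 for m in mutations if m.var_class in ("SNV", "MNV"))
    indels = sum(1 for m in mutations if m.var_class in ("insertion", "deletion"))
    tmb = (snvs + indels) / footprint_mb
    return BurdenReport(
        sample_id=sample_id,
        snv_count=snvs,
        indel_count=indels,
        footprint_mb=footprint_mb,
        tmb=tmb,
        snv_tmb=snvs / footprint_mb,
        indel_burden=indels / footprint_mb,
        load_class=classify_load(tmb),
    )


# ---------------------------------------------------------------------------
# Signature refitting
# ---------------------------------------------------------------------------

@dataclass
class RefitResult:
    weights: dict[str, float]
    cosine: float
    n_mutations: int
    pruned: list[str] = field(default_factory=list)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _nnls_fit(S: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    w, _ = nnls(S, v)
    return w, _cosine(S @ w, v)


def refit_signatures(
    vector: CatalogVector,
    catalog: SignatureCatalog,
    prune_threshold: float = 0.05,
    min_cosine_drop: float = 0.01,
    signatures: Sequence[str] | None = None,
) -> RefitResult:
    """Estimate signature contributions by NNLS with backward pruning.

    Solves ``min || v/||v||_1 - S w ||_2, w >= 0`` over the catalog
    columns, then repeatedly drops the smallest-weight active signature
    while its weight is below ``prune_threshold`` and dropping it costs
    less than ``min_cosine_drop`` in reconstruction cosine similarity,
    refitting after each removal. (Cosine similarity is nearly blind to
    removing a low-magnitude flat component, so weight and cosine cost
    must *both* be negligible before a signature is discarded; otherwise
    genuinely contributing broad signatures would always be pruned.)
    Weights are renormalized to sum 1.
    """
    names = list(signatures) if signatures is not None else list(catalog.names)
    if tuple(c for c in catalog.categories) != tuple(vector.categories):
        raise ValueError("catalog categories do not match vector scheme")
    n = vector.total
    if n == 0:
        return RefitResult(weights={}, cosine=0.0, n_mutations=0, pruned=[])
    v = vector.counts.astype(float) / n

    S = catalog.matrix(names)
    if np.linalg.matrix_rank(S) < min(S.shape):
        import warnings

        warnings.warn("signature catalog is rank-deficient; proceeding", stacklevel=2)
    active = list(names)
    w, cos = _nnls_fit(catalog.matrix(active), v)
    pruned: list[str] = []
    # drop zero-weight columns outright
    keep = [i for i, wi in enumerate(w) if wi > 1e-12]
    pruned += [active[i] for i in range(len(active)) if i not in keep]
    active = [active[i] for i in keep]
    w = w[keep]

    while len(active) > 1:
        i_min = int(np.argmin(w))
        trial = [s for j, s in enumerate(active) if j != i_min]
        w_trial, cos_trial = _nnls_fit(catalog.matrix(trial), v)
        if w[i_min] < prune_threshold and (cos - cos_trial) < min_cosine_drop:
            pruned.append(active[i_min])
            active, w, cos = trial, w_trial, cos_trial
        else:
            break

    total = w.sum()
    weights = {s: float(wi / total) for s, wi in zip(active, w) if wi / total > 0}
    return RefitResult(weights=weights, cosine=cos, n_mutations=n, pruned=pruned)


def flag_aetiology(
    refit: RefitResult,
    flag_map: Mapping[str, Sequence[str]] | None = None,
    floor: float = 0.05,
) -> dict[str, float]:
    """Aetiology groups whose summed signature weight exceeds `floor`.

    Low-weight matches are suppressed as an overfitting guard.
    """
    flag_map = flag_map if flag_map is not None else DEFAULT_AETIOLOGY_FLAGS
    out: dict[str, float] = {}
    for group, sigs in flag_map.items():
        weight = sum(refit.weights.get(s, 0.0) for s in sigs)
        if weight > floor:
            out[group] = weight
    return out


# ---------------------------------------------------------------------------
# Driver report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriverCall:
    gene: str
    protein_change: str
    aaf: float
    tier: str  # "high" (aaf >= 0.20) | "low"
    hotspot: bool
    variant: AnnotatedVariant


@dataclass
class DriverReport:
    sample_id: str
    calls: list[DriverCall]

    def by_gene(self) -> dict[str, list[DriverCall]]:
        out: dict[str, list[DriverCall]] = {}
        for c in self.calls:
            out.setdefault(c.gene, []).append(c)
        return out


def driver_report(
    mutations: Iterable[tuple[AnnotatedVariant, GenotypeCall]],
    sample_id: str = "",
    aaf_tier_threshold: float = 0.20,
    genes: Sequence[str] = DRIVER_GENES,
) -> DriverReport:
    """Report all somatic variants in the driver genes, with AAF tier.

    No AAF threshold is applied for inclusion — low-AAF driver variants
    are reported in the low-confidence tier. Hotspot matching is exact
    string equality on the HGVS-p shorthand.
    """
    gene_set = set(genes)
    calls = []
    for variant, gcall in mutations:
        if variant.gene not in gene_set:
            continue
        aaf = gcall.aaf
        tier = "high" if aaf >= aaf_tier_threshold else "low"
        hotspot = variant.protein_change in HOTSPOTS.get(variant.gene, ())
        calls.append(
            DriverCall(
                gene=variant.gene,
                protein_change=variant.protein_change,
                aaf=aaf,
                tier=tier,
                hotspot=hotspot,
                variant=variant,
            )
        )
    calls.sort(key=lambda c: (c.gene, -c.aaf))
    return DriverReport(sample_id=sample_id, calls=calls)
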