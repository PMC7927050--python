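"""Read/write the on-disk formats used by every other module.

VCF v4.2 is the variant exchange format. Annotations are *consumed*, never
computed: gene, consequence, population frequencies and predictor verdicts
must already be present as INFO tags following this schema:

=============  ======================================================
INFO tag       meaning
=============  ======================================================
``GENE``       gene symbol (string)
``IMPACT``     raw consequence term (``missense``, ``stop_gained`` ...)
``HGVSP``      protein change, HGVS-p shorthand (string)
``PAF_<DB>``   allele frequency in population database <DB> (float)
``PRED_<T>``   verdict of predictor <T>: ``D``/``T``/``U``
=============  ======================================================

FORMAT fields ``GT``, ``AD``, ``DP`` are parsed into :class:`GenotypeCall`.
Any other INFO *flag* is carried through on ``AnnotatedVariant.flags``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from .intervals import IntervalSet
from .types import (
    PREDICTOR_TOOLS,
    AnnotatedVariant,
    CandidateGene,
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    SignatureCatalog,
    impact_class_of,
)

log = logging.getLogger(__name__)

#: default population-database tags written by the simulator
DEFAULT_POP_DBS = ("gnomad", "exac", "onekg")

_VERDICT_CODES = {"D": "deleterious", "T": "tolerated", "U": "unavailable"}
_CODE_OF_VERDICT = {v: k for k, v in _VERDICT_CODES.items()}

VcfRecord = tuple[AnnotatedVariant, dict[str, GenotypeCall]]


class VcfParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sample_filter: Sequence[str] | None = None,
) -> list[VcfRecord]:
    """Parse an annotated VCF into ``(AnnotatedVariant, {sample: call})``.

    Multi-allelic records are decomposed into one entry per ALT allele;
    genotypes are re-expressed with respect to that allele. Records whose
    IMPACT term is unrecognized are kept with ``impact="other"`` and a
    warning. AD/DP absence marks depths unavailable rather than failing.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from None
    samples = list(vcf.samples)
    if sample_filter is not None:
        keep_idx = [i for i, s in enumerate(samples) if s in set(sample_filter)]
    else:
        keep_idx = list(range(len(samples)))

    out: list[VcfRecord] = []
    for rec in vcf:
        alts = rec.ALT or []
        info = dict(rec.INFO)
        for ai, alt in enumerate(alts):
            variant = _build_variant(rec, info, ai, alt, path)
            calls = _build_calls(rec, samples, keep_idx, ai)
            out.append((variant, calls))
    vcf.close()
    return out


def _per_alt(value, ai: int, n_alt: int):
    """INFO values may be scalar (shared) or per-ALT tuples."""
    if isinstance(value, (tuple, list)):
        return value[ai] if len(value) == n_alt else value[0]
    if isinstance(value, str) and n_alt > 1 and value.count(",") == n_alt - 1:
        return value.split(",")[ai]
    return value


def _build_variant(rec, info: dict, ai: int, alt: str, path: str) -> AnnotatedVariant:
    n_alt = len(rec.ALT)
    pop_freqs: dict[str, float] = {}
    verdicts: dict[str, str] = {}
    flags: set[str] = set()
    for key, value in info.items():
        if key.startswith("PAF_"):
            raw = _per_alt(value, ai, n_alt)
            try:
                # VCF floats are 32-bit; normalize to 6 significant digits
                # so write -> read round-trips exactly
                freq = float(f"{float(raw):.6g}")
            except (TypeError, ValueError):
                raise VcfParseError(
                    f"{path}: bad frequency {raw!r} in {key} at "
                    f"{rec.CHROM}:{rec.POS}"
                ) from None
            if not np.isnan(freq):
                pop_freqs[key[4:].lower()] = freq
        elif key.startswith("PRED_"):
            code = str(_per_alt(value, ai, n_alt)).strip()
            tool = key[5:].lower()
            if tool not in PREDICTOR_TOOLS:
                raise VcfParseError(
                    f"{path}: predictor tag for unknown tool {tool!r}"
                )
            if code not in _VERDICT_CODES:
                raise VcfParseError(
                    f"{path}: bad predictor code {code!r} in {key}"
                )
            verdicts[tool] = _VERDICT_CODES[code]
        elif value is True:
            flags.add(key)

    consequence = str(info.get("IMPACT", "")) if "IMPACT" in info else ""
    impact, known = impact_class_of(consequence) if consequence else ("other", True)
    if not known:
        log.warning(
            "%s: unknown impact %r at %s:%s, using 'other'",
            path, consequence, rec.CHROM, rec.POS,
        )
    return AnnotatedVariant(
        chrom=rec.CHROM,
        pos=rec.POS,
        ref=rec.REF,
        alt=alt,
        gene=str(info.get("GENE", "")),
        consequence=consequence,
        impact=impact,
        protein_change=str(info.get("HGVSP", "")),
        pop_freqs=pop_freqs,
        predictor_verdicts=verdicts,
        flags=frozenset(flags),
    )


def _build_calls(rec, samples, keep_idx, ai: int) -> dict[str, GenotypeCall]:
    calls: dict[str, GenotypeCall] = {}
    try:
        ad = rec.format("AD")
    except KeyError:
        ad = None
    try:
        dp = rec.format("DP")
    except KeyError:
        dp = None
    genotypes = rec.genotypes  # [[a0, a1, phased], ...]
    for i in keep_idx:
        sample = samples[i]
        alleles = genotypes[i][:-1]
        if any(a == -1 for a in alleles):
            gt = "missing"
        else:
            n_alt = sum(1 for a in alleles if a == ai + 1)
            n_called = len(alleles)
            if n_alt == n_called:
                gt = "hom_alt"
            elif n_alt > 0:
                gt = "het"
            else:
                gt = "hom_ref"
        if ad is not None and ad.shape[1] > ai + 1 and ad[i, 0] >= 0:
            ref_c = int(ad[i, 0])
            alt_c = int(ad[i, ai + 1])
            depth = int(dp[i, 0]) if dp is not None else ref_c + alt_c
            calls[sample] = GenotypeCall(
                sample, gt, ref_c, alt_c, max(depth, ref_c + alt_c)
            )
        else:
            depth = int(dp[i, 0]) if dp is not None and dp[i, 0] >= 0 else 0
            calls[sample] = GenotypeCall(
                sample, gt, 0, 0, depth, depths_available=False
            )
    return calls


_GT_CODE = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf(
    records: Iterable[VcfRecord],
    path: str | Path,
    sample_ids: Sequence[str],
    reference_name: str = "synthetic",
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic records with the annotation INFO schema above.

    Records are sorted by (chrom, pos, ref, alt); genotype columns follow
    ``sample_ids`` order. Samples without a call get ``./.``.
    """
    records = sorted(records, key=lambda rv: (rv[0].chrom, rv[0].pos, rv[0].ref, rv[0].alt))
    flag_keys = sorted({f for v, _ in records for f in v.flags})
    db_keys = sorted({db for v, _ in records for db in v.pop_freqs})
    lines = ["##fileformat=VCFv4.2", f"##reference={reference_name}"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append('##INFO=<ID=IMPACT,Number=1,Type=String,Description="Consequence term">')
    lines.append('##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein change">')
    for db in db_keys:
        lines.append(
            f'##INFO=<ID=PAF_{db.upper()},Number=1,Type=Float,'
            f'Description="Population AF ({db})">'
        )
    for tool in PREDICTOR_TOOLS:
        lines.append(
            f'##INFO=<ID=PRED_{tool.upper()},Number=1,Type=String,'
            f'Description="Predictor verdict ({tool}): D/T/U">'
        )
    for f in flag_keys:
        lines.append(f'##INFO=<ID={f},Number=0,Type=Flag,Description="{f}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols += list(sample_ids)
    lines.append("\t".join(cols))

    for variant, calls in records:
        info_parts = []
        if variant.gene:
            info_parts.append(f"GENE={variant.gene}")
        if variant.consequence:
            info_parts.append(f"IMPACT={variant.consequence}")
        if variant.protein_change:
            info_parts.append(f"HGVSP={variant.protein_change}")
        for db in sorted(variant.pop_freqs):
            info_parts.append(f"PAF_{db.upper()}={variant.pop_freqs[db]:.6g}")
        for tool in PREDICTOR_TOOLS:
            if tool in variant.predictor_verdicts:
                code = _CODE_OF_VERDICT[variant.predictor_verdicts[tool]]
                info_parts.append(f"PRED_{tool.upper()}={code}")
        for f in sorted(variant.flags):
            info_parts.append(f)
        fields = [
            variant.chrom, str(variant.pos), ".", variant.ref, variant.alt,
            ".", "PASS", ";".join(info_parts) or ".", "GT:AD:DP",
        ]
        for sid in sample_ids:
            call = calls.get(sid)
            if call is None:
                fields.append("./.:.:.")
            elif not call.depths_available:
                dp = str(call.depth) if call.depth else "."
                fields.append(f"{_GT_CODE[call.gt]}:.:{dp}")
            else:
                fields.append(
                    f"{_GT_CODE[call.gt]}:{call.ref_count},{call.alt_count}:{call.depth}"
                )
        lines.append("\t".join(fields))

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> list[Pedigree]:
    """Parse a PED-like TSV into per-family pedigrees.

    Columns: family_id, sample_id, father, mother, sex, phenotype
    (2 = affected), plus an optional 7th column marking a paired somatic
    sample (1/0). Families are returned in file order; per-family
    invariants (unique ids, >=1 affected sequenced member) are enforced.
    """
    families: dict[str, list[PedigreeMember]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected >= 6 PED columns")
        fam, sid, father, mother, sex, pheno = parts[:6]
        has_somatic = len(parts) > 6 and parts[6] == "1"
        member = PedigreeMember(
            sample_id=sid,
            affected=pheno == "2",
            sequenced_germline=True,
            has_somatic=has_somatic,
            father=father,
            mother=mother,
            sex=int(sex) if sex.isdigit() else 0,
        )
        if fam not in families:
            families[fam] = []
            order.append(fam)
        families[fam].append(member)
    return [Pedigree(fam, tuple(families[fam])) for fam in order]


def write_pedigree(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    lines = ["#family_id\tsample_id\tfather\tmother\tsex\tphenotype\tsomatic"]
    for ped in pedigrees:
        for m in ped.members:
            lines.append(
                "\t".join(
                    [
                        ped.family_id, m.sample_id, m.father, m.mother,
                        str(m.sex), "2" if m.affected else "1",
                        "1" if m.has_somatic else "0",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / gene map
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> IntervalSet:
    """Callable regions, 0-based half-open."""
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    lines = [f"{c}\t{s}\t{e}" for c, s, e in intervals]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_map(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Gene intervals as {gene: (chrom, start0, end0)} from a BED4 TSV."""
    genes: dict[str, tuple[str, int, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name = line.split("\t")[:4]
        if name in genes:
            raise ValueError(f"{path}:{lineno}: duplicate gene {name}")
        genes[name] = (chrom, int(start), int(end))
    return genes


def write_gene_map(genes: Mapping[str, tuple[str, int, int]], path: str | Path) -> None:
    lines = [
        f"{chrom}\t{start}\t{end}\t{name}"
        for name, (chrom, start, end) in genes.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Signature catalogs
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path, scheme: str = "") -> SignatureCatalog:
    """Load a COSMIC-layout TSV: category rows, one column per signature.

    Profiles within 1e-6 of unit sum are renormalized; anything further
    off, or any negative entry, is an error.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty signature catalog")
    categories = [str(c) for c in df.index]
    signatures = {str(col): df[col].to_numpy(dtype=float) for col in df.columns}
    return SignatureCatalog(categories, signatures, scheme=scheme)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {name: catalog.signatures[name] for name in catalog.names},
        index=list(catalog.categories),
    )
    df.index.name = "Type"
    df.to_csv(path, sep="\t", float_format="%.8g")


# ---------------------------------------------------------------------------
# Candidate table
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = (
    "gene",
    "family",
    "variant",
    "predictor_score",
    "max_pop_af",
    "evidence",
    "selection_criterion",
)


def write_candidate_table(
    candidates: Iterable[CandidateGene], path: str | Path
) -> None:
    """Final gene-evidence TSV, deterministically ordered (family, gene)."""
    rows = sorted(candidates, key=lambda c: (c.family_id, c.gene, c.variant_hgvs))
    lines = ["\t".join(CANDIDATE_COLUMNS)]
    for c in rows:
        score = "N/A" if c.predictor_score is None else str(c.predictor_score)
        af = "N/A" if c.max_pop_af == 0 else f"{c.max_pop_af:.8g}"
        lines.append(
            "\t".join(
                [c.gene, c.family_id, c.variant_hgvs, score, af,
                 c.evidence, c.selection_criterion]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_candidate_table(path: str | Path) -> list[CandidateGene]:
    lines = Path(path).read_text().splitlines()
    header = tuple(lines[0].split("\t"))
    if header != CANDIDATE_COLUMNS:
        raise ValueError(f"{path}: unexpected candidate-table header")
    out = []
    for line in lines[1:]:
        gene, fam, var, score, af, evidence, criterion = line.split("\t")
        out.append(
            CandidateGene(
                gene=gene,
                family_id=fam,
                variant_hgvs=var,
                predictor_score=None if score == "N/A" else int(score),
                max_pop_af=0.0 if af == "N/A" else float(af),
                evidence=evidence,
                selection_criterion=criterion,
            )
        )
    return out
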