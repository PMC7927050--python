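"""End-to-end orchestration: simulate -> prioritize -> twohit -> profile ->
report, reading and writing the documented on-disk layout so every stage is
independently runnable and the whole run is reproducible from config + seed.

Cohort directory layout (produced by `cohort_sim.write_cohort`):

    reference.fa[.fai]   genes.tsv   gene_sets.yaml   cohort.ped
    germline_callable.bed   germline/<FAM>.vcf
    somatic/<FAM>.vcf   somatic/<FAM>.bed   panel.tsv   truth_*.tsv
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, formats_io
from .cohort_sim import SimConfig, simulate_cohort, write_cohort
from .germline_prioritizer import (
    FamilyPrioritization,
    FilterConfig,
    GeneSets,
    prioritize_cohort,
)
from .mutational_profile import (
    BurdenReport,
    DriverReport,
    RefitResult,
    build_catalog,
    compute_burden,
    driver_report,
    flag_aetiology,
    refit_signatures,
)
from .resources import load_id_catalog, load_sbs_catalog
from .somatic_integration import (
    EVIDENCE_PAIRED,
    QcResult,
    SomaticSample,
    TwoHitEvidence,
    paired_qc,
    second_hit_scan,
    unpaired_filter,
)
from .types import CandidateGene


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run description; a run is reproducible from this
    plus the input directory alone."""

    outdir: str
    cohort_dir: str = ""  # empty: simulate into <outdir>/cohort
    seed: int = 0
    maf_threshold: float = 0.001
    min_deleterious_votes: int = 3
    inheritance: str = "both"
    min_shared_fraction: float = 0.70
    aaf_threshold: float = 0.20
    min_depth: int = 10
    alpha: float = 0.01
    delta: float = 0.15
    prune_threshold: float = 0.05
    min_cosine_drop: float = 0.01
    write_report: bool = True

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            maf_threshold=self.maf_threshold,
            min_deleterious_votes=self.min_deleterious_votes,
            inheritance=self.inheritance,
        )


@dataclass
class SampleProfile:
    sample_id: str
    family_id: str
    burden: BurdenReport
    sbs_refit: RefitResult
    id_refit: RefitResult
    aetiology: dict[str, float]
    drivers: DriverReport


@dataclass
class CohortSummary:
    prioritization: dict[str, FamilyPrioritization]
    candidates: list[CandidateGene]
    two_hit: dict[str, list[TwoHitEvidence]]  # family -> evidence
    profiles: dict[str, SampleProfile]  # sample -> profile
    qc_ledger: dict[str, QcResult]  # sample -> qc result (incl. failures)
    excluded_samples: list[str]

    def attrition_table(self) -> dict[str, dict[str, int]]:
        return {f: p.attrition for f, p in sorted(self.prioritization.items())}

    def crossfoot_check(self) -> None:
        """Summary counts must match the per-family tables; every G-S row
        must trace to a two-hit evidence record; excluded samples must not
        appear in profiles."""
        fams_with_gs = {
            c.family_id for c in self.candidates if c.evidence == EVIDENCE_PAIRED
        }
        for fam in fams_with_gs:
            hits = [
                e for e in self.two_hit.get(fam, []) if e.second_hit != "none"
            ]
            if not hits:
                raise AssertionError(f"G-S row without two-hit evidence: {fam}")
        round3 = {
            (p.family_id, pv.gene)
            for p in self.prioritization.values()
            for pv in p.round3
        }
        for c in self.candidates:
            if (c.family_id, c.gene) not in round3:
                raise AssertionError(
                    f"candidate {c.gene}/{c.family_id} lacks a surviving "
                    "prioritized variant"
                )
        for sid in self.excluded_samples:
            if sid in self.profiles:
                raise AssertionError(f"QC-excluded sample profiled: {sid}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_cohort_inputs(cohort_dir: Path):
    pedigrees = formats_io.read_pedigree(cohort_dir / "cohort.ped")
    gene_sets = GeneSets.load(cohort_dir / "gene_sets.yaml")
    germline_callable = formats_io.read_bed(cohort_dir / "germline_callable.bed")
    per_family_records = {}
    for ped in pedigrees:
        vcf = cohort_dir / "germline" / f"{ped.family_id}.vcf"
        per_family_records[ped.family_id] = formats_io.read_vcf(vcf)
    return pedigrees, gene_sets, germline_callable, per_family_records


def _read_panel(path: Path) -> dict[tuple, int]:
    counts: dict[tuple, int] = {}
    if not path.exists():
        return counts
    for line in path.read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, ref, alt, n = line.split("\t")
        counts[(chrom, int(pos), ref, alt)] = int(n)
    return counts


def run_pipeline(config: RunConfig) -> CohortSummary:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.cohort_dir:
        cohort_dir = Path(config.cohort_dir)
    else:
        cohort_dir = outdir / "cohort"
        write_cohort(simulate_cohort(SimConfig(seed=config.seed)), cohort_dir)

    pedigrees, gene_sets, germline_callable, records = _load_cohort_inputs(
        cohort_dir
    )
    ped_by_id = {p.family_id: p for p in pedigrees}
    reference = _read_fasta(cohort_dir / "reference.fa")
    sbs_catalog = load_sbs_catalog()
    id_catalog = load_id_catalog()
    panel = _read_panel(cohort_dir / "panel.tsv")

    # ---- germline prioritization ----------------------------------------
    per_family_variants = {
        fam: [v for v, _ in recs] for fam, recs in records.items()
    }
    per_family_genotypes = {
        fam: {v.key: calls for v, calls in recs}
        for fam, recs in records.items()
    }
    prioritization = prioritize_cohort(
        per_family_variants,
        per_family_genotypes,
        ped_by_id,
        gene_sets,
        config.filter_config,
    )
    _write_round_tables(prioritization, outdir)

    # ---- paired somatic integration & profiling -------------------------
    two_hit: dict[str, list[TwoHitEvidence]] = {}
    profiles: dict[str, SampleProfile] = {}
    qc_ledger: dict[str, QcResult] = {}
    excluded: list[str] = []

    for ped in pedigrees:
        fam = ped.family_id
        vcf_path = cohort_dir / "somatic" / f"{fam}.vcf"
        if not vcf_path.exists():
            continue
        sample_id = f"{fam}.T"
        callable_set = formats_io.read_bed(cohort_dir / "somatic" / f"{fam}.bed")
        unpaired = _is_unpaired(ped, vcf_path)
        qc = paired_qc(
            germline_callable, callable_set,
            config.min_shared_fraction, sample_id=sample_id,
        )
        qc_ledger[sample_id] = qc
        if not qc.passed:
            excluded.append(sample_id)
            continue

        sample = SomaticSample.from_records(
            formats_io.read_vcf(vcf_path),
            sample_id=sample_id,
            family_id=fam,
            callable=callable_set,
            paired=not unpaired,
            pooled_normal=frozenset(panel) if unpaired else None,
        )
        if unpaired:
            sample.mutations = unpaired_filter(sample.mutations, panel)

        burden = compute_burden(
            [v for v, _ in sample.mutations],
            callable_set.total_length() / 1e6,
            sample_id=sample_id,
        )
        sbs_vector = build_catalog(
            [v for v, _ in sample.mutations], reference, "SBS96", sample_id
        )
        id_vector = build_catalog(
            [v for v, _ in sample.mutations], reference, "ID", sample_id
        )
        sbs_refit = refit_signatures(
            sbs_vector, sbs_catalog,
            config.prune_threshold, config.min_cosine_drop,
        )
        id_refit = refit_signatures(
            id_vector, id_catalog,
            config.prune_threshold, config.min_cosine_drop,
        )
        profiles[sample_id] = SampleProfile(
            sample_id=sample_id,
            family_id=fam,
            burden=burden,
            sbs_refit=sbs_refit,
            id_refit=id_refit,
            aetiology=flag_aetiology(sbs_refit),
            drivers=driver_report(sample.mutations, sample_id=sample_id),
        )

        if not unpaired:
            germline_gts = {
                v.key: calls.get(_first_affected(ped))
                for v, calls in records[fam]
                if calls.get(_first_affected(ped)) is not None
            }
            two_hit[fam] = second_hit_scan(
                prioritization[fam].round3,
                sample,
                aaf_threshold=config.aaf_threshold,
                min_depth=config.min_depth,
                alpha=config.alpha,
                delta=config.delta,
                germline_genotypes=germline_gts,
                tmb_class=burden.load_class,
            )

    candidates = _assemble_candidates(prioritization, two_hit)
    summary = CohortSummary(
        prioritization=prioritization,
        candidates=candidates,
        two_hit=two_hit,
        profiles=profiles,
        qc_ledger=qc_ledger,
        excluded_samples=excluded,
    )
    summary.crossfoot_check()

    formats_io.write_candidate_table(candidates, outdir / "candidates.tsv")
    _write_profiles(summary, outdir)
    _write_manifest(config, outdir)
    if config.write_report:
        (outdir / "report.md").write_text(render_report(summary))
    return summary


def _first_affected(ped) -> str:
    return ped.affected_sequenced[0].sample_id


def _is_unpaired(ped, vcf_path: Path) -> bool:
    # a sample is unpaired iff a sibling marker file exists (written by the
    # simulator; a real deployment would flag this in the run config)
    return (vcf_path.parent / f"{ped.family_id}.unpaired").exists()


def _assemble_candidates(
    prioritization: dict[str, FamilyPrioritization],
    two_hit: dict[str, list[TwoHitEvidence]],
) -> list[CandidateGene]:
    """One row per (gene, family); paired evidence wins over germline-only."""
    hits_by_key: dict[tuple[str, str], TwoHitEvidence] = {}
    for fam, evidences in two_hit.items():
        for e in evidences:
            if e.second_hit != "none":
                hits_by_key[(e.gene, fam)] = e
    rows: dict[tuple[str, str], CandidateGene] = {}
    for fam, p in sorted(prioritization.items()):
        for pv in p.round3:
            key = (pv.gene, fam)
            if key in rows:
                continue
            v = pv.variant
            hgvs = v.protein_change or f"{v.chrom}:{v.pos}{v.ref}>{v.alt}"
            evidence = (
                EVIDENCE_PAIRED if key in hits_by_key else "G"
            )
            score = (
                None
                if all(
                    verdict == "unavailable"
                    for verdict in v.predictor_verdicts.values()
                )
                and v.impact == "truncating"
                else pv.predictor_score
            )
            rows[key] = CandidateGene(
                gene=pv.gene,
                family_id=fam,
                variant_hgvs=hgvs,
                predictor_score=score,
                max_pop_af=v.maf,
                evidence=evidence,
                selection_criterion=pv.selection_criterion,
            )
    return list(rows.values())


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

def _read_fasta(path: Path) -> dict[str, str]:
    from pyfaidx import Fasta

    return {name: str(rec[:]) for name, rec in Fasta(str(path)).items()}


def _write_round_tables(
    prioritization: dict[str, FamilyPrioritization], outdir: Path
) -> None:
    lines = ["#family\tround\tchrom\tpos\tref\talt\tgene\timpact\tscore\tcriterion"]
    for fam in sorted(prioritization):
        p = prioritization[fam]
        for v in p.round1:
            lines.append(
                f"{fam}\t1\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}"
                f"\t{v.impact}\t.\t."
            )
        for stage, pvs in (("2", p.round2), ("3", p.round3)):
            for pv in pvs:
                v = pv.variant
                lines.append(
                    f"{fam}\t{stage}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
                    f"\t{v.gene}\t{v.impact}\t{pv.predictor_score}"
                    f"\t{pv.selection_criterion or '.'}"
                )
    (outdir / "prioritization_rounds.tsv").write_text("\n".join(lines) + "\n")

    lines = ["#family\tinput\tround1\tround2\tround3"]
    for fam in sorted(prioritization):
        a = prioritization[fam].attrition
        lines.append(
            f"{fam}\t{a['input']}\t{a['round1']}\t{a['round2']}\t{a['round3']}"
        )
    (outdir / "attrition.tsv").write_text("\n".join(lines) + "\n")


def _write_profiles(summary: CohortSummary, outdir: Path) -> None:
    lines = [
        "#sample\tfamily\tsnv_count\tindel_count\tfootprint_mb\ttmb"
        "\tsnv_tmb\tindel_burden\tload_class"
    ]
    for sid in sorted(summary.profiles):
        b = summary.profiles[sid].burden
        lines.append(
            f"{sid}\t{summary.profiles[sid].family_id}\t{b.snv_count}"
            f"\t{b.indel_count}\t{b.footprint_mb:.6f}\t{b.tmb:.4f}"
            f"\t{b.snv_tmb:.4f}\t{b.indel_burden:.4f}\t{b.load_class}"
        )
    (outdir / "burden.tsv").write_text("\n".join(lines) + "\n")

    for scheme, attr in (("sbs", "sbs_refit"), ("id", "id_refit")):
        sigs = sorted(
            {
                s
                for p in summary.profiles.values()
                for s in getattr(p, attr).weights
            }
        )
        lines = ["sample\t" + "\t".join(sigs + ["cosine", "n_mutations"])]
        for sid in sorted(summary.profiles):
            r: RefitResult = getattr(summary.profiles[sid], attr)
            vals = [f"{r.weights.get(s, 0.0):.4f}" for s in sigs]
            lines.append(
                f"{sid}\t" + "\t".join(vals + [f"{r.cosine:.4f}", str(r.n_mutations)])
            )
        (outdir / f"signature_weights_{scheme}.tsv").write_text(
            "\n".join(lines) + "\n"
        )

    lines = ["#sample\tgene\tprotein_change\taaf\ttier\thotspot"]
    for sid in sorted(summary.profiles):
        for c in summary.profiles[sid].drivers.calls:
            lines.append(
                f"{sid}\t{c.gene}\t{c.protein_change}\t{c.aaf:.4f}"
                f"\t{c.tier}\t{int(c.hotspot)}"
            )
    (outdir / "drivers.tsv").write_text("\n".join(lines) + "\n")

    lines = ["#sample\tshared_fraction\tpassed"]
    for sid in sorted(summary.qc_ledger):
        q = summary.qc_ledger[sid]
        lines.append(f"{sid}\t{q.shared_fraction:.4f}\t{int(q.passed)}")
    (outdir / "qc_ledger.tsv").write_text("\n".join(lines) + "\n")

    lines = ["#family\tgene\tsecond_hit\tsomatic_aaf\ttmb_class"]
    for fam in sorted(summary.two_hit):
        for e in summary.two_hit[fam]:
            lines.append(
                f"{fam}\t{e.gene}\t{e.second_hit}\t{e.somatic_aaf:.4f}"
                f"\t{e.tmb_class}"
            )
    (outdir / "two_hit.tsv").write_text("\n".join(lines) + "\n")


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_sha256": digest,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def render_report(summary: CohortSummary) -> str:
    """Human-readable cohort report mirroring the pipeline's main outputs."""
    out = ["# Cohort summary", ""]
    out.append("## Prioritization attrition (variants per round)")
    out.append("family | input | round1 | round2 | round3")
    out.append("---|---|---|---|---")
    for fam, a in summary.attrition_table().items():
        out.append(
            f"{fam} | {a['input']} | {a['round1']} | {a['round2']} | {a['round3']}"
        )
    out.append("")
    out.append("## Candidate genes")
    if summary.candidates:
        out.append("gene | family | variant | evidence | criterion")
        out.append("---|---|---|---|---")
        for c in sorted(summary.candidates, key=lambda c: (c.family_id, c.gene)):
            out.append(
                f"{c.gene} | {c.family_id} | {c.variant_hgvs} | {c.evidence}"
                f" | {c.selection_criterion}"
            )
    else:
        out.append("No candidate genes survived prioritization.")
    out.append("")
    out.append("## Somatic profiles")
    tmbs = []
    for sid in sorted(summary.profiles):
        p = summary.profiles[sid]
        tmbs.append(p.burden.tmb)
        sigs = ", ".join(
            f"{s} {w:.2f}" for s, w in sorted(p.sbs_refit.weights.items())
        )
        flags = ", ".join(sorted(p.aetiology)) or "-"
        out.append(
            f"- {sid}: TMB {p.burden.tmb:.2f}/Mb ({p.burden.load_class}), "
            f"indels {p.burden.indel_burden:.2f}/Mb; SBS [{sigs}]; "
            f"aetiology: {flags}"
        )
    if tmbs:
        out.append("")
        out.append(
            f"TMB across samples: mean {np.mean(tmbs):.2f} "
            f"± {np.std(tmbs, ddof=1):.2f} mut/Mb (n={len(tmbs)})"
        )
    if summary.excluded_samples:
        out.append("")
        out.append(
            "QC-excluded samples: " + ", ".join(sorted(summary.excluded_samples))
        )
    return "\n".join(out) + "\n"
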