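"""Readers, writers and pipeline orchestration.

File formats: genotype TSV (``id`` plus one ``A/B``-or-``.`` column per
variant), phenotype TSV (one column per survey field, ``.`` for missing,
multiple ticked categories joined by ``;``), VCF v4.3 for the four biallelic
SNPs (the tri-allelic 5-HTTLPR system cannot be represented as a simple SNP
record and is deliberately excluded from the VCF), band TSV for RFLP lanes,
and YAML run configuration.

``run_pipeline`` ties the stages together: simulate-or-read → optional RFLP
calling → per-variant association → effector score → clinical comparison →
power, with an exclusion-accounting log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import association, clinical, effector, power, rflp
from .cohort import Cohort, Individual, NON_USER, TABLET_ONLY, USER
from .simulate import GeneratorConfig, default_config, generate_cohort
from .variants import HTTLPR, SNP_IDS, VARIANTS, VariantDef

PHENOTYPE_COLUMNS = [
    "id", "sex", "age", "age_at_onset", "triptan_injection", "triptan_nasal",
    "triptan_tablet", "triptan_unresponsive", "chronic", "heredity",
    "attack_frequency", "attack_duration", "period_duration",
    "severity_score", "autonomic_symptoms", "smoking", "alcohol_trigger",
    "specific_triggers", "disease_duration",
]
ANSWER_COLUMNS = [c for c in PHENOTYPE_COLUMNS
                  if c in clinical.DEFAULT_QUESTIONS]
MISSING = "."


class DataError(ValueError):
    """Malformed input data (exit code 2 territory)."""


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "yes" if value else "no"
    return str(value)


def write_cohort(cohort: Cohort, genotype_path, phenotype_path,
                 vcf_path=None) -> None:
    """Write genotype and phenotype TSVs and, optionally, a biallelic VCF."""
    variant_ids = list(cohort.variants)
    rows = []
    for ind in cohort:
        row = {"id": ind.id}
        for vid in variant_ids:
            g = ind.genotypes.get(vid)
            row[vid] = MISSING if g is None else "/".join(g)
        rows.append(row)
    pd.DataFrame(rows).to_csv(genotype_path, sep="\t", index=False)

    rows = []
    for ind in cohort:
        row = {
            "id": ind.id, "sex": ind.sex, "age": _fmt(ind.age),
            "age_at_onset": _fmt(ind.age_at_onset),
            "triptan_injection": _fmt(ind.usage_group == USER),
            "triptan_nasal": "no",
            "triptan_tablet": _fmt(ind.usage_group == TABLET_ONLY),
            "triptan_unresponsive": _fmt(ind.triptan_unresponsive),
            "chronic": _fmt(ind.chronic), "heredity": _fmt(ind.heredity),
            "disease_duration": _fmt(ind.numerics.get("disease_duration")),
        }
        for qid in ANSWER_COLUMNS:
            answers = ind.answers.get(qid, [])
            row[qid] = ";".join(answers) if answers else MISSING
        rows.append(row)
    pd.DataFrame(rows)[PHENOTYPE_COLUMNS].to_csv(
        phenotype_path, sep="\t", index=False)

    if vcf_path is not None:
        write_vcf(cohort, vcf_path)


def write_vcf(cohort: Cohort, path) -> None:
    """VCF v4.3 with the four biallelic SNPs (5-HTTLPR excluded)."""
    header = pysam.VariantHeader()
    header.add_meta("source", "triptanpgx")
    snps = [cohort.variants[v] for v in SNP_IDS if v in cohort.variants]
    for chrom in sorted({v.chrom for v in snps}, key=lambda c: (len(c), c)):
        header.contigs.add(chrom, length=100_000)
    header.formats.add("GT", 1, "String", "Genotype")
    for ind in cohort:
        header.add_sample(ind.id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        ordered = sorted(snps, key=lambda v: ((len(v.chrom), v.chrom), v.pos))
        for var in ordered:
            ref, *alts = var.alleles
            rec = vcf.new_record(contig=var.chrom, start=var.pos - 1,
                                 stop=var.pos, alleles=(ref, *alts),
                                 id=var.variant_id)
            index = {a: i for i, a in enumerate(var.alleles)}
            for ind in cohort:
                g = ind.genotypes.get(var.variant_id)
                if g is None:
                    rec.samples[ind.id]["GT"] = (None, None)
                else:
                    rec.samples[ind.id]["GT"] = tuple(sorted(index[a] for a in g))
            vcf.write(rec)


def _parse_genotype(token: str, vid: str, row_id: str):
    if token == MISSING:
        return None
    parts = token.split("/")
    alleles = VARIANTS[vid].alleles if vid in VARIANTS else None
    if len(parts) != 2 or (alleles and not set(parts) <= set(alleles)):
        raise DataError(f"row {row_id!r}, column {vid!r}: "
                        f"malformed genotype {token!r}")
    return tuple(parts)


def _parse_bool(token: str):
    if token == MISSING:
        return None
    if token not in ("yes", "no"):
        raise DataError(f"boolean field must be yes/no/., got {token!r}")
    return token == "yes"


def read_cohort(genotype_path, phenotype_path) -> Cohort:
    """Load a cohort from the TSV pair; usage group is derived here.

    Regular injection or nasal-spray use makes a *user*; tablet use only
    makes *tablet_only*; anyone else who answered the survey is a
    *non-user* (including respondents who tried triptans without effect and
    the ergotamine users).
    """
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str)
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if geno["id"].duplicated().any() or pheno["id"].duplicated().any():
        raise DataError("duplicated individual ids")
    variant_ids = [c for c in geno.columns if c != "id"]
    geno_by_id = {r["id"]: r for _, r in geno.iterrows()}

    individuals = []
    for _, row in pheno.iterrows():
        rid = row["id"]
        injection = _parse_bool(row["triptan_injection"]) or False
        nasal = _parse_bool(row["triptan_nasal"]) or False
        tablet = _parse_bool(row["triptan_tablet"]) or False
        unresponsive = _parse_bool(row["triptan_unresponsive"]) or False
        if injection or nasal:
            group = USER
        elif tablet:
            group = TABLET_ONLY
        else:
            group = NON_USER
        answers = {}
        for qid in ANSWER_COLUMNS:
            token = row[qid]
            selected = [] if token == MISSING else token.split(";")
            question = clinical.DEFAULT_QUESTIONS[qid]
            bad = [a for a in selected if a not in question.categories]
            if bad:
                raise DataError(f"row {rid!r}, column {qid!r}: "
                                f"unknown categories {bad}")
            answers[qid] = selected
        grow = geno_by_id.get(rid)
        genotypes = {vid: _parse_genotype(grow[vid], vid, rid) if grow is not None
                     else None for vid in variant_ids}
        individuals.append(Individual(
            id=rid, sex=row["sex"], age=float(row["age"]),
            usage_group=group,
            age_at_onset=(None if row["age_at_onset"] == MISSING
                          else float(row["age_at_onset"])),
            chronic=_parse_bool(row["chronic"]),
            heredity=_parse_bool(row["heredity"]),
            triptan_unresponsive=unresponsive,
            answers=answers,
            numerics={"disease_duration":
                      None if row["disease_duration"] == MISSING
                      else float(row["disease_duration"])},
            genotypes=genotypes))
    variants = {vid: VARIANTS.get(vid, VariantDef(vid, ()))
                for vid in variant_ids}
    return Cohort(individuals, variants)


def read_band_patterns(path) -> list[rflp.BandPattern]:
    """Band TSV: sample_id <tab> comma-separated fragment lengths."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    patterns = []
    for _, row in df.iterrows():
        try:
            lengths = tuple(int(x) for x in row["fragment_lengths"].split(","))
        except ValueError as exc:
            raise DataError(f"sample {row['sample_id']!r}: bad band list") from exc
        patterns.append(rflp.BandPattern(row["sample_id"], lengths))
    return patterns


def write_calls(calls: Sequence[rflp.TriallelicCall], path) -> None:
    rows = [{"sample_id": c.sample_id,
             "genotype": "/".join(c.genotype) if c.genotype else MISSING,
             "flags": ";".join(sorted(c.flags)) or MISSING}
            for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """One reproducible pipeline run: either file inputs or a generator."""

    output_dir: Path
    genotype_path: Optional[Path] = None
    phenotype_path: Optional[Path] = None
    generator: Optional[GeneratorConfig] = None
    band_path: Optional[Path] = None
    effector_overrides: dict[str, str] = field(default_factory=dict)
    correction_m: int = association.N_TESTED_VARIANTS
    reference_maf: dict[str, float] = field(
        default_factory=lambda: dict(power.DEFAULT_REFERENCE_MAF))
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.genotype_path is not None
        if have_files == (self.generator is not None):
            raise ValueError("exactly one of file inputs or a generator "
                             "configuration must be given")
        if self.correction_m < 1:
            raise ValueError("correction factor must be >= 1")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gen = None
    if "generator" in raw:
        graw = dict(raw["generator"])
        n = graw.pop("n_individuals")
        seed = graw.pop("seed", raw.get("seed", 0))
        gen = default_config(n, seed=seed, **graw)
    return RunConfig(
        output_dir=Path(raw["output_dir"]),
        genotype_path=Path(raw["genotype_path"]) if "genotype_path" in raw else None,
        phenotype_path=Path(raw["phenotype_path"]) if "phenotype_path" in raw else None,
        generator=gen,
        band_path=Path(raw["band_path"]) if "band_path" in raw else None,
        effector_overrides=raw.get("effector_overrides", {}),
        correction_m=raw.get("correction_m", association.N_TESTED_VARIANTS),
        seed=raw.get("seed", 0))


ANALYSES = [  # (label, variant, recoding) — the published six table rows
    ("rs1024905", "rs1024905", "raw"),
    ("rs6724624", "rs6724624", "raw"),
    ("rs5443", "rs5443", "raw"),
    ("rs2651899", "rs2651899", "raw"),
    ("5-HTTLPR:biallelic", HTTLPR, "biallelic"),
    ("5-HTTLPR:collapsed", HTTLPR, "collapsed"),
]


def association_table(cohort: Cohort,
                      m: int = association.N_TESTED_VARIANTS) -> pd.DataFrame:
    """Per-variant allele distributions with adjusted ORs (Table-2 layout)."""
    rows = []
    for label, vid, recoding in ANALYSES:
        table = association.count_alleles(cohort, vid, recoding)
        result = association.additive_logistic(cohort, vid, recoding=recoding)
        for allele in table.alleles:
            rows.append({
                "variant": label, "allele": allele,
                "users_pct": table.percentage(USER, allele),
                "users_n": table.users[allele],
                "nonusers_pct": table.percentage(NON_USER, allele),
                "nonusers_n": table.non_users[allele],
                "effect_allele": result.effect_allele,
                "OR": round(result.odds_ratio, 3),
                "CI95": f"{result.ci_low:.2f}-{result.ci_high:.2f}",
                "P": round(result.p_nominal, 4),
                "P_c": association.format_corrected_p(result.p_nominal, m),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write versioned reports.

    Returns the report bundle as a dict; files written to ``output_dir``:
    association TSV, effector JSON, clinical TSV, power JSON, HWE/call-rate
    TSV, run log JSON (seed and exclusion accounting), plus the synthetic
    cohort TSV/VCF when simulating.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed}

    try:
        if config.generator is not None:
            cohort = generate_cohort(config.generator)
            write_cohort(cohort, out / "genotypes.tsv", out / "phenotypes.tsv",
                         out / "snps.vcf")
            log["input"] = "simulated"
        else:
            cohort = read_cohort(config.genotype_path, config.phenotype_path)
            log["input"] = str(config.genotype_path)
    except Exception as exc:
        raise RuntimeError(f"[stage: input] {exc}") from exc

    sizes = cohort.group_sizes()
    log["n_total"] = len(cohort)
    log["n_users"] = sizes[USER]
    log["n_nonusers"] = sizes[NON_USER]
    log["n_tablet_only_excluded"] = sizes[TABLET_ONLY]
    log["n_unclassified"] = len(cohort) - sum(sizes.values())

    if config.band_path is not None:
        try:
            calls = [rflp.call_genotype(p)
                     for p in read_band_patterns(config.band_path)]
            write_calls(calls, out / "rflp_calls.tsv")
            log["rflp_lanes"] = len(calls)
            log["rflp_no_calls"] = sum(not c.is_call for c in calls)
        except Exception as exc:
            raise RuntimeError(f"[stage: rflp] {exc}") from exc

    try:
        assoc_df = association_table(cohort, config.correction_m)
        assoc_df.to_csv(out / "association.tsv", sep="\t", index=False)
        qc_rows = []
        for vid in cohort.variants:
            genos = [g for g in cohort.genotypes_for(vid) if g is not None]
            alleles = sorted({a for g in genos for a in g})
            if len(alleles) == 2:
                a = alleles[0]
                counts = (sum(g == (a, a) for g in genos),
                          sum(len(set(g)) == 2 for g in genos),
                          sum(a not in g for g in genos))
                hwe_p = association.hwe_exact_test(counts)
            elif len(alleles) == 3:
                idx = {al: i for i, al in enumerate(alleles)}
                mat = [[0] * 3 for _ in range(3)]
                for g in genos:
                    i, j = sorted(idx[a] for a in g)
                    mat[i][j] += 1
                hwe_p = association.hwe_exact_test(
                    mat, rng=np.random.default_rng(config.seed))
            else:
                hwe_p = float("nan")
            qc_rows.append({"variant": vid,
                            "call_rate": round(association.call_rate(cohort, vid), 4),
                            "hwe_p": round(hwe_p, 4)})
        pd.DataFrame(qc_rows).to_csv(out / "variant_qc.tsv", sep="\t",
                                     index=False)
    except Exception as exc:
        raise RuntimeError(f"[stage: association] {exc}") from exc

    try:
        tables = {label: association.count_alleles(cohort, vid, recoding)
                  for label, vid, recoding in ANALYSES
                  if label != "5-HTTLPR:collapsed"}
        tables = {("5-HTTLPR" if k == "5-HTTLPR:biallelic" else k): v
                  for k, v in tables.items()}
        # S is 5-HTTLPR's effector by the bi-allelic rule, not re-derived
        overrides = {HTTLPR: "S", **config.effector_overrides}
        spec = effector.identify_effector_alleles(tables, overrides)
        if HTTLPR not in config.effector_overrides:
            spec.sources[HTTLPR] = effector.LITERATURE
        scores = effector.compute_scores(cohort, spec)
        result = effector.score_regression(cohort, scores)
        log["n_complete_score"] = result.n_complete
        pd.DataFrame(sorted(result.scores.items()),
                     columns=["id", "score"]).to_csv(
            out / "effector_scores.tsv", sep="\t", index=False)
        report = {"effector_alleles": spec.alleles,
                  "sources": spec.sources,
                  "n_complete": result.n_complete,
                  "coefficients": result.coefficients,
                  "se": dict(zip(result.fit.names, map(float, result.fit.se))),
                  "p": result.p_values}
        (out / "effector_regression.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"[stage: effector] {exc}") from exc

    try:
        comparisons = clinical.compare_all(cohort)
        pd.DataFrame([{
            "feature": c.question_id, "test": c.test,
            "statistic": round(c.statistic, 3),
            "df": c.df if c.df is not None else MISSING,
            "p": round(c.p_display, 4),
            "flags": ";".join(sorted(c.flags)) or MISSING}
            for c in comparisons]).to_csv(out / "clinical.tsv", sep="\t",
                                          index=False)
        summary = clinical.summary_table(cohort)
        pd.DataFrame(summary).T.to_csv(out / "summary.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"[stage: clinical] {exc}") from exc

    try:
        n_cases, n_controls = sizes[NON_USER], sizes[USER]
        power_report = {}
        if n_cases > 0 and n_controls > 0:
            for vid, maf in config.reference_maf.items():
                query = power.PowerQuery(n_cases, n_controls / n_cases, maf)
                lo, hi = power.detectable_or(query)
                power_report[vid] = {"maf": maf, "or_low": round(lo, 3),
                                     "or_high": round(hi, 3)}
        (out / "power.json").write_text(
            json.dumps(power_report, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"[stage: power] {exc}") from exc

    (out / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {"log": log, "association": assoc_df, "power": power_report}
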