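"""File I/O, run configuration, and the end-to-end pipeline driver.

Formats: VCF (genotypes; GT field, "." missing), TSV matrices (expression,
dosages), a 1-based-inclusive annotation TSV (probe_id, gene_id, chrom,
tss, strand, snp_in_probe), newick (population tree). Every written TSV
carries ``# key=value`` provenance comment lines including the run seed.
"""

from __future__ import annotations

import io as _io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import cisqtl, popdiff, preprocess, sharing as sharing_mod
from .containers import ExpressionMatrix, GenotypeMatrix
from .synth import StudyConfig, SyntheticStudy, simulate_study

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TSV helpers with provenance headers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        lines = []
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", index_col=index_col)
    return df, meta


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, population: str | None = None) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF (GT field; biallelic records only,
    multi-allelic skipped with a logged count) or from a dosage TSV written
    by :func:`write_dosage_tsv`."""
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, population)
    return _read_dosage_tsv(path, population)


def _read_vcf(path: Path, population: str | None) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS),
                     var.REF, var.ALT[0]))
        dosages.append(dos)
    if n_multi:
        logger.info("%d multi-allelic records skipped in %s", n_multi, path)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]).set_index("snp_id")
    return GenotypeMatrix(
        population=population or path.stem,
        samples=samples,
        snps=snps,
        dosages=np.array(dosages).T if dosages else np.empty((len(samples), 0)),
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with unphased GT calls ("./." missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=popeqtl\n")
        for chrom in pd.unique(gm.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, (snp_id, row) in enumerate(gm.snps.iterrows()):
            calls = [
                "./." if math.isnan(d) else gt_strings[int(d)]
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp_id}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_tsv(gm: GenotypeMatrix, path, meta: dict | None = None) -> None:
    """Sample x SNP dosage matrix as TSV (empty cell = missing)."""
    df = pd.DataFrame(gm.dosages, index=gm.samples, columns=gm.snps.index)
    m = {"population": gm.population, **(meta or {})}
    m["snp_meta"] = ";".join(
        f"{i}:{r['chrom']}:{r['pos']}:{r['ref']}:{r['alt']}" for i, r in gm.snps.iterrows()
    )
    write_table(df, path, m)


def _read_dosage_tsv(path: Path, population: str | None) -> GenotypeMatrix:
    df, meta = read_table(path)
    if "snp_meta" in meta:
        recs = [s.split(":") for s in meta["snp_meta"].split(";")]
        snps = pd.DataFrame(
            recs, columns=["snp_id", "chrom", "pos", "ref", "alt"]
        ).set_index("snp_id")
        snps["pos"] = snps["pos"].astype(int)
        snps = snps.loc[df.columns]
    else:
        snps = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, df.shape[1] + 1), "ref": "A", "alt": "G"},
            index=df.columns,
        )
    return GenotypeMatrix(
        population=population or meta.get("population", path.stem),
        samples=list(df.index),
        snps=snps,
        dosages=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Expression / annotation
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path, meta: dict | None = None) -> None:
    m = {"stage": expr.stage, **(meta or {})}
    write_table(expr.values, path, m)
    write_table(expr.sample_meta, Path(str(path) + ".meta"), m)


def read_expression(path) -> ExpressionMatrix:
    values, meta = read_table(path)
    sample_meta, _ = read_table(Path(str(path) + ".meta"))
    return ExpressionMatrix(values=values, stage=meta.get("stage", "raw"),
                            sample_meta=sample_meta)


def write_annotation(annot: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(annot, path, meta)


def read_annotation(path) -> pd.DataFrame:
    df, _ = read_table(path)
    return df


# ---------------------------------------------------------------------------
# Run configuration and pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline settings (synthetic-input mode)."""

    out_dir: str = "popeqtl_run"
    seed: int = 0
    alphas: tuple[float, ...] = (0.01, 0.001)
    n_perms: int = 1_000
    window: int = 1_000_000
    maf: float = 0.05
    missingness: float = 0.20
    n_hidden: int = 16
    run_reduced: bool = True
    run_vst: bool = True
    run_sharing: bool = True
    run_stepwise: bool = True
    fst_window: int = 1_000
    study: StudyConfig = field(default_factory=StudyConfig)

    def validate(self) -> None:
        for a in self.alphas:
            if not (0 < a < 1):
                raise ValueError(f"alpha {a} out of range")
        if not (0 <= self.maf < 0.5) or not (0 < self.missingness <= 1):
            raise ValueError("invalid maf/missingness threshold")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        study_raw = raw.pop("study", None)
        cfg = cls(**raw)
        if study_raw:
            from .synth import PopulationSpec, TruthConfig

            pops = study_raw.pop("pops", None)
            truth = study_raw.pop("truth", None)
            kw = dict(study_raw)
            if pops is not None:
                kw["pops"] = tuple(PopulationSpec(**p) for p in pops)
            if truth is not None:
                kw["truth"] = TruthConfig(**truth)
            cfg.study = StudyConfig(**kw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    out_dir: Path
    study: SyntheticStudy
    results_corrected: dict[str, cisqtl.CisMapResult]
    results_reduced: dict[str, cisqtl.CisMapResult] | None
    summary: dict


def _prepare_population_datasets(
    study: SyntheticStudy, config: RunConfig
) -> tuple[dict[str, ExpressionMatrix], dict[str, ExpressionMatrix] | None]:
    """Normalize, stratification-correct admixed populations, and (optionally)
    fit factor residuals per population."""
    normalized = preprocess.normalize(study.expression)
    admixed = {p.name for p in study.config.pops if p.admixture_props is not None}
    corrected: dict[str, ExpressionMatrix] = {}
    reduced: dict[str, ExpressionMatrix] | None = {} if config.run_reduced else None
    for pop in study.genotypes:
        sub = normalized.subset_population(pop)
        if pop in admixed:
            pcs = preprocess.genotype_pca(
                study.genotypes[pop], n_axes=10, min_maf=config.maf,
                max_missing=config.missingness,
            )
            sub = preprocess.residualize_covariates(sub, pcs)
        corrected[pop] = sub
        if config.run_reduced:
            fm = preprocess.fit_factor_residuals(
                sub, preprocess.FactorModelConfig(n_hidden=config.n_hidden)
            )
            reduced[pop] = fm.residuals
    return corrected, reduced


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis on a synthetic study: simulate ->
    normalize -> stratification-correct -> REDUCE -> cis-map both datasets
    -> stepwise -> V_ST -> F_ST tree -> sharing statistics. All outputs are
    TSVs under ``config.out_dir`` with seed + config provenance headers."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "n_perms": config.n_perms,
            "window": config.window, "maf": config.maf, "miss": config.missingness}
    summary: dict = {"per_stage": {}}

    stage = "simulate"
    try:
        study = simulate_study(config.study, seed=config.seed)
        annot = preprocess.select_probes(study.annotation)
        write_annotation(annot, out / "annotation.tsv", prov)
        write_table(study.truth.as_frame(), out / "truth.tsv", prov, index=False)
        for pop, gm in study.genotypes.items():
            write_vcf(gm, out / f"genotypes_{pop}.vcf")
        write_expression(study.expression, out / "expression_raw.tsv", prov)
        summary["per_stage"]["simulate"] = {
            "n_snps": study.config.n_snps, "n_probes": study.config.n_probes,
            "n_planted": len(study.truth.planted_eqtls),
        }

        stage = "preprocess"
        genotypes = sharing_mod.harmonize_alleles(study.genotypes)
        corrected, reduced = _prepare_population_datasets(study, config)
        summary["per_stage"]["preprocess"] = {
            "probes_eligible": int(annot["eligible"].sum()),
        }

        stage = "map-cis"
        results_c: dict[str, cisqtl.CisMapResult] = {}
        results_r: dict[str, cisqtl.CisMapResult] | None = {} if config.run_reduced else None
        for i, pop in enumerate(sorted(genotypes)):
            res = cisqtl.map_cis(
                corrected[pop], genotypes[pop], annot, alphas=config.alphas,
                n_perms=config.n_perms, window=config.window, min_maf=config.maf,
                max_missing=config.missingness, seed=config.seed + 1000 + i,
            )
            results_c[pop] = res
            write_table(res.associations, out / f"assoc_corrected_{pop}.tsv", prov, index=False)
            write_table(res.best, out / f"best_corrected_{pop}.tsv", prov, index=False)
            if config.run_reduced:
                res_r = cisqtl.map_cis(
                    reduced[pop], genotypes[pop], annot, alphas=config.alphas,
                    n_perms=config.n_perms, window=config.window, min_maf=config.maf,
                    max_missing=config.missingness, seed=config.seed + 2000 + i,
                )
                results_r[pop] = res_r
                write_table(res_r.best, out / f"best_reduced_{pop}.tsv", prov, index=False)

        # Tables 1/2-style side-by-side report of counts and FDRs
        table_rows = []
        for pop in sorted(results_c):
            row = {"population": pop}
            for label, results in (("corrected", results_c), ("reduced", results_r or {})):
                if pop not in results:
                    continue
                res = results[pop]
                for a in config.alphas:
                    n_sig = int(res.best[f"significant_{a}"].sum())
                    row[f"{label}_sig_{a}"] = n_sig
                    row[f"{label}_fdr_{a}"] = cisqtl.fdr_expected(res.n_genes_tested, a, n_sig)
            table_rows.append(row)
        fdr_table = pd.DataFrame(table_rows)
        write_table(fdr_table, out / "significant_genes_fdr.tsv", prov, index=False)
        summary["per_stage"]["map-cis"] = fdr_table.to_dict("records")

        stage = "stepwise"
        if config.run_stepwise:
            step_rows = []
            for pop, res in results_c.items():
                for sr in cisqtl.stepwise_all(res, corrected[pop], genotypes[pop],
                                              alpha=config.alphas[0]):
                    for snp_id, step, p in sr.independent_snps:
                        step_rows.append((pop, sr.gene_id, step, snp_id, p))
            step_df = pd.DataFrame(step_rows, columns=["population", "gene_id", "step",
                                                       "snp_id", "p"])
            write_table(step_df, out / "stepwise.tsv", prov, index=False)
            multi = step_df.groupby(["population", "gene_id"]).size()
            summary["per_stage"]["stepwise"] = {
                "genes_with_multiple_effects": int((multi >= 2).sum())
            }

        stage = "vst"
        if config.run_vst:
            normalized = preprocess.normalize(study.expression)
            vst_table, vst_summary = popdiff.vst_scan(normalized)
            write_table(vst_table, out / "vst.tsv", prov, index=False)
            write_table(vst_summary, out / "vst_summary.tsv", prov, index=False)
            summary["per_stage"]["vst"] = {"pairs": len(vst_summary)}

        stage = "sharing"
        if config.run_sharing:
            alpha0 = config.alphas[0]
            sig_sets = cisqtl.significant_gene_sets(results_c, alpha0)
            summ = sharing_mod.sharing_matrix(sig_sets)
            write_table(summ.pair_counts, out / "sharing_pairs.tsv", prov)
            write_table(summ.histogram.to_frame(), out / "sharing_histogram.tsv", prov)
            fst_mat = popdiff.fst_distance_matrix(genotypes, window=config.fst_window)
            write_table(fst_mat, out / "fst_matrix.tsv", prov)
            tree = sharing_mod.build_population_tree(fst_mat)
            tree.write(str(out / "population_tree.nwk"))
            summary["per_stage"]["sharing"] = {
                "nonredundant": summ.n_nonredundant,
                "pct_ge2": summ.pct_ge2, "pct_all": summ.pct_all,
            }

        summary["seed"] = config.seed
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
    except Exception:
        logger.error("pipeline aborted at stage %r; partial outputs in %s", stage, out)
        raise
    return PipelineResult(
        out_dir=out, study=study, results_corrected=results_c,
        results_reduced=results_r, summary=summary,
    )
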