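"""End-to-end orchestration of the purity-aware comparison.

One configuration drives the whole analysis: cohort ingest (or synthesis),
stromal/immune scoring, global structure, differential expression with the
purity filter, gene-set enrichment with purity attribution and, when genomic
inputs are present, the frequency summaries. Every stage writes its table
under the output directory and logs its in/out gene counts; a manifest
records the configuration so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, builtin_signatures, generate_cohort
from .de import build_de_table, purity_filter, top_fraction
from .errors import InvalidConfigError, StageError
from .genomics import fraction_genome_altered, mutation_binomial_tests, read_segments
from .gmt import read_gmt, write_gmt
from .gsea import GeneSet, enrichment_analysis, results_table
from .ingest import (
    ExpressionMatrix,
    log_transform,
    merge_datasets,
    read_annotations,
    read_expression,
    to_tpm,
    write_annotations,
    write_expression,
)
from .purity import GeneSignature, estimate_scores, gene_purity_correlation
from .structure import (
    average_cell_line,
    correlate_pc_with_scores,
    correlation_cluster,
    rank_cell_lines,
    run_pca,
    select_top_variance_genes,
    to_newick,
)

log = logging.getLogger("purecell.pipeline")

#: Number of genes per truth block used for the synthetic-mode enrichment
#: sets; kept below the "fewer than 200 members" set-size rule.
SYNTHETIC_SET_SIZE = 150


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one analysis run.

    Threshold defaults are the analysis' canonical values: top 5000 variance
    genes, top 1 % of the DE ranking, purity filter at |r| > 0.2, reporting
    threshold r > 0.5, gene sets of < 200 members, set call cutoff
    q < 0.0001, enrichment-score exponent 0.25.
    """

    mode: str = "synthetic"                    # "synthetic" | "files"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    files: dict = field(default_factory=dict)  # files mode: paths, see run_pipeline
    top_k_genes: int = 5000
    de_fraction: float = 0.01
    purity_tau: float = 0.2
    report_r: float = 0.5
    set_max_size: int = 200
    set_q_cutoff: float = 1e-4
    member_alpha: float = 0.05
    ssgsea_exponent: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic":
            self.cohort.validate()
        elif "expression" not in self.files:
            raise InvalidConfigError("files mode requires an 'expression' input")
        if not 0 < self.de_fraction <= 1:
            raise InvalidConfigError("de_fraction must be in (0, 1]")
        if not 0 <= self.purity_tau <= 1:
            raise InvalidConfigError("purity_tau must be in [0, 1]")
        if self.top_k_genes < 1 or self.set_max_size < 2:
            raise InvalidConfigError("top_k_genes >= 1 and set_max_size >= 2 required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        for key, value in list(d["cohort"].items()):
            if isinstance(value, tuple):
                d["cohort"][key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        for key, value in list(cohort.items()):
            if isinstance(value, list):
                cohort[key] = tuple(value)
        return cls(cohort=CohortConfig(**cohort), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _load_files_inputs(files: dict) -> tuple:
    """Read the files-mode inputs and harmonise to one log2(TPM+1) matrix."""
    annotations = read_annotations(files["annotations"])
    specs = files["expression"]
    if isinstance(specs, (str, Path)):
        specs = [{"path": specs, "scale": files.get("scale", "tpm")}]
    matrices = []
    for spec in specs:
        m = read_expression(spec["path"], spec.get("scale", "tpm"))
        m = ExpressionMatrix(m.values, m.scale, annotations.loc[m.sample_ids])
        if m.scale != "log2_tpm_plus1":
            m = log_transform(to_tpm(m, strict=files.get("strict", True)))
        matrices.append(m)
    merged = matrices[0]
    for other in matrices[1:]:
        merged = merge_datasets(merged, other)
    sigs = read_gmt(files["signatures"])
    if len(sigs) < 2:
        raise InvalidConfigError("signature GMT must contain stromal and immune sets")
    stromal = GeneSignature(sigs[0].set_id, sigs[0].genes)
    immune = GeneSignature(sigs[1].set_id, sigs[1].genes)
    gene_sets = read_gmt(files["gene_sets"]) if "gene_sets" in files else []
    return merged, stromal, immune, gene_sets


def _synthetic_gene_sets(truth) -> list:
    """Mechanism-block gene sets for the synthetic enrichment contrast."""
    sets = []
    for mechanism, name in [
        ("stromal", "stromal program"),
        ("immune", "immune program"),
        ("culture_up", "culture-induced program"),
        ("culture_down", "culture-repressed program"),
    ]:
        genes = truth.genes_with_mechanism(mechanism)[:SYNTHETIC_SET_SIZE]
        if len(genes) >= 2:
            sets.append(GeneSet(set_id=mechanism, name=name, genes=tuple(genes)))
    return sets


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write the report bundle into ``out_dir``.

    Returns the manifest (also written as manifest.yaml). On stage failure
    the partially written bundle is removed and a StageError is raised.
    """
    config.validate()
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    manifest = {"package_version": __version__, "config": config.to_dict(), "stages": {}}

    def record(name, **counts):
        manifest["stages"][name] = counts
        log.info("stage %s: %s", name, counts)

    try:
        stage = "ingest"
        truth = None
        if config.mode == "synthetic":
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            matrix_tpm, truth = generate_cohort(cohort_cfg)
            stromal_sig, immune_sig = builtin_signatures(truth)
            gene_sets = _synthetic_gene_sets(truth)
            write_expression(matrix_tpm, out / "expression_tpm.tsv")
            write_annotations(matrix_tpm.annotations, out / "annotations.tsv")
            truth.write(out)
            write_gmt([stromal_sig, immune_sig], out / "signatures.gmt")
            if gene_sets:
                write_gmt(gene_sets, out / "gene_sets.gmt")
            matrix = log_transform(matrix_tpm)
        else:
            matrix, stromal_sig, immune_sig, gene_sets = _load_files_inputs(config.files)
        record("ingest", genes=int(matrix.values.shape[0]),
               samples=int(matrix.values.shape[1]))

        stage = "purity"
        tumours = matrix.tumour_ids()
        tumour_matrix = matrix.subset_samples(tumours)
        scores = estimate_scores(tumour_matrix, stromal_sig, immune_sig,
                                 config.ssgsea_exponent)
        scores.write(out / "purity_scores.tsv")
        corr = gene_purity_correlation(tumour_matrix, scores)
        corr.to_csv(out / "purity_correlations.tsv", sep="\t",
                    float_format="%.10g", index_label="gene_id")
        record("purity", tumours=len(tumours), genes=int(corr.shape[0]))

        stage = "structure"
        k = min(config.top_k_genes, matrix.values.shape[0])
        selected = select_top_variance_genes(matrix, k)
        sub = ExpressionMatrix(matrix.values.loc[selected], matrix.scale,
                               matrix.annotations)
        pca = run_pca(sub)
        pca.sample_scores.to_csv(out / "pca_scores.tsv", sep="\t",
                                 float_format="%.10g", index_label="sample_id")
        pd.DataFrame(
            {"variance_explained": pca.variance_explained},
            index=pca.sample_scores.columns[: len(pca.variance_explained)],
        ).to_csv(out / "pca_variance.tsv", sep="\t", float_format="%.10g",
                 index_label="component")
        r_stromal, r_immune = correlate_pc_with_scores(pca, tumours, scores)
        cluster = correlation_cluster(sub)
        (out / "dendrogram.nwk").write_text(to_newick(cluster) + "\n")
        ranking = rank_cell_lines(sub)
        ranking.to_csv(out / "cell_line_ranking.tsv", sep="\t",
                       float_format="%.10g", index=False)
        averages = []
        for subtype in sorted(ranking["comparison_subtype"].unique()):
            n_lines = (ranking["comparison_subtype"] == subtype).sum()
            if n_lines >= 2:
                _, mean_r = average_cell_line(sub, subtype)
                averages.append({"comparison_subtype": subtype,
                                 "mean_correlation": mean_r})
        pd.DataFrame(averages).to_csv(out / "average_cell_line.tsv", sep="\t",
                                      float_format="%.10g", index=False)
        record("structure", genes_selected=k,
               pc1_stromal_r=float(r_stromal), pc1_immune_r=float(r_immune))

        stage = "de"
        de = build_de_table(matrix, corr, tau=config.purity_tau,
                            report_r=config.report_r)
        de.to_csv(out / "de_table.tsv", sep="\t", float_format="%.10g",
                  index_label="gene_id")
        top_unfiltered = top_fraction(de, config.de_fraction)
        (out / "top_genes_unfiltered.txt").write_text("\n".join(top_unfiltered) + "\n")
        filtered, removed = purity_filter(de, config.purity_tau)
        (out / "removed_genes.txt").write_text("\n".join(removed) + "\n")
        filtered.to_csv(out / "de_table_filtered.tsv", sep="\t",
                        float_format="%.10g", index_label="gene_id")
        top_filtered = top_fraction(filtered, config.de_fraction)
        (out / "top_genes_filtered.txt").write_text("\n".join(top_filtered) + "\n")
        record("de", genes_in=int(de.shape[0]), top=len(top_unfiltered),
               removed_by_filter=len(removed), genes_after_filter=int(filtered.shape[0]),
               top_after_filter=len(top_filtered))

        stage = "gsea"
        if gene_sets:
            results = enrichment_analysis(de, gene_sets, corr,
                                          max_size=config.set_max_size,
                                          member_alpha=config.member_alpha)
            table = results_table(results)
            table["significant"] = table["q_value"] < config.set_q_cutoff
            table.to_csv(out / "gene_set_results.tsv", sep="\t",
                         float_format="%.10g", index=False)
            record("gsea", sets_in=len(gene_sets), sets_tested=len(results),
                   sets_significant=int(table["significant"].sum()))
        else:
            record("gsea", sets_in=0, sets_tested=0, sets_significant=0)

        stage = "genomics"
        files = config.files if config.mode == "files" else {}
        if "mutations" in files:
            summary = pd.read_csv(files["mutations"], sep="\t", index_col=0)
            tested = mutation_binomial_tests(summary)
            tested.to_csv(out / "mutation_tests.tsv", sep="\t",
                          float_format="%.10g", index_label="gene")
            record("genomics", genes_tested=int(tested.shape[0]))
        if "segments" in files:
            seg = read_segments(files["segments"])
            fga = fraction_genome_altered(seg)
            (out / "fraction_genome_altered.txt").write_text(f"{fga:.10g}\n")
            manifest["stages"].setdefault("genomics", {})["fraction_genome_altered"] = fga

        stage = "manifest"
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        return manifest
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for child in out.iterdir():
                if child.is_file():
                    child.unlink()
        raise StageError(stage, exc) from exc
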