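"""Synthetic tumour/cell-line cohorts with ground truth.

The generator emulates the statistical structure that the purity-aware
comparison assumes: bulk tumours are purity-weighted mixtures of a malignant
profile (one per subtype), a stromal profile and an immune profile; cell lines
are pure malignant profiles carrying multiplicative culture-adaptation fold
changes on designated gene blocks. Stromal- and immune-signature genes are
compartment-specific: elevated by the effect factor in their own compartment
and attenuated by the same factor in the other compartments, so that — as in
real bulk cohorts — their expression in monoculture is low and their tumour
expression tracks the non-malignant fraction. Multiplicative log-normal noise
is applied on the log2 scale and every sample is renormalised to TPM.

Ground truth (per-gene mechanism labels, per-tumour component fractions,
noise-free component profiles) is returned alongside the matrix so every
downstream stage can be validated without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .ingest import TPM_SUM, ExpressionMatrix, make_annotations
from .purity import GeneSignature

MECHANISMS = ("stromal", "immune", "culture_up", "culture_down", "null")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the reference study conditions used throughout the analysis
    and the test suite: 200 tumours, 50 cell lines, 2000 genes, 10 % stromal
    and immune blocks at 8-fold compartment effects, 5 % culture-up and
    culture-down blocks at 4-fold effects, malignant fraction ~ Beta(5, 2),
    and log2-scale Gaussian noise with sd 0.3.
    """

    n_tumours: int = 200
    n_cell_lines: int = 50
    n_genes: int = 2000
    subtype_labels: tuple = ("luminal", "basal")
    tumour_subtype_proportions: tuple = (0.5, 0.5)
    cell_line_subtype_proportions: tuple = (0.5, 0.5)
    frac_stromal_genes: float = 0.10
    frac_immune_genes: float = 0.10
    frac_culture_up: float = 0.05
    frac_culture_down: float = 0.05
    stromal_effect: float = 8.0
    immune_effect: float = 8.0
    culture_effect: float = 4.0
    purity_alpha: float = 5.0
    purity_beta: float = 2.0
    stromal_immune_split: float = 0.5
    split_jitter: float = 0.05
    frac_subtype_genes: float = 0.10
    subtype_effect: float = 4.0
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tumours, self.n_cell_lines, self.n_genes) < 1:
            raise InvalidConfigError("all counts must be >= 1")
        fracs = (
            self.frac_stromal_genes,
            self.frac_immune_genes,
            self.frac_culture_up,
            self.frac_culture_down,
        )
        if any(f < 0 for f in fracs) or not 0 <= self.frac_subtype_genes <= 1:
            raise InvalidConfigError("gene fractions must be nonnegative")
        if sum(fracs) > 1:
            raise InvalidConfigError(
                f"mechanism gene fractions sum to {sum(fracs):.3f} > 1"
            )
        for name in ("stromal_effect", "immune_effect", "culture_effect", "subtype_effect"):
            if getattr(self, name) <= 1:
                raise InvalidConfigError(f"{name} must be > 1")
        if len(self.subtype_labels) != len(set(self.subtype_labels)):
            raise InvalidConfigError("duplicate subtype labels")
        for props in (self.tumour_subtype_proportions, self.cell_line_subtype_proportions):
            if len(props) != len(self.subtype_labels):
                raise InvalidConfigError("subtype proportions must match subtype labels")
            if any(p < 0 for p in props) or abs(sum(props) - 1) > 1e-9:
                raise InvalidConfigError("subtype proportions must be a simplex vector")
        if math.isfinite(self.purity_alpha) and self.purity_alpha <= 0:
            raise InvalidConfigError("purity_alpha must be positive")
        if self.purity_beta <= 0:
            raise InvalidConfigError("purity_beta must be positive")
        if not 0 <= self.stromal_immune_split <= 1:
            raise InvalidConfigError("stromal_immune_split must be in [0, 1]")
        if self.noise_sd < 0 or self.split_jitter < 0:
            raise InvalidConfigError("noise_sd and split_jitter must be >= 0")
        counts = self.block_counts()
        for name, c in counts.items():
            frac = getattr(self, f"frac_{name}" if name.startswith("culture") else f"frac_{name}_genes")
            if frac > 0 and c == 0:
                raise InvalidConfigError(
                    f"n_genes={self.n_genes} too small to allocate a '{name}' block"
                )
        if sum(counts.values()) > self.n_genes:
            raise InvalidConfigError("mechanism blocks exceed the gene count")

    def block_counts(self) -> dict:
        return {
            "stromal": int(round(self.frac_stromal_genes * self.n_genes)),
            "immune": int(round(self.frac_immune_genes * self.n_genes)),
            "culture_up": int(round(self.frac_culture_up * self.n_genes)),
            "culture_down": int(round(self.frac_culture_down * self.n_genes)),
        }


@dataclass
class SyntheticTruth:
    """Latent quantities behind a generated cohort.

    gene_mechanism: per-gene label in {stromal, immune, culture_up,
        culture_down, null}.
    subtype_marker: per-gene subtype whose malignant profile over-expresses
        the gene ("none" for non-discriminating genes).
    sample_fractions: per-sample (malignant, stromal, immune) fractions,
        summing to 1; cell lines have malignant fraction 1.
    subtype_of_sample: per-sample subtype label.
    component_profiles: noise-free linear-scale profiles — one malignant
        column per subtype plus the shared stromal and immune columns.
    """

    gene_mechanism: pd.Series
    subtype_marker: pd.Series
    sample_fractions: pd.DataFrame
    subtype_of_sample: pd.Series
    component_profiles: pd.DataFrame

    def genes_with_mechanism(self, mechanism: str) -> list:
        if mechanism not in MECHANISMS:
            raise InvalidInputError(f"unknown mechanism {mechanism!r}")
        return list(self.gene_mechanism.index[self.gene_mechanism == mechanism])

    @property
    def tumour_fractions(self) -> pd.DataFrame:
        """Fractions restricted to tumour samples (malignant fraction < 1 a.s.)."""
        return self.sample_fractions[self.sample_fractions.index.str.startswith("TUM")]

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        genes = pd.DataFrame(
            {"mechanism": self.gene_mechanism, "subtype_marker": self.subtype_marker}
        )
        genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index_label="gene_id")
        samples = self.sample_fractions.copy()
        samples["subtype"] = self.subtype_of_sample
        samples.to_csv(out_dir / "truth_samples.tsv", sep="\t",
                       float_format="%.10g", index_label="sample_id")


def _assign_blocks(config: CohortConfig) -> tuple:
    counts = config.block_counts()
    labels = np.full(config.n_genes, "null", dtype=object)
    start = 0
    blocks = {}
    for name in ("stromal", "immune", "culture_up", "culture_down"):
        c = counts[name]
        blocks[name] = np.arange(start, start + c)
        labels[start:start + c] = name
        start += c
    n_sub = int(round(config.frac_subtype_genes * config.n_genes))
    null_idx = np.arange(start, config.n_genes)
    if n_sub > len(null_idx):
        raise InvalidConfigError("not enough null genes for the subtype-marker block")
    sub_idx = null_idx[:n_sub]
    return labels, blocks, sub_idx


def generate_cohort(config: CohortConfig) -> tuple:
    """Draw one cohort; returns (ExpressionMatrix on TPM scale, SyntheticTruth).

    All randomness flows through a single numpy Generator seeded with
    ``config.seed``; identical configurations therefore give byte-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(G)], name="gene_id")
    labels, blocks, sub_idx = _assign_blocks(config)

    base = np.exp2(rng.normal(config.base_log2_mean, config.base_log2_sd, G))

    subtype_marker = np.full(G, "none", dtype=object)
    n_labels = len(config.subtype_labels)
    marker_of = {s: sub_idx[i::n_labels] for i, s in enumerate(config.subtype_labels)}
    for s, idx in marker_of.items():
        subtype_marker[idx] = s

    # Compartment-restricted transcripts sit below the global average at
    # baseline: lowering each signature/marker block by its own fold change
    # keeps every compartment's total mRNA output balanced, so mixing does
    # not shift the relative abundance of unrelated genes (no compositional
    # artifact coupling null genes to purity).
    base[blocks["stromal"]] /= config.stromal_effect
    base[blocks["immune"]] /= config.immune_effect
    base[sub_idx] /= config.subtype_effect

    # Malignant profiles: subtype markers elevated in their subtype; the
    # stromal/immune signature blocks are expressed predominantly by their own
    # compartment, hence attenuated here.
    # Each component profile is itself TPM-normalised before mixing, so the
    # mixing weights are mRNA fractions and adding non-malignant mass does not
    # inflate a tumour's library size (no compositional artifact on null genes).
    def _normalise(prof):
        return prof / prof.sum() * TPM_SUM

    malignant = {}
    for s in config.subtype_labels:
        prof = base.copy()
        prof[marker_of[s]] *= config.subtype_effect
        prof[blocks["stromal"]] /= config.stromal_effect
        prof[blocks["immune"]] /= config.immune_effect
        malignant[s] = _normalise(prof)
    stromal = base.copy()
    stromal[blocks["stromal"]] *= config.stromal_effect
    stromal[blocks["immune"]] /= config.immune_effect
    stromal = _normalise(stromal)
    immune = base.copy()
    immune[blocks["immune"]] *= config.immune_effect
    immune[blocks["stromal"]] /= config.stromal_effect
    immune = _normalise(immune)

    tumour_ids = [f"TUM{i:04d}" for i in range(config.n_tumours)]
    cl_ids = [f"CL{i:03d}" for i in range(config.n_cell_lines)]
    t_sub = rng.choice(config.subtype_labels, config.n_tumours,
                       p=config.tumour_subtype_proportions)
    c_sub = rng.choice(config.subtype_labels, config.n_cell_lines,
                       p=config.cell_line_subtype_proportions)

    if math.isfinite(config.purity_alpha):
        purity = rng.beta(config.purity_alpha, config.purity_beta, config.n_tumours)
    else:
        purity = np.ones(config.n_tumours)
    split = np.clip(
        config.stromal_immune_split
        + rng.normal(0.0, config.split_jitter, config.n_tumours),
        0.0, 1.0,
    )
    f_str = (1 - purity) * split
    f_imm = (1 - purity) * (1 - split)

    cols = np.empty((G, config.n_tumours + config.n_cell_lines))
    for t in range(config.n_tumours):
        cols[:, t] = (
            purity[t] * malignant[t_sub[t]] + f_str[t] * stromal + f_imm[t] * immune
        )
    for c in range(config.n_cell_lines):
        prof = malignant[c_sub[c]].copy()
        prof[blocks["culture_up"]] *= config.culture_effect
        prof[blocks["culture_down"]] /= config.culture_effect
        cols[:, config.n_tumours + c] = prof

    if config.noise_sd > 0:
        cols = np.exp2(np.log2(cols) + rng.normal(0.0, config.noise_sd, cols.shape))
    cols = cols / cols.sum(axis=0) * TPM_SUM

    sample_ids = tumour_ids + cl_ids
    sample_subtype = np.concatenate([t_sub, c_sub])
    er_of = {config.subtype_labels[0]: "positive"}
    annotations = make_annotations(
        sample_ids,
        ["tumour"] * config.n_tumours + ["cell_line"] * config.n_cell_lines,
        [er_of.get(s, "negative") for s in sample_subtype],
        list(sample_subtype),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=gene_ids, columns=sample_ids), "tpm", annotations
    )

    fractions = pd.DataFrame(
        {
            "malignant": np.concatenate([purity, np.ones(config.n_cell_lines)]),
            "stromal": np.concatenate([f_str, np.zeros(config.n_cell_lines)]),
            "immune": np.concatenate([f_imm, np.zeros(config.n_cell_lines)]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    profiles = pd.DataFrame(
        {f"malignant_{s}": malignant[s] for s in config.subtype_labels}
        | {"stromal": stromal, "immune": immune},
        index=gene_ids,
    )
    truth = SyntheticTruth(
        gene_mechanism=pd.Series(labels, index=gene_ids, name="mechanism"),
        subtype_marker=pd.Series(subtype_marker, index=gene_ids, name="subtype_marker"),
        sample_fractions=fractions,
        subtype_of_sample=pd.Series(sample_subtype, index=fractions.index, name="subtype"),
        component_profiles=profiles,
    )
    return matrix, truth


def builtin_signatures(truth: SyntheticTruth) -> tuple:
    """Stromal and immune signatures read off the truth's gene blocks.

    These play the role that published stromal/immune signature lists play on
    real cohorts: disjoint marker lists for single-sample enrichment scoring.
    """
    stromal = truth.genes_with_mechanism("stromal")
    immune = truth.genes_with_mechanism("immune")
    if not stromal or not immune:
        raise InvalidInputError("cohort has an empty stromal or immune gene block")
    return (
        GeneSignature("stromal_signature", tuple(stromal)),
        GeneSignature("immune_signature", tuple(immune)),
    )
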