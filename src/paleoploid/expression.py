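"""Subgenome grouping and homoeolog expression-bias classification.

After two rounds of genome doubling, each reference chromosome corresponds
to four homoeologous column tracks in the polyploid descendant; these are
labelled A1-A4 per reference chromosome by descending retained-gene count.
Expression bias between duplicated copies is classified with the usual
differential-expression thresholds: a copy is "higher"/"lower" than its
partner when |log2 fold change| of mean FPKM exceeds the cutoff AND a
Welch t-test on log-transformed replicate values survives Benjamini-
Hochberg adjustment; everything else is "no significant difference".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fractionation import HomologyTable, MISSING
from .io import ExpressionMatrix

logger = logging.getLogger("paleoploid")

CATEGORIES = ("higher", "lower", "no-difference")


@dataclass
class SubgenomeAssignment:
    """Per reference chromosome: column indices labelled A1..A4."""

    labels: dict[str, dict[str, int]]  # ref chromosome -> label -> column index
    zero_coverage: list[tuple[str, str]] = field(default_factory=list)

    def column_of(self, chromosome: str, label: str) -> int:
        return self.labels[chromosome][label]


@dataclass
class BiasClassification:
    table: pd.DataFrame  # pair, condition, log2fc, p_adj, category
    skipped_pairs: int = 0

    def fractions(self) -> dict[str, float]:
        n = len(self.table)
        if n == 0:
            return {c: float("nan") for c in CATEGORIES}
        counts = self.table["category"].value_counts()
        return {c: counts.get(c, 0) / n for c in CATEGORIES}


def assign_subgenomes(table: HomologyTable, genome: str) -> SubgenomeAssignment:
    """Label the four homoeologous column tracks A1-A4 per reference
    chromosome by descending retained-gene count (ties broken by column
    index, which is deterministic)."""
    cols = table.cells(genome)
    if len(cols) != 4:
        raise ValueError(
            f"subgenome grouping expects multiplicity 4, got {len(cols)}")
    assignment: dict[str, dict[str, int]] = {}
    zero: list[tuple[str, str]] = []
    # group rows per reference chromosome
    row_chrom = [g.chromosome for g in table.rows]
    for chrom in dict.fromkeys(row_chrom):
        idx = [i for i, c in enumerate(row_chrom) if c == chrom]
        retained = [
            (sum(1 for i in idx if cols[ci][i] != MISSING), ci)
            for ci in range(4)
        ]
        ordered = sorted(retained, key=lambda t: (-t[0], t[1]))
        labels = {}
        for rank, (count, ci) in enumerate(ordered, 1):
            lab = f"A{rank}"
            labels[lab] = ci
            if count == 0:
                zero.append((chrom, lab))
        assignment[chrom] = labels
    if zero:
        logger.info("subgenomes: %d zero-coverage tracks flagged", len(zero))
    return SubgenomeAssignment(labels=assignment, zero_coverage=zero)


def classify_bias(expr: ExpressionMatrix,
                  duplicate_pairs: Iterable[tuple[str, str]],
                  fc_threshold: float = 1.0, alpha: float = 0.05,
                  pseudocount: float = 1.0,
                  conditions: Iterable[str] | None = None
                  ) -> BiasClassification:
    """Classify each duplicate pair, per condition, as higher / lower /
    no-difference for the first gene relative to the second.

    log2 fold change is computed on mean FPKM + pseudocount; significance by
    Welch's t on log2(FPKM + pseudocount) replicate values, BH-adjusted over
    all (pair, condition) tests.
    """
    conds = list(conditions) if conditions is not None else list(expr.groups)
    vals = expr.values
    rows = []
    skipped = 0
    for ga, gb in duplicate_pairs:
        if ga not in vals.index or gb not in vals.index:
            skipped += 1
            continue
        for cond in conds:
            cols = expr.groups[cond]
            if len(cols) < 2:
                skipped += 1
                continue
            xa = np.log2(vals.loc[ga, cols].to_numpy(dtype=float) + pseudocount)
            xb = np.log2(vals.loc[gb, cols].to_numpy(dtype=float) + pseudocount)
            log2fc = float(xa.mean() - xb.mean())
            if np.allclose(xa, xb):
                p = 1.0
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
                if np.isnan(p):
                    p = 1.0
            rows.append((ga, gb, cond, log2fc, p))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "condition",
                                     "log2fc", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = pd.Series(dtype=float)
    cat = np.where(
        (df["log2fc"].abs() > fc_threshold) & (df["p_adj"] < alpha),
        np.where(df["log2fc"] > 0, "higher", "lower"),
        "no-difference",
    )
    df["category"] = cat
    df = df.drop(columns=["p"])
    if skipped:
        logger.info("bias classification skipped %d pair/conditions", skipped)
    return BiasClassification(table=df, skipped_pairs=skipped)


def subgenome_pairs(table: HomologyTable, genome: str,
                    assignment: SubgenomeAssignment,
                    sub_a: str, sub_b: str) -> list[tuple[str, str]]:
    """Duplicate pairs retained in both of two subgenome tracks."""
    cols = table.cells(genome)
    pairs = []
    for ri, gene in enumerate(table.rows):
        labels = assignment.labels[gene.chromosome]
        a = cols[labels[sub_a]][ri]
        b = cols[labels[sub_b]][ri]
        if a != MISSING and b != MISSING:
            pairs.append((a, b))
    return pairs


def write_bias_report(bias: BiasClassification, path) -> None:
    bias.table.to_csv(path, sep="\t", index=False)
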