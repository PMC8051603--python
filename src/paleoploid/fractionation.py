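"""Reference-anchored homology table and genome-fractionation statistics.

The table lists every reference gene as a row, with per-genome groups of
homology columns whose count is that genome's expected collinear multiplicity
(a genome separated from the reference only by the eudicot triplication gets
3 columns against a single-copy reference; one that went through two further
doublings gets 4; and so on).  Cells hold the collinear partner gene id or a
dot for a missing (lost or translocated) gene.  From the table come the loss
rate (dot fraction), per-gene homology depth, the fraction of best-hit genes
that sit outside any collinear location, the distribution of consecutive-dot
run lengths, and a geometric-model fit to that distribution whose extension
parameter measures how far a gene-removal event tends to extend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .collinearity import CollinearBlock
from .io import MISSING, GeneSet, HomologPair

logger = logging.getLogger("paleoploid")


@dataclass
class HomologyTable:
    reference: str
    rows: list  # GeneLocus, chromosome-then-rank order
    columns: dict[str, list[list[str]]]  # genome -> [column][row] cell
    multiplicities: dict[str, int]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, genome: str, index: int) -> list[str]:
        return self.columns[genome][index]

    def cells(self, genome: str) -> list[list[str]]:
        if genome not in self.columns:
            raise KeyError(f"genome {genome!r} not in table")
        return self.columns[genome]


@dataclass
class RunHistogram:
    """Lengths of maximal dot runs strictly bordered by retained genes."""

    counts: dict[int, int]
    end_runs: int = 0

    @property
    def n_runs(self) -> int:
        return sum(self.counts.values())

    @property
    def genes_in_runs(self) -> int:
        return sum(length * n for length, n in self.counts.items())

    @property
    def short_run_gene_fraction(self) -> float:
        total = self.genes_in_runs
        if total == 0:
            return float("nan")
        short = sum(length * n for length, n in self.counts.items() if length <= 2)
        return short / total

    @property
    def short_run_fraction(self) -> float:
        """Fraction of runs (not genes) of length <= 2."""
        if self.n_runs == 0:
            return float("nan")
        return sum(n for length, n in self.counts.items() if length <= 2) / self.n_runs

    def lengths(self) -> list[int]:
        out = []
        for length in sorted(self.counts):
            out.extend([length] * self.counts[length])
        return out


@dataclass
class GeometricFit:
    """MLE fit of P(L=k) = (1-p) p^(k-1), k >= 1, to run lengths.

    p is the extension parameter: the probability that a deletion run extends
    by one more gene.
    """

    p: float
    mean_length: float
    log_likelihood: float
    n_runs: int


def build_homology_table(reference: GeneSet,
                         blocks_per_genome: Mapping[str, Sequence[CollinearBlock]],
                         multiplicities: Mapping[str, int]) -> HomologyTable:
    """Assemble the table from per-genome collinear blocks vs the reference.

    All anchors of one block occupy one column (column identity is consistent
    along a block); blocks are placed by descending anchor count into the
    first column where they do not collide; overflow beyond the genome's
    multiplicity is dropped and logged.
    """
    rows = [g for chrom in reference.chromosomes for g in reference.loci(chrom)]
    row_index = {g.gene_id: i for i, g in enumerate(rows)}
    columns: dict[str, list[list[str]]] = {}
    for genome, blocks in blocks_per_genome.items():
        mult = multiplicities.get(genome, 1)
        if mult < 1:
            raise ValueError(f"multiplicity for {genome!r} must be >= 1")
        cols = [[MISSING] * len(rows) for _ in range(mult)]
        seen_target: list[set[str]] = [set() for _ in range(mult)]
        n_overflow = 0
        for block in sorted(blocks, key=lambda b: (-len(b.anchors), b.block_id)):
            ref_on_a = block.genome_a == reference.genome
            cells = []
            for a in block.anchors:
                ref_gene = a.gene_a if ref_on_a else a.gene_b
                tgt_gene = a.gene_b if ref_on_a else a.gene_a
                if ref_gene not in row_index:
                    raise ValueError(
                        f"block references unknown reference gene {ref_gene!r}")
                cells.append((row_index[ref_gene], tgt_gene))
            placed = False
            for ci in range(mult):
                if all(cols[ci][ri] == MISSING and tg not in seen_target[ci]
                       for ri, tg in cells):
                    for ri, tg in cells:
                        cols[ci][ri] = tg
                        seen_target[ci].add(tg)
                    placed = True
                    break
            if not placed:
                n_overflow += 1
        if n_overflow:
            logger.info("homology table: %d %s blocks beyond multiplicity %d dropped",
                        n_overflow, genome, mult)
        columns[genome] = cols
    return HomologyTable(reference=reference.genome, rows=rows, columns=columns,
                         multiplicities={g: len(c) for g, c in columns.items()})


def homology_depth(table: HomologyTable, genome: str
                   ) -> tuple[dict[int, int], int]:
    """Per-reference-gene count of retained homologs in one genome's columns.

    Returns (histogram over depth 0..multiplicity, modal depth).
    """
    cols = table.cells(genome)
    hist: dict[int, int] = {d: 0 for d in range(len(cols) + 1)}
    for ri in range(table.n_rows):
        depth = sum(1 for col in cols if col[ri] != MISSING)
        hist[depth] += 1
    modal = max(hist, key=lambda d: (hist[d], d))
    return hist, modal


def loss_rate(table: HomologyTable, genome: str) -> float:
    """Fraction of dot cells among one genome's columns."""
    cols = table.cells(genome)
    total = table.n_rows * len(cols)
    if total == 0:
        return float("nan")
    dots = sum(1 for col in cols for cell in col if cell == MISSING)
    return dots / total


def translocation_fraction(best_hits: Iterable[HomologPair],
                           table: HomologyTable, genome: str) -> float:
    """Fraction of best-hit target genes absent from every collinear column.

    ``best_hits`` pair reference genes with their best-matching gene in
    ``genome``; a target gene present in no table column is taken to have
    left its ancestral (collinear) location.
    """
    collinear: set[str] = set()
    for col in table.cells(genome):
        collinear.update(c for c in col if c != MISSING)
    ref_ids = {g.gene_id for g in table.rows}
    n = n_out = 0
    for p in best_hits:
        tgt = p.gene_b if p.gene_a in ref_ids else p.gene_a
        n += 1
        if tgt not in collinear:
            n_out += 1
    return n_out / n if n else float("nan")


def deletion_run_histogram(table: HomologyTable, genome: str, column: int
                           ) -> RunHistogram:
    """Maximal dot runs in one column, strictly bordered by retained genes
    within one reference chromosome; runs touching a chromosome end are
    excluded from the histogram and counted separately."""
    col = table.cells(genome)[column]
    counts: dict[int, int] = {}
    end_runs = 0
    i = 0
    # group rows by reference chromosome (rows are chromosome-then-rank sorted)
    while i < table.n_rows:
        chrom = table.rows[i].chromosome
        j = i
        while j < table.n_rows and table.rows[j].chromosome == chrom:
            j += 1
        seg = col[i:j]
        k = 0
        while k < len(seg):
            if seg[k] == MISSING:
                start = k
                while k < len(seg) and seg[k] == MISSING:
                    k += 1
                if start == 0 or k == len(seg):
                    end_runs += 1
                else:
                    length = k - start
                    counts[length] = counts.get(length, 0) + 1
            else:
                k += 1
        i = j
    return RunHistogram(counts=counts, end_runs=end_runs)


def combined_run_histogram(table: HomologyTable, genome: str) -> RunHistogram:
    """Pooled run histogram over all of a genome's columns."""
    counts: dict[int, int] = {}
    end_runs = 0
    for ci in range(len(table.cells(genome))):
        h = deletion_run_histogram(table, genome, ci)
        end_runs += h.end_runs
        for length, n in h.counts.items():
            counts[length] = counts.get(length, 0) + n
    return RunHistogram(counts=counts, end_runs=end_runs)


def fit_geometric(hist: RunHistogram | Sequence[int]) -> GeometricFit:
    """Closed-form MLE of the geometric run-length model.

    For P(L=k) = (1-p) p^(k-1) on k >= 1 the MLE is p_hat = 1 - 1/mean(L).
    """
    lengths = hist.lengths() if isinstance(hist, RunHistogram) else list(hist)
    if not lengths:
        raise ValueError("no runs to fit")
    mean = sum(lengths) / len(lengths)
    p = 1.0 - 1.0 / mean
    if p <= 0:
        ll = 0.0  # all runs length 1: P = 1 under p = 0
        p = 0.0
    else:
        ll = sum(math.log(1 - p) + (L - 1) * math.log(p) for L in lengths)
    return GeometricFit(p=p, mean_length=mean, log_likelihood=ll,
                        n_runs=len(lengths))


def write_homology_table(table: HomologyTable, path) -> None:
    genomes = list(table.columns)
    with open(path, "w") as fh:
        header = ["reference"]
        for g in genomes:
            header += [f"{g}.{i + 1}" for i in range(len(table.columns[g]))]
        fh.write("\t".join(header) + "\n")
        for ri, gene in enumerate(table.rows):
            cells = [gene.gene_id]
            for g in genomes:
                cells += [table.columns[g][ci][ri]
                          for ci in range(len(table.columns[g]))]
            fh.write("\t".join(cells) + "\n")
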