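"""Readers and writers for the pipeline's external formats.

Gene positions come in as GFF3 or a BED-like TSV, homologous gene pairs as
BLAST tabular (outfmt 6) or a 3-column TSV, coding sequences as FASTA and
expression values as a gene x sample FPKM table.  Internally all coordinates
are 0-based half-open; GFF3 stays 1-based inclusive on disk.  The character
``.`` is reserved throughout as the missing-value marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("paleoploid")

MISSING = "."

BED_COLUMNS = ["gene_id", "genome", "chromosome", "start", "end", "strand"]


@dataclass(frozen=True)
class GeneLocus:
    """A gene model pinned to a chromosome, with its order rank.

    ``rank`` is the 0-based index of the gene along its chromosome when genes
    are sorted by start coordinate (ties broken by gene id).  Collinearity is
    computed on ranks, not base pairs.
    """

    gene_id: str
    genome: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )


class GeneSet:
    """Ordered gene loci of one genome, grouped by chromosome.

    Ranks are (re)assigned on construction: per chromosome, ascending start,
    ties broken lexicographically by gene id.
    """

    def __init__(self, genome: str, loci: Iterable[GeneLocus] = ()):
        self.genome = genome
        self._by_chrom: dict[str, list[GeneLocus]] = {}
        self._by_id: dict[str, GeneLocus] = {}
        raw: dict[str, list[GeneLocus]] = {}
        for loc in loci:
            raw.setdefault(loc.chromosome, []).append(loc)
        for chrom in sorted(raw):
            ordered = sorted(raw[chrom], key=lambda g: (g.start, g.gene_id))
            ranked = []
            for i, g in enumerate(ordered):
                g = GeneLocus(g.gene_id, g.genome, g.chromosome, g.start, g.end,
                              g.strand, rank=i)
                if g.gene_id in self._by_id:
                    raise ValueError(f"duplicate gene_id {g.gene_id!r} in genome {genome!r}")
                self._by_id[g.gene_id] = g
                ranked.append(g)
            self._by_chrom[chrom] = ranked

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def loci(self, chromosome: str) -> list[GeneLocus]:
        return self._by_chrom[chromosome]

    def __iter__(self) -> Iterator[GeneLocus]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> GeneLocus | None:
        return self._by_id.get(gene_id)


@dataclass(frozen=True)
class HomologPair:
    """One putative homologous gene pair (a BLASTP hit or a truth pair)."""

    gene_a: str
    gene_b: str
    score: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")

    def unordered(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM table with replicate-group labels.

    Sample ids follow the convention ``<condition>_rep<k>``; ``groups`` maps a
    condition label to its sample columns.
    """

    values: pd.DataFrame
    groups: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if not self.groups:
            groups: dict[str, list[str]] = {}
            for col in self.values.columns:
                cond = col.rsplit("_rep", 1)[0]
                groups.setdefault(cond, []).append(col)
            self.groups = groups


# ---------------------------------------------------------------------------
# gene loci


def _finish_geneset(genome: str, loci: list[GeneLocus], source: str) -> GeneSet:
    if not loci:
        logger.warning("no gene records found in %s", source)
    sorted_in = all(
        loci[i].start <= loci[i + 1].start
        for i in range(len(loci) - 1)
        if loci[i].chromosome == loci[i + 1].chromosome
    )
    if not sorted_in and loci:
        logger.info("input %s not sorted by start; sorting", source)
    return GeneSet(genome, loci)


def read_gene_loci(path: str | Path, fmt: str = "auto", genome: str | None = None) -> GeneSet:
    """Read gene positions from GFF3 or the 6-column BED-like TSV.

    GFF3 coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention.  Ranks are assigned per chromosome by ascending
    start, ties broken by gene id.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed-tsv"
    if fmt == "gff3":
        return _read_gff3(path, genome or path.stem)
    if fmt == "bed-tsv":
        return _read_bed_tsv(path, genome)
    raise ValueError(f"unknown gene-locus format {fmt!r}")


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def _read_gff3(path: Path, genome: str) -> GeneSet:
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            if cols[2] not in {"gene", "mRNA"}:
                continue
            if cols[2] == "mRNA" and _gff3_attr(cols[8], "Parent"):
                continue  # gene feature carries the locus
            gid = _gff3_attr(cols[8], "ID") or _gff3_attr(cols[8], "Name")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: feature without ID attribute")
            start1, end1 = int(cols[3]), int(cols[4])
            loci.append(GeneLocus(gid, genome, cols[0], start1 - 1, end1, cols[6]))
    return _finish_geneset(genome, loci, str(path))


def _read_bed_tsv(path: Path, genome: str | None) -> GeneSet:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    except pd.errors.EmptyDataError:
        logger.warning("empty gene table %s", path)
        return GeneSet(genome or path.stem)
    missing = set(BED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genomes = df["genome"].unique()
    if genome is None:
        if len(genomes) != 1:
            raise ValueError(f"{path}: multiple genomes {list(genomes)}; pass genome=")
        genome = str(genomes[0])
    else:
        df = df[df["genome"] == genome]
    loci = [
        GeneLocus(str(r.gene_id), genome, str(r.chromosome), int(r.start), int(r.end),
                  str(r.strand))
        for r in df.itertuples()
    ]
    return _finish_geneset(genome, loci, str(path))


def write_gene_loci(gs: GeneSet, path: str | Path) -> None:
    rows = [
        (g.gene_id, g.genome, g.chromosome, g.start, g.end, g.strand)
        for g in gs
    ]
    pd.DataFrame(rows, columns=BED_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homolog pairs


def read_homolog_pairs(path: str | Path, max_evalue: float = 1e-5) -> list[HomologPair]:
    """Read gene pairs from BLAST outfmt 6 (12 columns) or a 3-column TSV.

    Self-hits are dropped, rows failing ``max_evalue`` are dropped, and
    duplicate pairs are collapsed keeping the best score.  Pair orientation is
    kept as stored.
    """
    path = Path(path)
    best: dict[frozenset[str], HomologPair] = {}
    n_self = n_eval = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if len(cols) >= 12:
                    a, b = cols[0], cols[1]
                    evalue, score = float(cols[10]), float(cols[11])
                elif len(cols) == 3:
                    a, b = cols[0], cols[1]
                    score, evalue = float(cols[2]), 0.0
                else:
                    raise ValueError(f"expected 12 or 3 columns, got {len(cols)}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if a == b:
                n_self += 1
                continue
            if evalue > max_evalue:
                n_eval += 1
                continue
            pair = HomologPair(a, b, score=score, evalue=evalue)
            key = pair.unordered()
            if key not in best or score > best[key].score:
                best[key] = pair
    if n_self or n_eval:
        logger.info("%s: dropped %d self-hits, %d rows above e-value %.3g",
                    path, n_self, n_eval, max_evalue)
    return list(best.values())


def write_homolog_pairs(pairs: Iterable[HomologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.score:g}\n")


# ---------------------------------------------------------------------------
# sequences and expression


def read_cds(path: str | Path) -> dict[str, str]:
    """Read coding sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_cds(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
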