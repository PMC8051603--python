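"""Collinear (synteny) block detection from homologous gene pairs.

A block is a chain of anchor pairs whose ranks increase strictly on both
chromosomes (or increase on one and decrease on the other for an inversion),
with at most ``max_gap`` intervening genes between neighbouring anchors on
either chromosome.  Large gene families are removed before chaining because
they blur the dot plot.  Chaining is a longest-chain dynamic programme per
orientation; non-overlapping blocks are extracted greedily by descending
anchor count, each emitted block's anchors removed before re-chaining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io import GeneSet, HomologPair

logger = logging.getLogger("paleoploid")


@dataclass(frozen=True)
class CollinearityParams:
    """Chaining constraints.

    max_gap: largest number of intervening gene ranks allowed between
        neighbouring anchors, enforced on both chromosomes separately.
    max_family_size: gene families (connected components of the pair graph)
        larger than this are discarded before chaining.
    min_anchors: smallest chain accepted as a block.
    """

    max_gap: int = 50
    max_family_size: int = 30
    min_anchors: int = 5
    orientation: str = "both"  # parallel | antiparallel | both

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.orientation not in {"parallel", "antiparallel", "both"}:
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class Anchor:
    """One collinear gene pair inside a block, with its ranks."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int


@dataclass
class CollinearBlock:
    genome_a: str
    genome_b: str
    chromosome_a: str
    chromosome_b: str
    anchors: list[Anchor]
    orientation: str  # parallel | antiparallel
    median_ks: float | None = None
    event_label: str = "unassigned"
    block_id: int = -1

    def __len__(self) -> int:
        return len(self.anchors)

    def validate(self, params: CollinearityParams) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        if any(y <= x for x, y in zip(ra, ra[1:])):
            raise ValueError("rank_a not strictly increasing")
        if self.orientation == "parallel":
            if any(y <= x for x, y in zip(rb, rb[1:])):
                raise ValueError("rank_b not strictly increasing")
        else:
            if any(y >= x for x, y in zip(rb, rb[1:])):
                raise ValueError("rank_b not strictly decreasing")
        for x, y in zip(self.anchors, self.anchors[1:]):
            if y.rank_a - x.rank_a - 1 > params.max_gap:
                raise ValueError("gap on chromosome a exceeds max_gap")
            if abs(y.rank_b - x.rank_b) - 1 > params.max_gap:
                raise ValueError("gap on chromosome b exceeds max_gap")
        if len(self.anchors) < params.min_anchors:
            raise ValueError("fewer anchors than min_anchors")


def filter_families(pairs: Iterable[HomologPair], max_family_size: int = 30
                    ) -> list[HomologPair]:
    """Drop every pair touching a gene family larger than ``max_family_size``.

    A family is a connected component of the undirected pair graph.
    """
    pairs = list(pairs)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for p in pairs:
        ra, rb = find(p.gene_a), find(p.gene_b)
        if ra != rb:
            parent[ra] = rb
    size: dict[str, int] = {}
    for g in parent:
        size[find(g)] = size.get(find(g), 0) + 1
    kept = [p for p in pairs if size[find(p.gene_a)] <= max_family_size]
    if len(kept) < len(pairs):
        logger.info("family filter removed %d/%d pairs (families > %d genes)",
                    len(pairs) - len(kept), len(pairs), max_family_size)
    return kept


def _chain_dp(points: Sequence[tuple[int, int, int]], max_gap: int
              ) -> list[int]:
    """Longest strictly increasing chain under the gap constraint.

    ``points`` are (rank_a, rank_b, index) tuples sorted by (rank_a, rank_b).
    Returns indices into ``points`` of the best chain (ties: smallest start
    rank).  O(n^2), fine at per-chromosome-pair scale.
    """
    n = len(points)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        aj, bj, _ = points[j]
        for i in range(j):
            ai, bi, _ = points[i]
            if ai >= aj or bi >= bj:
                continue
            if aj - ai - 1 > max_gap or bj - bi - 1 > max_gap:
                continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best_len[j], -points[j][0])) if n else -1
    if end < 0:
        return []
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def _extract_chains(anchors: list[tuple[int, int, HomologPair]],
                    orientation: str, params: CollinearityParams
                    ) -> list[tuple[list[tuple[int, int, HomologPair]], str]]:
    """Greedy non-overlapping chain extraction for one orientation."""
    flip = orientation == "antiparallel"
    live = list(anchors)
    out = []
    while True:
        pts = sorted(
            ((ra, -rb if flip else rb, i) for i, (ra, rb, _) in enumerate(live)),
        )
        chain = _chain_dp(pts, params.max_gap)
        if len(chain) < params.min_anchors:
            break
        idx = [pts[c][2] for c in chain]
        out.append(([live[i] for i in idx], orientation))
        taken = set(idx)
        live = [a for i, a in enumerate(live) if i not in taken]
    return out


def detect_blocks(pairs: Iterable[HomologPair], loci_a: GeneSet, loci_b: GeneSet,
                  params: CollinearityParams = CollinearityParams()
                  ) -> list[CollinearBlock]:
    """Detect collinear blocks between two genomes (or within one).

    Anchors are grouped per chromosome pair; per orientation the top-scoring
    gap-constrained chain is extracted repeatedly (anchors of an emitted block
    removed first), competing orientations resolved by anchor count with ties
    to parallel.  Output order is deterministic: chromosome pair, then start
    rank.
    """
    by_cpair: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    n_unknown = 0
    intra = loci_a.genome == loci_b.genome
    for p in pairs:
        ga, gb = loci_a.get(p.gene_a), loci_b.get(p.gene_b)
        if ga is None or gb is None:
            # stored pair order need not match the (loci_a, loci_b) order
            ga, gb = loci_a.get(p.gene_b), loci_b.get(p.gene_a)
            if ga is not None and gb is not None:
                p = HomologPair(p.gene_b, p.gene_a, p.score, p.evalue)
            else:
                n_unknown += 1
                continue
        if intra and ga.gene_id == gb.gene_id:
            continue
        if intra and ((ga.chromosome, ga.rank) > (gb.chromosome, gb.rank)):
            # canonical orientation so each intra-genome pair is seen once
            ga, gb = gb, ga
            p = HomologPair(ga.gene_id, gb.gene_id, p.score, p.evalue)
        key = (ga.chromosome, gb.chromosome)
        by_cpair.setdefault(key, []).append((ga.rank, gb.rank, p))
    if n_unknown:
        logger.info("skipped %d pairs referencing unknown gene ids", n_unknown)

    blocks: list[CollinearBlock] = []
    orientations = (["parallel", "antiparallel"] if params.orientation == "both"
                    else [params.orientation])
    for (ca, cb) in sorted(by_cpair):
        live = by_cpair[(ca, cb)]
        # deduplicate identical rank coordinates (keep best-scoring pair)
        seen: dict[tuple[int, int], tuple[int, int, HomologPair]] = {}
        for ra, rb, p in live:
            cur = seen.get((ra, rb))
            if cur is None or p.score > cur[2].score:
                seen[(ra, rb)] = (ra, rb, p)
        live = list(seen.values())
        while True:
            candidates = []
            for ori in orientations:
                chains = _extract_chains(live, ori, params)
                if chains:
                    candidates.append(chains[0])
            if not candidates:
                break
            chain, ori = max(
                candidates,
                key=lambda c: (len(c[0]), c[1] == "parallel", -c[0][0][0]),
            )
            anchors = [Anchor(p.gene_a, p.gene_b, ra, rb) for ra, rb, p in chain]
            blocks.append(CollinearBlock(loci_a.genome, loci_b.genome, ca, cb,
                                         anchors, ori))
            used = {(a.rank_a, a.rank_b) for a in anchors}
            live = [t for t in live if (t[0], t[1]) not in used]
    blocks.sort(key=lambda b: (b.chromosome_a, b.chromosome_b,
                               b.anchors[0].rank_a, b.anchors[0].rank_b))
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def write_blocks(blocks: Iterable[CollinearBlock], path: str | Path) -> None:
    """One anchor row per line, MCScanX-spirit flat TSV."""
    with open(path, "w") as fh:
        fh.write("block_id\tgenome_a\tchr_a\tgene_a\trank_a\t"
                 "genome_b\tchr_b\tgene_b\trank_b\torientation\n")
        for b in blocks:
            for a in b.anchors:
                fh.write(f"{b.block_id}\t{b.genome_a}\t{b.chromosome_a}\t"
                         f"{a.gene_a}\t{a.rank_a}\t{b.genome_b}\t"
                         f"{b.chromosome_b}\t{a.gene_b}\t{a.rank_b}\t"
                         f"{b.orientation}\n")


def read_blocks(path: str | Path) -> list[CollinearBlock]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chr_a": str, "chr_b": str})
    blocks = []
    for bid, grp in df.groupby("block_id", sort=True):
        first = grp.iloc[0]
        anchors = [Anchor(r.gene_a, r.gene_b, int(r.rank_a), int(r.rank_b))
                   for r in grp.itertuples()]
        blocks.append(CollinearBlock(first.genome_a, first.genome_b,
                                     str(first.chr_a), str(first.chr_b),
                                     anchors, first.orientation,
                                     block_id=int(bid)))
    return blocks


def read_mcscanx(path: str | Path) -> list[CollinearBlock]:
    """Read an MCScanX-style collinearity text file (``## Alignment`` headers).

    Only gene ids and block grouping are recovered; ranks are filled with the
    within-block index and orientation is taken from the header's
    ``plus``/``minus`` tag when present.
    """
    blocks: list[CollinearBlock] = []
    cur: list[tuple[str, str]] | None = None
    ori = "parallel"
    chroms = ("", "")

    def flush() -> None:
        nonlocal cur
        if cur:
            anchors = [Anchor(a, b, i, i if ori == "parallel" else -i)
                       for i, (a, b) in enumerate(cur)]
            blocks.append(CollinearBlock("", "", chroms[0], chroms[1],
                                         anchors, ori, block_id=len(blocks)))
        cur = None

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## Alignment"):
                flush()
                cur = []
                ori = "antiparallel" if line.rstrip().endswith("minus") else "parallel"
                tail = line.split()[-2] if len(line.split()) >= 2 else ""
                chroms = tuple(tail.split("&")) if "&" in tail else ("", "")
            elif cur is not None and line and not line.startswith("#"):
                fields = line.replace(":", "\t").split()
                genes = [f for f in fields if not f.replace("-", "").isdigit()]
                if len(genes) >= 2:
                    cur.append((genes[0], genes[1]))
    flush()
    return blocks
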