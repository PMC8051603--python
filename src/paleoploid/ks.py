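"""Codon alignment and Nei–Gojobori (1986) Ka/Ks estimation.

The NG86 estimator counts, for every codon, the fraction of possible
single-nucleotide changes that are synonymous (giving fractional synonymous
site counts S and nonsynonymous counts N with S + N = 3 x codons), counts
observed synonymous/nonsynonymous differences by averaging over all minimal
mutation pathways between the two codons (pathways through stop codons
excluded), and applies the Jukes–Cantor correction
``d = -(3/4) ln(1 - (4/3) p)`` to the raw proportions.  The estimate is
flagged saturated when pS >= 3/4, where the correction is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Mapping

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

NUCS = "ACGT"


def _codon_table(table_id: int = 1):
    return unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=8)
def _stops(table_id: int) -> frozenset[str]:
    return frozenset(_codon_table(table_id).stop_codons)


@lru_cache(maxsize=8)
def _aa(table_id: int) -> Mapping[str, str]:
    return dict(_codon_table(table_id).forward_table)


@lru_cache(maxsize=None)
def syn_sites(codon: str, table_id: int = 1) -> float:
    """Fractional count of synonymous sites in one codon.

    Each of the 9 possible single-nucleotide changes is classified 0/1;
    changes producing a stop codon count as nonsynonymous.  The codon's
    synonymous site count is the summed synonymous fraction per position.
    """
    aa = _aa(table_id)
    stops = _stops(table_id)
    if codon in stops:
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for n in NUCS:
            if n == codon[pos]:
                continue
            mut = codon[:pos] + n + codon[pos + 1:]
            if mut not in stops and aa[mut] == aa[codon]:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal mutation pathways; pathways passing through a
    stop codon are excluded and the remainder reweighted.  If every pathway
    hits a stop, all pathways are used unweighted (degenerate but defined).
    """
    aa = _aa(table_id)
    stops = _stops(table_id)
    if c1 == c2:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                through_stop = True
                break
            if aa[cur] == aa[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not through_stop:
            paths.append((sd, nd))
    if not paths:
        # all pathways pass through stops; count unweighted ignoring stop rule
        for order in permutations(diff_pos):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in stops or aa.get(cur) != aa.get(nxt):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free aligned codon strings of equal length (multiple of 3)."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


@dataclass(frozen=True)
class KaKsEstimate:
    S: float
    N: float
    sd: float
    nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    saturated: bool


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _trim_frame(cds: str, table_id: int) -> str:
    cds = cds.upper().replace("U", "T")
    cds = cds[: len(cds) - len(cds) % 3]
    if cds[-3:] in _stops(table_id):
        cds = cds[:-3]
    return cds


def build_codon_alignment(cds_a: str, cds_b: str, table_id: int = 1
                          ) -> CodonAlignment:
    """Align two in-frame CDS at the protein level and map back to codons.

    Terminal stop codons are trimmed; an internal stop raises.  Codon columns
    containing a gap or an ambiguous base are removed.
    """
    stops = _stops(table_id)
    trimmed = []
    for name, cds in (("a", cds_a), ("b", cds_b)):
        cds = _trim_frame(cds, table_id)
        for i in range(0, len(cds), 3):
            if cds[i:i + 3] in stops:
                raise ValueError(
                    f"internal stop codon in sequence {name} at codon {i // 3}")
        trimmed.append(cds)
    ca, cb = trimmed
    prot_a = str(Seq(ca).translate(table=table_id))
    prot_b = str(Seq(cb).translate(table=table_id))

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    aln = aligner.align(prot_a.replace("X", "A"), prot_b.replace("X", "A"))[0]

    out_a, out_b = [], []
    ia = ib = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        # advance over gaps
        ia, ib = sa, sb
        for k in range(ea - sa):
            cod_a = ca[(ia + k) * 3:(ia + k) * 3 + 3]
            cod_b = cb[(ib + k) * 3:(ib + k) * 3 + 3]
            if set(cod_a) | set(cod_b) <= set(NUCS):
                out_a.append(cod_a)
                out_b.append(cod_b)
    if not out_a:
        raise ValueError("no aligned codon columns survive filtering")
    return CodonAlignment("".join(out_a), "".join(out_b))


def ng86_estimate(aln: CodonAlignment, table_id: int = 1) -> KaKsEstimate:
    """NG86 Ka/Ks for one gap-free codon alignment."""
    if aln.n_codons < 1:
        raise ValueError("empty alignment")
    S = N = sd = nd = 0.0
    for cod_a, cod_b in aln.codons():
        sa, sb = syn_sites(cod_a, table_id), syn_sites(cod_b, table_id)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        d_s, d_n = codon_differences(cod_a, cod_b, table_id)
        sd += d_s
        nd += d_n
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = _jc(pS)
    Ka = _jc(pN)
    return KaKsEstimate(S=S, N=N, sd=sd, nd=nd, pS=pS, pN=pN,
                        Ks=Ks, Ka=Ka, saturated=Ks is None)


def pair_ks(cds_a: str, cds_b: str, table_id: int = 1) -> KaKsEstimate:
    """Convenience: align then estimate."""
    return ng86_estimate(build_codon_alignment(cds_a, cds_b, table_id), table_id)


def block_median_ks(block, estimates: Mapping[tuple[str, str], KaKsEstimate]
                    ) -> float | None:
    """Median Ks over a block's anchors with defined, unsaturated estimates.

    Even anchor counts use the mean of the two central values.  Returns None
    (with no estimate usable) rather than raising, so sparse blocks survive.
    """
    vals = []
    for a in block.anchors:
        est = estimates.get((a.gene_a, a.gene_b)) or estimates.get((a.gene_b, a.gene_a))
        if est is not None and est.Ks is not None:
            vals.append(est.Ks)
    if not vals:
        return None
    vals.sort()
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0


def write_ks_table(estimates: Mapping[tuple[str, str], KaKsEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tS\tN\tsd\tnd\tKs\tKa\tsaturated\n")
        for (a, b), e in estimates.items():
            ks = f"{e.Ks:.6f}" if e.Ks is not None else "."
            ka = f"{e.Ka:.6f}" if e.Ka is not None else "."
            fh.write(f"{a}\t{b}\t{e.S:.4f}\t{e.N:.4f}\t{e.sd:.4f}\t{e.nd:.4f}\t"
                     f"{ks}\t{ka}\t{int(e.saturated)}\n")
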