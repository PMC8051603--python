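"""Forward simulator of polyploid genome evolution with full ground truth.

A single ancestral genome (chromosomes of ordered genes, each gene carrying
a codon sequence) is pushed through a timeline of events — whole-genome
triplication/duplication, speciation, chromosome fusion and inversion —
ordered oldest first.  Sequences accumulate synonymous substitutions at a
per-lineage clock (rate r x lineage multiplier), so every homolog pair has a
known true synonymous divergence.  After each polyploidy, duplicated gene
copies are deleted in geometric-length runs until a retention target is met,
emulating post-polyploidy fractionation; a configurable fraction of
surviving genes is then relocated, emulating transpositional shuffling.
The simulator emits exactly the formats the readers consume (gene tables,
CDS FASTA, homolog-pair TSV, expression TSV) plus a truth record, so every
pipeline stage can be validated against known parameters.

Sequences are built from codons of the six amino-acid families whose third
position is fully degenerate and whose other positions admit no synonymous
change (Ala, Gly, Pro, Thr, Val, Ser-TCN).  Synonymous evolution is then an
exact 4-state Jukes-Cantor process with one synonymous site per codon, which
the NG86 correction inverts without bias; nonsynonymous divergence stays 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import ExpressionMatrix, GeneLocus, GeneSet, HomologPair
from .karyotype import (AncestralSegment, Chromosome, Karyotype,
                        KaryotypeEvent, apply_event)

# codon families with exactly one synonymous site (the 4-fold third position)
FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")
NUCS = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TimelineEvent:
    """One event on the lineage tree, oldest first.

    kind: 'wgt' | 'wgd' | 'speciation' | 'fusion' | 'inversion'
    age: Mya.  lineage: name of the lineage the event happens in.
    For speciation, ``children`` names the two daughter lineages; for fusion,
    ``chromosomes`` names the two chromosome ids to join; for inversion,
    ``chromosomes`` is (chrom_id,) and ``span`` the gene-index range.
    """

    kind: str
    age: float
    lineage: str
    label: str = ""
    children: tuple[str, str] | None = None
    chromosomes: tuple[str, ...] = ()
    span: tuple[int, int] | None = None


@dataclass
class SimulationConfig:
    seed: int
    n_chromosomes: int = 7
    genes_per_chromosome: int = 60
    codons_per_gene: int = 150
    clock_rate: float = 5e-9  # synonymous substitutions / site / year
    root_lineage: str = "root"
    timeline: list[TimelineEvent] = field(default_factory=list)
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    fractionation_p: float = 0.4  # geometric run-extension parameter
    retention: dict[str, float] = field(default_factory=dict)  # event label -> kept fraction
    transposed_fraction: dict[str, float] = field(default_factory=dict)  # species -> fraction
    spurious_pair_fraction: float = 0.05
    expression_bias_fraction: float = 0.0
    expression_bias_log2fc: float = 2.0
    expression_replicate_sd: float = 0.25
    expression_conditions: tuple[str, ...] = ("root", "petiole", "leaf")
    expression_replicates: int = 3

    def __post_init__(self) -> None:
        ages = [e.age for e in self.timeline]
        if sorted(ages, reverse=True) != ages:
            raise ValueError("timeline ages must be non-increasing (oldest first)")
        if not 0 <= self.fractionation_p < 1:
            raise ValueError("fractionation_p must be in [0, 1)")
        for label, r in self.retention.items():
            if not 0 < r <= 1:
                raise ValueError(f"retention for {label!r} must be in (0, 1]")


# ---------------------------------------------------------------------------
# internal state


@dataclass
class SimGene:
    uid: int
    anc: int  # ancestral gene serial (chromosome-major)
    history: tuple[tuple[str, int], ...]  # (event label, copy index) path
    ds_marks: tuple[float, ...]  # ds accumulated at each history step
    ds: float
    seq: str
    transposed: bool = False


@dataclass
class LineageState:
    name: str
    multiplier: float
    age: float
    chromosomes: dict[str, list[SimGene]]  # ordered mapping chrom id -> genes
    karyotype: Karyotype


@dataclass
class TruthRecord:
    pairs: list[tuple[str, str, str, float]] = field(default_factory=list)
    # (gene_a_id, gene_b_id, divergence event label, true dS)
    deletion_runs: dict[str, list[int]] = field(default_factory=dict)
    karyotypes: dict[str, dict] = field(default_factory=dict)
    transposed: dict[str, list[str]] = field(default_factory=dict)
    bias_flags: dict[str, int] = field(default_factory=dict)  # gene id -> +-1 (copy biased up/down)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "pairs": self.pairs,
            "deletion_runs": self.deletion_runs,
            "karyotypes": self.karyotypes,
            "transposed": self.transposed,
            "bias_flags": self.bias_flags,
        }, indent=0))


@dataclass
class SimulatedDataset:
    gene_sets: dict[str, GeneSet]
    cds: dict[str, dict[str, str]]  # species -> gene id -> sequence
    pairs: dict[tuple[str, str], list[HomologPair]]
    expression: ExpressionMatrix | None
    truth: TruthRecord
    config: SimulationConfig


# ---------------------------------------------------------------------------
# sequence machinery


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    prefixes = rng.integers(0, len(FOURFOLD_PREFIXES), size=n_codons)
    thirds = rng.integers(0, 4, size=n_codons)
    return "".join(FOURFOLD_PREFIXES[p] + NUCS[t]
                   for p, t in zip(prefixes, thirds))


def _evolve_seq(seq: str, ds: float, rng: np.random.Generator) -> str:
    """Accumulate synonymous substitutions: Poisson(ds) hits per synonymous
    site, each replacing the third codon position by a uniform alternative."""
    if ds <= 0:
        return seq
    n_codons = len(seq) // 3
    n_events = rng.poisson(ds * n_codons)
    if n_events == 0:
        return seq
    chars = list(seq)
    sites = rng.integers(0, n_codons, size=n_events)
    picks = rng.integers(0, 3, size=n_events)
    for site, pick in zip(sites, picks):
        pos = site * 3 + 2
        alts = [n for n in NUCS if n != chars[pos]]
        chars[pos] = alts[pick]
    return "".join(chars)


def evolve_pair(ancestral_cds: str, target_ds: float, seed: int
                ) -> tuple[str, str]:
    """Evolve two descendants of one CDS to expected mutual synonymous
    divergence ``target_ds`` (half on each branch); synonymous-only."""
    if target_ds < 0:
        raise ValueError("target_ds must be >= 0")
    if len(ancestral_cds) < 3:
        raise ValueError("CDS too short")
    ancestral_cds = ancestral_cds[: len(ancestral_cds) - len(ancestral_cds) % 3]
    if not any(ancestral_cds[i:i + 2] in FOURFOLD_PREFIXES
               for i in range(0, len(ancestral_cds), 3)):
        raise ValueError("no synonymously degenerate codons in CDS")
    rng = np.random.default_rng(seed)
    a = _evolve_seq(ancestral_cds, target_ds / 2, rng)
    b = _evolve_seq(ancestral_cds, target_ds / 2, rng)
    return a, b


# ---------------------------------------------------------------------------
# fractionation


def _fractionate(genes_by_chrom: dict[str, list[SimGene]],
                 new_copy_suffixes: Iterable[str], retention: float,
                 p: float, rng: np.random.Generator) -> list[int]:
    """Delete genes from duplicated chromosome copies in geometric runs until
    each copy's retained fraction drops to ``retention``.  Returns realized
    run lengths."""
    runs: list[int] = []
    suffixes = list(new_copy_suffixes)
    for cid in list(genes_by_chrom):
        if not any(cid.endswith(s) for s in suffixes):
            continue
        genes = genes_by_chrom[cid]
        n = len(genes)
        target_del = round((1.0 - retention) * n)
        alive = [True] * n
        n_del = 0
        guard = 0
        # each run is placed where it fits entirely in live genes, so realized
        # run lengths follow the drawn geometric law; the budget may overshoot
        # by at most one run
        while n_del < target_del and guard < 20 * n:
            guard += 1
            # numpy geometric(q) counts trials to first success: support >= 1
            length = int(rng.geometric(1.0 - p)) if p > 0 else 1
            starts = [i for i in range(n - length + 1)
                      if all(alive[i:i + length])]
            if not starts:
                continue
            start = starts[int(rng.integers(0, len(starts)))]
            for i in range(start, start + length):
                alive[i] = False
            n_del += length
            runs.append(length)
        genes_by_chrom[cid] = [g for g, a in zip(genes, alive) if a]
    return runs


# ---------------------------------------------------------------------------
# the simulator


class _Sim:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.uid = 0
        self.truth = TruthRecord()
        self.lineages: dict[str, LineageState] = {}
        self._init_root()

    def _next_uid(self) -> int:
        self.uid += 1
        return self.uid

    def _init_root(self) -> None:
        cfg = self.cfg
        chroms: dict[str, list[SimGene]] = {}
        anc = 0
        for ci in range(cfg.n_chromosomes):
            cid = f"c{ci + 1}"
            genes = []
            for _ in range(cfg.genes_per_chromosome):
                genes.append(SimGene(
                    uid=self._next_uid(), anc=anc, history=(), ds_marks=(),
                    ds=0.0, seq=random_cds(cfg.codons_per_gene, self.rng)))
                anc += 1
            chroms[cid] = genes
        start_age = cfg.timeline[0].age if cfg.timeline else 0.0
        kary = Karyotype(cfg.root_lineage, [
            Chromosome(cid, [AncestralSegment(cid, 0, cfg.genes_per_chromosome)])
            for cid in chroms
        ])
        self.lineages[cfg.root_lineage] = LineageState(
            name=cfg.root_lineage,
            multiplier=cfg.rate_multipliers.get(cfg.root_lineage, 1.0),
            age=start_age, chromosomes=chroms, karyotype=kary)

    def _advance(self, lin: LineageState, to_age: float) -> None:
        dt = lin.age - to_age
        if dt < 0:
            raise ValueError(f"timeline not ordered: lineage {lin.name} at "
                             f"{lin.age} asked to advance to {to_age}")
        if dt == 0:
            return
        ds = self.cfg.clock_rate * lin.multiplier * dt * 1e6
        for genes in lin.chromosomes.values():
            for g in genes:
                g.seq = _evolve_seq(g.seq, ds, self.rng)
                g.ds += ds
        lin.age = to_age

    def _apply_polyploidy(self, lin: LineageState, kind: str, label: str) -> None:
        suffixes = "ab" if kind == "wgd" else "abc"
        new_chroms: dict[str, list[SimGene]] = {}
        for cid, genes in lin.chromosomes.items():
            for k, suf in enumerate(suffixes):
                copy = []
                for g in genes:
                    copy.append(SimGene(
                        uid=self._next_uid(), anc=g.anc,
                        history=g.history + ((label, k),),
                        ds_marks=g.ds_marks + (g.ds,), ds=g.ds, seq=g.seq))
                new_chroms[cid + suf] = copy
        lin.chromosomes = new_chroms
        lin.karyotype = apply_event(lin.karyotype,
                                    KaryotypeEvent(kind.upper()))
        retention = self.cfg.retention.get(label, 1.0)
        if retention < 1.0:
            runs = _fractionate(lin.chromosomes, list(suffixes), retention,
                                self.cfg.fractionation_p, self.rng)
            self.truth.deletion_runs.setdefault(
                f"{lin.name}:{label}", []).extend(runs)

    def _apply_speciation(self, lin: LineageState, ev: TimelineEvent) -> None:
        assert ev.children is not None
        del self.lineages[lin.name]
        for k, child in enumerate(ev.children):
            chroms: dict[str, list[SimGene]] = {}
            for cid, genes in lin.chromosomes.items():
                chroms[cid] = [SimGene(
                    uid=self._next_uid(), anc=g.anc,
                    history=g.history + ((ev.label or f"split:{lin.name}", k),),
                    ds_marks=g.ds_marks + (g.ds,), ds=g.ds, seq=g.seq)
                    for g in genes]
            self.lineages[child] = LineageState(
                name=child,
                multiplier=self.cfg.rate_multipliers.get(child, lin.multiplier),
                age=lin.age, chromosomes=chroms,
                karyotype=lin.karyotype.copy(child))

    def _apply_fusion(self, lin: LineageState, ev: TimelineEvent) -> None:
        a, b = ev.chromosomes
        product = ev.label or f"{a}+{b}"
        sat = f"sat_{product}"
        lin.chromosomes[product] = lin.chromosomes.pop(a) + lin.chromosomes.pop(b)
        k = apply_event(lin.karyotype,
                        KaryotypeEvent("EJ", operands=(a, b),
                                       products=(product, sat)))
        lin.karyotype = apply_event(k, KaryotypeEvent("LOSS", operands=(sat,)))

    def _apply_inversion(self, lin: LineageState, ev: TimelineEvent) -> None:
        (cid,) = ev.chromosomes
        lo, hi = ev.span
        genes = lin.chromosomes[cid]
        lin.chromosomes[cid] = genes[:lo] + genes[lo:hi][::-1] + genes[hi:]

    def run(self) -> None:
        for ev in self.cfg.timeline:
            lin = self.lineages.get(ev.lineage)
            if lin is None:
                raise ValueError(f"timeline references unknown lineage "
                                 f"{ev.lineage!r} at age {ev.age}")
            self._advance(lin, ev.age)
            if ev.kind in {"wgd", "wgt"}:
                self._apply_polyploidy(lin, ev.kind, ev.label or ev.kind)
            elif ev.kind == "speciation":
                self._apply_speciation(lin, ev)
            elif ev.kind == "fusion":
                self._apply_fusion(lin, ev)
            elif ev.kind == "inversion":
                self._apply_inversion(lin, ev)
            else:
                raise ValueError(f"unknown timeline event kind {ev.kind!r}")
        for lin in self.lineages.values():
            self._advance(lin, 0.0)

    # -- emission -----------------------------------------------------------

    def _transpose(self, lin: LineageState, fraction: float) -> list[str]:
        moved: list[str] = []
        if fraction <= 0:
            return moved
        all_pos = [(cid, i) for cid, genes in lin.chromosomes.items()
                   for i in range(len(genes))]
        n_move = round(fraction * len(all_pos))
        idx = self.rng.choice(len(all_pos), size=n_move, replace=False)
        chosen = [all_pos[i] for i in sorted(idx, reverse=True)]
        movers: list[SimGene] = []
        for cid, i in sorted(chosen, key=lambda t: (t[0], -t[1])):
            g = lin.chromosomes[cid].pop(i)
            g.transposed = True
            movers.append(g)
        cids = list(lin.chromosomes)
        for g in movers:
            cid = cids[int(self.rng.integers(0, len(cids)))]
            pos = int(self.rng.integers(0, len(lin.chromosomes[cid]) + 1))
            lin.chromosomes[cid].insert(pos, g)
        return movers and [f"{lin.name}G{g.uid:06d}" for g in movers] or []

    def emit(self) -> SimulatedDataset:
        cfg = self.cfg
        gene_sets: dict[str, GeneSet] = {}
        cds: dict[str, dict[str, str]] = {}
        gene_by_id: dict[str, SimGene] = {}
        species_of: dict[int, str] = {}
        for name, lin in self.lineages.items():
            frac = cfg.transposed_fraction.get(name, 0.0)
            moved = self._transpose(lin, frac)
            if moved:
                self.truth.transposed[name] = moved
            loci = []
            seqs = {}
            for cid, genes in lin.chromosomes.items():
                for i, g in enumerate(genes):
                    gid = f"{name}G{g.uid:06d}"
                    start = i * 1000
                    loci.append(GeneLocus(gid, name, cid, start, start + 900, "+"))
                    seqs[gid] = g.seq
                    gene_by_id[gid] = g
                    species_of[g.uid] = name
            gene_sets[name] = GeneSet(name, loci)
            cds[name] = seqs
            self.truth.karyotypes[name] = lin.karyotype.composition()

        # true homolog pairs grouped by ancestral gene
        by_anc: dict[int, list[tuple[str, SimGene]]] = {}
        for gid, g in gene_by_id.items():
            by_anc.setdefault(g.anc, []).append((gid, g))
        pair_lists: dict[tuple[str, str], list[HomologPair]] = {}
        for members in by_anc.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    gid_a, ga = members[i]
                    gid_b, gb = members[j]
                    k = 0
                    while (k < len(ga.history) and k < len(gb.history)
                           and ga.history[k] == gb.history[k]):
                        k += 1
                    if k < len(ga.history):
                        label = ga.history[k][0]
                        ds_div = ga.ds_marks[k]
                    elif k < len(gb.history):
                        label = gb.history[k][0]
                        ds_div = gb.ds_marks[k]
                    else:
                        continue  # same gene (cannot happen across ids)
                    true_ds = (ga.ds - ds_div) + (gb.ds - ds_div)
                    sp_a = species_of[ga.uid]
                    sp_b = species_of[gb.uid]
                    key = tuple(sorted((sp_a, sp_b)))
                    if key[0] != sp_a:
                        gid_a, gid_b = gid_b, gid_a
                    pair_lists.setdefault(key, []).append(
                        HomologPair(gid_a, gid_b, score=100.0, evalue=1e-50))
                    self.truth.pairs.append((gid_a, gid_b, label, true_ds))

        # spurious pairs
        if cfg.spurious_pair_fraction > 0:
            for key, plist in list(pair_lists.items()):
                sp_a, sp_b = key
                ids_a = [g.gene_id for g in gene_sets[sp_a]]
                ids_b = [g.gene_id for g in gene_sets[sp_b]]
                n_spur = round(cfg.spurious_pair_fraction * len(plist))
                for _ in range(n_spur):
                    a = ids_a[int(self.rng.integers(0, len(ids_a)))]
                    b = ids_b[int(self.rng.integers(0, len(ids_b)))]
                    if a != b:
                        plist.append(HomologPair(a, b, score=40.0, evalue=1e-6))

        expr = self._emit_expression(gene_sets, gene_by_id)
        return SimulatedDataset(gene_sets=gene_sets, cds=cds, pairs=pair_lists,
                                expression=expr, truth=self.truth, config=cfg)

    def _emit_expression(self, gene_sets, gene_by_id) -> ExpressionMatrix | None:
        cfg = self.cfg
        if not self.lineages:
            return None
        import pandas as pd

        # one matrix covering every emitted gene; duplicates share a baseline
        baseline: dict[int, float] = {}
        rows = {}
        samples = [f"{c}_rep{r + 1}" for c in cfg.expression_conditions
                   for r in range(cfg.expression_replicates)]
        biased: dict[str, int] = {}
        for gid, g in gene_by_id.items():
            if g.anc not in baseline:
                baseline[g.anc] = float(self.rng.normal(5.0, 2.0))
            mu = baseline[g.anc]
            if cfg.expression_bias_fraction > 0:
                if self.rng.random() < cfg.expression_bias_fraction:
                    sign = 1 if self.rng.random() < 0.5 else -1
                    mu = mu + sign * cfg.expression_bias_log2fc
                    biased[gid] = sign
            noise = self.rng.normal(0.0, cfg.expression_replicate_sd,
                                    size=len(samples))
            rows[gid] = np.maximum(0.0, 2.0 ** (mu + noise))
        self.truth.bias_flags = biased
        df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        return ExpressionMatrix(df)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the forward simulation and emit the dataset plus ground truth."""
    sim = _Sim(config)
    sim.run()
    return sim.emit()


# ---------------------------------------------------------------------------
# canned scenarios (the study-like conditions used throughout the tests)


def rate_scenario(seed: int, multipliers: Sequence[float] = (1.0, 1.143, 1.27),
                  event_age: float = 60.0, genes_per_chromosome: int = 50,
                  ) -> SimulationConfig:
    """Shared triplication followed immediately by a star split into species
    with the given whole-path rate multipliers — the substrate for shared-
    event rate correction."""
    species = [f"sp{i + 1}" for i in range(len(multipliers))]
    timeline = [
        TimelineEvent("wgt", event_age, "root", label="gamma"),
        TimelineEvent("speciation", event_age - 0.5, "root", label="split1",
                      children=(species[0], "rest1")),
    ]
    lin = "rest1"
    for i in range(1, len(species) - 1):
        timeline.append(TimelineEvent(
            "speciation", event_age - 0.5 - 0.1 * i, lin, label=f"split{i + 1}",
            children=(species[i], f"rest{i + 1}")))
        lin = f"rest{i + 1}"
    # the last 'rest' lineage IS the last species
    rename = {lin: species[-1]}
    timeline = [
        TimelineEvent(e.kind, e.age, rename.get(e.lineage, e.lineage), e.label,
                      tuple(rename.get(c, c) for c in e.children) if e.children else None,
                      e.chromosomes, e.span)
        for e in timeline
    ]
    return SimulationConfig(
        seed=seed, genes_per_chromosome=genes_per_chromosome,
        timeline=timeline,
        rate_multipliers=dict(zip(species, multipliers)),
        spurious_pair_fraction=0.0,
    )


def fractionation_scenario(seed: int, retention: float = 0.5,
                           transposed: float = 0.0, p: float = 0.4,
                           genes_per_chromosome: int = 120,
                           n_chromosomes: int = 5) -> SimulationConfig:
    """Outgroup reference splits off, then one WGD with geometric-run
    fractionation to ``retention`` per copy; optional transposition."""
    timeline = [
        TimelineEvent("speciation", 80.0, "root", label="ref_split",
                      children=("reference", "focal")),
        TimelineEvent("wgd", 40.0, "focal", label="wgd1"),
    ]
    return SimulationConfig(
        seed=seed, n_chromosomes=n_chromosomes,
        genes_per_chromosome=genes_per_chromosome,
        codons_per_gene=60,
        timeline=timeline, fractionation_p=p,
        retention={"wgd1": retention},
        transposed_fraction={"focal": transposed},
        spurious_pair_fraction=0.0,
    )


def timing_scenario(seed: int, when: str = "pre",
                    genes_per_chromosome: int = 40) -> SimulationConfig:
    """Two WGDs with one scheduled fusion of c1+c2 either before the first
    WGD ('pre'), between them ('between') or after the second ('post');
    a reference outgroup splits off before everything.  Noiseless
    (retention 1, no transposition, no spurious pairs)."""
    fusion_age = {"pre": 75.0, "between": 50.0, "post": 20.0}[when]
    timeline = [
        TimelineEvent("speciation", 90.0, "root", label="ref_split",
                      children=("reference", "focal")),
        TimelineEvent("wgd", 60.0, "focal", label="omega"),
        TimelineEvent("wgd", 30.0, "focal", label="alpha"),
    ]
    chrom = {"pre": ("c1", "c2"), "between": ("c1a", "c2a"),
             "post": ("c1aa", "c2aa")}[when]
    timeline.append(TimelineEvent("fusion", fusion_age, "focal",
                                  label="fus1", chromosomes=chrom))
    timeline.sort(key=lambda e: -e.age)
    return SimulationConfig(
        seed=seed, n_chromosomes=4,
        genes_per_chromosome=genes_per_chromosome, codons_per_gene=30,
        timeline=timeline, spurious_pair_fraction=0.0,
    )


def apiaceae_scenario(seed: int, genes_per_chromosome: int = 50,
                      retention_omega: float = 0.75,
                      retention_alpha: float = 0.8) -> SimulationConfig:
    """The study-like history: eudicot-wide triplication (130 Mya), an
    outgroup split, the Apiales-shared WGD (70 Mya), the Apiaceae-shared WGD
    (36 Mya) and a recent speciation, with moderate fractionation."""
    timeline = [
        TimelineEvent("wgt", 130.0, "root", label="gamma"),
        TimelineEvent("speciation", 125.0, "root", label="grape_split",
                      children=("grape", "apiales")),
        TimelineEvent("wgd", 70.0, "apiales", label="omega"),
        TimelineEvent("wgd", 36.0, "apiales", label="alpha"),
        TimelineEvent("speciation", 12.0, "apiales", label="cel_cor_split",
                      children=("celery", "coriander")),
    ]
    return SimulationConfig(
        seed=seed, genes_per_chromosome=genes_per_chromosome,
        codons_per_gene=120,
        timeline=timeline,
        rate_multipliers={"grape": 1.0, "apiales": 1.0,
                          "celery": 1.0, "coriander": 1.0},
        retention={"gamma": 0.55, "omega": retention_omega,
                   "alpha": retention_alpha},
        fractionation_p=0.4,
        spurious_pair_fraction=0.05,
    )


# ---------------------------------------------------------------------------
# writing a dataset to disk


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for sp, gs in ds.gene_sets.items():
        p = outdir / f"{sp}.genes.tsv"
        _io.write_gene_loci(gs, p)
        manifest[f"genes:{sp}"] = str(p)
        p = outdir / f"{sp}.cds.fasta"
        _io.write_cds(ds.cds[sp], p)
        manifest[f"cds:{sp}"] = str(p)
    for (a, b), plist in ds.pairs.items():
        p = outdir / f"{a}__{b}.pairs.tsv"
        _io.write_homolog_pairs(plist, p)
        manifest[f"pairs:{a}:{b}"] = str(p)
    if ds.expression is not None:
        p = outdir / "expression.tsv"
        _io.write_expression(ds.expression, p)
        manifest["expression"] = str(p)
    p = outdir / "truth.json"
    ds.truth.to_json(p)
    manifest["truth"] = str(p)
    return manifest
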