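"""Chromosome event algebra and ancestral-karyotype trajectory replay.

A karyotype is a set of chromosomes, each an ordered list of oriented
ancestral segments measured in ancestral gene-rank units.  Events transform
karyotypes: whole-genome doubling/tripling (WGD/WGT), arm exchange between
two chromosomes (X), end-to-end joining (EJ), nested chromosome fusion
(NCF), segmental inversion (Inv), satellite loss and renaming.  EJ and NCF
each yield one fused product plus one telomere-derived satellite chromosome;
satellite loss is what reduces the chromosome number.  Scripts in a small
one-event-per-line DSL are replayed deterministically with snapshots taken
at named checkpoints (evolutionary nodes), and segment content is conserved
through every event except explicit satellite losses.

The module also derives, from collinear blocks against a reference genome,
the correspondence profile of each chromosome and the parsimony rule that
times an ancestral fusion relative to the lineage's polyploidies: a fusion
seen in as many chromosome copies as the full ploidy product predates all
duplications; one seen in fewer copies happened between or after them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .collinearity import CollinearBlock


@dataclass(frozen=True)
class AncestralSegment:
    """A contiguous piece of an ancestral chromosome, in gene-rank units."""

    source: str
    start: int  # half-open [start, end)
    end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment span must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start

    def reverse(self) -> "AncestralSegment":
        return replace(self, orientation="-" if self.orientation == "+" else "+")


@dataclass
class Chromosome:
    id: str
    segments: list[AncestralSegment] = field(default_factory=list)
    is_satellite: bool = False

    def __len__(self) -> int:
        return sum(len(s) for s in self.segments)

    def normalize(self) -> None:
        """Merge adjacent segments that are contiguous pieces of the same
        ancestral chromosome in the same orientation."""
        merged: list[AncestralSegment] = []
        for seg in self.segments:
            if merged:
                prev = merged[-1]
                if prev.source == seg.source and prev.orientation == seg.orientation:
                    if seg.orientation == "+" and prev.end == seg.start:
                        merged[-1] = replace(prev, end=seg.end)
                        continue
                    if seg.orientation == "-" and seg.end == prev.start:
                        merged[-1] = replace(prev, start=seg.start)
                        continue
            merged.append(seg)
        self.segments = merged

    def split(self, pos: int) -> tuple[list[AncestralSegment], list[AncestralSegment]]:
        """Split the segment list at cumulative gene-rank position ``pos``."""
        if not 0 <= pos <= len(self):
            raise ValueError(f"breakpoint {pos} outside chromosome {self.id} "
                             f"(length {len(self)})")
        left: list[AncestralSegment] = []
        right: list[AncestralSegment] = []
        acc = 0
        for seg in self.segments:
            if acc + len(seg) <= pos:
                left.append(seg)
            elif acc >= pos:
                right.append(seg)
            else:
                cut = pos - acc
                if seg.orientation == "+":
                    left.append(replace(seg, end=seg.start + cut))
                    right.append(replace(seg, start=seg.start + cut))
                else:
                    left.append(replace(seg, start=seg.end - cut))
                    right.append(replace(seg, end=seg.end - cut))
            acc += len(seg)
        return left, right


class Karyotype:
    def __init__(self, node_label: str = "",
                 chromosomes: Iterable[Chromosome] = ()):
        self.node_label = node_label
        self.chromosomes: dict[str, Chromosome] = {}
        for c in chromosomes:
            self.add(c)

    def add(self, c: Chromosome) -> None:
        if c.id in self.chromosomes:
            raise ValueError(f"duplicate chromosome id {c.id!r}")
        self.chromosomes[c.id] = c

    def pop(self, cid: str) -> Chromosome:
        if cid not in self.chromosomes:
            raise KeyError(f"unknown chromosome {cid!r}")
        return self.chromosomes.pop(cid)

    def __getitem__(self, cid: str) -> Chromosome:
        return self.chromosomes[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.chromosomes

    @property
    def n_chromosomes(self) -> int:
        """Non-satellite chromosome count (what a karyotype figure reports)."""
        return sum(1 for c in self.chromosomes.values() if not c.is_satellite)

    @property
    def n_satellites(self) -> int:
        return sum(1 for c in self.chromosomes.values() if c.is_satellite)

    def content(self) -> Counter:
        """Multiset of unit (source, position) pieces — conservation currency."""
        counter: Counter = Counter()
        for c in self.chromosomes.values():
            for seg in c.segments:
                for pos in range(seg.start, seg.end):
                    counter[(seg.source, pos)] += 1
        return counter

    def copy(self, node_label: str | None = None) -> "Karyotype":
        k = Karyotype(node_label if node_label is not None else self.node_label)
        for c in self.chromosomes.values():
            k.add(Chromosome(c.id, list(c.segments), c.is_satellite))
        return k

    def composition(self) -> dict[str, list[tuple[str, int, int, str]]]:
        return {cid: [(s.source, s.start, s.end, s.orientation)
                      for s in c.segments]
                for cid, c in self.chromosomes.items()}


def ancestral_karyotype(chrom_ids: Sequence[str], genes_per_chrom: int = 100,
                        node_label: str = "ancestor") -> Karyotype:
    """A pristine karyotype: each chromosome one full-length own segment."""
    return Karyotype(node_label, [
        Chromosome(cid, [AncestralSegment(cid, 0, genes_per_chrom)])
        for cid in chrom_ids
    ])


# ---------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class KaryotypeEvent:
    kind: str  # WGT | WGD | X | EJ | NCF | INV | LOSS | REN | NODE
    operands: tuple[str, ...] = ()
    breakpoints: tuple[int, ...] = ()
    products: tuple[str, ...] = ()
    span: tuple[int, int] | None = None  # INV range

    def __str__(self) -> str:
        if self.kind in {"WGT", "WGD"}:
            return self.kind
        if self.kind == "NODE":
            return f"NODE {self.operands[0]}"
        if self.kind == "LOSS":
            return f"LOSS {self.operands[0]}"
        if self.kind == "REN":
            return f"REN {self.operands[0]} {self.products[0]}"
        if self.kind == "INV":
            return f"INV {self.operands[0]} {self.span[0]}..{self.span[1]}"
        if self.kind == "X":
            return (f"X {self.operands[0]}@{self.breakpoints[0]} "
                    f"{self.operands[1]}@{self.breakpoints[1]} -> "
                    f"{self.products[0]} {self.products[1]}")
        if self.kind == "EJ":
            return (f"EJ {self.operands[0]} {self.operands[1]} -> "
                    f"{self.products[0]} +{self.products[1]}")
        if self.kind == "NCF":
            return (f"NCF {self.operands[0]} {self.operands[1]}@"
                    f"{self.breakpoints[0]} -> {self.products[0]} "
                    f"+{self.products[1]}")
        raise ValueError(self.kind)


_WGX_SUFFIXES = {"WGD": "ab", "WGT": "abc"}


def apply_event(k: Karyotype, e: KaryotypeEvent) -> Karyotype:
    """Apply one event, returning a new karyotype (input untouched)."""
    k = _apply_event(k, e)
    for c in k.chromosomes.values():
        c.normalize()
    return k


def _apply_event(k: Karyotype, e: KaryotypeEvent) -> Karyotype:
    k = k.copy()
    if e.kind in _WGX_SUFFIXES:
        suffixes = _WGX_SUFFIXES[e.kind]
        old = [c for c in k.chromosomes.values() if not c.is_satellite]
        for c in old:
            k.pop(c.id)
        for c in old:
            for suf in suffixes:
                k.add(Chromosome(c.id + suf, list(c.segments)))
        return k
    if e.kind == "NODE":
        k.node_label = e.operands[0]
        return k
    if e.kind == "REN":
        c = k.pop(e.operands[0])
        k.add(Chromosome(e.products[0], c.segments, c.is_satellite))
        return k
    if e.kind == "LOSS":
        c = k[e.operands[0]] if e.operands[0] in k else None
        if c is None:
            raise KeyError(f"unknown chromosome {e.operands[0]!r}")
        if not c.is_satellite:
            raise ValueError(f"LOSS target {c.id!r} is not a satellite")
        k.pop(c.id)
        return k
    if e.kind == "INV":
        c = k[e.operands[0]]
        lo, hi = e.span
        left, rest = c.split(lo)
        mid, right = Chromosome("tmp", rest).split(hi - lo)
        c.segments = left + [s.reverse() for s in reversed(mid)] + right
        return k
    if e.kind == "X":
        c1, c2 = k.pop(e.operands[0]), k.pop(e.operands[1])
        l1, r1 = c1.split(e.breakpoints[0])
        l2, r2 = c2.split(e.breakpoints[1])
        k.add(Chromosome(e.products[0], l1 + r2))
        k.add(Chromosome(e.products[1], l2 + r1))
        return k
    if e.kind == "EJ":
        c1, c2 = k.pop(e.operands[0]), k.pop(e.operands[1])
        k.add(Chromosome(e.products[0], c1.segments + c2.segments))
        k.add(Chromosome(e.products[1], [], is_satellite=True))
        return k
    if e.kind == "NCF":
        inner, outer = k.pop(e.operands[0]), k.pop(e.operands[1])
        left, right = outer.split(e.breakpoints[0])
        k.add(Chromosome(e.products[0], left + inner.segments + right))
        k.add(Chromosome(e.products[1], [], is_satellite=True))
        return k
    raise ValueError(f"unknown event kind {e.kind!r}")


# ---------------------------------------------------------------------------
# DSL


def parse_event(line: str) -> KaryotypeEvent:
    """Parse one DSL line (see module docstring for the grammar)."""
    toks = line.split()
    kind = toks[0].upper().rstrip(".")
    if kind in {"WGD", "WGT"}:
        return KaryotypeEvent(kind)
    if kind == "NODE":
        return KaryotypeEvent("NODE", operands=(toks[1],))
    if kind == "LOSS":
        return KaryotypeEvent("LOSS", operands=(toks[1],))
    if kind == "REN":
        return KaryotypeEvent("REN", operands=(toks[1],), products=(toks[2],))
    if kind == "INV":
        lo, hi = toks[2].split("..")
        return KaryotypeEvent("INV", operands=(toks[1],), span=(int(lo), int(hi)))
    if kind == "X":
        (c1, p1), (c2, p2) = (t.split("@") for t in toks[1:3])
        assert toks[3] == "->"
        return KaryotypeEvent("X", operands=(c1, c2),
                              breakpoints=(int(p1), int(p2)),
                              products=(toks[4], toks[5]))
    if kind == "EJ":
        assert toks[3] == "->"
        return KaryotypeEvent("EJ", operands=(toks[1], toks[2]),
                              products=(toks[4], toks[5].lstrip("+")))
    if kind == "NCF":
        c2, p = toks[2].split("@")
        assert toks[3] == "->"
        return KaryotypeEvent("NCF", operands=(toks[1], c2),
                              breakpoints=(int(p),),
                              products=(toks[4], toks[5].lstrip("+")))
    raise ValueError(f"cannot parse event line: {line!r}")


@dataclass
class EventScript:
    events: list[KaryotypeEvent]

    @classmethod
    def parse(cls, text: str) -> "EventScript":
        events = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                events.append(parse_event(line))
            except Exception as exc:
                raise ValueError(f"script line {lineno}: {exc}") from exc
        return cls(events)

    @classmethod
    def load(cls, path: str | Path) -> "EventScript":
        return cls.parse(Path(path).read_text())

    def dump(self) -> str:
        return "\n".join(str(e) for e in self.events) + "\n"

    @property
    def checkpoints(self) -> list[str]:
        return [e.operands[0] for e in self.events if e.kind == "NODE"]


def replay_script(initial: Karyotype, script: EventScript
                  ) -> dict[str, Karyotype]:
    """Replay a script from an initial karyotype, snapshotting each NODE.

    If the script's first event is a NODE it must match the initial
    karyotype's label.  Raises with the failing event index on error.
    """
    if script.events and script.events[0].kind == "NODE":
        if initial.node_label and initial.node_label != script.events[0].operands[0]:
            raise ValueError(
                f"initial node {initial.node_label!r} != script start "
                f"{script.events[0].operands[0]!r}")
    snapshots: dict[str, Karyotype] = {}
    k = initial.copy()
    if not script.events or script.events[0].kind != "NODE":
        snapshots[initial.node_label or "initial"] = k.copy()
    for i, e in enumerate(script.events):
        try:
            k = apply_event(k, e)
        except Exception as exc:
            raise RuntimeError(f"event {i + 1} ({e}): {exc}") from exc
        if e.kind == "NODE":
            snapshots[e.operands[0]] = k.copy()
    return snapshots


# ---------------------------------------------------------------------------
# correspondence and merge timing


def correspondence_profile(blocks: Iterable[CollinearBlock], min_anchors: int = 1
                           ) -> dict[str, set[str]]:
    """Per target chromosome, the reference chromosomes it corresponds to
    (with at least ``min_anchors`` anchors in some block).

    Blocks are expected reference-vs-target (genome_a = reference).
    """
    profile: dict[str, set[str]] = {}
    for b in blocks:
        if len(b.anchors) < min_anchors:
            continue
        profile.setdefault(b.chromosome_b, set()).add(b.chromosome_a)
    return profile


def combination_counts(profile: Mapping[str, set[str]], size: int = 2
                       ) -> dict[frozenset[str], int]:
    """For every size-``size`` reference-chromosome combination, the number of
    distinct target chromosomes on which it co-occurs."""
    counts: dict[frozenset[str], int] = {}
    for refs in profile.values():
        for combo in combinations(sorted(refs), size):
            key = frozenset(combo)
            counts[key] = counts.get(key, 0) + 1
    return counts


def infer_merge_timing(counts: Mapping[frozenset[str], int],
                       ploidy_series: Sequence[int] = (2, 2)
                       ) -> dict[frozenset[str], str]:
    """Parsimony timing of ancestral-chromosome mergers from co-occurrence
    counts.

    With two successive duplications (x2, x2): a combination present on 4
    target chromosomes predates both (pre-first); on 2, it arose between
    them; on 1, after the last.  Other counts are flagged ambiguous.  The
    thresholds generalise to the running product of ``ploidy_series``.
    """
    # cumulative copy numbers newest-first: 1, m_last, m_last*m_prev, ...
    cum = [1]
    for m in reversed(list(ploidy_series)):
        cum.append(cum[-1] * m)
    out: dict[frozenset[str], str] = {}
    for combo, n in counts.items():
        if n == cum[-1]:
            out[combo] = "pre-first"
        elif n == 1:
            out[combo] = "post-last"
        elif n in cum:
            idx = cum.index(n)
            out[combo] = f"between-{idx}"
        else:
            out[combo] = "ambiguous"
    return out


def timing_label_apiaceae(label: str) -> str:
    """Map generic timing labels to the Apiales/Apiaceae event names."""
    return {
        "pre-first": "pre-ω",
        "between-1": "post-ω/pre-α",
        "post-last": "post-α",
    }.get(label, label)


# ---------------------------------------------------------------------------
# packaged trajectory fixture


def load_packaged_trajectory() -> tuple[Karyotype, EventScript]:
    """The shipped Apiales chromosome-evolution trajectory script plus its
    pre-triplication starting karyotype (7 chromosomes, 100 gene units each)."""
    from importlib.resources import files

    text = (files("paleoploid") / "data" / "apiales_trajectory.txt").read_text()
    script = EventScript.parse(text)
    init = ancestral_karyotype([f"E{i}" for i in range(1, 8)],
                               genes_per_chrom=100, node_label="E")
    return init, script


def write_karyotype_tsv(k: Karyotype, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tsegment_index\tsource\tstart\tend\torientation\tis_satellite\n")
        for cid, c in k.chromosomes.items():
            if not c.segments:
                fh.write(f"{cid}\t0\t.\t0\t0\t+\t{int(c.is_satellite)}\n")
            for i, s in enumerate(c.segments):
                fh.write(f"{cid}\t{i}\t{s.source}\t{s.start}\t{s.end}\t"
                         f"{s.orientation}\t{int(c.is_satellite)}\n")
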