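"""Homology table, loss statistics, deletion runs and the geometric fit."""

import re

import numpy as np
import pytest

from paleoploid.collinearity import Anchor, CollinearBlock
from paleoploid.fractionation import (GeometricFit, RunHistogram,
                                      build_homology_table,
                                      combined_run_histogram,
                                      deletion_run_histogram, fit_geometric,
                                      homology_depth, loss_rate,
                                      translocation_fraction)
from paleoploid.io import GeneLocus, GeneSet, HomologPair, MISSING


def _ref(n=10, chrom="r1", genome="ref"):
    return GeneSet(genome, [GeneLocus(f"{genome}_{chrom}_{i}", genome, chrom,
                                      i * 100, i * 100 + 50)
                            for i in range(n)])


def _block(ref, tgt_genes, ref_start=0, chrom="r1", bid=0):
    anchors = [Anchor(ref.loci(chrom)[ref_start + i].gene_id, g,
                      ref_start + i, i)
               for i, g in enumerate(tgt_genes)]
    return CollinearBlock("ref", "tgt", chrom, "t1", anchors, "parallel",
                          block_id=bid)


class TestTableConstruction:
    def test_single_block_fills_one_column(self):
        ref = _ref(10)
        blk = _block(ref, [f"t{i}" for i in range(6)], ref_start=1)
        table = build_homology_table(ref, {"tgt": [blk]}, {"tgt": 1})
        col = table.column("tgt", 0)
        assert col.count(MISSING) == 4
        assert col[1:7] == [f"t{i}" for i in range(6)]

    def test_overlapping_blocks_take_distinct_columns(self):
        ref = _ref(10)
        b1 = _block(ref, [f"x{i}" for i in range(6)], ref_start=0, bid=0)
        b2 = _block(ref, [f"y{i}" for i in range(5)], ref_start=3, bid=1)
        table = build_homology_table(ref, {"tgt": [b1, b2]}, {"tgt": 2})
        c0, c1 = table.cells("tgt")
        # larger block placed first, overlapping smaller one in column 2
        assert c0[0:6] == [f"x{i}" for i in range(6)]
        assert c1[3:8] == [f"y{i}" for i in range(5)]

    def test_no_blocks_all_dots(self):
        ref = _ref(5)
        table = build_homology_table(ref, {"tgt": []}, {"tgt": 3})
        assert all(cell == MISSING for col in table.cells("tgt") for cell in col)

    def test_conservation_dots_plus_genes(self, wgd_dataset, wgd_blocks):
        ref = wgd_dataset.gene_sets["reference"]
        table = build_homology_table(ref, {"focal": wgd_blocks}, {"focal": 2})
        cols = table.cells("focal")
        dots = sum(c.count(MISSING) for c in cols)
        filled = sum(len(c) - c.count(MISSING) for c in cols)
        assert dots + filled == table.n_rows * 2

    def test_unknown_reference_gene_raises(self):
        ref = _ref(5)
        bad = CollinearBlock("ref", "tgt", "r1", "t1",
                             [Anchor("ghost", "t0", 0, 0)] * 1, "parallel")
        with pytest.raises(ValueError, match="ghost"):
            build_homology_table(ref, {"tgt": [bad]}, {"tgt": 1})


class TestDepthAndLoss:
    def test_two_wgd_no_loss_modal_depth_four(self):
        from paleoploid.collinearity import (CollinearityParams, detect_blocks,
                                             filter_families)
        from paleoploid.simulate import (SimulationConfig, TimelineEvent,
                                         simulate_dataset)

        cfg = SimulationConfig(
            seed=21, n_chromosomes=3, genes_per_chromosome=50,
            codons_per_gene=30, spurious_pair_fraction=0.0,
            timeline=[
                TimelineEvent("speciation", 90.0, "root", label="s",
                              children=("reference", "focal")),
                TimelineEvent("wgd", 60.0, "focal", label="w1"),
                TimelineEvent("wgd", 30.0, "focal", label="w2"),
            ])
        ds = simulate_dataset(cfg)
        blocks = detect_blocks(
            filter_families(ds.pairs[("focal", "reference")], 60),
            ds.gene_sets["reference"], ds.gene_sets["focal"],
            CollinearityParams())
        table = build_homology_table(ds.gene_sets["reference"],
                                     {"focal": blocks}, {"focal": 4})
        hist, modal = homology_depth(table, "focal")
        assert modal == 4
        assert hist[4] >= 0.95 * table.n_rows

    def test_random_deletion_depth_matches_binomial(self, rng):
        ref = _ref(500)
        cols = []
        for ci in range(2):
            genes = [f"c{ci}_{i}" if rng.random() > 0.5 else MISSING
                     for i in range(500)]
            cols.append(genes)
        table = build_homology_table(ref, {"tgt": []}, {"tgt": 2})
        table.columns["tgt"] = cols
        hist, _ = homology_depth(table, "tgt")
        # depth ~ Binomial(2, 0.5): expect 125/250/125
        assert hist[1] == pytest.approx(250, abs=40)
        assert abs(hist[0] - hist[2]) < 60

    def test_loss_rate_arithmetic(self):
        ref = _ref(10)
        table = build_homology_table(ref, {"tgt": []}, {"tgt": 4})
        # fill 12 of 40 cells -> 28 dots -> 0.70
        cells = table.cells("tgt")
        n = 0
        for ci in range(4):
            for ri in range(10):
                if n < 12:
                    cells[ci][ri] = f"g{n}"
                    n += 1
        assert loss_rate(table, "tgt") == pytest.approx(0.70)

    def test_no_dots_zero_loss(self):
        ref = _ref(4)
        blk = _block(ref, list("abcd"))
        table = build_homology_table(ref, {"tgt": [blk]}, {"tgt": 1})
        assert loss_rate(table, "tgt") == 0.0

    def test_unknown_genome_raises(self):
        table = build_homology_table(_ref(3), {"tgt": []}, {"tgt": 1})
        with pytest.raises(KeyError):
            loss_rate(table, "nope")


class TestTranslocation:
    def test_all_collinear_zero(self):
        ref = _ref(5)
        blk = _block(ref, list("abcde"))
        table = build_homology_table(ref, {"tgt": [blk]}, {"tgt": 1})
        hits = [HomologPair(ref.loci("r1")[i].gene_id, g, 1)
                for i, g in enumerate("abcde")]
        assert translocation_fraction(hits, table, "tgt") == 0.0

    def test_two_of_ten_noncollinear(self):
        ref = _ref(10)
        blk = _block(ref, [f"t{i}" for i in range(8)])
        table = build_homology_table(ref, {"tgt": [blk]}, {"tgt": 1})
        hits = [HomologPair(ref.loci("r1")[i].gene_id, f"t{i}", 1)
                for i in range(8)]
        hits += [HomologPair(ref.loci("r1")[8].gene_id, "u1", 1),
                 HomologPair(ref.loci("r1")[9].gene_id, "u2", 1)]
        assert translocation_fraction(hits, table, "tgt") == pytest.approx(0.2)


class TestRuns:
    def _table_with_column(self, pattern, chrom_breaks=()):
        """pattern: string of 'G' (gene) and '.' (dot); chrom_breaks are
        indices where a new reference chromosome starts."""
        breaks = set(chrom_breaks)
        loci = []
        chrom = 0
        pos = 0
        for i in range(len(pattern)):
            if i in breaks:
                chrom += 1
                pos = 0
            loci.append(GeneLocus(f"r{i}", "ref", f"chr{chrom}",
                                  pos * 10, pos * 10 + 5))
            pos += 1
        ref = GeneSet("ref", loci)
        table = build_homology_table(ref, {"tgt": []}, {"tgt": 1})
        # rows are sorted chromosome-then-rank; chromosome names chosen so
        # lexicographic order matches construction order
        col = [f"g{i}" if ch == "G" else MISSING for i, ch in enumerate(pattern)]
        table.columns["tgt"] = [col]
        return table

    def test_hand_pattern(self):
        table = self._table_with_column("G.G..G")
        h = deletion_run_histogram(table, "tgt", 0)
        assert h.counts == {1: 1, 2: 1}
        assert h.short_run_gene_fraction == 1.0
        assert h.end_runs == 0

    def test_all_dots_is_one_end_run(self):
        table = self._table_with_column("....")
        h = deletion_run_histogram(table, "tgt", 0)
        assert h.counts == {} and h.end_runs == 1

    def test_runs_do_not_cross_chromosomes(self):
        # dots at the end of chr0 and the start of chr1 are separate end
        # runs, never one bordered run of length 4
        table = self._table_with_column("G....G", chrom_breaks=(3,))
        h = deletion_run_histogram(table, "tgt", 0)
        assert h.counts == {}
        assert h.end_runs == 2

    def test_matches_regex_oracle(self, rng):
        pattern = "".join(rng.choice(list("G."), size=400, p=[0.6, 0.4]))
        table = self._table_with_column(pattern)
        h = deletion_run_histogram(table, "tgt", 0)
        oracle = {}
        for m in re.finditer(r"(?<=G)(\.+)(?=G)", pattern):
            L = len(m.group(1))
            oracle[L] = oracle.get(L, 0) + 1
        assert h.counts == oracle

    def test_genes_in_runs_identity(self, rng):
        pattern = "".join(rng.choice(list("G."), size=200))
        table = self._table_with_column(pattern)
        h = deletion_run_histogram(table, "tgt", 0)
        assert h.genes_in_runs == sum(L * n for L, n in h.counts.items())


class TestGeometricFit:
    def test_all_singletons_p_zero(self):
        fit = fit_geometric([1, 1, 1, 1])
        assert fit.p == 0.0 and fit.mean_length == 1.0

    def test_closed_form_mean_two(self):
        fit = fit_geometric([2, 2])
        assert fit.p == pytest.approx(0.5)

    def test_mle_identity(self, rng):
        lengths = rng.geometric(0.4, size=500).tolist()
        fit = fit_geometric(lengths)
        assert fit.p == pytest.approx(1 - 1 / fit.mean_length)

    def test_recovery_and_grid_likelihood_oracle(self, rng):
        for p_true in (0.2, 0.4, 0.6, 0.8):
            lengths = rng.geometric(1 - p_true, size=2000).tolist()
            fit = fit_geometric(lengths)
            assert fit.p == pytest.approx(p_true, abs=0.03)
            # independent grid-search likelihood maximization
            grid = np.linspace(1e-6, 1 - 1e-6, 200001)
            n = len(lengths)
            s = sum(lengths)
            ll = n * np.log(1 - grid) + (s - n) * np.log(grid)
            p_grid = grid[int(np.argmax(ll))]
            assert fit.p == pytest.approx(p_grid, abs=1e-4)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fit_geometric([])

    def test_bias_and_rmse_across_p(self):
        rng = np.random.default_rng(99)
        for p_true in (0.2, 0.4, 0.6, 0.8):
            est = []
            for _ in range(50):
                lengths = rng.geometric(1 - p_true, size=1000)
                est.append(fit_geometric(lengths.tolist()).p)
            est = np.array(est)
            assert abs(est.mean() - p_true) < 0.01
            assert np.sqrt(np.mean((est - p_true) ** 2)) < 0.03


def test_pipeline_recovers_fractionation_parameter():
    """Blocks -> table -> runs -> fit recovers the generator's extension
    parameter when deletion is light enough that runs rarely merge."""
    from paleoploid.collinearity import (CollinearityParams, detect_blocks,
                                         filter_families)
    from paleoploid.simulate import fractionation_scenario, simulate_dataset

    ds = simulate_dataset(fractionation_scenario(
        seed=5, retention=0.9, p=0.4, genes_per_chromosome=300))
    blocks = detect_blocks(filter_families(ds.pairs[("focal", "reference")]),
                           ds.gene_sets["reference"], ds.gene_sets["focal"],
                           CollinearityParams())
    table = build_homology_table(ds.gene_sets["reference"],
                                 {"focal": blocks}, {"focal": 2})
    fit = fit_geometric(combined_run_histogram(table, "focal"))
    assert fit.p == pytest.approx(0.4, abs=0.05)
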