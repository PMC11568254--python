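"""Recombinant-gene classification, segments, windows, group fractions,
functional bias."""

import numpy as np
import pandas as pd
import pytest

from rbmrecomb import (
    NON_RECOMBINANT,
    RECOMBINANT_PAIR,
    RECOMBINANT_THIRD,
    RBMCollection,
    RBMPair,
    RBMTable,
    SimConfig,
    build_segments,
    classify_genes,
    cog_bias,
    f100,
    generate_ancestral,
    group_identical_fraction,
    group_members,
    make_daughter,
    plant_recombination,
    windowed_recombination,
)
from rbmrecomb.ani_units import UnitAssignment
from rbmrecomb.recomb import fig_groups_table

from conftest import make_genome, random_gene


def _pair(ga, gb, identity, aln=1000, start=0):
    mism = round(aln * (1 - identity / 100.0))
    return RBMPair(ga, gb, 100.0 * (aln - mism) / aln, aln, mism, "c1",
                   start, start + aln)


def _table(genome_a, genome_b, idents, prefix_a="a", prefix_b="b"):
    pairs = [_pair(f"{prefix_a}{i}", f"{prefix_b}{i}", ident, start=1010 * i)
             for i, ident in enumerate(idents)]
    return RBMTable(genome_a, genome_b, pairs)


class TestClassifyGenes:
    def _collection(self):
        # focal pair (A, B); third genome C reached via tables (A,C) and (B,C)
        t_ab = _table("A", "B", [99.9, 99.0, 99.0, 97.0], "a", "b")
        t_ac = _table("A", "C", [99.0, 99.9, 99.5, 98.0], "a", "c")
        t_bc = _table("B", "C", [99.0, 99.0, 99.0, 98.0], "b", "c")
        return t_ab, RBMCollection([t_ab, t_ac, t_bc])

    def test_threshold_and_third_partner_rules(self):
        t_ab, coll = self._collection()
        cls = classify_genes(t_ab, coll, theta=99.8)
        by_gene = cls.set_index("gene_a")
        assert by_gene.loc["a0", "klass"] == RECOMBINANT_PAIR  # 99.9 >= theta
        # a1: pair 99.0 but 99.9 to C -> third-partner recombinant
        assert by_gene.loc["a1", "klass"] == RECOMBINANT_THIRD
        assert by_gene.loc["a1", "partner_genome"] == "C"
        assert by_gene.loc["a1", "partner_identity"] == pytest.approx(99.9)
        # a2: best third is 99.5 < theta -> non-recombinant
        assert by_gene.loc["a2", "klass"] == NON_RECOMBINANT
        assert by_gene.loc["a3", "klass"] == NON_RECOMBINANT

    def test_classification_partitions_rbm_pairs(self):
        t_ab, coll = self._collection()
        cls = classify_genes(t_ab, coll, theta=99.8)
        counts = cls.klass.value_counts()
        assert counts.sum() == len(t_ab.pairs)
        assert set(cls.klass) <= {RECOMBINANT_PAIR, RECOMBINANT_THIRD,
                                  NON_RECOMBINANT}

    def test_inclusive_threshold(self):
        t = _table("A", "B", [99.8])
        cls = classify_genes(t, None, theta=99.8)
        assert cls.klass.iloc[0] == RECOMBINANT_PAIR

    def test_invalid_theta_rejected(self):
        t = _table("A", "B", [99.0])
        for theta in (90.0, 100.1, 50.0):
            with pytest.raises(ValueError):
                classify_genes(t, None, theta=theta)


class TestF100:
    def test_identical_genomes_score_1(self):
        assert f100(_table("A", "B", [100.0, 100.0, 100.0])) == 1.0

    def test_no_identical_pairs_score_0(self):
        assert f100(_table("A", "B", [99.9, 99.0])) == 0.0

    def test_theta_variant_and_symmetry(self, small_population):
        from rbmrecomb import compute_rbm

        a, b = small_population["genomes"][1:3]
        t_ab, t_ba = compute_rbm(a, b), compute_rbm(b, a)
        for theta in (100.0, 99.8):
            assert f100(t_ab, theta) == f100(t_ba, theta)
        assert f100(t_ab, 99.8) >= f100(t_ab, 100.0)

    def test_empty_table_undefined(self):
        with pytest.raises(ValueError):
            f100(RBMTable("A", "B", []))


def _units(rows):
    return UnitAssignment(
        pd.DataFrame(rows, columns=["genome_id", "genomovar", "phylogroup",
                                    "species"]),
        99.5, 98.0, 95.0)


class TestGroups:
    UNITS = _units([
        ("A", "g1", "p1", "s1"), ("A2", "g1", "p1", "s1"),
        ("B1", "g2", "p1", "s1"), ("B2", "g2", "p1", "s1"),
        ("C1", "g3", "p2", "s1"),
        ("D1", "g4", "p3", "s2"),
    ])

    def test_group_definitions(self):
        gm = lambda grp: group_members(self.UNITS, "A", grp)
        assert gm("A") == [("g1", ["A2"])]
        assert gm("B") == [("g2", ["B1", "B2"])]
        assert gm("C") == [("g3", ["C1"])]
        assert gm("D") == [("other_species", ["D1"])]
        assert gm("E") == [("p1", ["B1", "B2"])]
        assert gm("F") == [("s1", ["C1"])]

    def test_identical_copy_group_gives_fraction_1(self):
        rng = np.random.default_rng(11)
        g1 = make_genome("A", [random_gene(rng) for _ in range(6)])
        g2 = make_genome("B", [g.sequence for g in g1.genes])
        coll = RBMCollection.compute([g1, g2])
        assert group_identical_fraction(g1, ["B"], coll) == 1.0

    def test_union_monotonicity(self, small_population):
        """Adding a partner to the group never decreases the cumulative
        fraction, and the union is >= the best single partner."""
        genomes = small_population["genomes"][1:5]
        coll = RBMCollection.compute(genomes)
        focal = genomes[0]
        others = [g.genome_id for g in genomes[1:]]
        singles = [group_identical_fraction(focal, [m], coll, theta=99.8)
                   for m in others]
        prev = 0.0
        for i in range(1, len(others) + 1):
            frac = group_identical_fraction(focal, others[:i], coll, theta=99.8)
            assert frac >= prev - 1e-12
            prev = frac
        assert prev >= max(singles)

    def test_rbm_denominator_at_least_genome_denominator(self, small_population):
        genomes = small_population["genomes"][1:4]
        coll = RBMCollection.compute(genomes)
        focal = genomes[0]
        others = [g.genome_id for g in genomes[1:]]
        g_frac = group_identical_fraction(focal, others, coll, denominator="genome")
        r_frac = group_identical_fraction(focal, others, coll, denominator="rbm")
        assert r_frac >= g_frac

    def test_fig_groups_table_skips_empty_groups(self):
        rng = np.random.default_rng(12)
        seqs = [random_gene(rng) for _ in range(5)]
        genomes = [make_genome(n, seqs) for n in ("A", "A2")]
        coll = RBMCollection.compute(genomes)
        units = _units([("A", "g1", "p1", "s1"), ("A2", "g1", "p1", "s1")])
        table = fig_groups_table(genomes, coll, units)
        assert set(table.group) == {"A"}  # only same-genomovar partners exist
        assert (table.fraction == 1.0).all()


class TestSegments:
    def _classified(self, idents, genome):
        t = RBMTable("A", "B", [
            RBMPair(g.gene_id, g.gene_id.replace("g", "h"),
                    100.0 * (1000 - round(1000 * (1 - ident / 100))) / 1000,
                    1000, round(1000 * (1 - ident / 100)), g.contig_id,
                    g.start, g.end)
            for g, ident in zip(genome.genes, idents) if ident is not None
        ])
        return classify_genes(t, None, theta=99.8)

    def test_single_run_detected(self):
        genome = make_genome("A", ["ACGT" * 250] * 5)
        cls = self._classified([99.0, 100.0, 100.0, 100.0, 99.0], genome)
        segments, hist = build_segments(cls, genome)
        assert len(segments) == 1
        assert segments[0].gene_count == 3
        assert segments[0].first_gene == "g002" and segments[0].last_gene == "g004"
        assert hist.set_index("gene_count").loc[3, "n_segments"] == 1

    def test_span_arithmetic(self):
        genome = make_genome("A", ["A" * 1000, "C" * 1000], spacer="T" * 10)
        cls = self._classified([100.0, 100.0], genome)
        segments, _ = build_segments(cls, genome)
        assert segments[0].span_bp == 2010  # genes at 0-1000 and 1010-2010

    def test_non_rbm_gene_breaks_run(self):
        """A gene absent from the partner splits an otherwise contiguous
        run of recombinant genes."""
        genome = make_genome("A", ["ACGT" * 250] * 5)
        cls = self._classified([100.0, 100.0, None, 100.0, 100.0], genome)
        segments, _ = build_segments(cls, genome)
        assert [s.gene_count for s in segments] == [2, 2]

    def test_segment_gene_counts_sum_to_recombinant_count(self, small_population):
        from rbmrecomb import compute_rbm

        genomes = small_population["genomes"]
        a = genomes[5]  # a 99.5-target daughter: plenty of >=99.8 genes
        b = genomes[6]
        t = compute_rbm(a, b)
        cls = classify_genes(t, None, theta=99.8)
        segments, _ = build_segments(cls, a)
        n_rec = (cls.klass == RECOMBINANT_PAIR).sum()
        assert sum(s.gene_count for s in segments) == n_rec

    def test_planted_tract_recovered_exactly(self):
        """A single 3-gene tract planted into a diverged pair is recovered as
        exactly one segment covering those genes (no background at ANI 97 in
        degenerate mode)."""
        cfg = SimConfig(n_genes=60, degenerate=True, seed=31)
        anc = generate_ancestral(cfg)
        a = make_daughter(anc, "A", 98.5, cfg, np.random.default_rng(1)).genome
        b = make_daughter(anc, "B", 98.5, cfg, np.random.default_rng(2)).genome
        planted, events = plant_recombination(a, b, n_events=1,
                                              tract_gene_count_dist=3, seed=5)
        from rbmrecomb import compute_rbm

        cls = classify_genes(compute_rbm(planted, b), None, theta=99.8)
        segments, _ = build_segments(cls, planted)
        assert len(segments) == 1
        assert segments[0].gene_count == 3
        assert ",".join(
            g.gene_id for g in planted.genes[segments[0].first_index:
                                             segments[0].last_index + 1]
        ) == events.gene_ids.iloc[0]


class TestWindows:
    def test_no_recombinant_genes_gives_zero_everywhere(self):
        genome = make_genome("A", ["ACGT" * 250] * 30)
        t = RBMTable("A", "B", [
            RBMPair(g.gene_id, g.gene_id, 99.0, 1000, 10, g.contig_id,
                    g.start, g.end) for g in genome.genes])
        cls = classify_genes(t, None)
        win = windowed_recombination(cls, genome, ani=98.0, window=10_000,
                                     step=5_000)
        assert (win.recombinant_bp == 0).all()
        assert (win.rm_ratio == 0).all()

    def test_planted_tract_confined_to_overlapping_windows(self):
        cfg = SimConfig(n_genes=120, degenerate=True, seed=32)
        anc = generate_ancestral(cfg)
        a = make_daughter(anc, "A", 98.5, cfg, np.random.default_rng(3)).genome
        b = make_daughter(anc, "B", 98.5, cfg, np.random.default_rng(4)).genome
        planted, events = plant_recombination(a, b, n_events=1,
                                              tract_gene_count_dist=4, seed=6)
        from rbmrecomb import compute_rbm

        cls = classify_genes(compute_rbm(planted, b), None)
        win = windowed_recombination(cls, planted, ani=97.0, window=20_000,
                                     step=10_000)
        first = planted.genes[int(events.first_gene_index.iloc[0])]
        hot = win.loc[win.recombinant_bp > 0]
        assert len(hot) in (1, 2)  # only the windows overlapping the tract
        for row in hot.itertuples():
            assert row.start <= first.start < row.end + 20_000

    def test_window_below_10kb_rejected(self):
        genome = make_genome("A", ["ACGT" * 250] * 2)
        with pytest.raises(ValueError, match="10 kb"):
            windowed_recombination(pd.DataFrame(columns=["gene_a", "identity",
                                                         "klass"]),
                                   genome, ani=98.0, window=5000)


class TestCogBias:
    def test_hand_computed_chi_square(self):
        """Contingency [[30,70],[10,90]] -> chi2 = 12.5 without correction."""
        cls = pd.DataFrame({
            "gene_a": [f"r{i}" for i in range(100)] + [f"n{i}" for i in range(100)],
            "identity": [100.0] * 100 + [99.0] * 100,
            "klass": [RECOMBINANT_PAIR] * 100 + [NON_RECOMBINANT] * 100,
        })
        ann = {f"r{i}": ("J" if i < 30 else "K") for i in range(100)}
        ann.update({f"n{i}": ("J" if i < 10 else "K") for i in range(100)})
        out = cog_bias(cls, ann).set_index("category")
        assert out.loc["J", "chi2"] == pytest.approx(12.5)
        assert out.loc["J", "enriched"]
        assert out.loc["J", "p_value"] == pytest.approx(
            0.5 * 0.000407, rel=1e-2)  # one-sided

    def test_single_category_degenerate(self):
        cls = pd.DataFrame({
            "gene_a": ["a", "b"], "identity": [100.0, 99.0],
            "klass": [RECOMBINANT_PAIR, NON_RECOMBINANT],
        })
        with pytest.raises(ValueError, match="two categories"):
            cog_bias(cls, {"a": "J", "b": "J"})

    def test_type_i_error_control_under_null(self):
        """Recombinant genes drawn uniformly from the genome's categories:
        the per-category false-positive rate at q<0.05 stays within its
        binomial envelope over 200 simulated draws."""
        rng = np.random.default_rng(77)
        cats = list("JKLMNO")
        n_genes = 300
        ann = {f"g{i}": cats[i % len(cats)] for i in range(n_genes)}
        false_pos = trials = 0
        for _ in range(200):
            rec = rng.random(n_genes) < 0.3  # recombination independent of category
            cls = pd.DataFrame({
                "gene_a": [f"g{i}" for i in range(n_genes)],
                "identity": np.where(rec, 100.0, 99.0),
                "klass": np.where(rec, RECOMBINANT_PAIR, NON_RECOMBINANT),
            })
            out = cog_bias(cls, ann)
            false_pos += int(out.significant.sum())
            trials += len(out)
        rate = false_pos / trials
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)
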