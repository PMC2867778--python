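"""Enrichment, positional, spacing and GO statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from regmotif.core import Genome, Location, LocationSet
from regmotif.fixtures import (
    make_genes_and_go,
    make_genome,
    plant_sites,
    planted_pwm,
)
from regmotif.motif import Background, to_pssm
from regmotif.stats import (
    dinucleotide_shuffle,
    fisher_exact_two_sided,
    go_enrichment,
    library_enrichment,
    motif_enrichment,
    motif_go_association,
    positional_distribution,
    propagate_annotations,
    spacing_analysis,
    best_upstream_scores,
    upstream_region,
)
from regmotif.intervals import GeneModel


class TestFisher:
    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(300):
            n1, n2 = rng.integers(1, 80, size=2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            ours = fisher_exact_two_sided(k1, int(n1), k2, int(n2))
            table = [[k1, int(n1) - k1], [k2, int(n2) - k2]]
            ref = sps.fisher_exact(table).pvalue
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_balanced_table_p_one(self):
        assert fisher_exact_two_sided(10, 20, 10, 20) == pytest.approx(1.0)


class TestDinucShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        seq = "".join(rng.choice(list("ACGT"), size=400))
        shuf = dinucleotide_shuffle(seq, rng)
        count = lambda s: Counter(zip(s, s[1:]))
        assert count(seq) == count(shuf)
        assert shuf != seq  # overwhelmingly likely for 400 bp


def _enrichment_fixture():
    genome = make_genome(20_000, seed=31)
    pwm = planted_pwm()
    genome, sites = plant_sites(
        genome, pwm, 30, seed=32, min_gap=200, consensus_mode=True
    )
    # 50 target windows: 30 around planted sites, 20 empty; 50 clean controls
    targets, controls = [], []
    for loc in sites:
        targets.append(
            Location(loc.sequence_id, max(0, loc.start - 20), loc.end + 20)
        )
    rng = np.random.default_rng(33)
    # carve control/empty windows from a second, unplanted genome region
    clean = make_genome(20_000, seed=34)
    merged = {"chr1": genome["chr1"], "ctrl": clean["chr1"]}
    genome = Genome("g", merged)
    for i in range(20):
        s = 100 + i * 300
        targets.append(Location("ctrl", s, s + 50))
    for i in range(50):
        s = 8000 + i * 200
        controls.append(Location("ctrl", s, s + 50))
    return (
        genome,
        pwm,
        LocationSet("targets", targets),
        LocationSet("controls", controls),
    )


class TestMotifEnrichment:
    def test_targets_equal_controls(self):
        genome, pwm, targets, _ = _enrichment_fixture()
        pssm = to_pssm(pwm, Background.uniform())
        res = motif_enrichment(pssm, targets, targets, genome,
                               [0.5 * pssm.max_score])
        assert res.ratio[0] == pytest.approx(1.0)
        assert res.p[0] == pytest.approx(1.0)

    def test_cutoff_above_max_score(self):
        genome, pwm, targets, controls = _enrichment_fixture()
        pssm = to_pssm(pwm, Background.uniform())
        res = motif_enrichment(pssm, targets, controls, genome,
                               [pssm.max_score + 1])
        assert res.n_target_with_match == [0]
        assert res.p[0] == pytest.approx(1.0)

    def test_planted_counts_and_closed_form_p(self):
        genome, pwm, targets, controls = _enrichment_fixture()
        pssm = to_pssm(pwm, Background.uniform())
        cutoff = 0.9 * pssm.max_score
        res = motif_enrichment(pssm, targets, controls, genome, [cutoff])
        kt, kc = res.n_target_with_match[0], res.n_control_with_match[0]
        assert kt == 30 and kc == 0
        # closed-form hypergeometric two-sided oracle
        m = kt + kc
        probs = np.array(
            [
                math.comb(50, j) * math.comb(50, m - j) / math.comb(100, m)
                for j in range(max(0, m - 50), min(50, m) + 1)
            ]
        )
        obs = probs[kt - max(0, m - 50)]
        expected = probs[probs <= obs * (1 + 1e-9)].sum()
        assert res.p[0] == pytest.approx(expected, rel=1e-9)

    def test_shuffled_control_mode(self):
        genome, pwm, targets, _ = _enrichment_fixture()
        pssm = to_pssm(pwm, Background.uniform())
        res = motif_enrichment(pssm, targets, None, genome,
                               [0.9 * pssm.max_score], shuffle_seed=5)
        assert res.n_control == res.n_target
        assert res.n_target_with_match[0] > res.n_control_with_match[0]

    def test_increasing_cutoffs_required(self):
        genome, pwm, targets, controls = _enrichment_fixture()
        with pytest.raises(ValueError):
            motif_enrichment(pwm, targets, controls, genome, [5.0, 5.0])


class TestLibraryEnrichment:
    def test_single_motif_q_equals_p(self):
        genome, pwm, targets, controls = _enrichment_fixture()
        res = library_enrichment([pwm], targets, controls, genome,
                                 [10.0], background=Background.uniform())
        assert res[0].q[0] == pytest.approx(res[0].p[0])

    def test_planted_motif_ranks_first(self, rng):
        genome, pwm, targets, controls = _enrichment_fixture()
        decoys = [
            planted_pwm("".join(rng.choice(list("ACGT"), size=10)), name=f"d{i}")
            for i in range(9)
        ]
        lib = decoys[:4] + [pwm] + decoys[4:]
        results = library_enrichment(
            lib, targets, controls, genome,
            lambda m: [0.9 * to_pssm(m, Background.uniform()).max_score],
            background=Background.uniform(),
        )
        best = min(results, key=lambda r: (r.q[0], r.p[0]))
        assert best.motif == pwm.name


class TestPositionalDistribution:
    def _anchors(self, n=20, width=200):
        return LocationSet(
            "anchors",
            [Location("c", i * 1000, i * 1000 + width) for i in range(n)],
        )

    def test_concentrated_matches_tiny_p(self):
        anchors = self._anchors()
        matches = LocationSet(
            "m",
            [
                Location("c", int(a.midpoint) - 2, int(a.midpoint) + 3)
                for a in anchors
                for _ in range(5)
            ],
            sort=False,
        )
        res = positional_distribution(matches, anchors)
        assert res.n == 100
        assert res.pvalue < 1e-6

    def test_uniform_null_calibration(self):
        anchors = self._anchors()
        rng = np.random.default_rng(99)
        hits = 0
        reps = 100
        for _ in range(reps):
            # width-1 matches at uniform integer positions: midpoints are
            # exactly uniform over the anchor lattice (wider matches cannot
            # reach the outer bins, which would bias the edge bin counts)
            matches = LocationSet(
                "m",
                [
                    Location("c", p, p + 1)
                    for a in anchors
                    for p in rng.integers(a.start, a.end, size=50)
                ],
                sort=False,
            )
            res = positional_distribution(matches, anchors)
            hits += res.pvalue <= 0.01
        assert hits / reps <= 0.015 + 0.02  # 1.5x nominal plus binomial noise

    def test_distance_to_point_mode(self):
        anchors = self._anchors(n=10)
        matches = LocationSet(
            "m",
            [Location("c", a.start + 10, a.start + 15) for a in anchors] * 3,
            sort=False,
        )
        res = positional_distribution(matches, anchors, mode="distance_to_point")
        assert res.n == 30

    def test_single_match_rejected(self):
        anchors = self._anchors(2)
        with pytest.raises(ValueError):
            positional_distribution(
                LocationSet("m", [Location("c", 5, 10)]), anchors
            )

    def test_underpowered_flagged(self):
        anchors = self._anchors(3)
        matches = LocationSet(
            "m", [Location("c", 10, 15), Location("c", 1010, 1015)], sort=False
        )
        assert positional_distribution(matches, anchors).underpowered


class TestSpacing:
    def _planted(self, gap=30, n=100, seq_len=200_000, seed=1):
        rng = np.random.default_rng(seed)
        a, b = [], []
        starts = rng.choice(seq_len // 200, size=n, replace=False) * 200
        for s in starts:
            a.append(Location("c", int(s), int(s) + 10))
            b.append(Location("c", int(s) + 10 + gap, int(s) + 20 + gap))
        return LocationSet("a", a), LocationSet("b", b), {"c": seq_len}

    def test_planted_gap_detected(self):
        a, b, lens = self._planted()
        res = spacing_analysis(a, b, max_gap=100, window=5, n_permutations=500,
                               seed=2, sequence_lengths=lens)
        w30 = 30 // 5
        assert res.q[w30] == res.q.min()
        assert res.q[w30] <= 0.05
        assert res.gap_histogram[30] == 100
        assert res.gap_histogram.sum() == res.n_pairs == 100

    def test_self_pairs_excluded(self):
        single = LocationSet("a", [Location("c", 10, 20)])
        res = spacing_analysis(single, single, max_gap=50, window=5,
                               n_permutations=10, seed=0,
                               sequence_lengths={"c": 1000})
        assert res.empty and res.n_pairs == 0

    def test_null_no_detection(self):
        rng = np.random.default_rng(7)
        clean = 0
        reps = 10
        for r in range(reps):
            a = LocationSet(
                "a",
                [Location("c", int(s), int(s) + 10)
                 for s in rng.integers(0, 49_000, size=40)],
            )
            b = LocationSet(
                "b",
                [Location("c", int(s), int(s) + 10)
                 for s in rng.integers(0, 49_000, size=40)],
            )
            res = spacing_analysis(a, b, max_gap=100, window=5,
                                   n_permutations=300, seed=r,
                                   sequence_lengths={"c": 50_000})
            clean += not (res.q <= 0.05).any()
        assert clean >= 8


class TestGO:
    def _fixture(self):
        universe = [f"g{i}" for i in range(20)]
        annotations = {g: {"T"} for g in universe[:5]}
        ancestry = {"T": {"root"}, "root": set()}
        return universe, annotations, ancestry

    def test_closed_form_worked_example(self):
        universe, annotations, ancestry = self._fixture()
        res = go_enrichment(universe[:5], annotations, ancestry, universe)
        by_term = {r.term: r for r in res}
        assert by_term["T"].p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert by_term["T"].k == 5 and by_term["T"].K == 5

    def test_no_annotated_study_genes_empty(self):
        universe, annotations, ancestry = self._fixture()
        assert go_enrichment(universe[10:15], annotations, ancestry, universe) == []

    def test_universal_term_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        annotations = {g: {"ALL"} for g in universe}
        res = go_enrichment(universe[:3], annotations, {"ALL": set()}, universe)
        assert res[0].p == pytest.approx(1.0)

    def test_propagation_monotone_on_random_dag(self, rng):
        terms = [f"t{i}" for i in range(15)]
        ancestry = {}
        for i, t in enumerate(terms):
            # parents only among earlier terms -> acyclic by construction
            k = int(rng.integers(0, min(i, 3) + 1))
            ancestry[t] = set(rng.choice(terms[:i], size=k, replace=False)) if i else set()
        genes = [f"g{i}" for i in range(40)]
        annotations = {
            g: set(rng.choice(terms, size=int(rng.integers(1, 4)), replace=False))
            for g in genes
        }
        full = propagate_annotations(annotations, ancestry)
        counts = {}
        for g in genes:
            for t in full[g]:
                counts[t] = counts.get(t, 0) + 1
        for t, parents in ancestry.items():
            for p in parents:
                assert counts.get(p, 0) >= counts.get(t, 0)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            propagate_annotations({"g": {"a"}}, {"a": {"b"}, "b": {"a"}})

    def test_study_outside_universe_rejected(self):
        universe, annotations, ancestry = self._fixture()
        with pytest.raises(ValueError):
            go_enrichment(["nope"], annotations, ancestry, universe)


class TestUpstreamAnalyses:
    def _fixture(self):
        genome = make_genome(10_000, seed=61)
        genes, annotations, ancestry = make_genes_and_go(
            genome, n_genes=20, n_terms=3, enriched_term_size=10, seed=62
        )
        pwm = planted_pwm()
        # plant the motif upstream of exactly the 10 term_1-annotated genes
        seq = list(genome["chr1"])
        for gene in genes[:10]:
            region = upstream_region(gene, genes, genome, 150)
            mid = (region.start + region.end) // 2
            seq[mid : mid + 10] = pwm.consensus()
        genome = Genome("g", {"chr1": "".join(seq)})
        return genome, genes, annotations, ancestry, pwm

    def test_planted_term_ranks_first(self):
        genome, genes, annotations, ancestry, pwm = self._fixture()
        pssm = to_pssm(pwm, Background.uniform())
        res = motif_go_association(
            pssm, genes, genome, upstream_bp=150,
            score_cutoff=0.9 * pssm.max_score,
            annotations=annotations, ancestry=ancestry,
            background=Background.uniform(),
        )
        assert res[0].term == "term_1"
        assert res[0].k == 10

    def test_cutoff_above_max_empty(self):
        genome, genes, annotations, ancestry, pwm = self._fixture()
        pssm = to_pssm(pwm, Background.uniform())
        assert motif_go_association(
            pssm, genes, genome, 150, pssm.max_score + 5,
            annotations, ancestry, background=Background.uniform(),
        ) == []

    def test_upstream_shorter_than_width_rejected(self):
        genome, genes, annotations, ancestry, pwm = self._fixture()
        with pytest.raises(ValueError):
            motif_go_association(pwm, genes, genome, 5, 1.0,
                                 annotations, ancestry)

    def test_best_upstream_scores_oracle(self):
        genome, genes, annotations, ancestry, pwm = self._fixture()
        from regmotif.scan import window_scores
        from regmotif.core import encode

        pssm = to_pssm(pwm, Background.uniform())
        table = best_upstream_scores([pssm], genes[:5], genome, 150)
        for gene in genes[:5]:
            region = upstream_region(gene, genes[:5], genome, 150)
            seq = genome["chr1"][region.start : region.end]
            codes = encode(seq)
            best = -np.inf
            for mat in (pssm.matrix, pssm.matrix[::-1, ::-1]):
                sc = window_scores(codes, mat)
                if sc.size:
                    best = max(best, sc[np.isfinite(sc)].max())
            assert table.loc[gene.gene_id].iloc[0] == pytest.approx(best)

    def test_gene_at_sequence_start_gets_sentinel(self):
        genome = make_genome(1000, seed=3)
        gene = GeneModel("g1", Location("chr1", 0, 100, "+"))
        table = best_upstream_scores(
            [planted_pwm()], [gene], genome, 100
        )
        assert table.loc["g1"].iloc[0] == -np.inf
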