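"""Vote-counting consensus: same-species, cross-species, miRNA pairing."""

import itertools
import math

import numpy as np
import pytest

from demeta import (
    DEThresholds,
    HomologyMap,
    TargetMap,
    consensus_features,
    cross_species_consensus,
    mirna_mrna_integration,
)
from demeta.consensus import default_k
from tests.conftest import build_table

UP_ROW = (2.0, 0.001, 0.002)       # clear up call at defaults
DOWN_ROW = (-2.0, 0.001, 0.002)    # clear down call
NULL_ROW = (0.0, 0.9, 0.95)        # clear non_de

CALL_ROWS = {"up": UP_ROW, "down": DOWN_ROW, "non_de": NULL_ROW}


def tables_from_patterns(patterns, species="human"):
    """One feature per call pattern; pattern[i] is the call in table i
    ('up'/'down'/'non_de'/'absent')."""
    n = len(next(iter(patterns.values())))
    tables = []
    for i in range(n):
        rows = [(feat, *CALL_ROWS[pat[i]])
                for feat, pat in patterns.items() if pat[i] != "absent"]
        if not rows:
            rows = [("__filler__", *NULL_ROW)]
        tables.append(build_table(rows, dataset_id=f"D{i}", species=species))
    return tables


def vote_oracle(pattern, k):
    """Brute-force consensus rule on one call pattern."""
    up = pattern.count("up")
    down = pattern.count("down")
    if up >= k and down == 0:
        return "up"
    if down >= k and up == 0:
        return "down"
    return None


class TestConsensusExamples:
    def test_single_dataset(self):
        tables = tables_from_patterns({"G1": ("up",)})
        (hit,) = consensus_features(tables)
        assert hit.direction == "up" and hit.n_support == 1 and hit.n_selected == 1

    def test_mean_over_supporting_tables_only(self):
        t1 = build_table([("G", 1.0, 0.001, 0.002)], dataset_id="D1")
        t2 = build_table([("G", 2.0, 0.001, 0.002)], dataset_id="D2")
        t3 = build_table([("G", 0.05, 0.9, 0.95)], dataset_id="D3")
        t4 = build_table([("G", -0.05, 0.8, 0.9)], dataset_id="D4")
        (hit,) = consensus_features([t1, t2, t3, t4])
        assert hit.direction == "up"
        assert hit.consensus_log2fc == pytest.approx(1.5)  # non-calls not averaged
        assert hit.n_support == 2 and hit.n_selected == 4

    def test_opposite_call_vetoes(self):
        tables = tables_from_patterns({"G1": ("up", "up", "down")})
        assert consensus_features(tables) == []

    def test_absent_features_neither_support_nor_veto(self):
        tables = tables_from_patterns({"G1": ("up", "up", "absent", "absent")})
        # k = ceil(4/2) = 2 judged against n=4, not the 2 containing tables
        (hit,) = consensus_features(tables)
        assert hit.n_support == 2
        tables3 = tables_from_patterns({"G1": ("up", "absent", "absent", "absent")})
        assert consensus_features(tables3) == []

    def test_mixed_species_rejected(self):
        t1 = build_table([("G", *UP_ROW)], dataset_id="D1", species="human")
        t2 = build_table([("G", *UP_ROW)], dataset_id="D2", species="mouse")
        with pytest.raises(ValueError, match="species"):
            consensus_features([t1, t2])

    def test_invalid_k_rejected(self):
        tables = tables_from_patterns({"G1": ("up", "up")})
        with pytest.raises(ValueError):
            consensus_features(tables, k=3)
        with pytest.raises(ValueError):
            consensus_features(tables, k=0)

    def test_evidence_carries_adjusted_statistics(self):
        tables = tables_from_patterns({"G1": ("up", "non_de")})
        (hit,) = consensus_features(tables)
        assert [e.dataset_id for e in hit.evidence] == ["D0", "D1"]
        assert all(not math.isnan(e.p_adjusted) for e in hit.evidence)
        assert [e.call for e in hit.evidence] == ["up", "non_de"]


class TestExhaustiveVoteCounting:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_all_call_patterns_match_oracle(self, n):
        patterns = {
            f"F{i:04d}": pat
            for i, pat in enumerate(itertools.product(("up", "down", "non_de"), repeat=n))
        }
        tables = tables_from_patterns(patterns)
        for k in range(1, n + 1):
            hits = {f.feature_id: f.direction
                    for f in consensus_features(tables, k=k)
                    if f.feature_id != "__filler__"}
            expected = {feat: vote_oracle(pat, k)
                        for feat, pat in patterns.items() if vote_oracle(pat, k)}
            assert hits == expected, (n, k)

    def test_default_k_is_ceil_half(self):
        assert [default_k(n) for n in range(1, 6)] == [1, 1, 2, 2, 3]

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_monotone_in_k(self, n):
        patterns = {
            f"F{i:04d}": pat
            for i, pat in enumerate(
                itertools.product(("up", "down", "non_de", "absent"), repeat=n))
            if any(c != "absent" for c in pat)
        }
        tables = tables_from_patterns(patterns)
        previous = None
        for k in range(1, n + 1):
            current = {f.feature_id for f in consensus_features(tables, k=k)}
            if previous is not None:
                assert current <= previous
            previous = current

    @pytest.mark.parametrize("seed", [42, 99, 123])
    def test_threshold_tightening_only_adds_via_veto_release(self, seed):
        """Per-feature DE calls are monotone in the cutoffs, so support
        counts never grow under tightening; the consensus *set* can still
        gain a feature, but only when the tightening removes an
        opposite-direction call that previously vetoed it."""
        rng = np.random.default_rng(seed)
        tables = [
            build_table(
                [(f"F{j}", float(rng.normal(0, 1.5)), float(rng.uniform(0, 1)),
                  float(rng.uniform(0, 1))) for j in range(300)],
                dataset_id=f"D{i}")
            for i in range(4)
        ]
        loose_t = DEThresholds()
        loose = {f.feature_id: f for f in consensus_features(tables, loose_t)}
        for tight_t in (DEThresholds(min_abs_fc=1.8), DEThresholds(max_p=0.005)):
            tight = {f.feature_id: f for f in consensus_features(tables, tight_t)}
            for feat, f in tight.items():
                if feat in loose:
                    assert f.n_support <= loose[feat].n_support
                else:
                    # the only route in: a veto present at loose thresholds
                    loose_calls = {t.meta.dataset_id: t.classify(loose_t).get(feat)
                                   for t in tables if feat in t}
                    opposite = "down" if f.direction == "up" else "up"
                    assert opposite in loose_calls.values(), feat

    def test_veto_release_under_tightening(self):
        """A weak opposing call vetoes consensus at default cutoffs; a
        stricter fold-change floor silences that call and the feature
        enters the consensus set — intended behaviour of the veto rule."""
        tables = [
            build_table([("G", 2.0, 0.001, 0.002)], dataset_id="D1"),
            build_table([("G", 2.1, 0.001, 0.002)], dataset_id="D2"),
            build_table([("G", -0.6, 0.01, 0.02)], dataset_id="D3"),  # |FC|=1.52
            build_table([("G", 0.0, 0.9, 0.95)], dataset_id="D4"),
        ]
        assert consensus_features(tables) == []
        (hit,) = consensus_features(tables, DEThresholds(min_abs_fc=1.8))
        assert hit.direction == "up" and hit.n_support == 2

    def test_permutation_invariance(self):
        patterns = {
            f"F{i}": pat
            for i, pat in enumerate(itertools.product(("up", "down", "non_de"), repeat=3))
        }
        tables = tables_from_patterns(patterns)
        a = consensus_features(tables)
        b = consensus_features(tables[::-1])
        assert [(f.feature_id, f.direction, f.n_support) for f in a] == \
               [(f.feature_id, f.direction, f.n_support) for f in b]
        for fa, fb in zip(a, b):
            assert fa.consensus_log2fc == pytest.approx(fb.consensus_log2fc)


class TestCrossSpecies:
    def homology(self, *pairs):
        return HomologyMap(pairs=frozenset(pairs))

    def test_reported_pair(self):
        human = tables_from_patterns({"H": ("up", "up", "non_de")})
        mouse = tables_from_patterns({"M": ("up", "non_de")}, species="mouse")
        (pair,) = cross_species_consensus(human, mouse, self.homology(("H", "M")))
        assert (pair.human_gene, pair.mouse_gene, pair.direction) == ("H", "M", "up")
        assert pair.human.consensus_log2fc == pytest.approx(2.0)
        assert pair.mouse.consensus_log2fc == pytest.approx(2.0)

    def test_one_to_many_homology_excluded(self):
        human = tables_from_patterns({"H": ("up",)})
        mouse = tables_from_patterns({"M1": ("up",), "M2": ("up",)}, species="mouse")
        hom = self.homology(("H", "M1"), ("H", "M2"))
        assert cross_species_consensus(human, mouse, hom) == []

    def test_direction_mismatch_not_reported(self):
        human = tables_from_patterns({"H": ("up",)})
        mouse = tables_from_patterns({"M": ("down",)}, species="mouse")
        assert cross_species_consensus(human, mouse, self.homology(("H", "M"))) == []

    def test_noncoding_tables_rejected(self):
        human = [build_table([("H", *UP_ROW)], biotype_scope="noncoding")]
        mouse = tables_from_patterns({"M": ("up",)}, species="mouse")
        with pytest.raises(ValueError, match="non-coding"):
            cross_species_consensus(human, mouse, self.homology(("H", "M")))

    def test_empty_homology_warns_and_returns_empty(self, caplog):
        human = tables_from_patterns({"H": ("up",)})
        mouse = tables_from_patterns({"M": ("up",)}, species="mouse")
        with caplog.at_level("WARNING"):
            out = cross_species_consensus(human, mouse, HomologyMap(pairs=frozenset()))
        assert out == [] and "homology" in caplog.text

    def test_one_to_one_filter(self):
        hom = self.homology(("H1", "M1"), ("H2", "M2"), ("H2", "M3"), ("H4", "M2"))
        assert hom.one_to_one().pairs == {("H1", "M1")}


class TestMirnaIntegration:
    def consensus_of(self, patterns, species="human", scope="coding"):
        tables = [
            build_table(rows, dataset_id=f"D{i}", species=species, biotype_scope=scope)
            for i, rows in enumerate(patterns)
        ]
        return consensus_features(tables, DEThresholds(use_adjusted=True))

    def test_opposite_direction_pair_reported(self):
        mirna = self.consensus_of([[("miR-X", *UP_ROW)]], scope="noncoding")
        genes = self.consensus_of([[("G", *DOWN_ROW)]])
        targets = TargetMap(edges={"miR-X": frozenset({"G"})})
        ((m, g),) = mirna_mrna_integration(mirna, genes, targets)
        assert (m.feature_id, g.feature_id) == ("miR-X", "G")

    def test_same_direction_not_reported(self):
        mirna = self.consensus_of([[("miR-X", *UP_ROW)]], scope="noncoding")
        genes = self.consensus_of([[("G", *UP_ROW)]])
        targets = TargetMap(edges={"miR-X": frozenset({"G"})})
        assert mirna_mrna_integration(mirna, genes, targets) == []

    def test_non_target_not_reported(self):
        mirna = self.consensus_of([[("miR-X", *UP_ROW)]], scope="noncoding")
        genes = self.consensus_of([[("G", *DOWN_ROW)]])
        targets = TargetMap(edges={"miR-X": frozenset({"H"})})
        assert mirna_mrna_integration(mirna, genes, targets) == []

    def test_random_maps_match_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        mirnas = [f"miR-{i}" for i in range(10)]
        genes = [f"G{i}" for i in range(50)]
        mirna_rows = [[(m, *(UP_ROW if rng.random() < 0.5 else DOWN_ROW))
                       for m in mirnas]]
        gene_rows = [[(g, *(UP_ROW if rng.random() < 0.5 else DOWN_ROW))
                      for g in genes]]
        mirna_cons = self.consensus_of(mirna_rows, scope="noncoding")
        gene_cons = self.consensus_of(gene_rows)
        edges = {
            m: frozenset(g for g in genes if rng.random() < 0.2) for m in mirnas
        }
        targets = TargetMap(edges=edges)
        got = {(m.feature_id, g.feature_id)
               for m, g in mirna_mrna_integration(mirna_cons, gene_cons, targets)}
        dir_of = {f.feature_id: f.direction for f in mirna_cons + gene_cons}
        expected = {
            (m, g)
            for m in mirnas for g in genes
            if g in edges[m] and dir_of[m] != dir_of[g]
        }
        assert got == expected

    def test_target_map_rejects_self_edges(self):
        with pytest.raises(ValueError, match="self-edge"):
            TargetMap(edges={"miR-X": frozenset({"miR-X"})})
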