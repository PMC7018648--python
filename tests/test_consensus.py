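"""Co-occurrence tallies, Cuthill-McKee ordering, core extraction, heat map."""

import numpy as np
import pytest

from remedynet import (
    DetectionConfig,
    Partition,
    apply_threshold,
    bandwidth,
    build_network,
    cooccurrence_matrix,
    detect_communities,
    extract_core,
    generate_planted_corpus,
    normalize_weights,
    rcm_order,
    render_heatmap,
)
from remedynet.consensus import CooccurrenceMatrix, CoreSet, write_matrix
from remedynet.errors import ValidationError
from remedynet.synthdata import PlantedDesign


def part(assignment):
    return Partition(dict(assignment), 0.0)


class TestCooccurrenceMatrix:
    def test_direct_tally(self):
        ps = [
            part({"a": 0, "b": 0, "c": 1}),
            part({"a": 0, "b": 0, "c": 0}),
            part({"a": 0, "b": 1, "c": 1}),
        ]
        m = cooccurrence_matrix(ps, ["a", "b", "c"])
        assert m.pair_count("a", "b") == 2
        assert m.pair_count("b", "c") == 2
        assert m.pair_count("a", "c") == 1
        assert m.n_thresholds == 3

    def test_identical_partitions_count_T_within_zero_across(self):
        p = part({"a": 0, "b": 0, "c": 1, "d": 1})
        m = cooccurrence_matrix([p] * 6, ["a", "b", "c", "d"])
        assert m.pair_count("a", "b") == 6
        assert m.pair_count("c", "d") == 6
        assert m.pair_count("a", "c") == 0

    def test_all_singletons_gives_zero_off_diagonal(self):
        p = part({"a": 0, "b": 1, "c": 2})
        m = cooccurrence_matrix([p, p], ["a", "b", "c"])
        off = m.counts[~np.eye(3, dtype=bool)]
        assert (off == 0).all()

    def test_diagonal_records_presence_at_every_threshold(self):
        p = part({"a": 0, "b": 1})
        m = cooccurrence_matrix([p] * 4, ["a", "b"])
        assert (np.diag(m.counts) == 4).all()

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValidationError):
            cooccurrence_matrix(
                [part({"a": 0}), part({"b": 0})], ["a"]
            )

    def test_symmetry_and_bounds_enforced_on_build(self):
        with pytest.raises(ValidationError):
            CooccurrenceMatrix(
                order=["a", "b"],
                counts=np.array([[1, 2], [3, 1]]),
                n_thresholds=5,
            )
        with pytest.raises(ValidationError):
            CooccurrenceMatrix(
                order=["a", "b"],
                counts=np.array([[9, 0], [0, 9]]),
                n_thresholds=5,
            )


class TestRcmOrder:
    def test_single_node_identity(self):
        m = CooccurrenceMatrix(order=["a"], counts=np.array([[1]]), n_thresholds=1)
        assert rcm_order(m).tolist() == [0]

    def test_blocks_stay_contiguous(self):
        counts = np.zeros((6, 6), int)
        for blk in ([0, 2, 4], [1, 3, 5]):  # interleaved blocks
            for i in blk:
                for j in blk:
                    counts[i, j] = 2
        m = CooccurrenceMatrix(
            order=list("abcdef"), counts=counts, n_thresholds=2
        )
        perm = rcm_order(m)
        halves = {frozenset(perm[:3].tolist()), frozenset(perm[3:].tolist())}
        assert halves == {frozenset({0, 2, 4}), frozenset({1, 3, 5})}

    def test_shuffled_path_reordered_to_bandwidth_one(self):
        n = 8
        rng = np.random.default_rng(1)
        shuffle = rng.permutation(n)
        counts = np.zeros((n, n), int)
        for a, b in zip(shuffle[:-1], shuffle[1:]):
            counts[a, b] = counts[b, a] = 1
        np.fill_diagonal(counts, 1)
        m = CooccurrenceMatrix(
            order=[f"n{i}" for i in range(n)], counts=counts, n_thresholds=1
        )
        perm = rcm_order(m)
        permuted = (counts[np.ix_(perm, perm)] > 0).astype(int)
        assert bandwidth(permuted) == 1

    def test_bandwidth_never_increases_and_perm_is_bijection(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = int(rng.integers(3, 15))
            pat = (rng.random((n, n)) < 0.3).astype(int)
            counts = ((pat + pat.T) > 0).astype(int)
            np.fill_diagonal(counts, 1)
            m = CooccurrenceMatrix(
                order=[f"n{i}" for i in range(n)],
                counts=counts,
                n_thresholds=1,
            )
            perm = rcm_order(m)
            assert sorted(perm.tolist()) == list(range(n))
            before = bandwidth(counts)
            after = bandwidth(counts[np.ix_(perm, perm)])
            assert after <= before


class TestExtractCore:
    def test_identical_partitions_make_every_within_pair_core(self):
        p = part({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1})
        m = cooccurrence_matrix([p] * 6, list("abcde"))
        core = extract_core(m)
        assert set(core.core_pairs) == {
            ("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"),
        }
        assert core.core_groups == [["a", "b", "c"], ["d", "e"]]

    def test_planted_noiseless_corpus_core_groups_are_modules(self):
        design = PlantedDesign(
            n_modules=3,
            ingredients_per_module=6,
            n_recipes=90,
            recipe_len=(3, 6),
            p_noise=0.0,
            seed=2,
        )
        corpus, labels = generate_planted_corpus(design)
        net = normalize_weights(build_network(corpus, min_recipes=1))
        partitions = []
        for t in (0.0, 0.05, 0.1):
            sub = apply_threshold(net, t)
            partitions.append(
                detect_communities(sub, DetectionConfig(n_runs=20, seed=5))
            )
        m = cooccurrence_matrix(partitions, net.nodes)
        core = extract_core(m)
        planted = {}
        for tok in net.nodes:
            planted.setdefault(labels.module[tok], set()).add(tok)
        assert {frozenset(g) for g in core.core_groups} == {
            frozenset(g) for g in planted.values()
        }

    def test_singles_come_from_top_row_mass_outside_pairs(self):
        # b-c always together (core pair); a co-occurs broadly but not always
        ps = [
            part({"a": 0, "b": 0, "c": 0, "d": 1, "e": 2}),
            part({"a": 0, "b": 0, "c": 0, "d": 0, "e": 1}),
            part({"a": 1, "b": 0, "c": 0, "d": 1, "e": 1}),
        ]
        m = cooccurrence_matrix(ps, list("abcde"))
        core = extract_core(m, single_top_fraction=0.4)
        assert ("b", "c") in core.core_pairs
        assert "a" in core.core_singles
        assert "b" not in core.core_singles  # already in a core pair

    def test_core_set_json_round_trip(self):
        core = CoreSet(
            core_pairs=[("a", "b")],
            core_groups=[["a", "b"]],
            core_singles=["c"],
            rule={"single_top_fraction": 0.05},
        )
        back = CoreSet.from_json(core.to_json())
        assert back.core_pairs == [("a", "b")]
        assert back.core_singles == ["c"]


class TestHeatmapAndExport:
    def test_heatmap_and_tsv_written(self, tmp_path):
        p = part({"a": 0, "b": 0, "c": 1})
        m = cooccurrence_matrix([p] * 2, ["a", "b", "c"])
        perm = rcm_order(m)
        out = tmp_path / "heat.png"
        render_heatmap(m, perm, out)
        assert out.exists() and out.stat().st_size > 0
        tsv = tmp_path / "heat.png.tsv"
        lines = tsv.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 rows

    def test_invalid_permutation_rejected(self, tmp_path):
        p = part({"a": 0, "b": 0})
        m = cooccurrence_matrix([p], ["a", "b"])
        with pytest.raises(ValidationError):
            render_heatmap(m, np.array([0, 0]), tmp_path / "x.png")

    def test_matrix_tsv_round_trips_counts(self, tmp_path):
        p = part({"a": 0, "b": 0, "c": 1})
        m = cooccurrence_matrix([p] * 3, ["a", "b", "c"])
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "\ta\tb\tc"
        got = np.array(
            [row.split("\t")[1:] for row in lines[1:]], dtype=int
        )
        assert (got == m.counts).all()
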