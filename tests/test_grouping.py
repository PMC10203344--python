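"""AV-Group formation, cover similarity and subgroup clustering."""

import numpy as np
import pandas as pd
import pytest

from pdd.association import SRMatrix
from pdd.dataset import AV, AddressTable, CategoricalDataset, build_address_table
from pdd.disentangle import DisentangledSpace, PrincipalComponent
from pdd.grouping import AVGroup, av_clustering, av_similarity, subgroup_clustering


def _space_with_edges(av_index, edges, k):
    """Build a fake DS whose rsr has the given significant edges."""
    rsr = np.zeros((k, k))
    for i, j, w in edges:
        rsr[i, j] = rsr[j, i] = w
    pc = PrincipalComponent(1, 1.0, np.ones(k) / np.sqrt(k), np.arange(k, dtype=float))
    return DisentangledSpace(pc, rsr, True, ds_index=1, max_assoc=rsr.max())


def _sr(av_index):
    return SRMatrix(av_index, np.zeros((len(av_index), len(av_index))))


class TestAvClustering:
    def setup_method(self):
        self.av_index = [AV(f"A{i}", "v") for i in range(6)]

    def test_no_edges_no_groups(self):
        ds = _space_with_edges(self.av_index, [], 6)
        assert av_clustering(ds, _sr(self.av_index)) == []

    def test_chain_forms_one_group(self):
        ds = _space_with_edges(self.av_index, [(0, 1, 3.0), (1, 2, 3.0)], 6)
        groups = av_clustering(ds, _sr(self.av_index))
        assert len(groups) == 1
        assert groups[0].members == set(self.av_index[:3])

    def test_two_components_two_groups(self):
        ds = _space_with_edges(self.av_index, [(0, 1, 3.0), (2, 3, 2.5)], 6)
        groups = av_clustering(ds, _sr(self.av_index))
        assert [g.members for g in groups] == [
            {self.av_index[2], self.av_index[3]},
            {self.av_index[0], self.av_index[1]},
        ]  # ordered by descending max |score| (scores = index here)

    def test_matches_networkx_components_on_random_graphs(self, rng):
        import networkx as nx

        for _ in range(25):
            k = 12
            av_index = [AV(f"A{i}", "v") for i in range(k)]
            w = rng.normal(scale=2.0, size=(k, k))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            pc = PrincipalComponent(1, 1.0, np.ones(k) / np.sqrt(k), rng.normal(size=k))
            ds = DisentangledSpace(pc, w, True, ds_index=1, max_assoc=w.max())
            groups = av_clustering(ds, _sr(av_index), threshold=1.96)
            g = nx.Graph()
            for i in range(k):
                for j in range(i + 1, k):
                    if w[i, j] > 1.96:
                        g.add_edge(i, j)
            want = {
                frozenset(av_index[i] for i in comp)
                for comp in nx.connected_components(g)
                if len(comp) >= 2
            }
            assert {frozenset(gr.members) for gr in groups} == want

    def test_every_member_has_significant_partner(self, rng):
        # statistical-connectedness invariant, checked directly on the rsr
        k = 10
        av_index = [AV(f"A{i}", "v") for i in range(k)]
        w = rng.normal(scale=2.0, size=(k, k))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        pc = PrincipalComponent(1, 1.0, np.ones(k) / np.sqrt(k), rng.normal(size=k))
        ds = DisentangledSpace(pc, w, True, ds_index=1, max_assoc=w.max())
        for g in av_clustering(ds, _sr(av_index), threshold=1.96):
            idx = {av: i for i, av in enumerate(av_index)}
            for av in g.members:
                partners = [
                    b for b in g.members
                    if b != av and w[idx[av], idx[b]] > 1.96
                ]
                assert partners, "member without a significant partner"


def _table_from_covers(covers):
    return AddressTable({av: np.asarray(c, dtype=np.int64) for av, c in covers.items()})


class TestAvSimilarity:
    def test_identical_disjoint_and_half(self):
        a, b, c, d = (AV("A1", "a"), AV("A2", "b"), AV("A3", "c"), AV("A4", "d"))
        table = _table_from_covers(
            {
                a: list(range(10)),
                b: list(range(10)),
                c: list(range(10, 20)),
                d: list(range(5, 15)),
            }
        )
        assert av_similarity(table, a, b) == 1.0
        assert av_similarity(table, a, c) == 0.0
        assert av_similarity(table, a, d) == 0.5  # overlap 5 of 10+10

    def test_two_empty_covers_rejected(self):
        table = _table_from_covers({})
        with pytest.raises(ValueError):
            av_similarity(table, AV("A1", "a"), AV("A2", "b"))


class TestSubgroupClustering:
    def test_fully_similar_group_stays_whole(self):
        avs = [AV("A1", "a"), AV("A2", "b"), AV("A3", "c")]
        table = _table_from_covers({av: list(range(20)) for av in avs})
        group = AVGroup(1, 1, set(avs))
        subgroups = subgroup_clustering(group, table, cutoff=0.5)
        assert len(subgroups) == 1
        assert subgroups[0].members == set(avs)
        assert subgroups[0].code == (1, 1, 1)

    def test_two_blocks_split_cleanly(self):
        # within-block overlap ~0.9, between-block ~0.1
        a1, a2 = AV("A1", "a"), AV("A2", "b")
        b1, b2 = AV("A3", "c"), AV("A4", "d")
        table = _table_from_covers(
            {
                a1: list(range(0, 20)),
                a2: list(range(2, 22)),
                b1: list(range(50, 70)),
                b2: list(range(52, 72)),
            }
        )
        group = AVGroup(2, 1, {a1, a2, b1, b2})
        subgroups = subgroup_clustering(group, table, cutoff=0.5)
        assert len(subgroups) == 2
        assert {frozenset(s.members) for s in subgroups} == {
            frozenset({a1, a2}),
            frozenset({b1, b2}),
        }
        # ordinals: equal sizes break ties lexically
        assert subgroups[0].code[2] == 1 and subgroups[1].code[2] == 2

    def test_dissimilar_pair_gives_singletons(self):
        a, b = AV("A1", "a"), AV("A2", "b")
        table = _table_from_covers({a: list(range(10)), b: list(range(20, 30))})
        group = AVGroup(1, 1, {a, b})
        subgroups = subgroup_clustering(group, table, cutoff=0.5)
        assert [len(s.members) for s in subgroups] == [1, 1]

    def test_subgroups_partition_group(self, rng):
        from pdd.association import build_sr_matrix
        from pdd.disentangle import build_spaces, select_significant_ds
        from conftest import random_dataset

        ds = random_dataset(rng, m=60, alphabet="xy")
        table = build_address_table(ds)
        _, sr = build_sr_matrix(ds, table)
        for space in select_significant_ds(build_spaces(sr, threshold=0.5), 0.5):
            for group in av_clustering(space, sr, threshold=0.5):
                subs = subgroup_clustering(group, table)
                union = set()
                total = 0
                for s in subs:
                    assert not (s.members & union)
                    union |= s.members
                    total += len(s.members)
                assert union == group.members and total == len(group.members)

    def test_bad_cutoff_rejected(self):
        group = AVGroup(1, 1, {AV("A1", "a"), AV("A2", "b")})
        with pytest.raises(ValueError):
            subgroup_clustering(group, _table_from_covers({}), cutoff=0.0)
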