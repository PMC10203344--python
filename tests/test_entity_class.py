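"""Entity clustering, class-status rules, integration and accuracy."""

import numpy as np
import pandas as pd
import pytest

from pdd.dataset import AV, CategoricalDataset
from pdd.entity_class import (
    COR,
    CRA,
    INC,
    OL,
    UND,
    ClassStatusRecord,
    assign_class_status,
    cluster_entities,
    compute_accuracy,
    integrate_class_status,
)
from pdd.grouping import AVSubgroup


def _dataset(rows, attrs):
    eids = list(range(1, len(rows) + 1))
    cells = pd.DataFrame(rows, index=eids, columns=attrs)
    return CategoricalDataset(eids, list(attrs), cells)


class TestClusterEntities:
    def setup_method(self):
        self.dsus = [
            AVSubgroup((1, 1, 1), {AV("A1", "x"), AV("A2", "x"), AV("A3", "x")}),
            AVSubgroup((2, 1, 1), {AV("A1", "y"), AV("A2", "y")}),
        ]

    def test_perfect_match_and_outlier(self):
        ds = _dataset(
            [["x", "x", "x"], ["z", "z", "z"]], ("A1", "A2", "A3")
        )
        clusters = cluster_entities(ds, self.dsus)
        by_code = {c.dsu_code: c for c in clusters}
        assert by_code[(1, 1, 1)].members == [1]
        assert by_code[(1, 1, 1)].sharing[1] == 1.0
        assert by_code[(0, 0, 0)].members == [2]

    def test_fractional_sharing_argmax(self):
        # shares 2/3 with DSU1 and 1/2 with DSU2 -> DSU1
        ds = _dataset([["x", "y", "x"]], ("A1", "A2", "A3"))
        clusters = cluster_entities(ds, self.dsus)
        by_code = {c.dsu_code: c for c in clusters}
        assert by_code[(1, 1, 1)].members == [1]
        assert by_code[(1, 1, 1)].sharing[1] == pytest.approx(2 / 3)

    def test_matches_brute_force_argmax(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, m=30)
        dsus = [
            AVSubgroup((1, 1, 1), {AV("A1", "x"), AV("A2", "y")}),
            AVSubgroup((1, 1, 2), {AV("A3", "z")}),
            AVSubgroup((2, 1, 1), {AV("A2", "x"), AV("A4", "y"), AV("A1", "z")}),
        ]
        clusters = cluster_entities(ds, dsus)
        assignment = {}
        for c in clusters:
            for e in c.members:
                assignment[e] = c.dsu_code
        for e in ds.entity_ids:
            avs = ds.entity_avs(e)
            shares = {
                d.code: len(avs & d.members) / len(d.members) for d in dsus
            }
            best = max(shares.values())
            if best == 0:
                assert assignment[e] == (0, 0, 0)
            else:
                # lowest code among maximizers
                want = min(code for code, s in shares.items() if s == best)
                assert assignment[e] == want

    def test_every_entity_in_exactly_one_cluster(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, m=25)
        clusters = cluster_entities(ds, self.dsus)
        seen = [e for c in clusters for e in c.members]
        assert sorted(seen) == ds.entity_ids


class TestClassStatusRules:
    @pytest.mark.parametrize(
        "f, given, want",
        [
            ({"Abs": 0, "Prs": 1}, "Abs", (CRA, "Prs")),  # mislabel readjusted
            ({"Abs": 0, "Prs": 0}, "Abs", (OL, None)),  # no patterns at all
            ({"Abs": 13, "Prs": 0}, "Abs", (COR, "Abs")),  # clear correct
            ({"Abs": 2, "Prs": 5}, "Abs", (INC, None)),
            ({"Abs": 3, "Prs": 3}, "Abs", (UND, None)),
            ({"Abs": 0, "Prs": 2, "Oth": 2}, "Abs", (UND, None)),  # Cra tie
        ],
    )
    def test_rule_table(self, f, given, want):
        assert assign_class_status(f, given) == want

    def test_exhaustive_against_brute_force(self, rng):
        """Statuses are exhaustive and mutually exclusive over random f maps."""
        classes = ["a", "b", "c"]

        def brute(f, given):
            fg = f[given]
            others = [f[c] for c in classes if c != given]
            mx = max(f.values())
            if all(v == 0 for v in f.values()):
                return OL
            if fg == 0:
                top = [c for c in classes if f[c] == mx]
                return CRA if len(top) == 1 else UND
            if any(v > fg for v in others):
                return INC
            if any(v == fg for v in others):
                return UND
            return COR

        for _ in range(500):
            f = {c: int(rng.integers(0, 4)) for c in classes}
            given = classes[int(rng.integers(3))]
            status, adj = assign_class_status(f, given)
            assert status == brute(f, given)
            assert (adj is not None) == (status in (COR, CRA))


def _rec(eid, status, given=None, adjusted=None, mode="wCL", f=None):
    return ClassStatusRecord(eid, f or {}, given, status, adjusted, mode)


class TestIntegration:
    def test_outlier_rescued_by_ncl(self):
        # an outlier in wCL found as Presence in nCL becomes Presence
        w = _rec(1, OL, given="Abs")
        n = _rec(1, COR, given="Prs", mode="nCL")
        assert integrate_class_status(w, n) == (CRA, "Prs")

    def test_wcl_correct_beats_ncl_incorrect(self):
        w = _rec(2, COR, given="Prs")
        n = _rec(2, INC, given="Prs", mode="nCL")
        assert integrate_class_status(w, n) == (COR, "Prs")

    def test_agreement_stays_correct(self):
        w = _rec(3, COR, given="Abs")
        n = _rec(3, COR, given="Abs", mode="nCL")
        assert integrate_class_status(w, n) == (COR, "Abs")

    def test_wcl_readjustment_stands(self):
        w = _rec(4, CRA, given="Abs", adjusted="Prs")
        n = _rec(4, INC, given="Abs", mode="nCL")
        assert integrate_class_status(w, n) == (CRA, "Prs")

    def test_double_outlier_remains_outlier(self):
        w = _rec(5, OL, given="Abs")
        n = _rec(5, OL, given="Abs", mode="nCL")
        assert integrate_class_status(w, n) == (OL, None)

    def test_eid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_class_status(_rec(1, COR, "a"), _rec(2, COR, "a", mode="nCL"))


class TestAccuracy:
    def test_printed_fraction_92_minus_2(self):
        # 90 correct of 92 entities -> 97.83%
        records = [_rec(i, COR, "a") for i in range(90)] + [
            _rec(90, INC, "a"),
            _rec(91, UND, "a"),
        ]
        assert compute_accuracy(records) == pytest.approx(97.83, abs=0.01)

    def test_printed_fraction_270_minus_54(self):
        records = [_rec(i, COR, "a") for i in range(216)] + [
            _rec(300 + i, INC, "a") for i in range(54)
        ]
        assert compute_accuracy(records) == pytest.approx(80.00, abs=1e-9)

    def test_all_correct_is_100(self):
        assert compute_accuracy([_rec(i, COR, "a") for i in range(7)]) == 100.0

    def test_readjustment_credited_only_after(self):
        records = [_rec(0, COR, "a")] + [_rec(1, CRA, "a", adjusted="b")]
        assert compute_accuracy(records, readjusted=False) == 50.0
        assert compute_accuracy(records, readjusted=True) == 100.0
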