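"""dD/cD diffing: matching, edit classification, per-spot audits."""

import itertools
import math

import numpy as np
import pytest

from ihcaudit.audit import (
    Category,
    EditKind,
    EditRecord,
    audit_spot,
    classify_edits,
    ki67_percent,
    match_marks,
    tally_records,
)
from ihcaudit.marks import Label, Mark, MarkSet, Provenance, Role
from ihcaudit.stereology import full_tiling_grid

from conftest import random_markset


def greedy_oracle(dd, cd, tolerance):
    """Exhaustive greedy matching: enumerate all candidate pairs, take
    them in (distance, i, j) order, skipping used marks."""
    cands = []
    for i, d in enumerate(dd):
        for j, c in enumerate(cd):
            dist = math.hypot(d.x - c.x, d.y - c.y)
            if dist <= tolerance:
                cands.append((dist, i, j))
    cands.sort()
    used_d, used_c, pairs = set(), set(), []
    for dist, i, j in cands:
        if i in used_d or j in used_c:
            continue
        used_d.add(i)
        used_c.add(j)
        pairs.append((i, j))
    return pairs


def mk(coords_labels, role=Role.DD, spot_id="s"):
    return MarkSet(spot_id, role, [Mark(x, y, lab) for x, y, lab in coords_labels])


P, N = Label.POSITIVE, Label.NEGATIVE


class TestMatchMarks:
    def test_identical_sets_all_paired_at_zero_tolerance(self):
        dd = mk([(10, 10, P), (20, 20, N)])
        cd = mk([(10, 10, P), (20, 20, N)], role=Role.CD)
        pairs, dd_only, cd_only = match_marks(dd, cd, tolerance=0)
        assert pairs == [(0, 0), (1, 1)] and not dd_only and not cd_only

    def test_disjoint_sets_all_singletons(self):
        dd = mk([(0, 0, P)])
        cd = mk([(500, 500, N)], role=Role.CD)
        pairs, dd_only, cd_only = match_marks(dd, cd, tolerance=5)
        assert pairs == [] and dd_only == [0] and cd_only == [0]

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_marks(mk([]), mk([], role=Role.CD), tolerance=-1)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dd = random_markset(rng, int(rng.integers(1, 11)), 60, 60)
        cd = random_markset(rng, int(rng.integers(1, 11)), 60, 60, role=Role.CD)
        tol = float(rng.uniform(0, 20))
        pairs, dd_only, cd_only = match_marks(dd, cd, tol)
        assert pairs == greedy_oracle(dd, cd, tol)
        assert sorted([i for i, _ in pairs] + dd_only) == list(range(len(dd)))
        assert sorted([j for _, j in pairs] + cd_only) == list(range(len(cd)))

    def test_tie_broken_by_index_order(self):
        # two dd marks equidistant from one cd mark: lower dd index wins
        dd = mk([(8, 10, P), (12, 10, P)])
        cd = mk([(10, 10, P)], role=Role.CD)
        pairs, _, _ = match_marks(dd, cd, tolerance=5)
        assert pairs == [(0, 0)]


class TestClassifyEdits:
    def setup_method(self):
        self.tissue = np.zeros((100, 100), dtype=bool)
        self.tissue[:, 50:] = True  # right half is epithelium

    def test_identical_sets_all_true(self):
        dd = mk([(60, 10, P), (70, 20, N)])
        cd = mk([(60, 10, P), (70, 20, N)], role=Role.CD)
        pairs, dd_only, cd_only = match_marks(dd, cd, 5)
        recs = classify_edits(pairs, dd, cd, dd_only, cd_only, self.tissue)
        assert {r.category for r in recs} == {Category.TRUE_POSITIVE, Category.TRUE_NEGATIVE}
        assert all(r.edit_kind is EditKind.NONE for r in recs)

    def test_label_flip_directions(self):
        dd = mk([(60, 10, P), (70, 20, N)])
        cd = mk([(60, 10, N), (70, 20, P)], role=Role.CD)
        pairs, dd_only, cd_only = match_marks(dd, cd, 5)
        recs = classify_edits(pairs, dd, cd, dd_only, cd_only, self.tissue)
        cats = {(r.x, r.y): r.category for r in recs}
        assert cats[(60, 10)] is Category.FALSE_POSITIVE_LABEL
        assert cats[(70, 20)] is Category.FALSE_NEGATIVE_LABEL

    def test_cd_only_attribution_by_tissue_mask(self):
        cd = mk([(10, 10, P), (80, 80, N)], role=Role.CD)  # left=outside, right=inside
        recs = classify_edits([], mk([]), cd, [], [0, 1], self.tissue)
        cats = {(r.x, r.y): r.category for r in recs}
        assert cats[(10, 10)] is Category.UNDETECTED_BY_TISSUE_MASK
        assert cats[(80, 80)] is Category.UNDETECTED_BY_NUCLEAR
        assert all(r.edit_kind is EditKind.ADD for r in recs)

    def test_dd_only_is_false_detection(self):
        dd = mk([(60, 10, P)])
        recs = classify_edits([], dd, mk([], role=Role.CD), [0], [], self.tissue)
        assert [r.category for r in recs] == [Category.FALSE_DETECTION]

    def test_out_of_bounds_cd_mark_raises(self):
        cd = mk([(150, 10, P)], role=Role.CD)
        with pytest.raises(ValueError, match="outside"):
            classify_edits([], mk([]), cd, [], [0], self.tissue)

    def test_record_category_edit_consistency_enforced(self):
        with pytest.raises(ValueError):
            EditRecord(0, 0, Category.TRUE_POSITIVE, EditKind.DELETE)


class TestKi67Percent:
    @pytest.mark.parametrize("p,n,expected", [(3, 1, 75.0), (0, 5, 0.0), (7, 0, 100.0)])
    def test_values(self, p, n, expected):
        assert ki67_percent(p, n) == expected

    def test_zero_denominator_undefined(self):
        assert math.isnan(ki67_percent(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ki67_percent(-1, 2)


class TestAuditSpot:
    def test_no_edits_when_sets_equal(self):
        tissue = np.ones((200, 200), dtype=bool)
        grid = full_tiling_grid(200, 200, 200, 200)
        dd = mk([(50, 50, P), (60, 60, N), (70, 70, N)])
        cd = dd.replace(dd.marks, role=Role.CD)
        a = audit_spot(dd, cd, grid, tissue)
        assert a.n_edits == 0 and a.ki67_dd == a.ki67_cd
        assert a.n_cd_nuclei == 3

    def test_added_negatives_lower_ki67(self):
        tissue = np.ones((200, 200), dtype=bool)
        grid = full_tiling_grid(200, 200, 200, 200)
        dd = mk([(50, 50, P), (60, 60, N)])
        cd = mk([(50, 50, P), (60, 60, N),
                 (80, 80, N), (90, 90, N)], role=Role.CD)
        a = audit_spot(dd, cd, grid, tissue)
        assert a.n_edits == 2
        assert a.tallies[Category.UNDETECTED_BY_NUCLEAR] == 2
        assert a.ki67_dd == 50.0 and a.ki67_cd == 25.0
        assert a.ki67_cd < a.ki67_dd

    def test_conservation_identity(self, rng):
        """Every grid-counted cD mark is classified exactly once."""
        tissue = rng.random((300, 300)) < 0.7
        grid = full_tiling_grid(300, 300, 150, 150)
        for _ in range(10):
            dd = random_markset(rng, 40, 300, 300)
            cd = random_markset(rng, 40, 300, 300, role=Role.CD)
            a = audit_spot(dd, cd, grid, tissue, tolerance=8)
            cd_cats = (Category.TRUE_POSITIVE, Category.TRUE_NEGATIVE,
                       Category.FALSE_POSITIVE_LABEL, Category.FALSE_NEGATIVE_LABEL,
                       Category.UNDETECTED_BY_TISSUE_MASK, Category.UNDETECTED_BY_NUCLEAR)
            assert sum(a.tallies[c] for c in cd_cats) == a.n_cd_nuclei
            assert a.n_edits == sum(a.tallies[c] for c in Category
                                    if c not in (Category.TRUE_POSITIVE,
                                                 Category.TRUE_NEGATIVE))

    def test_swap_symmetry(self, rng):
        """Swapping dD and cD swaps ADD/DELETE and the two label errors."""
        tissue = np.ones((300, 300), dtype=bool)
        grid = full_tiling_grid(300, 300, 150, 150)
        dd = random_markset(rng, 35, 300, 300)
        cd = random_markset(rng, 30, 300, 300, role=Role.CD)
        a = audit_spot(dd, cd, grid, tissue, tolerance=10)
        b = audit_spot(cd.replace(cd.marks, role=Role.DD),
                       dd.replace(dd.marks, role=Role.CD), grid, tissue, tolerance=10)
        assert a.tallies[Category.FALSE_DETECTION] == \
            b.tallies[Category.UNDETECTED_BY_NUCLEAR] + \
            b.tallies[Category.UNDETECTED_BY_TISSUE_MASK]
        assert a.tallies[Category.FALSE_POSITIVE_LABEL] == \
            b.tallies[Category.FALSE_NEGATIVE_LABEL]
        assert a.tallies[Category.FALSE_NEGATIVE_LABEL] == \
            b.tallies[Category.FALSE_POSITIVE_LABEL]
        assert a.tallies[Category.TRUE_POSITIVE] == b.tallies[Category.TRUE_POSITIVE]

    def test_grid_restriction_before_matching(self):
        """Marks on forbidden lines are excluded from the audit entirely."""
        tissue = np.ones((100, 100), dtype=bool)
        grid = full_tiling_grid(100, 100, 100, 100)
        dd = mk([(0, 0, P), (50, 50, P)])     # (0,0) on forbidden corner
        cd = mk([(50, 50, P)], role=Role.CD)
        a = audit_spot(dd, cd, grid, tissue)
        assert a.n_edits == 0 and a.n_cd_nuclei == 1
        assert a.tallies[Category.FALSE_DETECTION] == 0


def test_tally_records_counts_every_category():
    recs = [EditRecord(1, 1, Category.FALSE_DETECTION, EditKind.DELETE),
            EditRecord(2, 2, Category.FALSE_DETECTION, EditKind.DELETE),
            EditRecord(3, 3, Category.TRUE_POSITIVE, EditKind.NONE)]
    t = tally_records(recs)
    assert t[Category.FALSE_DETECTION] == 2 and t[Category.TRUE_POSITIVE] == 1
    assert sum(t.values()) == 3
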