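"""Contact map, annotation merging and pbs cluster detection.

The detection is checked against an exhaustive O(n²) brute-force recount
on random instances, and on planted clusters with known ground truth.
"""

import numpy as np
import pytest

from srpatch.conservation import (
    ResidueAnnotation,
    annotate,
    build_contact_map,
    conserved_burial_split,
    count_pbs_per_repeat,
    find_pbs,
)
from srpatch.sasa import SasaResult, SasaParams
from srpatch.structure import Atom, Chain, RepeatDefinition, Residue, Structure


def ca_structure(coords) -> Structure:
    residues = [Residue("A", i + 1, i, [Atom("CA", "C", np.asarray(c, float))])
                for i, c in enumerate(coords)]
    return Structure([Chain("A", residues)])


def fake_sasa(relative: dict[int, float]) -> SasaResult:
    burial = {i: ("exposed" if v > 0.20 else "buried") for i, v in relative.items()}
    return SasaResult(np.zeros(0), {}, relative, burial, SasaParams())


def brute_force_pbs(coords, grades, exposed, radius=10.0, min_neighbours=5):
    """Independent exhaustive recount of the centre definition."""
    n = len(coords)
    eligible = [grades[i] >= 7 and i in exposed for i in range(n)]
    centres = set()
    for i in range(n):
        if not eligible[i]:
            continue
        count = 0
        for j in range(n):
            if j == i or abs(i - j) <= 1 or not eligible[j]:
                continue
            if np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])) <= radius:
                count += 1
        if count > min_neighbours:
            centres.add(i)
    return centres


class TestContactMap:
    def test_sequence_neighbours_never_contact(self):
        cm = build_contact_map(ca_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]))
        assert not cm.matrix[0, 1] and not cm.matrix[1, 2]

    def test_distance_boundary_inclusive(self):
        cm = build_contact_map(ca_structure([[0, 0, 0], [50, 0, 0], [10.0, 0, 0]]))
        assert cm.matrix[0, 2]  # d exactly 10.0 counts

    def test_just_outside_radius(self):
        cm = build_contact_map(ca_structure([[0, 0, 0], [50, 0, 0], [10.001, 0, 0]]))
        assert not cm.matrix[0, 2]

    def test_strict_mode(self):
        s = ca_structure([[0, 0, 0], [50, 0, 0], [10.0, 0, 0]])
        assert not build_contact_map(s, inclusive=False).matrix[0, 2]

    def test_symmetry(self, bundle):
        cm = build_contact_map(bundle)
        assert (cm.matrix == cm.matrix.T).all()
        assert not cm.matrix.diagonal().any()


class TestAnnotate:
    @pytest.mark.parametrize("grade, rel, conserved, burial", [
        (7, 0.5, True, "exposed"),
        (6, 0.5, False, "exposed"),
        (9, 0.1, True, "buried"),
    ])
    def test_threshold_composition(self, grade, rel, conserved, burial):
        s = ca_structure([[0, 0, 0], [3.8, 0, 0]])
        ann = annotate(s, {0: grade, 1: 1}, fake_sasa({0: rel, 1: 0.5}))
        assert ann[0].conserved is conserved
        assert ann[0].burial_class == burial
        assert ann[0].eligible == (conserved and burial == "exposed")

    def test_missing_grade_treated_nonconserved(self):
        s = ca_structure([[0, 0, 0], [3.8, 0, 0]])
        ann = annotate(s, {0: 9}, fake_sasa({0: 0.5, 1: 0.5}))
        assert ann[1].grade == 1 and not ann[1].conserved


class TestFindPbs:
    def _run(self, coords, grades, exposed_rel):
        s = ca_structure(coords)
        ann = annotate(s, grades, fake_sasa(exposed_rel))
        return find_pbs(ann, build_contact_map(s))

    def test_no_conserved_residues_no_centres(self):
        coords = [[i * 3.8, 0, 0] for i in range(10)]
        res = self._run(coords, {i: 3 for i in range(10)}, {i: 0.5 for i in range(10)})
        assert res.centres == set()

    def test_exactly_five_neighbours_is_not_a_centre(self):
        # centre at origin; 5 eligible residues nearby at even seq offsets
        coords = [[0, 0, 0]] + [[200 + 10 * i, 0, 0] for i in range(1, 11)]
        for k, pos in zip((2, 4, 6, 8, 10), ([4, 0, 0], [0, 4, 0], [0, 0, 4],
                                             [4, 4, 0], [0, 4, 4])):
            coords[k] = pos
        grades = {i: 9 if (i == 0 or i % 2 == 0) else 1 for i in range(11)}
        rel = {i: 0.5 for i in range(11)}
        res = self._run(coords, grades, rel)
        assert res.neighbour_counts[0] == 5
        assert 0 not in res.centres

    def test_six_neighbours_is_a_centre(self):
        coords = [[0, 0, 0]] + [[200 + 10 * i, 0, 0] for i in range(1, 14)]
        for k, pos in zip((2, 4, 6, 8, 10, 12), ([4, 0, 0], [0, 4, 0], [0, 0, 4],
                                                 [4, 4, 0], [0, 4, 4], [4, 0, 4])):
            coords[k] = pos
        grades = {i: 9 if i % 2 == 0 else 1 for i in range(14)}
        res = self._run(coords, grades, {i: 0.5 for i in range(14)})
        assert 0 in res.centres

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 120))
            coords = rng.uniform(0, 30, size=(n, 3))
            grades = {i: int(rng.integers(1, 10)) for i in range(n)}
            rel = {i: float(rng.uniform(0, 0.6)) for i in range(n)}
            exposed = {i for i, v in rel.items() if v > 0.20}
            res = self._run(list(coords), grades, rel)
            assert res.centres == brute_force_pbs(coords, grades, exposed)

    def test_grade_threshold_monotonicity(self, bundle, bundle_sasa, planted_grades):
        cm = build_contact_map(bundle)
        strict = find_pbs(annotate(bundle, planted_grades, bundle_sasa,
                                   conserved_grade=8), cm)
        loose = find_pbs(annotate(bundle, planted_grades, bundle_sasa,
                                  conserved_grade=7), cm)
        assert strict.centres <= loose.centres

    def test_radius_monotonicity(self, bundle, bundle_sasa, planted_grades):
        ann = annotate(bundle, planted_grades, bundle_sasa)
        small = find_pbs(ann, build_contact_map(bundle, radius=8.0))
        large = find_pbs(ann, build_contact_map(bundle, radius=10.0))
        assert small.centres <= large.centres

    def test_annotation_order_irrelevant(self, bundle, bundle_sasa, planted_grades, rng):
        ann = annotate(bundle, planted_grades, bundle_sasa)
        cm = build_contact_map(bundle)
        ref = find_pbs(ann, cm)
        shuffled = list(ann)
        rng.shuffle(shuffled)
        res = find_pbs(shuffled, cm)
        assert res.centres == ref.centres
        assert res.neighbour_counts == ref.neighbour_counts


class TestPerRepeat:
    def _result(self, centres):
        from srpatch.conservation import PbsResult
        return PbsResult(set(centres), {c: 6 for c in centres})

    def test_all_centres_in_one_repeat(self):
        reps = [RepeatDefinition("SR1", 0, 9), RepeatDefinition("SR2", 10, 19)]
        res = count_pbs_per_repeat(self._result({1, 3, 5}), reps)
        assert res.per_repeat_counts == {"SR1": 3, "SR2": 0}

    def test_flagged_region_runs(self):
        # counts [6, 7, 2, 6] over SR1..SR4 -> regions [SR1, SR2] and [SR4]
        reps = [RepeatDefinition(f"SR{k}", 10 * (k - 1), 10 * k - 1) for k in (1, 2, 3, 4)]
        centres = (list(range(0, 6)) + list(range(10, 17)) + [21, 23]
                   + list(range(30, 36)))
        res = count_pbs_per_repeat(self._result(centres), reps)
        assert res.per_repeat_counts == {"SR1": 6, "SR2": 7, "SR3": 2, "SR4": 6}
        assert res.flagged_regions == [["SR1", "SR2"], ["SR4"]]

    def test_no_region_when_all_low(self):
        reps = [RepeatDefinition("SR1", 0, 9), RepeatDefinition("SR2", 10, 19)]
        res = count_pbs_per_repeat(self._result({0, 2, 12}), reps)
        assert res.flagged_regions == []

    def test_unassigned_bucket(self):
        reps = [RepeatDefinition("SR1", 0, 9)]
        res = count_pbs_per_repeat(self._result({2, 15}), reps)
        assert res.per_repeat_counts["unassigned"] == 1


class TestBurialSplit:
    def _ann(self, flags):
        return [ResidueAnnotation(i, "A", i + 1, 9, True, b, 0.5)
                for i, b in enumerate(flags)]

    def test_one_third_two_thirds(self):
        split = conserved_burial_split(self._ann(["buried", "exposed", "exposed"]))
        assert split == pytest.approx((1 / 3, 2 / 3))

    def test_all_exposed(self):
        assert conserved_burial_split(self._ann(["exposed"] * 4)) == (0.0, 1.0)

    def test_ten_percent_buried(self):
        split = conserved_burial_split(self._ann(["buried"] + ["exposed"] * 9))
        assert split == pytest.approx((0.1, 0.9))

    def test_no_conserved_is_undefined(self):
        ann = [ResidueAnnotation(0, "A", 1, 3, False, "exposed", 0.5)]
        assert conserved_burial_split(ann) is None
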