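import numpy as np
import pytest

from _oracles import template_match_oracle, window_starts_oracle
from conftest import make_element, random_element_set
from ramaquery import (
    AngleTemplate,
    BackboneSpec,
    ElementSet,
    SequencePattern,
    build_backbone,
    composition,
    data_path,
    extract_nmers,
    filter_pattern,
    match_template,
    read_template,
)
from ramaquery.geometry import is_consecutive


def chain_with_breaks(rng, length, break_after=()):
    """Random-dihedral chain with distance breaks after the given 0-based indices."""
    angles = [(float(p), float(s)) for p, s in rng.uniform(-180, 180, size=(length, 2))]
    chain = build_backbone(BackboneSpec(angles=angles))
    for idx in break_after:
        for res in chain.residues[idx + 1 :]:
            for atom in res.atoms.values():
                atom.coords[:] = atom.coords + 50.0
    return chain


class TestExtractNmers:
    def test_contiguous_chain_window_count(self, helical_chain):
        assert len(extract_nmers([helical_chain], 4)) == 6  # 9 - 4 + 1

    def test_break_in_every_window_yields_nothing(self, rng):
        chain = chain_with_breaks(rng, 6, break_after=(2,))
        assert len(extract_nmers([chain], 4)) == 0

    def test_break_splits_into_both_sides(self, rng):
        # 8 residues, break between 5 and 6 (1-based): 3-mers = 3 + 1
        chain = chain_with_breaks(rng, 8, break_after=(4,))
        element_set = extract_nmers([chain], 3)
        assert len(element_set) == 4
        assert [e.start for e in element_set] == ["1", "2", "3", "6"]

    def test_counts_match_brute_force_on_random_breaks(self, rng):
        for _ in range(20):
            length = int(rng.integers(5, 15))
            breaks = tuple(np.flatnonzero(rng.random(length - 1) < 0.2))
            chain = chain_with_breaks(rng, length, break_after=breaks)
            flags = [is_consecutive(chain, i) for i in range(length - 1)]
            for n in (2, 4, 7):
                expected = window_starts_oracle(flags, length, n)
                got = extract_nmers([chain], n)
                assert [e.start for e in got] == [str(s + 1) for s in expected]

    def test_edge_windows_use_neighbours_outside_window(self, helical_chain):
        element_set = extract_nmers([helical_chain], 4)
        interior = element_set.elements[2]  # starts at residue 3: all angles defined
        assert all(c.phi is not None and c.psi is not None for c in interior.conformations)

    def test_n_out_of_range_raises(self, helical_chain):
        for n in (1, 10):
            with pytest.raises(ValueError):
                extract_nmers([helical_chain], n)


class TestMatchTemplate:
    def tmpl(self, constraints, tol=40.0):
        return AngleTemplate(constraints=constraints, tol=tol)

    def test_exact_and_near_miss(self):
        template = self.tmpl([(None, None), (-60.0, -30.0), (None, None)])
        hit = make_element([(0, 0), (-60, -30), (0, 0)])
        miss = make_element([(0, 0), (-105, -30), (0, 0)])  # |diff| = 45 > 40
        element_set = ElementSet(n=3, elements=[hit, miss])
        assert list(match_template(element_set, template)) == [True, False]

    def test_wraparound_difference_matches(self):
        template = self.tmpl([(170.0, None), (None, None)])
        wrapped = make_element([(-170, 0), (0, 0)])  # circular distance 20
        element_set = ElementSet(n=2, elements=[wrapped])
        assert list(match_template(element_set, template)) == [True]

    def test_undefined_angle_at_constrained_position_never_matches(self):
        template = self.tmpl([(None, None), (-60.0, None)])
        element_set = ElementSet(n=2, elements=[make_element([(0, 0), (None, -30)])])
        assert list(match_template(element_set, template)) == [False]

    def test_length_mismatch_raises(self, small_set):
        with pytest.raises(ValueError):
            match_template(small_set, self.tmpl([(0.0, 0.0)]))

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(20):
            element_set = random_element_set(rng, n=4, count=40)
            constraints = [
                (
                    float(rng.uniform(-180, 180)) if rng.random() < 0.6 else None,
                    float(rng.uniform(-180, 180)) if rng.random() < 0.6 else None,
                )
                for _ in range(4)
            ]
            if all(p is None and s is None for p, s in constraints):
                constraints[0] = (0.0, None)
            template = self.tmpl(constraints)
            mask = match_template(element_set, template)
            expected = [
                template_match_oracle(e, constraints, 40.0) for e in element_set
            ]
            assert list(mask) == expected


class TestFilterPattern:
    def test_include_pattern(self):
        element_set = ElementSet(
            n=5,
            elements=[
                make_element([(0, 0)] * 5, sequence=s) for s in ("AAPAA", "AAAAA")
            ],
        )
        mask = filter_pattern(element_set, SequencePattern(include="--P--"))
        assert list(mask) == [True, False]

    def test_exclude_pattern(self):
        element_set = ElementSet(
            n=5,
            elements=[
                make_element([(0, 0)] * 5, sequence=s) for s in ("PAAAA", "AAAAA")
            ],
        )
        mask = filter_pattern(
            element_set, SequencePattern(include="-----", exclude="P----")
        )
        assert list(mask) == [False, True]

    def test_all_wildcards_select_everything(self, small_set):
        mask = filter_pattern(small_set, SequencePattern(include="----", exclude="----"))
        assert mask.all()

    def test_include_and_exclude_of_same_pattern_is_empty(self, rng):
        element_set = random_element_set(rng, n=4, count=30)
        pattern = SequencePattern(include="-A--", exclude="-A--")
        assert not filter_pattern(element_set, pattern).any()

    def test_length_mismatch_raises(self, small_set):
        with pytest.raises(ValueError):
            filter_pattern(small_set, SequencePattern(include="---"))


class TestComposition:
    def element_set(self):
        return ElementSet(
            n=3,
            elements=[make_element([(0, 0)] * 3, sequence=s) for s in ("AAP", "AGP", "CAP")],
        )

    def test_tally(self):
        assert composition(self.element_set(), 2) == {"A": 2, "G": 1}

    def test_masked_tally(self):
        assert composition(self.element_set(), 2, mask=[True, False, False]) == {"A": 1}

    def test_empty_set_is_empty(self):
        assert composition(ElementSet(n=3, elements=[]), 1) == {}

    def test_counts_sum_to_selection_size(self, rng):
        element_set = random_element_set(rng, n=4, count=37)
        mask = rng.random(37) < 0.5
        counts = composition(element_set, 3, mask=mask)
        assert sum(counts.values()) == int(mask.sum())

    def test_invalid_position_raises(self):
        with pytest.raises(ValueError):
            composition(self.element_set(), 4)


class TestMaskComposition:
    def test_and_of_masks_is_subset_of_each(self, rng):
        element_set = random_element_set(rng, n=4, count=60)
        m1 = match_template(element_set, AngleTemplate([(0.0, None)] * 4, tol=120))
        m2 = filter_pattern(element_set, SequencePattern(include="-A--"))
        both = m1 & m2
        assert not (both & ~m1).any()
        assert not (both & ~m2).any()
        assert (~(m1 | m2) == (~m1 & ~m2)).all()


class TestTemplateFiles:
    def test_shipped_turn_templates_load(self):
        type1 = read_template(data_path("turn_type1.txt"), n=4)
        assert type1.constraints == ((None, None), (-80.0, -25.0), (-80.0, -25.0), (None, None))
        assert type1.tol == 40.0
        type2 = read_template(data_path("turn_type2.txt"), n=4)
        assert type2.constraints == ((None, None), (-90.0, 130.0), (80.0, 25.0), (None, None))

    def test_wildcards_and_comments(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text("# comment\n1\t*\t-30\n3\t100\t*\n")
        template = read_template(path, n=3, tol=25.0)
        assert template.constraints == ((None, -30.0), (None, None), (100.0, None))
        assert template.tol == 25.0

    @pytest.mark.parametrize(
        "content", ["1\t2\n", "0\t10\t10\n", "5\t10\t10\n", "x\t10\t10\n", "1\t*\t*\n"]
    )
    def test_malformed_files_raise(self, tmp_path, content):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(ValueError):
            read_template(path, n=3)
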