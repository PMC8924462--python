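"""Atlas enumeration and event classification, including the exhaustive
224-case truth-table check against an independently hand-coded oracle."""

import itertools

import pytest

from crcatlas.atlas import (
    Category,
    MARKER_COMBOS,
    annotate_clusters,
    atlas_table,
    classify_event,
    enumerate_atlas,
    parse_canonical,
)
from crcatlas.events import (
    Panel,
    Ploidy,
    SizeClass,
    ValidationError,
    WbcReference,
    is_ctc,
    is_ctec,
)

from conftest import make_event


class TestEnumerateAtlas:
    def test_exactly_71_leaves(self):
        assert len(enumerate_atlas()) == 71

    def test_branch_counts(self):
        leaves = enumerate_atlas()
        aneuploid = [l for l in leaves if l.ploidy_axis is not Ploidy.DIPLOID]
        diploid = [l for l in leaves if l.ploidy_axis is Ploidy.DIPLOID]
        assert len(aneuploid) == 64  # 2 sizes x 4 ploidy classes x 8 combos
        assert len(diploid) == 7  # size-agnostic, >= 1 positive marker

    def test_contains_expected_leaf(self):
        strings = {l.canonical_string for l in leaves()}
        assert "large|triploid|PM+CD31-Vim-" in strings

    def test_canonical_strings_unique_and_roundtrip(self):
        for leaf in enumerate_atlas():
            assert parse_canonical(leaf.canonical_string) == leaf
        strings = [l.canonical_string for l in enumerate_atlas()]
        assert len(set(strings)) == 71

    def test_deterministic_order(self):
        assert [l.canonical_string for l in enumerate_atlas()] == [
            l.canonical_string for l in enumerate_atlas()
        ]

    def test_diploid_leaves_size_agnostic(self):
        for leaf in enumerate_atlas():
            if leaf.ploidy_axis is Ploidy.DIPLOID:
                assert leaf.size_axis == "any"
                assert any(leaf.marker_combo)
            else:
                assert leaf.size_axis in ("small", "large")

    def test_atlas_table_export(self):
        rows = atlas_table()
        assert len(rows) == 71
        assert rows[0]["index"] == 0
        assert set(rows[0]) == {
            "index", "size_axis", "ploidy_axis", "pm", "cd31", "vim",
            "canonical_string",
        }


def leaves():
    return enumerate_atlas()


# --- independent hand-coded oracle for the classification gates ----------

_PLOIDY_NAME = {1: "haploid", 3: "triploid", 4: "tetraploid"}


def oracle_category(small, cd45, spots, pm, cd31, vim):
    """Plain nested-if restatement of the gate order, written separately
    from the implementation."""
    aneuploid = spots not in (0, 2)
    any_marker = pm or cd31 or vim
    if cd45:
        if any_marker or aneuploid:
            return ("hematologic_crc",)
        return ("normal_wbc",)
    if spots == 0:
        return ("qc_fail",)
    if aneuploid:
        name = _PLOIDY_NAME.get(spots, "multiploid")
        size = "small" if small else "large"
        return ("atlas_leaf", f"{size}|{name}|PM{'+' if pm else '-'}"
                              f"CD31{'+' if cd31 else '-'}Vim{'+' if vim else '-'}")
    if any_marker:
        return ("atlas_leaf", f"any|diploid|PM{'+' if pm else '-'}"
                              f"CD31{'+' if cd31 else '-'}Vim{'+' if vim else '-'}")
    return ("diploid_null",)


class TestClassifyTruthTable:
    def test_exhaustive_224_grid_matches_oracle(self):
        atlas_strings = {l.canonical_string for l in enumerate_atlas()}
        n_cases = 0
        for small, cd45, spots, (pm, cd31, vim) in itertools.product(
            (True, False), (True, False), range(7), MARKER_COMBOS
        ):
            ev = make_event(
                cd45=cd45, pm=pm, cd31=cd31, vim=vim, cep8_spots=spots,
                diameter_um=8.0 if small else 15.0,
            )
            cls = classify_event(ev)
            expected = oracle_category(small, cd45, spots, pm, cd31, vim)
            assert cls.category.value == expected[0], (small, cd45, spots, pm, cd31, vim)
            if expected[0] == "atlas_leaf":
                assert cls.leaf.canonical_string == expected[1]
                # every produced leaf must be a member of the atlas
                assert cls.leaf.canonical_string in atlas_strings
            else:
                assert cls.leaf is None
            n_cases += 1
        assert n_cases == 224

    def test_every_event_maps_to_exactly_one_category(self):
        for small, cd45, spots, (pm, cd31, vim) in itertools.product(
            (True, False), (True, False), range(7), MARKER_COMBOS
        ):
            ev = make_event(cd45=cd45, pm=pm, cd31=cd31, vim=vim,
                            cep8_spots=spots, diameter_um=8.0 if small else 15.0)
            cls = classify_event(ev)
            assert cls.category in Category


class TestClassifyExamples:
    def test_fusion_cluster_phenotype(self):
        ev = make_event(diameter_um=15.0, cd45=False, cep8_spots=6,
                        pm=True, cd31=True, vim=True, cluster_id="c1")
        cls = classify_event(ev)
        assert cls.category is Category.ATLAS_LEAF
        assert cls.leaf.canonical_string == "large|multiploid|PM+CD31+Vim+"
        assert "fusion_cluster" in cls.annotations

    def test_diploid_multi_marker_leaf(self):
        ev = make_event(cd45=False, cep8_spots=2, pm=True, cd31=True, vim=True,
                        panel_marker_name="CK18")
        cls = classify_event(ev)
        assert cls.category is Category.ATLAS_LEAF
        assert cls.leaf.canonical_string == "any|diploid|PM+CD31+Vim+"

    def test_residual_leukocyte(self):
        ev = make_event(diameter_um=8.0, cd45=True, cep8_spots=2)
        assert classify_event(ev).category is Category.NORMAL_WBC

    def test_cd45_positive_aneuploid_marker_cell(self):
        ev = make_event(diameter_um=15.0, cd45=True, cep8_spots=3,
                        pm=True, cd31=True, panel_marker_name="CK18")
        assert classify_event(ev).category is Category.HEMATOLOGIC_CRC

    def test_stem_panel_event_gets_stem_like(self):
        ev = make_event(cd45=False, panel=Panel.STEM, panel_marker_name="CD133",
                        pm=True, cd31=False, vim=False, cep8_spots=3)
        cls = classify_event(ev)
        assert cls.category is Category.ATLAS_LEAF
        assert "stem_like" in cls.annotations

    def test_size_recorded_for_reporting(self):
        cls = classify_event(make_event(diameter_um=8.0))
        assert cls.size is SizeClass.SMALL


class TestAnnotations:
    def test_classical_flags_imply_predicates(self):
        for small, cd45, spots, (pm, cd31, vim) in itertools.product(
            (True, False), (True, False), range(7), MARKER_COMBOS
        ):
            ev = make_event(cd45=cd45, pm=pm, cd31=cd31, vim=vim,
                            cep8_spots=spots, diameter_um=8.0 if small else 15.0)
            cls = classify_event(ev)
            if "classical_CTC" in cls.annotations:
                assert is_ctc(ev) and not ev.vim
            if "classical_CTEC" in cls.annotations:
                assert is_ctec(ev) and not ev.vim
            if "EMT_CTC" in cls.annotations:
                assert is_ctc(ev) and ev.vim
            if "mesenchymal_CTEC" in cls.annotations:
                assert is_ctec(ev) and ev.vim

    def test_naked_nuclei_flag(self):
        ev = make_event(cd45=False, pm=False, cd31=False, vim=False, cep8_spots=5)
        assert "naked_nuclei" in classify_event(ev).annotations


class TestAnnotateClusters:
    def test_endothelial_progenitor_cluster(self):
        evs = [
            make_event(cd45=False, cd133=True, cd31=True, cep8_spots=3,
                       cluster_id="k1"),
            make_event(cd45=False, cd133=True, cd31=True, cep8_spots=4,
                       cluster_id="k1"),
        ]
        out = annotate_clusters(evs, [classify_event(e) for e in evs])
        for cls in out:
            assert "endothelial_progenitor_like" in cls.annotations
            assert "CTM_member" in cls.annotations

    def test_null_ctm_members_flagged_naked(self):
        evs = [
            make_event(cd45=False, cep8_spots=3, cluster_id="k2"),
            make_event(cd45=False, cep8_spots=5, cluster_id="k2"),
            make_event(cd45=False, cep8_spots=4, cluster_id="k2"),
        ]
        out = annotate_clusters(evs, [classify_event(e) for e in evs])
        for cls in out:
            assert "naked_nuclei" in cls.annotations
            assert "CTM_member" in cls.annotations

    def test_singleton_unchanged(self):
        evs = [make_event(cd45=False, cep8_spots=3, cluster_id="solo")]
        before = [classify_event(e) for e in evs]
        out = annotate_clusters(evs, before)
        assert out[0].annotations == before[0].annotations

    def test_wbc_only_cluster_not_ctm(self):
        evs = [
            make_event(cd45=True, cep8_spots=2, cluster_id="w"),
            make_event(cd45=True, cep8_spots=2, cluster_id="w"),
        ]
        out = annotate_clusters(evs, [classify_event(e) for e in evs])
        for cls in out:
            assert "CTM_member" not in cls.annotations

    def test_mismatched_lengths_rejected(self):
        evs = [make_event()]
        with pytest.raises(ValidationError):
            annotate_clusters(evs, [])

    def test_originals_not_mutated(self):
        evs = [
            make_event(cd45=False, cep8_spots=3, cluster_id="m"),
            make_event(cd45=False, cep8_spots=3, cluster_id="m"),
        ]
        before = [classify_event(e) for e in evs]
        snapshots = [set(c.annotations) for c in before]
        annotate_clusters(evs, before)
        assert [set(c.annotations) for c in before] == snapshots
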