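"""Closest-congener statistics, distribution groups and leave-one-out."""

import pytest

from congener_gap import (
    closest_congener,
    congener_table,
    distance_matrix,
    genus_distribution_table,
    genus_table_frame,
    leave_one_out,
    select_statistics_set,
)
from congener_gap.congener import CongenerStatRow, assign_distribution_group
from congener_gap.distances import species_pair_summary
from congener_gap.io import TaxonAnnotation
from conftest import toy_alignment


def ann(key, genus, subfamily="Cryptorhynchinae", group=1, island=False, km=100.0):
    return TaxonAnnotation(key, genus, subfamily, group, island, km)


# ------------------------------------------------------- distribution groups


@pytest.mark.parametrize(
    "subfamily, island, km, expected",
    [
        ("Cryptorhynchinae", False, 400.0, "C2"),
        ("Apioninae", False, 400.0, "C2"),       # same range, wider C2 band
        ("Ceutorhynchinae", False, 400.0, "C2"),
        ("Cryptorhynchinae", False, 600.0, "C3"),
        ("Apioninae", False, 600.0, "C2"),       # below the 2000 km cutoff
        ("Apioninae", False, 2500.0, "C3"),
        ("Cryptorhynchinae", False, 30.0, "C1"),
        ("Cryptorhynchinae", True, 3000.0, "ISL"),  # island overrides range
        ("Cryptorhynchinae", False, 50.0, "C1"),    # boundary: "up to 50 km"
        ("Cryptorhynchinae", False, 500.0, "C2"),   # boundary: "50 to 500 km"
        ("Apioninae", False, 2000.0, "C2"),
    ],
)
def test_assign_distribution_group(subfamily, island, km, expected):
    a = ann("G_s", "G", subfamily=subfamily, island=island, km=km)
    assert assign_distribution_group(a) == expected


def test_assign_distribution_group_unknown_subfamily():
    with pytest.raises(ValueError, match="other"):
        assign_distribution_group(ann("G_s", "G", subfamily="other"))


# ------------------------------------------------------------ statistics set


def test_select_statistics_set():
    annotations = {
        "A_ref": ann("A_ref", "A", group=1),
        "A_cong": ann("A_cong", "A", group=2),
        "A_out": ann("A_out", "A", group=3),
    }
    reference, congeners = select_statistics_set(annotations)
    assert reference == {"A_ref"}
    assert congeners == {"A_ref", "A_cong"}


def test_select_statistics_set_enumerated():
    groups = [1, 2, 3, 1, 3, 2]
    annotations = {
        f"G_sp{i}": ann(f"G_sp{i}", "G", group=g) for i, g in enumerate(groups)
    }
    reference, congeners = select_statistics_set(annotations)
    assert reference == {k for k, a in annotations.items() if a.confidence_group == 1}
    assert congeners == {
        k for k, a in annotations.items() if a.confidence_group in (1, 2)
    }


def test_all_group3_gives_empty_sets():
    annotations = {"G_a": ann("G_a", "G", group=3)}
    reference, congeners = select_statistics_set(annotations)
    assert reference == set() and congeners == set()


# ----------------------------------------------------------- closest congener


def test_closest_congener_two_singletons():
    # two species, one specimen each, 5% apart
    base = "ACGT" * 25
    other = "TCGT" * 5 + "ACGT" * 20  # 5 mismatches in 100 sites
    aln = toy_alignment({"GenA_aaa": [base], "GenA_bbb": [other]})
    mat = distance_matrix(aln)
    annotations = {"GenA_aaa": ann("GenA_aaa", "GenA"), "GenA_bbb": ann("GenA_bbb", "GenA")}
    row = closest_congener("GenA_aaa", mat, annotations, {"GenA_aaa", "GenA_bbb"})
    assert row.closest_congener == "GenA_bbb"
    assert row.min_dist == pytest.approx(0.05)


def test_closest_congener_matches_bruteforce_argmin(small_dataset, small_matrix):
    annotations = small_dataset.annotations
    reference, congeners = select_statistics_set(annotations)
    rows = congener_table(small_matrix, annotations)
    assert rows, "expected at least one reference species with congeners"
    for row in rows:
        candidates = {
            sp: species_pair_summary(row.reference_species, sp, small_matrix).min_dist
            for sp in congeners
            if sp != row.reference_species
            and annotations[sp].genus == row.genus
            and small_matrix.records_of_species(sp)
        }
        best = min(candidates.values())
        assert row.min_dist == pytest.approx(best)
        assert candidates[row.closest_congener] == pytest.approx(best)
        # ties reported lexicographically first
        assert row.closest_congener == row.tied_congeners[0]
        assert list(row.tied_congeners) == sorted(row.tied_congeners)


def test_group2_species_never_appear_as_reference(small_dataset, small_matrix):
    rows = congener_table(small_matrix, small_dataset.annotations)
    for row in rows:
        assert small_dataset.annotations[row.reference_species].confidence_group == 1


def test_lonely_reference_species_is_omitted():
    aln = toy_alignment({"GenA_aaa": ["ACGT"], "GenB_bbb": ["ACGA"]})
    mat = distance_matrix(aln)
    annotations = {"GenA_aaa": ann("GenA_aaa", "GenA"), "GenB_bbb": ann("GenB_bbb", "GenB")}
    rows = congener_table(mat, annotations)
    assert rows == []  # no congeners in either genus


def test_genus_alias_merges_genera():
    base = "ACGT" * 25
    other = "TCGT" * 5 + "ACGT" * 20
    aln = toy_alignment({"Mogulones_aaa": [base], "Datonychus_bbb": [other]})
    mat = distance_matrix(aln)
    annotations = {
        "Mogulones_aaa": ann("Mogulones_aaa", "Mogulones", subfamily="Ceutorhynchinae"),
        "Datonychus_bbb": ann("Datonychus_bbb", "Datonychus", subfamily="Ceutorhynchinae"),
    }
    aliases = {"Datonychus": "Mogulones"}
    rows = congener_table(mat, annotations, genus_aliases=aliases)
    assert {r.reference_species for r in rows} == {"Mogulones_aaa", "Datonychus_bbb"}
    assert all(r.genus == "Mogulones" for r in rows)


# ----------------------------------------------------------------- genus table


def test_genus_table_arithmetic():
    rows = [
        CongenerStatRow(f"GenA_sp{i}", "GenA", "C2", f"GenA_other{i}", d / 100)
        for i, d in enumerate([2, 4, 6, 8])
    ]
    table = genus_distribution_table(rows)
    assert len(table) == 1
    cell = table[0]
    assert cell.min_of_min == pytest.approx(0.02)
    assert cell.avg_of_min == pytest.approx(0.05)
    assert cell.n_reference_species == 4
    frame = genus_table_frame(table)
    assert frame.loc[0, "C2_min"] == "2.0"
    assert frame.loc[0, "C2_avg"] == "5.0"
    assert frame.loc[0, "ISL_min"] == ""  # empty cells stay blank


def test_single_species_cell_min_equals_avg():
    rows = [CongenerStatRow("GenA_a", "GenA", "ISL", "GenA_b", 0.038)]
    cell = genus_distribution_table(rows)[0]
    assert cell.min_of_min == cell.avg_of_min == pytest.approx(0.038)


def test_genus_cell_min_is_global_min_over_cell(small_dataset, small_matrix):
    rows = congener_table(small_matrix, small_dataset.annotations)
    table = genus_distribution_table(rows)
    for cell in table:
        cell_rows = [
            r
            for r in rows
            if r.genus == cell.genus and r.distribution_group == cell.distribution_group
        ]
        assert cell.min_of_min == pytest.approx(min(r.min_dist for r in cell_rows))
        assert cell.min_of_min <= cell.avg_of_min + 1e-12
        assert cell.n_reference_species == len(cell_rows)


# ---------------------------------------------------------------- leave-one-out


def _loo(dataset, matrix, excluded):
    rows = congener_table(matrix, dataset.annotations)
    sub = dataset.alignment.drop_species(excluded)
    return rows, leave_one_out(excluded, rows, distance_matrix(sub), dataset.annotations)


def test_leave_one_out_three_species_toy():
    base = "ACGT" * 25
    near = "TCGT" * 2 + "ACGT" * 23   # 2% from base
    far = "TCGT" * 10 + "ACGT" * 15   # 10% from base
    aln = toy_alignment({"GenA_aaa": [base], "GenA_bbb": [near], "GenA_ccc": [far]})
    mat = distance_matrix(aln)
    annotations = {k: ann(k, "GenA") for k in ["GenA_aaa", "GenA_bbb", "GenA_ccc"]}
    rows = congener_table(mat, annotations)
    by_ref = {r.reference_species: r for r in rows}
    assert by_ref["GenA_aaa"].closest_congener == "GenA_bbb"
    assert by_ref["GenA_aaa"].min_dist == pytest.approx(0.02)

    sub = aln.drop_species("GenA_bbb")
    result = leave_one_out("GenA_bbb", rows, distance_matrix(sub), annotations)
    after = {r.reference_species: r for r in result.rows}
    # the next congener takes over, at the larger pair distance
    assert after["GenA_aaa"].closest_congener == "GenA_ccc"
    assert after["GenA_aaa"].min_dist == pytest.approx(0.10)
    assert {ref for ref, _, _ in result.changed} == {"GenA_aaa", "GenA_ccc"}


def test_leave_one_out_unreferenced_species_changes_nothing():
    base = "ACGT" * 25
    near = "TCGT" * 2 + "ACGT" * 23
    lone = "GGGG" * 25
    aln = toy_alignment({"GenA_aaa": [base], "GenA_bbb": [near], "GenB_zzz": [lone]})
    annotations = {
        "GenA_aaa": ann("GenA_aaa", "GenA"),
        "GenA_bbb": ann("GenA_bbb", "GenA"),
        "GenB_zzz": ann("GenB_zzz", "GenB"),
    }
    mat = distance_matrix(aln)
    rows = congener_table(mat, annotations)
    sub = aln.drop_species("GenB_zzz")
    result = leave_one_out("GenB_zzz", rows, distance_matrix(sub), annotations)
    assert result.changed == []


def test_leave_one_out_never_decreases_minima(small_dataset, small_matrix):
    annotations = small_dataset.annotations
    rows = congener_table(small_matrix, annotations)
    before = {r.reference_species: r.min_dist for r in rows}
    # remove each of a few species and check monotonicity of remaining minima
    some_species = sorted(annotations)[::5][:6]
    for excluded in some_species:
        sub = small_dataset.alignment.drop_species(excluded)
        result = leave_one_out(
            excluded, rows, distance_matrix(sub), annotations
        )
        for row in result.rows:
            if row.reference_species in before:
                assert row.min_dist >= before[row.reference_species] - 1e-12
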