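"""Site mapping, conservation classing and PL-binding categories."""

import numpy as np
import pytest

from protomito.core_io import AlignmentBlock
from protomito.cox3_pl import (
    categorize, classify_conservation, map_reference_sites, strength_heatmap,
)
from protomito.similarity_scoring import blosum62


def _gapless_alignment(ref, *others):
    ids = [ref.id] + [f"rec{i}" for i in range(len(others))]
    return AlignmentBlock(ids, [ref.residues, *others])


class TestSiteMapping:
    def test_gapless_reference_maps_position_to_column(self, cox3_reference, pl_sites):
        block = _gapless_alignment(cox3_reference, cox3_reference.residues)
        cmap, unmapped = map_reference_sites(block, cox3_reference.id, pl_sites)
        assert not unmapped
        for s in pl_sites:
            assert cmap[s.site_id] == s.reference_position

    def test_single_gap_shifts_columns_after_it(self, cox3_reference, pl_sites):
        k = 50  # gap inserted before reference position 51
        row = cox3_reference.residues[:k] + "-" + cox3_reference.residues[k:]
        other = "A" * len(row)
        block = AlignmentBlock([cox3_reference.id, "x"], [row, other])
        cmap, _ = map_reference_sites(block, cox3_reference.id, pl_sites)
        for s in pl_sites:
            expected = s.reference_position + (1 if s.reference_position > k else 0)
            assert cmap[s.site_id] == expected

    def test_absent_reference_is_hard_error(self, cox3_reference, pl_sites):
        block = AlignmentBlock(["a", "b"], ["MK", "ML"])
        with pytest.raises(KeyError):
            map_reference_sites(block, "missing", pl_sites)

    def test_random_gaps_match_coordinate_walk_oracle(self, cox3_reference,
                                                      pl_sites, rng):
        seq = cox3_reference.residues
        for _ in range(20):
            row = list(seq)
            for _ in range(int(rng.integers(1, 15))):
                row.insert(int(rng.integers(len(row))), "-")
            row = "".join(row)
            block = AlignmentBlock([cox3_reference.id, "x"], [row, "A" * len(row)])
            cmap, _ = map_reference_sites(block, cox3_reference.id, pl_sites)
            # oracle: walk the gapped row counting residues
            pos = 0
            walk = {}
            for col, aa in enumerate(row, start=1):
                if aa != "-":
                    pos += 1
                    walk[pos] = col
            for s in pl_sites:
                assert cmap[s.site_id] == walk[s.reference_position]


class TestConservation:
    def test_identical_record_all_sites_identical_strong(self, cox3_reference,
                                                         pl_sites):
        block = _gapless_alignment(cox3_reference, cox3_reference.residues)
        prof = classify_conservation(block, "rec0", cox3_reference.id, pl_sites)
        assert set(prof.site_classes.values()) == {"identical"}
        assert prof.category == "strong"
        assert prof.e90_conserved == 1

    def test_two_pe_two_pg_conserved_is_weak(self, cox3_reference, pl_sites):
        m = blosum62()
        row = list(cox3_reference.residues)
        kept = {"PE1", "PE2", "PG1", "PG2"}
        for s in pl_sites:
            if s.site_id in kept or s.role == "E90_like":
                continue
            ref_aa = row[s.reference_position - 1]
            row[s.reference_position - 1] = next(
                aa for aa in "PGCDNEQHRKW" if aa != ref_aa and m[aa, ref_aa] <= 0)
        block = _gapless_alignment(cox3_reference, "".join(row))
        prof = classify_conservation(block, "rec0", cox3_reference.id, pl_sites)
        assert prof.pl_conserved == {"PE": 2, "PG": 2}
        assert prof.category == "weak"

    def test_category_boundary_is_exactly_three(self):
        assert categorize({"PE": 2, "PG": 2}) == "weak"
        assert categorize({"PE": 3, "PG": 2}) == "intermediate"
        assert categorize({"PE": 2, "PG": 3}) == "intermediate"
        assert categorize({"PE": 5, "PG": 5}) == "strong"

    def test_positive_substitution_counts_as_conserved(self, cox3_reference,
                                                       pl_sites):
        m = blosum62()
        row = list(cox3_reference.residues)
        target = next(s for s in pl_sites if s.site_id == "PE1")
        ref_aa = row[target.reference_position - 1]
        row[target.reference_position - 1] = next(
            aa for aa in "ACDEFGHIKLMNPQRSTVWY"
            if aa != ref_aa and m[aa, ref_aa] > 0)
        block = _gapless_alignment(cox3_reference, "".join(row))
        prof = classify_conservation(block, "rec0", cox3_reference.id, pl_sites)
        assert prof.site_classes["PE1"] == "positive"
        assert prof.pl_conserved["PE"] == 5

    def test_classes_match_sitewise_matrix_oracle(self, cox3_reference,
                                                  pl_sites, rng):
        m = blosum62()
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            row = list(cox3_reference.residues)
            for s in pl_sites:
                if rng.random() < 0.5:
                    row[s.reference_position - 1] = str(rng.choice(aas))
            block = _gapless_alignment(cox3_reference, "".join(row))
            prof = classify_conservation(block, "rec0", cox3_reference.id, pl_sites)
            for s in pl_sites:
                aa = row[s.reference_position - 1]
                ref_aa = cox3_reference.residues[s.reference_position - 1]
                if aa == ref_aa:
                    expected = "identical"
                elif m[aa, ref_aa] > 0:
                    expected = "positive"
                else:
                    expected = "other"
                assert prof.site_classes[s.site_id] == expected

    def test_mutation_toward_reference_is_monotone(self, cox3_reference, pl_sites):
        m = blosum62()
        row = list(cox3_reference.residues)
        for s in pl_sites:  # start with every site non-conserved
            ref_aa = cox3_reference.residues[s.reference_position - 1]
            row[s.reference_position - 1] = next(
                aa for aa in "PGCDNEQHRKW" if aa != ref_aa and m[aa, ref_aa] <= 0)
        prev = -1
        for s in pl_sites:
            row[s.reference_position - 1] = cox3_reference.residues[
                s.reference_position - 1]
            block = _gapless_alignment(cox3_reference, "".join(row))
            prof = classify_conservation(block, "rec0", cox3_reference.id, pl_sites)
            assert prof.conserved_total >= prev
            prev = prof.conserved_total


class TestHeatmap:
    def test_identical_records_identical_rows(self, cox3_reference, pl_sites):
        block = _gapless_alignment(
            cox3_reference, cox3_reference.residues, cox3_reference.residues)
        profs = [classify_conservation(block, rid, cox3_reference.id, pl_sites)
                 for rid in ("rec0", "rec1")]
        df = strength_heatmap(profs, pl_sites)
        assert (df.loc["rec0"] == df.loc["rec1"]).all()

    def test_empty_profile_list_gives_empty_report(self, pl_sites):
        assert strength_heatmap([], pl_sites).empty

    def test_planted_gradient_orders_rows(self, cox3_reference, pl_sites, rng):
        m = blosum62()
        rows, expected = [], []
        for n_conserved in (10, 6, 2):
            row = list(cox3_reference.residues)
            pl_site_list = [s for s in pl_sites if s.role != "E90_like"]
            for s in pl_site_list[n_conserved:]:
                ref_aa = cox3_reference.residues[s.reference_position - 1]
                row[s.reference_position - 1] = next(
                    aa for aa in "PGCDNEQHRKW" if aa != ref_aa and m[aa, ref_aa] <= 0)
            rows.append("".join(row))
            expected.append(n_conserved)
        block = AlignmentBlock(
            [cox3_reference.id, "hi", "mid", "lo"],
            [cox3_reference.residues, *rows])
        profs = [classify_conservation(block, rid, cox3_reference.id, pl_sites)
                 for rid in ("hi", "mid", "lo")]
        totals = [p.conserved_total for p in profs]
        assert totals == sorted(totals, reverse=True) == expected
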