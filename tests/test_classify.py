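"""Architecture classification: CC calling, merging, typing, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbsevolve import classify
from nbsevolve.classify import (
    NBS_LRR,
    NON_NBS_LRR,
    classify_architecture,
    detect_cc,
    letters_of,
    merge_hits,
    motif_order_conserved,
    pearson_r,
    type_count_table,
)
from nbsevolve.core_io import CoilTrack, DomainHit


class TestDetectCC:
    def test_single_run_spans_whole_track(self):
        track = CoilTrack("p1", (0.9,) * 30)
        (hit,) = detect_cc(track, min_len=8)
        assert (hit.start, hit.end, hit.domain_class) == (1, 30, "C")

    def test_all_below_threshold(self):
        assert detect_cc(CoilTrack("p1", (0.4,) * 30)) == []

    def test_two_separated_runs(self):
        scores = (0.9,) * 10 + (0.1,) * 10 + (0.9,) * 10
        hits = detect_cc(CoilTrack("p1", scores), min_len=8)
        assert [(h.start, h.end) for h in hits] == [(1, 10), (21, 30)]

    def test_short_run_dropped(self):
        scores = (0.9,) * 5 + (0.1,) * 25
        assert detect_cc(CoilTrack("p1", scores), min_len=8) == []

    def test_threshold_is_inclusive(self):
        (hit,) = detect_cc(CoilTrack("p1", (0.5,) * 10), threshold=0.5, min_len=8)
        assert (hit.start, hit.end) == (1, 10)


def _brute_force_merge(hits, gap_max):
    """Oracle: repeatedly merge any same-class pair closer than gap_max."""
    units = [[h.domain_class, h.start, h.end] for h in hits]
    changed = True
    while changed:
        changed = False
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                ci, si, ei = units[i]
                cj, sj, ej = units[j]
                if ci != cj:
                    continue
                gap = max(si, sj) - min(ei, ej) - 1
                if gap <= gap_max:
                    units[i] = [ci, min(si, sj), max(ei, ej)]
                    del units[j]
                    changed = True
                    break
            if changed:
                break
    units.sort(key=lambda u: ((u[1] + u[2]) / 2, u[1], u[0]))
    return "".join(u[0] for u in units)


class TestMergeHits:
    def test_no_hits(self):
        assert merge_hits([]) == []

    def test_clustered_lrr_hits_become_one_letter(self):
        hits = [
            DomainHit("p", "L", 500, 520),
            DomainHit("p", "L", 535, 560),
            DomainHit("p", "L", 580, 600),
        ]
        merged = merge_hits(hits, gap_max=150)
        assert letters_of(merged) == "L"
        assert (merged[0].start, merged[0].end) == (500, 600)

    def test_distant_same_class_hits_stay_separate(self):
        hits = [DomainHit("p", "N", 100, 250), DomainHit("p", "N", 600, 750)]
        assert letters_of(merge_hits(hits, gap_max=150)) == "NN"

    def test_different_classes_never_merge(self):
        hits = [DomainHit("p", "C", 10, 40), DomainHit("p", "N", 45, 200)]
        assert letters_of(merge_hits(hits, gap_max=150)) == "CN"

    def test_order_by_midpoint(self):
        hits = [
            DomainHit("p", "L", 900, 1100),
            DomainHit("p", "N", 300, 600),
            DomainHit("p", "C", 10, 40),
        ]
        assert letters_of(merge_hits(hits)) == "CNL"

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            merge_hits([DomainHit("a", "N", 1, 9), DomainHit("b", "N", 1, 9)])

    def test_idempotent(self):
        hits = [
            DomainHit("p", "L", 500, 520),
            DomainHit("p", "L", 535, 560),
            DomainHit("p", "N", 100, 260),
        ]
        once = merge_hits(hits)
        assert merge_hits(once) == [
            DomainHit(h.protein_id, h.domain_class, h.start, h.end, h.evalue, "merged")
            for h in once
        ]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("NTCLR"),
                st.integers(min_value=1, max_value=1500),
                st.integers(min_value=1, max_value=300),
            ),
            min_size=1,
            max_size=12,
        ),
        st.integers(min_value=0, max_value=300),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, raw, gap_max):
        hits = [DomainHit("p", c, s, s + w) for c, s, w in raw]
        assert letters_of(merge_hits(hits, gap_max)) == _brute_force_merge(
            hits, gap_max
        )


class TestClassifyArchitecture:
    @pytest.mark.parametrize(
        "letters,subclass",
        [
            ("CNL", NBS_LRR),
            ("TNC", NON_NBS_LRR),
            ("CNLCN", NBS_LRR),
            ("N", NON_NBS_LRR),
            ("RN", NON_NBS_LRR),
            ("NL", NBS_LRR),
        ],
    )
    def test_type_and_subclass(self, letters, subclass):
        arch = classify_architecture("g", letters)
        assert arch.type_name == letters
        assert arch.subclass == subclass
        assert arch.is_nbs

    def test_no_nbarc_flagged(self):
        arch = classify_architecture("g", "CL")
        assert not arch.is_nbs

    def test_empty_letters_error(self):
        with pytest.raises(ValueError, match="not an NBS candidate"):
            classify_architecture("g", "")

    def test_partition_is_exclusive_and_exhaustive(self):
        """Every architecture has exactly one type and one subclass."""
        for letters in ("CNL", "NL", "CN", "N", "TNC", "CNLCN", "NNN", "RN"):
            arch = classify_architecture("g", letters)
            assert arch.subclass in (NBS_LRR, NON_NBS_LRR)
            assert (arch.subclass == NBS_LRR) == ("L" in letters)


class TestTypeCountTable:
    def test_empty_input_all_zero(self):
        table = type_count_table([])
        assert (table.values == 0).all()

    def test_subtotals_sum_to_species_total(self, paper_shape_run):
        table = paper_shape_run["table"]
        for sp in table.columns:
            assert (
                table.loc["Total (NBS-LRR)", sp]
                + table.loc["Total (non-NBS-LRR)", sp]
                == table.loc["Total", sp]
            )

    def test_focal_species_subclass_split(self, paper_shape_run):
        table = paper_shape_run["table"]
        assert table.loc["Total (NBS-LRR)", "Doff"] == 22
        assert table.loc["Total (non-NBS-LRR)", "Doff"] == 52
        assert table.loc["Total", "Doff"] == 74

    def test_grand_total(self, paper_shape_run):
        table = paper_shape_run["table"]
        assert sorted(
            table.loc["Total", [c for c in table.columns if c != "All species"]]
        ) == sorted([74, 118, 169, 57, 12, 15, 210])
        assert table.loc["Total", "All species"] == 655

    def test_non_nbs_genes_excluded(self):
        archs = [
            classify_architecture("g1", "CNL", "sp"),
            classify_architecture("g2", "CL", "sp"),  # no NB-ARC
        ]
        table = type_count_table(archs)
        assert table.loc["Total", "sp"] == 1


class TestPearson:
    def test_perfect_linearity(self):
        r, p = pearson_r([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_anti_linearity(self):
        r, _ = pearson_r([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        r, _ = pearson_r([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_r([1, 2], [3, 4])

    def test_matches_covariance_oracle(self):
        """r agrees with the direct centered-moment formula to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(3, 51)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            r, _ = pearson_r(x, y)
            assert abs(r - expected) < 1e-12


class TestMotifOrder:
    CANON = (6, 5, 3, 1, 7, 2, 8, 4)

    def test_full_canonical_order_conserved(self):
        assert motif_order_conserved(self.CANON, self.CANON)

    def test_reversal_not_conserved(self):
        assert not motif_order_conserved(tuple(reversed(self.CANON)), self.CANON)

    def test_subsequence_with_missing_motifs_conserved(self):
        assert motif_order_conserved((6, 3, 7, 8), self.CANON)

    def test_single_swap_breaks_conservation(self):
        assert not motif_order_conserved((5, 6, 3, 1), self.CANON)

    def test_motifs_outside_canonical_ignored(self):
        assert motif_order_conserved((6, 99, 5, 3), self.CANON)

    def test_duplicate_canonical_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            motif_order_conserved((1, 2), (1, 1, 2))
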