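"""Amide counting, deuteration percentages, Woods rows and residue profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allomap import hdx, synthetic_data as sd
from allomap.hdx import (
    DEUTERIUM_MASS,
    FD,
    PeptideUptakeTable,
    WoodsRow,
    count_exchangeable_amides,
    difference_table,
    greedy_minimal_cover,
    percent_deuteration,
    residue_interpolation,
    uptake_curves,
)


class TestCountExchangeableAmides:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", 2),  # no prolines: L - 2
            ("APAA", 2),  # proline at position 2 collapses to the same formula
            ("AAPA", 1),  # proline at position 3 removes one amide
            ("AA", 0),  # boundary: L - 2 = 0 -> unusable
        ],
    )
    def test_worked_examples(self, seq, expected):
        if expected <= 0:
            with pytest.raises(ValueError):
                count_exchangeable_amides(seq)
        else:
            assert count_exchangeable_amides(seq) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            count_exchangeable_amides("A")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=30))
    def test_formulations_agree_on_random_peptides(self, seq):
        # the compact rule and the explicit amide bookkeeping are asserted
        # against each other inside the function; any disagreement raises
        expected = len(seq) - 2 - seq[2:].count("P")
        if expected <= 0:
            with pytest.raises(ValueError):
                count_exchangeable_amides(seq)
        else:
            assert count_exchangeable_amides(seq) == expected


class TestPercentDeuteration:
    def test_fd_normalized_midpoint(self):
        pct, flag = percent_deuteration("AAAAA", 1005.0, 1000.0, m_fd=1010.0)
        assert pct == pytest.approx(50.0)
        assert not flag

    def test_zero_uptake(self):
        pct, _ = percent_deuteration("AAAAA", 1000.0, 1000.0, m_fd=1010.0)
        assert pct == 0.0

    def test_theoretical_max_without_fd(self):
        # N_ex = 4, d_frac = 0.9: full exchange reads 100%
        seq = "AAAAAA"
        dm = 4 * 0.9 * DEUTERIUM_MASS
        pct, _ = percent_deuteration(seq, 1000.0 + dm, 1000.0, d_frac=0.9)
        assert pct == pytest.approx(100.0)

    def test_fd_row_reads_100_percent(self):
        pct, _ = percent_deuteration("AAAAA", 1010.0, 1000.0, m_fd=1010.0)
        assert pct == pytest.approx(100.0)

    def test_invalid_fd_mass_rejected(self):
        with pytest.raises(ValueError):
            percent_deuteration("AAAAA", 1005.0, 1000.0, m_fd=999.0)

    def test_out_of_range_clipped_and_flagged(self):
        pct, flag = percent_deuteration("AAAAA", 1020.0, 1000.0, m_fd=1010.0)
        assert pct == 110.0 and flag


def make_tables(protected=None, k_int=0.0015, noise=0.0, seed_mut=6, n=30):
    seq = "".join("ACDEFGHIKLMNQRSTVWY"[i % 19] for i in range(n))
    peps = sd.ladder_peptides(n)
    wt = sd.simulate_hdx_peptides(
        seq, sd.ProtectionProfile.uniform(n, k_int=k_int), peps,
        noise_da=noise, seed=5,
    )
    mut = sd.simulate_hdx_peptides(
        seq,
        sd.ProtectionProfile.uniform(
            n, k_int=k_int, protected=protected or set(), protected_pf=10.0
        ),
        peps, noise_da=noise, seed=seed_mut,
    )
    return mut, wt


class TestDifferenceTable:
    def test_identity_gives_all_no_change(self):
        mut, wt = make_tables()
        rows = difference_table(wt, wt, 300.0)
        assert all(r.classification == "no-change" for r in rows)
        assert all(r.delta_pct == 0.0 for r in rows)

    def test_band_boundary_is_strict(self):
        row = hdx.classify(-5.0)
        assert row == "no-change"
        assert hdx.classify(-5.0001) == "protected"
        assert hdx.classify(5.0) == "no-change"
        assert hdx.classify(5.0001) == "deprotected"

    def test_synthetic_protection_classified(self):
        mut, wt = make_tables(protected=set(range(20, 26)))
        rows = difference_table(mut, wt, 300.0)
        for r in rows:
            if r.start >= 20 and r.end <= 25:
                assert r.classification == "protected"
            if r.end < 20 or r.start > 25:
                assert r.classification == "no-change"

    def test_no_matching_peptides_rejected(self):
        mut, wt = make_tables()
        other = sd.simulate_hdx_peptides(
            "AAAAAAAAAA", sd.ProtectionProfile.uniform(10), [(1, 10)],
            noise_da=0.0, seed=1,
        )
        with pytest.raises(ValueError, match="no peptides matched"):
            difference_table(mut, other, 300.0)


class TestGreedyCover:
    def peptide(self, start, end, value=-8.0):
        length = end - start + 1
        return WoodsRow(
            peptide_id=f"{start}-{end}", sequence="A" * length,
            start=start, end=end, delta_pct=value,
            classification=hdx.classify(value),
        )

    def test_spec_example_never_selects_long_peptide(self):
        rows = [
            self.peptide(1, 20), self.peptide(1, 6),
            self.peptide(5, 12), self.peptide(11, 20),
        ]
        chosen = greedy_minimal_cover(rows)
        spans = {(r.start, r.end) for r in chosen}
        assert spans == {(1, 6), (5, 12), (11, 20)}

    def test_matches_brute_force_shortest_peptide_cover(self):
        # exhaustive search over all covering subsets; the scheme's objective
        # is spatial resolution, so covers are ranked by (longest peptide
        # used, then summed length)
        rows = [
            self.peptide(*span)
            for span in [(1, 20), (1, 6), (5, 12), (11, 20)]
        ]
        need = set(range(1, 21))
        best = None
        best_key = None
        for k in range(1, len(rows) + 1):
            for combo in itertools.combinations(rows, k):
                covered = set()
                for r in combo:
                    covered.update(range(r.start, r.end + 1))
                if covered >= need:
                    key = (
                        max(r.end - r.start + 1 for r in combo),
                        sum(r.end - r.start + 1 for r in combo),
                    )
                    if best_key is None or key < best_key:
                        best_key = key
                        best = {(r.start, r.end) for r in combo}
        greedy = {(r.start, r.end) for r in greedy_minimal_cover(rows)}
        assert greedy == best

    def test_each_selection_is_locally_shortest(self):
        # defining property: walking left to right, every chosen peptide is
        # the shortest one covering the first still-uncovered position
        rows = [
            self.peptide(*span)
            for span in [(1, 20), (1, 6), (5, 12), (11, 20), (3, 9), (14, 20)]
        ]
        chosen = greedy_minimal_cover(rows)
        covered: set[int] = set()
        need = set()
        for r in rows:
            need.update(range(r.start, r.end + 1))
        for r in sorted(chosen, key=lambda r: r.start):
            pos = min(need - covered)
            candidates = [c for c in rows if c.start <= pos <= c.end]
            shortest = min(
                candidates, key=lambda c: (c.end - c.start + 1, c.start)
            )
            assert (r.start, r.end) == (shortest.start, shortest.end)
            covered.update(range(r.start, r.end + 1))
        assert covered >= need


class TestResidueInterpolation:
    def test_single_peptide_spreads_over_coverage(self):
        rows = [
            WoodsRow("1-10", "A" * 10, 1, 10, -8.0, "protected"),
        ]
        prof = residue_interpolation(rows, "all-peptides", n_residues=15)
        assert np.allclose(prof.values[:10], -8.0)
        assert np.all(prof.no_data[10:])
        assert np.all(np.isnan(prof.values[10:]))

    def test_equal_length_peptides_average(self):
        rows = [
            WoodsRow("1-10", "A" * 10, 1, 10, -10.0, "protected"),
            WoodsRow("1-10b", "C" + "A" * 9, 1, 10, 0.0, "no-change"),
        ]
        prof = residue_interpolation(rows, "all-peptides")
        assert np.allclose(prof.values, -5.0)

    def test_exact_recovery_of_flat_value(self):
        # any mixture of peptide lengths recovers a constant difference
        rows = [
            WoodsRow("1-20", "A" * 20, 1, 20, -12.0, "protected"),
            WoodsRow("1-6", "A" * 6, 1, 6, -12.0, "protected"),
            WoodsRow("5-12", "A" * 8, 5, 12, -12.0, "protected"),
        ]
        for scheme in ("all-peptides", "short-peptides"):
            prof = residue_interpolation(rows, scheme)
            assert np.allclose(prof.values[~prof.no_data], -12.0)

    def test_ground_truth_block_recovered(self):
        mut, wt = make_tables(protected=set(range(20, 26)), noise=0.02)
        rows = difference_table(mut, wt, 300.0)
        prof = residue_interpolation(rows, "short-peptides", n_residues=30)
        protected = prof.residue_index[
            ~prof.no_data & (prof.values < -hdx.NO_CHANGE_BAND)
        ]
        assert len(protected) > 0
        # contiguous block overlapping the true 20-25 window
        assert np.all(np.diff(protected) == 1)
        assert set(protected) & set(range(20, 26))
        # smearing bounded by peptide length: nothing outside 15-30
        assert protected.min() >= 15 and protected.max() <= 30


class TestUptakeCurves:
    def test_mean_and_spread(self):
        table = PeptideUptakeTable(
            data=pd.DataFrame(
                {
                    "sequence": ["AAAAA"] * 4,
                    "start": [1] * 4, "end": [5] * 4,
                    "timepoint": [30.0, 30.0, FD, FD],
                    "replicate": [1, 2, 1, 2],
                    "centroid_mass": [1005.0, 1005.2, 1010.0, 1010.0],
                }
            ),
            m0={("AAAAA", 1, 5): 1000.0},
        )
        curves = uptake_curves(table, ("AAAAA", 1, 5))
        assert len(curves) == 1
        assert curves["mean_pct"].iloc[0] == pytest.approx(51.0)
        assert curves["sd_pct"].iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_single_replicate_sd_is_missing_not_zero(self):
        table = PeptideUptakeTable(
            data=pd.DataFrame(
                {
                    "sequence": ["AAAAA"], "start": [1], "end": [5],
                    "timepoint": [30.0], "replicate": [1],
                    "centroid_mass": [1002.0],
                }
            ),
            m0={("AAAAA", 1, 5): 1000.0},
        )
        curves = uptake_curves(table, ("AAAAA", 1, 5))
        assert np.isnan(curves["sd_pct"].iloc[0])

    def test_saturating_profile_monotone(self):
        mut, wt = make_tables(k_int=0.001)
        key = wt.peptides()[0]
        curves = uptake_curves(wt, key)
        assert np.all(np.diff(curves["mean_pct"]) >= -1e-9)

    def test_unknown_peptide_rejected(self):
        mut, wt = make_tables()
        with pytest.raises(ValueError, match="unknown peptide"):
            uptake_curves(wt, ("ZZZZ", 1, 4))


def test_uptake_table_round_trips_csv(tmp_path):
    mut, _ = make_tables(noise=0.02)
    path = tmp_path / "uptake.csv"
    mut.to_csv(path)
    back = PeptideUptakeTable.from_csv(path)
    assert set(back.peptides()) == set(mut.peptides())
    pd.testing.assert_frame_equal(
        back.data.reset_index(drop=True),
        mut.data.reset_index(drop=True),
        check_dtype=False,
    )
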