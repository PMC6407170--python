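"""Marker QC: MAF/missingness stats, threshold filters, count surface,
and the location/block phenotype adjustment."""

import numpy as np
import pandas as pd
import pytest

from gpsurface import (
    QCGrid,
    adjust_phenotype,
    compute_marker_stats,
    filter_markers,
    marker_count_surface,
)
from .conftest import make_matrix


def brute_force_stats(dosages):
    """Independent per-entry tally of MAF and missing fraction."""
    n, p = dosages.shape
    maf, pmms = np.zeros(p), np.zeros(p)
    for j in range(p):
        called, total, n_miss = 0, 0, 0
        for i in range(n):
            if np.isnan(dosages[i, j]):
                n_miss += 1
            else:
                called += 1
                total += dosages[i, j]
        pmms[j] = n_miss / n
        if called == 0:
            maf[j] = 0.0
        else:
            f = total / (2 * called)
            maf[j] = min(f, 1 - f)
    return maf, pmms


class TestComputeMarkerStats:
    def test_textbook_frequency(self):
        m = make_matrix([[0], [2], [2], [2]])
        s = compute_marker_stats(m)
        assert s.maf[0] == pytest.approx(0.25)  # f = 6/8 = 0.75
        assert s.pmms[0] == 0.0

    def test_missing_calls_excluded_from_frequency(self):
        m = make_matrix([[2], [np.nan], [0], [np.nan]])
        s = compute_marker_stats(m)
        assert s.pmms[0] == pytest.approx(0.5)
        assert s.maf[0] == pytest.approx(0.5)  # f = 2/4

    def test_all_missing_marker_flagged(self):
        m = make_matrix([[np.nan, 1], [np.nan, 1]])
        s = compute_marker_stats(m)
        assert s.no_calls[0] and not s.no_calls[1]
        assert s.maf[0] == 0.0 and s.pmms[0] == 1.0

    def test_matches_brute_force_tally(self, random_panel):
        s = compute_marker_stats(random_panel)
        maf, pmms = brute_force_stats(random_panel.dosages)
        np.testing.assert_allclose(s.maf, maf)
        np.testing.assert_allclose(s.pmms, pmms)

    def test_invariant_to_line_and_marker_order(self, random_panel, rng):
        s = compute_marker_stats(random_panel)
        li = rng.permutation(random_panel.n_lines)
        mi = rng.permutation(random_panel.n_markers)
        shuffled = random_panel.subset_lines(li).subset_markers(mi)
        s2 = compute_marker_stats(shuffled)
        np.testing.assert_allclose(s2.maf, s.maf[mi])
        np.testing.assert_allclose(s2.pmms, s.pmms[mi])


class TestFilterMarkers:
    def test_identity_filter_keeps_all(self, random_panel):
        s = compute_marker_stats(random_panel)
        out, kept = filter_markers(random_panel, s, 0.0, 1.0)
        assert kept.size == random_panel.n_markers

    def test_matches_brute_force_predicate(self, random_panel):
        s = compute_marker_stats(random_panel)
        _, kept = filter_markers(random_panel, s, 0.1, 0.2)
        expected = [j for j in range(random_panel.n_markers)
                    if s.maf[j] >= 0.1 and s.pmms[j] <= 0.2]
        assert kept.tolist() == expected

    def test_boundary_is_inclusive(self):
        m = make_matrix([[0.0, 0.0], [1.0, 2.0], [1.0, 2.0], [2.0, 2.0]])
        s = compute_marker_stats(m)  # maf = [0.5, 0.25]
        _, kept = filter_markers(m, s, 0.5, 1.0)
        assert kept.tolist() == [0]

    def test_idempotent(self, random_panel):
        s = compute_marker_stats(random_panel)
        once, _ = filter_markers(random_panel, s, 0.1, 0.3)
        s2 = compute_marker_stats(once)
        twice, kept2 = filter_markers(once, s2, 0.1, 0.3)
        assert kept2.size == once.n_markers
        assert np.array_equal(twice.dosages, once.dosages, equal_nan=True)


class TestMarkerCountSurface:
    def test_single_marker_hand_case(self):
        # one marker with maf 0.3, pmms 0.1 on a 10-line panel
        col = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, np.nan])[:, None]
        m = make_matrix(col)
        s = compute_marker_stats(m)
        assert s.maf[0] == pytest.approx(1 / 3)
        grid = QCGrid((0.2, 0.4), (0.05, 0.5))
        counts = marker_count_surface(m, grid)
        assert counts.tolist() == [[0, 1], [0, 0]]

    def test_equals_per_cell_filtering(self, random_panel):
        s = compute_marker_stats(random_panel)
        grid = QCGrid((0.05, 0.1, 0.2, 0.3), (0.05, 0.1, 0.2, 0.5))
        counts = marker_count_surface(random_panel, grid)
        for a, maf in enumerate(grid.maf_levels):
            for b, pmms in enumerate(grid.pmms_levels):
                _, kept = filter_markers(random_panel, s, maf, pmms)
                assert counts[a, b] == kept.size

    def test_monotone_along_both_axes(self, random_panel):
        grid = QCGrid((0.05, 0.1, 0.2, 0.3), (0.05, 0.1, 0.2, 0.5))
        counts = marker_count_surface(random_panel, grid)
        assert np.all(np.diff(counts, axis=0) <= 0)  # stricter MAF -> fewer
        assert np.all(np.diff(counts, axis=1) >= 0)  # looser PMMS -> more

    def test_full_sweep_grid_shape(self):
        grid = QCGrid.full_sweep()
        assert grid.shape == (12, 27)
        assert grid.n_cells == 324

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            QCGrid((0.2, 0.1), (0.5,))
        with pytest.raises(ValueError):
            QCGrid((0.1,), (0.5, 1.2))


class TestAdjustPhenotype:
    def test_single_block_reduces_to_centered_means(self):
        df = pd.DataFrame({"line": ["A", "B"], "value": [1.0, 3.0],
                           "location": ["X", "X"], "block": [1, 1]})
        adj = adjust_phenotype(df)
        got = dict(zip(adj.line_ids, adj.values))
        assert got["A"] == pytest.approx(-1.0)
        assert got["B"] == pytest.approx(1.0)

    def test_balanced_location_offsets_cancel(self):
        lines = ["A", "B", "C"]
        base = {"A": 1.0, "B": 2.0, "C": 4.0}
        rows = []
        for loc, off in [("X", 5.0), ("Y", -5.0)]:
            for l in lines:
                rows.append({"line": l, "value": base[l] + off,
                             "location": loc, "block": 1})
        adj = adjust_phenotype(pd.DataFrame(rows))
        ref = adjust_phenotype(pd.DataFrame(
            [{"line": l, "value": base[l], "location": loc, "block": 1}
             for loc in ("X", "Y") for l in lines]))
        order = np.argsort(adj.line_ids)
        np.testing.assert_allclose(adj.values[order], ref.values[np.argsort(ref.line_ids)],
                                   atol=1e-10)

    def test_unbalanced_matches_normal_equations(self, rng):
        # small unbalanced layout solved independently via pinv(X'X) X'y
        rows = []
        lines = [f"L{i}" for i in range(6)]
        effects = rng.standard_normal(6)
        for loc in ("X", "Y"):
            for b in (1, 2):
                chosen = rng.choice(6, size=rng.integers(3, 6), replace=False)
                for i in chosen:
                    rows.append({
                        "line": lines[i], "location": loc, "block": b,
                        "value": effects[i] + {"X": 2.0, "Y": -1.0}[loc]
                        + 0.3 * b + rng.standard_normal() * 0.1,
                    })
        df = pd.DataFrame(rows)
        adj = adjust_phenotype(df)

        uniq = list(pd.unique(df["line"]))
        cols = [np.ones((len(df), 1)),
                pd.get_dummies(df["location"]).to_numpy(float),
                pd.get_dummies(df["location"].astype(str) + "/" + df["block"].astype(str)).to_numpy(float),
                pd.get_dummies(df["line"]).reindex(columns=uniq, fill_value=0).to_numpy(float)]
        X = np.hstack(cols)
        y = df["value"].to_numpy(float)
        beta = np.linalg.pinv(X.T @ X) @ X.T @ y  # min-norm normal equations
        line_eff = beta[-len(uniq):]
        line_eff -= line_eff.mean()
        got = dict(zip(adj.line_ids, adj.values))
        for lid, expected in zip(uniq, line_eff):
            assert got[lid] == pytest.approx(expected, abs=1e-8)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="value"):
            adjust_phenotype(pd.DataFrame({"line": ["A"]}))
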