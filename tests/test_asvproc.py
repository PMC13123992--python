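"""Taxonomic assignment, control filtering, standardization, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fowldna import simulate as sim
from fowldna.asvproc import (
    aggregate_to_dates,
    apply_control_filter,
    assign_taxonomy,
    checklist_means,
    control_filter_threshold,
    focal_matrix,
    pool_community,
    standardize_depth,
)
from fowldna.containers import AsvTable, ConfigError


def hit(asv, species, genus, family, ident, score=400.0):
    return {
        "asv_id": asv, "subject_species": species, "subject_genus": genus,
        "subject_family": family, "pct_identity": ident, "score": score,
    }


class TestAssignTaxonomy:
    def test_every_branch_of_the_assignment_rule(self):
        """Single species >=98 -> species; equal-identity congeners ->
        genus; equal-identity confamilials -> family; cross-family ties ->
        excluded; sub-98 single species -> genus; no hits -> excluded."""
        hits = pd.DataFrame(
            [
                # species-level: single best species at >= 98
                hit("A1", "Anas acuta", "Anas", "Anatidae", 99.1),
                hit("A1", "Anas crecca", "Anas", "Anatidae", 93.0, 300.0),
                # genus-level: two congeners tied at the top identity
                hit("A2", "Anas acuta", "Anas", "Anatidae", 99.0),
                hit("A2", "Anas crecca", "Anas", "Anatidae", 99.0),
                # family-level: tie across genera within one family
                hit("A3", "Anas acuta", "Anas", "Anatidae", 98.4),
                hit("A3", "Aythya marila", "Aythya", "Anatidae", 98.4),
                # excluded: best hits span two families
                hit("A4", "Anas acuta", "Anas", "Anatidae", 91.0),
                hit("A4", "Esox lucius", "Esox", "Esocidae", 91.0),
                # sub-98 single species falls back to its genus
                hit("A5", "Anas acuta", "Anas", "Anatidae", 96.5),
            ]
        )
        out = {a.asv_id: a for a in assign_taxonomy(hits, asv_ids=["A1", "A2", "A3", "A4", "A5", "A6"])}
        assert (out["A1"].rank, out["A1"].name, out["A1"].basis) == (
            "species", "Anas acuta", "single_species_ge98")
        assert (out["A2"].rank, out["A2"].name) == ("genus", "Anas")
        assert (out["A3"].rank, out["A3"].name) == ("family", "Anatidae")
        assert out["A4"].rank == "excluded"
        assert (out["A5"].rank, out["A5"].name, out["A5"].basis) == ("genus", "Anas", "tie_lca_genus")
        assert (out["A6"].rank, out["A6"].basis) == ("excluded", "no_hits")
        assert len(out) == 6  # totality: one assignment per ASV

    def test_truncates_to_top_five_by_score_then_identity(self):
        rows = [hit("A1", f"Sp {i}", f"G{i}", "Anatidae", 90.0 + i, score=100.0 + i) for i in range(7)]
        # the 2 lowest-scoring rows are discarded; top-5 max identity = 96
        out = assign_taxonomy(pd.DataFrame(rows))[0]
        assert out.best_identity == 96.0
        # a >=98 hit outside the top five by score must not produce a species call
        rows.append(hit("A1", "Hidden species", "Hidden", "Anatidae", 99.9, score=1.0))
        out = assign_taxonomy(pd.DataFrame(rows))[0]
        assert out.name != "Hidden species"

    def test_malformed_identity_rejected(self):
        bad = pd.DataFrame([hit("A1", "x", "y", "z", 140.0)])
        with pytest.raises(ConfigError):
            assign_taxonomy(bad)


def toy_table(field_counts, control_counts, n_dates=2):
    """ASV table with given field and extraction/PCR-blank count columns."""
    field_counts = np.asarray(field_counts)
    control_counts = np.asarray(control_counts)
    n_asv = field_counts.shape[0]
    asvs = [f"A{i}" for i in range(n_asv)]
    cols, meta = {}, []
    for j in range(field_counts.shape[1]):
        name = f"F{j}"
        cols[name] = field_counts[:, j]
        meta.append((name, pd.Timestamp("2020-10-01") + pd.Timedelta(days=7 * (j % n_dates)), "field", j))
    for j in range(control_counts.shape[1]):
        name = f"C{j}"
        cols[name] = control_counts[:, j]
        stype = "extraction_blank" if j % 2 == 0 else "pcr_blank"
        meta.append((name, pd.Timestamp("2020-10-01"), stype, j))
    counts = pd.DataFrame(cols, index=asvs)
    meta = pd.DataFrame(meta, columns=["sample_id", "date", "sample_type", "replicate"]).set_index("sample_id")
    return AsvTable(counts, meta)


class TestControlFilter:
    def test_worked_example_control_sums_10_0_2_0(self):
        # per-ASV control sums {10, 0, 2, 0} -> mean of non-zero = 6
        table = toy_table(
            field_counts=np.zeros((4, 2), dtype=int),
            control_counts=np.array([[7, 3], [0, 0], [2, 0], [0, 0]]),
        )
        assert control_filter_threshold(table) == 6.0

    def test_all_zero_controls_give_zero_threshold(self):
        table = toy_table(np.ones((3, 2), dtype=int), np.zeros((3, 2), dtype=int))
        assert control_filter_threshold(table) == 0.0
        filtered = apply_control_filter(table, 0.0)
        pd.testing.assert_frame_equal(filtered.counts, table.counts)

    def test_single_nonzero_control_asv(self):
        table = toy_table(np.ones((2, 1), dtype=int), np.array([[7], [0]]))
        assert control_filter_threshold(table) == 7.0

    def test_per_control_mode(self):
        # column totals {9, 3} -> per-control mean 6
        table = toy_table(np.zeros((4, 1), dtype=int), np.array([[7, 3], [0, 0], [2, 0], [0, 0]]))
        assert control_filter_threshold(table, mode="per_control") == 6.0
        with pytest.raises(ConfigError):
            control_filter_threshold(table, mode="bogus")

    def test_no_controls_is_a_configuration_error(self):
        counts = pd.DataFrame({"F0": [1, 2]}, index=["A0", "A1"])
        meta = pd.DataFrame(
            [("F0", pd.Timestamp("2020-10-01"), "field", 1)],
            columns=["sample_id", "date", "sample_type", "replicate"],
        ).set_index("sample_id")
        with pytest.raises(ConfigError):
            control_filter_threshold(AsvTable(counts, meta))

    def test_fewer_than_is_strict_and_blanks_untouched(self):
        # field totals: A0=6 (== threshold, retained), A1=5 (< 6, removed)
        table = toy_table(
            field_counts=np.array([[3, 3], [2, 3], [10, 10], [0, 6]]),
            control_counts=np.array([[7, 3], [0, 0], [2, 0], [0, 0]]),
        )
        thr = control_filter_threshold(table)
        assert thr == 6.0
        filtered = apply_control_filter(table, thr)
        assert list(filtered.counts.index) == ["A0", "A2", "A3"]
        # blank columns carried through for QC
        assert set(filtered.counts.columns) == set(table.counts.columns)

    @given(st.integers(0, 30))
    @settings(derandomize=True, max_examples=40)
    def test_filter_monotone_in_threshold(self, thr):
        rng = np.random.default_rng(123)
        table = toy_table(rng.integers(0, 20, size=(8, 3)), rng.integers(0, 4, size=(8, 2)))
        lower = set(apply_control_filter(table, thr).counts.index)
        higher = set(apply_control_filter(table, thr + 1).counts.index)
        assert higher <= lower


class TestStandardizeDepth:
    def test_equal_depths_is_identity(self):
        table = toy_table(np.array([[5, 5], [5, 5]]), np.zeros((2, 1), dtype=int))
        out = standardize_depth(table)
        assert np.allclose(out.counts[out.field_samples], table.counts[table.field_samples])

    def test_ratio_scaling(self):
        # depths {1000, 500}: a count of 8 in the deep sample becomes 4
        table = toy_table(np.array([[8, 8], [992, 492]]), np.zeros((2, 1), dtype=int))
        out = standardize_depth(table)
        assert out.counts.loc["A0", "F0"] == pytest.approx(4.0)
        assert out.counts.loc["A0", "F1"] == pytest.approx(8.0)

    def test_column_sums_equal_min_depth_and_idempotent(self):
        rng = np.random.default_rng(7)
        table = toy_table(rng.integers(0, 50, size=(10, 4)), rng.integers(0, 3, size=(10, 2)))
        out = standardize_depth(table)
        dmin = table.field_depths().min()
        sums = out.counts[out.field_samples].sum(axis=0)
        assert np.allclose(sums, dmin, rtol=1e-6)
        twice = standardize_depth(out)
        pd.testing.assert_frame_equal(twice.counts, out.counts)

    def test_zero_depth_sample_dropped_with_warning(self, caplog):
        import logging

        table = toy_table(np.array([[5, 0], [5, 0]]), np.zeros((2, 1), dtype=int))
        with caplog.at_level(logging.WARNING):
            out = standardize_depth(table)
        assert out.field_samples == ["F0"]
        assert any("zero-depth" in r.message for r in caplog.records)


def simple_assignments(asvs, taxa):
    from fowldna.asvproc import TaxAssignment

    return [TaxAssignment(a, "species", t, 99.0, "single_species_ge98") for a, t in zip(asvs, taxa)]


class TestAggregateToDates:
    def test_plain_group_by_without_pools(self):
        table = toy_table(np.array([[4, 6], [1, 2], [10, 20]]), np.zeros((3, 1), dtype=int), n_dates=2)
        assignments = simple_assignments(["A0", "A1", "A2"], ["X", "X", "Y"])
        cm = aggregate_to_dates(table, assignments, pools=())
        assert cm.values.loc[pd.Timestamp("2020-10-01"), "X"] == 5
        assert cm.values.loc[pd.Timestamp("2020-10-08"), "Y"] == 20

    def test_pooling_sums_pair_members_and_conserves_total(self):
        table = toy_table(np.array([[4, 6], [1, 2], [10, 20]]), np.zeros((3, 1), dtype=int), n_dates=1)
        assignments = simple_assignments(
            ["A0", "A1", "A2"], ["Anas platyrhynchos", "Anas rubripes", "Y"]
        )
        pools = (("Anas platyrhynchos", "Anas rubripes"),)
        cm = aggregate_to_dates(table, assignments, pools=pools)
        assert "Anas platyrhynchos/Anas rubripes" in cm.taxa
        assert cm.values["Anas platyrhynchos/Anas rubripes"].iloc[0] == 13
        unpooled = aggregate_to_dates(table, assignments, pools=())
        assert cm.values.to_numpy().sum() == pytest.approx(unpooled.values.to_numpy().sum(), rel=1e-6)

    def test_three_equal_replicates_triple_the_single_value(self):
        col = np.array([[4], [6]])
        table = toy_table(np.hstack([col, col, col]), np.zeros((2, 1), dtype=int), n_dates=1)
        single = toy_table(col, np.zeros((2, 1), dtype=int), n_dates=1)
        assignments = simple_assignments(["A0", "A1"], ["X", "Y"])
        three = aggregate_to_dates(table, assignments, pools=())
        one = aggregate_to_dates(single, assignments, pools=())
        assert np.allclose(three.values.to_numpy(), 3 * one.values.to_numpy())

    def test_pool_naming_absent_taxon_is_noop(self):
        table = toy_table(np.array([[4]]), np.zeros((1, 1), dtype=int), n_dates=1)
        assignments = simple_assignments(["A0"], ["X"])
        cm = aggregate_to_dates(table, assignments, pools=(("Nope a", "Nope b"),))
        assert cm.taxa == ["X"]

    def test_excluded_asvs_dropped(self):
        from fowldna.asvproc import TaxAssignment

        table = toy_table(np.array([[4], [9]]), np.zeros((2, 1), dtype=int), n_dates=1)
        assignments = [
            TaxAssignment("A0", "species", "X", 99.0, "single_species_ge98"),
            TaxAssignment("A1", "excluded", "", 91.0, "below_family_excluded"),
        ]
        cm = aggregate_to_dates(table, assignments, pools=())
        assert cm.taxa == ["X"]
        assert cm.values.to_numpy().sum() == 4


class TestChecklistMeans:
    def test_single_checklist_verbatim(self):
        cl = pd.DataFrame(
            [("c1", "2020-10-01", "X", 10), ("c1", "2020-10-01", "Y", 3)],
            columns=["checklist_id", "date", "species", "count"],
        )
        cm = checklist_means(cl)
        assert cm.values.loc[pd.Timestamp("2020-10-01"), "X"] == 10
        assert cm.extra["n_checklists"].iloc[0] == 1

    def test_absent_species_counts_as_zero(self):
        # X on one of two checklists: mean (10 + 0)/2 = 5; Y never seen that day
        cl = pd.DataFrame(
            [
                ("c1", "2020-10-01", "X", 10),
                ("c2", "2020-10-01", "Z", 4),
                ("c1", "2020-10-08", "Y", 6),
            ],
            columns=["checklist_id", "date", "species", "count"],
        )
        cm = checklist_means(cl)
        d1 = pd.Timestamp("2020-10-01")
        assert cm.values.loc[d1, "X"] == 5
        assert cm.values.loc[d1, "Y"] == 0

    def test_missing_date_excluded_with_warning(self, caplog):
        import logging

        cl = pd.DataFrame(
            [("c1", "2020-10-01", "X", 10)],
            columns=["checklist_id", "date", "species", "count"],
        )
        with caplog.at_level(logging.WARNING):
            cm = checklist_means(cl, dates=["2020-10-01", "2020-10-08"])
        assert len(cm.dates) == 1
        assert any("no checklists" in r.message for r in caplog.records)


def test_end_to_end_recovery_proportional_to_truth():
    """With no contamination, no overdispersion, lag kernel concentrated at
    0 and equal shedding, standardized reads per date are proportional to
    true abundance up to multinomial noise."""
    cfg = sim.default_config(
        seed=13, read_depth_per_sample=200_000, read_overdispersion=0.0,
        contamination_rate=0.0, lag_kernel=(1.0, 0, 0, 0, 0, 0),
    )
    truth = sim.simulate_abundance(cfg)
    rs = sim.simulate_reads(truth, cfg)
    assignments = assign_taxonomy(rs.hits, asv_ids=list(rs.asv_table.counts.index))
    std = standardize_depth(rs.asv_table)
    cm = aggregate_to_dates(std, assignments, pools=())
    for d in cm.dates:
        t = truth.values.loc[d]
        r = cm.values.loc[d]
        shared = [s for s in t.index if t[s] > 50]
        t_shares = (t[shared] / t[shared].sum()).to_numpy()
        r_shares = (r[shared] / r[shared].sum()).to_numpy()
        assert np.allclose(t_shares, r_shares, atol=0.01)


def test_pool_community_and_focal_matrix_roundtrip(bundle):
    focal = focal_matrix(bundle.surveys.focal)
    pooled = pool_community(focal, (("Anas platyrhynchos", "Anas rubripes"),))
    assert "Anas platyrhynchos" not in pooled.taxa
    assert "Anas platyrhynchos/Anas rubripes" in pooled.taxa
    assert pooled.values.to_numpy().sum() == pytest.approx(focal.values.to_numpy().sum())
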