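"""Rarefaction, core-genus screen, PC-taxon screen, dominance, rrn and MCN."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import acidonet as an
from acidonet.screen import CoreCriteria


class TestRarefy:
    def test_columns_sum_to_depth(self, bundle):
        rar = an.rarefy(bundle["table"], 5000, seed=0)
        assert (rar.counts.sum(axis=0) == 5000).all()

    def test_exhaustive_depth_returns_column_unchanged(self, tiny_table):
        rar = an.rarefy(tiny_table, 100, seed=1)
        pd.testing.assert_series_equal(rar.counts["S1"], tiny_table.counts["S1"])

    def test_marginal_expectation_hypergeometric(self, tiny_table):
        """Mean rarefied count over seeds approaches depth * count / total."""
        depth = 50
        means = np.zeros(4)
        n_rep = 200
        for s in range(n_rep):
            means += an.rarefy(tiny_table, depth, seed=s).counts["S4"].to_numpy()
        means /= n_rep
        expected = depth * tiny_table.counts["S4"] / tiny_table.counts["S4"].sum()
        assert np.allclose(means, expected, rtol=0.05, atol=0.6)

    def test_shallow_sample_dropped_with_warning(self, tiny_table):
        with pytest.warns(UserWarning, match="shallower"):
            rar = an.rarefy(tiny_table, 101, seed=0)
        assert "S1" not in rar.counts.columns  # S1 sums to exactly 100

    def test_invalid_depth(self, tiny_table):
        with pytest.raises(ValueError):
            an.rarefy(tiny_table, 0)


class TestToRelative:
    def test_columns_sum_to_one_and_idempotent(self, tiny_table):
        rel = an.to_relative(tiny_table)
        assert np.allclose(rel.counts.sum(axis=0), 1.0, atol=1e-9)
        again = an.to_relative(rel)
        assert np.allclose(again.counts.values, rel.counts.values)

    def test_simple_values(self):
        t = an.AbundanceTable(pd.DataFrame({"S1": [2, 2]}, index=["a", "b"]))
        assert np.allclose(an.to_relative(t).counts["S1"], [0.5, 0.5])

    def test_zero_column_rejected(self):
        t = an.AbundanceTable(pd.DataFrame({"S1": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="degenerate"):
            an.to_relative(t)


def brute_force_core(rel: pd.DataFrame, c: CoreCriteria):
    """Independent re-evaluation of the three core predicates, row by row."""
    n_s = rel.shape[1]
    n_g = rel.shape[0]
    out = set()
    for g in rel.index:
        row = rel.loc[g]
        ubiq = (row > 0).sum() > c.ubiquity_frac * n_s
        abund = row.mean() > c.abundant_cutoff
        hits = 0
        for s in rel.columns:
            col = rel[s]
            rank = int((col > col[g]).sum()) + 1
            if col[g] > 0 and rank <= c.frequent_rank_quantile * n_g:
                hits += 1
        freq = hits > c.frequent_sample_frac * n_s
        if ubiq and abund and freq:
            out.add(g)
    return out


class TestCoreGenera:
    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            counts = pd.DataFrame(
                rng.integers(0, 40, size=(12, 9)),
                index=[f"G{i}" for i in range(12)],
                columns=[f"S{j}" for j in range(9)],
            )
            counts.iloc[0] += 30  # ensure at least one plausible core genus
            table = an.AbundanceTable(counts)
            crit = CoreCriteria()
            core, flags = an.screen_core_genera(table, crit)
            rel = an.to_relative(table).counts
            assert core == brute_force_core(rel, crit)

    def test_planted_core_genus_recovered(self, bundle):
        genus_tab = bundle["table"].aggregate_by("genus")
        core, flags = an.screen_core_genera(genus_tab)
        # the keystone genus is ubiquitous, abundant (>2%) and top-ranked
        assert "Nitrospira" in core
        assert flags.loc["Nitrospira"].all()

    def test_low_abundance_fails_mean_cutoff(self):
        counts = pd.DataFrame({f"S{j}": [5, 9995] for j in range(6)},
                              index=["rare", "dominant"])
        table = an.AbundanceTable(counts)
        _, flags = an.screen_core_genera(table)
        assert not flags.loc["rare", "abundant"]  # mean rel. abundance 5e-4 < 1e-3

    def test_empty_table(self):
        table = an.AbundanceTable(pd.DataFrame(index=pd.Index([], name="t"), columns=[]))
        core, flags = an.screen_core_genera(table)
        assert core == set() and flags.empty


class TestPcTaxa:
    def test_exact_copy_of_marker_selected(self, tiny_table):
        rel = an.to_relative(tiny_table).counts
        marker = rel.loc["T1"].to_numpy()
        sel, frame, group = an.screen_pc_taxa(tiny_table, ["T1", "T3"], marker)
        assert sel == ["T1"]
        assert frame.loc["T1", "r"] == pytest.approx(1.0)
        assert np.allclose(group, rel.loc["T1"])

    def test_constant_marker_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="constant"):
            an.screen_pc_taxa(tiny_table, ["T1"], np.ones(5))

    def test_type_one_error_controlled(self):
        """An independent taxon is selected in about alpha of the runs (with
        r_min=0 the screen reduces to the p-value test)."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            counts = pd.DataFrame(
                rng.integers(1, 100, size=(5, 36)),
                index=[f"T{i}" for i in range(5)],
                columns=[f"S{j}" for j in range(36)],
            )
            marker = rng.normal(size=36)
            table = an.AbundanceTable(counts)
            sel, _, _ = an.screen_pc_taxa(table, ["T0"], marker, r_min=0.0, p_max=0.05)
            hits += bool(sel)
        # one-sided selection halves the nominal two-sided rate
        assert hits / n_rep < 0.06

    def test_planted_taxon_recovered(self):
        """The keystone tracks the (log-scale) comammox amoA marker in nearly
        all surveys when the qPCR table is tied to the community."""
        found = 0
        for seed in range(20):
            spec = an.CommunitySpec(seed=seed)
            meta = an.generate_metadata(spec)
            table, truth = an.generate_community(spec, meta)
            marker = an.generate_guild_amoa(meta, spec, truth, table)["comammox"]
            sel, _, _ = an.screen_pc_taxa(
                table, [truth.keystone_id], marker.to_numpy(), r_min=0.5
            )
            found += truth.keystone_id in sel
        assert found >= 18


class TestDominance:
    def test_shares_and_label(self):
        g = pd.DataFrame({"AOA": [10.0], "AOB": [10.0], "comammox": [80.0]}, index=["S1"])
        out = an.classify_dominant_oxidizer(g)
        assert out.loc["S1", "label"] == "comammox"
        assert out.loc["S1", "share_comammox"] == pytest.approx(0.8)

    def test_tie_broken_alphabetically_and_flagged(self):
        g = pd.DataFrame({"AOA": [50.0], "AOB": [50.0], "comammox": [0.0]}, index=["S1"])
        out = an.classify_dominant_oxidizer(g)
        assert out.loc["S1", "label"] == "AOA"
        assert bool(out.loc["S1", "tie"])

    def test_all_zero_unclassifiable(self):
        g = pd.DataFrame({"AOA": [0.0], "AOB": [0.0], "comammox": [0.0]}, index=["S1"])
        out = an.classify_dominant_oxidizer(g)
        assert bool(out.loc["S1", "unclassifiable"]) and out.loc["S1", "label"] is None

    def test_planted_dominance_fraction(self):
        """Comammox dominates roughly the planted ~62% of samples."""
        fracs = []
        for seed in range(20):
            spec = an.CommunitySpec(seed=seed)
            meta = an.generate_metadata(spec)
            copies = an.linear_copies(an.generate_guild_amoa(meta, spec))
            out = an.classify_dominant_oxidizer(copies)
            fracs.append((out["label"] == "comammox").mean())
        assert abs(np.mean(fracs) - 0.62) < 0.10


class TestRrnAndMcn:
    def test_assignment_rank_fallback(self, tiny_table):
        lookup = an.RrnLookup(pd.DataFrame([
            {"name": "sp2", "rank": "species", "copies": 4.0},
            {"name": "G1", "rank": "genus", "copies": 2.0},
            {"name": "F2", "rank": "family", "copies": 6.0},
        ]))
        out = an.assign_rrn(tiny_table, lookup)
        assert out.loc["T1", "provenance"] == "genus" and out.loc["T1", "copies"] == 2.0
        assert out.loc["T2", "provenance"] == "species" and out.loc["T2", "copies"] == 4.0
        assert out.loc["T3", "provenance"] == "family" and out.loc["T3", "copies"] == 6.0

    def test_unmatched_flagged(self, tiny_table):
        lookup = an.RrnLookup(pd.DataFrame([{"name": "G1", "rank": "genus", "copies": 2.0}]))
        with pytest.warns(UserWarning, match="unmatched"):
            out = an.assign_rrn(tiny_table, lookup)
        assert out.loc["T2", "provenance"] == "unmatched"
        assert np.isnan(out.loc["T2", "copies"])

    def test_mcn_hand_values(self):
        t = an.AbundanceTable(pd.DataFrame({"S1": [50, 50]}, index=["a", "b"]))
        mcn = an.compute_mcn(t, pd.Series({"a": 1.0, "b": 3.0}))
        assert mcn["S1"] == pytest.approx(2.0)
        one = an.compute_mcn(
            an.AbundanceTable(pd.DataFrame({"S1": [7]}, index=["a"])),
            pd.Series({"a": 1.0}),
        )
        assert one["S1"] == pytest.approx(1.0)

    def test_mcn_bounded_and_scale_invariant(self, bundle):
        rrn = pd.Series(bundle["truth"].rrn_map)
        m_counts = an.compute_mcn(bundle["table"], rrn)
        m_rel = an.compute_mcn(an.to_relative(bundle["table"]), rrn)
        assert np.allclose(m_counts, m_rel)
        assert (m_counts >= rrn.min() - 1e-9).all()
        assert (m_counts <= rrn.max() + 1e-9).all()

    def test_unmatched_mass_renormalized(self):
        t = an.AbundanceTable(
            pd.DataFrame({"S1": [25, 25, 50]}, index=["a", "b", "c"])
        )
        rrn = pd.Series({"a": 1.0, "b": 3.0})  # c unmatched
        with pytest.warns(UserWarning):
            renorm = an.compute_mcn(t, rrn, min_coverage=0.6)
        assert renorm["S1"] == pytest.approx(2.0)
        with pytest.warns(UserWarning):
            raw = an.compute_mcn(t, rrn, renormalize=False, min_coverage=0.6)
        assert raw["S1"] == pytest.approx(1.0)

    def test_mcn_ph_recovery(self):
        """Planted low-rrn acid taxa give a positive MCN-pH correlation."""
        hits = 0
        for seed in range(20):
            spec = an.CommunitySpec(seed=seed)
            meta = an.generate_metadata(spec)
            table, truth = an.generate_community(spec, meta)
            mcn = an.compute_mcn(table, pd.Series(truth.rrn_map))
            hits += stats.pearsonr(mcn, meta["pH"])[0] > 0.6
        assert hits >= 18
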