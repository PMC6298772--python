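"""Screen scoring: filtering, normalization, LFC, second-best gene ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from erktools import screen
from erktools.io import GuideLibrary, ScreenCountMatrix
from erktools import simulate as sim

from conftest import screen_oracle


def _matrix(rows: dict, reference="plasmid") -> ScreenCountMatrix:
    return ScreenCountMatrix(
        pd.DataFrame(rows).set_index("guide_id"), reference_sample=reference
    )


class TestFilter:
    def test_boundary_29_excluded_30_retained(self):
        m = _matrix({"guide_id": ["g1", "g2"], "plasmid": [30, 100],
                     "final": [29, 30]})
        kept = screen.filter_low_counts(m, "final", threshold=30)
        assert kept == {"g2"}

    def test_scope_both_requires_reference_too(self):
        m = _matrix({"guide_id": ["g1"], "plasmid": [10], "final": [500]})
        assert screen.filter_low_counts(m, "final", 30, scope="both") == set()
        assert screen.filter_low_counts(m, "final", 30, scope="sample") == {"g1"}

    def test_threshold_zero_keeps_everything(self):
        m = _matrix({"guide_id": ["g1", "g2"], "plasmid": [0, 1], "final": [0, 2]})
        assert screen.filter_low_counts(m, "final", threshold=0) == {"g1", "g2"}

    def test_empty_matrix_is_error(self):
        m = ScreenCountMatrix(
            pd.DataFrame({"plasmid": [], "final": []}, dtype=np.int64), "plasmid"
        )
        with pytest.raises(ValueError, match="empty"):
            screen.filter_low_counts(m, "final")


class TestNormalize:
    def test_closed_form_column(self):
        m = _matrix({"guide_id": ["a", "b", "c"], "plasmid": [10, 30, 60],
                     "final": [1, 1, 1]})
        rpm = screen.normalize_to_depth(m)
        np.testing.assert_allclose(rpm["plasmid"], [1e5, 3e5, 6e5])

    def test_single_guide_gets_full_scale(self):
        m = _matrix({"guide_id": ["a"], "plasmid": [5], "final": [7]})
        assert screen.normalize_to_depth(m)["plasmid"].iloc[0] == pytest.approx(1e6)

    def test_zero_total_column_names_sample(self):
        m = _matrix({"guide_id": ["a"], "plasmid": [0], "final": [7]})
        with pytest.raises(ValueError, match="plasmid"):
            screen.normalize_to_depth(m)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 10_000), min_size=2, max_size=2),
                    min_size=1, max_size=40))
    def test_columns_sum_to_one_million(self, rows):
        if sum(r[0] for r in rows) == 0 or sum(r[1] for r in rows) == 0:
            return
        m = _matrix({"guide_id": [f"g{i}" for i in range(len(rows))],
                     "plasmid": [r[0] for r in rows],
                     "final": [r[1] for r in rows]})
        rpm = screen.normalize_to_depth(m)
        np.testing.assert_allclose(rpm.sum(axis=0), [1e6, 1e6], atol=1e-3)


class TestGuideLFC:
    def test_identity_and_closed_form(self):
        assert screen.guide_lfc(5.0, 5.0) == 0.0
        assert screen.guide_lfc(7.0, 0.0, pseudocount=1.0) == pytest.approx(3.0)

    def test_antisymmetry(self):
        a, b = 123.4, 7.8
        assert screen.guide_lfc(a, b) == pytest.approx(-screen.guide_lfc(b, a), abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            screen.guide_lfc(-1.0, 2.0)


class TestRankGenes:
    def _library(self, genes):
        rows = [(f"{g}_sg{i}", g, g == "CONTROL") for g, n in genes.items()
                for i in range(n)]
        f = pd.DataFrame(rows, columns=["guide_id", "gene", "is_control"])
        return GuideLibrary(f)

    def _table(self, lib, lfcs, passed=None):
        f = lib.frame.copy()
        f["lfc"] = lfcs
        f["passed_filter"] = True if passed is None else passed
        return f

    def test_second_order_statistics(self):
        lib = self._library({"A": 4})
        t = self._table(lib, [5.0, 3.0, 1.0, 0.0])
        out = screen.rank_genes(t, lib).set_index("gene")
        assert out.loc["A", "second_best_enriched"] == 3.0
        assert out.loc["A", "second_best_depleted"] == 1.0

    def test_tied_guides(self):
        lib = self._library({"A": 2})
        out = screen.rank_genes(self._table(lib, [2.0, 2.0]), lib).set_index("gene")
        assert out.loc["A", "second_best_enriched"] == 2.0

    def test_single_guide_gene_excluded_not_ranked(self):
        lib = self._library({"A": 2, "B": 2})
        t = self._table(lib, [1.0, 2.0, 3.0, 4.0], passed=[True, True, True, False])
        out = screen.rank_genes(t, lib).set_index("gene")
        assert out.loc["B", "excluded"] and out.loc["B", "exclusion_reason"] == "lt2_guides"
        assert pd.isna(out.loc["B", "enrichment_rank"])
        assert out.loc["A", "enrichment_rank"] == 1

    def test_controls_reported_but_unranked(self):
        lib = self._library({"A": 2, "CONTROL": 3})
        t = self._table(lib, [0.5, 0.2, 0.1, 0.0, -0.1])
        out = screen.rank_genes(t, lib).set_index("gene")
        assert out.loc["CONTROL", "excluded"]
        assert out.loc["CONTROL", "exclusion_reason"] == "control"
        assert out.loc["CONTROL", "second_best_enriched"] == 0.0
        ranks = out.loc[~out["excluded"], "enrichment_rank"]
        assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_matches_brute_force_on_200_random_genes(self, rng):
        genes = {f"G{i:03d}": 4 for i in range(200)}
        lib = self._library(genes)
        lfcs = rng.normal(size=len(lib.frame))
        t = self._table(lib, lfcs)
        out = screen.rank_genes(t, lib).set_index("gene")
        # brute force: sort each gene's lfcs, take index -2 / 1
        df = t.groupby("gene")["lfc"].apply(lambda s: np.sort(s.to_numpy()))
        for gene, vals in df.items():
            assert out.loc[gene, "second_best_enriched"] == pytest.approx(vals[-2])
            assert out.loc[gene, "second_best_depleted"] == pytest.approx(vals[1])
        order = out.loc[~out["excluded"]].sort_values(
            ["second_best_enriched", "gene"], ascending=[False, True]
        )
        assert list(order["enrichment_rank"]) == list(range(1, 201))


class TestRunScreen:
    def test_agrees_with_direct_formula_transcription(self, rng):
        for trial in range(10):
            n = int(rng.integers(6, 50))
            genes = [f"G{i}" for i in range(max(2, n // 3))]
            gene_of = {f"g{i}": genes[i % len(genes)] for i in range(n)}
            lib = GuideLibrary(pd.DataFrame(
                {"guide_id": list(gene_of), "gene": list(gene_of.values()),
                 "is_control": False}))
            raw = pd.DataFrame(
                rng.integers(0, 2000, size=(n, 3)),
                index=pd.Index(list(gene_of), name="guide_id"),
                columns=["plasmid", "untreated_final", "treated_final"],
            )
            if (raw.sum(axis=0) == 0).any():
                continue
            m = ScreenCountMatrix(raw, "plasmid")
            gt, rk = screen.run_screen(m, lib, "treated_final")
            lfcs, stats, enr, dep = screen_oracle(
                raw, gene_of, "treated_final", "plasmid")
            got = gt.set_index("guide_id")
            for g, lfc in lfcs.items():
                assert got.loc[g, "lfc"] == pytest.approx(lfc, abs=1e-12)
            assert set(got.index[got["passed_filter"]]) == set(lfcs)
            rk = rk.set_index("gene")
            for gene, (se, sd) in stats.items():
                assert rk.loc[gene, "second_best_enriched"] == pytest.approx(se, abs=1e-12)
                assert rk.loc[gene, "second_best_depleted"] == pytest.approx(sd, abs=1e-12)
            for gene, r in enr.items():
                assert rk.loc[gene, "enrichment_rank"] == r
            for gene, r in dep.items():
                assert rk.loc[gene, "depletion_rank"] == r

    def test_self_comparison_is_all_zero(self):
        lib, m, _ = sim.simulate_screen(sim.ScreenSimSpec(n_genes=20, seed=1))
        gt, rk = screen.run_screen(m, lib, "plasmid")
        passed = gt[gt["passed_filter"]]
        assert np.allclose(passed["lfc"], 0.0)
        ranked = rk[~rk["excluded"]]
        assert np.allclose(ranked["second_best_enriched"], 0.0)

    def test_antisymmetry_under_sample_swap(self, rng):
        lib, m, _ = sim.simulate_screen(sim.ScreenSimSpec(n_genes=30, seed=13))
        swapped = ScreenCountMatrix(
            m.counts.rename(columns={"plasmid": "treated_final",
                                     "treated_final": "plasmid"}),
            "plasmid",
        )
        gt1, rk1 = screen.run_screen(m, lib, "treated_final", threshold=0)
        gt2, rk2 = screen.run_screen(swapped, lib, "treated_final", threshold=0)
        np.testing.assert_allclose(gt1["lfc"], -gt2["lfc"], atol=1e-12)
        r1 = rk1.set_index("gene")
        r2 = rk2.set_index("gene")
        ranked = r1.index[~r1["excluded"]]
        assert (r1.loc[ranked, "enrichment_rank"] ==
                r2.loc[ranked, "depletion_rank"]).all()

    def test_scale_invariance_of_one_sample(self):
        lib, m, _ = sim.simulate_screen(sim.ScreenSimSpec(n_genes=25, seed=3))
        scaled = m.counts.copy()
        scaled["treated_final"] = scaled["treated_final"] * 7
        m2 = ScreenCountMatrix(scaled, "plasmid")
        gt1, rk1 = screen.run_screen(m, lib, "treated_final", threshold=0)
        gt2, rk2 = screen.run_screen(m2, lib, "treated_final", threshold=0)
        np.testing.assert_allclose(gt1["norm_sample"], gt2["norm_sample"], rtol=1e-12)
        np.testing.assert_allclose(gt1["lfc"], gt2["lfc"], atol=1e-12)
        np.testing.assert_allclose(
            rk1["second_best_enriched"], rk2["second_best_enriched"], atol=1e-12)
        assert (rk1["enrichment_rank"].fillna(-1) == rk2["enrichment_rank"].fillna(-1)).all()
        assert (rk1["depletion_rank"].fillna(-1) == rk2["depletion_rank"].fillna(-1)).all()

    def test_planted_gene_tops_ranking_at_low_noise(self):
        # recovery machinery check under modest overdispersion
        hits = 0
        for seed in range(10):
            lib, m, _ = sim.simulate_screen(sim.ScreenSimSpec(
                n_genes=500, mean_depth=500, nb_dispersion=0.05,
                planted_effects={"MAPK1": 2.0}, seed=seed))
            _, rk = screen.run_screen(m, lib, "treated_final")
            hits += rk.set_index("gene").loc["MAPK1", "enrichment_rank"] == 1
        assert hits >= 9
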