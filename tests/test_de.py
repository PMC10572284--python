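"""Differential expression: exact Wilcoxon, fold changes, ranking, contrasts."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import allosc
from allosc import ConfigurationError, SynthConfig
from allosc.de import (
    de_test,
    logistic_lr_p,
    prepost_contrast,
    rank_de,
    wilcoxon_exact_p,
)
from allosc.synth import simulate_counts
from conftest import make_normalized


def rank_sum_enumeration_p(x, y):
    """Independent oracle: enumerate every split of the pooled sample."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = np.asarray(x + y, dtype=float)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    le = ge = total = 0
    for combo in combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
    return float(min(1, 2 * min(Fraction(le, total), Fraction(ge, total))))


class TestWilcoxonExact:
    def test_matches_enumeration_oracle_with_ties(self):
        """Exact p equals full-permutation enumeration for all sizes <= 8."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for n1 in (3, 5, 8):
            for n2 in (3, 6, 8):
                for _ in range(5):
                    x = rng.integers(0, 4, n1).astype(float)
                    y = rng.integers(0, 4, n2).astype(float)
                    worst = max(worst, abs(wilcoxon_exact_p(x, y) - rank_sum_enumeration_p(x, y)))
        assert worst < 1e-10

    def test_fully_separated_groups_closed_form(self):
        x = np.full(5, np.log(101.0))
        y = np.zeros(5)
        assert wilcoxon_exact_p(x, y) == pytest.approx(2 / 252, abs=1e-12)

    def test_all_tied_values_give_p_one(self):
        assert wilcoxon_exact_p(np.ones(4), np.ones(6)) == 1.0


class TestDeTest:
    def _two_group_nm(self, values):
        nm = make_normalized(values)
        n = values.shape[1]
        cells_in = set(nm.barcodes[: n // 2])
        cells_out = set(nm.barcodes[n // 2:])
        return nm, cells_in, cells_out

    def test_separated_gene_fold_change_and_p(self):
        values = np.zeros((2, 10), dtype=int)
        values[0, :5] = 100
        values[1] = 1  # constant gene keeps cell totals positive on both sides
        nm = make_normalized(values)
        # give each cell the same total so normalized in-group values are ln(101)
        nm.values[0, :5] = np.log(101.0)
        nm.values[0, 5:] = 0.0
        res = de_test(nm, set(nm.barcodes[:5]), set(nm.barcodes[5:]), min_pct=0.0)
        row = res.set_index("gene_id").loc["g000"]
        assert row["avg_log2FC"] == pytest.approx(np.log2(101.0), abs=1e-9)
        assert row["p_value"] == pytest.approx(2 / 252, abs=1e-12)

    def test_fold_change_antisymmetric(self):
        rng = np.random.default_rng(1)
        values = rng.poisson(3.0, size=(20, 16))
        nm, a, b = self._two_group_nm(values)
        fwd = de_test(nm, a, b, min_pct=0.0).set_index("gene_id")["avg_log2FC"]
        rev = de_test(nm, b, a, min_pct=0.0).set_index("gene_id")["avg_log2FC"]
        np.testing.assert_allclose(fwd.values, -rev.loc[fwd.index].values, atol=1e-12)

    def test_min_pct_filter_skips_rare_genes(self):
        rng = np.random.default_rng(2)
        values = rng.poisson(2.0, size=(5, 60)) + 1
        values[0] = 0
        values[0, 0] = 1  # expressed in ~3% of one group only
        nm, a, b = self._two_group_nm(values)
        res = de_test(nm, a, b, min_pct=0.05)
        assert "g000" not in set(res["gene_id"])

    def test_small_groups_rejected(self):
        nm = make_normalized(np.ones((3, 6), dtype=int))
        with pytest.raises(ConfigurationError):
            de_test(nm, set(nm.barcodes[:2]), set(nm.barcodes[2:]))

    def test_adjusted_never_below_raw(self, small_study):
        counts, truth = small_study.counts, small_study.truth
        nm = allosc.normalize(counts)
        tl = truth.cell_clusters
        res = de_test(nm, set(tl.index[tl == 0]), set(tl.index[tl != 0]))
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()

    def test_null_type_one_error_calibrated(self):
        """Raw p < 0.05 fraction under the null stays near the nominal level."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = rng.negative_binomial(2, 2 / 3, size=(2000, 120))
            nm = make_normalized(values)
            res = de_test(nm, set(nm.barcodes[:60]), set(nm.barcodes[60:]), min_pct=0.0)
            fracs.append((res["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_logistic_lr_agrees_on_strong_signal(self):
        x_in = np.log1p(np.random.default_rng(3).poisson(8.0, 40)).astype(float)
        x_out = np.zeros(40)
        assert logistic_lr_p(x_in, x_out) < 1e-6
        assert logistic_lr_p(np.ones(10), np.ones(12)) == 1.0

    def test_marker_recovery_on_planted_clusters(self):
        """Planted log2FC=2 markers reach adjusted p < 0.01 almost always."""
        rates = []
        for seed in range(10):
            cfg = SynthConfig(
                rng_seed=seed, n_patients=1, include_thirdparty=False,
                n_clusters=3, contaminant_cluster=False, doublet_rate=0.0,
                dead_cell_rate=0.0, prepost_gene_count=0,
            )
            counts, truth = simulate_counts(cfg)
            nm = allosc.normalize(counts)
            tl = truth.cell_clusters
            for k, markers in truth.marker_genes.items():
                res = de_test(nm, set(tl.index[tl == k]), set(tl.index[tl != k]))
                hits = set(res.loc[res["p_adjusted"] < 0.01, "gene_id"])
                rates.append(len(hits & set(markers)) / len(markers))
        assert np.mean(rates) >= 0.9


class TestRankDe:
    def test_empty_input(self):
        res = rank_de(pd.DataFrame(columns=["gene_id", "avg_log2FC", "p_adjusted"]))
        assert res.empty

    def test_absolute_fold_change_ordering(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "avg_log2FC": [1.5, -2.0],
                "p_adjusted": [1e-8, 1e-8],
            }
        )
        ranked = rank_de(df, alpha=1e-5)
        assert list(ranked["gene_id"]) == ["b", "a"]

    def test_boundary_alpha_is_strict(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b"], "avg_log2FC": [1.0, 1.0], "p_adjusted": [1e-5, 0.9e-5]}
        )
        ranked = rank_de(df, alpha=1e-5)
        assert list(ranked["gene_id"]) == ["b"]


class TestPrepostContrast:
    def test_planted_downshift_recovered_and_controls_clean(self):
        """Post-transplant down-shifted genes rank on top with negative log2FC;
        donor and third-party hit lists are disjoint for a donor-only shift."""
        neg_ok, sig_counts, overlap = 0, [], 0
        seeds = range(1, 6)
        for seed in seeds:
            cfg = SynthConfig(rng_seed=seed)
            counts, truth = simulate_counts(cfg)
            qc = allosc.compute_qc_metrics(counts)
            nm = allosc.normalize(allosc.filter_cells(counts, qc))
            assign = truth.cell_clusters.loc[nm.barcodes]
            hits = {}
            for stim in ("don", "thirdP"):
                res = prepost_contrast(nm, assign, truth.prepost_cluster, stimulus=stim)
                hits[stim] = set(res.loc[res["p_adjusted"] < 0.01, "gene_id"])
                if stim == "don":
                    planted = res[res["gene_id"].isin(truth.prepost_genes)]
                    neg_ok += (planted["avg_log2FC"] < 0).all()
                    sig_counts.append(len(hits[stim] & set(truth.prepost_genes)))
            overlap += len(hits["don"] & hits["thirdP"])
        assert neg_ok == len(list(seeds))
        assert np.mean(sig_counts) >= 0.8 * len(truth.prepost_genes)
        assert overlap == 0

    def test_null_prepost_contrast_yields_no_hits(self):
        """Identical pre/post distributions: at most one false hit over seeds."""
        total_hits = 0
        for seed in range(10):
            cfg = SynthConfig(
                rng_seed=seed, n_patients=1, include_thirdparty=False,
                prepost_gene_count=0, n_genes=800, n_clusters=2,
                contaminant_cluster=False, doublet_rate=0.0, dead_cell_rate=0.0,
            )
            counts, truth = simulate_counts(cfg)
            nm = allosc.normalize(counts)
            assign = truth.cell_clusters
            res = prepost_contrast(nm, assign, 0, stimulus="don")
            total_hits += int((res["p_adjusted"] < 0.01).sum())
        assert total_hits <= 1

    def test_missing_timepoint_warns_and_skips(self):
        rng = np.random.default_rng(5)
        nm = make_normalized(rng.poisson(2.0, size=(10, 12)), timepoint="pre")
        assign = pd.Series(0, index=nm.barcodes)
        with pytest.warns(UserWarning):
            assert prepost_contrast(nm, assign, 0, stimulus="don") is None
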