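"""Chain filter cascade, clonotype construction and Shannon diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allosc import (
    CellClonotype,
    ConfigurationError,
    EmptyResultError,
    apply_filter_cascade,
    build_clonotypes,
    clonotype_overlap,
    diversity_table,
    locus_fraction_filter,
    productivity_filter,
    select_primary_chain,
    shannon_diversity,
    vdj_table,
)
from allosc.tcr import is_productive, load_segment_order


def chain(cell, locus, reads, junction="TGTGCAGCAGCA", productive=True,
          v=None, d="", j=None):
    v = v or {"TRA": "TRAV2", "TRB": "TRBV9", "TRD": "TRDV1"}[locus]
    j = j or {"TRA": "TRAJ10", "TRB": "TRBJ1-1", "TRD": "TRDJ1"}[locus]
    aa = "" if len(junction) % 3 else str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(junction).translate())
    return dict(cell_id=cell, locus=locus, v_call=v, d_call=d, j_call=j,
                junction=junction, junction_aa=aa, consensus_count=reads,
                productive=productive)


class TestProductivity:
    def test_in_frame_no_stop(self):
        assert is_productive("TGTGCAGCA") is True
        assert is_productive("TGTTGAGCA") is False  # internal stop
        assert is_productive("TGTGCAGC") is False  # frameshift
        assert is_productive("") is None
        assert is_productive("TGTNNAGCA") is None

    def test_read_threshold_inclusive(self):
        chains = pd.DataFrame([chain("c", "TRA", 24), chain("c2", "TRA", 25)])
        kept = productivity_filter(chains, min_reads=25)
        assert list(kept["cell_id"]) == ["c2"]

    def test_stop_codon_chain_removed_even_with_flag_unset(self):
        rows = [chain("c", "TRA", 100, junction="TGTTGAGCA")]
        rows[0]["productive"] = None
        kept = productivity_filter(pd.DataFrame(rows))
        assert kept.empty

    def test_flag_takes_precedence_over_sequence(self):
        rows = [chain("c", "TRA", 100, productive=False)]
        assert productivity_filter(pd.DataFrame(rows)).empty


class TestPrimaryChainSelection:
    def test_single_chain_top_one(self):
        sel = select_primary_chain(pd.DataFrame([chain("c", "TRA", 40)]))
        assert sel["top"] == 1.0

    @pytest.mark.parametrize(
        "reads,expected_top,kept",
        [((30, 5), 30 / 35, True), ((30, 10), 0.75, False)],
    )
    def test_dominance_rule(self, reads, expected_top, kept):
        rows = [chain("c", "TRA", reads[0]),
                chain("c", "TRA", reads[1], junction="TGTGCAGCAGCC")]
        sel, trace = apply_filter_cascade(pd.DataFrame(rows))
        t = trace.iloc[0]
        assert t["top"] == pytest.approx(expected_top)
        assert (len(sel) == 1) == kept

    def test_tie_broken_by_junction_sequence(self):
        rows = [chain("c", "TRA", 30, junction="TGTGCAGCAGCC"),
                chain("c", "TRA", 30, junction="TGTGCAGCAGCA")]
        sel = select_primary_chain(pd.DataFrame(rows))
        assert sel["junction"] == "TGTGCAGCAGCA"

    def test_top_denominator_includes_unproductive_reads(self):
        # unproductive 30-read chain suppresses a productive 60-read chain
        rows = [chain("c", "TRA", 60),
                chain("c", "TRA", 30, junction="TGTTGAGCAGCA", productive=False)]
        sel, trace = apply_filter_cascade(pd.DataFrame(rows))
        assert trace.iloc[0]["top"] == pytest.approx(60 / 90)
        assert sel.empty


class TestLocusFraction:
    def test_single_locus_retained(self):
        df = pd.DataFrame([chain("c", "TRB", 50)])
        out = locus_fraction_filter(df)
        assert out["flocus"].iloc[0] == 1.0

    @pytest.mark.parametrize(
        "tra,trb,tra_kept", [(12, 100, True), (10, 100, False)]
    )
    def test_fraction_boundary(self, tra, trb, tra_kept):
        df = pd.DataFrame([chain("c", "TRA", tra), chain("c", "TRB", trb)])
        out = locus_fraction_filter(df)
        assert ("TRA" in set(out["locus"])) == tra_kept
        assert "TRB" in set(out["locus"])

    def test_flocus_sums_to_one_per_cell(self):
        df = pd.DataFrame(
            [chain("c", "TRA", 40), chain("c", "TRB", 60), chain("d", "TRB", 10)]
        )
        out = locus_fraction_filter(df, _annotate_only=True)
        sums = out.groupby("cell_id")["flocus"].sum()
        assert np.allclose(sums.values, 1.0)


class TestCascade:
    def test_idempotent_on_own_output(self):
        rows = [
            chain("c1", "TRA", 26), chain("c1", "TRA", 24, junction="TGTGCAGCAGCC"),
            chain("c1", "TRB", 300),
            chain("c2", "TRA", 40), chain("c2", "TRB", 45),
            chain("c3", "TRB", 30), chain("c3", "TRB", 3, junction="TGTGCAGCAGCC"),
        ]
        sel1, _ = apply_filter_cascade(pd.DataFrame(rows))
        sel2, _ = apply_filter_cascade(sel1[[c for c in sel1.columns if c not in ("top", "flocus")]])
        key_cols = ["cell_id", "locus", "junction", "consensus_count"]
        pd.testing.assert_frame_equal(
            sel1[key_cols].reset_index(drop=True), sel2[key_cols].reset_index(drop=True)
        )

    def test_trd_passes_cascade_but_never_forms_clonotypes(self):
        rows = [chain("c", "TRA", 100), chain("c", "TRB", 90), chain("c", "TRD", 80)]
        sel, _ = apply_filter_cascade(pd.DataFrame(rows))
        assert set(sel["locus"]) == {"TRA", "TRB", "TRD"}
        cts = build_clonotypes(sel)
        assert len(cts) == 1 and cts[0].paired_key is not None
        assert "TRD" not in cts[0].paired_key


class TestClonotypes:
    def test_unpaired_cell_has_no_paired_key(self):
        sel, _ = apply_filter_cascade(pd.DataFrame([chain("c", "TRB", 50)]))
        cts = build_clonotypes(sel)
        assert cts[0].trb is not None and cts[0].tra is None
        assert cts[0].paired_key is None

    def test_identical_chains_share_key(self):
        rows = [chain("a", "TRA", 50), chain("a", "TRB", 60),
                chain("b", "TRA", 70), chain("b", "TRB", 40)]
        sel, _ = apply_filter_cascade(pd.DataFrame(rows))
        a, b = build_clonotypes(sel)
        assert a.paired_key == b.paired_key


class TestShannonDiversity:
    def test_two_equiprobable_clonotypes(self):
        cells = [CellClonotype(f"x{i}", tra=["TRA:A", "TRA:B"][i % 2]) for i in range(4)]
        d = shannon_diversity(cells, "TRA")
        assert d.H == pytest.approx(math.log(2), abs=1e-12)
        assert d.EH == pytest.approx(1.0, abs=1e-12)
        assert (d.S, d.N) == (2, 4)

    def test_monoclonal_equitability_zero(self):
        cells = [CellClonotype(f"x{i}", tra="TRA:A", trb="TRB:B") for i in range(20)]
        assert shannon_diversity(cells, "TRA_AND_TRB").EH == 0.0

    def test_all_distinct_equitability_one(self):
        cells = [CellClonotype(f"x{i}", tra=f"TRA:{i}", trb=f"TRB:{i}") for i in range(20)]
        assert shannon_diversity(cells, "TRA_AND_TRB").EH == pytest.approx(1.0, abs=1e-12)

    def test_no_eligible_cells_raises(self):
        with pytest.raises(EmptyResultError):
            shannon_diversity([CellClonotype("x", trb="TRB:A")], "TRA")

    def test_formula_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 9, size=12)
        cells = [
            CellClonotype(f"x{i}_{r}", tra=f"TRA:{i}")
            for i, n in enumerate(counts)
            for r in range(n)
        ]
        d = shannon_diversity(cells, "TRA")
        N = counts.sum()
        h = 0.0
        for n in counts:
            h -= (n / N) * math.log(n / N)
        assert d.H == pytest.approx(h, abs=1e-12)

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=12), st.integers(2, 5))
    @settings(max_examples=50, deadline=None)
    def test_equitability_invariant_under_relabeling_and_duplication(self, counts, dup):
        cells = [
            CellClonotype(f"x{i}_{r}", tra=f"TRA:{i}")
            for i, n in enumerate(counts)
            for r in range(n)
        ]
        base = shannon_diversity(cells, "TRA").EH
        relabeled = [
            CellClonotype(c.cell_id, tra="TRA:zz" + c.tra) for c in cells
        ]
        assert shannon_diversity(relabeled, "TRA").EH == pytest.approx(base, abs=1e-12)
        duplicated = [
            CellClonotype(f"{c.cell_id}_{r}", tra=c.tra) for c in cells for r in range(dup)
        ]
        assert shannon_diversity(duplicated, "TRA").EH == pytest.approx(base, abs=1e-12)

    @given(st.lists(st.integers(2, 20), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_equitability_decreases_under_concentration(self, counts):
        """Moving one cell from a minority to the majority clonotype lowers EH.

        Counts start at 2 so no clonotype vanishes and S stays fixed.
        """
        counts = sorted(counts)
        cells = [
            CellClonotype(f"x{i}_{r}", tra=f"TRA:{i}")
            for i, n in enumerate(counts)
            for r in range(n)
        ]
        before = shannon_diversity(cells, "TRA").EH
        moved = list(counts)
        moved[-1] += 1
        moved[0] -= 1
        cells2 = [
            CellClonotype(f"y{i}_{r}", tra=f"TRA:{i}")
            for i, n in enumerate(moved)
            for r in range(n)
        ]
        after = shannon_diversity(cells2, "TRA").EH
        assert after <= before + 1e-12

    def test_expected_equitability_monotone_in_clonality(self):
        """Stronger power-law concentration never raises expected EH."""
        from allosc.synth import SynthConfig, simulate_repertoire

        cells = [f"c{i}" for i in range(300)]
        means = []
        for alpha in (0.0, 1.0, 2.0):
            ehs = []
            for seed in range(3):
                cfg = SynthConfig(
                    rng_seed=seed, clonality_alpha=alpha,
                    unique_clonotype_fraction=0.5, secondary_chain_prob=0.0,
                    unproductive_chain_prob=0.0, reads_per_chain_mean=100.0,
                )
                chains, _ = simulate_repertoire(cfg, cells)
                sel, _ = apply_filter_cascade(chains)
                cts = build_clonotypes(sel)
                ehs.append(shannon_diversity(cts, "TRA_AND_TRB").EH)
            means.append(np.mean(ehs))
        assert means[0] >= means[1] >= means[2]


class TestVdjTable:
    def test_single_cell_proportion_one(self):
        sel, _ = apply_filter_cascade(pd.DataFrame([chain("c", "TRA", 50)]))
        table = vdj_table(sel)
        assert table["proportion"].iloc[0] == 1.0

    def test_counts_and_proportions(self):
        rows = []
        for i in range(10):
            v = "TRAV2" if i < 2 else f"TRAV{3 + i}"
            rows.append(chain(f"c{i}", "TRA", 50, v=v,
                              junction="TGT" + "GCA" * (3 + i % 3)))
        sel, _ = apply_filter_cascade(pd.DataFrame(rows))
        table = vdj_table(sel)
        two = table[table["v_call"] == "TRAV2"]
        assert two["n_cells"].iloc[0] == 2
        assert two["proportion"].iloc[0] == pytest.approx(0.2)
        assert table.groupby("locus")["proportion"].sum().iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_segments_ordered_genomically_and_unknown_last(self):
        order = load_segment_order()
        rows = [chain("c1", "TRA", 50, v="TRAV41"),
                chain("c2", "TRA", 50, v="TRAV1-1", junction="TGTGCAGCAGCG"),
                chain("c3", "TRA", 50, v="TRAV999", junction="TGTGCAGCAGTT")]
        sel, _ = apply_filter_cascade(pd.DataFrame(rows))
        table = vdj_table(sel, segment_order=order)
        assert list(table["v_call"]) == ["TRAV1-1", "TRAV41", "TRAV999"]


class TestOverlap:
    def test_disjoint_and_identical_repertoires(self):
        a = [CellClonotype(f"a{i}", tra=f"TRA:{i}") for i in range(5)]
        b = [CellClonotype(f"b{i}", tra=f"TRA:x{i}") for i in range(5)]
        mat = clonotype_overlap({"s1": a, "s2": b}, level="TRA")
        assert mat.loc["s1", "s2"] == 0
        mat2 = clonotype_overlap({"s1": a, "s2": a}, level="TRA")
        assert mat2.loc["s1", "s2"] == 5

    def test_planted_shared_clonotypes_recovered(self):
        from allosc.synth import SynthConfig, simulate_repertoire

        cfg = SynthConfig(rng_seed=4, shared_clonotypes=3, unique_clonotype_fraction=1.0,
                          secondary_chain_prob=0.0, unproductive_chain_prob=0.0,
                          reads_per_chain_mean=100.0)
        cells = [f"P0_pre_don-C{i}" for i in range(50)] + [f"P0_post_don-C{i}" for i in range(50)]
        sample_of = {c: c.split("-")[0] for c in cells}
        chains, truth = simulate_repertoire(cfg, cells, sample_of=sample_of)
        sel, _ = apply_filter_cascade(chains)
        by_sample = {}
        for ct in build_clonotypes(sel):
            by_sample.setdefault(sample_of[ct.cell_id], []).append(ct)
        mat = clonotype_overlap(by_sample, level="TRA_AND_TRB")
        assert mat.loc["P0_pre_don", "P0_post_don"] == 3


def test_diversity_table_shape(small_study):
    sel, _ = apply_filter_cascade(small_study.chains)
    by_sample = {}
    som = dict(small_study.counts.cell_meta["sample_id"])
    for ct in build_clonotypes(sel):
        by_sample.setdefault(som[ct.cell_id], []).append(ct)
    table = diversity_table(by_sample)
    assert set(table["level"]) == {"TRA", "TRB", "TRA_AND_TRB"}
    assert ((table["EH"] >= 0) & (table["EH"] <= 1)).all()
    assert (table["H"] >= 0).all()
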