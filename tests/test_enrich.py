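"""Binomial family enrichment, UTR-bias control, generic category test."""

import dataclasses
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainmask import (
    binomial_enrichment,
    build_design,
    category_enrichment_fdr,
    family_enrichment,
    raw_log2,
    simulate_hybridization,
    simulate_strain,
    utr_bias_profile,
)
from strainmask.arrayio import ArrayDesign
from strainmask.normalize import RatioTrack


def binomial_tail_oracle(k, n, p0):
    """Exact enumeration of P(X >= k) from the binomial pmf."""
    return sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))


class TestBinomialEnrichment:
    def test_zero_successes_is_whole_tail(self):
        assert binomial_enrichment(0, 10, 0.3) == pytest.approx(1.0)

    def test_all_successes_closed_form(self):
        assert binomial_enrichment(10, 10, 0.5) == pytest.approx(0.5**10)

    def test_seven_of_ten_exact_fraction(self):
        assert binomial_enrichment(7, 10, 0.5) == pytest.approx(176 / 1024)

    @settings(derandomize=True, max_examples=100)
    @given(
        n=st.integers(1, 20),
        frac=st.floats(0.0, 1.0),
        p0=st.sampled_from([0.1, 0.3, 0.5, 0.62, 0.9]),
    )
    def test_agrees_with_enumeration_oracle_up_to_n20(self, n, frac, p0):
        k = round(frac * n)
        assert binomial_enrichment(k, n, p0) == pytest.approx(binomial_tail_oracle(k, n, p0), rel=1e-9)

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_degenerate_background_rejected(self, p0):
        with pytest.raises(ValueError, match="background"):
            binomial_enrichment(1, 2, p0)

    def test_k_outside_range_rejected(self):
        with pytest.raises(ValueError):
            binomial_enrichment(3, 2, 0.5)

    def test_monotone_in_background_proportion(self):
        # the UTR-bias control relies on this: a larger background
        # proportion can only weaken over-representation evidence
        ps = [binomial_enrichment(30, 100, p0) for p0 in (0.2, 0.3, 0.4)]
        assert ps[0] < ps[1] < ps[2]


def make_annotated_track(n=2000, utr_frac=0.6, var_rate_cds=0.05, var_rate_utr=0.15, family=None, fam_var_rate=None, seed=0):
    """Design + track with Bernoulli 'variable' probes at chosen rates."""
    rng = np.random.default_rng(seed)
    is_utr = rng.random(n) < utr_frac
    fam_col = np.array([""] * n, dtype=object)
    rate = np.where(is_utr, var_rate_utr, var_rate_cds)
    if family is not None:
        in_fam = rng.random(n) < family
        fam_col[in_fam] = "FAM"
        if fam_var_rate is not None:
            rate = np.where(in_fam, fam_var_rate, rate)
    variable = rng.random(n) < rate
    m = np.where(variable, 2.0, 0.1)
    design = ArrayDesign(
        pd.DataFrame(
            {
                "probe_id": [f"P{i:05d}" for i in range(n)],
                "seq_id": [f"S{i // 4:05d}" for i in range(n)],
                "region": np.where(is_utr, "UTR", "CDS"),
                "chrom": "Sctg_00",
                "position": np.arange(n),
                "families": fam_col,
            }
        )
    )
    track = RatioTrack(pd.DataFrame({"probe_id": design.table["probe_id"], "M": m, "A": 10.0}), strain="s")
    return design, track


class TestUtrBias:
    def test_counts_and_shares_from_printed_inputs(self):
        # 68,270 probes of which 42,073 UTR; 13,141 variable of which 9,585 UTR
        n = 68270
        region = np.array(["CDS"] * n, dtype=object)
        region[:42073] = "UTR"
        m = np.zeros(n)
        m[:9585] = 1.5  # variable UTR probes
        m[42073 : 42073 + (13141 - 9585)] = 1.5  # variable CDS probes
        design = ArrayDesign(
            pd.DataFrame(
                {
                    "probe_id": [f"P{i:05d}" for i in range(n)],
                    "seq_id": [f"S{i // 4:05d}" for i in range(n)],
                    "region": region,
                    "chrom": "Sctg_00",
                    "position": np.arange(n),
                    "families": "",
                }
            )
        )
        track = RatioTrack(pd.DataFrame({"probe_id": design.table["probe_id"], "M": m, "A": 10.0}))
        prof = utr_bias_profile(track, design)
        assert prof.n_utr == 42073 and prof.n_probes == 68270
        assert round(100 * prof.overall_utr_share) == 62
        assert prof.n_variable == 13141 and prof.n_variable_utr == 9585
        assert round(100 * prof.variable_utr_share) == 73
        assert prof.biased

    def test_region_shuffle_removes_bias_within_noise(self):
        design, track = make_annotated_track(n=4000, var_rate_cds=0.1, var_rate_utr=0.1, seed=1)
        prof = utr_bias_profile(track, design)
        se = np.sqrt(0.6 * 0.4 / prof.n_variable)
        assert abs(prof.variable_utr_share - prof.overall_utr_share) < 4 * se

    def test_no_variable_probes_flagged(self):
        design, track = make_annotated_track(n=400, var_rate_cds=0.0, var_rate_utr=0.0, seed=2)
        prof = utr_bias_profile(track, design)
        assert prof.n_variable == 0 and not prof.biased


class TestFamilyEnrichment:
    def test_unknown_family_rejected_by_name(self, tiny_design):
        _, track = make_annotated_track(n=400)
        design, track = make_annotated_track(n=400)
        with pytest.raises(ValueError, match="GHOST"):
            family_enrichment(track, design, "GHOST")

    def test_null_family_p_values_not_small_in_most_draws(self):
        hits = 0
        for seed in range(100):
            design, track = make_annotated_track(n=1500, family=0.05, fam_var_rate=None, seed=seed)
            r = family_enrichment(track, design, "FAM")
            if r.pvalue_vs_all > 0.05:
                hits += 1
        assert hits >= 90

    def test_hypervariable_family_significant_against_both_backgrounds(self):
        design, track = make_annotated_track(n=2000, family=0.05, fam_var_rate=0.6, seed=3)
        r = family_enrichment(track, design, "FAM")
        assert r.pvalue_vs_all < 0.05 and r.pvalue_vs_utr < 0.05

    def test_all_utr_family_dual_background_ordering(self):
        # family entirely in the UTR, UTR probes globally more variable:
        # the UTR-only background is the harder test
        rng = np.random.default_rng(4)
        n = 4000
        is_utr = rng.random(n) < 0.6
        fam = np.array([""] * n, dtype=object)
        fam_idx = np.where(is_utr)[0][:200]
        fam[fam_idx] = "FAM"
        rate = np.where(is_utr, 0.3, 0.05)
        m = np.where(rng.random(n) < rate, 2.0, 0.1)
        design = ArrayDesign(
            pd.DataFrame(
                {
                    "probe_id": [f"P{i:05d}" for i in range(n)],
                    "seq_id": [f"S{i // 4:05d}" for i in range(n)],
                    "region": np.where(is_utr, "UTR", "CDS"),
                    "chrom": "Sctg_00",
                    "position": np.arange(n),
                    "families": fam,
                }
            )
        )
        track = RatioTrack(pd.DataFrame({"probe_id": design.table["probe_id"], "M": m, "A": 10.0}))
        r = family_enrichment(track, design, "FAM")
        assert r.p_utr >= r.p_all
        assert r.pvalue_vs_utr >= r.pvalue_vs_all

    def test_simulated_te_like_vs_gst_like_contrast(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_supercontigs=10, genes_per_supercontig=50)
        d = build_design(cfg)
        truth = simulate_strain(d, cfg, "high")
        ref, test = simulate_hybridization(d, truth, cfg)
        track = raw_log2(test, ref)
        te = family_enrichment(track, d, "TE")
        gst = family_enrichment(track, d, "GST")
        assert te.pvalue_vs_all < 0.05 and te.pvalue_vs_utr < 0.05
        assert gst.pvalue_vs_all > 0.1 and gst.pvalue_vs_utr > 0.1


class TestCategoryEnrichment:
    def test_target_equals_universe_nothing_enriched(self):
        u = {f"S{i}" for i in range(50)}
        cat = {s: ["lab"] for s in u}
        df = category_enrichment_fdr(cat, u, u)
        assert (df["pvalue"] == 1.0).all()
        assert not df["significant"].any()

    def test_label_covering_target_and_tiny_universe_slice_is_enriched(self):
        u = {f"S{i}" for i in range(1000)}
        target = {f"S{i}" for i in range(10)}
        cat = {s: ["hot"] for s in target}
        df = category_enrichment_fdr(cat, target, u)
        row = df.set_index("label").loc["hot"]
        assert row["significant"]
        # hypergeometric closed form for full overlap
        from scipy.stats import hypergeom

        assert row["pvalue"] == pytest.approx(hypergeom.sf(9, 1000, 10, 10))

    def test_single_label_reduces_to_plain_hypergeometric(self):
        u = {f"S{i}" for i in range(100)}
        target = {f"S{i}" for i in range(20)}
        cat = {f"S{i}": ["only"] for i in range(0, 50)}
        df = category_enrichment_fdr(cat, target, u)
        assert len(df) == 1
        assert df["qvalue"].iloc[0] == pytest.approx(df["pvalue"].iloc[0])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            category_enrichment_fdr({}, set(), set())

    def test_target_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            category_enrichment_fdr({}, {"X"}, {"Y"})

    def test_null_labels_false_discovery_rate_controlled(self):
        rng = np.random.default_rng(5)
        universe = [f"S{i:04d}" for i in range(300)]
        total_rejections = 0
        for _ in range(100):
            cat = {}
            for lab in range(40):
                for s in rng.choice(universe, size=15, replace=False):
                    cat.setdefault(s, []).append(f"L{lab}")
            target = set(rng.choice(universe, size=50, replace=False))
            df = category_enrichment_fdr(cat, target, set(universe), fdr=0.05)
            total_rejections += int(df["significant"].sum())
        # all labels are null: BH at 5% keeps false discoveries rare
        assert total_rejections <= 0.05 * 100 * 2
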