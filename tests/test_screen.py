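"""Plate normalization and the hit-calling funnel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senescreen.screen import (
    DegeneratePlateError,
    ScreenThresholds,
    assemble_hit_table,
    call_primary_hits,
    confirm_deconvolution,
    expression_filter,
    normalize_plates,
    robust_z,
    seed_enrichment_pvalue,
    seed_flag,
    top_hits,
    triage_hits,
)
from conftest import make_plate


def oracle_robust_z(x):
    """Independent brute-force median/MAD robust Z."""
    x = [float(v) for v in x]
    s = sorted(x)
    n = len(s)
    med = (s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0)
    dev = sorted(abs(v - med) for v in x)
    mad = (dev[n // 2] if n % 2 else (dev[n // 2 - 1] + dev[n // 2]) / 2.0)
    return [(v - med) / (1.4826 * mad) for v in x]


class TestRobustZ:
    def test_identical_values_raise_degenerate_error(self):
        with pytest.raises(DegeneratePlateError):
            robust_z([5, 5, 5, 5])

    def test_median_maps_to_zero_and_hand_value(self):
        z = robust_z([1, 2, 3, 4, 5])
        assert z[2] == 0.0
        assert z[4] == pytest.approx(2 / 1.4826, abs=1e-9)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = rng.normal(size=rng.integers(3, 40)) * rng.uniform(0.1, 50)
            np.testing.assert_allclose(robust_z(x), oracle_robust_z(x), atol=1e-12)

    @given(
        st.lists(
            st.integers(-10_000, 10_000).map(lambda v: v / 4.0),
            min_size=3,
            max_size=30,
        ),
        st.integers(-1000, 1000),
        st.floats(0.25, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_location_scale_equivariance(self, xs, shift, scale):
        x = np.asarray(xs)
        try:
            base = robust_z(x)
        except DegeneratePlateError:
            return
        np.testing.assert_allclose(robust_z(x + shift), base, atol=1e-7, rtol=1e-7)
        np.testing.assert_allclose(robust_z(x * scale), base, atol=1e-7, rtol=1e-7)

    def test_mean_sd_switch(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        z = robust_z(x, center="mean", scale="sd")
        np.testing.assert_allclose(z, (x - x.mean()) / x.std(ddof=1))


class TestNormalizePlates:
    def test_pct_of_control_is_100_at_control_median(self, flat_plate):
        plate = flat_plate([100.0, 100.0] + [100.0 + d for d in range(-5, 5)])
        z = normalize_plates(plate)
        ctrl_median = 100.0
        at_median = z[z["cell_count"] == ctrl_median]
        assert (at_median["pct_count"] == 100.0).all()

    def test_double_control_median_scores_200_pct(self, flat_plate):
        counts = [100.0, 100.0, 200.0] + [100.0 + d for d in range(-4, 5)]
        z = normalize_plates(flat_plate(counts))
        assert z.loc[z["cell_count"] == 200.0, "pct_count"].iloc[0] == 200.0

    def test_planted_outlier_recovers_hand_value(self, flat_plate):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 5, size=30).tolist()
        sample = base[2:]
        med = np.median(sample)
        mad = np.median(np.abs(np.asarray(sample) - med))
        outlier = med + 5 * 1.4826 * mad
        counts = base + [outlier]
        z = normalize_plates(flat_plate(counts))
        got = z.loc[z["cell_count"] == outlier, "z_count"].iloc[0]
        # hand value on the full sample-well set (controls excluded)
        full = np.asarray(sample + [outlier])
        med2 = np.median(full)
        mad2 = 1.4826 * np.median(np.abs(full - med2))
        assert got == pytest.approx((outlier - med2) / mad2, abs=1e-9)

    def test_controls_excluded_from_location_estimate(self, flat_plate):
        # extreme controls must not move the sample-well Z-scores
        counts_a = [100.0, 100.0] + [100.0 + d for d in range(-5, 5)]
        counts_b = [100.0, 1000.0] + [100.0 + d for d in range(-5, 5)]
        za = normalize_plates(flat_plate(counts_a))
        zb = normalize_plates(flat_plate(counts_b))
        sa = za[za["reagent_class"] == "smartpool"]["z_count"].to_numpy()
        sb = zb[zb["reagent_class"] == "smartpool"]["z_count"].to_numpy()
        np.testing.assert_allclose(sa, sb)

    def test_shuffling_wells_leaves_z_unchanged(self, flat_plate):
        plate = flat_plate([100.0, 100.0] + list(np.linspace(80, 130, 12)))
        z1 = normalize_plates(plate).set_index("well")["z_count"]
        shuffled = plate.sample(frac=1.0, random_state=3).reset_index(drop=True)
        z2 = normalize_plates(shuffled).set_index("well")["z_count"]
        np.testing.assert_allclose(z1.sort_index(), z2.sort_index())

    def test_missing_controls_error(self, flat_plate):
        plate = flat_plate([100.0] * 2 + list(np.linspace(90, 110, 10)), n_controls=0)
        with pytest.raises(ValueError, match="non-targeting"):
            normalize_plates(plate)

    def test_degenerate_plate_names_plate(self, flat_plate):
        plate = flat_plate([100.0] * 12)
        with pytest.raises(DegeneratePlateError, match="P1"):
            normalize_plates(plate)

    def test_missing_channel_values_error_lists_wells(self, flat_plate):
        plate = flat_plate([100.0, 100.0] + list(np.linspace(90, 110, 10)))
        plate.loc[5, "edu_intensity"] = np.nan
        with pytest.raises(ValueError, match=plate.loc[5, "well"]):
            normalize_plates(plate)


class TestExpressionFilter:
    def test_all_zero_over_three_replicates_is_unexpressed(self):
        counts = pd.DataFrame(
            {"r1": [0, 0], "r2": [0, 0], "r3": [0, 1]}, index=["A", "B"]
        )
        expr = expression_filter(counts)
        assert not expr["A"]  # zero in all three replicates
        assert expr["B"]  # any nonzero replicate keeps the gene

    def test_exact_exclusion_count_on_toy_matrix(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(10, size=(10, 3)),
            index=[f"G{i}" for i in range(10)],
            columns=["r1", "r2", "r3"],
        )
        counts.iloc[[1, 3, 4, 8]] = 0
        counts.iloc[[0, 2, 5, 6, 7, 9]] += 1  # guarantee nonzero elsewhere
        expr = expression_filter(counts)
        assert (~expr).sum() == 4

    def test_any_zero_rule(self):
        counts = pd.DataFrame({"r1": [0], "r2": [3], "r3": [5]}, index=["A"])
        assert expression_filter(counts)["A"]
        assert not expression_filter(counts, zero_rule="any")["A"]

    def test_absent_gene_policy(self):
        counts = pd.DataFrame({"r1": [1]}, index=["A"])
        expr = expression_filter(counts, genes=["A", "B"])
        assert expr["B"]  # conservative default: retained
        expr2 = expression_filter(counts, genes=["B"], absent_policy="not_expressed")
        assert not expr2["B"]

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"r1": [-1]}, index=["A"])
        with pytest.raises(ValueError, match="non-negative"):
            expression_filter(counts)


def hit_frame(rows):
    df = pd.DataFrame(rows).set_index("gene")
    return df


class TestFunnel:
    def test_boundary_z_exactly_2_is_primary_hit(self):
        z = pd.DataFrame(
            {
                "reagent_class": ["smartpool", "smartpool"],
                "gene": ["A", "B"],
                "z_count": [2.0, 1.999],
                "z_edu": [0.0, 0.0],
                "z_area": [0.0, 0.0],
            }
        )
        hits = call_primary_hits(z, {"A": True, "B": True})
        assert hits.loc["A", "primary_hit"]
        assert not hits.loc["B", "primary_hit"]

    def test_unexpressed_gene_never_a_hit(self):
        z = pd.DataFrame(
            {
                "reagent_class": ["smartpool"],
                "gene": ["A"],
                "z_count": [3.5],
                "z_edu": [2.0],
                "z_area": [-3.0],
            }
        )
        hits = call_primary_hits(z, {"A": False})
        assert not hits.loc["A", "primary_hit"]

    def test_triage_boundaries_inclusive_and_combined(self):
        rows = [
            dict(gene="A", z_count=3, z_edu=1.5, z_area=-2.0, expressed=True, primary_hit=True),
            dict(gene="B", z_count=3, z_edu=3.0, z_area=0.0, expressed=True, primary_hit=True),
            dict(gene="C", z_count=3, z_edu=1.49, z_area=-2.5, expressed=True, primary_hit=True),
            dict(gene="D", z_count=3, z_edu=2.0, z_area=-2.1, expressed=True, primary_hit=True),
            dict(gene="E", z_count=3, z_edu=0.0, z_area=0.0, expressed=True, primary_hit=True),
            dict(gene="F", z_count=1, z_edu=2.0, z_area=-3.0, expressed=True, primary_hit=False),
        ]
        hits = triage_hits(hit_frame(rows))
        assert set(hits.index[hits["triaged_hit"]]) == {"A", "D"}
        # OR-combine accepts single-channel passes
        hits_or = triage_hits(hit_frame(rows), ScreenThresholds(triage_combine="or"))
        assert set(hits_or.index[hits_or["triaged_hit"]]) == {"A", "B", "C", "D"}

    def test_top_hits_ranking_deterministic(self):
        rows = [
            dict(gene=g, z_count=zc, z_edu=2.0, z_area=-3.0, expressed=True,
                 primary_hit=True, triaged_hit=True)
            for g, zc in [("B", 5.0), ("A", 5.0), ("C", 7.0), ("D", 4.0)]
        ]
        assert top_hits(hit_frame(rows), 3) == ["C", "A", "B"]

    def test_deconvolution_two_of_four_confirms(self):
        def dz(gene, zs):
            return pd.DataFrame(
                {
                    "reagent_class": "duplex",
                    "gene": gene,
                    "duplex_index": range(1, len(zs) + 1),
                    "z_count": zs,
                    "z_edu": 0.0,
                    "z_area": 0.0,
                }
            )

        table = pd.concat([dz("A", [2.4, 2.1, 0.3, -1.0]), dz("B", [2.4, 0.3, 0.3, 0.3])])
        per_gene, per_dup = confirm_deconvolution(table, ["A", "B", "C"])
        assert per_gene.loc["A", "confirmed_hit"]
        assert per_gene.loc["A", "n_duplexes_recapitulating"] == 2
        assert not per_gene.loc["B", "confirmed_hit"]
        # gene with zero duplex records is untested, not failed
        assert per_gene.loc["C", "n_duplexes_tested"] == 0
        assert not per_gene.loc["C", "confirmed_hit"]

    def test_funnel_monotone_on_synthetic_screen(self, screen_data):
        primary, duplex, counts, truth = screen_data
        z = normalize_plates(primary)
        hits = triage_hits(call_primary_hits(z, expression_filter(counts)))
        conf, _ = confirm_deconvolution(
            normalize_plates(duplex), hits.index[hits["triaged_hit"]]
        )
        table = assemble_hit_table(hits, conf)
        assert table["confirmed_hit"].sum() <= table["triaged_hit"].sum()
        assert table["triaged_hit"].sum() <= table["primary_hit"].sum()
        assert table["primary_hit"].sum() <= table["expressed"].sum()
        # implication per gene, not only counts
        assert not (table["confirmed_hit"] & ~table["triaged_hit"]).any()
        assert not (table["triaged_hit"] & ~table["primary_hit"]).any()
        assert not (table["primary_hit"] & ~table["expressed"]).any()


def oracle_hypergeom_tail(M, K, n, k):
    from math import comb

    return sum(comb(K, i) * comb(M - K, n - i) for i in range(k, min(K, n) + 1)) / comb(M, n)


class TestSeedFlag:
    def test_hypergeometric_matches_bruteforce_tail(self):
        # 100-duplex library, one seed on 10 duplexes, 8 of the 10 hit
        # duplexes carry it
        p = seed_enrichment_pvalue(M=100, K=10, n=10, k=8)
        assert p == pytest.approx(oracle_hypergeom_tail(100, 10, 10, 8), rel=1e-12)

    def _library(self, seeds):
        return pd.DataFrame(
            {
                "reagent_id": [f"d{i}" for i in range(len(seeds))],
                "gene": [f"G{i // 4}" for i in range(len(seeds))],
                "seed_seq": seeds,
            }
        )

    def test_unique_seeds_flag_nothing(self):
        lib = self._library([f"AAAAA{i:02d}"[:7] for i in range(40)])
        recap = lib.iloc[:8].copy()
        recap["recapitulates"] = True
        flags = seed_flag(lib, recap, hit_genes=["G0", "G1"])
        assert not flags.any()

    def test_shared_enriched_seed_flags_fully_covered_gene_only(self):
        # 40 duplexes / 10 genes; seed "AAAAAAA" sits on 8 duplexes spread
        # over 4 hit genes; G0's two recapitulating duplexes both carry it,
        # G1 has one enriched and one clean duplex
        seeds = [f"CGT{i:04d}"[:7] for i in range(40)]
        for i in (0, 1, 4, 8, 12, 16, 20, 24):
            seeds[i] = "AAAAAAA"
        lib = self._library(seeds)
        recap_rows = [0, 1, 4, 5, 8, 12, 16, 20]  # duplex indices that recapitulate
        recap = lib.iloc[recap_rows].copy()
        recap["recapitulates"] = True
        hit_genes = sorted(recap["gene"].unique())
        flags = seed_flag(lib, recap, hit_genes=hit_genes)
        assert flags["G0"]  # both duplexes carry the enriched seed
        assert not flags["G1"]  # one clean duplex -> not flagged

    def test_missing_seeds_skip_with_warning(self, caplog):
        lib = self._library([None] * 8)
        recap = lib.iloc[:2].copy()
        recap["recapitulates"] = True
        with caplog.at_level("WARNING"):
            flags = seed_flag(lib, recap, hit_genes=["G0"])
        assert not flags.any()
        assert any("seed" in r.message for r in caplog.records)


def test_thresholds_validation():
    with pytest.raises(ValueError):
        ScreenThresholds(z_count_min=-1)
    with pytest.raises(ValueError):
        ScreenThresholds(z_area_max=1.0)
    with pytest.raises(ValueError):
        ScreenThresholds(triage_combine="xor")
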