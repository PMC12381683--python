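import math

import numpy as np
import pytest

from cnvselscan import sim
from cnvselscan.core import SamplePanel
from cnvselscan.popgen import (
    WindowGrid,
    genomewide_fst,
    log2_pi_ratio,
    site_pi,
    site_table,
    site_wc_components,
    window_table,
)

from conftest import make_record
from oracles import pi_pairwise_bruteforce, wc_longhand


class TestSiteComponents:
    def test_fixed_difference_gives_unit_fst(self):
        comp = site_wc_components([(0, 0, 15), (15, 0, 0)])
        a, b, c = comp
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_groups_non_positive(self):
        comp = site_wc_components([(7, 6, 2), (7, 6, 2)])
        a, b, c = comp
        assert a / (a + b + c) <= 0

    def test_monomorphic_site_skipped(self):
        assert site_wc_components([(10, 0, 0), (12, 0, 0)]) is None

    def test_empty_group_skipped(self):
        assert site_wc_components([(0, 0, 0), (5, 3, 2)]) is None

    def test_matches_longhand_oracle_on_random_sites(self):
        """|implementation - longhand transcription| < 1e-12 on 500 sites."""
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 500:
            c1 = tuple(rng.multinomial(int(rng.integers(2, 16)),
                                       rng.dirichlet([1, 1, 1])))
            c2 = tuple(rng.multinomial(int(rng.integers(2, 16)),
                                       rng.dirichlet([1, 1, 1])))
            got = site_wc_components([c1, c2])
            want = wc_longhand(c1, c2)
            assert (got is None) == (want is None)
            if got is None:
                continue
            assert np.allclose(got, want, atol=1e-12, rtol=0)
            checked += 1


class TestSitePi:
    def test_examples(self):
        assert site_pi(4, 2) == pytest.approx(2 / 3)
        assert site_pi(10, 0) == 0.0
        assert site_pi(2, 1) == 1.0

    def test_exact_against_pairwise_bruteforce(self):
        """site_pi equals the mean pairwise difference for all n <= 60."""
        for n in range(2, 61):
            for alt in range(n + 1):
                assert site_pi(n, alt) == pytest.approx(
                    float(pi_pairwise_bruteforce(n, alt)), abs=1e-12
                )

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ValueError):
            site_pi(1, 0)


def _panel(n=4):
    samples = [f"HL{i}" for i in range(n // 2)] + [
        f"LL{i}" for i in range(n // 2)
    ]
    return SamplePanel(samples, {s: s[:2] for s in samples})


class TestWindows:
    def test_grid_layout_and_clipping(self):
        grid = WindowGrid(100, 40, {"c": 250})
        wins = grid.windows("c")
        assert wins.tolist() == [[1, 100], [41, 140], [81, 180], [121, 220],
                                 [161, 250], [201, 250], [241, 250]]

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            WindowGrid(100, 200, {})

    def test_single_site_window_equals_site_ratio(self):
        panel = _panel(8)
        rec = make_record("r", pos=5000, svlen=-100,
                          genotypes=[0, 1, 2, 0, 1, 1, 0, 2])
        grid = WindowGrid(10_000, 10_000, {"chr1": 10_000})
        tab = window_table([rec], panel, grid)
        sites = site_table([rec], panel)
        assert tab.loc[0, "fst"] == pytest.approx(
            sites.loc[0, "fst_site"], abs=1e-15
        )

    def test_two_site_window_is_ratio_of_sums(self):
        panel = _panel(30)
        fixed = make_record("f", pos=1000, svlen=-100,
                            genotypes=[2] * 15 + [0] * 15)
        flat = make_record("n", pos=2000, svlen=-100,
                           genotypes=([0] * 7 + [1] * 6 + [2] * 2) * 2)
        grid = WindowGrid(10_000, 10_000, {"chr1": 10_000})
        tab = window_table([fixed, flat], panel, grid)
        a1, b1, c1 = wc_longhand((0, 0, 15), (15, 0, 0))
        a2, b2, c2 = wc_longhand((7, 6, 2), (7, 6, 2))
        want = (a1 + a2) / (a1 + b1 + c1 + a2 + b2 + c2)
        assert tab.loc[0, "fst"] == pytest.approx(want, abs=1e-12)
        # strictly between the two per-site ratios
        lo = a2 / (a2 + b2 + c2)
        assert lo < tab.loc[0, "fst"] < 1.0

    def test_window_pi_divides_by_span(self):
        panel = _panel(4)
        # one site with pi = 2/3 in each group in a full 100 kb window
        rec = make_record("r", pos=50_000, svlen=-100,
                          genotypes=[1, 1, 1, 1])
        grid = WindowGrid(100_000, 100_000, {"chr1": 100_000})
        tab = window_table([rec], panel, grid)
        assert tab.loc[0, "pi_hl"] == pytest.approx(2 / 3 / 100_000)
        assert tab.loc[0, "n_sites"] == 1

    def test_empty_window_zero_pi_nan_fst(self):
        panel = _panel(4)
        grid = WindowGrid(1000, 1000, {"chr1": 2000})
        rec = make_record("r", pos=100, svlen=-10, genotypes=[0, 1, 1, 0])
        tab = window_table([rec], panel, grid)
        empty = tab.iloc[1]
        assert empty["pi_hl"] == 0.0 and empty["pi_ll"] == 0.0
        assert math.isnan(empty["fst"]) and math.isnan(empty["log2_ratio"])


class TestLogRatio:
    def test_values(self):
        assert log2_pi_ratio(0.002, 0.001) == pytest.approx(1.0)
        assert log2_pi_ratio(0.004, 0.004) == 0.0

    def test_zero_diversity_undefined(self):
        assert math.isnan(log2_pi_ratio(0.0, 0.001))
        assert math.isnan(log2_pi_ratio(0.001, 0.0))
        assert math.isnan(log2_pi_ratio(0.0, 0.0))


class TestSimulationLevelBehaviour:
    def test_null_simulation_mean_windowed_fst_near_zero(self):
        cfg = sim.SimConfig(n_variants=4000, chrom_lengths={"c1": 20_000_000},
                            target_fst=0.0, length_range=(500, 2000), seed=21)
        records, panel, _ = sim.simulate_genotype_matrix(cfg)
        grid = WindowGrid(100_000, 100_000, chrom_lengths=cfg.chrom_lengths)
        tab = window_table(records, panel, grid)
        assert abs(tab["fst"].mean()) < 0.01

    def test_upper_tail_shrinks_with_density(self):
        """No spurious fixed top-tail signal under the null: the 99th
        percentile of windowed FST decreases as site density grows."""
        q99 = {}
        for n_var in (500, 8000):
            cfg = sim.SimConfig(
                n_variants=n_var, chrom_lengths={"c1": 20_000_000},
                target_fst=0.0, length_range=(500, 2000), seed=5,
            )
            records, panel, _ = sim.simulate_genotype_matrix(cfg)
            grid = WindowGrid(100_000, 10_000, chrom_lengths=cfg.chrom_lengths)
            tab = window_table(records, panel, grid)
            q99[n_var] = tab["fst"].quantile(0.99)
        assert q99[8000] < q99[500]

    def test_bounds_hold_everywhere(self):
        cfg = sim.SimConfig(n_variants=2000, chrom_lengths={"c1": 20_000_000},
                            target_fst=0.2, length_range=(500, 2000),
                            missing_rate=0.1, seed=8)
        records, panel, _ = sim.simulate_genotype_matrix(cfg)
        grid = WindowGrid(chrom_lengths=cfg.chrom_lengths)
        tab = window_table(records, panel, grid)
        assert (tab["fst"].dropna() <= 1.0 + 1e-12).all()
        assert (tab["pi_hl"] >= 0).all() and (tab["pi_ll"] >= 0).all()
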