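import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnvselscan import sim
from cnvselscan.core import SamplePanel
from cnvselscan.stats import (
    FrequencySpectrum,
    bin_fisher_tests,
    chrom_distribution_tests,
    freq_bin,
    frequency_spectrum,
    grm,
    grm_pca,
    group_frequencies,
)

from conftest import make_record
from oracles import chi2_2x2_longhand, fisher_two_sided_enumeration, grm_double_loop


class TestGroupFrequencies:
    def test_all_het_is_half(self, panel_30):
        rec = make_record("r", genotypes=[1] * 15 + [0] * 15)
        freqs = group_frequencies([rec], panel_30)
        assert freqs.loc[0, "freq_hl"] == 0.5
        assert freqs.loc[0, "freq_ll"] == 0.0

    def test_one_het_lands_in_first_bin(self, panel_30):
        rec = make_record("r", genotypes=[0] * 14 + [1] + [0] * 15)
        freqs = group_frequencies([rec], panel_30)
        assert freqs.loc[0, "freq_hl"] == pytest.approx(1 / 30)
        assert freq_bin(freqs.loc[0, "freq_hl"]) == 0

    def test_fixed_lands_in_last_bin(self, panel_30):
        rec = make_record("r", genotypes=[2] * 30)
        freqs = group_frequencies([rec], panel_30)
        assert freqs.loc[0, "freq_hl"] == 1.0
        assert freq_bin(1.0) == 9

    def test_spectrum_conserves_counts(self, panel_30):
        rng = np.random.default_rng(3)
        records = [
            make_record(
                f"r{i}", pos=1000 * (i + 1),
                genotypes=rng.choice([-1, 0, 1, 2], size=30,
                                     p=[0.3, 0.3, 0.2, 0.2]),
            )
            for i in range(200)
        ]
        freqs = group_frequencies(records, panel_30)
        spec = frequency_spectrum(freqs)
        assert spec.counts_hl.sum() + spec.n_undefined_hl == 200
        assert spec.counts_ll.sum() + spec.n_undefined_ll == 200


class TestChromTests:
    def _records(self, counts_by_chrom, panel):
        """counts_by_chrom: chrom -> (n with HL presence, n with LL presence);
        variants are built presence-disjoint for clarity."""
        recs = []
        k = 0
        for chrom, (n_hl, n_ll) in counts_by_chrom.items():
            for _ in range(n_hl):
                recs.append(make_record(f"h{k}", chrom=chrom, pos=1000 + k,
                                        svlen=-100,
                                        genotypes=[1] + [0] * 29))
                k += 1
            for _ in range(n_ll):
                recs.append(make_record(f"l{k}", chrom=chrom, pos=1000 + k,
                                        svlen=-100,
                                        genotypes=[0] * 15 + [1] + [0] * 14))
                k += 1
        return recs

    def test_identical_counts_give_p_one(self, panel_30):
        recs = self._records({"c1": (10, 10), "c2": (5, 5)}, panel_30)
        out = chrom_distribution_tests(recs, panel_30)
        assert (out["p"] == 1.0).all()
        assert not out["significant"].any()

    def test_matches_longhand_yates_chi_square(self):
        table = [[30, 970], [10, 990]]
        chi2, p = chi2_2x2_longhand(table, yates=True)
        got_chi2, got_p, _, _ = sps.chi2_contingency(np.array(table),
                                                     correction=True)
        assert got_chi2 == pytest.approx(chi2, rel=1e-12)
        assert got_p == pytest.approx(p, rel=1e-12)

    def test_bonferroni_multiplier_is_tests_performed(self, panel_30):
        counts = {f"c{i}": (3, 3) for i in range(28)}
        counts["c_diff"] = (12, 2)
        recs = self._records(counts, panel_30)
        out = chrom_distribution_tests(recs, panel_30)
        assert len(out) == 29
        row = out[out["chrom"] == "c_diff"].iloc[0]
        assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p"] * 29))


class TestBinFisher:
    def test_matches_enumeration_example(self):
        table = [[3, 7], [10, 2]]
        odds, p = sps.fisher_exact(table)
        assert p == pytest.approx(fisher_two_sided_enumeration(table),
                                  abs=1e-12)

    def test_identical_spectra_all_p_one(self):
        counts = np.array([5, 3, 2, 0, 0, 0, 1, 0, 0, 4])
        spec = FrequencySpectrum(counts.copy(), counts.copy())
        out = bin_fisher_tests(spec)
        assert (out["p"] == 1.0).all()

    def test_empty_bin_convention(self):
        hl = np.array([10, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        ll = np.array([10, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        out = bin_fisher_tests(FrequencySpectrum(hl, ll))
        assert (out["p"].iloc[1:] == 1.0).all()

    def test_extreme_bin_matches_oracle(self):
        spec = FrequencySpectrum(
            np.array([0, 20, 0, 0, 0, 0, 0, 0, 0, 10]),
            np.array([15, 2, 0, 0, 0, 0, 0, 0, 0, 13]),
        )
        out = bin_fisher_tests(spec)
        for _, row in out.iterrows():
            a, c = int(row["count_hl"]), int(row["count_ll"])
            if a + c == 0:
                continue
            table = [[a, 30 - a], [c, 30 - c]]
            assert row["p"] == pytest.approx(
                fisher_two_sided_enumeration(table), abs=1e-12
            )


class TestGrmPca:
    def test_grm_matches_double_loop(self, panel_30):
        rng = np.random.default_rng(11)
        records = [
            make_record(f"r{i}", pos=1000 * (i + 1),
                        genotypes=rng.choice([-1, 0, 1, 2], size=30,
                                             p=[0.05, 0.4, 0.35, 0.2]))
            for i in range(60)
        ]
        G = grm(records)
        want = grm_double_loop(np.vstack([r.genotypes for r in records]))
        assert np.max(np.abs(G - want)) < 1e-10
        assert np.allclose(G, G.T)
        evals = np.linalg.eigvalsh(G)
        assert evals.min() > -1e-9

    def test_clones_give_rank_one_separation(self):
        rng = np.random.default_rng(1)
        a = rng.choice([0, 1, 2], size=100)
        b = rng.choice([0, 1, 2], size=100)
        g = np.vstack([np.tile(a, (4, 1)), np.tile(b, (4, 1))]).T
        samples = [f"HL{i}" for i in range(4)] + [f"LL{i}" for i in range(4)]
        panel = SamplePanel(samples, {s: s[:2] for s in samples})
        records = [
            make_record(f"r{i}", pos=500 * (i + 1), genotypes=g[i])
            for i in range(100)
        ]
        coords, _ = grm_pca(records, panel, 2)
        pc1 = coords["PC1"].to_numpy()
        assert np.ptp(pc1[:4]) < 1e-8 and np.ptp(pc1[4:]) < 1e-8
        assert abs(pc1[0] - pc1[4]) > 1e-3

    def test_pc1_separates_differentiated_groups(self):
        """At moderate differentiation the leading PC splits HL from LL."""
        cfg = sim.SimConfig(n_variants=1000,
                            chrom_lengths={"c1": 50_000_000},
                            target_fst=0.2, seed=14)
        records, panel, _ = sim.simulate_genotype_matrix(cfg)
        coords, var_exp = grm_pca(records, panel)
        hl = coords[coords["group"] == "HL"]["PC1"]
        ll = coords[coords["group"] == "LL"]["PC1"]
        assert hl.min() > ll.max() or ll.min() > hl.max()
        assert var_exp[0] > var_exp[1]

    def test_monomorphic_only_is_error(self, panel_30):
        rec = make_record("r", genotypes=[0] * 30)
        with pytest.raises(ValueError, match="polymorphic"):
            grm([rec])
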