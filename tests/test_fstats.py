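import numpy as np
import pandas as pd
import pytest

from admixkit.data import FreqTable, allele_frequencies
from admixkit.fstats import (
    F4Ratio,
    FourPopulationTest,
    ThreePopulationTest,
    f4_ratio_ancestry,
    four_pop_test,
    three_pop_test,
)
from admixkit import simulate as sim

N_SNPS = 20_000
BIG_N = 10**9  # effectively infinite sample size: no sampling correction


def _blocks(n, g=50):
    return (np.arange(n) * g) // n


def _table(**cols):
    n = len(next(iter(cols.values())))
    p = pd.DataFrame(cols)
    counts = pd.DataFrame({k: np.full(n, BIG_N) for k in cols})
    return FreqTable(p, counts)


@pytest.fixture(scope="module")
def diverged_freqs():
    """Frequencies for two independently drifted populations A, B."""
    rng = np.random.default_rng(21)
    anc = sim.ancestral_frequencies(N_SNPS, rng)
    pa = sim.drift_frequencies(anc, 0.15, rng)
    pb = sim.drift_frequencies(anc, 0.15, rng)
    return anc, pa, pb, rng


class TestFourPopulationTest:
    def test_identical_sisters_give_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 500)
        q = rng.uniform(0.1, 0.9, 500)
        ft = _table(A=p, B=p.copy(), C=q, D=rng.uniform(0.1, 0.9, 500))
        res = four_pop_test(ft, "A", "B", "C", "D", block_ids=_blocks(500, 10))
        assert res.statistic == 0.0
        assert res.z == 0.0

    def test_antisymmetry_identities(self, diverged_freqs):
        rng = np.random.default_rng(3)
        ft = _table(
            A=rng.uniform(0.1, 0.9, 2000),
            B=rng.uniform(0.1, 0.9, 2000),
            C=rng.uniform(0.1, 0.9, 2000),
            D=rng.uniform(0.1, 0.9, 2000),
        )
        blocks = _blocks(2000, 20)
        base = four_pop_test(ft, "A", "B", "C", "D", block_ids=blocks)
        swap_ab = four_pop_test(ft, "B", "A", "C", "D", block_ids=blocks)
        swap_cd = four_pop_test(ft, "A", "B", "D", "C", block_ids=blocks)
        swap_pairs = four_pop_test(ft, "C", "D", "A", "B", block_ids=blocks)
        assert swap_ab.statistic == pytest.approx(-base.statistic)
        assert swap_cd.statistic == pytest.approx(-base.statistic)
        assert swap_pairs.statistic == pytest.approx(base.statistic)
        assert swap_ab.se == pytest.approx(base.se)

    def test_null_tree_calibration(self):
        """Unadmixed tree ((A,B),(C,D)): rejection rate at |Z|>3 stays <= 1%."""
        n_reject = 0
        n_runs = 200
        for seed in range(n_runs):
            freqs, blocks = sim.simulate_null_tree_freqs(
                n_snps=20_000, seed=seed
            )
            res = four_pop_test(freqs, "A", "B", "C", "D", block_ids=blocks)
            n_reject += abs(res.z) > 3
        assert n_reject / n_runs <= 0.01

    def test_admixed_leaf_rejects_tree(self, diverged_freqs):
        """X = 80% C-related + 20% A-related ancestry violates ((A,B),(C,X))."""
        rng = np.random.default_rng(31)
        anc = sim.ancestral_frequencies(N_SNPS, rng)
        node1 = sim.drift_frequencies(anc, 0.05, rng)
        node2 = sim.drift_frequencies(anc, 0.05, rng)
        pa = sim.drift_frequencies(node1, 0.05, rng)
        pb = sim.drift_frequencies(node1, 0.05, rng)
        pc = sim.drift_frequencies(node2, 0.05, rng)
        px = 0.8 * pc + 0.2 * pa
        ft = _table(A=pa, B=pb, C=pc, X=px)
        res = four_pop_test(ft, "A", "B", "C", "X", block_ids=_blocks(N_SNPS))
        assert res.z < -3

    def test_distinct_labels_required(self):
        ft = _table(A=np.full(10, 0.5), B=np.full(10, 0.5))
        with pytest.raises(ValueError, match="distinct"):
            FourPopulationTest(ft, "A", "A", "B", "B", block_ids=_blocks(10, 2))


class TestThreePopulationTest:
    def test_zero_when_x_equals_a_without_sampling_noise(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 1000)
        ft = _table(X=p, A=p.copy(), B=rng.uniform(0.2, 0.8, 1000))
        res = three_pop_test(ft, "X", "A", "B", block_ids=_blocks(1000, 10))
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_simple_outgroup_is_positive(self):
        # X diverged before the A/B split: (p_X-p_A)(p_X-p_B) shares the
        # drift on the path from X to the A/B ancestor -> positive f3
        rng = np.random.default_rng(41)
        anc = sim.ancestral_frequencies(N_SNPS, rng)
        node = sim.drift_frequencies(anc, 0.1, rng)
        ft = _table(
            X=sim.drift_frequencies(anc, 0.1, rng),
            A=sim.drift_frequencies(node, 0.05, rng),
            B=sim.drift_frequencies(node, 0.05, rng),
        )
        res = three_pop_test(ft, "X", "A", "B", block_ids=_blocks(N_SNPS))
        assert res.statistic > 0
        assert res.z > 3

    def test_mixture_cohort_is_significantly_negative(self, small_pools):
        """An 80/20 mosaic cohort (10 generations old) gives f3 Z < -3."""
        pool_a, pool_b, snps = small_pools
        rng = np.random.default_rng(42)
        cohort = sim.simulate_pulse(pool_a, pool_b, 0.8, 10.0, 20, rng, large_n=True)
        xf = allele_frequencies(cohort.genotypes)
        fa, na = sim.reference_frequencies(pool_a, 100, rng)
        fb, nb = sim.reference_frequencies(pool_b, 100, rng)
        ft = FreqTable.from_arrays(
            {
                "X": (xf.freq("admixed"), xf.counts("admixed")),
                "A": (fa, na),
                "B": (fb, nb),
            }
        )
        res = three_pop_test(ft, "X", "A", "B", snps=snps)
        assert res.z < -3

    def test_sampling_correction_removes_positive_bias(self):
        # X is an exact 50/50 mixture of A and B, so the true f3 is
        # -E[(pA-pB)^2]/4; observing X through only 8 alleles biases the raw
        # product upward (here past zero) and the correction restores it
        rng = np.random.default_rng(43)
        pa = rng.uniform(0.2, 0.8, N_SNPS)
        pb = rng.uniform(0.2, 0.8, N_SNPS)
        px_true = 0.5 * (pa + pb)
        truth = -np.mean((pa - pb) ** 2) / 4
        n_x = 8
        px = rng.binomial(n_x, px_true) / n_x
        p = pd.DataFrame({"X": px, "A": pa, "B": pb})
        counts = pd.DataFrame(
            {"X": np.full(N_SNPS, n_x), "A": np.full(N_SNPS, BIG_N), "B": np.full(N_SNPS, BIG_N)}
        )
        ft = FreqTable(p, counts)
        raw = three_pop_test(
            ft, "X", "A", "B", block_ids=_blocks(N_SNPS), sample_correction=False
        )
        corrected = three_pop_test(ft, "X", "A", "B", block_ids=_blocks(N_SNPS))
        assert raw.statistic > truth + 0.02  # inflated by ~E[p(1-p)]/(n-1)
        assert corrected.statistic == pytest.approx(truth, abs=3 * corrected.se)

    def test_x_must_differ_from_references(self):
        ft = _table(X=np.full(10, 0.5), A=np.full(10, 0.4))
        with pytest.raises(ValueError, match="differ"):
            ThreePopulationTest(ft, "X", "X", "A", block_ids=_blocks(10, 2))


class TestF4Ratio:
    @pytest.fixture(scope="class")
    def panel(self):
        rng = np.random.default_rng(51)
        anc = sim.ancestral_frequencies(N_SNPS, rng)
        mid_a = sim.drift_frequencies(anc, 0.08, rng)
        mid_b = sim.drift_frequencies(anc, 0.08, rng)
        return {
            "O1": sim.drift_frequencies(mid_a, 0.1, rng),
            "O2": sim.drift_frequencies(mid_b, 0.1, rng),
            "R1": sim.drift_frequencies(mid_a, 0.08, rng),
            "R2": sim.drift_frequencies(mid_b, 0.08, rng),
        }

    def test_target_equal_to_either_reference(self, panel):
        for target_of, expect in (("R2", 0.0), ("R1", 1.0)):
            ft = _table(X=panel[target_of].copy(), **panel)
            res = f4_ratio_ancestry(
                ft, "O1", "O2", "R1", "R2", "X", block_ids=_blocks(N_SNPS)
            )
            assert res.proportion == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.05, 0.2, 0.5, 0.8])
    def test_convex_combination_recovery(self, panel, alpha):
        """X built as alpha*R1 + (1-alpha)*R2 must estimate alpha."""
        ft = _table(X=alpha * panel["R1"] + (1 - alpha) * panel["R2"], **panel)
        res = f4_ratio_ancestry(
            ft, "O1", "O2", "R1", "R2", "X", block_ids=_blocks(N_SNPS)
        )
        assert abs(res.proportion - alpha) < 2 * res.se

    def test_uninformative_denominator_errors(self):
        rng = np.random.default_rng(52)
        # outgroup difference independent of the R1-R2 contrast
        ft = _table(
            O1=rng.uniform(0.2, 0.8, 5000),
            O2=rng.uniform(0.2, 0.8, 5000),
            R1=rng.uniform(0.2, 0.8, 5000),
            R2=rng.uniform(0.2, 0.8, 5000),
            X=rng.uniform(0.2, 0.8, 5000),
        )
        with pytest.raises(ValueError, match="uninformative"):
            f4_ratio_ancestry(ft, "O1", "O2", "R1", "R2", "X", block_ids=_blocks(5000))

    def test_jackknife_se_tracks_replicate_scatter(self):
        """Across replicates, SD(estimates)/mean(jackknife SE) in [0.5, 2]."""
        estimates, ses = [], []
        alpha = 0.2
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            anc = sim.ancestral_frequencies(4000, rng)
            mid_a = sim.drift_frequencies(anc, 0.08, rng)
            mid_b = sim.drift_frequencies(anc, 0.08, rng)
            r1 = sim.drift_frequencies(mid_a, 0.08, rng)
            r2 = sim.drift_frequencies(mid_b, 0.08, rng)
            x_true = alpha * r1 + (1 - alpha) * r2
            n = 20
            ft = _table(
                O1=sim.drift_frequencies(mid_a, 0.1, rng),
                O2=sim.drift_frequencies(mid_b, 0.1, rng),
                R1=r1,
                R2=r2,
                X=rng.binomial(n, x_true) / n,
            )
            res = f4_ratio_ancestry(
                ft, "O1", "O2", "R1", "R2", "X", block_ids=_blocks(4000)
            )
            estimates.append(res.proportion)
            ses.append(res.se)
        ratio = np.std(estimates, ddof=1) / np.mean(ses)
        assert 0.5 <= ratio <= 2.0
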