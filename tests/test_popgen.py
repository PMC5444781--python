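import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefscape.popgen import (
    GenotypeTable,
    SiteGenotypes,
    allele_freqs,
    chord_distance,
    chord_matrix,
    diversity,
    fst_wc,
    read_genepop,
    site_chord_matrix,
    standardize,
    write_genepop,
)

from conftest import genepop_text_toy


# --- independent oracles -----------------------------------------------------

def wc_oracle(pops):
    """Textbook Weir & Cockerham (1984) components, plain loops.

    ``pops`` is a list of (n_ind, n_loci, 2) integer arrays (0 = missing).
    Returns (theta, f_is) from components summed over loci and alleles.
    """
    n_loci = pops[0].shape[1]
    A_sum = B_sum = C_sum = 0.0
    for locus in range(n_loci):
        samples = []
        for calls in pops:
            g = [tuple(x) for x in calls[:, locus, :] if 0 not in x]
            if g:
                samples.append(g)
        r = len(samples)
        if r < 2:
            continue
        ns = [len(g) for g in samples]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({a for g in samples for pair in g for a in pair})
        for al in alleles:
            p = [sum(pair.count(al) for pair in g) / (2 * len(g))
                 for g in samples]
            h = [sum(1 for pair in g if pair.count(al) == 1) / len(g)
                 for g in samples]
            pbar = sum(n * pi for n, pi in zip(ns, p)) / (r * nbar)
            s2 = sum(n * (pi - pbar) ** 2 for n, pi in zip(ns, p)) / ((r - 1) * nbar)
            hbar = sum(n * hi for n, hi in zip(ns, h)) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            A_sum += a
            B_sum += b
            C_sum += c
    theta = A_sum / (A_sum + B_sum + C_sum) if (A_sum + B_sum + C_sum) else math.nan
    f_is = 1 - C_sum / (B_sum + C_sum) if (B_sum + C_sum) else math.nan
    return theta, f_is


def fis_oracle_single_pop(calls):
    """Single-population W&C F_IS via the r=1 variance components."""
    n_loci = calls.shape[1]
    B = C = 0.0
    for locus in range(n_loci):
        g = [tuple(x) for x in calls[:, locus, :] if 0 not in x]
        n = len(g)
        if n < 2:
            continue
        for al in sorted({a for pair in g for a in pair}):
            p = sum(pair.count(al) for pair in g) / (2 * n)
            h = sum(1 for pair in g if pair.count(al) == 1) / n
            B += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            C += h / 2
    return 1 - C / (B + C) if (B + C) else math.nan


def chord_oracle(p, q):
    s = sum(math.sqrt(pa * qa) for pa, qa in zip(p, q))
    return (2 * math.sqrt(2) / math.pi) * math.sqrt(max(0.0, 1 - s))


def random_table(rng, n_sites=3, n_loci=4, max_alleles=5, miss=0.1):
    sites = []
    for s in range(n_sites):
        n_ind = int(rng.integers(5, 25))
        calls = rng.integers(1, max_alleles + 1, size=(n_ind, n_loci, 2))
        mask = rng.random((n_ind, n_loci)) < miss
        calls[mask] = 0
        sites.append(SiteGenotypes(code=f"P{s}", calls=calls,
                                   individuals=[f"P{s}_{i}" for i in range(n_ind)]))
    return GenotypeTable(loci=[f"L{j}" for j in range(n_loci)], sites=sites)


# --- GENEPOP I/O -------------------------------------------------------------

class TestGenepopIO:
    def test_toy_file_counts(self, tmp_path):
        p = tmp_path / "toy.gen"
        p.write_text(genepop_text_toy())
        t = read_genepop(p)
        assert t.loci == ["LocusA", "LocusB"]
        assert [s.code for s in t.sites] == ["P1_01", "P2_01"]
        assert [s.n for s in t.sites] == [2, 3]
        assert tuple(t.sites[0].calls[0, 0]) == (1, 1)

    def test_missing_parsed_as_zero(self, tmp_path):
        p = tmp_path / "toy.gen"
        p.write_text(genepop_text_toy())
        t = read_genepop(p)
        assert tuple(t.sites[1].calls[1, 1]) == (0, 0)

    def test_all_missing_individual_retained(self, tmp_path):
        p = tmp_path / "am.gen"
        p.write_text("t\nL1\npop\nX1 , 0000\nX2 , 0102\n")
        t = read_genepop(p)
        assert t.sites[0].n == 2

    def test_roundtrip_identity(self, tmp_path, rng):
        table = random_table(rng)
        for digits in (2, 3):
            out = tmp_path / f"rt{digits}.gen"
            write_genepop(table, out, digits=digits)
            back = read_genepop(out)
            assert back.loci == table.loci
            for a, b in zip(table.sites, back.sites):
                assert np.array_equal(a.calls, b.calls)
                assert a.individuals == b.individuals
        # 3-digit write is byte-stable
        w1 = tmp_path / "a.gen"
        w2 = tmp_path / "b.gen"
        write_genepop(table, w1)
        write_genepop(read_genepop(w1), w2)
        assert w1.read_text() == w2.read_text()

    def test_ragged_locus_count_is_error(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nL1\nL2\npop\nX1 , 0101\n")
        with pytest.raises(ValueError, match="line"):
            read_genepop(p)

    def test_non_numeric_allele_is_error(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nL1\npop\nX1 , 01xx\n")
        with pytest.raises(ValueError, match="line"):
            read_genepop(p)


# --- frequencies and diversity -------------------------------------------------

class TestFrequencies:
    def test_two_individuals_aa_ab(self):
        calls = np.array([[[1, 1]], [[1, 2]]])
        t = GenotypeTable(loci=["L1"], sites=[
            SiteGenotypes("P", ["a", "b"], calls)])
        saf = allele_freqs(t)
        assert saf.freqs[("P", "L1")] == {1: 0.75, 2: 0.25}

    def test_missing_excluded_from_denominator(self):
        calls = np.array([[[1, 1]], [[0, 0]], [[1, 2]]])
        t = GenotypeTable(loci=["L1"], sites=[
            SiteGenotypes("P", list("abc"), calls)])
        saf = allele_freqs(t)
        assert saf.n[("P", "L1")] == 2
        assert saf.freqs[("P", "L1")][1] == 0.75

    def test_frequencies_sum_to_one(self, rng):
        t = random_table(rng)
        saf = allele_freqs(t)
        for d in saf.freqs.values():
            if d:
                assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)


class TestDiversity:
    def test_unbiased_hexp_formula(self):
        # 10 individuals, biallelic, p = 0.5 -> H_exp = (20/19) * 0.5
        calls = np.zeros((10, 1, 2), dtype=int)
        calls[:5] = [1, 1]
        calls[5:] = [2, 2]
        t = GenotypeTable(loci=["L1"], sites=[
            SiteGenotypes("P", [f"i{k}" for k in range(10)], calls)])
        d = diversity(t)
        assert d.per_site["H_exp"][0] == pytest.approx((20 / 19) * 0.5)
        assert d.per_site["H_obs"][0] == 0.0

    def test_monomorphic_site_gives_nan_fis(self):
        calls = np.tile([1, 1], (6, 1, 1))
        t = GenotypeTable(loci=["L1"], sites=[
            SiteGenotypes("P", [f"i{k}" for k in range(6)], calls)])
        d = diversity(t)
        assert d.per_site["H_obs"][0] == 0.0
        assert d.per_site["H_exp"][0] == 0.0
        assert np.isnan(d.per_site["F_IS"][0])

    def test_hwe_proportions_give_near_zero_fis(self):
        # exact HWE counts: p = 0.5, n = 100 -> 25 AA, 50 AB, 25 BB
        calls = np.zeros((100, 1, 2), dtype=int)
        calls[:25] = [1, 1]
        calls[25:75] = [1, 2]
        calls[75:] = [2, 2]
        t = GenotypeTable(loci=["L1"], sites=[
            SiteGenotypes("P", [f"i{k}" for k in range(100)], calls)])
        d = diversity(t)
        oracle = fis_oracle_single_pop(calls)
        assert d.per_site["F_IS"][0] == pytest.approx(oracle, abs=1e-12)
        assert abs(d.per_site["F_IS"][0]) < 0.02

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(20):
            t = random_table(rng, n_sites=1)
            d = diversity(t)
            oracle = fis_oracle_single_pop(t.sites[0].calls)
            got = d.per_site["F_IS"][0]
            if math.isnan(oracle):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(oracle, abs=1e-10)


class TestFst:
    def test_fixed_alternate_alleles_give_theta_one(self):
        c1 = np.tile([1, 1], (10, 1, 1))
        c2 = np.tile([2, 2], (10, 1, 1))
        t = GenotypeTable(loci=["L1"], sites=[
            SiteGenotypes("P1", [f"a{k}" for k in range(10)], c1),
            SiteGenotypes("P2", [f"b{k}" for k in range(10)], c2)])
        theta, pair = fst_wc(t)
        assert theta == pytest.approx(1.0)
        assert pair.loc["P1", "P2"] == pytest.approx(1.0)

    def test_identical_populations_give_nonpositive_theta(self, rng):
        calls = rng.integers(1, 4, size=(15, 3, 2))
        t = GenotypeTable(loci=["L1", "L2", "L3"], sites=[
            SiteGenotypes("P1", [f"a{k}" for k in range(15)], calls.copy()),
            SiteGenotypes("P2", [f"b{k}" for k in range(15)], calls.copy())])
        theta, _ = fst_wc(t)
        assert theta <= 1e-9

    def test_matches_variance_component_oracle(self, rng):
        for _ in range(25):
            t = random_table(rng, n_sites=int(rng.integers(2, 5)))
            theta, _ = fst_wc(t)
            oracle, _ = wc_oracle([s.calls for s in t.sites])
            if math.isnan(oracle):
                assert np.isnan(theta)
            else:
                assert theta == pytest.approx(oracle, abs=1e-10)


# --- chord distance ------------------------------------------------------------

class TestChordDistance:
    def test_identical_frequencies_give_zero(self):
        f = {"L1": {1: 0.3, 2: 0.7}}
        assert chord_distance(f, f) == 0.0

    def test_disjoint_biallelic_value(self):
        x = {"L1": {1: 1.0}}
        y = {"L1": {2: 1.0}}
        assert chord_distance(x, y) == pytest.approx(2 * math.sqrt(2) / math.pi)

    def test_relabeling_invariance(self, rng):
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        x = {"L1": dict(zip([1, 2, 3, 4], p))}
        y = {"L1": dict(zip([1, 2, 3, 4], q))}
        perm = [3, 1, 4, 2]
        xp = {"L1": dict(zip(perm, p))}
        yp = {"L1": dict(zip(perm, q))}
        assert chord_distance(x, y) == pytest.approx(chord_distance(xp, yp))

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            x = {"L1": dict(zip(range(1, k + 1), p))}
            y = {"L1": dict(zip(range(1, k + 1), q))}
            assert chord_distance(x, y) == pytest.approx(
                chord_oracle(p, q), abs=1e-10)
            # dense-array route agrees with the dict route
            arr = np.stack([p, q])[:, None, :]
            assert chord_matrix(arr)[0, 1] == pytest.approx(
                chord_oracle(p, q), abs=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_metric_axioms_on_random_frequency_pairs(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        p = rng.dirichlet(np.ones(k))
        q = rng.dirichlet(np.ones(k))
        x = {"L1": dict(zip(range(k), p))}
        y = {"L1": dict(zip(range(k), q))}
        dxy = chord_distance(x, y)
        assert dxy >= 0
        assert dxy == pytest.approx(chord_distance(y, x), abs=1e-12)
        assert chord_distance(x, x) == 0.0

    def test_undefined_locus_dropped(self, caplog):
        x = {"L1": {1: 1.0}, "L2": {}}
        y = {"L1": {1: 0.5, 2: 0.5}, "L2": {1: 1.0}}
        with caplog.at_level("WARNING"):
            d = chord_distance(x, y)
        assert "dropped" in caplog.text
        assert d == pytest.approx(chord_oracle([1.0, 0.0], [0.5, 0.5]))


class TestStandardize:
    def test_max_becomes_one_and_ratios_preserved(self):
        m = np.array([[0.0, 0.45, 0.09], [0.45, 0.0, 0.3], [0.09, 0.3, 0.0]])
        out = standardize(m)
        assert out.max() == pytest.approx(1.0)
        assert out[0, 2] / out[1, 2] == pytest.approx(0.09 / 0.3)

    def test_all_zero_unchanged_with_warning(self, caplog):
        m = np.zeros((3, 3))
        with caplog.at_level("WARNING"):
            out = standardize(m)
        assert np.array_equal(out, m)
        assert "skipped" in caplog.text
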