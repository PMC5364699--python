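"""Selection tests, including three independent oracles:

* a recursive exhaustive aligner for affine-gap global alignment scores,
* a from-scratch Nei-Gojobori site/pathway calculator built directly on the
  genetic code,
* a permutation-enumeration Mann-Whitney test.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from paleodup.genome_io import ValidationError
from paleodup.selection import (CodonAlignment, KaKsResult, PairExclusion,
                                align_protein_pair, backtranslate,
                                compare_classes, compute_pair_kaks,
                                filter_pairs, kaks_ng86, mannwhitney_exact)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = -10.0
GAP_EXTEND = -0.5


def oracle_align_score(a, b):
    """Exhaustive enumeration of all global alignments with affine gaps.

    Exponential; only usable for short sequences.  States: 0 = none/match,
    1 = gap in a (insertion), 2 = gap in b (deletion).
    """
    best = [-math.inf]

    def go(i, j, state, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, 0, score + BLOSUM62[a[i], b[j]])
        if j < len(b):  # gap in a
            cost = GAP_EXTEND + (GAP_OPEN if state != 1 else 0.0)
            go(i, j + 1, 1, score + cost)
        if i < len(a):  # gap in b
            cost = GAP_EXTEND + (GAP_OPEN if state != 2 else 0.0)
            go(i + 1, j, 2, score + cost)

    go(0, 0, 0, 0.0)
    return best[0]


class TestAlignProteinPair:
    def test_identity(self):
        aln = align_protein_pair("MKV", "MKV")
        assert aln.a_gapped == "MKV"
        assert aln.identity == 1.0
        assert aln.coverage == 1.0

    def test_single_gap(self):
        aln = align_protein_pair("MKV", "MV")
        assert sorted((aln.a_gapped, aln.b_gapped)) == ["M-V", "MKV"]
        assert aln.identity == pytest.approx(1.0)  # aligned columns match
        assert aln.coverage == pytest.approx(1.0)

    def test_invalid_residue(self):
        with pytest.raises(ValidationError, match="invalid"):
            align_protein_pair("MKO", "MK")

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            align_protein_pair("", "MK")

    @pytest.mark.parametrize("seed", range(25))
    def test_score_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = "ARNDCQEGHILKMFPSTWYV"
        n, m = rng.integers(2, 7, size=2)
        a = "".join(alphabet[i] for i in rng.integers(20, size=n))
        b = "".join(alphabet[i] for i in rng.integers(20, size=m))
        aln = align_protein_pair(a, b)
        assert aln.score == pytest.approx(oracle_align_score(a, b))


class TestBacktranslate:
    def test_third_position_difference(self):
        paln = align_protein_pair("MK", "MK")
        caln = backtranslate(paln, "ATGAAA", "ATGAAG")
        assert caln.n_codon_columns == 2
        assert caln.columns[1] == ("AAA", "AAG")

    def test_gap_column_becomes_codon_gap(self):
        paln = align_protein_pair("MKV", "MV")
        caln = backtranslate(paln, "ATGAAAGTT", "ATGGTT")
        assert ("AAA", "---") in caln.columns

    def test_internal_stop_excluded(self):
        paln = align_protein_pair("MK", "MK")
        with pytest.raises(PairExclusion) as err:
            backtranslate(paln, "ATGTAA", "ATGAAA")
        assert err.value.reason == "internal_stop"

    def test_translation_mismatch_excluded(self):
        paln = align_protein_pair("MK", "MK")
        with pytest.raises(PairExclusion) as err:
            backtranslate(paln, "ATGCCC", "ATGAAA")
        assert err.value.reason == "translation_mismatch"


# ---------------------------------------------------------------------------
# NG86 oracle built independently from the genetic code


_CODE = unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)


def _oracle_aa(codon):
    return _CODE.forward_table[codon]


def oracle_syn_sites(codon):
    total = 0.0
    for pos in range(3):
        syn = ok = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in _STOPS:
                continue
            ok += 1
            syn += _oracle_aa(alt) == _oracle_aa(codon)
        if ok:
            total += syn / ok
    return total


def oracle_differences(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _oracle_aa(nxt) == _oracle_aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return len(diff) / 2, len(diff) / 2
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_kaks(codons_a, codons_b):
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        S += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        N += 3 - (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        sd, nd = oracle_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return None if p >= 0.75 else \
            (0.0 if p == 0 else -0.75 * math.log(1 - 4 * p / 3))
    return S, N, Sd, Nd, jc(pS), jc(pN)


SENSE = sorted(_CODE.forward_table)


def _codon_aln(codons_a, codons_b):
    return CodonAlignment("a", "b", list(zip(codons_a, codons_b)), 1.0, 1.0)


class TestKaksNg86:
    def test_identical_sequences(self):
        codons = [SENSE[i % len(SENSE)] for i in range(100)]
        r = kaks_ng86(_codon_aln(codons, codons))
        assert r.Sd == r.Nd == 0
        assert r.Ka == r.Ks == 0.0
        assert r.omega is None

    def test_single_synonymous_change(self):
        a = ["CCT"] + ["ATG"] * 9
        b = ["CCC"] + ["ATG"] * 9
        r = kaks_ng86(_codon_aln(a, b))
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.Ka == 0.0
        S, N, Sd, Nd, ks, ka = oracle_kaks(a, b)
        assert r.Ks == pytest.approx(ks)
        assert r.S_sites == pytest.approx(S)

    def test_single_nonsynonymous_change(self):
        a = ["AAA"] + ["ATG"] * 9
        b = ["GAA"] + ["ATG"] * 9
        r = kaks_ng86(_codon_aln(a, b))
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        assert r.Ks == 0.0
        assert r.Ka > 0
        assert r.omega is None  # Ks == 0
        _, _, _, _, _, ka = oracle_kaks(a, b)
        assert r.Ka == pytest.approx(ka)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            a = [SENSE[i] for i in rng.integers(len(SENSE), size=10)]
            b = [SENSE[i] for i in rng.integers(len(SENSE), size=10)]
            r = kaks_ng86(_codon_aln(a, b))
            S, N, Sd, Nd, ks, ka = oracle_kaks(a, b)
            assert r.S_sites == pytest.approx(S)
            assert r.N_sites == pytest.approx(N)
            assert r.Sd == pytest.approx(Sd)
            assert r.Nd == pytest.approx(Nd)
            if ks is None:
                assert r.saturated
            else:
                assert r.Ks == pytest.approx(ks)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = [SENSE[i] for i in rng.integers(len(SENSE), size=20)]
        b = [SENSE[i] for i in rng.integers(len(SENSE), size=20)]
        r1 = kaks_ng86(_codon_aln(a, b))
        r2 = kaks_ng86(_codon_aln(b, a))
        assert r1.S_sites == pytest.approx(r2.S_sites)
        assert r1.Sd == pytest.approx(r2.Sd)
        assert r1.Nd == pytest.approx(r2.Nd)

    def test_sites_sum_to_three_per_column(self):
        rng = np.random.default_rng(0)
        a = [SENSE[i] for i in rng.integers(len(SENSE), size=30)]
        b = [SENSE[i] for i in rng.integers(len(SENSE), size=30)]
        r = kaks_ng86(_codon_aln(a, b))
        assert r.S_sites + r.N_sites == pytest.approx(3 * 30)

    def test_extra_synonymous_difference_never_decreases_ks(self):
        # fourfold-degenerate third positions: add one syn change at a time
        base = ["GGA"] * 50
        prev = 0.0
        for k in range(1, 15):
            other = ["GGC"] * k + ["GGA"] * (50 - k)
            r = kaks_ng86(_codon_aln(base, other))
            assert r.Ks is not None and r.Ks >= prev
            prev = r.Ks

    def test_zero_columns_invalid(self):
        with pytest.raises(ValidationError):
            kaks_ng86(CodonAlignment("a", "b", [("---", "ATG")], 1.0, 1.0))


class TestComputePairKaks:
    def test_end_to_end(self):
        cds_a = "ATGCCTAAA"
        cds_b = "ATGCCCAAA"
        r = compute_pair_kaks("a", "b", cds_a, cds_b)
        assert r.Sd == pytest.approx(1.0)
        assert r.Nd == 0.0

    def test_internal_stop_pair_excluded(self):
        with pytest.raises(PairExclusion):
            compute_pair_kaks("a", "b", "ATGTAAAAA", "ATGAAAAAA")


class TestFilterPairs:
    @staticmethod
    def result(identity=0.9, coverage=0.9, saturated=False):
        return KaKsResult("a", "b", 100, 200, 5, 5, 0.05, 0.025, 0.05, 0.03,
                          0.6, ["saturated"] if saturated else [],
                          identity, coverage)

    def test_low_identity(self):
        kept, log = filter_pairs([self.result(identity=0.25)])
        assert kept == []
        assert log[0][1] == "low_identity"

    def test_low_coverage(self):
        kept, log = filter_pairs([self.result(coverage=0.4)])
        assert log[0][1] == "low_coverage"

    def test_saturated_among_ten(self):
        results = [self.result() for _ in range(9)] + \
            [self.result(saturated=True)]
        kept, log = filter_pairs(results)
        assert len(kept) == 9
        assert len(log) == 1


def oracle_mannwhitney(x, y):
    """Two-sided p by enumerating index permutations of the pooled sample."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                   for xi in xs for yj in ys)

    center = n * len(y) / 2
    dev = abs(u_stat(x, y) - center)
    hits = total = 0
    for perm in itertools.permutations(range(len(pooled)), n):
        xs = [pooled[i] for i in perm]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(perm)]
        total += 1
        hits += abs(u_stat(xs, ys) - center) >= dev - 1e-12
    return hits / total


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mannwhitney_exact([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p == 1.0

    def test_extreme_separation(self):
        u, p = mannwhitney_exact([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)
        assert p == pytest.approx(oracle_mannwhitney([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6, size=2)
        x = list(rng.integers(0, 6, size=n).astype(float))
        y = list(rng.integers(0, 6, size=m).astype(float))
        _, p = mannwhitney_exact(x, y)
        assert p == pytest.approx(oracle_mannwhitney(x, y))

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        x = list(rng.normal(size=6))
        y = list(rng.normal(size=7))
        _, p = mannwhitney_exact(x, y)
        assert p == pytest.approx(
            scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue)


class TestCompareClasses:
    def _results(self, omegas, label):
        out = []
        for i, om in enumerate(omegas):
            out.append(KaKsResult(f"{label}{i}", f"{label}{i}x", 100, 200,
                                  om * 10, om * 20, 0.1, 0.05, 0.5, 0.5 * om,
                                  om, [], 0.9, 0.9))
        return out

    def test_ordering_recovered_from_simulated_omegas(self, rng):
        a = list(rng.normal(0.15, 0.03, size=30).clip(0.01))
        c = list(rng.normal(0.40, 0.05, size=30).clip(0.01))
        results = self._results(a, "A") + self._results(c, "C")
        classes = {r.key(): ("A" if r.gene_a.startswith("A") else "C")
                   for r in results}
        comp = compare_classes(results, classes)
        assert comp.stats["A"]["mean_omega"] < comp.stats["C"]["mean_omega"]
        assert comp.pvalues[("A", "C")] < 0.05
        assert comp.methods[("A", "C")] == "asymptotic"

    def test_exact_used_for_small_groups(self):
        results = self._results([0.1, 0.2, 0.3], "A") + \
            self._results([0.4, 0.5, 0.6], "B")
        classes = {r.key(): r.gene_a[0] for r in results}
        comp = compare_classes(results, classes)
        assert comp.methods[("A", "B")] == "exact"
        assert comp.pvalues[("A", "B")] == pytest.approx(0.1)

    def test_empty_class_warned(self):
        results = self._results([0.1, 0.2], "A")
        classes = {r.key(): "A" for r in results}
        classes[("zzz", "zzz2")] = "B"
        comp = compare_classes(results, classes)
        assert any("B" in w for w in comp.warnings)
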