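"""Selection-pressure estimation on gene pairs.

Protein pairs are globally aligned (BLOSUM62, affine gaps), the alignment is
back-translated onto the coding sequences, and Ka/Ks is estimated with the
Nei–Gojobori counting method: per-codon synonymous site fractions from the
standard genetic code, observed differences averaged over all mutational
pathways (pathways through stop codons discarded), and a Jukes–Cantor
multiple-hit correction on both proportions.  Rate distributions between
divergence classes are compared with two-sided Mann–Whitney U tests (exact
enumeration for small samples, normal approximation with tie correction
otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from statistics import mean, median

import scipy.stats

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_io import STOP_CODONS, ValidationError

__all__ = [
    "ProteinAlignment",
    "CodonAlignment",
    "KaKsResult",
    "ClassComparison",
    "PairExclusion",
    "align_protein_pair",
    "backtranslate",
    "kaks_ng86",
    "compute_pair_kaks",
    "filter_pairs",
    "mannwhitney_exact",
    "compare_classes",
]

_CODON_TABLE = unambiguous_dna_by_id[1]
_AA = {codon: aa for codon, aa in _CODON_TABLE.forward_table.items()}
_NUCS = "ACGT"
_PROTEIN_ALPHABET = frozenset("ARNDCQEGHILKMFPSTWYVBZX")


def _syn_fraction_table() -> dict[str, float]:
    """Synonymous site count per sense codon (sum of per-position fractions;
    changes to stop codons drop out of the possible-change denominator)."""
    table = {}
    for codon in _AA:
        s = 0.0
        for pos in range(3):
            n_syn = n_valid = 0
            for nt in _NUCS:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                n_valid += 1
                if _AA[alt] == _AA[codon]:
                    n_syn += 1
            if n_valid:
                s += n_syn / n_valid
        table[codon] = s
    return table


_SYN_SITES = _syn_fraction_table()


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all mutational pathways that avoid stop codons."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff)
    if k == 0:
        return (0.0, 0.0)
    totals = []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _AA[nxt] == _AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return (k / 2.0, k / 2.0)
    return (mean(t[0] for t in totals), mean(t[1] for t in totals))


# cache: there are only 61*61 sense codon pairs
_PATHWAY_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _pathway_counts_cached(a: str, b: str) -> tuple[float, float]:
    key = (a, b)
    got = _PATHWAY_CACHE.get(key)
    if got is None:
        got = _pathway_counts(a, b)
        _PATHWAY_CACHE[key] = got
        _PATHWAY_CACHE[(b, a)] = got
    return got


class PairExclusion(Exception):
    """A gene pair dropped from selection analysis, with the reason why."""

    def __init__(self, reason: str, detail: str = "") -> None:
        super().__init__(f"{reason}: {detail}" if detail else reason)
        self.reason = reason


@dataclass
class ProteinAlignment:
    gene_a: str
    gene_b: str
    a_gapped: str
    b_gapped: str
    score: float

    @property
    def n_aligned_columns(self) -> int:
        return sum(1 for x, y in zip(self.a_gapped, self.b_gapped)
                   if x != "-" and y != "-")

    @property
    def identity(self) -> float:
        cols = self.n_aligned_columns
        if cols == 0:
            return 0.0
        matches = sum(1 for x, y in zip(self.a_gapped, self.b_gapped)
                      if x == y and x != "-")
        return matches / cols

    @property
    def coverage(self) -> float:
        shorter = min(len(self.a_gapped.replace("-", "")),
                      len(self.b_gapped.replace("-", "")))
        return self.n_aligned_columns / shorter if shorter else 0.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # gap of length k costs 10 + 0.5*k; biopython's open score is the
    # first gapped position, so it already includes one extension
    aligner.open_gap_score = -10.5
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def align_protein_pair(a: str, b: str, gene_a: str = "a",
                       gene_b: str = "b") -> ProteinAlignment:
    """Global affine-gap protein alignment (BLOSUM62, open 10, extend 0.5)."""
    for name, seq in ((gene_a, a), (gene_b, b)):
        if not seq:
            raise ValidationError(f"{name}: empty protein sequence")
        bad = set(seq) - _PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"{name}: invalid residues {''.join(sorted(bad))}")
    aln = _ALIGNER.align(a, b)[0]
    return ProteinAlignment(gene_a, gene_b, str(aln[0]), str(aln[1]),
                            float(aln.score))


@dataclass
class CodonAlignment:
    """Protein-guided codon alignment: one (codon, codon) pair per protein
    alignment column, with '---' for gaps."""

    gene_a: str
    gene_b: str
    columns: list[tuple[str, str]]
    protein_identity: float
    coverage: float

    @property
    def n_codon_columns(self) -> int:
        return len(self.columns)

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [(ca, cb) for ca, cb in self.columns
                if "-" not in ca and "-" not in cb
                and set(ca + cb) <= set(_NUCS)]


def backtranslate(protein_aln: ProteinAlignment, cds_a: str,
                  cds_b: str) -> CodonAlignment:
    """Expand each aligned residue column to its source codon.

    Raises :class:`PairExclusion` (reasons ``internal_stop``,
    ``length_mismatch``, ``translation_mismatch``) when a CDS does not back
    the protein.
    """
    out_cols: list[tuple[str, str]] = []
    pos = {"a": 0, "b": 0}
    seqs = {"a": cds_a.upper(), "b": cds_b.upper()}
    prots = {"a": protein_aln.a_gapped, "b": protein_aln.b_gapped}
    for tag in ("a", "b"):
        cds = seqs[tag]
        n_res = len(prots[tag].replace("-", ""))
        if len(cds) != 3 * n_res:
            raise PairExclusion("length_mismatch",
                                f"cds {tag} has {len(cds)} nt for {n_res} residues")
    for x, y in zip(protein_aln.a_gapped, protein_aln.b_gapped):
        col = []
        for tag, res in (("a", x), ("b", y)):
            if res == "-":
                col.append("---")
                continue
            i = pos[tag]
            codon = seqs[tag][3 * i:3 * i + 3]
            pos[tag] += 1
            if codon in STOP_CODONS:
                raise PairExclusion("internal_stop",
                                    f"cds {tag} codon {i}")
            aa = _AA.get(codon, "X")
            if res != "X" and "N" not in codon and aa != res:
                raise PairExclusion(
                    "translation_mismatch",
                    f"cds {tag} codon {i} ({codon}->{aa}) vs residue {res}")
            col.append(codon)
        out_cols.append((col[0], col[1]))
    return CodonAlignment(protein_aln.gene_a, protein_aln.gene_b, out_cols,
                          protein_aln.identity, protein_aln.coverage)


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    omega: float | None
    flags: list[str] = field(default_factory=list)
    protein_identity: float = 1.0
    coverage: float = 1.0
    pair_type: str = ""

    @property
    def saturated(self) -> bool:
        return "saturated" in self.flags

    def key(self) -> tuple[str, str]:
        a, b = sorted((self.gene_a, self.gene_b))
        return (a, b)


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def kaks_ng86(aln: CodonAlignment) -> KaKsResult:
    cols = aln.ungapped_columns()
    if not cols:
        raise ValidationError(
            f"{aln.gene_a}/{aln.gene_b}: no ungapped codon columns")
    S = N = Sd = Nd = 0.0
    for ca, cb in cols:
        S += (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        N += (3.0 - _SYN_SITES[ca] + 3.0 - _SYN_SITES[cb]) / 2.0
        sd, nd = _pathway_counts_cached(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    flags = []
    if Ks is None or Ka is None:
        flags.append("saturated")
    omega = None
    if Ks is not None and Ka is not None and Ks > 0:
        omega = Ka / Ks
    return KaKsResult(aln.gene_a, aln.gene_b, S, N, Sd, Nd, pS, pN,
                      Ks, Ka, omega, flags,
                      aln.protein_identity, aln.coverage)


def compute_pair_kaks(gene_a: str, gene_b: str, cds_a: str, cds_b: str,
                      protein_a: str | None = None,
                      protein_b: str | None = None) -> KaKsResult:
    """Align, back-translate and estimate in one step.

    Raises :class:`PairExclusion` when the pair cannot be processed.
    """
    from .genome_io import translate_cds

    for tag, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3 != 0:
            raise PairExclusion("length_not_multiple_of_3", f"cds {tag}")
        if any(cds[i:i + 3].upper() in STOP_CODONS for i in range(0, len(cds), 3)):
            raise PairExclusion("internal_stop", f"cds {tag}")
    pa = protein_a if protein_a is not None else translate_cds(cds_a)
    pb = protein_b if protein_b is not None else translate_cds(cds_b)
    paln = align_protein_pair(pa, pb, gene_a, gene_b)
    caln = backtranslate(paln, cds_a, cds_b)
    return kaks_ng86(caln)


def filter_pairs(results: list[KaKsResult], min_identity: float = 0.3,
                 min_coverage: float = 0.5,
                 prior_exclusions: list[tuple[tuple[str, str], str]] | None = None
                 ) -> tuple[list[KaKsResult], list[tuple[tuple[str, str], str]]]:
    """Drop low-similarity and saturated pairs; return (retained, log).

    The log lists ``((gene_a, gene_b), reason)`` for every exclusion,
    including any pairs already excluded upstream (``prior_exclusions``).
    """
    retained = []
    log: list[tuple[tuple[str, str], str]] = list(prior_exclusions or [])
    for r in results:
        if r.protein_identity < min_identity:
            log.append((r.key(), "low_identity"))
        elif r.coverage < min_coverage:
            log.append((r.key(), "low_coverage"))
        elif r.saturated:
            log.append((r.key(), "saturated"))
        else:
            retained.append(r)
    return retained, log


def _u_statistic(x: list[float], y: list[float]) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mannwhitney_exact(x: list[float], y: list[float]) -> tuple[float, float]:
    """Two-sided exact Mann–Whitney U by complete enumeration of labelings.

    Ties are handled by the half-count convention.  Returns ``(U, p)``.
    """
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = list(x) + list(y)
    observed = _u_statistic(x, y)
    center = n * m / 2.0
    dev = abs(observed - center)
    total = 0
    extreme = 0
    idx = range(n + m)
    for chosen in combinations(idx, n):
        cset = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in cset]
        total += 1
        if abs(_u_statistic(xs, ys) - center) >= dev - 1e-12:
            extreme += 1
    return observed, extreme / total


@dataclass
class ClassComparison:
    """Per-class rate summaries plus pairwise Mann–Whitney p-values on omega."""

    stats: dict[str, dict[str, float]]
    pvalues: dict[tuple[str, str], float]
    methods: dict[tuple[str, str], str]
    warnings: list[str] = field(default_factory=list)


def compare_classes(results: list[KaKsResult],
                    classes: dict[tuple[str, str], str],
                    exact_max_n: int = 8) -> ClassComparison:
    """Compare Ka, Ks and omega distributions between divergence classes.

    ``classes`` maps canonical pair keys to class labels.  The Mann–Whitney
    test runs on omega; exact enumeration when both groups have at most
    ``exact_max_n`` members, normal approximation with tie correction
    otherwise.
    """
    groups: dict[str, list[KaKsResult]] = {}
    for r in results:
        label = classes.get(r.key())
        if label is None:
            continue
        groups.setdefault(str(label), []).append(r)
    warnings_list = [f"class {lab} has no members" for lab in
                     sorted(set(map(str, classes.values())) - set(groups))]
    stats: dict[str, dict[str, float]] = {}
    omegas: dict[str, list[float]] = {}
    for label in sorted(groups):
        rs = groups[label]
        ka = [r.Ka for r in rs if r.Ka is not None]
        ks = [r.Ks for r in rs if r.Ks is not None]
        om = [r.omega for r in rs if r.omega is not None]
        omegas[label] = om
        stats[label] = {
            "n": len(rs),
            "mean_Ka": mean(ka) if ka else float("nan"),
            "median_Ka": median(ka) if ka else float("nan"),
            "mean_Ks": mean(ks) if ks else float("nan"),
            "median_Ks": median(ks) if ks else float("nan"),
            "mean_omega": mean(om) if om else float("nan"),
            "median_omega": median(om) if om else float("nan"),
        }
    pvalues: dict[tuple[str, str], float] = {}
    methods: dict[tuple[str, str], str] = {}
    labels = sorted(omegas)
    for la, lb in combinations(labels, 2):
        x, y = omegas[la], omegas[lb]
        if not x or not y:
            warnings_list.append(f"comparison {la} vs {lb} skipped (empty omega)")
            continue
        if len(x) <= exact_max_n and len(y) <= exact_max_n:
            _, p = mannwhitney_exact(x, y)
            methods[(la, lb)] = "exact"
        else:
            p = float(scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic").pvalue)
            methods[(la, lb)] = "asymptotic"
        pvalues[(la, lb)] = p
    return ClassComparison(stats, pvalues, methods, warnings_list)
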