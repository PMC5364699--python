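"""Genome-evolution simulator with ground truth.

Simulates a paleodiploid reference genome and a descendant genome shaped by
speciation, one whole-genome duplication with per-copy fractionation, and
tandem duplications, together with coding/protein sequences, annotation
terms, a homology hit table and a ground-truth record — so every pipeline
stage can be tested without external downloads.

Divergence is planted per pair relationship through branch-wise sequence
evolution: synonymous substitution events arrive as Poisson(Ks x S_sites)
and nonsynonymous events as Poisson(omega x Ks x N_sites), each applied at a
uniformly chosen mutational opportunity of the current sequence (changes
creating stop codons are never offered).  Branch lengths are chosen so that
pairwise planted Ks values are exactly the event ages: orthologs diverge at
``ks_speciation``, WGD copies at ``ks_wgd``, post-WGD tandem siblings at
draws around ``ks_tandem_mean``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (Gene, GeneIndex, HomologHit, STOP_CODONS,
                        TermAnnotation, ValidationError, translate_cds,
                        write_fasta, write_gff3, write_term_table)
from .selection import _AA, _SYN_SITES

__all__ = ["EvolutionParams", "SyntheticDataset", "simulate", "evolve_pair"]

_SENSE_CODONS = sorted(_AA)
_NUCS = "ACGT"

# Highest one-branch Ks whose expected substitution proportion stays below
# the Jukes-Cantor saturation guard (p < 0.74).
KS_REACHABLE_MAX = -0.75 * math.log(1.0 - 4.0 * 0.74 / 3.0)


def _mutation_ops() -> tuple[dict[str, tuple], dict[str, tuple]]:
    syn: dict[str, tuple] = {}
    non: dict[str, tuple] = {}
    for codon in _SENSE_CODONS:
        s, n = [], []
        for pos in range(3):
            for nt in _NUCS:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                (s if _AA[alt] == _AA[codon] else n).append((pos, nt))
        syn[codon] = tuple(s)
        non[codon] = tuple(n)
    return syn, non


_SYN_OPS, _NON_OPS = _mutation_ops()


def _evolve_branch(codons: list[str], ks: float, omega: float,
                   rng: np.random.Generator) -> list[str]:
    """Evolve a codon list along one branch of length ``ks`` (synonymous
    substitutions per synonymous site) at nonsynonymous/synonymous ratio
    ``omega``.  Events pick uniformly among the current sequence's allowed
    single-nucleotide changes of the matching kind."""
    codons = list(codons)
    n_cod = len(codons)
    S = sum(_SYN_SITES[c] for c in codons)
    N = 3.0 * n_cod - S
    n_syn = int(rng.poisson(ks * S)) if ks > 0 else 0
    n_non = int(rng.poisson(omega * ks * N)) if ks > 0 and omega > 0 else 0
    kinds = np.array([0] * n_syn + [1] * n_non, dtype=np.int8)
    rng.shuffle(kinds)
    syn_counts = np.fromiter((len(_SYN_OPS[c]) for c in codons),
                             dtype=np.int64, count=n_cod)
    non_counts = np.fromiter((len(_NON_OPS[c]) for c in codons),
                             dtype=np.int64, count=n_cod)
    for kind in kinds:
        table = _SYN_OPS if kind == 0 else _NON_OPS
        counts = syn_counts if kind == 0 else non_counts
        cum = np.cumsum(counts)
        total = int(cum[-1]) if n_cod else 0
        if total == 0:
            continue
        r = int(rng.integers(total))
        i = int(np.searchsorted(cum, r, side="right"))
        within = r - (int(cum[i - 1]) if i > 0 else 0)
        pos, nt = table[codons[i]][within]
        codons[i] = codons[i][:pos] + nt + codons[i][pos + 1:]
        syn_counts[i] = len(_SYN_OPS[codons[i]])
        non_counts[i] = len(_NON_OPS[codons[i]])
    return codons


def evolve_pair(cds: str, ks_target: float, omega: float,
                seed: int | np.random.Generator) -> str:
    """Return a copy of ``cds`` diverged from it by ``ks_target`` at ratio
    ``omega``.  ``cds`` must be stop-free and in frame."""
    if len(cds) % 3 != 0:
        raise ValidationError("cds length not a multiple of 3")
    codons = [cds[i:i + 3].upper() for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS or c not in _AA for c in codons):
        raise ValidationError("cds must be stop-free unambiguous codons")
    if ks_target < 0 or omega < 0:
        raise ValidationError("rates must be non-negative")
    if ks_target > KS_REACHABLE_MAX:
        raise ValidationError(
            f"unreachable target: Ks {ks_target:.3f} exceeds the saturation "
            f"limit {KS_REACHABLE_MAX:.3f}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return "".join(_evolve_branch(codons, ks_target, omega, rng))


_DEFAULT_ARRAY_WEIGHTS = {size: 0.5 ** (size - 2) for size in range(2, 17)}


@dataclass
class EvolutionParams:
    seed: int = 7
    n_ref_genes: int = 2000
    n_chromosomes: int = 5
    gene_length_codons: int = 200
    ks_speciation: float = 1.5
    ks_wgd: float = 0.7
    ks_tandem_mean: float = 0.3
    ks_tandem_sd: float = 0.05
    ks_pre_tandem: float = 0.1  # ancestral divergence between pre-WGD sibs
    frac_tandem_pre_wgd: float = 0.05
    retention_prob: float = 0.25  # probability a family is co-retained
    loss_prob: float = 0.05       # probability both WGD copies are lost
    sub1_bias: float = 0.52       # single-copy survivors leaning to subgenome1
    n_tandem_arrays: int = 100
    array_size_weights: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_ARRAY_WEIGHTS))
    omega_by_class: dict[str, float] = field(
        default_factory=lambda: {"A": 0.15, "B": 0.21, "C": 0.35})
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.74, "B": 0.11, "C": 0.06,
                                 "unannotated": 0.09})
    term_vocab_size: int = 1500
    terms_per_gene: tuple[int, int] = (1, 4)
    n_inversions: int = 0
    intergenic_bp: int = 1000

    def validate(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValidationError("class_proportions must sum to 1")
        if not (0 < self.ks_tandem_mean < self.ks_wgd < self.ks_speciation):
            raise ValidationError(
                "need ks_tandem_mean < ks_wgd < ks_speciation (all > 0)")
        if self.retention_prob + self.loss_prob > 1:
            raise ValidationError("retention_prob + loss_prob must be <= 1")
        for k, v in self.omega_by_class.items():
            if v < 0:
                raise ValidationError(f"omega_by_class[{k}] must be >= 0")
        if self.n_ref_genes < self.n_chromosomes:
            raise ValidationError("need at least one gene per chromosome")
        if any(w < 0 for w in self.array_size_weights.values()):
            raise ValidationError("array size weights must be >= 0")


def _intended_class(terms_a: frozenset, terms_b: frozenset) -> str:
    # simulator-side statement of the divergence-class definition; the
    # pipeline classifier is tested against it
    if not terms_a or not terms_b:
        return "unannotated"
    if terms_a == terms_b:
        return "A_conserved"
    if terms_a & terms_b:
        return "B_subfunctionalized"
    return "C_neofunctionalized"


class _TermEvolver:
    """Derives descendant term sets per intended family class; fresh terms
    come from a private namespace so class-C sets stay disjoint."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self._fresh = 0

    def fresh_term(self) -> str:
        self._fresh += 1
        return f"IPRN{self._fresh:06d}"

    def derive(self, terms: frozenset[str], family_class: str) -> frozenset[str]:
        if family_class == "unannotated":
            return frozenset()
        if family_class == "A":
            return terms
        if family_class == "B":
            ordered = sorted(terms)
            keep = set(ordered)
            others = ordered[1:]  # ordered[0] is the always-kept core term
            if others and self.rng.random() < 0.5:
                keep.discard(others[int(self.rng.integers(len(others)))])
            keep.add(self.fresh_term())
            return frozenset(keep)
        if family_class == "C":
            return frozenset(self.fresh_term() for _ in terms)
        raise ValidationError(f"unknown family class {family_class!r}")


@dataclass
class _Family:
    fam: int
    group: int             # homology group (pre-WGD sibs share one)
    chrom_idx: int
    anc_seq: list[str]
    anc_terms: frozenset[str]
    family_class: str = "A"
    omega: float = 0.15
    status: str = "co_retained"   # co_retained | only_sub1 | only_sub2 | lost
    ref_gene: str = ""
    pre_array: int = -1           # index of planted pre-WGD array, or -1


@dataclass
class _DescGene:
    gene_id: str
    family: int
    subgenome: str
    chrom: str
    seq: list[str]
    terms: frozenset[str]
    array: str | None = None


@dataclass
class SyntheticDataset:
    params: EvolutionParams
    ref_index: GeneIndex
    desc_index: GeneIndex
    ref_cds: dict[str, str]
    desc_cds: dict[str, str]
    ref_terms: TermAnnotation
    desc_terms: TermAnnotation
    hits: list[HomologHit]
    hit_rows: list[tuple]
    ground_truth: dict

    @property
    def ref_protein(self) -> dict[str, str]:
        return {g: translate_cds(s) for g, s in self.ref_cds.items()}

    @property
    def desc_protein(self) -> dict[str, str]:
        return {g: translate_cds(s) for g, s in self.desc_cds.items()}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref_gff": out / "ref.gff3",
            "desc_gff": out / "desc.gff3",
            "ref_cds": out / "ref.cds.fasta",
            "desc_cds": out / "desc.cds.fasta",
            "ref_protein": out / "ref.protein.fasta",
            "desc_protein": out / "desc.protein.fasta",
            "ref_terms": out / "ref.terms.tsv",
            "desc_terms": out / "desc.terms.tsv",
            "hits": out / "hits.tsv",
            "ground_truth": out / "ground_truth.json",
        }
        write_gff3(self.ref_index, paths["ref_gff"])
        write_gff3(self.desc_index, paths["desc_gff"])
        write_fasta(self.ref_cds, paths["ref_cds"])
        write_fasta(self.desc_cds, paths["desc_cds"])
        write_fasta(self.ref_protein, paths["ref_protein"])
        write_fasta(self.desc_protein, paths["desc_protein"])
        write_term_table(self.ref_terms, paths["ref_terms"])
        write_term_table(self.desc_terms, paths["desc_terms"])
        with open(paths["hits"], "w") as fh:
            for row in self.hit_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, sort_keys=True, indent=1)
            fh.write("\n")
        return paths


def _pair_key(a: str, b: str) -> str:
    x, y = sorted((a, b))
    return f"{x}|{y}"


def simulate(params: EvolutionParams) -> SyntheticDataset:  # noqa: C901
    """Run the full simulation; all randomness flows from ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    termev = _TermEvolver(rng)
    L = params.gene_length_codons
    n_chrom = params.n_chromosomes

    class_labels = sorted(params.class_proportions)
    class_p = np.array([params.class_proportions[c] for c in class_labels])

    # ------------------------------------------------------------- ancestor
    per_chrom = [params.n_ref_genes // n_chrom] * n_chrom
    for i in range(params.n_ref_genes % n_chrom):
        per_chrom[i] += 1
    families: list[_Family] = []
    chrom_loci: list[list[int]] = []  # ancestral order of family ids per chrom
    vocab = [f"IPR{i + 1:06d}" for i in range(params.term_vocab_size)]
    fam_counter = 0
    for ci in range(n_chrom):
        loci = []
        for _ in range(per_chrom[ci]):
            seq = [
                _SENSE_CODONS[int(k)]
                for k in rng.integers(len(_SENSE_CODONS), size=L)
            ]
            lo, hi = params.terms_per_gene
            k = int(rng.integers(lo, hi + 1))
            terms = frozenset(
                vocab[int(i)] for i in rng.choice(params.term_vocab_size,
                                                  size=k, replace=False))
            families.append(_Family(fam_counter, fam_counter, ci, seq, terms))
            loci.append(fam_counter)
            fam_counter += 1
        chrom_loci.append(loci)

    # ----------------------------------------- pre-speciation tandem arrays
    n_pre = int(round(params.frac_tandem_pre_wgd * params.n_tandem_arrays))
    pre_sources: list[int] = []
    occupied: set[int] = set()
    order = rng.permutation(len(families))
    for idx in order:
        if len(pre_sources) == n_pre:
            break
        fam = families[int(idx)].fam
        if fam in occupied:
            continue
        pre_sources.append(fam)
        occupied.update((fam - 1, fam, fam + 1))
    pre_arrays: list[dict] = []
    for ai, src_fam in enumerate(sorted(pre_sources)):
        src = families[src_fam]
        sib_seq = _evolve_branch(src.anc_seq, params.ks_pre_tandem,
                                 params.omega_by_class["A"], rng)
        sib = _Family(fam_counter, src.group, src.chrom_idx, sib_seq,
                      src.anc_terms)
        families.append(sib)
        loci = chrom_loci[src.chrom_idx]
        loci.insert(loci.index(src_fam) + 1, sib.fam)
        side = "subgenome1" if rng.random() < 0.5 else "subgenome2"
        src.pre_array = sib.pre_array = ai
        src.status = sib.status = \
            "only_sub1" if side == "subgenome1" else "only_sub2"
        pre_arrays.append({"subgenome": side,
                           "families": [src.fam, sib.fam]})
        fam_counter += 1

    # ---------------------------------- family classes and retention status
    p_co, p_loss = params.retention_prob, params.loss_prob
    p_rest = 1.0 - p_co - p_loss
    status_labels = ["co_retained", "lost", "only_sub1", "only_sub2"]
    status_p = np.array([p_co, p_loss, p_rest * params.sub1_bias,
                         p_rest * (1 - params.sub1_bias)])
    for fam in families:
        fam.family_class = class_labels[
            int(rng.choice(len(class_labels), p=class_p))]
        fam.omega = params.omega_by_class.get(fam.family_class,
                                              params.omega_by_class["A"])
        if fam.pre_array < 0:
            fam.status = status_labels[
                int(rng.choice(len(status_labels), p=status_p))]

    # --------------------------------------------------- reference genome
    ref_cds: dict[str, str] = {}
    ref_terms_map: dict[str, frozenset] = {}
    ref_genes: list[Gene] = []
    ref_seq_by_fam: dict[int, list[str]] = {}
    gid = 0
    spacing = 3 * L + params.intergenic_bp
    for ci in range(n_chrom):
        chrom = f"V{ci + 1:02d}"
        for pos, fam_id in enumerate(chrom_loci[ci]):
            fam = families[fam_id]
            gid += 1
            gene_id = f"REFg{gid:05d}"
            fam.ref_gene = gene_id
            seq = _evolve_branch(fam.anc_seq, params.ks_speciation / 2,
                                 fam.omega, rng)
            ref_seq_by_fam[fam_id] = seq
            start = 1 + pos * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            ref_genes.append(Gene(gene_id, chrom, start, start + 3 * L - 1,
                                  strand))
            ref_cds[gene_id] = "".join(seq)
            ref_terms_map[gene_id] = fam.anc_terms
    ref_chrom_lengths = {f"V{ci + 1:02d}": len(chrom_loci[ci]) * spacing
                         for ci in range(n_chrom)}
    ref_index = GeneIndex("reference", ref_genes, ref_chrom_lengths)

    # --------------------------------------- descendant: WGD + fractionation
    stem_ks = (params.ks_speciation - params.ks_wgd) / 2
    copy_ks = params.ks_wgd / 2
    retained: dict[tuple[int, str], bool] = {}
    for fam in families:
        retained[(fam.fam, "subgenome1")] = fam.status in ("co_retained",
                                                           "only_sub1")
        retained[(fam.fam, "subgenome2")] = fam.status in ("co_retained",
                                                           "only_sub2")

    # choose post-WGD tandem hosts among retained copy slots
    slots = [(fam.fam, sub) for fam in families
             for sub in ("subgenome1", "subgenome2")
             if retained[(fam.fam, sub)] and fam.pre_array < 0]
    n_post = params.n_tandem_arrays - n_pre
    host_idx = rng.choice(len(slots), size=min(n_post, len(slots)),
                          replace=False)
    sizes = sorted(params.array_size_weights)
    size_p = np.array([params.array_size_weights[s] for s in sizes],
                      dtype=float)
    size_p /= size_p.sum()
    ks_td_cap = 0.9 * params.ks_wgd
    post_hosts: dict[tuple[int, str], dict] = {}
    for hi in sorted(int(i) for i in host_idx):
        size = int(sizes[int(rng.choice(len(sizes), p=size_p))])
        ks_td = float(np.clip(rng.normal(params.ks_tandem_mean,
                                         params.ks_tandem_sd),
                              0.05, ks_td_cap))
        post_hosts[slots[hi]] = {"size": size, "ks": ks_td}

    # evolve the shared (speciation -> WGD) stem once per retained family
    pre_wgd_seq: dict[int, list[str]] = {}
    for fam in families:
        if retained[(fam.fam, "subgenome1")] or retained[(fam.fam, "subgenome2")]:
            pre_wgd_seq[fam.fam] = _evolve_branch(fam.anc_seq, stem_ks,
                                                  fam.omega, rng)

    desc_genes_meta: list[_DescGene] = []
    desc_order: dict[str, list[_DescGene]] = {}
    dgid = 0
    arrays_truth: list[dict] = []
    pre_array_members: dict[int, list[str]] = {ai: [] for ai in
                                               range(len(pre_arrays))}

    def new_desc_gene(fam: _Family, sub: str, chrom: str, seq: list[str],
                      array: str | None) -> _DescGene:
        nonlocal dgid
        dgid += 1
        terms = termev.derive(fam.anc_terms, fam.family_class)
        g = _DescGene(f"DESg{dgid:05d}", fam.fam, sub, chrom, seq, terms,
                      array)
        desc_genes_meta.append(g)
        desc_order.setdefault(chrom, []).append(g)
        return g

    array_counter = 0
    for sub_i, sub in enumerate(("subgenome1", "subgenome2")):
        for ci in range(n_chrom):
            chrom = f"S{ci + 1 + sub_i * n_chrom:02d}"
            for fam_id in chrom_loci[ci]:
                fam = families[fam_id]
                if not retained[(fam_id, sub)]:
                    continue
                pre_seq = pre_wgd_seq[fam_id]
                host = post_hosts.get((fam_id, sub))
                if host is None:
                    seq = _evolve_branch(pre_seq, copy_ks, fam.omega, rng)
                    g = new_desc_gene(fam, sub, chrom, seq, None)
                    if fam.pre_array >= 0:
                        pre_array_members[fam.pre_array].append(g.gene_id)
                else:
                    array_counter += 1
                    aid = f"PT{array_counter:04d}"
                    shared = _evolve_branch(pre_seq, copy_ks - host["ks"] / 2,
                                            fam.omega, rng)
                    members = []
                    for _ in range(host["size"]):
                        seq = _evolve_branch(shared, host["ks"] / 2,
                                             fam.omega, rng)
                        members.append(new_desc_gene(fam, sub, chrom, seq, aid))
                    arrays_truth.append({
                        "id": aid, "chromosome": chrom, "subgenome": sub,
                        "timing": "post_wgd", "ks": host["ks"],
                        "members": [m.gene_id for m in members],
                        "family": fam_id,
                    })

    for ai, pre in enumerate(pre_arrays):
        members = pre_array_members[ai]
        array_counter += 1
        aid = f"PT{array_counter:04d}"
        for g in desc_genes_meta:
            if g.gene_id in members:
                g.array = aid
        arrays_truth.append({
            "id": aid,
            "chromosome": next(g.chrom for g in desc_genes_meta
                               if g.gene_id == members[0]),
            "subgenome": pre["subgenome"], "timing": "pre_wgd",
            "ks": params.ks_pre_tandem + params.ks_speciation,
            "members": members, "family": pre["families"][0],
        })
    arrays_truth.sort(key=lambda a: a["id"])

    # optional rearrangement stress: random order inversions per chromosome
    if params.n_inversions > 0:
        for chrom in sorted(desc_order):
            genes = desc_order[chrom]
            for _ in range(params.n_inversions):
                if len(genes) < 2:
                    break
                i, j = sorted(int(x) for x in
                              rng.integers(len(genes), size=2))
                genes[i:j + 1] = genes[i:j + 1][::-1]

    desc_cds: dict[str, str] = {}
    desc_terms_map: dict[str, frozenset] = {}
    desc_genes: list[Gene] = []
    desc_chrom_lengths: dict[str, int] = {}
    for ci in range(2 * n_chrom):
        chrom = f"S{ci + 1:02d}"
        genes = desc_order.get(chrom, [])
        for pos, g in enumerate(genes):
            start = 1 + pos * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            desc_genes.append(Gene(g.gene_id, chrom, start,
                                   start + 3 * L - 1, strand))
            desc_cds[g.gene_id] = "".join(g.seq)
            if g.terms:
                desc_terms_map[g.gene_id] = g.terms
        desc_chrom_lengths[chrom] = max(1, len(genes) * spacing)
    desc_index = GeneIndex("descendant", desc_genes, desc_chrom_lengths)

    # -------------------------------------------------------------- hits
    groups: dict[int, list[tuple[str, str]]] = {}  # group -> (gene_id, kind)
    fam_by_id = {f.fam: f for f in families}
    for fam in families:
        groups.setdefault(fam.group, []).append((fam.ref_gene, "ref"))
    for g in desc_genes_meta:
        groups.setdefault(fam_by_id[g.family].group, []).append(
            (g.gene_id, "desc"))
    all_seqs = dict(ref_cds)
    all_seqs.update(desc_cds)
    hit_rows: list[tuple] = []
    hits: list[HomologHit] = []
    for group in sorted(groups):
        members = sorted(groups[group])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i][0], members[j][0]
                sa, sb = all_seqs[a], all_seqs[b]
                ident = sum(x == y for x, y in zip(sa, sb)) / len(sa)
                bitscore = round(2.0 * ident * L, 1)
                row = (a, b, round(100 * ident, 2), L, 0, 0, 1, L, 1, L,
                       "1e-50", bitscore)
                hit_rows.append(row)
                hits.append(HomologHit(a, b, 1e-50, bitscore))

    # ------------------------------------------------------- ground truth
    pair_classes: dict[str, str] = {}
    pair_rates: dict[str, dict[str, float]] = {}
    term_of = dict(ref_terms_map)
    for g in desc_genes_meta:
        term_of[g.gene_id] = g.terms

    def planted_ks(a_kind, a_meta, b_kind, b_meta) -> float:
        # a/b: ("ref", family) or ("desc", _DescGene)
        if a_kind == "ref" and b_kind == "ref":
            # pre-WGD sib loci: ancestral divergence plus both ref branches
            return params.ks_pre_tandem + params.ks_speciation
        if a_kind != b_kind:
            fa = a_meta if a_kind == "ref" else b_meta
            dg = b_meta if a_kind == "ref" else a_meta
            same_family = fa.fam == dg.family
            return params.ks_speciation if same_family else \
                params.ks_speciation + params.ks_pre_tandem
        ga, gb = a_meta, b_meta
        if ga.family != gb.family:  # descendant copies of pre-WGD sib loci
            return params.ks_pre_tandem + params.ks_speciation
        if ga.subgenome != gb.subgenome:
            return params.ks_wgd
        # same family, same subgenome -> post-WGD tandem siblings
        arr = next(x for x in arrays_truth if x["id"] == ga.array)
        return arr["ks"]

    meta_of: dict[str, tuple] = {}
    for fam in families:
        meta_of[fam.ref_gene] = ("ref", fam)
    for g in desc_genes_meta:
        meta_of[g.gene_id] = ("desc", g)
    for group in sorted(groups):
        members = sorted(groups[group])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i][0], members[j][0]
                key = _pair_key(a, b)
                pair_classes[key] = _intended_class(term_of[a], term_of[b])
                ka, ma = meta_of[a]
                kb, mb = meta_of[b]
                fam = ma if ka == "ref" else fam_by_id[ma.family]
                pair_rates[key] = {"ks": planted_ks(ka, ma, kb, mb),
                                   "omega": fam.omega}

    ground_truth = {
        "seed": params.seed,
        "families": {
            str(f.fam): {
                "ref_gene": f.ref_gene,
                "class": f.family_class,
                "omega": f.omega,
                "status": f.status,
                "group": f.group,
            } for f in families
        },
        "desc_lineage": {
            g.gene_id: {
                "family": g.family,
                "ref_gene": fam_by_id[g.family].ref_gene,
                "subgenome": g.subgenome,
                "array": g.array,
            } for g in desc_genes_meta
        },
        "arrays": arrays_truth,
        "pair_classes": pair_classes,
        "pair_rates": pair_rates,
    }

    return SyntheticDataset(
        params=params,
        ref_index=ref_index,
        desc_index=desc_index,
        ref_cds=ref_cds,
        desc_cds=desc_cds,
        ref_terms=TermAnnotation(ref_terms_map),
        desc_terms=TermAnnotation(desc_terms_map),
        hits=hits,
        hit_rows=hit_rows,
        ground_truth=ground_truth,
    )
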