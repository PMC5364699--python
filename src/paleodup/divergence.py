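"""Annotation-term based functional-divergence classification.

A pair of term sets maps to one of four classes: conserved (identical sets),
sub-functionalized (partial overlap), neo-functionalized (both annotated but
disjoint) or unannotated (either set empty).  A pair with exactly one
annotated member is treated as unannotated, not neo-functionalized:
divergence is undefined against an empty set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .duplication import GenePair
from .genome_io import GeneIndex, TermAnnotation, ValidationError

__all__ = [
    "DivergenceClass",
    "DivergenceSummary",
    "TermOverlap",
    "FamilyAttribution",
    "classify_pair",
    "classify_pairs",
    "summarize_divergence",
    "term_overlap",
    "attribute_family",
]


class DivergenceClass(str, Enum):
    A_CONSERVED = "A_conserved"
    B_SUBFUNCTIONALIZED = "B_subfunctionalized"
    C_NEOFUNCTIONALIZED = "C_neofunctionalized"
    UNANNOTATED = "unannotated"


def classify_pair(terms_a: frozenset[str] | set[str],
                  terms_b: frozenset[str] | set[str]) -> DivergenceClass:
    if not terms_a or not terms_b:
        return DivergenceClass.UNANNOTATED
    sa, sb = set(terms_a), set(terms_b)
    if sa == sb:
        return DivergenceClass.A_CONSERVED
    if sa & sb:
        return DivergenceClass.B_SUBFUNCTIONALIZED
    return DivergenceClass.C_NEOFUNCTIONALIZED


def classify_pairs(pairs: list[GenePair], annotation: TermAnnotation
                   ) -> dict[tuple[str, str], DivergenceClass]:
    return {
        p.key(): classify_pair(annotation.terms_for(p.gene_a),
                               annotation.terms_for(p.gene_b))
        for p in pairs
    }


@dataclass
class DivergenceSummary:
    """Per-pair-class counts with percentages on both bases (of total pairs
    and of annotated pairs), each reported to one decimal."""

    pair_class: str
    total_pairs: int
    n_unannotated: int
    n_A: int
    n_B: int
    n_C: int

    @property
    def n_annotated(self) -> int:
        return self.total_pairs - self.n_unannotated

    def pct_of_total(self, n: int, ndigits: int = 1) -> float:
        return round(100.0 * n / self.total_pairs, ndigits) \
            if self.total_pairs else 0.0

    def pct_of_annotated(self, n: int, ndigits: int = 1) -> float:
        return round(100.0 * n / self.n_annotated, ndigits) \
            if self.n_annotated else 0.0

    def check(self) -> None:
        if self.n_A + self.n_B + self.n_C + self.n_unannotated != self.total_pairs:
            raise ValidationError("divergence class counts do not partition pairs")


def summarize_divergence(pairs: list[GenePair], annotation: TermAnnotation
                         ) -> dict[str, DivergenceSummary]:
    """Counts and percentages per pair type (ortholog / wgd / tandem ...)."""
    buckets: dict[str, list[GenePair]] = {}
    for p in pairs:
        buckets.setdefault(p.pair_type, []).append(p)
        if p.pair_type == "ortholog":
            # orthologs are additionally summarized per subgenome
            buckets.setdefault(f"ortholog:{p.context}", []).append(p)
    out = {}
    for label in sorted(buckets):
        counts = {c: 0 for c in DivergenceClass}
        for p in buckets[label]:
            counts[classify_pair(annotation.terms_for(p.gene_a),
                                 annotation.terms_for(p.gene_b))] += 1
        summary = DivergenceSummary(
            pair_class=label,
            total_pairs=len(buckets[label]),
            n_unannotated=counts[DivergenceClass.UNANNOTATED],
            n_A=counts[DivergenceClass.A_CONSERVED],
            n_B=counts[DivergenceClass.B_SUBFUNCTIONALIZED],
            n_C=counts[DivergenceClass.C_NEOFUNCTIONALIZED],
        )
        summary.check()
        out[label] = summary
    return out


@dataclass
class TermOverlap:
    """Venn partition of the terms observed in two gene groups."""

    terms_only_a: frozenset[str]
    terms_shared: frozenset[str]
    terms_only_b: frozenset[str]
    genes_annotated_a: int
    genes_annotated_b: int
    n_genes_a: int
    n_genes_b: int

    @property
    def proportion_annotated_a(self) -> float:
        return self.genes_annotated_a / self.n_genes_a if self.n_genes_a else 0.0

    @property
    def proportion_annotated_b(self) -> float:
        return self.genes_annotated_b / self.n_genes_b if self.n_genes_b else 0.0


def term_overlap(genes_a: set[str], genes_b: set[str],
                 annotation: TermAnnotation) -> TermOverlap:
    ta: set[str] = set()
    tb: set[str] = set()
    ann_a = ann_b = 0
    for g in genes_a:
        terms = annotation.terms_for(g)
        if terms:
            ann_a += 1
            ta |= terms
    for g in genes_b:
        terms = annotation.terms_for(g)
        if terms:
            ann_b += 1
            tb |= terms
    return TermOverlap(
        terms_only_a=frozenset(ta - tb),
        terms_shared=frozenset(ta & tb),
        terms_only_b=frozenset(tb - ta),
        genes_annotated_a=ann_a,
        genes_annotated_b=ann_b,
        n_genes_a=len(genes_a),
        n_genes_b=len(genes_b),
    )


@dataclass
class FamilyAttribution:
    """How many members of a term-defined gene family trace to WGD duplicate
    pairs versus tandem arrays."""

    family: str
    defining_terms: frozenset[str]
    n_total: int
    n_from_wgd: int
    n_from_td: int
    member_gene_ids: list[str] = field(default_factory=list)


def attribute_family(family: str, family_terms: set[str],
                     annotation: TermAnnotation, wgd_genes: set[str],
                     td_genes: set[str], all_genes: GeneIndex
                     ) -> FamilyAttribution:
    if not family_terms:
        raise ValidationError("family must be defined by at least one term")
    members = [gid for gid in sorted(all_genes.genes)
               if annotation.terms_for(gid) & family_terms]
    return FamilyAttribution(
        family=family,
        defining_terms=frozenset(family_terms),
        n_total=len(members),
        n_from_wgd=sum(1 for g in members if g in wgd_genes),
        n_from_td=sum(1 for g in members if g in td_genes),
        member_gene_ids=members,
    )
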