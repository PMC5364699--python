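"""Gene-pair derivation: syntenic orthologs, WGD duplicates, tandem paralogs,
plus fractionation accounting and pre-/post-WGD dating of tandem arrays."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .genome_io import GeneIndex, HomologHit
from .synteny import SUB1, SUB2, SubgenomeAssignment, SyntenyBlock, UNASSIGNED

__all__ = [
    "GenePair",
    "FractionationResult",
    "TandemArray",
    "TandemDating",
    "orthologs_from_blocks",
    "wgd_pairs",
    "fractionation_summary",
    "detect_tandem_arrays",
    "expand_array_pairs",
    "date_tandem_arrays",
]

ORTHOLOG = "ortholog"
WGD_DUPLICATE = "wgd_duplicate"
TANDEM_PARALOG = "tandem_paralog"


@dataclass(frozen=True)
class GenePair:
    """A typed gene pair; ``gene_a < gene_b`` lexicographically.

    ``context`` holds the subgenome label for orthologs, the shared
    reference gene id for WGD duplicates, and the array id for tandem
    paralogs.  ``ref_gene``/``desc_gene`` keep the reference/descendant
    orientation of ortholog pairs (canonical ordering loses it); ``score``
    carries the anchor bitscore where applicable.
    """

    gene_a: str
    gene_b: str
    pair_type: str
    context: str = ""
    ref_gene: str = ""
    desc_gene: str = ""
    score: float = 0.0

    @staticmethod
    def make(x: str, y: str, pair_type: str, context: str = "",
             ref_gene: str = "", desc_gene: str = "",
             score: float = 0.0) -> "GenePair":
        a, b = sorted((x, y))
        return GenePair(a, b, pair_type, context, ref_gene, desc_gene, score)

    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def orthologs_from_blocks(assignment: SubgenomeAssignment,
                          blocks: list[SyntenyBlock] | None = None
                          ) -> list[GenePair]:
    """One ortholog pair per anchor in an assigned block, labeled with its
    subgenome.  Unassigned blocks contribute nothing; a reference gene may
    yield one pair per subgenome."""
    blocks = assignment.blocks if blocks is None else blocks
    pairs: list[GenePair] = []
    seen: set[tuple[str, str]] = set()
    for b in blocks:
        label = assignment.label(b.block_id)
        if label == UNASSIGNED:
            continue
        for a in b.anchors:
            key = (a.ref_gene_id, a.desc_gene_id)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(GenePair.make(
                a.ref_gene_id, a.desc_gene_id, ORTHOLOG, context=label,
                ref_gene=a.ref_gene_id, desc_gene=a.desc_gene_id,
                score=a.score))
    pairs.sort(key=GenePair.key)
    return pairs


def _best_partner_by_subgenome(orthologs: list[GenePair]
                               ) -> dict[str, dict[str, GenePair]]:
    """ref gene -> subgenome -> best-scoring ortholog pair."""
    out: dict[str, dict[str, GenePair]] = {}
    for p in orthologs:
        if p.pair_type != ORTHOLOG:
            continue
        slot = out.setdefault(p.ref_gene, {})
        prev = slot.get(p.context)
        # higher score wins; ties go to the lexicographically smaller id
        if prev is None or p.score > prev.score or (
                p.score == prev.score and p.desc_gene < prev.desc_gene):
            slot[p.context] = p
    return out


def wgd_pairs(orthologs: list[GenePair]) -> list[GenePair]:
    """Descendant-descendant pairs for reference genes retained in both
    subgenomes (context = the shared reference gene id)."""
    by_ref = _best_partner_by_subgenome(orthologs)
    pairs = []
    for ref_gene in sorted(by_ref):
        slot = by_ref[ref_gene]
        if SUB1 in slot and SUB2 in slot:
            pairs.append(GenePair.make(
                slot[SUB1].desc_gene, slot[SUB2].desc_gene,
                WGD_DUPLICATE, context=ref_gene))
    return pairs


@dataclass
class FractionationResult:
    """Retention/fractionation accounting over reference genes.

    Identities: ``fractionated = retained_sub1 + retained_sub2 - 2*co_retained``
    and ``distinct_ref_genes = retained_sub1 + retained_sub2 - co_retained``.
    """

    retained_sub1: int
    retained_sub2: int
    co_retained: int
    status: dict[str, str] = field(default_factory=dict)

    @property
    def fractionated(self) -> int:
        return self.retained_sub1 + self.retained_sub2 - 2 * self.co_retained

    @property
    def distinct_ref_genes(self) -> int:
        return self.retained_sub1 + self.retained_sub2 - self.co_retained

    @property
    def pct_fractionated(self) -> float:
        if self.distinct_ref_genes == 0:
            return 0.0
        return 100.0 * self.fractionated / self.distinct_ref_genes


def fractionation_summary(orthologs: list[GenePair]) -> FractionationResult:
    """Per-reference-gene retention status derived from subgenome-labeled
    ortholog pairs."""
    subs_by_ref: dict[str, set[str]] = {}
    for p in orthologs:
        if p.pair_type != ORTHOLOG:
            continue
        subs_by_ref.setdefault(p.ref_gene, set()).add(p.context)
    status = {}
    r1 = r2 = co = 0
    for ref_gene in sorted(subs_by_ref):
        subs = subs_by_ref[ref_gene]
        if SUB1 in subs and SUB2 in subs:
            status[ref_gene] = "co_retained"
            co += 1
            r1 += 1
            r2 += 1
        elif SUB1 in subs:
            status[ref_gene] = "only_sub1"
            r1 += 1
        elif SUB2 in subs:
            status[ref_gene] = "only_sub2"
            r2 += 1
    return FractionationResult(r1, r2, co, status)


@dataclass
class TandemArray:
    """A run of near-adjacent homologous genes on one chromosome."""

    array_id: str
    chromosome: str
    member_gene_ids: list[str]  # rank-ordered
    max_intervening: int

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def detect_tandem_arrays(desc: GeneIndex, hits: list[HomologHit],
                         max_intervening: int = 1) -> list[TandemArray]:
    """Arrays as connected components of the same-chromosome homology graph
    restricted to rank distance <= max_intervening + 1 (singletons dropped)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for h in hits:
        q, s = h.query_id, h.subject_id
        if q not in desc or s not in desc or q == s:
            continue
        gq, gs = desc[q], desc[s]
        if gq.chromosome != gs.chromosome:
            continue
        if abs(gq.rank - gs.rank) > max_intervening + 1:
            continue
        parent.setdefault(q, q)
        parent.setdefault(s, s)
        union(q, s)

    components: dict[str, list[str]] = {}
    for gid in parent:
        components.setdefault(find(gid), []).append(gid)

    arrays = []
    for members in components.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda gid: desc[gid].rank)
        arrays.append(TandemArray("", desc[members[0]].chromosome,
                                  members, max_intervening))
    arrays.sort(key=lambda a: (a.chromosome, desc[a.member_gene_ids[0]].rank))
    for i, a in enumerate(arrays, start=1):
        a.array_id = f"TA{i:04d}"
    return arrays


def expand_array_pairs(array: TandemArray) -> list[GenePair]:
    """All C(n, 2) unordered member pairs of one array."""
    return [GenePair.make(x, y, TANDEM_PARALOG, context=array.array_id)
            for x, y in combinations(array.member_gene_ids, 2)]


@dataclass
class TandemDating:
    """Per-array pre-/post-WGD call plus the derived counts.

    An array is ``pre_wgd`` only if every member is a descendant anchor gene
    of an assigned syntenic block (i.e. the array follows the ancestral gene
    order); otherwise ``post_wgd``.
    """

    timing: dict[str, str]
    n_pre_arrays: int
    n_post_arrays: int
    n_pre_genes: int
    n_post_genes: int
    pre_by_subgenome: dict[str, int]  # subgenome -> number of pre-WGD arrays


def date_tandem_arrays(arrays: list[TandemArray],
                       orthologs: list[GenePair]) -> TandemDating:
    anchor_sub: dict[str, str] = {}
    for p in orthologs:
        if p.pair_type == ORTHOLOG:
            anchor_sub[p.desc_gene] = p.context
    timing: dict[str, str] = {}
    n_pre = n_post = genes_pre = genes_post = 0
    pre_by_sub: dict[str, int] = {SUB1: 0, SUB2: 0}
    for a in arrays:
        if a.member_gene_ids and all(m in anchor_sub for m in a.member_gene_ids):
            timing[a.array_id] = "pre_wgd"
            n_pre += 1
            genes_pre += a.size
            subs = {anchor_sub[m] for m in a.member_gene_ids}
            # arrays live on one chromosome, hence normally one subgenome
            lab = sorted(subs)[0]
            pre_by_sub[lab] = pre_by_sub.get(lab, 0) + 1
        else:
            timing[a.array_id] = "post_wgd"
            n_post += 1
            genes_post += a.size
    return TandemDating(timing, n_pre, n_post, genes_pre, genes_post, pre_by_sub)


def tandem_chromosome_summary(arrays: list[TandemArray],
                              desc: GeneIndex) -> dict[str, dict[str, float]]:
    """Per-chromosome tandem load: array count, tandem gene count and the
    percentage of that chromosome's genes that are tandem duplicated."""
    out: dict[str, dict[str, float]] = {}
    for chrom, genes in desc.by_chromosome.items():
        chrom_arrays = [a for a in arrays if a.chromosome == chrom]
        n_tandem = sum(a.size for a in chrom_arrays)
        out[chrom] = {
            "n_arrays": len(chrom_arrays),
            "n_tandem_genes": n_tandem,
            "n_genes": len(genes),
            "pct_tandem": 100.0 * n_tandem / len(genes) if genes else 0.0,
        }
    return out
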