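"""Collinear-block detection and subgenome partitioning.

Anchors (inter-genome homologous gene pairs) are chained per chromosome pair
by a maximal-score dynamic program in gene-rank space, then descendant blocks
that overlap the same reference region are split into two non-overlapping
subgenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GeneIndex, HomologHit, ValidationError

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "SubgenomeAssignment",
    "ChainParams",
    "CoverageSummary",
    "build_anchors",
    "chain_blocks",
    "partition_subgenomes",
    "block_stats",
]

SUB1 = "subgenome1"
SUB2 = "subgenome2"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Anchor:
    """An inter-genome homologous gene pair placed in rank space."""

    ref_gene_id: str
    desc_gene_id: str
    ref_chrom: str
    desc_chrom: str
    ref_rank: int
    desc_rank: int
    score: float  # bitscore of the underlying hit; tie-breaking only


@dataclass
class SyntenyBlock:
    block_id: str
    ref_chrom: str
    desc_chrom: str
    anchors: list[Anchor]
    orientation: str  # "same" | "inverted"
    chain_score: float
    ref_span_bp: int = 0
    desc_span_bp: int = 0

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def ref_rank_span(self) -> tuple[int, int]:
        ranks = [a.ref_rank for a in self.anchors]
        return (min(ranks), max(ranks))

    @property
    def desc_rank_span(self) -> tuple[int, int]:
        ranks = [a.desc_rank for a in self.anchors]
        return (min(ranks), max(ranks))


@dataclass
class ChainParams:
    """Anchor-chaining parameters.

    ``min_block_size`` is the minimum number of anchors per block and
    ``max_gap`` the largest allowed rank gap (in either genome) between
    consecutive chained anchors.  The chain score is
    ``n_anchors * match_score + sum(gap_penalty * (rank_gap - 1))`` where
    ``rank_gap`` is the larger of the two per-genome rank gaps, so adjacent
    anchors cost nothing.
    """

    max_evalue: float = 1e-20
    min_block_size: int = 15
    max_gap: int = 25
    gap_penalty: float = -1.0
    match_score: float = 1.0

    def __post_init__(self) -> None:
        if self.min_block_size < 2:
            raise ValidationError("min_block_size must be >= 2")
        if self.max_gap < 1:
            raise ValidationError("max_gap must be >= 1")


def build_anchors(hits: list[HomologHit], ref: GeneIndex,
                  desc: GeneIndex) -> list[Anchor]:
    """Turn inter-genome hits into anchors; intra-genome hits are skipped.

    A hit whose ids occur in neither genome raises a ``ValidationError``
    listing the offending ids.
    """
    anchors = []
    unknown: set[str] = set()
    for h in hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in ref and gid not in desc:
                unknown.add(gid)
        if unknown:
            continue
        if h.query_id in ref and h.subject_id in desc:
            rg, dg = ref[h.query_id], desc[h.subject_id]
        elif h.subject_id in ref and h.query_id in desc:
            rg, dg = ref[h.subject_id], desc[h.query_id]
        else:
            continue  # intra-genome
        anchors.append(Anchor(rg.gene_id, dg.gene_id, rg.chromosome,
                              dg.chromosome, rg.rank, dg.rank, h.bitscore))
    if unknown:
        raise ValidationError(
            "hits reference unknown gene ids: " + ", ".join(sorted(unknown)))
    anchors.sort(key=lambda a: (a.ref_chrom, a.desc_chrom, a.ref_rank,
                                a.desc_rank, a.desc_gene_id))
    return anchors


def _best_chain(anchors: list[Anchor], orientation: str,
                params: ChainParams) -> tuple[float, list[int]]:
    """Maximal-score monotone chain among ``anchors`` (sorted by rank).

    Returns ``(score, indices)``; empty chain when no anchor exists.
    Descendant ranks must be strictly increasing ("same") or strictly
    decreasing ("inverted"); reference ranks strictly increasing.
    """
    n = len(anchors)
    if n == 0:
        return (float("-inf"), [])
    sign = 1 if orientation == "same" else -1
    best = [params.match_score] * n
    prev = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            rgap = ai.ref_rank - aj.ref_rank
            dgap = sign * (ai.desc_rank - aj.desc_rank)
            if rgap < 1 or dgap < 1:
                continue
            if rgap > params.max_gap or dgap > params.max_gap:
                continue
            cand = best[j] + params.match_score \
                + params.gap_penalty * (max(rgap, dgap) - 1)
            if cand > best[i] + 1e-12:
                best[i] = cand
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -anchors[i].ref_rank))
    chain = []
    i = end
    while i != -1:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    return (best[end], chain)


def chain_blocks(anchors: list[Anchor], params: ChainParams,
                 ref: GeneIndex | None = None,
                 desc: GeneIndex | None = None) -> list[SyntenyBlock]:
    """Greedy maximal-score chain decomposition per chromosome pair.

    Chains are extracted by descending score (ties: more anchors, then
    orientation "same"); each anchor joins at most one block; chains shorter
    than ``min_block_size`` are discarded.  When gene indexes are supplied,
    bp spans are annotated on the blocks.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_chrom, a.desc_chrom), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (ref_chrom, desc_chrom) in sorted(groups):
        pool = sorted(groups[(ref_chrom, desc_chrom)],
                      key=lambda a: (a.ref_rank, a.desc_rank, a.desc_gene_id))
        while pool:
            candidates = []
            for orientation in ("same", "inverted"):
                score, idx = _best_chain(pool, orientation, params)
                if idx:
                    candidates.append((score, len(idx), orientation, idx))
            if not candidates:
                break
            # highest score, then longer, then "same" first
            candidates.sort(key=lambda c: (-c[0], -c[1], c[2] != "same"))
            score, length, orientation, idx = candidates[0]
            if length < params.min_block_size:
                break
            chosen = [pool[i] for i in idx]
            blocks.append(SyntenyBlock(
                block_id="", ref_chrom=ref_chrom, desc_chrom=desc_chrom,
                anchors=chosen, orientation=orientation, chain_score=score))
            taken = set(idx)
            pool = [a for i, a in enumerate(pool) if i not in taken]

    blocks.sort(key=lambda b: (b.ref_chrom, b.desc_chrom,
                               b.ref_rank_span[0], b.desc_rank_span[0]))
    for i, b in enumerate(blocks, start=1):
        b.block_id = f"SB{i:04d}"
        if ref is not None and desc is not None:
            rgenes = [ref[a.ref_gene_id] for a in b.anchors]
            dgenes = [desc[a.desc_gene_id] for a in b.anchors]
            b.ref_span_bp = max(g.end for g in rgenes) - min(g.start for g in rgenes) + 1
            b.desc_span_bp = max(g.end for g in dgenes) - min(g.start for g in dgenes) + 1
    return blocks


@dataclass
class SubgenomeAssignment:
    """Mapping block_id -> subgenome label, plus the blocks themselves."""

    labels: dict[str, str]
    blocks: list[SyntenyBlock]
    removed: set[str] = field(default_factory=set)  # curation-filter casualties

    def label(self, block_id: str) -> str:
        return self.labels.get(block_id, UNASSIGNED)

    def assigned_blocks(self, subgenome: str) -> list[SyntenyBlock]:
        return [b for b in self.blocks if self.labels.get(b.block_id) == subgenome]


def _overlaps(a: SyntenyBlock, b: SyntenyBlock) -> bool:
    if a.ref_chrom != b.ref_chrom:
        return False
    (a0, a1), (b0, b1) = a.ref_rank_span, b.ref_rank_span
    return a0 <= b1 and b0 <= a1


def partition_subgenomes(blocks: list[SyntenyBlock],
                         ref: GeneIndex) -> SubgenomeAssignment:
    """Partition blocks into two non-overlapping subgenomes.

    Blocks overlapping on reference gene-rank intervals are clustered; within
    a cluster blocks are taken by descending chain score and packed into two
    internally non-overlapping sets (leftovers stay unassigned).  Per-cluster
    labels are harmonized across clusters by descendant-chromosome majority
    vote, then globally relabeled so subgenome1 carries the larger total
    anchor count.  Unassigned blocks whose reference span overlaps a
    higher-scoring assigned block by more than half are recorded as removed
    (the automated stand-in for manual curation).
    """
    # -- cluster by reference overlap (union-find)
    parent = list(range(len(blocks)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if _overlaps(blocks[i], blocks[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(len(blocks)):
        clusters.setdefault(find(i), []).append(i)

    labels: dict[str, str] = {}
    chrom_votes: dict[str, dict[str, int]] = {}  # desc_chrom -> {label: anchors}

    def cluster_sort_key(members: list[int]) -> tuple:
        b = blocks[min(members, key=lambda i: (blocks[i].ref_chrom,
                                               blocks[i].ref_rank_span[0]))]
        return (b.ref_chrom, b.ref_rank_span[0])

    for members in sorted(clusters.values(), key=cluster_sort_key):
        ordered = sorted(members, key=lambda i: (-blocks[i].chain_score,
                                                 blocks[i].block_id))
        set_a: list[int] = []
        set_b: list[int] = []
        for i in ordered:
            if not any(_overlaps(blocks[i], blocks[j]) for j in set_a):
                set_a.append(i)
            elif not any(_overlaps(blocks[i], blocks[j]) for j in set_b):
                set_b.append(i)
            else:
                labels[blocks[i].block_id] = UNASSIGNED
        # cluster-local: best aggregate score first
        if sum(blocks[i].chain_score for i in set_b) > \
           sum(blocks[i].chain_score for i in set_a):
            set_a, set_b = set_b, set_a

        # harmonize with previously assigned clusters via descendant chromosomes
        def agreement(first: list[int], second: list[int]) -> int:
            score = 0
            for lab, grp in ((SUB1, first), (SUB2, second)):
                for i in grp:
                    votes = chrom_votes.get(blocks[i].desc_chrom, {})
                    score += votes.get(lab, 0) - sum(
                        v for k, v in votes.items() if k != lab)
            return score
        if agreement(set_b, set_a) > agreement(set_a, set_b):
            set_a, set_b = set_b, set_a
        for lab, grp in ((SUB1, set_a), (SUB2, set_b)):
            for i in grp:
                labels[blocks[i].block_id] = lab
                votes = chrom_votes.setdefault(blocks[i].desc_chrom, {})
                votes[lab] = votes.get(lab, 0) + blocks[i].n_anchors

    # -- global relabel: subgenome1 has the larger total anchor count
    totals = {SUB1: 0, SUB2: 0}
    for b in blocks:
        lab = labels.get(b.block_id, UNASSIGNED)
        if lab in totals:
            totals[lab] += b.n_anchors
    if totals[SUB2] > totals[SUB1]:
        flip = {SUB1: SUB2, SUB2: SUB1}
        labels = {bid: flip.get(lab, lab) for bid, lab in labels.items()}

    # -- curation stand-in: drop dominated unassigned blocks
    removed: set[str] = set()
    by_id = {b.block_id: b for b in blocks}
    for b in blocks:
        if labels.get(b.block_id) != UNASSIGNED:
            continue
        (b0, b1) = b.ref_rank_span
        span = b1 - b0 + 1
        for other in blocks:
            if other.block_id == b.block_id or other.chain_score <= b.chain_score:
                continue
            if labels.get(other.block_id) == UNASSIGNED:
                continue
            if not _overlaps(b, other):
                continue
            (o0, o1) = other.ref_rank_span
            overlap = min(b1, o1) - max(b0, o0) + 1
            if overlap > 0.5 * span:
                removed.add(b.block_id)
                break
    del by_id
    return SubgenomeAssignment(labels=labels, blocks=list(blocks), removed=removed)


@dataclass
class CoverageSummary:
    """Per-subgenome coverage statistics (Table-1 shaped)."""

    per_subgenome: dict[str, dict[str, float]]
    total_blocks: int
    total_span_bp: int
    total_genes_in_spans: int
    total_anchor_genes: int
    genome_length_bp: int
    genome_n_genes: int

    @property
    def pct_genome_length(self) -> float:
        return 100.0 * self.total_span_bp / self.genome_length_bp

    @property
    def pct_genome_genes(self) -> float:
        return 100.0 * self.total_genes_in_spans / self.genome_n_genes


def block_stats(assignment: SubgenomeAssignment,
                desc: GeneIndex) -> CoverageSummary:
    """Coverage per subgenome: block counts, descendant bp spans and gene
    counts (both genes-inside-spans and anchor genes are reported)."""
    if desc.total_length_bp <= 0:
        raise ValidationError("descendant genome has zero length")
    per: dict[str, dict[str, float]] = {}
    total_span = 0
    all_genes_in_spans: set[str] = set()
    all_anchor_genes: set[str] = set()
    n_blocks_total = 0
    for sub in (SUB1, SUB2):
        blocks = assignment.assigned_blocks(sub)
        span_bp = 0
        genes_in_spans: set[str] = set()
        anchor_genes: set[str] = set()
        for b in blocks:
            dgenes = [desc[a.desc_gene_id] for a in b.anchors]
            lo = min(g.start for g in dgenes)
            hi = max(g.end for g in dgenes)
            span_bp += hi - lo + 1
            for g in desc.by_chromosome.get(b.desc_chrom, []):
                if g.start >= lo and g.end <= hi:
                    genes_in_spans.add(g.gene_id)
            anchor_genes.update(g.gene_id for g in dgenes)
        per[sub] = {
            "n_blocks": len(blocks),
            "span_bp": span_bp,
            "n_genes_in_spans": len(genes_in_spans),
            "n_anchor_genes": len(anchor_genes),
            "pct_genome_length": 100.0 * span_bp / desc.total_length_bp,
            "pct_genome_genes": 100.0 * len(genes_in_spans) / desc.n_genes,
        }
        total_span += span_bp
        all_genes_in_spans |= genes_in_spans
        all_anchor_genes |= anchor_genes
        n_blocks_total += len(blocks)
    return CoverageSummary(
        per_subgenome=per,
        total_blocks=n_blocks_total,
        total_span_bp=total_span,
        total_genes_in_spans=len(all_genes_in_spans),
        total_anchor_genes=len(all_anchor_genes),
        genome_length_bp=desc.total_length_bp,
        genome_n_genes=desc.n_genes,
    )
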