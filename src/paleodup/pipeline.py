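"""End-to-end orchestration: one config in, publication-style summary tables out.

Stage order: genome loading -> synteny -> pair derivation (orthologs, WGD
duplicates, tandem paralogs) -> functional divergence -> selection (Ka/Ks)
-> Ks-peak dating.  Every run writes TSV/JSON outputs with fixed names under
the output directory and returns a :class:`RunReport` with per-stage record
counts and a parameter echo.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dating, divergence, duplication, selection, synteny
from .duplication import (GenePair, ORTHOLOG, TANDEM_PARALOG, WGD_DUPLICATE,
                          date_tandem_arrays, detect_tandem_arrays,
                          expand_array_pairs, fractionation_summary,
                          orthologs_from_blocks, tandem_chromosome_summary,
                          wgd_pairs)
from .genome_io import (GeneIndex, TermAnnotation, ValidationError,
                        read_fasta, read_gff3, read_hit_table,
                        read_term_table)
from .simulate import EvolutionParams, simulate
from .synteny import SUB1, SUB2, ChainParams

__all__ = ["PipelineConfig", "RunReport", "run", "summarize_tables"]


@dataclass
class PipelineConfig:
    """Either six real input paths or a simulate block — never both."""

    out_dir: Path
    inputs: dict[str, str] | None = None
    simulate: EvolutionParams | None = None
    chain: ChainParams = field(default_factory=ChainParams)
    max_intervening: int = 1
    min_identity: float = 0.3
    min_coverage: float = 0.5
    ks_max: float = 3.0
    bandwidth: str | float = "silverman"
    families: dict[str, list[str]] = field(default_factory=dict)
    run_selection: bool = True

    REQUIRED_INPUTS = ("ref_gff", "desc_gff", "ref_cds", "desc_cds",
                      "ref_terms", "desc_terms", "hits")

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValidationError(
                "config must provide exactly one of input paths or a "
                "simulate block")
        if self.inputs is not None:
            missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise ValidationError(
                    "missing input paths: " + ", ".join(missing))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs: dict = {"out_dir": Path(doc.get("out_dir", "paleodup_out"))}
        if "inputs" in doc:
            kwargs["inputs"] = {k: str(v) for k, v in doc["inputs"].items()}
        if "simulate" in doc:
            sim = doc["simulate"] or {}
            if "terms_per_gene" in sim:
                sim["terms_per_gene"] = tuple(sim["terms_per_gene"])
            kwargs["simulate"] = EvolutionParams(**sim)
        if "chain" in doc:
            kwargs["chain"] = ChainParams(**doc["chain"])
        for key in ("max_intervening", "min_identity", "min_coverage",
                    "ks_max", "bandwidth", "families", "run_selection"):
            if key in doc:
                kwargs[key] = doc[key]
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def echo(self) -> dict:
        doc = {
            "out_dir": str(self.out_dir),
            "chain": dataclasses.asdict(self.chain),
            "max_intervening": self.max_intervening,
            "min_identity": self.min_identity,
            "min_coverage": self.min_coverage,
            "ks_max": self.ks_max,
            "bandwidth": self.bandwidth,
            "families": self.families,
            "run_selection": self.run_selection,
        }
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["terms_per_gene"] = list(sim["terms_per_gene"])
            sim["array_size_weights"] = {
                str(k): v for k, v in sim["array_size_weights"].items()}
            doc["simulate"] = sim
        if self.inputs is not None:
            doc["inputs"] = dict(self.inputs)
        return doc


@dataclass
class RunReport:
    schema_version: int
    config: dict
    counts: dict[str, int]
    warnings: list[str]
    tables: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class StageOutputs:
    """In-memory results of a full run (what ``run`` writes to disk)."""

    ref: GeneIndex
    desc: GeneIndex
    annotation: TermAnnotation
    blocks: list
    assignment: synteny.SubgenomeAssignment
    coverage: synteny.CoverageSummary
    orthologs: list[GenePair]
    wgd: list[GenePair]
    tandem: list[GenePair]
    arrays: list
    fractionation: duplication.FractionationResult
    tandem_dating: duplication.TandemDating
    summaries: dict[str, divergence.DivergenceSummary]
    pair_classes: dict[tuple[str, str], divergence.DivergenceClass]
    kaks: list[selection.KaKsResult]
    exclusions: list
    comparisons: dict[str, selection.ClassComparison]
    peaks: list[dating.KsPeak]
    ordering: dating.EventOrdering | None
    report: RunReport


def _merge_annotations(a: TermAnnotation, b: TermAnnotation) -> TermAnnotation:
    merged = {g: set(t) for g, t in a.items()}
    for g, t in b.items():
        merged.setdefault(g, set()).update(t)
    return TermAnnotation(merged)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        ds = simulate(config.simulate)
        return (ds.ref_index, ds.desc_index, ds.ref_cds, ds.desc_cds,
                _merge_annotations(ds.ref_terms, ds.desc_terms), ds.hits)
    paths = config.inputs
    ref = read_gff3(paths["ref_gff"], "reference")
    desc = read_gff3(paths["desc_gff"], "descendant")
    ref_cds = read_fasta(paths["ref_cds"], "cds")
    desc_cds = read_fasta(paths["desc_cds"], "cds")
    annotation = _merge_annotations(read_term_table(paths["ref_terms"]),
                                    read_term_table(paths["desc_terms"]))
    hits = read_hit_table(paths["hits"], config.chain.max_evalue)
    cds = {**ref_cds.sequences, **desc_cds.sequences}
    invalid = {**ref_cds.invalid, **desc_cds.invalid}
    return ref, desc, cds, invalid, annotation, hits


def run(config: PipelineConfig, write: bool = True) -> StageOutputs:
    config.validate()
    warnings_log: list[str] = []
    out_dir = Path(config.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- stage: load / simulate
    if config.simulate is not None:
        ref, desc, ref_cds, desc_cds, annotation, hits = _load_inputs(config)
        cds = {**ref_cds, **desc_cds}
        invalid_cds: dict[str, str] = {}
    else:
        ref, desc, cds, invalid_cds, annotation, hits = _load_inputs(config)

    # ---- stage: synteny
    anchors = synteny.build_anchors(hits, ref, desc)
    blocks = synteny.chain_blocks(anchors, config.chain, ref, desc)
    assignment = synteny.partition_subgenomes(blocks, ref)
    coverage = synteny.block_stats(assignment, desc)

    # ---- stage: pair derivation
    orthologs = orthologs_from_blocks(assignment)
    wgd = wgd_pairs(orthologs)
    fractionation = fractionation_summary(orthologs)
    arrays = detect_tandem_arrays(desc, hits, config.max_intervening)
    tandem: list[GenePair] = []
    for arr in arrays:
        tandem.extend(expand_array_pairs(arr))
    tdating = date_tandem_arrays(arrays, orthologs)
    all_pairs = orthologs + wgd + tandem
    seen_types: dict[tuple[str, str], str] = {}
    for p in orthologs + wgd + tandem:
        if p.pair_type != ORTHOLOG and seen_types.get(p.key()) not in (
                None, p.pair_type):
            warnings_log.append(
                f"pair {p.key()} appears as both {seen_types[p.key()]} "
                f"and {p.pair_type}")
        seen_types[p.key()] = p.pair_type

    # ---- stage: divergence
    summaries = divergence.summarize_divergence(all_pairs, annotation)
    pair_classes = divergence.classify_pairs(all_pairs, annotation)

    wgd_genes = {g for p in wgd for g in (p.gene_a, p.gene_b)}
    td_genes = {g for a in arrays for g in a.member_gene_ids}
    single1 = {p.desc_gene for p in orthologs
               if fractionation.status.get(p.ref_gene) == "only_sub1"}
    single2 = {p.desc_gene for p in orthologs
               if fractionation.status.get(p.ref_gene) == "only_sub2"}
    venn_subgenomes = divergence.term_overlap(single1, single2, annotation)
    venn_events = divergence.term_overlap(wgd_genes, td_genes, annotation)
    family_rows = []
    for fam_label in sorted(config.families):
        fam = divergence.attribute_family(
            fam_label, set(config.families[fam_label]), annotation,
            wgd_genes, td_genes, desc)
        family_rows.append(fam)

    # ---- stage: selection
    kaks_results: list[selection.KaKsResult] = []
    exclusions: list[tuple[tuple[str, str], str]] = []
    comparisons: dict[str, selection.ClassComparison] = {}
    if config.run_selection:
        for p in all_pairs:
            key = p.key()
            bad = [g for g in key if g in invalid_cds or g not in cds]
            if bad:
                exclusions.append((key, "invalid_cds"))
                continue
            try:
                r = selection.compute_pair_kaks(p.gene_a, p.gene_b,
                                                cds[p.gene_a], cds[p.gene_b])
            except selection.PairExclusion as exc:
                exclusions.append((key, exc.reason))
                continue
            r.pair_type = p.pair_type if p.pair_type != ORTHOLOG \
                else f"{ORTHOLOG}:{p.context}"
            kaks_results.append(r)
        kaks_results, exclusions = selection.filter_pairs(
            kaks_results, config.min_identity, config.min_coverage,
            exclusions)
        class_map = {k: v.value for k, v in pair_classes.items()}
        for bucket in sorted({r.pair_type for r in kaks_results}):
            rs = [r for r in kaks_results if r.pair_type == bucket]
            sub_classes = {r.key(): class_map[r.key()] for r in rs
                           if class_map.get(r.key()) not in (None, "unannotated")}
            if len(set(sub_classes.values())) >= 2:
                comparisons[bucket] = selection.compare_classes(rs, sub_classes)

    # ---- stage: dating
    peaks: list[dating.KsPeak] = []
    ordering = None
    if config.run_selection:
        ks_by_class: dict[str, list[float]] = {}
        for r in kaks_results:
            if r.Ks is not None:
                ks_by_class.setdefault(r.pair_type, []).append(r.Ks)
        # pooled ortholog class for event ordering
        pooled = [v for lab, vs in ks_by_class.items()
                  if lab.startswith(ORTHOLOG) for v in vs]
        if pooled:
            ks_by_class[ORTHOLOG] = pooled
        for label in sorted(ks_by_class):
            try:
                dist = dating.ks_density(ks_by_class[label], label,
                                         config.ks_max, config.bandwidth)
            except ValidationError as exc:
                warnings_log.append(str(exc))
                continue
            peaks.append(dating.find_peaks(dist))
        event_peaks = [p for p in peaks if p.pair_class in
                       (ORTHOLOG, WGD_DUPLICATE, TANDEM_PARALOG)]
        if len(event_peaks) >= 2:
            ordering = dating.order_events(event_peaks)

    counts = {
        "ref_genes": ref.n_genes,
        "desc_genes": desc.n_genes,
        "hits": len(hits),
        "anchors": len(anchors),
        "blocks": len(blocks),
        "blocks_assigned": sum(1 for b in blocks
                               if assignment.label(b.block_id) != "unassigned"),
        "ortholog_pairs": len(orthologs),
        "wgd_pairs": len(wgd),
        "tandem_arrays": len(arrays),
        "tandem_pairs": len(tandem),
        "kaks_retained": len(kaks_results),
        "kaks_excluded": len(exclusions),
    }

    tables: dict[str, str] = {}
    if write:
        tables = _write_outputs(
            out_dir, ref, desc, blocks, assignment, coverage, all_pairs,
            pair_classes, annotation, summaries, fractionation, arrays,
            tdating, kaks_results, exclusions, comparisons, peaks, ordering,
            venn_subgenomes, venn_events, family_rows)
    report = RunReport(schema_version=1, config=config.echo(),
                       counts=counts, warnings=warnings_log, tables=tables)
    if write:
        report.to_json(out_dir / "report.json")
    return StageOutputs(ref, desc, annotation, blocks, assignment, coverage,
                        orthologs, wgd, tandem, arrays, fractionation,
                        tdating, summaries, pair_classes, kaks_results,
                        exclusions, comparisons, peaks, ordering, report)


def summarize_tables(out: StageOutputs) -> dict[str, pd.DataFrame]:
    """The four publication-style summary tables as DataFrames."""
    cov = out.coverage
    t1_rows = []
    for sub in (SUB1, SUB2):
        d = cov.per_subgenome[sub]
        t1_rows.append({
            "category": sub,
            "n_blocks": int(d["n_blocks"]),
            "genomic_length_mb": round(d["span_bp"] / 1e6, 2),
            "n_genes": int(d["n_genes_in_spans"]),
            "n_anchor_genes": int(d["n_anchor_genes"]),
        })
    t1_rows.append({
        "category": "total",
        "n_blocks": cov.total_blocks,
        "genomic_length_mb": round(cov.total_span_bp / 1e6, 2),
        "n_genes": cov.total_genes_in_spans,
        "n_anchor_genes": cov.total_anchor_genes,
    })
    t1_rows.append({
        "category": "genome",
        "n_blocks": "",
        "genomic_length_mb": round(cov.genome_length_bp / 1e6, 2),
        "n_genes": cov.genome_n_genes,
        "n_anchor_genes": "",
    })
    t1_rows.append({
        "category": "percentage",
        "n_blocks": "",
        "genomic_length_mb": round(cov.pct_genome_length, 2),
        "n_genes": round(cov.pct_genome_genes, 2),
        "n_anchor_genes": "",
    })
    table1 = pd.DataFrame(t1_rows)

    t2_rows = []
    for label, s in sorted(out.summaries.items()):
        t2_rows.append({
            "category": label,
            "total_pairs": s.total_pairs,
            "n_unannotated": s.n_unannotated,
            "n_conserved_A": s.n_A,
            "n_subfunctionalized_B": s.n_B,
            "n_neofunctionalized_C": s.n_C,
            "pct_A_of_total": s.pct_of_total(s.n_A),
            "pct_A_of_annotated": s.pct_of_annotated(s.n_A),
        })
    table2 = pd.DataFrame(t2_rows)

    f = out.fractionation
    table3 = pd.DataFrame([{
        "retained_sub1": f.retained_sub1,
        "retained_sub2": f.retained_sub2,
        "co_retained": f.co_retained,
        "fractionated": f.fractionated,
        "distinct_ref_genes": f.distinct_ref_genes,
        "pct_fractionated": round(f.pct_fractionated, 2),
    }])

    table4 = pd.DataFrame([])
    return {"table1": table1, "table2": table2, "table3": table3,
            "table4": table4}


def _write_outputs(out_dir, ref, desc, blocks, assignment, coverage,
                   all_pairs, pair_classes, annotation, summaries,
                   fractionation, arrays, tdating, kaks_results, exclusions,
                   comparisons, peaks, ordering, venn_subgenomes,
                   venn_events, family_rows) -> dict[str, str]:
    tables: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        tables[name.split(".")[0]] = str(path)

    save("blocks.tsv", pd.DataFrame([{
        "block_id": b.block_id, "ref_chrom": b.ref_chrom,
        "desc_chrom": b.desc_chrom, "orientation": b.orientation,
        "n_anchors": b.n_anchors, "chain_score": b.chain_score,
        "ref_rank_start": b.ref_rank_span[0],
        "ref_rank_end": b.ref_rank_span[1],
        "desc_rank_start": b.desc_rank_span[0],
        "desc_rank_end": b.desc_rank_span[1],
        "ref_span_bp": b.ref_span_bp, "desc_span_bp": b.desc_span_bp,
        "subgenome": assignment.label(b.block_id),
        "curation_removed": b.block_id in assignment.removed,
    } for b in blocks]))

    save("anchors.tsv", pd.DataFrame([{
        "block_id": b.block_id, "ref_gene": a.ref_gene_id,
        "desc_gene": a.desc_gene_id, "ref_rank": a.ref_rank,
        "desc_rank": a.desc_rank, "score": a.score,
    } for b in blocks for a in b.anchors]))

    save("pairs.tsv", pd.DataFrame([{
        "gene_a": p.gene_a, "gene_b": p.gene_b, "pair_type": p.pair_type,
        "context": p.context,
        "divergence_class": pair_classes[p.key()].value,
        "terms_a": ";".join(sorted(annotation.terms_for(p.gene_a))),
        "terms_b": ";".join(sorted(annotation.terms_for(p.gene_b))),
        "shared_terms": ";".join(sorted(annotation.terms_for(p.gene_a)
                                        & annotation.terms_for(p.gene_b))),
    } for p in all_pairs]))

    save("arrays.tsv", pd.DataFrame([{
        "array_id": a.array_id, "chromosome": a.chromosome,
        "n_members": a.size, "members": ";".join(a.member_gene_ids),
        "timing": tdating.timing[a.array_id],
    } for a in arrays]))

    save("tandem_by_chromosome.tsv", pd.DataFrame([
        {"chromosome": chrom, **vals}
        for chrom, vals in sorted(
            tandem_chromosome_summary(arrays, desc).items())
    ]))

    save("kaks.tsv", pd.DataFrame([{
        "gene_a": r.gene_a, "gene_b": r.gene_b, "pair_type": r.pair_type,
        "divergence_class": pair_classes.get(r.key(),
                                             divergence.DivergenceClass.UNANNOTATED).value,
        "S_sites": round(r.S_sites, 2), "N_sites": round(r.N_sites, 2),
        "Sd": round(r.Sd, 3), "Nd": round(r.Nd, 3),
        "Ka": None if r.Ka is None else round(r.Ka, 5),
        "Ks": None if r.Ks is None else round(r.Ks, 5),
        "omega": None if r.omega is None else round(r.omega, 5),
        "protein_identity": round(r.protein_identity, 4),
        "coverage": round(r.coverage, 4),
        "flags": ";".join(r.flags),
    } for r in kaks_results]))

    save("kaks_exclusions.tsv", pd.DataFrame(
        [{"gene_a": k[0], "gene_b": k[1], "reason": reason}
         for k, reason in exclusions]))

    save("class_comparison.tsv", pd.DataFrame([
        {"pair_type": bucket, "class_a": a, "class_b": b,
         "p_value": p, "method": comp.methods[(a, b)]}
        for bucket, comp in sorted(comparisons.items())
        for (a, b), p in sorted(comp.pvalues.items())
    ]))

    # summary tables
    outs = StageOutputs(ref, desc, annotation, blocks, assignment, coverage,
                        [p for p in all_pairs if p.pair_type == ORTHOLOG],
                        [p for p in all_pairs if p.pair_type == WGD_DUPLICATE],
                        [p for p in all_pairs if p.pair_type == TANDEM_PARALOG],
                        arrays, fractionation, tdating, summaries,
                        pair_classes, kaks_results, exclusions, comparisons,
                        peaks, ordering,
                        RunReport(1, {}, {}, [], {}))
    for name, df in summarize_tables(outs).items():
        if name == "table4":
            df = pd.DataFrame([{
                "family": fam.family,
                "defining_terms": ";".join(sorted(fam.defining_terms)),
                "n_total": fam.n_total,
                "n_from_wgd": fam.n_from_wgd,
                "n_from_td": fam.n_from_td,
            } for fam in family_rows])
        save(f"{name}.tsv", df)

    def venn_doc(v):
        return {
            "terms_only_a": sorted(v.terms_only_a),
            "terms_shared": sorted(v.terms_shared),
            "terms_only_b": sorted(v.terms_only_b),
            "n_only_a": len(v.terms_only_a),
            "n_shared": len(v.terms_shared),
            "n_only_b": len(v.terms_only_b),
            "proportion_annotated_a": v.proportion_annotated_a,
            "proportion_annotated_b": v.proportion_annotated_b,
        }
    with open(out_dir / "venn.json", "w") as fh:
        json.dump({"single_copy_subgenomes": venn_doc(venn_subgenomes),
                   "wgd_vs_tandem": venn_doc(venn_events)},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")
    tables["venn"] = str(out_dir / "venn.json")

    peaks_doc = {
        "peaks": [{"pair_class": p.pair_class,
                   "primary_mode": p.primary_mode,
                   "primary_density": p.primary_density,
                   "secondary_modes": p.secondary_modes,
                   "flags": p.flags} for p in peaks],
    }
    if ordering is not None:
        peaks_doc["event_order"] = ordering.order
        peaks_doc["event_order_description"] = ordering.describe()
        peaks_doc["unresolved"] = [list(t) for t in ordering.unresolved]
    with open(out_dir / "peaks.json", "w") as fh:
        json.dump(peaks_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    tables["peaks"] = str(out_dir / "peaks.json")
    return tables
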