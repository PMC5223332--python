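"""End-to-end driver: raw source records -> assembled table -> metric summary.

This is thin glue over the stage modules, in the order the stages run:
ingest per style, drug normalization over the unique raw names, indication
mapping (with compound splitting and phenotypic remap) over the unique
targets, subtype tagging over the unique entire values, assembly, metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .defaults import DEFAULT_RELATION_ALLOWLIST, DEFAULT_ROLE_BLOCKLIST
from .did_table import DIDRow, assemble
from .drug_norm import DrugNormalization, Lexicons, normalize_drug
from .errors import InputError
from .indication_norm import IndicationMapping, compound_map
from .ingest import (
    DEFAULT_MAX_TEXT_LEN,
    FilterReport,
    ParsedPair,
    RawSourceRecord,
    SourceStyle,
    ingest_freetext_source,
    ingest_hierarchy_source,
    ingest_pair_source,
)
from .lexicon import Authority, ConceptDictionary, RemapTable, SemanticTypeScheme
from .metrics import (
    ENTITIES,
    STAGES,
    DrugBasis,
    coverage,
    overlap,
    richness,
    tr_drugs,
    tr_indications,
    zipf,
)
from .subtypes import SubtypeAnnotation, tag_subtypes

__all__ = ["PipelineResult", "run_sources", "run_world", "metrics_summary"]


@dataclass
class PipelineResult:
    rows: list[DIDRow]
    pairs: list[ParsedPair]
    reports: dict[str, FilterReport]
    drug_norms: dict[str, DrugNormalization]
    indication_maps: dict[str, list[IndicationMapping]]
    subtype_maps: dict[str, list[SubtypeAnnotation]]


def run_sources(
    sources: Mapping[str, Sequence[RawSourceRecord]],
    drug_dicts: Sequence[ConceptDictionary],
    ranking: Sequence[Authority],
    indication_dict: ConceptDictionary,
    scheme: SemanticTypeScheme,
    remap: RemapTable,
    lexicons: Optional[Lexicons] = None,
    cui_authority: Optional[str] = None,
    relation_allowlist=DEFAULT_RELATION_ALLOWLIST,
    role_blocklist=DEFAULT_ROLE_BLOCKLIST,
    freetext_max_len: int = DEFAULT_MAX_TEXT_LEN,
) -> PipelineResult:
    """Run the full construction pipeline over per-source record lists."""
    all_pairs: list[ParsedPair] = []
    reports: dict[str, FilterReport] = {}
    for source_id in sorted(sources):
        records = list(sources[source_id])
        if not records:
            continue
        style = records[0].style
        if style is SourceStyle.PAIR:
            pairs, report = ingest_pair_source(
                records, relation_allowlist, role_blocklist
            )
        elif style is SourceStyle.HIERARCHY:
            pairs, report = ingest_hierarchy_source(records)
        elif style is SourceStyle.FREETEXT:
            pairs, report = ingest_freetext_source(
                records, max_len=freetext_max_len, indication_dict=indication_dict
            )
        else:  # pragma: no cover - enum is closed
            raise InputError(f"unknown source style {style!r}")
        all_pairs.extend(pairs)
        reports[source_id] = report

    drug_norms = {
        name: normalize_drug(name, drug_dicts, ranking, lexicons, cui_authority)
        for name in sorted({p.raw_drug_name for p in all_pairs})
    }
    indication_maps = {
        target: compound_map(target, indication_dict, scheme, remap)
        for target in sorted({p.target for p in all_pairs})
    }
    subtype_maps = {
        value: tag_subtypes(value)
        for value in sorted({p.entire_value for p in all_pairs})
    }
    rows = assemble(all_pairs, drug_norms, indication_maps, subtype_maps)
    return PipelineResult(
        rows=rows,
        pairs=all_pairs,
        reports=reports,
        drug_norms=drug_norms,
        indication_maps=indication_maps,
        subtype_maps=subtype_maps,
    )


def run_world(world) -> PipelineResult:
    """Run the pipeline over a synthetic world's emitted sources."""
    from .synthetic_data import emit_sources

    sources = emit_sources(world)
    return run_sources(
        sources,
        drug_dicts=list(world.dictionaries),
        ranking=list(world.ranking),
        indication_dict=world.dictionaries[-1],
        scheme=world.scheme,
        remap=world.remap,
        cui_authority=world.cui_authority,
    )


def metrics_summary(rows: Sequence[DIDRow], basis: DrugBasis = "either") -> dict:
    """All integration metrics of a table as one JSON-style structure.

    The layout matches :func:`didkit.synthetic_data.expected_metrics` so a
    pipeline run over a synthetic world can be compared with the generator's
    analytic computation for exact equality.
    """
    trd = tr_drugs(rows, basis)
    tri = tr_indications(rows)
    summary: dict = {
        "tr": {
            "drug": [trd.n_normalized, trd.n_unnormalized, trd.n_unique_raw, trd.tr],
            "indication": [tri.n_normalized, tri.n_unnormalized,
                           tri.n_unique_raw, tri.tr],
        },
        "overlap": {},
        "zipf": {},
    }
    for entity in ENTITIES:
        for stage in STAGES:
            stats = overlap(rows, entity, stage, basis)
            summary["overlap"][f"{entity}/{stage}"] = {
                "per_source": dict(stats.per_source),
                "pooled": stats.pooled,
            }
            summary["zipf"][f"{entity}/{stage}"] = {
                str(k): v for k, v in zipf(rows, entity, stage, basis).items()
            }
    cov = coverage(rows, "normalized", basis)
    summary["coverage"] = {
        "totals": dict(cov.totals),
        "counts": {s: dict(c) for s, c in cov.counts.items()},
        "percentages": {s: dict(p) for s, p in cov.percentages.items()},
    }
    summary["richness"] = {
        stage: {
            s: [r.indications_per_drug, r.drugs_per_indication]
            for s, r in richness(rows, stage, basis).items()
        }
        for stage in STAGES
    }
    return summary
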