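"""Instrument selection, cross-GWAS validation, and LD pruning.

Instruments are exposure-GWAS variants below a genome-wide significance
threshold (strict ``p < threshold``).  To guard against winner's-curse /
selection bias, instruments can be validated against additional exposure
GWASs at the gene level: a gene counts as replicated when it harbours a
significant variant in the main exposure GWAS *and* in at least one of the
additional GWASs.  Finally a greedy p-value-ordered pruning step reduces
the set to pairwise r^2 below a threshold, mimicking clumping's
"keep the most significant" behaviour.

Every removal is recorded in an audit trail so the selection funnel is
reconstructible from the output alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .summary_data import GeneMap, GwasTable, LdMatrix

__all__ = ["AuditEntry", "InstrumentSet", "select_instruments", "validate_by_shared_genes", "ld_prune"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AuditEntry:
    variant_id: str
    step: str  # "select" | "validate" | "prune"
    action: str  # "removed" | "flagged"
    reason: str


@dataclass
class InstrumentSet:
    """An ordered set of instrument variant ids plus its selection history."""

    variant_ids: list[str]
    provenance: dict = field(default_factory=dict)
    audit: list[AuditEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("instrument ids must be unique")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def removed_ids(self, step: str | None = None) -> list[str]:
        return [
            e.variant_id
            for e in self.audit
            if e.action == "removed" and (step is None or e.step == step)
        ]


def _order_key(table: GwasTable):
    """Ascending p-value; ties broken by (chrom, pos) then id."""

    def key(vid: str):
        rec = table.get(vid)
        pos = rec.pos if rec.pos is not None else 0
        return (rec.pvalue, rec.chrom, pos, vid)

    return key


def select_instruments(exposure: GwasTable, p_threshold: float = 5e-8) -> InstrumentSet:
    """Select exposure variants with ``p < p_threshold``, ordered by ascending p.

    An empty result is returned with a warning rather than an error; the
    downstream pipeline aborts with a clear message when it needs instruments.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    hits = [vid for vid, rec in exposure.records.items() if rec.pvalue < p_threshold]
    hits.sort(key=_order_key(exposure))
    if not hits:
        logger.warning(
            "no variant in %s passes p < %g; returning empty instrument set",
            exposure.trait_id,
            p_threshold,
        )
    return InstrumentSet(
        variant_ids=hits,
        provenance={"p_threshold": p_threshold, "n_candidates": len(exposure)},
    )


def validate_by_shared_genes(
    primary: InstrumentSet,
    exposure: GwasTable,
    others: list[GwasTable],
    gene_map: GeneMap,
    p_threshold: float = 5e-8,
) -> InstrumentSet:
    """Keep instruments whose gene replicates in at least one additional GWAS.

    A gene is *shared* when it contains a variant with ``p < p_threshold`` in
    the main exposure GWAS and a variant with ``p < p_threshold`` in at least
    one of ``others``.  Instruments without a gene annotation are dropped with
    audit reason ``unannotated``.  With an empty ``others`` list the set is
    returned unchanged (logged identity).
    """
    if not others:
        logger.info("no additional exposure GWASs supplied; validation is the identity")
        return InstrumentSet(
            variant_ids=list(primary.variant_ids),
            provenance={**primary.provenance, "validated_against": []},
            audit=list(primary.audit),
        )

    def significant_genes(table: GwasTable) -> set[str]:
        return {
            gene_map.gene_of(vid)
            for vid, rec in table.records.items()
            if rec.pvalue < p_threshold and vid in gene_map
        }

    main_genes = significant_genes(exposure)
    other_genes: set[str] = set()
    for table in others:
        other_genes |= significant_genes(table)
    shared = main_genes & other_genes

    kept: list[str] = []
    audit = list(primary.audit)
    for vid in primary.variant_ids:
        gene = gene_map.gene_of(vid)
        if gene is None:
            audit.append(AuditEntry(vid, "validate", "removed", "unannotated"))
        elif gene in shared:
            kept.append(vid)
        else:
            audit.append(AuditEntry(vid, "validate", "removed", f"gene {gene} not replicated"))
    logger.info(
        "gene validation: %d shared genes, %d/%d instruments kept",
        len(shared),
        len(kept),
        len(primary),
    )
    return InstrumentSet(
        variant_ids=kept,
        provenance={
            **primary.provenance,
            "validated_against": [t.trait_id for t in others],
            "n_shared_genes": len(shared),
        },
        audit=audit,
    )


def ld_prune(
    instruments: InstrumentSet,
    exposure: GwasTable,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
) -> InstrumentSet:
    """Greedy p-ordered pruning to a pairwise ``r^2 < r2_threshold`` set.

    Variants are visited in ascending exposure p-value; a variant is kept iff
    its r^2 with every previously kept variant is below the threshold.
    Variants absent from the LD matrix pass through with an audit flag
    ``no-LD-info`` (they cannot be checked).
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must lie in (0, 1], got {r2_threshold}")
    order = sorted(instruments.variant_ids, key=_order_key(exposure))
    kept: list[str] = []
    kept_in_ld: list[str] = []
    audit = list(instruments.audit)
    for vid in order:
        if vid not in ld:
            kept.append(vid)
            audit.append(AuditEntry(vid, "prune", "flagged", "no-LD-info"))
            logger.warning("variant %s has no LD information; kept unchecked", vid)
            continue
        clash = next((k for k in kept_in_ld if ld.value(vid, k) >= r2_threshold), None)
        if clash is None:
            kept.append(vid)
            kept_in_ld.append(vid)
        else:
            audit.append(
                AuditEntry(vid, "prune", "removed", f"r2 >= {r2_threshold} with {clash}")
            )
    return InstrumentSet(
        variant_ids=kept,
        provenance={**instruments.provenance, "r2_threshold": r2_threshold},
        audit=audit,
    )
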