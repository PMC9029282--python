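"""Data model and I/O for GWAS summary statistics and annotation inputs.

The central container is :class:`GwasTable`, a validated collection of
per-variant association summaries (:class:`SummaryRecord`).  When the trait
is the exposure the record's ``beta``/``se`` hold the per-allele instrument
effect and its standard error; when it is the outcome they hold the
variant-outcome effect and its standard error.  Auxiliary inputs are a
variant-to-gene annotation (:class:`GeneMap`) and a pairwise squared-
correlation matrix for LD pruning (:class:`LdMatrix`).

All on-disk formats are plain tab-separated text with a header row.
Real-world summary files use wildly inconsistent column names, so the
readers resolve a documented alias table (``COLUMN_ALIASES``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SummaryRecord",
    "GwasTable",
    "GeneMap",
    "LdMatrix",
    "COLUMN_ALIASES",
    "read_summary_table",
    "write_summary_table",
    "read_gene_map",
    "write_gene_map",
    "read_ld_matrix",
    "write_ld_matrix",
]

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Canonical column name -> accepted aliases (case-insensitive match).
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "rs_id", "markername", "id"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "position", "bp", "base_pair_location"),
    "effect_allele": ("effect_allele", "ea", "a1", "allele1"),
    "other_allele": ("other_allele", "oa", "a2", "allele2", "non_effect_allele"),
    "eaf": ("eaf", "freq", "effect_allele_frequency", "eaf_a1", "maf"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "se": ("se", "stderr", "standard_error"),
    "pvalue": ("pvalue", "p", "pval", "p_value"),
    "n": ("n", "samplesize", "sample_size", "n_samples"),
}

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "n")


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association summary for one trait.

    ``pos`` is 1-based; ``pos``, ``eaf`` and ``n`` may be missing (``None``).
    Alleles are single upper-case nucleotides and must differ.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str = ""
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def invalid_reason(self) -> str | None:
        """Return a human-readable invariant violation, or None if valid."""
        if not self.variant_id or any(c.isspace() for c in self.variant_id):
            return "invalid variant id"
        for allele in (self.effect_allele, self.other_allele):
            if allele not in VALID_ALLELES:
                return f"allele {allele!r} is not a single nucleotide"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not np.isfinite(self.beta):
            return "non-finite effect estimate"
        if not (np.isfinite(self.se) and self.se > 0):
            return "standard error not positive"
        if not (np.isfinite(self.pvalue) and 0 < self.pvalue <= 1):
            return "p-value outside (0, 1]"
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return "EAF outside [0, 1]"
        if self.pos is not None and self.pos < 0:
            return "negative position"
        if self.n is not None and self.n <= 0:
            return "non-positive sample size"
        return None

    @property
    def palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def flipped(self) -> "SummaryRecord":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class GwasTable:
    """A validated GWAS summary-statistics table for one trait.

    Records are keyed by variant id (unique within a table) and keep their
    input order.  ``n_rejected``/``rejections`` record rows that violated
    :class:`SummaryRecord` invariants during reading.
    """

    trait_id: str
    role: str  # "exposure" | "outcome"
    records: dict[str, SummaryRecord] = field(default_factory=dict)
    n_rejected: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("exposure", "outcome"):
            raise ValueError(f"role must be 'exposure' or 'outcome', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def get(self, variant_id: str) -> SummaryRecord | None:
        return self.records.get(variant_id)

    @classmethod
    def from_records(
        cls, records: list[SummaryRecord], trait_id: str, role: str
    ) -> "GwasTable":
        table = cls(trait_id=trait_id, role=role)
        for rec in records:
            table.add(rec)
        return table

    def add(self, rec: SummaryRecord) -> None:
        if rec.variant_id in self.records:
            raise ValueError(f"duplicate variant id {rec.variant_id!r} in {self.trait_id!r}")
        self.records[rec.variant_id] = rec

    def to_frame(self) -> pd.DataFrame:
        cols = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
        rows = [{c: getattr(rec, c) for c in cols} for rec in self.records.values()]
        return pd.DataFrame(rows, columns=list(cols))


@dataclass(frozen=True)
class GeneMap:
    """Many-to-one variant -> gene-symbol annotation."""

    entries: dict[str, str]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.entries

    def gene_of(self, variant_id: str) -> str | None:
        return self.entries.get(variant_id)

    def variants_in(self, gene: str) -> list[str]:
        return [v for v, g in self.entries.items() if g == gene]


@dataclass
class LdMatrix:
    """Pairwise squared correlations (r^2) between variants.

    Symmetric with unit diagonal; entries in [0, 1].
    """

    ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.ids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix shape does not match the number of ids")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("LD r^2 entries must lie in [0, 1]")
        asym = np.max(np.abs(self.r2 - self.r2.T)) if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"LD matrix asymmetry {asym:.3g} exceeds tolerance 1e-8")
        self.r2 = 0.5 * (self.r2 + self.r2.T)
        if n and np.max(np.abs(np.diag(self.r2) - 1.0)) > 1e-8:
            raise ValueError("LD matrix diagonal must be 1")
        np.fill_diagonal(self.r2, 1.0)
        self._index = {v: i for i, v in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate variant ids in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    """Map canonical names to actual column names via the alias table."""
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, str] = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    return resolved


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(v)


def read_summary_table(
    path: str | Path, role: str, trait_id: str | None = None
) -> GwasTable:
    """Read a tab-separated GWAS summary-statistics file.

    Rows violating :class:`SummaryRecord` invariants are rejected with a
    logged reason and counted on the returned table.  A missing required
    column or zero valid rows is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    resolved = _resolve_columns(list(df.columns))
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header={list(df.columns)}")

    table = GwasTable(trait_id=trait_id or path.stem, role=role)
    for _, row in df.iterrows():
        vid = str(row[resolved["variant_id"]])
        try:
            rec = SummaryRecord(
                variant_id=vid,
                effect_allele=str(row[resolved["effect_allele"]]).upper(),
                other_allele=str(row[resolved["other_allele"]]).upper(),
                beta=float(row[resolved["beta"]]),
                se=float(row[resolved["se"]]),
                pvalue=float(row[resolved["pvalue"]]),
                chrom=str(row[resolved["chrom"]]) if "chrom" in resolved and not pd.isna(row[resolved["chrom"]]) else "",
                pos=_opt_int(row[resolved["pos"]]) if "pos" in resolved else None,
                eaf=_opt_float(row[resolved["eaf"]]) if "eaf" in resolved else None,
                n=_opt_int(row[resolved["n"]]) if "n" in resolved else None,
            )
        except (TypeError, ValueError):
            table.n_rejected += 1
            table.rejections.append((vid, "unparseable row"))
            logger.warning("%s: rejected %s (unparseable row)", path.name, vid)
            continue
        reason = rec.invalid_reason()
        if reason is None and rec.variant_id not in table:
            table.add(rec)
        else:
            reason = reason or "duplicate variant id"
            table.n_rejected += 1
            table.rejections.append((vid, reason))
            logger.warning("%s: rejected %s (%s)", path.name, vid, reason)
    if len(table) == 0:
        raise ValueError(f"{path}: no valid summary rows")
    return table


def write_summary_table(table: GwasTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> GeneMap:
    """Read a two-column (variant, gene) TSV; duplicate identical rows collapse.

    A variant mapped to two different genes is fatal (annotation must be
    many-to-one).
    """
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs two columns (variant, gene)")
    entries: dict[str, str] = {}
    for vid, gene in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        if not vid or any(c.isspace() for c in vid):
            raise ValueError(f"{path}: invalid variant id {vid!r} in gene map")
        if vid in entries and entries[vid] != gene:
            raise ValueError(f"{path}: variant {vid} mapped to both {entries[vid]} and {gene}")
        entries[vid] = gene
    return GeneMap(entries=entries)


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    pd.DataFrame(
        {"variant_id": list(gene_map.entries), "gene": list(gene_map.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square r^2 matrix TSV with a leading id column and matching header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != ids:
        raise ValueError(f"{path}: LD matrix row ids do not match column ids")
    return LdMatrix(ids=ids, r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.ids, columns=ld.ids).to_csv(path, sep="\t")
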