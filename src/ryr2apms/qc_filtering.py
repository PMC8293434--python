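"""Row-exclusion rules applied before enrichment scoring.

Four composable, pure filters implement the standard AP-MS quality control
steps for the two table dialects:

* drop reverse hits, contaminants and site-only identifications
  (search-engine flag columns);
* drop immunoglobulin- and keratin-related hits, the classic antibody /
  handling contaminants of pull-down experiments;
* keep only protein groups with a minimum number of unique peptides
  (default 3) on the LFQ path;
* keep only hits reaching a PSM count of at least ``min_psm`` (default 5)
  in at least one condition AND ``min_peptides`` peptides (default 2) on
  the spectral-count path.

Every filter returns the reduced table together with a :class:`FilterReport`
naming exactly which rows it removed, so each exclusion is auditable.  The
kept set of a filter chain does not depend on filter order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ConfigurationError
from .tables_io import ProteinGroupTable, PsmTable

__all__ = [
    "FilterReport",
    "filter_flags",
    "filter_ig_keratin",
    "filter_min_unique_peptides",
    "filter_psm_threshold",
    "DEFAULT_IG_PATTERNS",
    "DEFAULT_KERATIN_PATTERNS",
]

# Conventional AP-MS contaminant patterns, matched case-insensitively against
# gene symbol and protein description.  Config-visible: pass your own lists.
DEFAULT_IG_PATTERNS = (r"^Igh", r"^Igk", r"^Igl", r"^Jchain$", r"immunoglobulin")
DEFAULT_KERATIN_PATTERNS = (r"^Krt", r"keratin")


@dataclass(frozen=True)
class FilterReport:
    """Audit record of one filter application."""

    rule_name: str
    removed_ids: tuple[str, ...]
    kept_count: int


def _partition(table, keep_predicate, rule_name: str):
    kept, removed = [], []
    for row in table.rows:
        (kept if keep_predicate(row) else removed).append(row)
    report = FilterReport(
        rule_name=rule_name,
        removed_ids=tuple(r.protein_id for r in removed),
        kept_count=len(kept),
    )
    return table.replace_rows(kept), report


def filter_flags(table: ProteinGroupTable) -> tuple[ProteinGroupTable, FilterReport]:
    """Remove reverse hits, contaminants and site-only identifications."""
    return _partition(
        table,
        lambda r: not (r.flag_reverse or r.flag_contaminant or r.flag_site_only),
        "flags",
    )


def _compile(patterns, what: str) -> list[re.Pattern]:
    if not patterns:
        raise ConfigurationError(f"{what} pattern list must be non-empty")
    compiled = []
    for pat in patterns:
        try:
            compiled.append(re.compile(pat, re.IGNORECASE))
        except re.error as exc:
            raise ConfigurationError(f"invalid {what} pattern {pat!r}: {exc}")
    return compiled


def filter_ig_keratin(
    table: ProteinGroupTable,
    ig_patterns=DEFAULT_IG_PATTERNS,
    keratin_patterns=DEFAULT_KERATIN_PATTERNS,
) -> tuple[ProteinGroupTable, FilterReport]:
    """Remove immunoglobulin-related and keratin-related hits.

    A row is removed when its gene symbol or description matches any of the
    (case-insensitive) regexes.  Rows with empty gene symbol and no
    description match are kept.
    """
    regexes = _compile(ig_patterns, "immunoglobulin") + _compile(keratin_patterns, "keratin")

    def keep(row) -> bool:
        for rx in regexes:
            if row.gene_symbol and rx.search(row.gene_symbol):
                return False
            if row.description and rx.search(row.description):
                return False
        return True

    return _partition(table, keep, "ig_keratin")


def filter_min_unique_peptides(
    table: ProteinGroupTable, min_unique: int = 3
) -> tuple[ProteinGroupTable, FilterReport]:
    """Keep protein groups identified by at least ``min_unique`` unique peptides."""
    if min_unique < 1:
        raise ConfigurationError("min_unique must be >= 1")
    return _partition(
        table, lambda r: r.unique_peptides >= min_unique, "min_unique_peptides"
    )


def filter_psm_threshold(
    table: PsmTable, min_psm: int = 5, min_peptides: int = 2
) -> tuple[PsmTable, FilterReport]:
    """Keep hits with PSM >= ``min_psm`` in at least one condition and
    at least ``min_peptides`` peptides identified."""
    if min_psm < 1 or min_peptides < 1:
        raise ConfigurationError("PSM and peptide thresholds must be >= 1")
    return _partition(
        table,
        lambda r: max(r.psm.values(), default=0) >= min_psm
        and r.peptides >= min_peptides,
        "psm_threshold",
    )
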