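"""Dual-control LFQ enrichment ratios and the cross-experiment enrichment score.

A pull-down experiment carries three channels per protein: the anti-bait
immunoprecipitation, an IgG isotype control, and a beads-only control.
Specific interactors are expected to show higher LFQ intensity in the
anti-bait channel than in either control, so each protein gets two
enrichment ratios,

    ratio_igg   = anti_bait / IgG
    ratio_beads = anti_bait / beads,

with zero intensities first replaced by a fixed background floor (default
50,000 instrument units) so that ratios are always finite and positive.
A protein counts as enriched against a control when the corresponding
ratio is strictly greater than the cutoff (default 1.5).

Across E independent pull-down experiments a protein therefore has up to
2·E enrichment ratios; its *enrichment score* is the number of those
ratios strictly above the cutoff (for the three-experiment design used
here, an integer from 0 to 6).  Scores map onto confidence tiers:
0 unscored, 1–2 low, 3–4 high, 5–6 top; "high confidence" means
score >= 3.  A protein absent from an experiment simply contributes no
ratios there — absence is no evidence, not missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, DataError
from .tables_io import ProteinGroup, ProteinGroupTable

__all__ = [
    "EnrichmentRecord",
    "RatioPair",
    "ScoreRecord",
    "CATEGORIES",
    "TIERS",
    "impute_floor",
    "compute_ratio_pair",
    "classify_enrichment",
    "enrichment_score",
    "assign_tier",
    "score_experiments",
    "ratio_pairs_from_table",
]

DEFAULT_FLOOR = 50_000.0
DEFAULT_CUTOFF = 1.5

CATEGORIES = ("bait", "both_enriched", "igg_only", "beads_only", "not_enriched")
TIERS = ("unscored", "low", "high", "top")

#: canonical channel roles, in (anti-bait, IgG control, beads-only control) order
DEFAULT_CHANNELS = ("anti_bait", "igg", "beads")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One protein's dual-control enrichment ratios and category."""

    protein_id: str
    ratio_igg: float
    ratio_beads: float
    category: str = ""
    imputed_channels: tuple[str, ...] = ()


@dataclass(frozen=True)
class RatioPair:
    """One protein's ratio pair from one experiment; either ratio may be absent."""

    experiment_label: str
    ratio_igg: float | None = None
    ratio_beads: float | None = None


@dataclass(frozen=True)
class ScoreRecord:
    """Cross-experiment enrichment score and confidence tier."""

    protein_id: str
    score: int
    tier: str
    #: (experiment_label, tuple of ratio names that exceeded the cutoff)
    contributing: tuple[tuple[str, tuple[str, ...]], ...] = ()


def impute_floor(intensity: float, floor: float = DEFAULT_FLOOR) -> float:
    """Replace a zero intensity with the background floor.

    Positive intensities pass through unchanged; zero (a non-detection)
    becomes ``floor`` so that ratios stay finite and positive.
    """
    if intensity < 0:
        raise DataError(f"negative intensity {intensity!r}")
    if floor <= 0:
        raise ConfigurationError("floor must be positive")
    return intensity if intensity > 0 else floor


def compute_ratio_pair(
    row: ProteinGroup,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    floor: float = DEFAULT_FLOOR,
) -> EnrichmentRecord:
    """Compute anti-bait/IgG and anti-bait/beads ratios after floor imputation.

    ``channels`` names the (anti-bait, IgG, beads) channel labels in that
    order.  Every channel whose raw intensity was exactly 0 is listed in
    ``imputed_channels``.
    """
    if len(channels) != 3:
        raise ConfigurationError("channels must name (anti_bait, igg, beads)")
    missing = [c for c in channels if c not in row.lfq]
    if missing:
        raise ConfigurationError(
            f"{row.protein_id}: row lacks channel(s) {missing}"
        )
    anti, igg, beads = (row.lfq[c] for c in channels)
    imputed = tuple(c for c, v in zip(channels, (anti, igg, beads)) if v == 0)
    return EnrichmentRecord(
        protein_id=row.protein_id,
        ratio_igg=impute_floor(anti, floor) / impute_floor(igg, floor),
        ratio_beads=impute_floor(anti, floor) / impute_floor(beads, floor),
        imputed_channels=imputed,
    )


def classify_enrichment(
    record: EnrichmentRecord,
    cutoff: float = DEFAULT_CUTOFF,
    bait_id: str = "",
) -> EnrichmentRecord:
    """Fill in the enrichment category from the ratio pair.

    Comparisons are strict: a ratio exactly equal to the cutoff does not
    count as enriched.
    """
    if record.protein_id == bait_id:
        category = "bait"
    elif record.ratio_igg > cutoff and record.ratio_beads > cutoff:
        category = "both_enriched"
    elif record.ratio_igg > cutoff:
        category = "igg_only"
    elif record.ratio_beads > cutoff:
        category = "beads_only"
    else:
        category = "not_enriched"
    return replace(record, category=category)


def enrichment_score(
    protein_id: str,
    pairs: Iterable[RatioPair],
    cutoff: float = DEFAULT_CUTOFF,
) -> ScoreRecord:
    """Count enrichment ratios strictly above the cutoff across experiments.

    Each experiment contributes at most one :class:`RatioPair`; a second
    pair with the same label is a :class:`DataError`.  Absent ratios
    contribute nothing.
    """
    seen: set[str] = set()
    score = 0
    contributing: list[tuple[str, tuple[str, ...]]] = []
    for pair in pairs:
        if pair.experiment_label in seen:
            raise DataError(
                f"{protein_id}: duplicate ratio pair for experiment "
                f"{pair.experiment_label!r}"
            )
        seen.add(pair.experiment_label)
        hits = tuple(
            name
            for name, value in (("igg", pair.ratio_igg), ("beads", pair.ratio_beads))
            if value is not None and value > cutoff
        )
        score += len(hits)
        if hits:
            contributing.append((pair.experiment_label, hits))
    return ScoreRecord(
        protein_id=protein_id,
        score=score,
        tier=assign_tier(score),
        contributing=tuple(contributing),
    )


def assign_tier(score: int) -> str:
    """Map an enrichment score onto its confidence tier.

    0 -> unscored, 1-2 -> low, 3-4 -> high, 5-6 -> top.  The
    "high-confidence interactor" set is tier in {high, top}, i.e. score >= 3.
    """
    if not 0 <= score <= 6:
        raise ValueError(f"enrichment score out of range: {score}")
    if score == 0:
        return "unscored"
    if score <= 2:
        return "low"
    if score <= 4:
        return "high"
    return "top"


def ratio_pairs_from_table(
    table: ProteinGroupTable,
    experiment_label: str,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    floor: float = DEFAULT_FLOOR,
) -> dict[str, RatioPair]:
    """Compute one RatioPair per protein in an experiment table."""
    pairs: dict[str, RatioPair] = {}
    for row in table.rows:
        rec = compute_ratio_pair(row, channels=channels, floor=floor)
        pairs[row.protein_id] = RatioPair(
            experiment_label=experiment_label,
            ratio_igg=rec.ratio_igg,
            ratio_beads=rec.ratio_beads,
        )
    return pairs


def score_experiments(
    experiments: Sequence[tuple[str, ProteinGroupTable]],
    bait_id: str = "",
    channels: Sequence[str] = DEFAULT_CHANNELS,
    floor: float = DEFAULT_FLOOR,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[dict[str, list[EnrichmentRecord]], list[ScoreRecord]]:
    """Score every protein seen in any of several pull-down experiments.

    Returns per-experiment classified :class:`EnrichmentRecord` lists (bait
    included, labelled as such) and cross-experiment :class:`ScoreRecord`
    rows for every non-bait protein, sorted by score descending then
    accession ascending.
    """
    labels = [label for label, _ in experiments]
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate experiment labels: {labels}")

    per_exp_records: dict[str, list[EnrichmentRecord]] = {}
    pair_lists: dict[str, list[RatioPair]] = {}
    for label, table in experiments:
        records = []
        for row in table.rows:
            rec = compute_ratio_pair(row, channels=channels, floor=floor)
            records.append(classify_enrichment(rec, cutoff=cutoff, bait_id=bait_id))
        per_exp_records[label] = records
        for pid, pair in ratio_pairs_from_table(
            table, label, channels=channels, floor=floor
        ).items():
            pair_lists.setdefault(pid, []).append(pair)

    scores = [
        enrichment_score(pid, pairs, cutoff=cutoff)
        for pid, pairs in pair_lists.items()
        if pid != bait_id
    ]
    scores.sort(key=lambda s: (-s.score, s.protein_id))
    return per_exp_records, scores
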