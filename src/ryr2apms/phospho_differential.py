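"""Phosphomimetic differential-binding analysis on spectral counts.

The bait RyR2 carries serine 2814, a CaMKII phosphorylation site; the
S2814A knock-in mimics the unphosphorylatable state and S2814D the
constitutively phosphorylated state.  For each co-purified protein the
PSM counts from the WT, S2814A and S2814D pull-downs are normalized to
the bait's PSM and compared as two ratios,

    S2814A/WT  and  S2814D/WT,

which place the protein in one of four quadrants around 1.0: increased
binding to the dephospho-mimic and decreased to the phospho-mimic
(``a_up_d_down``, the expected direction when phosphorylation weakens an
interaction), both up, both down, or the reverse (``a_down_d_up``).

Normalization modes
-------------------
``wt_bait`` (default): every condition is divided by the *WT* bait PSM,
a single constant, so the condition ratios of the normalized values equal
the raw PSM ratios exactly.  ``per_sample_bait``: each condition is
divided by that condition's own bait PSM, correcting per-sample IP
efficiency at the cost of the exact cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError, DataError
from .tables_io import PsmTable

__all__ = [
    "PhosphoRecord",
    "QUADRANTS",
    "normalize_psm",
    "condition_ratios",
    "classify_quadrant",
    "phospho_analysis",
]

QUADRANTS = (
    "a_up_d_down", "both_up", "both_down", "a_down_d_up", "unchanged", "undefined",
)

WT = "WT"
S2814A = "S2814A"
S2814D = "S2814D"


@dataclass(frozen=True)
class PhosphoRecord:
    """Bait-normalized PSM values, condition ratios and quadrant for one protein."""

    protein_id: str
    norm_psm: dict[str, float]
    raw_psm: dict[str, int]
    mode: str = "wt_bait"
    ratio_a_wt: float | None = None
    ratio_d_wt: float | None = None
    quadrant: str = ""


def normalize_psm(
    table: PsmTable,
    mode: str = "wt_bait",
    wt_label: str = WT,
) -> list[PhosphoRecord]:
    """Normalize every non-bait row's PSM counts to the bait PSM.

    In ``wt_bait`` mode the denominator is the bait's PSM in the WT
    condition for every column; in ``per_sample_bait`` mode each condition
    uses its own bait PSM.  A zero bait PSM in a required denominator is a
    :class:`DataError` naming the condition.
    """
    if mode not in ("wt_bait", "per_sample_bait"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    try:
        bait = table.get(table.bait_id)
    except KeyError:
        raise DataError(f"bait not found: {table.bait_id!r}")
    if wt_label not in table.conditions:
        raise ConfigurationError(f"condition {wt_label!r} not in table")

    denominators: dict[str, int] = {}
    for condition in table.conditions:
        denom = bait.psm[wt_label] if mode == "wt_bait" else bait.psm[condition]
        if denom == 0:
            raise DataError(
                f"bait PSM is zero in condition {wt_label if mode == 'wt_bait' else condition!r}"
            )
        denominators[condition] = denom

    records = []
    for row in table.rows:
        if row.protein_id == table.bait_id:
            continue
        records.append(PhosphoRecord(
            protein_id=row.protein_id,
            norm_psm={c: row.psm[c] / denominators[c] for c in table.conditions},
            raw_psm=dict(row.psm),
            mode=mode,
        ))
    return records


def condition_ratios(
    record: PhosphoRecord,
    pseudo: float = 0.0,
    wt_label: str = WT,
    a_label: str = S2814A,
    d_label: str = S2814D,
) -> PhosphoRecord:
    """Fill in the S2814A/WT and S2814D/WT ratios.

    With ``pseudo == 0`` and a zero WT value the ratios are undefined and
    the record's quadrant becomes ``undefined``.  In ``wt_bait`` mode with
    no pseudo-count the ratios are computed from the raw PSM counts: the
    shared normalization constant cancels algebraically, and the raw-count
    quotient realizes that cancellation exactly in floating point as well.
    """
    if pseudo < 0:
        raise ConfigurationError("pseudo-count must be >= 0")

    if record.mode == "wt_bait" and pseudo == 0:
        wt, a, d = (record.raw_psm[k] for k in (wt_label, a_label, d_label))
    else:
        wt = record.norm_psm[wt_label] + pseudo
        a = record.norm_psm[a_label] + pseudo
        d = record.norm_psm[d_label] + pseudo

    if wt == 0:
        return replace(record, ratio_a_wt=None, ratio_d_wt=None, quadrant="undefined")
    return replace(record, ratio_a_wt=a / wt, ratio_d_wt=d / wt)


def classify_quadrant(record: PhosphoRecord, threshold: float = 1.0) -> PhosphoRecord:
    """Assign the quadrant of the (S2814A/WT, S2814D/WT) ratio pair.

    Comparisons against the threshold are strict; a ratio exactly equal to
    the threshold yields ``unchanged``.  Undefined ratios yield ``undefined``.
    """
    if record.ratio_a_wt is None or record.ratio_d_wt is None:
        return replace(record, quadrant="undefined")
    a, d = record.ratio_a_wt, record.ratio_d_wt
    if a == threshold or d == threshold:
        quadrant = "unchanged"
    elif a > threshold and d < threshold:
        quadrant = "a_up_d_down"
    elif a > threshold and d > threshold:
        quadrant = "both_up"
    elif a < threshold and d < threshold:
        quadrant = "both_down"
    else:
        quadrant = "a_down_d_up"
    return replace(record, quadrant=quadrant)


def phospho_analysis(
    table: PsmTable,
    mode: str = "wt_bait",
    pseudo: float = 0.0,
    threshold: float = 1.0,
    wt_label: str = WT,
    a_label: str = S2814A,
    d_label: str = S2814D,
) -> list[PhosphoRecord]:
    """Run normalize -> ratios -> quadrant for every non-bait row."""
    out = []
    for record in normalize_psm(table, mode=mode, wt_label=wt_label):
        record = condition_ratios(
            record, pseudo=pseudo, wt_label=wt_label, a_label=a_label, d_label=d_label
        )
        out.append(classify_quadrant(record, threshold=threshold))
    return out
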