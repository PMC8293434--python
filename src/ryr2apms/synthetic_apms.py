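"""Synthetic multi-experiment AP-MS data with known ground truth.

The generator emulates the processed tables the pipeline consumes, at the
scale of a single-bait cardiac pull-down study: one dominant bait protein
(RyR2), a few dozen true interactors whose anti-bait LFQ intensity exceeds
both controls by a configurable fold-change, a large pool of nonspecific
background binders, and a handful of keratin/immunoglobulin contaminant
rows.  LFQ intensities are log-normal around class-dependent means (the
conventional generative assumption for label-free proteomics); spectral
counts are Poisson with condition means scaled by per-class phosphomimetic
multipliers.

Because every row is generated from its own random stream keyed by
``(seed, experiment_index, protein_index)``, outputs are bit-reproducible
and adding proteins does not perturb existing rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .phospho_differential import S2814A, S2814D, WT, PhosphoRecord
from .enrichment_scoring import ScoreRecord
from .tables_io import ProteinGroup, ProteinGroupTable, PsmRow, PsmTable

__all__ = [
    "SimParams",
    "TruthEntry",
    "SyntheticTruth",
    "RecoverySummary",
    "generate_experiment",
    "generate_study",
    "generate_psm_study",
    "evaluate_recovery",
]

BAIT_ID = "E9Q401"      # mouse RyR2 accession
BAIT_GENE = "Ryr2"

# contaminant gene symbols cycled over the n_contaminant rows
_CONTAMINANT_GENES = ("Krt1", "Ighg1", "Krt10", "Igkc", "Krt5", "Iglc1")

# fraction of true interactors assigned to each phosphomimetic effect class,
# mirroring a study in which most interactors bind more to the dephospho-mimic
# and less to the phospho-mimic
_CLASS_FRACTIONS = {
    "a_up_d_down": 0.60,
    "both_up": 0.15,
    "both_down": 0.15,
    "unchanged": 0.10,
}

# stream-key sentinel for per-protein quantities shared across experiments
_SHARED_STREAM = 1_000_003


@dataclass
class SimParams:
    """Study-level parameters of the synthetic AP-MS experiment.

    Defaults emulate the structure of a three-experiment RyR2 pull-down
    study: roughly 180 identified proteins per experiment of which ~25 are
    genuine interactors, a ten-fold anti-bait enrichment for true
    interactors over the shared control mean, log-scale intensity noise
    with sigma 0.3, 10% dropout of true-interactor intensities, and a bait
    spectral-count depth of ~300 PSM per condition.
    """

    n_true: int = 25
    n_background: int = 150
    n_contaminant: int = 6
    n_experiments: int = 3
    bait_intensity: float = 1.0e9
    interactor_enrichment: float = 10.0
    background_enrichment: float = 1.0
    lfq_cv: float = 0.3
    dropout_p: float = 0.1
    psm_depth: float = 300.0
    #: effect-class -> (S2814A multiplier, S2814D multiplier) on PSM means
    phospho_effects: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "a_up_d_down": (1.5, 0.5),
        "both_up": (1.6, 1.6),
        "both_down": (0.6, 0.6),
        "unchanged": (1.0, 1.0),
    })
    seed: int = 0
    #: per-protein control-channel mean intensity is drawn log-uniformly here
    abundance_range: tuple[float, float] = (2.0e5, 5.0e6)
    #: per-protein base PSM mean (WT condition) is drawn log-uniformly here
    psm_base_range: tuple[float, float] = (20.0, 200.0)

    def validate(self) -> None:
        if min(self.n_true, self.n_background, self.n_contaminant) < 0:
            raise ConfigurationError("protein counts must be >= 0")
        if self.n_experiments < 1:
            raise ConfigurationError("n_experiments must be >= 1")
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1]")
        if self.lfq_cv < 0:
            raise ConfigurationError("lfq_cv must be >= 0")
        for positive, name in (
            (self.bait_intensity, "bait_intensity"),
            (self.interactor_enrichment, "interactor_enrichment"),
            (self.background_enrichment, "background_enrichment"),
            (self.psm_depth, "psm_depth"),
        ):
            if positive <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for cls, (ma, md) in self.phospho_effects.items():
            if ma <= 0 or md <= 0:
                raise ConfigurationError(f"multipliers for {cls!r} must be > 0")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one synthetic protein."""

    protein_id: str
    gene_symbol: str
    clazz: str                       # bait | true_interactor | background | contaminant
    expected_quadrant: str | None    # None when no directional effect is simulated
    expected_enriched: bool          # should score 2 per experiment (noise-free)


@dataclass(frozen=True)
class SyntheticTruth:
    entries: dict[str, TruthEntry]

    def bait_id(self) -> str:
        baits = [e.protein_id for e in self.entries.values() if e.clazz == "bait"]
        if len(baits) != 1:
            raise DataError(f"expected exactly one bait, found {len(baits)}")
        return baits[0]

    def of_class(self, clazz: str) -> list[TruthEntry]:
        return [e for e in self.entries.values() if e.clazz == clazz]


@dataclass(frozen=True)
class RecoverySummary:
    """Sensitivity/specificity of high-confidence calls and quadrant accuracy."""

    n_true: int
    n_negative: int
    sensitivity: float
    specificity: float
    quadrant_accuracy: float
    quadrant_accuracy_by_class: dict[str, float]


# ---------------------------------------------------------------------------
# protein roster (deterministic in params, shared across experiments)
# ---------------------------------------------------------------------------

def _rng(params: SimParams, *key: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, *key])


def _phospho_class(index: int, params: SimParams) -> str:
    """Deterministic class assignment for true interactor ``index``.

    Classes fill fixed fractions of the roster in a stable order so the
    composition does not depend on the seed.
    """
    classes = [c for c in _CLASS_FRACTIONS if c in params.phospho_effects]
    if not classes:
        raise ConfigurationError("phospho_effects must contain at least one class")
    counts = {c: int(math.floor(_CLASS_FRACTIONS[c] * params.n_true)) for c in classes}
    # distribute the remainder to the earliest classes
    short = params.n_true - sum(counts.values())
    for c in classes:
        if short <= 0:
            break
        counts[c] += 1
        short -= 1
    cum = 0
    for c in classes:
        cum += counts[c]
        if index < cum:
            return c
    return classes[-1]


def _expected_quadrant(multipliers: tuple[float, float]) -> str | None:
    ma, md = multipliers
    if ma > 1 and md < 1:
        return "a_up_d_down"
    if ma > 1 and md > 1:
        return "both_up"
    if ma < 1 and md < 1:
        return "both_down"
    if ma < 1 and md > 1:
        return "a_down_d_up"
    return None  # a multiplier of exactly 1 carries no expected direction


def _roster(params: SimParams) -> list[TruthEntry]:
    entries = [TruthEntry(BAIT_ID, BAIT_GENE, "bait", None, True)]
    for i in range(params.n_true):
        cls = _phospho_class(i, params)
        entries.append(TruthEntry(
            protein_id=f"SIM-INT-{i:03d}",
            gene_symbol=f"Int{i:03d}",
            clazz="true_interactor",
            expected_quadrant=_expected_quadrant(params.phospho_effects[cls]),
            expected_enriched=True,
        ))
    for i in range(params.n_background):
        entries.append(TruthEntry(
            protein_id=f"SIM-BKG-{i:03d}",
            gene_symbol=f"Bkg{i:03d}",
            clazz="background",
            expected_quadrant=None,
            expected_enriched=False,
        ))
    for i in range(params.n_contaminant):
        entries.append(TruthEntry(
            protein_id=f"SIM-CON-{i:03d}",
            gene_symbol=_CONTAMINANT_GENES[i % len(_CONTAMINANT_GENES)],
            clazz="contaminant",
            expected_quadrant=None,
            expected_enriched=False,
        ))
    return entries


def _truth(params: SimParams) -> SyntheticTruth:
    return SyntheticTruth(entries={e.protein_id: e for e in _roster(params)})


def _abundance(params: SimParams, protein_index: int) -> float:
    """Per-protein control-channel mean intensity, constant across experiments."""
    lo, hi = params.abundance_range
    u = _rng(params, _SHARED_STREAM, protein_index).random()
    return float(lo * (hi / lo) ** u)


def _psm_base(params: SimParams, protein_index: int, lo: float, hi: float) -> float:
    u = _rng(params, _SHARED_STREAM + 1, protein_index).random()
    return float(lo * (hi / lo) ** u)


# ---------------------------------------------------------------------------
# LFQ experiment generation
# ---------------------------------------------------------------------------

def generate_experiment(
    params: SimParams, experiment_index: int
) -> tuple[ProteinGroupTable, SyntheticTruth]:
    """Generate one pull-down experiment table (anti_bait / igg / beads).

    Intensities are log-normal around class means: for true interactors the
    anti-bait mean is ``interactor_enrichment`` times the shared control
    mean, for background and contaminant rows ``background_enrichment``
    times.  True-interactor intensities are additionally set to zero with
    probability ``dropout_p`` per channel, emulating stochastic missingness
    of genuine signals; the bait is never dropped.
    """
    params.validate()
    roster = _roster(params)
    rows = []
    for pidx, entry in enumerate(roster):
        rng = _rng(params, experiment_index, pidx)
        if entry.clazz == "bait":
            control_mean = params.bait_intensity / 50.0  # bait leaks into controls
            anti_mean = params.bait_intensity
        else:
            control_mean = _abundance(params, pidx)
            fold = (params.interactor_enrichment
                    if entry.clazz == "true_interactor"
                    else params.background_enrichment)
            anti_mean = control_mean * fold

        sigma = params.lfq_cv
        noise = rng.standard_normal(3)
        values = [m * math.exp(sigma * z)
                  for m, z in zip((anti_mean, control_mean, control_mean), noise)]
        if entry.clazz == "true_interactor" and params.dropout_p > 0:
            drop = rng.random(3) < params.dropout_p
            values = [0.0 if d else v for v, d in zip(values, drop)]

        peptides = 50 if entry.clazz == "bait" else max(1, int(rng.poisson(8.0)))
        rows.append(ProteinGroup(
            protein_id=entry.protein_id,
            gene_symbol=entry.gene_symbol,
            unique_peptides=peptides,
            lfq={"anti_bait": values[0], "igg": values[1], "beads": values[2]},
            description=("immunoglobulin" if entry.gene_symbol.startswith("Ig")
                         else "keratin" if entry.gene_symbol.startswith("Krt")
                         else ""),
        ))

    table = ProteinGroupTable(
        channels=("anti_bait", "igg", "beads"),
        rows=tuple(rows),
        provenance=f"synthetic experiment {experiment_index} (seed={params.seed})",
    )
    table.validate()
    return table, _truth(params)


def generate_study(
    params: SimParams,
) -> tuple[list[tuple[str, ProteinGroupTable]], SyntheticTruth]:
    """Generate all ``n_experiments`` pull-down tables with shared truth."""
    experiments = []
    truth = _truth(params)
    for idx in range(params.n_experiments):
        table, _ = generate_experiment(params, idx)
        experiments.append((f"exp{idx + 1}", table))
    return experiments, truth


# ---------------------------------------------------------------------------
# PSM study generation
# ---------------------------------------------------------------------------

def generate_psm_study(params: SimParams) -> tuple[PsmTable, SyntheticTruth]:
    """Generate the three-condition (WT / S2814A / S2814D) spectral-count table.

    PSM counts are Poisson with mean ``base × multiplier`` where the base is
    a per-protein WT abundance and the multipliers come from the protein's
    phosphomimetic effect class (background and contaminants use (1, 1)).
    The bait's mean is ``psm_depth`` in every condition.
    """
    params.validate()
    roster = _roster(params)
    psm_exp_index = params.n_experiments  # stream index after the LFQ experiments
    rows = []
    for pidx, entry in enumerate(roster):
        rng = _rng(params, psm_exp_index, pidx)
        if entry.clazz == "bait":
            means = (params.psm_depth,) * 3
        else:
            if entry.clazz == "true_interactor":
                base = _psm_base(params, pidx, *params.psm_base_range)
                ma, md = params.phospho_effects[_phospho_class(pidx - 1, params)]
            else:
                base = _psm_base(params, pidx, 1.0, 50.0)
                ma, md = 1.0, 1.0
            means = (base, base * ma, base * md)
        counts = [int(rng.poisson(m)) for m in means]
        lam = means[0]
        peptides = 40 if entry.clazz == "bait" else max(1, int(round(math.sqrt(lam))))
        rows.append(PsmRow(
            protein_id=entry.protein_id,
            gene_symbol=entry.gene_symbol,
            psm={WT: counts[0], S2814A: counts[1], S2814D: counts[2]},
            peptides=peptides,
        ))
    table = PsmTable(conditions=(WT, S2814A, S2814D), rows=tuple(rows), bait_id=BAIT_ID)
    table.validate()
    return table, _truth(params)


# ---------------------------------------------------------------------------
# writing a study to disk in the input dialects
# ---------------------------------------------------------------------------

def write_study(params: SimParams, outdir) -> dict[str, object]:
    """Write a full synthetic study in the dialects the readers consume.

    Emits ``exp<i>_proteinGroups.tsv`` per experiment, ``psm.tsv`` and a
    ``truth.tsv`` ground-truth table; returns the paths plus experiment
    labels and the bait accession.
    """
    import pandas as pd
    from pathlib import Path
    from .tables_io import write_protein_groups, write_psm_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    experiments, truth = generate_study(params)
    exp_paths = []
    for label, table in experiments:
        path = outdir / f"{label}_proteinGroups.tsv"
        write_protein_groups(table, path)
        exp_paths.append((label, path))
    psm_table, _ = generate_psm_study(params)
    psm_path = outdir / "psm.tsv"
    write_psm_table(psm_table, psm_path)
    truth_path = outdir / "truth.tsv"
    pd.DataFrame([
        {"protein_id": e.protein_id, "gene_symbol": e.gene_symbol,
         "class": e.clazz,
         "expected_quadrant": e.expected_quadrant or "",
         "expected_enriched": e.expected_enriched}
        for e in truth.entries.values()
    ]).to_csv(truth_path, sep="\t", index=False)
    return {
        "experiments": exp_paths,
        "psm": psm_path,
        "truth": truth_path,
        "bait_id": BAIT_ID,
    }


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(
    truth: SyntheticTruth,
    scores: Sequence[ScoreRecord],
    quadrants: Sequence[PhosphoRecord] = (),
) -> RecoverySummary:
    """Compare pipeline calls against ground truth.

    Sensitivity: fraction of true interactors called high-confidence
    (tier high or top, i.e. score >= 3).  Specificity: fraction of
    background + contaminant proteins with score <= 2 (proteins absent
    from the score list count as score 0).  Quadrant accuracy: fraction of
    true interactors with a simulated directional effect and a defined
    observed quadrant whose quadrant matches the expectation.
    """
    known = set(truth.entries)
    for rec in list(scores) + list(quadrants):
        if rec.protein_id not in known:
            raise DataError(f"id not present in truth: {rec.protein_id!r}")

    score_by_id = {s.protein_id: s.score for s in scores}
    true_ids = [e.protein_id for e in truth.of_class("true_interactor")]
    negative_ids = [e.protein_id
                    for e in truth.entries.values()
                    if e.clazz in ("background", "contaminant")]

    n_true = len(true_ids)
    n_neg = len(negative_ids)
    sensitivity = (
        sum(score_by_id.get(pid, 0) >= 3 for pid in true_ids) / n_true
        if n_true else float("nan")
    )
    specificity = (
        sum(score_by_id.get(pid, 0) <= 2 for pid in negative_ids) / n_neg
        if n_neg else float("nan")
    )

    quad_by_id = {q.protein_id: q.quadrant for q in quadrants}
    per_class_hits: dict[str, list[bool]] = {}
    for pid in true_ids:
        expected = truth.entries[pid].expected_quadrant
        observed = quad_by_id.get(pid)
        if expected is None or observed in (None, "", "undefined"):
            continue
        per_class_hits.setdefault(expected, []).append(observed == expected)
    all_hits = [h for hits in per_class_hits.values() for h in hits]
    return RecoverySummary(
        n_true=n_true,
        n_negative=n_neg,
        sensitivity=sensitivity,
        specificity=specificity,
        quadrant_accuracy=(sum(all_hits) / len(all_hits)) if all_hits else float("nan"),
        quadrant_accuracy_by_class={
            cls: sum(hits) / len(hits) for cls, hits in per_class_hits.items()
        },
    )
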