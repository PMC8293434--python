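# Methods

## Problem setting

`ryr2apms` implements the computational tail of a single-bait
affinity-purification mass-spectrometry (AP-MS) study of the cardiac
ryanodine receptor RyR2. The bench side produces two kinds of processed
tables, which are this package's inputs:

1. **Protein-group tables** (MaxQuant `proteinGroups.txt` style) with
   per-channel label-free quantification (LFQ) intensities for three
   pull-down channels run in parallel: anti-RyR2 antibody, IgG isotype
   control, and beads-only control.
2. **Spectral-count tables** (Proteome Discoverer export style) with
   peptide-spectrum-match (PSM) counts per protein across three mouse
   genotypes: WT, S2814A (phospho-ablated RyR2) and S2814D
   (phosphomimetic RyR2).

The pipeline answers two questions: *which co-purified proteins are
specific RyR2 interactors rather than nonspecific background?* and *how
does the phosphorylation-mimic status at serine 2814 change their
binding?*

## Quality control

Rows are removed by four composable, pure filters, each returning an
audit report naming the removed accessions:

- search-engine flag filter: reverse (decoy) hits, contaminant-database
  hits, and "only identified by site" groups;
- immunoglobulin/keratin filter: the classic antibody and handling
  contaminants of pull-down experiments, matched case-insensitively
  against gene symbol and description. Default patterns are the gene
  prefixes `Igh*`, `Igk*`, `Igl*`, `Jchain`, `Krt*` plus the description
  substrings "immunoglobulin" and "keratin"; the match rule is a
  package choice (the conventional one in AP-MS practice) and is fully
  configurable;
- unique-peptide filter (LFQ path): keep groups with ≥ 3 unique
  peptides. The threshold is applied to the table-wide razor+unique
  count, the only count the MaxQuant dialect reports per group;
- PSM filter (spectral path): keep hits with PSM ≥ 5 in *at least one*
  of the three genotype conditions and ≥ 2 peptides identified.

The kept set is independent of filter order (each filter's predicate
depends only on the row), a property the test suite asserts over random
tables.

## Enrichment ratios and the 0–6 score

For each protein in one experiment two ratios are formed from LFQ
intensities, `anti_bait/IgG` and `anti_bait/beads`. Zero intensities
(non-detections) are first replaced by a fixed background floor of
**50,000** instrument units, so ratios are always finite and positive;
the floor is applied to any zero channel, numerator or denominator, and
every imputation is recorded on the output record. A protein is
*enriched* against a control when the ratio is **strictly** greater than
the cutoff **1.5**; a ratio exactly at the cutoff never counts.

Across E pull-down experiments (default E = 3) a protein has up to 2·E
ratios. Its **enrichment score** is the number of available ratios
strictly above the cutoff — an integer 0–6 for the three-experiment
design. A protein absent from an experiment's table contributes no
ratios there: absence is treated as no evidence, not as missing data, so
coverage differences across experiments simply cap the attainable score.
Scores map to confidence tiers

| score | tier |
|---|---|
| 0 | unscored |
| 1–2 | low |
| 3–4 | high |
| 5–6 | top |

and "high-confidence interactor" means score ≥ 3. The bait itself is
excluded from scored-protein counts and from all summary tallies.
Score tables are ordered by score descending, then accession ascending,
so repeated runs produce byte-identical files.

## Phosphomimetic differential binding

PSM counts are normalized to the bait PSM and compared as two ratios,
`S2814A/WT` and `S2814D/WT`, which place each protein in a quadrant
around 1.0: `a_up_d_down` (more binding to the dephospho-mimic, less to
the phospho-mimic), `both_up`, `both_down`, `a_down_d_up`; a ratio
exactly equal to 1.0 yields `unchanged`, and a zero WT value with no
pseudo-count yields `undefined`. Comparisons are strict on both axes.

Two normalization modes exist. The default **`wt_bait`** divides every
condition by the single WT bait PSM. Because the constant is shared, the
condition ratios of normalized values are algebraically the raw count
ratios; to make that cancellation *exact in floating point* as well, the
ratios in this mode (with pseudo-count 0) are computed directly from the
raw counts. **`per_sample_bait`** divides each condition by its own bait
PSM, correcting per-sample IP efficiency; there the constant does not
cancel and ratios are computed from the normalized values. A
non-negative pseudo-count is available for sparse tables (default 0).
Quadrant analysis is restricted by default to proteins with enrichment
score ≥ 2, the set for which the interactor call has at least two
independent lines of support.

## Synthetic data generator

The generator produces the same table dialects the readers consume, with
known ground truth, so that scoring and quadrant classification can be
validated by parameter recovery without any external data. Its defaults
describe the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_true` / `n_background` / `n_contaminant` | 25 / 150 / 6 | roster sizes; ~180 identified proteins per experiment, a few dozen genuine interactors |
| `n_experiments` | 3 | pull-down experiments for cross-validation |
| `bait_intensity` | 1e9 | anti-bait LFQ mean of the bait (bait dominance); controls receive 1/50 of it (antibody-independent leak) |
| `interactor_enrichment` | 10 | fold-change of the anti-bait mean over the shared control mean for true interactors |
| `background_enrichment` | 1 | same fold-change for nonspecific binders |
| `lfq_cv` | 0.3 | σ of the natural-log intensity noise |
| `dropout_p` | 0.1 | probability that a true interactor's intensity in a channel is recorded as 0 |
| `psm_depth` | 300 | Poisson mean of the bait PSM per condition |
| `phospho_effects` | `a_up_d_down: (1.5, 0.5)`, `both_up: (1.6, 1.6)`, `both_down: (0.6, 0.6)`, `unchanged: (1, 1)` | per-class multipliers on the S2814A / S2814D PSM means |
| `abundance_range` | 2e5–5e6 | log-uniform per-protein control-channel mean |
| `psm_base_range` | 20–200 | log-uniform per-protein WT PSM mean for true interactors |

LFQ intensities are log-normal around class-dependent means; the IgG and
beads channels share one mean per protein, held constant across
experiments, so experiment-to-experiment variation enters only through
the noise draw — emulating parallel sample processing. PSM counts are
Poisson. True interactors are assigned to phospho-effect classes in
fixed fractions (60% `a_up_d_down`, 15% `both_up`, 15% `both_down`, 10%
`unchanged`), reflecting a study in which phosphorylation at the site
weakens most interactions. Dropout models stochastic missingness of
genuine signals and is therefore applied to true-interactor rows (any of
their three channels, never the bait); zeros in control channels of
background rows are not simulated, since for nonspecific binders a
missing control value is a data artifact the ratio method is known not
to be robust to, rather than a feature of the biology being emulated.
Contaminant rows carry `Krt*`/`Ig*` gene symbols so the
immunoglobulin/keratin filter removes them.

Random streams are split per `(seed, experiment_index, protein_index)`
using NumPy's seed-sequence mechanism, so adding proteins or experiments
never perturbs existing rows and every output is a pure function of the
parameters.

**What the generator does not emulate:** peptide-level evidence,
retention-time or m/z structure, intensity-dependent (left-censored)
missingness, correlated noise between channels, shared peptides between
protein groups, and batch effects between experiments beyond independent
noise. Passing recovery tests therefore demonstrates the pipeline's
logic under the stated generative assumptions, not its behavior on any
particular real dataset.

## Parameter recovery under the default conditions

`evaluate_recovery` compares pipeline calls to ground truth: sensitivity
is the fraction of true interactors called high-confidence (score ≥ 3),
specificity the fraction of background/contaminant proteins kept at
score ≤ 2 (absence from the score list counts as 0), and quadrant
accuracy the fraction of true interactors with a simulated directional
effect whose observed quadrant matches it. The acceptance suite runs the
default study at a fixed seed and requires sensitivity ≥ 0.9,
specificity ≥ 0.9 and ≥ 0.85 quadrant accuracy for the (1.5, 0.5) effect
class; the suite's observed values are ~0.92, ~0.96 and 1.0.

## Numerical and design choices

- **Strict inequalities** at the 1.5 enrichment cutoff and the 1.0
  quadrant threshold; ties are deliberately conservative (not enriched /
  unchanged).
- **Floor imputation before ratio formation**, applied to any zero
  channel. An anti-bait intensity of 1e7 over an all-zero control yields
  exactly 200; an all-zero row yields unit ratios and is flagged as
  fully imputed rather than dropped.
- **Protein identity** is the leading accession of a semicolon-separated
  group cell (the "majority protein" convention); duplicate accessions
  within a table are an error, not a silent merge.
- **Exact cancellation** in `wt_bait` mode as described above; the test
  suite asserts bit-exact equality with raw-count ratios on random
  tables.
- **Deterministic ordering** everywhere (input order preserved by
  readers and filters; scores sorted by score then accession) so diffs
  between runs are meaningful.
- Rows with unparseable numeric cells abort the read with the offending
  row named; silent coercion to NaN is never performed.

## Known limitations

- The enrichment score is a count, not a probabilistic interaction model
  (no SAINT/CompPASS-style likelihoods, no FDR on interactions); it
  inherits the resolution limits of a 0–6 integer scale.
- No statistical test is attached to the quadrant classification; with
  single-sample PSM counts per genotype, a ratio's departure from 1.0 is
  descriptive.
- LFQ ratios across experiments are compared without cross-experiment
  normalization beyond ratio formation itself, which assumes the
  control channels capture each experiment's background scale.
- The immunoglobulin/keratin patterns are prefix heuristics; unusual
  gene symbols beginning with `Igl`/`Igh` would be removed even if not
  immunoglobulin genes (pattern lists are configurable per run).
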