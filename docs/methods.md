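# Methods

## Problem setting

The package screens for ligands with plausible dual pharmacology across
two receptors by structural analogy: if a compound active at receptor 1
is highly similar to a compound active at receptor 2 under many
independent molecular representations, the pair is a candidate dual
chemotype. The pipeline wraps this core idea with bioactivity curation
upstream and selectivity / network-pharmacology triage downstream.

## Curation model

A bioactivity record is retained when (i) the assay organism and target
type match the configured requirements (defaults: *Homo sapiens*,
`SINGLE PROTEIN`); (ii) its assay description matches the role's
mode-of-action keywords; (iii) its data-validity comment is empty.
Mode matching is case-insensitive substring matching with veto
patterns — for the agonist role the default accepts `agonis` / `partial
agonis` and vetoes `antagonis`; for the PAM role it accepts `positive
allosteric` / `pam`. Keyword lists are configuration, not science: the
upstream databases describe assay intent in free text, so the defaults
are a starting point that users should adapt to their extract.

Deduplication keeps one assay type per compound by a configurable
priority (default EC50 > IP > Ki > IC50; the unitless cooperativity
factor log(αβ) is summarized separately) and replaces duplicate values
within the kept type by their arithmetic mean. Potency gates are
inclusive: EC50 ≤ 500 nM for role A; EC50/IP ≤ 1000 nM *or*
log(αβ) > 0 (strictly — a cooperativity factor of exactly 1 is no
potentiation) for role B. Concentrations are normalized to nM at parse
time (nM, µM, mM, M accepted; anything else is a per-record rejection
with a reason).

Structure standardization is salt stripping (largest organic fragment)
plus RDKit canonicalization, and is idempotent. Ionization/tautomer
enumeration at physiological pH is deliberately **not** performed: the
downstream fingerprints are 2-D and largely charge-insensitive, so the
lighter normalization changes nothing downstream while keeping the
stage dependency-free. This is a documented simplification, not an
approximation of a specific commercial protocol.

## Fingerprint registry

The default registry holds 13 binary fingerprints, all computed with
RDKit so results are bit-exact across runs:

| name | family | bits |
|---|---|---|
| maccs | structural keys | 166 |
| morgan_r2 / morgan_r3 | circular (atom identity) | 1024 |
| feat_morgan_r2 / feat_morgan_r3 | circular (pharmacophoric features) | 1024 |
| rdkit_path5 / rdkit_path7 | branched subgraph paths | 2048 |
| rdkit_linear6 | linear paths | 2048 |
| atom_pair | atom pairs | 2048 |
| torsion | topological torsions | 2048 |
| pattern | substructure pattern hash | 2048 |
| layered | layered substructure hash | 2048 |
| avalon | Avalon enumeration | 1024 |

The consensus logic is roster-agnostic; any set of specs can be
registered, and the hashed lengths (1024/2048) are recorded in each
spec for reproducibility. Two caveats follow from the roster being a
choice: (a) published hit counts obtained with a different 13-FP roster
will not reproduce bit-for-bit, since fingerprint implementations
differ across toolkits; (b) torsion-family fingerprints are empty for
molecules with fewer than four heavy atoms — the Tanimoto convention
below handles this.

Tanimoto similarity is c/(a+b−c) on set-bit counts; two all-zero
vectors score 0.0 (an undefined 0/0 in the formula; empty fingerprints
share no evidence of similarity). The vectorized cross-matrix path uses
an integer intersection mat-mul and is tested element-wise against the
scalar kernel and against RDKit's own Tanimoto.

## Threshold calibration

For each fingerprint, `n_pairs` random unordered compound pairs (no
self-pairs; with replacement across pairs) are drawn from a background
library and the (1 − α) quantile of their similarity distribution under
the **nearest-rank rule** (sorted values, index ⌈(1−α)·n⌉, no
interpolation) becomes the threshold. Defaults: α = 0.05,
n_pairs = 10⁵. Nearest-rank was chosen because it is exactly
reproducible and oracle-testable; at n_pairs = 10⁵ the seed-to-seed
variability of the 95th percentile is far below the ~0.05 similarity
granularity that matters here (tested).

The background defaults to the union of the two input ligand sets —
meaningful thresholds require the background to resemble the library
being screened. Reference thresholds calibrated on database-wide
samples (the published procedure used 10⁷ ChEMBL pairs) can be injected
verbatim through the JSON threshold-table interface, which records
threshold, n_pairs, seed and quantile rule per fingerprint.

## Consensus vote

Every cross-set pair is scored under all registered fingerprints; a
fingerprint votes when its similarity **meets (≥, inclusive)** its
threshold, and a pair passes at `min_votes` ≥ 3 of 13 by default. The
≥ 3 fingerprints must agree within a single pair; an alternative
accumulation semantics (a compound collects passing fingerprints across
different partners) is available behind `accumulate_votes=True`.
Candidate lists are the distinct compounds of each set appearing in any
passing pair. Evaluation is full |A|×|B| with no pre-screening; the
implementation is tested for exact equivalence against an explicit
double loop and for monotonicity in thresholds and vote count.

## Chemical-space analysis

MACCS keys feed three read-outs. (1) PCA of the pooled key matrix after
per-column standardization; zero-variance keys are dropped and logged,
and component signs are fixed by making each component's
largest-magnitude loading positive, so plots are reproducible.
(2) Mean Tanimoto similarities: intra-set means exclude the Tc = 1
self-diagonal (including it inflates the mean by 1/n and would blur
comparisons between sets of different size); cross-set means cover all
ordered pairs. (3) Overlap counts: a member of one set is counted when
its **maximum** similarity over the other set is ≥ 0.80 (inclusive) —
for counting purposes max-over-the-other-set and any-pair semantics
coincide. Scaffold grouping uses Bemis–Murcko frameworks (ring systems
plus linkers, substituents stripped); acyclic molecules share a
dedicated `acyclic` group.

## Selectivity filter

The window is off-target potency / on-target potency, both in nM, so
larger is safer; a candidate is excluded when any non-allowlisted
off-target record yields a window below 10 (configurable, must be > 1).
This orientation — requiring the candidate to be ≥ 10-fold more potent
at the intended target — follows standard selectivity usage.
P-glycoprotein is allowlisted by default (transporter binding is not
pharmacological promiscuity). Candidates without off-target records are
retained; qualitative-only flags annotate but never exclude. Off-target
data are consumed from a file, never fetched live, because database
query results drift.

## Network enrichment

Seed proteins are expanded by the `n_extra` non-seed nodes with the
highest **maximum** edge score to any seed (union-over-seeds
semantics — the per-seed alternative is a flag), ties broken
lexicographically so expansion is deterministic. Enrichment of the
expanded node set against GMT gene sets uses the upper-tail
hypergeometric probability P(X ≥ k) (delegated to SciPy's log-space
survival function; tested against exact rational enumeration for all
populations N ≤ 12) and Benjamini–Hochberg step-up FDR (statsmodels;
tested against the hand formula), with significance at FDR ≤ 0.05
inclusive. The background defaults to all nodes of the supplied edge
list and is overridable; terms with zero query hits are omitted.

## Synthetic benchmark

The generator emulates the structure of a dual-ligand screening
problem, not its biology:

* **Molecules** are template-assembled: ring-system cores (five shared
  families, four private per set) decorated with 1–3 substituents from
  a 14-fragment vocabulary at ring positions that can accept them.
  Template assembly guarantees valid, standardization-stable chemistry
  with controllable similarity — no generative model involved.
* **Planted pairs** (default 20% of `n_per_set` = 50, i.e. 10 pairs)
  share a core, sites and all but one substituent, the odd one swapped
  for a near analog (methyl→ethyl, F→Cl, ...). Decoys use set-private
  cores, so cross-set decoy similarity is low under every fingerprint.
* **Activity tables** give every ligand a passing record (cycling
  through edge cases: boundary potency at exactly the cutoff, duplicate
  values needing the mean, assay-type priority, µM units, positive
  cooperativity) and add dedicated failing compounds covering each
  rejection rule, so curation has a zero-discrepancy ground truth.
* **Off-target tables** make a chosen fraction (default 0.3) of
  candidates promiscuous by construction (window sampled in [1, 9))
  and include a P-glycoprotein record to exercise the allowlist.
* **PPI fixture**: a random scored graph (60 nodes by default) whose
  two seeds share ten high-scoring neighbors; the planted term is
  exactly that neighbor set, decoy terms are uniform samples.

All randomness flows from one seed; stage *k* uses
`numpy.random.default_rng([seed, k])`, so fixtures are independently
reproducible and byte-identical across runs.

What passing on this benchmark shows — and what it does not: it
validates the *machinery* (rule application, threshold semantics, vote
logic, statistics) and the qualitative behavior (planted analogs
recovered, decoys rejected at an α-consistent rate). It does not show
that real screening libraries separate as cleanly: real bioactivity
data have correlated assay noise, congeneric series, and activity
cliffs that template decoys do not emulate, and real background
libraries give higher, fingerprint-dependent thresholds.

## Problem sizes and numerical choices

Default analysis sizes — 50 compounds per set, 10⁵ calibration pairs
per fingerprint, 60-node networks — were chosen as the smallest sizes
at which the planted/decoy similarity modes are well separated and the
95th-percentile threshold estimate is stable to the third decimal;
everything scales linearly (calibration) or as |A|×|B| (screening).
Ties in the nearest-rank quantile are kept; all boundary comparisons in
the pipeline (potency cutoffs, votes, overlap cutoff, FDR cutoff) are
inclusive, matching their definitions above. Degenerate inputs
(empty sets, single-compound libraries, all-constant key columns) raise
typed errors rather than returning silent NaNs.

## Known limitations

* The 13-fingerprint roster is a documented stand-in; reproducing a
  published hit list requires the original roster and its thresholds
  (injectable via the threshold-table JSON).
* No 3-D, pharmacophore or count fingerprints; no tautomer/ionization
  enumeration; no stereo enumeration.
* Selectivity comparisons mix assay types when the input table does;
  the filter does not attempt like-for-like assay matching.
* Enrichment results depend on the supplied edge list and gene sets;
  no live database retrieval is performed by design.
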