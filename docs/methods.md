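# Methods

## The problem

Automated function prediction (AFP) assigns Gene Ontology (GO) terms to
proteins. How a method is *evaluated* changes the answer: cross-validation
(CV) mixes annotations from all time points, while a real deployment trains
on today's annotation database and is judged against annotations acquired
later. `afpbench` implements three evaluation protocols over a time-stamped
annotation corpus with cutoff year t1:

* **CV** — proteins are shuffled into k folds (default k = 5); each fold's
  complete annotation sets are predicted from the remaining proteins'
  complete sets. Time is ignored.
* **NA (Novel Annotations)** — train on the annotations available at t1
  (set A); test on the annotations acquired *after* t1 by proteins that were
  already annotated at t1 (set B).
* **NP (Novel Proteins)** — same training set A; test on the post-t1
  annotations of proteins that had none at t1 (set C). Training and test
  protein sets are disjoint.

Two exclusion rules define set B: a (protein, term) pair already present in
the propagated training set is never re-tested (even if it reappears with a
new evidence code), and a pair whose term has a strictly more specific
training annotation on the same protein carries no new information and is
dropped. Because the training set is ancestor-closed, the second rule is
implied by the first; both are applied explicitly and verified independently
in the tests.

## Ontology handling

Terms form a DAG per namespace (molecular function F, biological process P,
cellular component C). `is_a` and `part_of` edges are traversed as parent
edges; other OBO relationships are ignored, as are obsolete terms and
cross-namespace links. These are the common conventions of CAFA-style
pipelines; the underlying data does not pin them down further.

Curation filters, in order: keep only experimental/curated evidence codes
(EXP, IDA, IMP, IGI, IEP, TAS by default); drop namespace roots and
explicitly excluded categories (for real GO data the uninformative
'protein binding', GO:0005515); propagate by the true path rule; then drop
terms annotating fewer than `min_proteins` (default 10) distinct proteins.
The size filter is applied once, on the *propagated* set — the conservative
reading, since propagated counts are the ones the evaluation sees. Term
identifiers are opaque strings, so synthetic ontologies work everywhere.

Ground-truth annotations propagate as set closure (a protein annotated to a
term is annotated to all its ancestors below the root). Prediction scores
propagate by assigning each parent the maximum score among its descendants
and itself; both operations are idempotent, and both are validated against
exhaustive graph-enumeration oracles.

## Metrics

At threshold t a pair is predicted when score ≥ t. With N test proteins:

    P_pc(t) = (1/N) Σ_i TP_i/(TP_i + FP_i)
    R_pc(t) = (1/N) Σ_i TP_i/(TP_i + FN_i)
    F-max_pc = max_t 2 P_pc R_pc / (P_pc + R_pc)

A protein with no predictions at t contributes 0 to the precision average.
**This deliberately follows the plain over-all-N average rather than the
CAFA assessor's convention of averaging precision over covered proteins
only**; with full-coverage predictors the two coincide, otherwise this
variant is the stricter one.

Term-centric F-max computes per-term precision/recall over test proteins,
maximises the harmonic mean per term, and averages over terms with at least
one positive test protein (terms never predicted score 0; terms with no
positives are excluded and reported). Per-term AUC is the rank-based
(Mann–Whitney) ROC area with ties counting one half, cross-checked in tests
against a pair-counting oracle.

Thresholds default to the grid {0.01, …, 1.00}; an exhaustive sweep over
the distinct observed scores is available (`thresholds="observed"`) and is
what the oracle-equivalence tests use. F-max on the default grid is within
0.01 of the exhaustive value, and both are invariant under strictly
monotone score transforms.

**NA ground-truth masking.** Annotations known at training time are removed
from the NA test truth. For the affected (protein, term) cells the package
additionally *masks* the pair during evaluation — it is neither a true
positive nor a false positive — so a method is not penalised for
re-predicting established knowledge. Removal-only semantics (known pairs
count as ordinary negatives) is available via `mask_training=False`.

Test proteins are the proteins of the (propagated) test set; proteins whose
annotations all fall outside the evaluated term universe drop out rather
than contributing undefined 0/0 recalls. Cross-protocol comparisons are
restricted to the common term universe — the intersection of each setup's
annotated terms (train ∪ test).

## Predictors

* **GBA** (guilt by association, neighbour voting): score(p, j) = fraction
  of p's direct network neighbours annotated with j in the training set.
  Zero-neighbour proteins score 0. When a continuous kernel is supplied the
  network is its positive off-diagonal support (threshold configurable).
* **Node-degree classifier**: every term scored by the protein's degree,
  max-normalised into [0, 1]; a diagnostic for how much apparent accuracy
  multifunctionality alone explains. Rank metrics are unaffected by the
  normalisation.
* **Kernel kNN**: fraction of the k most kernel-similar training proteins
  (ties broken by stable kernel order, self excluded) annotated with the
  term; a light supervised baseline over the same kernels.
* **External score tables**: any method's predictions enter as
  protein/term/score rows (clipped to [0, 1], unknown terms dropped and
  counted, duplicates keep the maximum).

## Feature encodings

* **e-max homology features**: e-max_j(s) = max over training proteins s′
  annotated with j of −log10(e(s, s′)/10). The e-value divisor 10 is applied
  verbatim and is configurable; log base 10 is used (e-values are quoted in
  decades, and the base only rescales features uniformly). Aligner-reported
  e-values of 0 are floored at 1e-180; missing hits and sub-zero scores give
  feature 0.
* **Low-complexity features**: the amino-acid composition of the length-20
  window with the fewest distinct residues (ties → leftmost), over the 20
  standard residues.
* **Network adjacency**: binary interaction indicator vectors over a fixed
  protein universe; multiple networks concatenate, and the union of edge
  lists equals the entrywise OR of encodings.
* **Kernels**: linear kernels per feature block, cosine normalisation
  K(z1,z2)/√(K(z1,z1)K(z2,z2)) (unit diagonal, idempotent), combination by
  entrywise addition — identical to the linear kernel over concatenated
  features.

## Drift diagnostics

Per-term prevalence is the fraction of a set's proteins annotated with the
term; the discrepancy |p_tr − p_tst|/(p_tr + p_tst) measures train/test
label drift in [0, 1] (signed variant keeps direction). Terms absent from
both sets are excluded, not scored 0. CV discrepancy averages per-fold
tables across folds. Pearson correlation (Spearman behind a flag) relates
per-term AUC to per-term discrepancy; paired t-tests compare two protocols'
per-term metric vectors, with the zero-variance case reported as an exact
tie (p = 1 for zero mean difference, p = 0 otherwise, with a warning).

In the pipeline's AUC-vs-discrepancy correlation, only terms with at least
10 positive test proteins enter (`MIN_AUC_SUPPORT`): an ROC area estimated
from 3–5 positives is dominated by sampling noise and can flip the sign of
the correlation on small corpora.

## The synthetic corpus generator

The generator produces desk-scale corpora carrying the statistical
structure the protocol comparison depends on. Defaults (chosen once, as a
qualitative miniature of a real species corpus that regenerates in
seconds): 1000 proteins, 150 terms, DAG depth 5 with mean branching 3 and
15 % diamond motifs, years 2000–2014 with cutoff 2009.

* **Annotation accrual**: each protein receives Poisson(3) annotation
  events per era (pre- and post-cutoff), so a drift-free corpus accrues
  comparably many annotations on both sides of the cutoff. 20 % of
  proteins are designated novel a priori: no pre-cutoff events, at least
  one post-cutoff event (set C is never empty).
* **Category drift**: each term's sampling odds change by the factor
  `drift_rate` per year (default 1.5), with a random direction per term —
  the strong annotation-practice bias that separates temporal protocols
  from CV. `drift_rate=1` switches it off.
* **Specificity shift**: term log-odds additionally tilt toward deeper
  terms over time (`specificity_shift`, default 0.05/year), emulating the
  tendency of later annotations to be more specific.
* **Functional coherence**: each protein has 2 anchor branches of the
  ontology whose terms are up-weighted ×9 in its event sampling. Without
  this modularity a protein's future annotations would be independent of
  its past ones and no network- or homology-based predictor could have
  genuine per-term signal; with it, network neighbours and homologs share
  function, which is the premise of GBA.
* **Network**: edge rate grows with the number of shared pre-cutoff terms
  and — scaled by `degree_coupling` — with the pair's annotation counts,
  reproducing the positive degree–multifunctionality correlation of real
  association networks (r > 0.3 at the default coupling).
* **Similarity**: pairs hit with probability equal to the Jaccard overlap
  of their propagated term sets; e-values are log-uniform in
  [1e-30, 1e-3], tighter for higher overlap (identical term sets always
  hit at ≤ 1e-10).

Everything is deterministic under the configuration seed (independent
integer-seeded RNG streams per component, no iteration-order dependence).

**What the generator does not emulate**: real sequence content (similarity
is sampled from functional overlap, not alignments), the size and shape of
the full GO (tens of thousands of terms, three namespaces), literature
co-mention features, evidence-code structure beyond uniform sampling, and
species-specific annotation depth. Passing tests therefore demonstrate the
correctness of the protocols and metrics and the qualitative mechanics of
annotation drift — not performance levels transferable to real corpora.

## Known behaviour of the no-drift null

With drift and specificity shift off, pre- and post-cutoff sampling
distributions are identical, yet two residual effects remain in the NA
protocol and are worth understanding when interpreting null experiments:

1. The NA exclusion rules create a *structural* prevalence deficit — a
   protein cannot newly acquire a term it already holds, so saturated and
   community-preferred terms have p_tst < p_tr. Together with the
   sampling-noise floor of rare terms (E|p_tr−p_tst|/(p_tr+p_tst) ≈ 0.1 at
   2000 proteins and 150 terms), the mean no-drift NA discrepancy settles
   near 0.12–0.13 rather than 0. On well-populated terms (prevalence
   ≥ 0.1) the no-drift CV discrepancy is below 0.05 and shrinks with
   corpus size.
2. CV F-max remains higher than NA F-max even without drift (≈ +0.2 for
   GBA at the default sizes) because the tasks differ structurally: CV
   tests full annotation profiles, NA only the sparse novel residue with
   the easy, already-known pairs masked. The temporal protocols are harder
   than CV for reasons that include, but are not exhausted by,
   distribution drift.

## Problem sizes used in tests and reproduction

Unit and property tests run on hand-built DAGs (≤ 6 terms) and random
structures (≤ 20 terms, ≤ 10 proteins) against brute-force oracles; the
protocol-ordering checks run the full pipeline on five 1000-protein
corpora; null experiments use ten 2000-protein corpora. The complete suite
and the reproduction script each finish in a few minutes on one CPU.
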