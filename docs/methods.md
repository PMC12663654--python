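# Methods

This note documents the models, rules and numerical choices behind
`dicer-atlas`, and what the synthetic study conditions do and do not
establish about real proteome data.

## Problem setting

Dicer (Dcr) proteins cleave double-stranded RNA into small RNAs. A
canonical Dicer carries, N- to C-terminal: three helicase subdomains
(DEAD/DExD-box, ResIII, Helicase-C), the dimerization domain DUF283, the
3′-overhang-binding PAZ domain, a tandem pair of RNase III domains
(IIIa/IIIb) and a dsRNA-binding domain (dsRBD). In fungi most Dicers lack
one or more of these at the sequence level, and the package implements
the rule system used to survey that diversity from profile-HMM hit
tables, together with the downstream evolutionary and structural
analyses.

## Dicer gate and category rules

Hits are read from HMMER `--domtblout` tables (envelope coordinates,
per-domain independent E-values) or an equivalent six-column TSV. The
detection threshold is E-value ≤ 10⁻³, inclusive. Overlapping hits on
one protein are resolved greedily by ascending E-value (ties: higher bit
score, then smaller start); overlap means any shared residue. Envelope
rather than alignment coordinates are used because envelopes bound the
full homologous region, which matters for region extraction.

A protein passes the **Dicer gate** iff it retains ≥ 2 non-overlapping
RNase III hits and at least one RNA-binding domain (any helicase
subdomain, DUF283, PAZ or dsRBD). "Tandem" is implemented as at least two
retained RNase III hits with the 5′-most taken as IIIa; no adjacency
constraint is imposed because none is defined by the rule system.

Categories are driven by the set *M* of missing units among
HEL (= any helicase subdomain), DUF283, PAZ, dsRBD:

| M | category |
|---|----------|
| ∅ | canonical |
| {dsRBD} | non-canonical A |
| {PAZ} | non-canonical B |
| {HEL, dsRBD} | non-canonical C |
| {PAZ, dsRBD} | non-canonical D |
| anything else | non-canonical E |

E is deliberately a catch-all: A–D are defined by exact patterns, and
every remaining pattern (all |M| ≥ 3 patterns and any pattern involving
DUF283) falls to E, which keeps the six categories a partition of the
gate-passing space — verified by enumerating all 2⁴ unit patterns.
Helicase-subdomain completeness (all three present) is recorded as
metadata but never drives the category. Percentages are rounded half-up
to one decimal.

Terminal lengths use the two most conserved landmarks: the N-terminal
length is the residue count before DUF283, the C-terminal length the
count after the second RNase III hit (IIIb). Annotation duplicates
(same species, byte-identical sequence, same UniProt accession) collapse
to the lexicographically smallest accession; same-locus entries with
differing sequence are kept as isoforms.

## PAZ regions

Where a PAZ hit exists, the cPAZ region is its envelope. Where it does
not, the fungal PAZ (fPAZ) is the inter-domain region between DUF283 and
the *first* RNase III hit (IIIa is upstream by definition), i.e.
`DUF283.end + 1 … RNaseIIIa.start − 1`; empty spans yield no region. No
minimum-length filter is applied — downstream alignment tooling is the
right place for such a decision.

## Similarity networks

Sequence mode: edges require identity ≥ 50 % and coverage ≥ 80 % on
*both* sequences (the conservative symmetric reading; the coverage
direction is otherwise ambiguous). Structure mode: models must have mean
pLDDT ≥ 70 (CA B-factors), asymmetric TM-scores are averaged, and edges
require TM ≥ 0.9. All thresholds are inclusive. Clusters are connected
components ordered by descending size; hubs are maximum-degree members
with lexicographic tie-breaks. Singletons are reported and flagged
rather than silently dropped, so the retained-node count is always
auditable.

## ER Mk model and ancestral reconstruction

cPAZ presence/absence is modeled as a two-state continuous-time Markov
chain with equal rates (ER): over a branch of length *t*,
P(switch) = (1 − e^(−2qt))/2. The likelihood uses Felsenstein pruning
with per-node rescaling (stable on multi-thousand-tip trees); the rate
MLE is a bounded 1-D maximization over q ∈ [10⁻⁸, 100/mean-branch-length]
with tolerance 10⁻⁸; marginal node probabilities come from the standard
inside/outside pass with per-node renormalization of the outside vector
(which cancels in the marginal). The root prior is uniform (0.5, 0.5) —
the ER stationary distribution, consistent with midpoint rooting of a
reversible process. Zero-length branches give identity transition
tables; polytomies are handled by the general recursion without
binarization. When all tips share one state the MLE sits at the lower
bound and is flagged rather than reported as a real rate.

Correctness is established two ways: exhaustive enumeration over
internal-node states on trees of ≤ 5 tips (agreement to < 10⁻¹⁰), and
parameter recovery on simulated characters (q = 0.5 on pure-birth trees;
median absolute error decreases over 50 → 200 → 800 tips).

## Structure metrics

Mean pLDDT is the arithmetic mean of CA B-factors; only the first chain
of the first model is read, as single-chain Dicer predictions are the
use case. The molecular-ruler metric is the Euclidean CA–CA distance
between the first residue of the PAZ/fPAZ segment and the first residue
of the RNase IIIa segment ("N-terminus of the domain" = first residue of
the interval; no finer definition is warranted by the inputs). Note that
PDB fixed-format coordinates carry three decimals, so distances measured
through written files are exact to ~10⁻³ Å; in-memory transforms
preserve distances to floating-point precision.

## HMM evaluation

Sensitivity is TP/(TP+FN) over a labeled positive set; precision is
reported only when TP+FP > 0 and is otherwise undefined (never coerced
to 0 or 1). Detections are a plain id set produced by any external
search engine at the caller's threshold; the module never runs the
search, which keeps the metric testable offline.

## Synthetic study conditions

The generator plants, per protein, a category-consistent domain layout
with realistic segment sizes (e.g. DEAD 150–200 aa, RNase III 70–110 aa,
linkers 10–120 aa), plus Poisson-distributed decoy hits with E-values
strictly above 10⁻³ placed only in inter-domain gaps — decoys never
overlap planted segments, so classifier ground truth is unambiguous.
The default category mix follows the observed fungal category shares
scaled to 85 %, with 15 % non-Dicer decoy proteins. Proteins are grouped
into proteomes of 1–3 and assigned phyla at survey-like frequencies.
Sequences are i.i.d. uniform over the 20 amino acids; the classifier
uses only coordinates and lengths. Similarity tables plant clusters
whose within-identity jitters upward and between-identity downward from
the plan values, so the 50 % threshold separates them exactly. Trees are
pure-birth (Yule) with unit birth rate, giving expected total branch
length of roughly the tip count.

Consequently, passing tests show the *rules and algorithms* are
implemented correctly and are recoverable under clean planted signal;
they do not show robustness to real-proteome phenomena the generator
deliberately omits: homologous decoys overlapping true segments,
fragmented gene models, compositional bias, indels, or structure realism
beyond planted anchor distances.

## Problem sizes

The default verification workloads are sized to run on one CPU in a few
minutes: 500-protein proteomes for recovery, 100 trees of ≤ 5 tips for
enumeration checks, 50 replicates each at 50/200/800 tips for rate
recovery, 100 random graphs of ≤ 40 nodes for the clustering oracle.

## Known limitations

- The dsRBD-missing share reported per-protein in the original survey
  is not derivable from category counts alone (dsRBD detection varies
  within category E) and is not reproduced here.
- Whether thresholding should use full-sequence rather than per-domain
  E-values is ambiguous in the rule system's provenance; the per-domain
  value is used.
- The fPAZ definition does not trim the connector helix; coverage
  direction in published similarity cut-offs and TM normalization
  (shorter vs longer chain) are likewise unspecified upstream, and the
  package picks the symmetric/averaged conventions documented above.
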