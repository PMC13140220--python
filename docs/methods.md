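# Methods

This note documents the models, numerical choices and design decisions behind
`bblkit`, and what the synthetic studies do and do not demonstrate.

## Likelihood model and fitting

Sequences evolve on a fixed rooted topology under a reversible continuous-time
Markov chain. Three model kinds are implemented:

- **Nucleotide GTR+Γ** (the primary reconstruction model): six
  exchangeabilities (GT fixed at 1), stationary frequencies taken from the
  observed data (with a 0.5 pseudocount), discrete-gamma rate variation.
- **JTT+Γ** over amino acids, with the published Jones–Taylor–Thornton
  exchangeabilities embedded as constants; frequencies default to the observed
  ones (+F).
- **M0 codon model** over the 61 sense codons of the standard code with F1×4
  frequencies computed from the observed nucleotide composition; free
  parameters κ (transition/transversion) and ω (nonsynonymous/synonymous).

All generators are normalized to one expected substitution per site, so branch
lengths are in substitutions per site of the respective state space.
Transition matrices use the symmetric eigendecomposition available for
reversible chains (exact for any branch length); partial likelihoods are
rescaled per node, so trees of any size stay in range. Site patterns are
compressed once per partition. Gaps, `N`, and any character outside the model
alphabet (including stop codons observed in pseudogenized tips) enter as
missing data — a partial likelihood of 1 over all states.

**Partitioning.** Protein-coding alignments use the standard codon-position
partition (positions 1+2 vs 3). Each class carries its own exchangeabilities,
frequencies and gamma shape α, plus a class rate multiplier constrained to a
column-weighted mean of 1; branch lengths are shared across classes. Fully
unlinking branch lengths per class would double the parameter count without
benefit on a fixed topology; the multiplier captures the dominant effect (the
~2–3× faster third position).

**Optimization.** `fit()` alternates (i) one L-BFGS-B pass over the
log-transformed free parameters (exchangeabilities, α, κ/ω, class rates) and
(ii) one Brent pass over each branch length in postorder, bounded to
[10⁻⁸, 10] substitutions/site, until the round-to-round improvement falls
below 10⁻⁶ log-units or `max_rounds` is reached (a `ConvergenceWarning` is
emitted in the latter case; the best-found state is returned). For the
protein and codon models the default ensemble path reuses the
nucleotide-fitted branch lengths and optimizes a single tree scale together
with the model parameters (`scale_only=True`); this keeps the 61-state codon
fit desk-scale while leaving full per-branch optimization available.

**Discrete gamma.** Category rates are the means of `ncat` equal-probability
bins of Gamma(α, α) (ncat = 5 by default), floored at 10⁻⁸ so that a
degenerate category cannot produce an exactly-impossible site pattern during
optimization.

**Marginal posteriors.** Empirical-Bayes marginal posteriors at a named
internal node are computed by the inside–outside recursion, mixing gamma
categories by their per-site posterior weight. For reversible models this is
identical to rerooting at the query node. MAP ties are broken by fixed
(alphabetical) state order and always flagged ambiguous. Joint (max-posterior
path) reconstruction is out of scope; all reported ancestors are marginal,
which is what resurrection pipelines consume. Where a workflow calls for a
fully Bayesian reconstruction (e.g. MrBayes with model averaging), this
package deliberately substitutes empirical-Bayes marginals under ML-fitted
GTR+Γ: it is deterministic and desk-scale, and on densely sampled,
low-divergence gene families the per-site MAP states of the two approaches
coincide at the vast majority of positions.

## Curation rules

- **Ancestral gaps.** Gap-containing columns are grouped into maximal blocks
  with identical tip presence/absence patterns (no fixed window). Each block
  is a binary character whose most-parsimonious state set at the query node is
  found by inside–outside Sankoff DP (verified against exhaustive search).
  Equal-cost ties resolve to *absent* — the shorter ancestor — with a warning,
  which matches how inference-artifact gaps (insertions private to pseudogenes
  or outgroups) are conventionally removed. The mask must respect codon
  boundaries for the curated sequence to stay in frame; scripted indels in the
  generator are codon-aligned by construction.
- **Ambiguity threshold.** A state is kept iff its posterior is ≥ 0.6;
  equality keeps (the source rule states "above 0.6 were kept" and assigns
  "below 0.6" to ambiguous, leaving equality unspecified — equality-keeps is
  this package's convention and is logged). Flagging is monotone in the
  threshold (property-tested).
- **Resolution order.** (1) all codon-resolved models agree → consensus;
  (2) alternatives synonymous → MAP ("silent"); (3) missense → ranked
  amino-acid preference policy per reference position. The policy is always an
  explicit user-supplied configuration, never an implicit heuristic: the
  qualitative judgments of the original curation (functional relevance,
  phylogenetic pattern) cannot be reproduced algorithmically, only recorded.
  In pipeline mode missense sites without a policy entry keep the MAP state
  with a logged fallback; library callers get an error by default.
- **Replayability.** `assemble_ancestor` writes an audit record per ambiguous
  codon; `replay` reconstructs the curated sequence from MAP states + audit
  trail and is asserted bit-exact in tests.

## Regions and hybrids

Numbering is full-length THCAS preprotein numbering (residue 1 = initiator
Met). Insertion columns relative to the reference are labelled anchor+letter
(e.g. `358a`). The ASA-loop is residues 354–380 by definition — a 27-position
span (the span is used as stated even though it is sometimes described as 26
residues; the discrepancy is flagged rather than resolved). Distance-based
classification defaults: FBS = any heavy atom ≤ 4.5 Å from any FAD atom (and
not in the SBR); the SBR's distance component uses ≤ 6 Å to the declared
cavity reference (a bound ligand, an explicit centroid, or by default the FAD
isoalloxazine ring, over whose re-face the substrate cavity sits). No cutoffs
are canonical — "may contribute to shaping the cavity" is inherently
qualitative — so the table-loading path, which bypasses all distance logic, is
the default in the pipeline and the only path guaranteed to reproduce a given
published annotation. Structure reading is plain coordinate parsing (first
altloc, heavy atoms only) via biotite.

Hybrids realize protein-level edits at codon level: substituted or inserted
residues copy the donor's codon (traceable nucleotide provenance); when no
donor CDS is available, the most frequent codon for that residue in the
backbone gene is used. Ordered multi-donor layers are supported (later layers
override earlier ones at the same column), which expresses
reverse-engineering designs that undo one mutation set and add another.
`diff → apply-all` is the identity from backbone to donor protein
(property-tested on 100 random pairs).

## Assay quantification

Specific activity = Σ product (µmol L⁻¹) / (t[min] · c_enzyme[g L⁻¹]),
replicates aggregated as mean ± sample sd (n−1), triplicates by default.
Selectivity fractions use replicate-summed concentrations of THCA, CBDA and
CBCA only — unidentified trace products are outside the table and hence the
denominator. Optima report the argmax level; contiguous levels within 5% of
the maximum form the reported range, and maxima at the series boundary are
flagged. Michaelis–Menten fitting is deliberately excluded: CBGA's low
aqueous solubility makes K_m estimation unreliable, which is why standardized
specific-activity assays are the comparison of choice for these enzymes.

## Synthetic studies

The generator (`bblkit.simulate`) emulates the structure of a curated
oxidocyclase dataset, and its defaults are the packaged study conditions:

- **Topology:** 15 tips — an outgroup pair, a three-tip "clade H" grade, and a
  recent three-subclade radiation — with named internal nodes HCa, Ca and
  A1A2a mirroring the ancestor definitions (MRCAs of clade H + the
  cannabis-specific clade, of the cannabis-specific clade, and of the
  THCAS/CBCAS subclades). Root-to-tip height ≈ 0.21–0.24 substitutions/site,
  with subclade divergences of a few percent, like the real gene family.
- **Sequences:** 536 core codons (the full-length preprotein scale; scaled-down
  lengths keep the event structure at proportional positions). GTR with
  elevated transitions (AG = CT = 4), π = (0.31, 0.19, 0.22, 0.28), α = 1
  (matching the nucleotide model reported for these data), 5 categories,
  third-position rate ≈ 1.9× positions 1+2. Root codons are drawn
  stop-free; stops may still arise along branches, as in real pseudogenizing
  families, and are treated as missing by the protein/codon models.
- **Indels:** scripted, not stochastic — one 4-codon insertion on the branch to
  Ca (reference residues 359–362 at full scale) inherited by the entire
  cannabis-specific clade, plus a 2-codon insertion private to a pseudogene
  tip. Scripting keeps the truth exact; realistic indel length distributions
  are a non-goal.
- **Pseudogenes:** two tips carry 1-nt frameshift deletions re-padded with `N`
  (the standard pre-processing that keeps pseudogenes codon-aligned).
- **Assays:** the characterized enzyme panel's activities and selectivities
  (THCAS 50 µmol·min⁻¹·g⁻¹ at 95/0/5; A1A2a 84% relative at 87/0/13; Ca 50%
  at 60/30/10; CBDAS 12% at 3/89/8) serve as generator truth under the
  standardized conditions (30 µg mL⁻¹ enzyme, 75 µM CBGA, 30 min, pH 5,
  30 °C), with 2% relative Gaussian noise truncated at zero and a substrate
  cap. pH and temperature profiles peak at 5.5 and plateau at 45–50 °C.
- **Randomness:** one seed; independent spawned streams per component
  (sequence evolution, insertion content, assay noise), so outputs are
  bit-reproducible and component-independent.

**What passing tests show — and don't.** The generator matches the inference
model family (GTR+Γ along a tree), so recovery results validate the
machinery, not model adequacy on real data: real alignments carry alignment
error, selection, recombination and model misspecification that the generator
deliberately omits. Wet-lab quantities (activities, selectivities, expression)
are inputs to the assay simulator, not reproducible outputs.

**Recovery and calibration.** Under the study conditions, site-level MAP
recovery at the named ancestors is ≥ 95% and the mean maximum posterior
tracks realized accuracy to within a few percent (the reconstruction is
calibrated). Recovery at a node depends on the information around it, not
only on tree height: on a sparse 8-tip tree whose root sits behind two long
(0.12) basal branches at height 0.24, root recovery is ~0.89–0.94 — with the
mean posterior agreeing, i.e. the engine is honest about it — while densely
sampled 16-tip trees give ≥ 0.95 up to height ≈ 0.2. The packaged recovery
check therefore uses a 16-tip tree of height 0.15, and additionally asserts
calibration, which is the substantive invariant.

## Problem sizes

The test suite runs scaled-down studies (120 codons for the shared pipeline
fixture; 1000 codons for the recovery check; ≤ 6 taxa for all
exhaustive-oracle comparisons). `scripts/acceptance.py` uses 250 codons and
15 tips with the full JTT/codon-M0 consensus — about a minute on one CPU.
These sizes are the package's chosen study scale; all algorithms are
O(sites × nodes × states²) per likelihood evaluation and run the full-length
study (536 codons) in a few minutes.

## Known limitations

- No topology search, no MCMC: the tree is an input, and Bayesian
  reconstruction is approximated by empirical-Bayes marginals (see above).
- PAML-style `Mgene = 4` partition linkage is replaced by proportional branch
  lengths with per-class rate multipliers.
- The codon model is M0 with F1×4 only; no site-class ω mixtures.
- Partial nucleotide ambiguity codes (R, Y, ...) are treated as fully missing.
- Identity percentages exclude columns gapped in either sequence, and each
  maximal gap run counts as one indel event; published identity figures may
  use other conventions (signal-peptide trimming, terminal-gap handling), so
  small discrepancies against externally computed percentages are expected.
- Distance-derived region annotation depends on the chosen cutoffs and on the
  coordinate file; only table-loaded annotations are guaranteed to match a
  published region assignment.
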