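# Methods

This note documents the models, conventions, numerical choices and
simulation designs behind `aarcode`, and what the passing test suite does
and does not demonstrate about real data.

## Repeat detection and presence semantics

A homopolymeric amino-acid repeat (AAR) is a maximal contiguous run of one
amino acid with length ≥ `min_len` (default 4, a global configuration
parameter). The low threshold captures repeats at every stage of their
expansion/contraction cycle, including short remnants of fragmented
("cryptically simple") repeats; no mismatch tolerance is applied — an
interrupted repeat is two runs.

Every downstream statistic is **presence/absence per protein**: a protein
either contains at least one qualifying run of X or it does not. Run
counts and run lengths never enter the statistics; this deliberately
measures which "knobs" a protein carries, not how far each is turned.

Two detection paths exist: a per-sequence linear scan (the reference
semantics) and a vectorized pass over a concatenated byte array used for
simulation-scale proteomes. They are asserted equal on random inputs by a
property test; the scanner is additionally checked against an independent
regular-expression oracle on 10⁴ seeded sequences of lengths 1–2000.

**Sanitization.** FASTA input is upper-cased; characters outside the
canonical 20-letter alphabet (X, U, B, Z, J, O, stops, gaps) are either
rejected or dropped. Dropping records the deletion position, and the
scanners treat those positions as hard run boundaries: a removed character
always terminates a run, so sanitization can never fabricate a repeat that
was absent from the raw sequence (the conservative choice). Coordinates
are 0-based half-open internally.

## The parameter system

With `PERCENT_SCALE = 100` (a single global constant asserted in tests),
%X₄ = 100·n_X/N, %(X₄+Z₄) = 100·n_XZ/N, RR(X₄/Z₄) = %X₄/%Z₄ and
OV(X₄+Z₄) = %(X₄+Z₄)/(%X₄)². OV magnitudes depend on the percent
convention — a fraction-scale implementation would differ by 100× — but
every rank-based downstream step (Spearman clustering) is provably
invariant to the choice, which a test verifies explicitly. Ratios with a
zero denominator are assigned exactly 0. Matrix rows, columns and feature
names use the fixed alphabetical one-letter order A,C,D,…,Y; the full
feature vector is 400 RR entries then 400 OV entries, row-major. RR
diagonal entries (identically 1) are retained in the 800-length vector —
they are removed later, as constant rows, by the clustering preprocessing
rather than by the parameter system.

Taxon summaries (m%X₄, mRR, mOV) are element-wise arithmetic means over
member species, with SEMs (reported as 0, flagged, for single-member
taxa).

## Contingency statistics

All screens reduce to 2×2 tables. χ² uses the standard closed form
(with 1 df); the Yates continuity correction is off by default and enabled
only where an analysis explicitly asks for it. Tables with a zero margin
are untestable and are excluded from screens with a logged flag, as are
associations with an empty group or set. Cells with expected counts < 5
are flagged (`low_expected`) but still tested with χ² — fidelity to the
method as practiced — with Fisher's exact test available as an option.

Benjamini–Hochberg runs **within** each screen family (the 190 pairs; the
set of group×(sub)cluster associations) at q = 0.05 by default;
cross-family correction is out of scope. The fold for an association is
observed/expected for the focal cell; fold enrichment of a set within a
group is (|group∩set|/|group|)/(|set|/N).

For interactome assortativity the per-AAR statistic is the fraction of the
distinct interactors of X-bearing focal proteins that bear X, normalized
to the proteome-wide X-bearing fraction, with a 1-df goodness-of-fit χ²
against that baseline; the edge-level statistic compares the fraction of
focal-incident edges whose endpoints both bear an AAR against the squared
marginal bearing fraction (independence null at the node level — the
appropriate null unit is genuinely ambiguous, and node-level is the
documented default).

## Clustering and trees

Feature tables hold parameters as rows ("genes") and species/taxa as
columns ("arrays"). Preprocessing drops constant rows (e.g. the RR
diagonal), then iterates to a fixed point: center rows by mean, scale rows
to unit sum of squares, scale columns to unit sum of squares. A single
pass of these three steps is not idempotent (column scaling perturbs row
means); iterating to convergence (tol 1e-10, cap 100) makes the operation
exactly idempotent and changes rank-based distances negligibly.

Distances are d = 1 − Spearman ρ (average ranks for ties); constant
vectors are an error naming the offender. Agglomeration is average
linkage (UPGMA-style on the given, generally non-ultrametric distances),
with labels sorted lexicographically first so ties break toward the
lexicographically smallest member on every platform. Dendrograms over
species are read as unrooted topologies (root degree-2 node suppressed,
heights discarded) and compared by Robinson–Foulds distance — the
symmetric difference of nontrivial bipartition sets — with "correct tree"
defined as RF = 0. An independent brute-force agglomeration oracle
(n ≤ 7) and an independent bipartition library check these paths.

PCA standardizes variables, extracts components by SVD, and applies an
in-house varimax rotation (iteration cap 25 by default); the varimax
objective is verified never to decrease.

## Random-tetrapeptide (RND₄) controls

Control sets are 20 non-homopolymeric tetrapeptides built either by
residue-level reshuffling of the 80 residues of the 20 homopeptides
(preserving overall composition exactly) or by anchoring each peptide with
one of the 20 letters and drawing three uniform residues. Residue-level
(not peptide-level) reshuffling is the only reading that produces mixed
peptides rather than reproducing the homopeptides. Draws yielding a
homopolymeric tetrapeptide are rejected — a control must not contain the
test pattern; whether the original analyses rejected such accidents is
unstated, so the rejection rule is a documented choice here. Five
replicate sets per scheme (labels a–e, f–j) use independently derived
seeds. Control presence is exact substring matching, and everything
downstream (parameters, clustering) is byte-for-byte the same code path.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes with known
ground truth. A synthetic proteome plants per-protein AAR presence
(independent Bernoulli p_X; letter-disjoint pairs can receive an exact
joint draw with P(both) = θ·p_X·p_Z and preserved marginals, so the
planted co-occurrence fold is exactly θ), then writes i.i.d. background
sequence from a database-average composition and inserts one run per
selected letter (length 4 + Poisson(1)) at a uniform position, avoiding
previously planted intervals where possible. Accidental background runs
are deliberately not suppressed — the scanner sees sequence, not intent —
and their per-protein rate is bounded by (L−3)·f_X⁴.

Defaults chosen once: protein length ~ Normal(300, 100) truncated at 60;
database-average residue frequencies; presence probabilities of 0.15/0.12
for the developmentally enriched letters and 0.02 background
(`DEFAULT_P_INSERT`), or a uniform 0.15 (`UNIFORM_P_INSERT`) where every
pairwise table needs valid χ² expected counts.

**Clade drift.** A clade evolves parameters root→leaves by a seeded
Gaussian random walk with sd `drift_scale` per unit branch length, applied
to logit(p_X) for the 20 marginals and to atanh(ρ_XZ) for all 190 pairwise
associations of a Gaussian copula over the presence indicators (a smooth
monotone reparameterization of each pair's log joint-odds; thresholding
the latent Gaussian preserves every marginal exactly; the correlation
matrix is projected to the PSD cone by eigenvalue clipping). Leaves then
realize presence matrices and, optionally, full sequences.

**Annotations.** Planted fold enrichments solve the inclusion
probabilities so the expected term size and the expected fold equal their
targets exactly (p_in = e·S/N; naive odds multiplication would bias the
realized fold low for non-negligible group sizes). **Networks.** Edges are
sampled with probability β·α^(endpoints share the AAR), with β solved for
the target mean degree; α is an edge-odds boost.

What the generators do *not* emulate: real protein evolution
(substitutions, indels, domain architecture), codon-level slippage,
length/usage covariation, GO term overlap structure, or scale-free degree
distributions. Passing tests therefore demonstrate that the statistics
recover the structures they are defined to measure, at realistic sizes —
not that real proteomes contain those structures.

## Simulation study designs

Problem sizes were fixed as the package's own validation design:

- **Screen calibration**: 200 null seeds × 2000 proteins, uniform
  p = 0.15 (so all 190 tables have expected counts ≥ 5). The calibrated
  quantity is the raw per-test type-I rate at level q (≈ q); the
  BH-corrected rejection fraction respects the FDR bound. The family-wise
  "any rejection" rate approximates q for the pairwise screen; for the
  set-enrichment screen it is additionally sensitive to χ² far-tail
  approximation error and is reported rather than bounded.
- **Power**: a θ = 5 joint-odds boost for (A, G), 100 seeds × 5000
  proteins.
- **Fold-enrichment recovery**: e = 3, term size 500, N = 10 000, mean of
  5 replicates.
- **Assortativity recovery**: α = 3, 2000 nodes, bearing fraction 0.02,
  mean degree 6, focal = 20 sampled bearers, mean over 40 seeds. The
  set-based interactor-proportion estimator converges to α only in this
  sparse regime: with bearing fraction p the per-edge proportion is capped
  at α/(αp + 1 − p), and deduplicating the interactor set attenuates it
  further as the focal set grows — mirroring the realistic situation of a
  small curated panel inside a large proteome.
- **Clade recovery**: 9 leaves, 3000 proteins/leaf, drift 1.5, 50 seeds.
  The reference tree is ultrametric (time-scaled, total depth 0.05
  drift-time units): with all leaves at equal depth, the expected
  correlation between two leaf profiles is a function of divergence time
  alone, which is exactly the regime average-linkage clustering
  reconstructs — the analogue of using a real, clock-scaled phylogeny.
  Recovery clusters the OV (co-occurrence) parameter block: the 400 OV
  features carry the full 210 drifting dimensions (20 marginals + 190
  pairwise associations), whereas the RR block is a rank-19 function of
  the marginals whose walk noise otherwise dominates the distance
  estimate. Restricting to an informative parameter family mirrors the
  established practice of excluding low-signal parameters (e.g. rare,
  weakly correlated repeats, or the signal-free RR diagonal) before
  clustering. Tetrapeptide-control features computed on the *same*
  sequence proteomes go through the identical pipeline as the contrast.

## Known limitations

- Pairwise association in `ProteomeSpec` is exact only for letter-disjoint
  boosted pairs; arbitrary interaction structure is available only through
  the copula used by clade generation, where the pairwise joint odds are
  controlled approximately (monotonically) rather than exactly.
- χ² screens on sparse tables (expected < 5) are anti-conservative in the
  far tail; they are flagged, and Fisher's exact test is available, but
  the default remains χ² for methodological fidelity.
- The interactome assortativity normalization assumes the presence map
  covers the whole proteome; proteins absent from it count as bearing
  nothing.
- Ortholog presence tables include partial sequences as-is; absence in a
  taxon can reflect sequence incompleteness, and empty ortholog sets are
  reported missing, never 0.
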