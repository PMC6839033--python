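# aarcode

Quantitative analysis of homopolymeric amino-acid repeats (AARs) in
proteomes: detection, combinatorial statistics, functional enrichment,
interactome assortativity, and alignment-free phylogenetic profiling.

## The problem

Homopolymeric repeats — polyalanine, polyglutamine and the other 18 — are
abundant in developmental proteins (HOX, FOX, SOX and related transcription
factors), where their expansion and contraction can tune morphology and
behavior. Whether they form a coherent, combinatorial regulatory system is
a quantitative question: do particular AARs, and particular *combinations*
of AARs, occur in functionally related proteins more often than chance, do
AAR-bearing proteins preferentially interact with partners bearing the same
repeat, and do the proteome-wide occurrence patterns of the 20 repeat types
carry phylogenetic signal?

`aarcode` implements the full analysis system for these questions, for
anyone working on low-complexity regions, developmental gene families, or
alignment-free comparative proteomics.

## The parameter system

For a proteome of N proteins, a protein "contains X₄" if it has a run of
at least 4 identical residues of amino acid X (pure contiguity, threshold
configurable). With n_X proteins containing X₄ and n_XZ containing both
X₄ and Z₄:

    %X₄        = 100 · n_X / N
    %(X₄+Z₄)   = 100 · n_XZ / N
    RR(X₄/Z₄)  = %X₄ / %Z₄                 (repeat ratio)
    OV(X₄+Z₄)  = %(X₄+Z₄) / (%X₄)²         (normalized overlap)

Any ratio with a zero denominator is assigned 0. The 20×20 RR and OV
matrices give 800 parameters per proteome (128 when restricted to the
eight AARs most common in developmental proteins, polyA/E/G/H/P/Q/R/S).
Around this core the package provides:

- **Pairwise co-occurrence screens** — χ² tests of all 190 AAR pairs with
  Benjamini–Hochberg FDR control;
- **Combination groups** (`A*`, `A+G`, `A-G`) screened against annotated
  protein sets (GO-style terms pooled into semantic (sub)clusters), with
  fold enrichments and cross-species trends;
- **Interactome assortativity** — the excess of same-AAR bearing among a
  protein set's interaction partners over the proteome baseline;
- **Phylogenetic profiling** — parameter tables clustered with Spearman
  rank correlation and average linkage, read as unrooted trees and scored
  against reference phylogenies by Robinson–Foulds distance, with
  random-tetrapeptide (RND₄) control sets profiled by identical machinery;
- **PCA with varimax rotation** of taxon-level occurrence profiles;
- **Synthetic-data generators** with exact ground truth for every input
  the pipeline consumes (proteomes, drifting clades, assortative networks,
  annotation tables).

## Worked example

```python
from aarcode import (ProteomeSpec, gen_proteome, profile_proteome,
                     compute_parameters, pairwise_cooccurrence_screen)
from aarcode.workflows import DEFAULT_P_INSERT

spec = ProteomeSpec(n_proteins=5000, p_insert={**DEFAULT_P_INSERT},
                    pair_boost={("A", "G"): 3.0}, seed=42)
proteome, truth = gen_proteome(spec)            # FASTA-level sequences
profile = profile_proteome(proteome)            # scan all 5000 sequences
params = compute_parameters(profile)

print(f"%A4 = {params.pct['A']:.2f}%   %G4 = {params.pct['G']:.2f}%")
print(f"%(A4+G4) = {params.pct_pair.at['A','G']:.2f}%")
print(f"RR(A/G) = {params.rr.at['A','G']:.3f}   OV(A+G) = {params.ov.at['A','G']:.5f}")

screen = pairwise_cooccurrence_screen(profile, q=0.05)
hit = screen.results.set_index("unit_id").loc["A+G"]
print(f"A+G co-occurrence: chi2 = {hit['statistic']:.1f}, "
      f"adjusted p = {hit['p_adj']:.2e}, fold = {hit['fold']:.2f}")
print(f"{screen.n_rejected} of {screen.n_tested} pairs significant at FDR 0.05")
```

prints

```
%A4 = 17.10%   %G4 = 13.16%
%(A4+G4) = 5.88%
RR(A/G) = 1.299   OV(A+G) = 0.02011
A+G co-occurrence: chi2 = 406.6, adjusted p = 3.82e-88, fold = 2.61
1 of 190 pairs significant at FDR 0.05
```

The generator planted a 3-fold joint-occurrence boost for the (A, G) pair;
the screen recovers exactly that pair as the single significant
combination, with the detected marginal rates slightly above the planted
0.15/0.12 because accidental background runs also count — the scanner sees
sequence, not intent.

A command-line pipeline mirrors the library
(`aarcode scan|params|null|cooccur|enrich|network|cluster|pca|simulate`);
every run directory is self-describing (config, input checksums, log).

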