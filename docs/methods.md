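# Methods

`dacemhc` re-creates, as one tested pipeline, the genetics workflow used to
study MHC class II β exon 2 variation in upstream versus downstream river
populations of longnose dace (*Rhinichthys cataractae*): amplicon
genotyping by read clustering, duplicate-based repeatability, within- and
among-population diversity and equilibrium statistics, codon-level
selection inference, and neutral microsatellite counterparts. This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## The amplicon and its synthetic stand-in

The target is a 236-bp amplicon: 207 bp of the class II β second exon
(the peptide-binding region) followed by 29 bp of the downstream intron.
No sequence data are deposited with the study, so `synthgen` generates
allele catalogs with known truth and the whole pipeline is validated
against that truth.

`gen_allele_pool` builds `n_alleles` (default 8) sequences that differ at
exactly `n_segregating` (default 16) biallelic positions over a random
stop-free coding background. Segregating sites are placed in *distinct*
exon codons: each variant base is validated against the base sequence, and
confining sites to separate codons guarantees that no combination of
variants can assemble an in-frame stop. At least one exon variant is
forced to be nonsynonymous. Intron positions are unconstrained. The
reading frame is taken to start at the first amplicon base (frame offset
0, 69 codons); the original study reports 68 residues from 207 bp, so its
frame discards one codon, but which one is not stated and nothing
downstream depends on the choice.

Diploid genotypes are drawn from per-site allele frequencies with an
optional inbreeding coefficient *f*:
`P(hom i) = f·p_i + (1−f)·p_i²`, `P(het ij) = (1−f)·2p_ip_j`.

Reads copy one of the individual's alleles (the first with probability
`allele_balance`, default 0.5, for heterozygotes), then acquire
i.i.d. substitutions at `sub_rate` per base and — mimicking the dominant
454 error mode without a flowgram model — at most one single-base
insertion or deletion per homopolymer run of length ≥ 2, with probability
`hp_indel_rate × run length` per run. Per-sample depth is fixed at 500 by
default; a log-uniform draw over [101, 14027], the per-amplicon range
reported for the real data, is available (`depth: null`). Chimeric reads
and PCR stochasticity are not modelled. A configurable fraction of
individuals (default 0.27 ≈ 26/95) is "re-amplified": an independent read
set with fresh error draws from the same genotype.

What the generator does *not* emulate — paralogous loci co-amplifying,
quality-score structure, primer/adapter artifacts, chimeras — bounds what
passing tests show about real data: they validate the statistical
machinery and the calling logic under the stated error model, not
robustness to artifacts outside it.

## Allele calling (three steps) and repeatability

1. **Within-sample clustering.** Reads are deduplicated; pairwise
   p-distances come from edlib global alignments (edit distance over the
   longer length); an average-linkage (UPGMA) dendrogram is cut wherever
   an internal branch — the difference between a node's and its parent's
   merge heights — spans at least `min_branch` (default 0.1) of the total
   tree height. The threshold is *relative* deliberately: on an absolute
   p-distance scale 0.1 would merge any alleles diverging at fewer than
   10% of sites, far coarser than real MHC allele divergence (≤ 16/236
   here), whereas the relative reading separates any clusters whose
   divergence stands out against the sample's own error scale and keeps
   the parameter meaningful across error rates. Each cluster emits a
   majority-rule consensus (columns anchored on the cluster's modal
   sequence, indel votes included); clusters with fewer than 2 reads are
   presumed errors. For very deep samples (> 300 distinct sequences) only
   sequences seen twice enter the dendrogram and singletons are attached
   to the nearest consensus afterwards — consensus calls are unchanged
   because majority voting is dominated by repeated sequences.
2. **Global catalog.** Putative alleles pool across samples by exact
   identity; groups seen in ≥ `min_support` (default 2) distinct samples
   become catalog alleles, labelled A1, A2, … by decreasing support.
   `allow_singletons` admits single-sample alleles — the published
   procedure's robustness rerun, and provably required for total recovery
   whenever an allele's only carrier is one sample.
3. **Assignment.** Every read is matched to its nearest catalog allele by
   edit distance (exact ties split a read equally); alleles comprising at
   least `min_fraction` (default 0.2) of a sample's reads are called.
   More than two passing alleles ⇒ `ambiguous`; none, or depth < 20 ⇒
   `failed`. The 20% rule is what makes the pipeline robust to spurious
   catalog entries: recurrent-error alleles attract far fewer than 20% of
   any sample's reads and are never called.

Repeatability is the percentage of replicate pairs with identical
unordered allele sets; discordant pairs are reported for exclusion from
downstream statistics, as in the original analysis.

## Diversity and equilibrium statistics

* Haplotype (gene) diversity and expected heterozygosity use the unbiased
  estimator `(n/(n−1))(1 − Σp_i²)` throughout.
* Sequence descriptors over the allele alignment weighted by copy counts:
  segregating sites S among present alleles, mean pairwise differences
  `k = Σ_{i<j} c_i c_j d_ij / C(n,2)` (identical-copy pairs in the
  denominator, the DnaSP convention), and π = k/L with L = 236.
* The Hardy–Weinberg exact test conditions on allele counts. A complete
  enumeration of genotype tables serves samples up to ~12 gene copies and
  doubles as the oracle for the Markov chain used at realistic sizes
  (default 100,000 steps, 1,000 dememorization). The chain randomly
  transposes entries of the allele-pairing array; a uniform pairing of
  copies induces exactly the conditional table distribution, so every
  proposal is accepted and the p-value is the visited fraction of states
  no more probable than the observed table.
* The Ewens–Watterson test compares `F = Σp_i²` with null configurations
  drawn from the Ewens sampling formula conditional on the observed allele
  number (θ matched to E[k] by Newton iteration, rejection on k;
  default 1,000 accepted samples). The reported p is one-sided,
  `P(F_null ≥ F_obs)`: small p means the sample is more homozygous than
  neutrality predicts, p near 1 means unusually even.

## Structure: Φ_ST, hierarchical AMOVA, Dxy

Distances between alleles are raw nucleotide difference counts, used
directly as squared distances in Excoffier-style sums of squares
(`SS(pool) = (1/n)Σ_{i<j} d_ij`, computed as quadratic forms over allele
count vectors). Pairwise Φ_ST is the two-level variance-component ratio
with a permutation test that reassigns whole individuals (default 110
permutations, honoring the published setting; the observed value counts
in the null set, so p ≥ 1/(n_perm+1)).

The hierarchical AMOVA decomposes variance across four levels — within
individuals, among individuals within sites, among sites within rivers,
among rivers — by method of moments with unbalanced-design coefficients
(each individual contributes exactly two copies, which fixes the
individual-level coefficient at 2). Components may be negative as
estimated; they are floored at zero only for percent-of-variation.
Permutation schemes per tested level: gene copies re-paired among
individuals within sites (within-individual and among-individual levels;
the within-individual p counts permuted components *at or below* the
observed one, a deficit being the heterozygote-deficiency signal), whole
individuals among sites within rivers, and whole sites among rivers
(default 3,024 permutations). The decomposition was checked against
simulations of the nested random-effects model with known variances, and
the two-level case with 0/1 distances agrees with the haploid
Weir–Cockerham θ to machine precision.

Dxy is `Σ_ij x_i y_j d_ij / L` over the two populations' allele
frequencies.

## Codon-level selection

Nei–Gojobori (1986) pathway counting: per-codon synonymous site fractions
(changes into stop codons count as nonsynonymous, so syn + nonsyn = 3 for
every sense codon), pairwise differences averaged over mutational
pathways with stop-crossing pathways excluded, per-pair proportions
averaged over copy-count-weighted sequence pairs, Jukes–Cantor correction
`d = −(3/4)ln(1 − 4p/3)` applied to the averaged proportions and flagged
NaN at p ≥ 3/4. A weight of 2 is exactly equivalent to listing a sequence
twice (identical pairs enter the average with zero distance).

The Z-test of dN − dS = 0 bootstraps codon *sites* (500 replicates by
default, codon integrity preserved) for the standard error and refers Z
to the normal distribution two-sided; degenerate cases (identical
sequences, zero bootstrap variance, undefined correction) return p = 1.
Type-I error was verified at ~5% over 500 neutral simulated alignments.

Recombination: the Hudson–Kaplan lower bound Rm from four-gamete-violating
biallelic site pairs with interval culling (greedy disjoint intervals by
right endpoint).

The per-window scan for nonsynonymous excess is a deliberately simple
frequentist substitute for Bayesian variable-ω models with recombination:
non-overlapping windows of 10 codons score the weighted pairwise pN − pS;
the null shuffles codon columns alignment-wide (default 200 permutations);
a window is flagged only when its exceedance probability reaches 0.95 in
two independently seeded runs, mirroring the two-run agreement rule used
with MCMC samplers. Its outputs are labelled as window-level flags, not
per-residue posterior probabilities.

The allele tree is Saitou–Nei neighbor joining (via scikit-bio) on
Jukes–Cantor distances, written as unrooted Newick.

## Microsatellites

GENEPOP files (2- or 3-digit alleles, `0…0` missing) are parsed and
written natively. Pairwise F_ST is Weir–Cockerham θ with variance
components summed over alleles and loci (ratio of sums); missing
genotypes are excluded per locus. Rarefied allelic richness uses the
hypergeometric form `Σ_a [1 − C(N−N_a, g)/C(N, g)]`. Isolation by
distance: genetic distances transformed as F_ST/(1−F_ST) with negative
estimates floored at 0 (keeping the log-linear regression defined; the
handling is not specified in the original), geographic distances
log-transformed, then Mantel or partial Mantel tests (Pearson r over
lower triangles, joint row/column permutations, one-sided with the
observed value included; default 100,000 permutations). The partial test
residualizes both matrices on the control by linear regression and
re-residualizes the permuted matrix each draw; a control collinear with
one matrix yields r = 0 by convention.

## Reproducibility and problem sizes

One master seed expands into fixed per-stage seeds via
`SeedSequence([master, stage_index])`; every stochastic stage names its
stage explicitly, a rerun with the same config is bit-identical, and all
TSV outputs carry the config digest. The test suite exercises the full
study layout (six sites, three rivers, ~100 amplified samples including
duplicates) at depth 101–200 for the recovery checks, and smaller layouts
(2–4 sites, 5–10 individuals, depth 40–150) elsewhere; Monte-Carlo checks
use 100,000-step HWE chains, 500-replicate bootstraps over 500 neutral
alignments, and 100-case topology sweeps. These sizes were chosen so the
whole suite completes in well under an hour on one core while keeping
every tolerance at the sampling-error scale of the statistic it checks.

## Known limitations

* The clustering step assumes one locus; co-amplifying paralogs would
  appear as >2-allele (`ambiguous`) calls rather than being deconvolved.
* The recurrent-error catalog entries that survive the two-sample rule at
  realistic error rates inflate the catalog (harmlessly for genotypes);
  real pipelines typically add a BLAST/identity screen, which is out of
  scope here.
* The Ewens–Watterson null conditions on k by rejection; for extreme
  (n, k) combinations acceptance can be slow, and the test errors out
  rather than silently under-sampling.
* The window scan detects *regions* of nonsynonymous excess; it does not
  estimate per-residue ω and is not a substitute for codon-model MCMC.
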