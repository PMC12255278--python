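# Methods

This note documents the models and procedures implemented in `sgchem`, their
assumptions, the tunables that matter, and the design choices made where the
problem was genuinely open.

## Mass arithmetic

All ions are treated as singly protonated [M+H]+ (proton mass 1.00728 Da);
multiply charged species are out of scope, so occasional half-spaced ions in
real in-source spectra (e.g. an [M+2H]2+ echo of a large glycoside) are
simply not matched. m/z comparisons use an absolute tolerance, default
0.02 Da, matching the two-decimal precision at which SG fragment values are
customarily reported; chemotyping uses a coarser 0.05 Da window because its
targets are one-decimal values (416.3 / 414.3).

Residue masses ship as a TSV resource (hexose C6H10O5, deoxyhexose C6H10O4,
pentose C5H8O4, malonylhexoside C9H12O8, hydroxylation O, saturation H2,
acetylation C2H2O, water H2O); each tabulated mass is validated against its
composition via pyteomics at load time (1e-4 Da) and the table is
user-extensible.

`assign_formula` searches a bounded CHNO space exhaustively. Candidates are
restricted to chemically valid even-electron neutrals — integer RDBE ≥ 0,
i.e. even H+N parity. This constraint is load-bearing: without it, radical
compositions (e.g. C24H49O6, RDBE 0.5) can beat genuine aglycone formulas on
mass error alone, and no neutral molecule has half-integer RDBE. Ties on
mass error are broken by |RDBE − 7| (steroidal aglycones cluster at RDBE
5–8) and then lexicographic composition; the tie-break rule is arbitrary but
deterministic and documented. A mass with no candidate inside tolerance
returns an explicit no-assignment result.

`decompose_glycan` enumerates residue multisets for a chain mass
(molecular − aglycone ion), with at most 6 of each sugar and at most one
malonylhexoside/acetyl per chain — observed SG chains carry ≤ 5 sugars and
at most a single acyl decoration.

## Synthetic study generator

The generator emulates a two-chemotype factorial experiment: 3 S- and 4
U-chemo-genotypes, roots and leaves sampled from vegetative plants, roots,
leaves and stems from flowering plants (stems cannot be harvested from
vegetative plants that must be kept for propagation). The compound library
contains 18 glycosides covering all 12 SA census species, including the six
worked structures: an SGA tetraoside (molecular ion ≈ 1034.55), two
triosides (886.52, 870.52) with their unsaturated analogues, a root-only
malonylated SGA (954.51), the unsaturated SSG pentoside (1195.5662) and its
saturated flowering-only analogue. The chemotype rule is structural: leaf
compounds of the U chemotype carry aglycones one H2 (2.016 Da) below the S
analogues, and roots of both chemotypes share the unsaturated forms.
Saturated/unsaturated analogue pairs co-elute in the simulation, which makes
the planted "compound family" of each retention-time cluster the ground
truth for network-component tests.

Abundances are log-normal around baseline × group multiplier (default
sigma 0.4 on the natural-log scale, a mid-range biological CV for
metabolite intensities). Each compound emits
`max(1, round(k·log10(abundance)))` scans (k = 3), a monotone
abundance→scan-count map chosen once; real scan density depends on
acquisition rate and peak width, which are not modelled. Every scan carries
the full fragment ladder (base peak mid-ladder; true relative intensities
are unconstrained by printed spectra and are configurable) plus decoy peaks
drawn uniformly over m/z 100–1300 excluding ±0.05 Da around all true ions,
so decoys cannot silently complete a glycosylation ladder. The feature
table adds an artifact feature at m/z 329.32 (the conventional
TIC_SG exclusion) and unrelated noise features that should end as network
singletons. A fixed seed fixes every artifact bit-for-bit; with the noise
channels at zero the generator's per-sample glycoside counts are an exact
oracle for the census.

What the generator does *not* emulate: chromatographic peak shapes, isotope
envelopes, adducts other than [M+H]+, co-eluting isomer interference, and
retention-time drift between samples. Tests passing on this data therefore
validate the decision rules and bookkeeping of the pipeline, not its
robustness to instrument artifacts.

## Mass-difference network

Edges require both a neutral-loss match (smallest-error loss wins) and
co-elution within `rt_window` (default 0.1 min): in-source fragments of one
compound share a chromatographic peak, so a tight window is correct; the
value is configurable for data with more retention jitter. The saturation
difference H2 is included in the default loss table as a biotransformation
edge class so S/U analogue pairs connect. Edges are undirected (mass
differences are unsigned). Node association labels use a 0.75 intensity
fraction threshold per grouping level — any level holding ≥ 75% of a node's
summed intensity claims the node, otherwise it is neutral; published
network figures color nodes without stating a cutoff, so the threshold is
explicit and configurable here.

## Chemotyping

Presence of the diagnostic fragment is `EIC maximum > threshold`; the
automatic threshold is 5× the median of the full trace (zeros included).
The median over all scans estimates the baseline; for a sparse trace it is
zero and any strictly positive maximum counts as present. (A median over
only the nonzero values would be dominated by the peak itself and defeat
the rule.) The S call dominates: a sample with both 416.3 and 414.3 is S.

## Census

A scan is counted for an SA species only when a chain of glycosyl losses
(hexose/deoxyhexose/pentose, with malonylhexoside allowed as the terminal
step onto the aglycone) connects some heavier peak down to the SA fragment;
reachability is computed bottom-up over the sorted peak list and the
deepest chain from the heaviest peak is reported. When several SA species
qualify in one scan the whole scan is attributed to the heaviest — so a
saturated aglycone pre-empts the in-source dehydration artifact of its
unsaturated analogue. (The alternative reading — count every qualifying
species using its heaviest ladder ion — was considered and rejected as it
double-counts scans.) Each retained scan adds exactly one count, so the
grand total equals the number of retained scans.

## Diversity indices

Margalef richness (S − 1)/ln N and Pielou evenness J = H′/ln S with natural
logarithms throughout. Degenerate inputs: all-zero counts are undefined
(NaN); N = 1 gives D<sub>mg</sub> = 0 by continuity of the numerator; S = 1
leaves J undefined and excluded from summaries. TIC<sub>SG</sub> sums
network-node intensities per sample, excluding any feature within tolerance
of the configured artifact masses (default one signal, m/z 329.32,
list-configurable). Group summaries are descriptive (mean ± sd per
chemotype × organ × ontogeny); mixed-model marginal means are deliberately
out of scope.

## GLM-ASCA

Per species, a log-link Poisson GLM (statsmodels IRLS) on a sum-to-zero
coded factorial design. Effect matrices live on the linear-predictor (log)
scale — the only scale where term contributions add — and are
column-centered before SVD; with the Gaussian/identity family the
construction reduces exactly to classical ASCA (group-mean deviation
matrices on balanced designs), which the tests verify against hand-computed
means. Explained variance per latent variable is the squared-singular-value
fraction of its term's matrix.

Permutation validation uses the squared Frobenius norm of the term's effect
matrix; the null permutes the tested term's design rows while the other
terms' columns stay fixed, which for a single-factor model is free label
permutation. For that single-factor case the saturated-model MLE is the
group-mean fit, so permutation nulls are computed in closed form (with a
0.5/n continuity floor for empty cells) rather than by repeated IRLS; the
closed form is verified against statsmodels. p = (1 + #{null ≥ obs})/(B+1).
The interaction-term permutation scheme (permuting the interaction block
only) is approximate and inherits the usual caveats of restricted
permutation for non-orthogonal designs.

The pseudo-R² screen compares each variable's 1 − deviance/null-deviance
against the median over refits on row-permuted responses; variables beating
their permutation median are retained for decomposition. An intercept-only
comparison is not used because any factor structure inflates it uniformly.

In the bundled pipeline, the second model (sample-type × ontogeny) is
fitted on root and leaf samples only: stems exist only at flowering in this
design, so their interaction cells are empty and the full design is rank
deficient.

## qPCR expression model

Counts are `round(E^(Cq1 − Cq))` with Cq1 = 37, a conventional
single-molecule baseline cycle (configurable; the transform's downstream
contrasts are invariant to it). Efficiencies come from 1–1000× dilution
series as E = 10^(−1/slope) of Cq on log10 concentration, clipped to
(1, 2.2] with warnings outside (1.6, 2.1); reference genes may assume
E = 2. Technical replicates enter as repeated Poisson observations, never
averaged.

The model is log-linear Poisson: gene × condition fixed effects plus
sample (and genotype, when present) random effects with Gaussian ridge
penalties (default prior sd 1.0 on the natural-log scale — deliberately
weak; set it to the known loading dispersion when available). A weak ridge
on fixed effects (sd 5.0) keeps conditions with zero detected template at a
finite, near-detection-limit estimate. Soft normalization adds a tight
penalty (sd 0.1) on each reference gene's deviations from its own mean
condition effect, pulling sample effects toward values that equalize the
references instead of dividing counts by them; the penalty strength is the
stability assumption and is exposed as a tunable. Estimation is penalized
maximum likelihood by Newton iteration with Laplace (inverse-Hessian)
intervals; a random-walk Metropolis sampler over the same penalized
posterior is available (defaults 110 000 iterations, thinning 100, burn-in
10 000, with an effective-sample-size warning). Pairwise condition
contrasts per gene are Wald tests on the log2 scale with Benjamini–Hochberg
adjustment (the conventional FDR method).

## Ordination

Preprocessing: sum-normalize each sample, log10(x + ε) with ε = half the
smallest positive normalized value (a data-driven pseudo-count), then
mean-center columns. PCA by SVD. PCoA is a direct Gower-centering +
symmetric eigendecomposition so that the negative eigenvalues produced by
non-Euclidean distances (Manhattan) are reported, never corrected or
dropped silently; coordinates are returned for positive eigenvalues.
PERMANOVA is delegated to scikit-bio (unrestricted permutations,
single-factor), with the pseudo-F scale-invariance and calibration checked
in the test suite.

## Problem sizes used in validation

Calibration suites run at sizes chosen to give stable estimates at modest
cost: permutation type-I error for the ASCA term test uses 500 null
simulations × 499 permutations (16 samples, 4 species, Poisson mean 20,
via the closed-form single-factor path); PERMANOVA calibration uses 500
simulations × 199 permutations at n = 12; qPCR interval coverage uses 200
simulated datasets (2 genes × 2 conditions × 8 samples × 3 replicates).
The default end-to-end pipeline (35 samples, ~90 features, ~4700 scans,
1000-permutation ASCA validation) completes in a few minutes on one CPU.

## Known limitations

- Glc/Gal and other stereoisomers are indistinguishable by mass; "hexose"
  is a mass class, not a sugar identity.
- No adduct handling beyond [M+H]+ and no isotope-pattern scoring.
- The census counts scans, so it measures relative glycoside diversity, not
  absolute quantity; co-eluting isobaric isomers merge unless they produce
  distinct scans.
- The soft-normalization penalty is a fixed-variance stand-in for a full
  hierarchical prior; its default strength encodes "references are stable
  to within ~15%".
- The interaction-term permutation scheme in GLM-ASCA is approximate (see
  above).
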