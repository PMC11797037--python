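# Methods

## The generative model

The simulator is a deliberately reduced multispecies coalescent.  Four
ingroup lineages sit on a rooted asymmetric species tree (((P1,P2),P3),P4)
with a single outgroup used only for polarization.  Per site, three steps
run independently:

1. **Lineage arrangement.**  If a hybrid taxon is configured, it joins
   parent 1's lineage with probability γ, else parent 2's.  Each
   introgression edge then fires with probability given by its retention
   profile evaluated at the site's folded coordinate; a firing edge
   re-attaches the recipient lineage as sister of the donor.  When several
   edges are configured, at most one fires per site (first in list order).
2. **Topology.**  The resulting local quartet is reduced to one focal
   triplet: the cherry plus its nearest neighbour.  Within the internal
   branch of length `T` (coalescent units) the two cherry lineages coalesce
   with probability 1 − e^(−T), fixing the concordant pairing; otherwise
   the three pairings of the triplet are equally likely.  Hence the
   concordant pair occurs with probability 1 − (2/3)e^(−T) and each
   discordant pair with (1/3)e^(−T).
3. **Mutation.**  One mutation is placed on the internal branch subtending
   the sampled pair, so every emitted site is a pairwise split.  Singleton
   and triple-derived sites can be mixed in at configured rates (default 0)
   purely for input realism.

Assumptions this buys, and their cost: there is no linkage (sites are
independent given position), no recurrent mutation, no polymorphism within
species, and only one ILS-bearing branch — deeper coalescences are
collapsed, so under the species arrangement the fourth taxon never appears
in an emitted pair.  Pairs involving the deepest taxon arise only through
re-attachment (gene flow).  This is exactly the resolution at which the
downstream statistics operate (triplet pattern frequencies and pairwise
splits), which is why their null calibration and power can be validated
against closed forms; it is *not* a model of real sequence evolution, and
absolute split-frequency spectra of real genomes (where all six pairs
appear at appreciable frequency through deeper coalescence) are outside
what passing tests demonstrate.

If a re-attachment lands on the deepest lineage the local tree would be
balanced; the third slot of the reduced triplet is then filled by the
mover's original sister when available, else by ingroup order.  The rule is
deterministic and only affects which discordant codes ILS produces in that
arrangement; no default scenario triggers it.

Hybrid attachment is resolved before introgression.  A consequence worth
knowing: with both processes active, "recent" gene flow acts on the modern
recipient lineage while the hybrid keeps its parental attachment, so
erosion of hybrid–parent sharing at chromosome ends is emulated by flow
*into the hybrid* rather than by flow between a parent and the fourth
taxon (see the ancestry tests).

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `t_internal` (T) | 1.0 | coalescent units | substantial but not saturating ILS: ~24.5% discordant sites, a regime where both D and enrichment need their full machinery |
| T in the HHS factory | 0.5 | coalescent units | puts hybrid-parent : parents-exclusive split classes at (0.5 − e^(−T)/6)/(e^(−T)/3) ≈ 1.97, the "nearly double" excess that distinguishes HHS from balanced ILS |
| introgression rate f | 0.3 | probability | strong but partial replacement; D ≈ 0.4 locally at the plateau |
| retention profile | logistic, r0 = 0.35, scale = 0.08 | folded coordinate | retention ≈ f at telomeres, ≈ 0 at centers, transition about a third of the way in — telomere-limited gene flow |
| chromosome map | 25 chromosomes, 40–80 Mb, fixed internal seed | bp | zebrafish-like karyotype; site density uniform |
| `d_window` | 200 | ABBA/BABA sites | fixed-count windows equalize null variance across uneven site density |
| `split_window` / `split_step` | 500 / 10 | pairwise splits | standard operating point of the windowed split analysis |
| enrichment null p | 1/6 | — | six unordered pairs of four taxa under equal relatedness |
| `alpha` | 0.001 | — | the source analysis states no alpha; 0.001 with optional Bonferroni across the six codes, both recorded in output headers |
| `min_region_windows` | 10 | windows | discards one-off excursions; with step 10 a region must persist across ≥ 90 additional sites |
| `n_bins` | 10 | folded bins | matches the 10-per-chromosome jackknife partitioning |

The simulator exposes divergence and gene-flow parameters as free
parameters rather than asserting organism-true values, because no published
demographic estimates exist for the motivating system; the defaults above
are the package's study conditions and are not retuned per analysis.

## Numerical and design choices

* **Window construction for D** is by informative-site rank, centred on
  each site with the extra site of an even window on the left, shifted
  inward at chromosome ends so the window size never changes; a chromosome
  with fewer informative sites than one window yields a single flagged
  whole-chromosome window.  Centred (vs trailing) placement was an open
  choice; centred keeps the track aligned with local signal.
* **Null band** uses exact Binomial(n, 1/2) quantiles mapped through
  D = 2k/n − 1.  Discreteness makes coverage ≥ the nominal level, so the
  empirical outside-rate sits slightly below 5%; tests allow for this.
* **Enrichment** uses the exact binomial upper tail (`binom.sf`), not a
  normal approximation; `critical_count` exposes the resulting threshold
  (k* = 111 at n = 500, α = 0.001).  Exact rather than normal bands were
  an open choice; exact keeps small-α calibration honest.
* **Jackknife partitions** are equal *site count* (not equal bp), the
  remainder going to the leftmost bins; a chromosome with fewer sites than
  bins is a named error.
* **Folding** is r = min(pos − 1, L − pos)/(L/2) clamped to [0, 1]; exact
  1.0 is attained only in the limit (the midpoint of a finite chromosome
  folds to 1 − O(1/L)).
* **Split codes** require all four ingroup calls present; any missing call
  demotes the site to `other` so windowed proportions stay comparable.
  Heterozygous diploid calls collapse to missing by default (configurable
  ref/alt rules exist): the consensus-per-species design has no
  within-taxon polymorphism to represent.
* **Polarization** requires agreement among all *non-missing* outgroups;
  sites with zero outgroup calls are removed and counted, not errors.
  Whether one missing basal taxon should disqualify a site was an open
  question; requiring agreement among the called outgroups keeps more data
  and the count is logged for audit.
* **γ̂ estimator**: defined in the README; unbiased under the reduced model
  (the ILS background cancels exactly: c1 − c0 ∝ γ(1 − e^(−T))).  The
  per-bin hybridization z compares the weaker parental class against the
  ILS background conditional on their sum (Binomial(N, 1/2) null).  It
  replaces likelihood-based hybrid detection, which is out of scope; the
  pipeline prints the formula into the ancestry table header so the
  quantity cannot be mistaken for a likelihood-based γ.
* **Determinism**: one `numpy` Generator per scenario; the draw order is
  documented in `sim.py`'s module docstring, and identical scenario + seed
  reproduces output byte for byte, including VCFs.
* **Truth intervals for introgression recovery** are defined analytically:
  the chromosome-end region where the expected (recipient,donor)-pair
  probability, ρ(r)(1 − (2/3)e^(−T)) + (1 − ρ(r))(1/3)e^(−T), exceeds the
  enrichment threshold k*/n — i.e. where the signal is detectable in
  principle.  Recovery is scored as bp Jaccard against these intervals.

## Problem sizes used in validation

The test and acceptance runs use 5×10^4–10^6 sites per scenario: 10^5 sites
for null calibration (≥ 100 disjoint 200-site D windows), 5×10^5 for
introgression localization, 2.1×10^5 per γ value (≥ 2×10^4 pairwise splits
per folded bin), and 10^6 for simulator-vs-closed-form agreement (3-SE
comparisons resolve deviations of ~10^-3).  These sizes were chosen so that
each assertion's sampling error is several times smaller than the effect it
checks.

## Known limitations

* The reduced model cannot produce all six pairwise splits under a pure
  species tree, unlike real genomes; genome-wide split spectra are
  therefore not comparable to exome data except through the gene-flow
  channels.
* The γ̂ estimator equals likelihood-based γ only under this model's
  symmetry assumptions; on real data the two can diverge, and no numeric
  agreement with published per-bin γ profiles is claimed.
* Windowed D values at neighbouring sites share up to 199 of 200 sites;
  the per-site track is for localization, and calibration statements apply
  to disjoint windows only.
* Site filters (depth, SNP clustering) are implemented for real call sets
  but are no-ops on simulated input, which carries no depth annotations or
  clustered artefacts.
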