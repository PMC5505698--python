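# Methods

`enuscreen` models the computational arm of a three-generation ENU
(N-ethyl-N-nitrosourea) mutagenesis screen in a large animal: a mutagenized
G0 sire transmits random germline point mutations to G1 offspring; G1 boars
are bred to wild-type sows and their G2 daughters are backcrossed to the G1
sire, exposing recessive mutations in G3.  The package simulates this design
end to end and implements the analyses that run on the resulting data — trio
de novo mutation calling, substitution-spectrum summaries, parametric
two-point linkage, a causative-variant filter cascade, and the burden and
power arithmetic used to size such screens.

## Mutagenesis and the substitution spectrum

Each gamete of the mutagenized founder acquires `Binomial(G, r)` point
mutations, `G` the genome size in bp and `r` the per-site rate.  The two
calibrated dose levels are `r = 1.63e-6` (65 mg/kg) and `r = 5.86e-6`
(85 mg/kg).  Positions are uniform without replacement; mutation sets of
different gametes are disjoint by construction — an idealization: the true
collision probability at these rates is of order `G r^2`, i.e. negligible,
and disjointness matches the assumption the downstream cross-trio exclusion
filter relies on.

Substitution classes use the six strand-collapsed types.  Only the aggregate
transition fraction (0.712) is a calibrated quantity; the default per-class
split (G:C>A:T 0.45, A:T>G:C 0.262, four transversions at 0.072 each) is a
package default shaped like a typical ENU spectrum, not a published
breakdown, and is fully configurable.  Sampling has two modes:

* no reference sequence attached — the class is drawn from the marginal
  spectrum and the reference base uniformly between the class's two strand
  representations, so the configured aggregate spectrum is reproduced
  exactly;
* reference sequence attached — the class is drawn conditioned on the actual
  base (renormalizing the compatible classes).  Conditioning re-weights the
  aggregate slightly (for a 50% GC genome the expected transition fraction
  drops from 0.712 to ~0.70); spectrum calibration checks therefore run on
  sequence-free toy genomes.

## Meiosis

Recombination follows Haldane's map function, `theta = (1 - e^(-2d))/2` with
`d` in Morgans from a uniform 1 cM/Mb map; no crossover interference;
chromosomes assort independently.  All simulated chromosomes are autosomal —
X-linked inheritance is not modelled.  Only tracked loci (planted mutations,
background polymorphisms, array markers, the phenotype locus) are propagated
through meiosis.

## Breeding scheme and phenotypes

One tracked G1 boar per family is mated to `dams_per_g1` unrelated wild-type
sows (default 4, litter size 8) and `g2_dams_backcrossed` of his daughters
(default 4) are mated back to him.  Offspring sex is Bernoulli(1/2); if too
few G2 females arise, extra litters are drawn up to a configured cap before
a breeding-structure error is raised.  Phenotypes come from a single-locus
model: dominant carriers, or recessive alt-homozygotes, are affected with
probability `penetrance`; everyone else is unaffected.

## Sequencing read-outs

* **Reduced-representation (2b-RAD-like) counts.**  Tag loci are idealized
  as a Bernoulli(`rad_fraction`) site sample shared by all individuals — the
  downstream analysis depends only on callable-site counts, not on
  restriction-site geometry.  Depth is Poisson(`mean_depth`); alternate
  reads are `Binomial(depth, p)` with `p = epsilon, 1/2, 1-epsilon` for
  genotypes 0/1/2, i.e. i.i.d. base errors with no mapping or strand
  artifacts.
* **SNP array.**  Markers are evenly spaced per chromosome with founder
  allele frequencies uniform on [0.05, 0.5] and independent missingness.
* **WGS call sets.**  Per-individual variant lists read directly off the
  simulated diplotypes (no read-level noise), plus a known-polymorphism
  catalogue containing the background SNPs and array markers — never the
  planted mutations.

Background polymorphisms segregate in all founders at density
`background_poly_rate` (default 1e-3 per site for trio studies) with allele
frequencies uniform on [0.05, 0.5], a common-SNP band chosen once as
a plain stand-in for a site-frequency spectrum.

## Trio de novo calling

Per-genotype read likelihoods are `Binomial(depth, p)` as above; zero depth
yields the flat, uninformative triple.  The trio posterior enumerates all 27
parent-parent-child genotype configurations with Hardy-Weinberg parental
priors (`pop_alt_freq`) and transmission in which each gamete carries a
Mendelian allele with probability `1 - mu` and the mutated alternative with
probability `mu`.  `pp_dnm` is the posterior mass of configurations whose
child genotype cannot arise by Mendelian transmission; `pp_null` the mass of
Mendelian configurations with a non-reference child.  The implementation is
required (and property-tested) to agree with direct enumeration to machine
precision.

Calling criteria keep the screen's printed values as strict inequalities:
`pp_dnm > 0.9`, `pp_null < 0.001`, every trio member covered by at least 10
reads, and sites called in more than one trio removed entirely.  The
coverage rule is the stringent "every member" reading; a `depth_rule`
switch (`all`/`any`) exposes the permissive alternative.

Prior defaults are the caller's design choice: `mu = 5e-6` matches the
mutagenized regime the caller targets, and `pop_alt_freq = 1e-6` represents
residual, uncatalogued segregating variation.  The second value matters: at
20x coverage the Mendelian (inherited-het) explanation of a de novo site is
suppressed by the parental read likelihoods by only ~1e-6 (no stray alt
read) to ~1e-4 (one error read), so a polymorphism prior at catalogued-SNP
scale (1e-3) would push `pp_null` past the 0.001 criterion for most genuine
de novo sites and collapse sensitivity.  With the defaults, sensitivity is
limited instead by the child's own read draws (clearing `pp_dnm > 0.9` at
20x needs roughly six alternate reads), an irreducible cost of the printed
thresholds of a few percent.  False positives require simultaneous
multi-read error stacks and stay far below one per 1e6 callable sites in
the audit against the simulation truth record.

The pooled mutation frequency is (calls) / (pooled callable sites across the
family's trios), callable meaning the depth rule holds; the 95% interval is
the exact Poisson (chi-square) interval on the call count divided by the
callable-site total.  The callable-site denominator is this package's
definition — reduced-representation studies rarely print theirs.

## Parametric two-point linkage

The LOD score is `log10 L(theta) / L(0.5)` where `L` is the exact joint
probability of marker genotypes and affection status under a single-locus
disease model: founder two-locus diplotypes from the marker allele frequency
and disease allele frequency `q` (default 1e-4) in linkage equilibrium,
two-locus haplotype transmission with recombination `theta`, penetrances
`(f0, f1, f2)` (defaults (0,1,1) dominant, (0,0,1) recessive — the source
study's parametric settings are unpublished, so full penetrance is the
default and everything is configurable).  Missing genotypes are summed over;
unknown affection contributes a factor of one.

The likelihood is computed by recursive conditioning on parental two-locus
genotypes (16 ordered states), sire first, vectorized over markers and the
theta grid.  The sire-daughter backcross loop is handled exactly: the G2
dam's natal family is peeled with the G1 sire's state held as an explicit
axis, so her backcross offspring condition on both parents consistently.
Any other loop raises an unsupported-structure error.  The implementation is
property-tested for exact equality against full-joint enumeration over all
two-locus genotype configurations on small pedigrees, including the loop.

Data incompatible with `theta = 0` evaluate to a likelihood of zero there;
the LOD is reported as the sentinel -99 rather than minus infinity.

**Marker QC** keeps markers with observed call rate >= 0.90 and sample minor
allele frequency >= 0.05.

**Region extraction.**  A two-point profile contains three kinds of markers:
linked (LOD >= 3), *excluding* (clear recombination evidence against tight
linkage; LOD at `theta = 0.05` at or below -2, the classical exclusion-
mapping cut), and *uninformative* — typically markers at which the key
meiotic parent is homozygous, which can never reach the threshold and carry
no evidence either way.  Roughly 60% of chip markers are uninformative in a
given sire at frequencies uniform on [0.05, 0.5], so uninformative runs of
several markers are the norm, and a rule that breaks regions at every
sub-threshold marker fragments the profile and regularly drops the true
locus into a gap.  Regions are therefore defined as runs of linked markers
through which uninformative markers pass freely, tolerating up to
`merge_gap_markers` (default 2) consecutive excluding markers; support
bounds extend to the nearest excluding marker beyond each end.  This yields
one broad support interval per true locus — tens of Mb, the scale such
family studies report — rather than a string of fragments.  Profiles
without exclusion information fall back to the narrow flanking-marker rule.

The case-control allelic association test is a Pearson chi-square on the
2x2 allele-count table (df 1).

## Candidate filter cascade

Five pure intersections, applied in a fixed order with per-stage counts for
audit: (1) inheritance pattern — dominant: heterozygous in every affected
(het, not merely carrying: an F1 dominant from mutagenesis is expected
heterozygous) and absent from every control; recessive: alt-homozygous in
every affected and not in any control; (2) position inside a linkage
region; (3) not in the known-polymorphism catalogue, matched on
chromosome+position+alt so reference-encoding dialects cannot mask a hit;
(4) protein-disrupting consequence, implemented as {missense, nonsense};
UTR and near-splice variants are kept in an advisory list, never the final
set; (5) complete co-segregation with the phenotype over the whole pedigree
under full penetrance.  Because the stages are intersections, order affects
only the per-stage counts, never the final set (property-tested).

Consequence annotation is codon-aware and strand-aware on single-transcript
gene models (1-based inclusive coordinates; CDS > UTR > intron > intergenic
precedence; stop-gain reported as nonsense, stop-loss folded into missense;
splice sites carry a flag rather than a class).

## Screen-design arithmetic

The burden chain from a per-site rate `r`: genome-wide mutations
`floor(r x G)`; coding mutations `floor(r x n_genes x mean_CDS)`;
amino-acid-changing mutations `floor(coding x 0.55)`; fold over the
spontaneous rate `r / 1.2e-8` (unrounded); animals to screen per gene
`round_to_ten(n_genes / functional)`.  The floor/nearest-ten/one-decimal
display conventions are explicit constants because they are what make the
chain land on the familiar screen-sizing figures (4,580 / 16,466 / 57 / 31 /
710) rather than buried arithmetic.

Backcross detection power: each G2 dam carries the G1 variant with
probability 1/2 and each of her backcross offspring is affected with
probability `penetrance/4`, so
`P(detect) = 1 - [1/2 + 1/2 (1 - penetrance/4)^offspring]^dams`
(cross-checked against a Monte-Carlo oracle).

Physiological reference ranges eliminate outliers first — the iterative
3-SD rule by default, a Tukey IQR fence as the alternative (`trim=`) — then
take the 2.5th-97.5th percentile band; deviants must exceed mean +/- 2 SD
strictly on the first measurement and on at least `n_confirm - 1` repeats.
The outlier-elimination step is unspecified in the protocols this models;
the 3-SD rule is this package's choice, isolated behind the strategy switch.

## Determinism and problem sizes

All randomness flows from explicit seeds through a stage-labelled seed tree;
two runs with the same configuration are byte-identical in every output.
The test suite runs the screen at desk scale: toy genomes of 2x10 Mb for
trio studies and 5x20 Mb with 500 array markers for linkage, 20 seeded
replicates for the end-to-end and coverage suites — sizes at which every
property is informative while the whole suite completes in a few minutes on
one CPU.

## What the simulator does and does not show

Passing tests demonstrate the *procedure* is implemented correctly and is
calibrated under the generative model: binomial read errors, idealized tag
sampling, disjoint mutation sets, uniform recombination, single-transcript
genes, no indels or structural variants, no mapping or batch artifacts, no
population structure among founders.  Real screen data violate most of
these in ways that raise false-positive rates and depress sensitivity;
results here bound what the analysis can do under ideal conditions, not
what it will achieve on a sequencer's output.  The linkage engine is
two-point by design; multipoint chaining of markers is out of scope, and
the broad support intervals it reports are the honest price of that choice.
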