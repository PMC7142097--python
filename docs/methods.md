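# Methods

`meganumt` implements a trio-based analysis showing how large, rare
nuclear-mitochondrial DNA segments (mega-NUMTs) can masquerade as
paternally transmitted mtDNA heteroplasmy, together with a synthetic cohort
generator that provides ground-truth labels for every stage.

## The signal and the confounder

mtDNA is maternally inherited: a child's mtDNA haplotype is the mother's.
A child who shares several sub-homoplasmic mtDNA variants with the father —
variants absent from the mother — therefore looks like evidence of
biparental inheritance.  The alternative explanation is nuclear: if the
father carries an autosomal insertion of `Nmt` concatenated mtDNA-derived
fragment copies, his mtDNA-aligned reads contain `DPnu/2 × Nmt` reads per
discriminating site from the single inserted haplotype (he is heterozygous,
hence the `/2`) on top of `DPmt` reads of true mtDNA.  Every
insertion-derived allele then appears at the mixed-haplotype fraction

    HTF = (DPnu/2 · Nmt) / (DPnu/2 · Nmt + DPmt)

and the insertion is transmitted autosomally with probability 1/2.  Two
consequences distinguish the confounder from genuine paternal mtDNA:
structural read evidence at the nuclear locus, and an *inverse* correlation
between the haplotype's allele fraction and true mtDNA content (genuine
heteroplasmy would be diluted by neither).

## Variant filtering (`mt_calls`)

Variant records carry depth and per-strand alternate read counts on the
16,569 bp circular reference.  The filter cascade retains single-nucleotide
substitutions with AF > 1%, depth ≥ 200×, at least two reads per strand
supporting the minor allele, outside six low-complexity regions (66–71,
300–316, 513–525, 3106–3107, 12418–12425, 16182–16194).  All comparisons
are strict in the stated direction; boundary behaviour is pinned by tests.

The minor-allele strand rule needs a definition when AF > 50%, where the
minor allele is the *reference*.  We apply the rule to reference strand
counts when they are carried in the input (falling back to alt counts with a
logged warning otherwise), and we exempt conservatively homoplasmic calls
(AF > 95%): a fixed allele has no minor-allele reads whose strand balance
could indicate an artefact, and removing such calls would empty every
homoplasmy-based rule downstream (the homoplasmy-mismatch exclusion and the
father heteroplasmy counts both operate on filtered callsets).

Homoplasmy is AF > 95% (strict); heteroplasmy is 1% < AF ≤ 95%.

## Trio screen (`trio_screen`)

Per trio, on filtered callsets with a 5% screening threshold:

1. *informative variants*: father variants at AF > 5% whose key
   (position, alt) is absent from the mother's filtered callset — presence
   in the mother at any retained AF makes a variant non-informative;
2. *shared paternal variants*: informative variants detected in the child
   at AF > 5% — at least one makes the trio a putative mixed-haplotype trio;
3. *homoplasmy-mismatch exclusion*: if the father carries ≥ 3 homoplasmies
   not seen in the child at AF > 5%, genuine paternal mtDNA transmission is
   excluded (it would carry the whole haplotype), and the trio is removed;
   otherwise it is a mixed-haplotype candidate.

Extra siblings never change a trio's status; each receives its own
father–child classification with the same rules.

The independent father-led route selects fathers with strictly more than 12
heteroplasmies at AF > 1% (the package also reports the cohort's own Tukey
fence, Q3 + 1.5·IQR with linear-interpolation quartiles) who carry a NUMT
that is rare (cohort frequency < 0.1%) and large (outermost mtDNA
breakpoints > 500 bp apart, linear distance).  This route recovers
transmissions whose haplotype fraction falls below the 5% screen.

**Scaling note.** The 0.1% rarity cut presumes a cohort of tens of
thousands of individuals; in a scaled-down synthetic cohort a single
father–child carrier pair already exceeds it.  The threshold is an explicit
parameter everywhere, and on synthetic cohorts we pass the equivalent
"carried by at most ~6 individuals" value (`6.5 / cohort size`), mirroring
the most common rare NUMT observed in the study regime.

## NUMT detection (`numt_detect`, `splitalign`)

Detection consumes aligned reads (SAM); alignment itself is out of scope.

* *Discordant pairs*: exactly one end on a nuclear contig, mate on the
  mitochondrial contig, both at mapping quality ≥ 20.
* *Clustering*: single-linkage chaining of nuclear-end positions per
  (contig, orientation) with gaps ≤ 500 bp; clusters need ≥ 5 pairs.
  Orientation is the ordered pair (nuclear-end strand, mt-end strand), so
  the two junction geometries of an insertion form separate clusters.
* *Split reads*: soft-clipped reads (clip ≥ 20 bp) within 1000 bp of a
  cluster, plus clipped reads aligned only to the mitochondrial contig.
* *Realignment*: each candidate is scanned over every breakpoint `k`; the
  prefix and suffix are aligned as whole pieces (fitting alignment, free
  reference ends; match +1, mismatch −1, gap open −2, extend −1) against
  the nuclear window (both strands) and the circular mtDNA reference (both
  strands, origin handled by sequence extension with modular coordinates).
  The breakpoint maximising the combined score wins; ties prefer the
  smallest breakpoint and leftmost placement.  A piece of length L is
  accepted at fitting score ≥ (2·0.9 − 1)·L — exactly the 90% identity rule
  for ungapped alignments, while additionally penalising gapped patchwork
  paths whose "identity" would be ill-defined; a read reaching that bound
  over its whole length on one reference is contiguous, not split.  The
  scan is exact and deterministic: the fitting-DP rows of the full read are
  the scores of every prefix, so one pass per reference/strand scores all
  breakpoints, and a windowed traceback recovers coordinates and identity
  for the winner.  Micro-homology at a junction can shift the reported
  breakpoint by a base or two among co-optimal placements; junction
  clustering absorbs this with a ±5 bp tolerance.
* *Junctions*: split alignments agreeing within ±5 bp on both sides merge
  into a junction (support = count) after canonicalisation (nuclear side
  first for nu-mt; smaller position first for mt-mt; swapping flips both
  strands so opposite-orientation sightings coincide).  A junction joining
  two mtDNA locations with more than two supporting split reads is
  mega-NUMT evidence — concatenated fragments inside the insertion.
* *Cohort grouping*: per-sample calls merge (single linkage) when both the
  nuclear and the mtDNA footprints agree within 1 kb; carriers are unioned
  and cohort frequency is carriers / individuals.  Calls carry a reference
  build tag and grouping refuses mixed builds.

The mtDNA breakpoint span is the linear distance between the outermost
breakpoints as printed, with no circular wrap.

## Copy number and haplotype fraction (`copy_htf`)

Per informative variant, `Nmt = Altmt / (DPadjnumt/2)`, folding alt counts
above 50% AF (`Altmt = DPmtvar − Altmt′`: an apparent majority call means
the reported alt reads are the true mtDNA).  `DPadjnumt` is the mean
per-base nuclear depth over 1 kb flanks on each side of the detected
insertion interval, excluding ±200 bp around the junctions where clipped
reads distort coverage.  The per-carrier summary is the median of
per-variant estimates (robust to junction-proximal outliers).

The HTF grid covers nuclear depths 35–50×, true mtDNA depths 200–4500× and
1–20 copies.  Confidence bands model the alt count as
`Binomial(n = round(DPnu/2·Nmt + DPmt), p = HTF)` with exact binomial
quantiles — no normal approximation, since alt counts are small at one
copy.  `af_depth_correlation` is the Pearson product-moment r of observed
AF against mtDNA depth with a two-sided p-value; the expected direction is
negative.  (The quantity is reported as r, not R²: a coefficient of
determination cannot be negative, so output metadata carries
`statistic: pearson_r`.)

## Cohort statistics and QC (`cohort_stats`)

Clopper-Pearson intervals use beta quantiles (`scipy.stats.beta`), with
closed bounds 0 and 1 at the success boundaries; the test suite checks them
against an independent inversion of the exact binomial tail sums.  Sex is
called female when mean chrX depth is at least 10× mean chrY depth
(inclusive; zero chrY depth maps to female — the source rule states no tie
case, so inclusivity is documented and tested).  The contamination
heuristic counts nuclear heterozygous allele fractions strictly outside
[25%, 75%].

## Synthetic cohorts (`synthetic`)

The generator emulates the study regime: nuclear depth uniform 30–99×, true
mtDNA depth uniform 200–4500×, 150 bp reads, maternal mtDNA transmission,
father/mother divergence of 1–5 sites (same haplogroup) or 20–40 sites
(different haplogroups), planted mega-NUMTs of 1–3 fragments (400–1200 bp
each, either strand, outermost breakpoints > 600 bp apart) in 2–20 copies,
transmitted with probability 1/2 (or forced per planted spec so truth
labels are exact).  Sites are drawn outside the masked regions.

Choices that keep ground truth exact, and their cost in realism:

* NUMT-defining alleles are *additions* to the carrier's own haplotype at
  sites inside the inserted fragments, and background/divergence sites are
  placed outside the fragments.  Expected carrier AF is then exactly the
  HTF closed form (verified by a χ² goodness-of-fit test).  Real NUMTs also
  overlap the carrier's own variant sites, which would pull homoplasmies
  inside the insert below AF 1.
* Carrier trios draw mtDNA depth ≥ 600× (the analysed cohort is post-QC at
  ≥ 500×) and depths are rejection-sampled until the carrier's expected HTF
  lies within [0.07, 0.45] — the observed mixed-haplotype signature band
  (reported AFs 5–25%) with margin, so labels are robust to binomial noise.
  Each NUMT carries 13–22 defining sites, consistent with carriers
  exceeding the >12-heteroplasmy fence.
* Variant depth is Poisson around the expected site depth (mtDNA depth plus
  `DPnu/2·K` at NUMT sites); alt reads are binomial at the expected AF;
  strands split 50/50 binomially (no strand-bias model); homoplasmies are
  sampled at allele probability 0.995.  There is no sequencing-error model
  beyond this, no indel simulation and no repeat/segmental-duplication
  context.
* Read evidence is emitted as already-aligned SAM records: per nu-mt
  junction side, Poisson(0.35·dp_nu) discordant pairs of homogeneous
  orientation; per unique junction (two nu-mt, plus the mt-mt joins between
  consecutive concatemer fragments including the tandem wrap when K ≥ 2),
  Poisson(0.2·dp_nu) split reads whose sequences are literally the two
  reference sides; concordant background pairs cover ±2.2 kb of the
  insertion at the sample's nuclear depth so flanking-depth estimation
  works end-to-end.  The rates are calibrated to the order of magnitude of
  reported read support (discordant ~5–40, split ~2–17 at 30–99×); support
  for a unique junction is not scaled with copy number, treating the
  collapsed alignment of the tandem array onto the reference as
  breakpoint-local coverage.  Only carrier-family samples receive reads;
  detection on a sample without reads is a no-op.

All randomness flows from the single config seed (`numpy.random.default_rng`);
bundles are byte-identical across reruns.  Because the generator plants
clean, well-separated signals, passing tests show the pipeline's rules and
plumbing are correct — they do not show robustness to alignment artefacts,
repeat context, contamination or low-complexity noise in real cohorts.

## Pipeline (`pipeline`)

Fixed stage order: QC (trio mtDNA depth ≥ 500×, parental sex consistency
from sex-chromosome depths, extreme-heterozygote counts reported) → trio
screen → father heteroplasmy outliers → NUMT detection on flagged families →
cohort grouping → father-led screen → candidate co-segregation annotation →
copy-number estimates → transmission summary over father-screen hits
(transmitted = the child carries the father's grouped call).  Trio
classification never reads NUMT calls, so the two discovery routes stay
independent.  Thresholds are echoed into the report; reports are
deterministic given the bundle and parameters.

## Problem sizes in the checks

The acceptance suite exercises: a 500-trio cohort with 5 planted fathers
(label recovery), 500 replicates per cell of the K ∈ {2,5,10,20} ×
DPmt ∈ {500,1500,4000} recovery grid, 1,000 constructed 150-mers against
the exhaustive per-breakpoint realignment oracle (on a 500 bp nuclear
window and a 700 bp circular mtDNA stand-in, so the oracle's quadratic scan
stays cheap), a 50-case Clopper-Pearson grid at 1e-9 agreement, and the
full 4 × 44 × 20 HTF grid.  `scripts/acceptance.py` re-runs the same
computations at a 150-trio scale and writes the headline numbers as JSON.

## Known limitations

* No realignment/pileup generation: inputs are call tables and aligned
  reads; aligner idiosyncrasies (clip placement, mapq calibration) are out
  of scope.
* Haplogroup assignment, relatedness verification and contamination mixture
  estimation are not implemented; the pedigree is trusted.
* The breakpoint span is linear; an origin-spanning NUMT's span is not
  computed on the circle (only split-read realignment honours circularity).
* No GRCh37↔38 liftover: grouping refuses mixed reference builds.
* The simulator does not model NUMT alleles overlapping carrier variant
  sites, strand bias, or depth-dependent error.
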