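# Methods

## The assay being modelled

Two transgenic *rosy* alleles, each null for xanthine dehydrogenase activity
through a single point mutation (*ry606N* at −468, *ry609N* at +3506), sit at
the same landing site on homologous chromosomes of a female.  Meiotic
recombination between them can reassemble a functional *ry⁺* allele, and
dietary purine kills all larvae without one, so a screen of ~10⁶ progeny
recovers the handful of recombinant gametes.  Each recovered recombinant is
typed at two flanking restriction-site markers (KpnI at −3149, destroyed on
*ry606N*; AgeI at +6998, destroyed on *ry609N*) and sequenced across the 21
silent polymorphisms to map its conversion tract.

Locus coordinates are signed and have no zero (+1 corresponds to assembly
coordinate 3R:8,859,890).  The package converts to assembly coordinates
before any distance arithmetic; this is the only safe way to measure spans
that straddle the origin.

## Classification

The parental flank configurations are *ry606N* = KpnI⁻ AgeI⁺ and *ry609N* =
KpnI⁺ AgeI⁻.  A single exchange between the selected sites must join the
KpnI⁺ left arm of *ry609N* to the AgeI⁺ right arm of *ry606N*, so
KpnI⁺ AgeI⁺ is called a crossover; either parental configuration is a
noncrossover conversion on the corresponding recipient; KpnI⁻ AgeI⁻ matches
no single-event product and is reported as anomalous.  The call is wrong
exactly when a conversion tract co-converts a flanking marker; the simulator
quantifies this (see below), and with 800-bp mean tracts such events are a
small minority because both flanks sit ≳2.7 kb from the nearest selected
site.

## Tract-length estimation

For a noncrossover with outermost converted sites c₁ ≤ c₂ and nearest
*observed* unconverted heterologies u_L < c₁ and u_R > c₂ (assembly
coordinates):

* minimum = c₂ − c₁ (0 for a single converted site: the span convention);
* maximum = u_R − u_L − 1 (the widest interval strictly between the bounds;
  the exclusive convention is a package choice and is stated here because
  only the drawing of the bounds, not the formula, is conventional);
* midpoint estimate = (c₂ + u_R)/2 − (c₁ + u_L)/2, i.e. each tract end is
  placed halfway between the last converted and first unconverted site.

min ≤ mid ≤ max holds identically (u_R ≥ c₂ + 1 and u_L ≤ c₁ − 1).  When no
unconverted site is observed on a side the bound degenerates to one base
beyond the outermost converted marker and the estimate is flagged censored
on that side; censored and incompletely genotyped records are tallied
separately in summaries rather than pooled into tract means.  Discontinuous
conversion (an unconverted site inside the converted span) is flagged and
retained, with the full span used for the minimum.  The two flanking
restriction-site markers participate as ordinary heterologies in bounding,
since they are *bona fide* sequence differences between the transgenes.

## The forward simulator

The generator is deliberately minimal — the simplest model that reproduces
the assay's observable structure:

* each transmitted chromatid carries an event with probability
  `event_rate` (default 3 × 10⁻⁵, the scale of the observed per-progeny
  rates); gametes are independent — the assay sees one chromatid per progeny,
  so tetrad structure is unobservable and not modelled;
* the DSB position is uniform on `dsb_window` (default: the full −3149…+6998
  marker span); the recipient chromatid is a fair choice between the two
  parental alleles;
* the conversion tract extends left and right of the DSB by independent
  geometric lengths with mean `mean_tract_bp`/2 each (default 800 bp total —
  the scale of observed mid-tract estimates; geometric tails are the minimal
  single-parameter tract model);
* the event resolves as a crossover with probability `p_co` (default 0.68,
  the crossover share of events recovered at the endogenous locus, 112/165);
* conversion is unidirectional (recipient copies donor across the tract;
  donor is never altered).  For a crossover the exchange falls at a tract
  end; with recipient-only conversion the two reciprocal products are
  algebraically the same whichever end is chosen — a recipient/donor
  junction at the left tract edge and a donor/recipient junction at the
  right edge — and the transmitted chromatid is a fair draw between them.

Under this geometry at most one crossover product can be wild type at both
null sites (the junction on the side of the recipient's null site must fall
between the selected sites), and it is transmitted with probability ½ —
which is precisely the factor-2 selection correction applied when counts are
converted to map units.  Position effects between landing sites are emulated
solely by scaling `event_rate` (to zero for fully silent sites); no
chromatin mechanism is modelled.

What the simulator therefore does *not* emulate: crossover interference,
heteroduplex repair direction bias, sister-chromatid events, genotyping
error, and any mechanistic cause of rate variation.  Passing tests show that
the classifier and estimators are faithful to this generative model, not
that real tracts are geometric.

One behaviour of the real assay that the simulation makes explicit: selected
noncrossovers are a length-biased sample (a tract must cover the recipient's
null site to be recovered), so the mean midpoint estimate among recovered
NCOs (~1.6 kb in simulation at an 800-bp true mean, with 25 markers over
10 kb) substantially exceeds the unconditional mean tract length.  Observed
tract-length summaries from such screens should be read with both the
length-biasing and the marker-resolution ceiling in mind.

## Rate statistics

Rates are plain proportions, with zero-count rates carried as 0 plus an
explicit no-events flag.  Locations are compared with a two-sided Fisher
exact test on the 2×2 table *(events, thousands of progeny screened)*, with
thousands rounded half-up — the events-versus-thousands layout is the
convention under which the assay's published p-values reproduce, and the
table builder refuses counts exceeding the rounded thousands.  The two-sided
p sums all conditional tables whose hypergeometric probability does not
exceed the observed one (1 + 10⁻⁷ relative tie tolerance); the
implementation delegates to `scipy.stats.fisher_exact`, and the test suite
checks it against exact integer enumeration on every table with total ≤ 40.
No multiple-testing correction is applied; raw p-values are reported.

Map units are 100 × `recovery_factor` × CO/progeny with `recovery_factor`
= 2 by default (the selection correction above).  Per-Mb normalization uses
the inclusive 3974-bp span between the selected sites — the interval within
which an exchange is selectable — which is the package's normalization
choice for intragenic densities; regional standard-map rates are simply
genetic length / physical length of the flanking-gene interval.

## Numerical and design choices

* Five marker-table rows (−527, −468, −332, −323, −320) are assigned to the
  *ry606N* haplotype per the construction record of the alleles; this is the
  only assignment under which *ry⁺* selection is coherent (the packaged
  fixture's docstring details it).  Indels are point markers at their stated
  position; inserted bases never count toward distances.
* Progeny estimation from the untreated bottle supports both ×(tray − 1)
  (default: the untreated bottle estimates each *treated* bottle) and
  ×tray multipliers.
* A conversion tract extending beyond the marker span is truncated to the
  span for state substitution (with a warning); the recorded true tract is
  untouched.
* All randomness in a run flows from the single integer seed in the
  configuration; repeated runs are byte-identical.
* Simulation sizes in the test suite (10⁵-event classifier/bracketing
  screens, 2 × 10⁶-gamete parameter recovery, 3-standard-error Monte-Carlo
  tolerances) were chosen to keep each property sharp at interactive
  runtimes.

## Known limitations

* The tract model is single-parameter; real tract-length distributions may
  have heavier tails, which would raise flank co-conversion rates above the
  simulated ones.
* Anomalous (KpnI⁻ AgeI⁻) records are counted but not mechanistically
  interpreted (they would require double events or marker loss).
* The per-Mb density compares a 4-kb transgenic interval against Mb-scale
  standard-map intervals; fine-scale rate heterogeneity within the regional
  intervals is not modelled.
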