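# Methods

`tcsorg` classifies the genetic and domain organisation of prokaryotic
two-component system (TCS) genes. This note records the model, the
parameters that matter, the numerical choices made where the procedure was
genuinely open, what the synthetic generator does and does not emulate, and
the known limitations.

## The classification scheme

**Inputs.** A per-gene coordinate table (replicon, 1-based inclusive
start/stop on the forward axis, strand) and a per-protein table of
signalling-domain hits, each hit classed as HATPase (`h`), phosphotransfer
(`P`, HisKA/Hpt-type) or receiver (`R`) through a domain-name → class map.
The package performs no HMM scanning: domain calls are inputs, as produced
by annotation databases. Domains outside the three signalling classes are
ignored. Overlapping hits within one protein are resolved deterministically
(keep the hit with the smaller start; on ties the longer one) so that the
per-protein hit list is non-nesting — the upstream annotation is silent on
overlaps and a reproducible rule is required.

**Architecture strings.** Hits are scanned N→C. Every `h` whose immediately
preceding, still-unconsumed signalling domain is a `P` merges with it into a
transmitter `T` (the Ph unit of a histidine kinase); an `h` without such a
partner is dropped and counted, because an isolated HATPase domain carries
no phospho-accepting histidine. `R` and unpaired `P` pass through in order.
Three choices here were open and are fixed as follows:

* *Adjacency* means no intervening signalling domain and no residue-gap
  limit. The hit tables carry no reliable inter-domain spacing semantics,
  and the Ph unit is defined by domain order, not by distance.
* The order `hP` does **not** form a transmitter: in canonical kinases the
  phospho-acceptor domain is N-terminal to the ATPase domain.
* Pairing is greedy left-to-right, each `P` serving at most one `h`. On all
  hit sequences of length ≤ 6 this is provably equivalent (tested
  exhaustively) to the pairing that maximises the number of adjacent Ph
  units, because adjacent-pair selection on a path admits a greedy optimum.

**Categories.** From the string: ≥1 T and ≥1 R → hybrid HK; ≥1 T → HK;
≥1 R → RR; only P → PP (phosphotransfer protein); empty string →
excluded. Genes flagged `mispredicted` are excluded outright; genes flagged
`incomplete_hk` are forced to the kinase side (HK, or hybrid HK if they
carry a receiver) even when no transmitter survives the scan. Hybrid
kinases count as HKs wherever categories are aggregated; census tables
expose both the aggregate and the split.

**Clusters and foci.** Within one replicon, consecutive TCS genes are
linked when the count of intervening bases (`right.start − left.end − 1`)
is ≤ the cutoff; abutting genes are 0 bp apart and overlapping genes are
negative. A *cluster* is a maximal linked run regardless of strand; a
*focus* additionally breaks at every strand change; an orphan is a size-1
focus. Only TCS genes participate — intervening non-TCS genes neither
break nor create linkage, because distances are computed on the TCS-only
gene list. Foci render two string views 5'→3' (member order reversed on
the minus strand): a gene string over HK/RR/PP joined by `>`, and a domain
string joining member architectures with `-` at gene junctions. Identical
start coordinates are ordered by end then locus tag. Replicons default to
linear topology; circular topology is supported (the wrap interval between
the last and first gene is evaluated, requiring the replicon length) but
off by default since coordinate tables rarely state topology reliably.

**The 200 bp default cutoff.** Ranking inter-gene distances ascending and
reading rank as a function of distance separates a steep pile of tandem
pairs near 0 bp from a pseudo-linear random regime at large distances; the
boundary sits near 200 bp in genome-scale data, which is also a standard
operon-prediction threshold. 200 bp is therefore the default `cutoff_bp`
everywhere, and the `cutoff` module re-derives the value from data.

## Cut-off estimation

`fit_random_regime` fits rank = slope·distance + intercept by least squares
to the largest `tail_fraction` (default 0.5) of the non-negative distances;
negative distances (overlaps) are real intervals and stay in the curve but
are excluded from the fit, being definitionally non-random.
`estimate_cutoff` scans distinct distances from large to small and returns
the largest distance whose empirical rank deviates from the fitted line by
more than `departure_tolerance × n` intervals (default 0.05). The absolute
deviation is used: the tail fit's intercept absorbs the paired mass, so
below the knee the empirical curve falls *below* the line. On a pure
background no departure ever exceeds the tolerance (deviations scale as
√n) and the estimator returns 0 with `knee_found=False`.
`false_positive_rate` extrapolates the fitted line: slope × cutoff predicts
the number of random-regime intervals admitted below the cutoff, divided by
the configured denominator (default: total interval count; a per-gene basis
can be supplied, since the appropriate denominator is a reporting choice).

## Metrics

Per replicon: **Dissemination** = 100 × orphan genes / TCS genes;
**Sophistication** = 100 × genes in foci of > 2 genes / TCS genes. The
gene basis is the default because a focus-count basis ("% of foci with > 2
genes") measures a different, size-biased quantity; both are available via
`basis=` and labelled in output. The diversity family counts distinct
focus gene-organisation strings (overall, and among > 2-gene foci).
Replicons with zero TCS genes are excluded from per-replicon averages;
dataset-level percentages are gene-weighted. Group comparisons (e.g.
plasmid vs whole-dataset focus-size distributions) use Pearson's χ² with
df = k − 1 against expected counts taken directly or rescaled from a
reference group's proportions; expected cells < 5 raise a warning flag,
not an error.

## Synthetic data

The generator emulates database-style TCS extracts: each replicon carries
`foci_per_replicon` planted foci drawn from a focus-size distribution
(default 58% orphans, 39.5% pairs, 2% triads, 0.5% tetrads — the survey-
scale focus frequencies), each realised from a weighted template menu of
architecture tuples (HK–RR pairs, hybrid `TR` orphans, phosphorelays
`TRP-R`, `TRRP-R`, `T-R-T-R`, RR/PP orphans). Intra-focus gaps are normal
(loc 20 bp, scale 24 bp, truncated to [−60, 150]), giving ≈ 20% negative
gaps — overlapping tandem genes, matching the well-documented overlap
frequency. Inter-focus spacings are uniform on [1 000, 20 000] bp. Because
gaps are truncated at `gap_max` and spacings start at `spacing_min`, the
planted partition is recoverable exactly at any cutoff in
`[gap_max, spacing_min)`; the tests exploit this window.

For cut-off recovery studies, `mixture_intervals_config` plants only pairs
with near-flat gaps over a chosen pairing scale (default 150 bp) against
the uniform background, mimicking the two-regime rank curve.

What the generator does **not** emulate: non-TCS genes (the pipeline never
sees them), nucleotide sequence, gene-length variation beyond a
domain-count proxy, replicon-specific gene-density gradients, and
phylogenetic correlation between replicons. Passing tests therefore
validate the interval arithmetic, partition logic and estimator behaviour
under the stated geometry — not robustness to annotation error (start-site
mis-calls shift distances directly) or to taxon-specific organisation.

## Validation fixtures and problem sizes

Census arithmetic is validated against fixtures reconstructed from the
printed tables of a genome-wide survey of 1,405 prokaryotic replicons
(43,426 curated TCS genes); where a printed table is under-determined below
its marginals, any integer decomposition matching the totals is used — the
validated statistics depend only on the marginals. Property suites run on
1,000 simulated replicons; the clustering oracle check enumerates all gap
patterns over a boundary-straddling grid for 2–8 genes; cut-off recovery
uses 20 seeds of a 6-replicon, 40-foci-per-replicon mixture (≈ 480 genes
per seed). These sizes keep the whole suite under a minute while leaving
every estimate's sampling error far inside the asserted windows.

## Known limitations

* The default domain-class map is minimal (HisKA variants, Hpt, HATPase_c,
  Response_reg); real analyses should supply the fuller curated map for
  their annotation source.
* The knee estimator assumes a single background regime; strongly
  heterogeneous replicon mixtures can bow the tail and bias the knee.
* Circular-topology handling evaluates a single wrap interval; a ring in
  which *every* adjacent pair is linked is reported in coordinate order.
* Sophistication is unstable on replicons with few TCS genes (it is a
  percentage of a small count); the per-replicon tables report the raw
  counts alongside.
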