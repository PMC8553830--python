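# Methods

## Coordinate model

All junctions are held internally as 0-based, half-open intervals
(BED convention): `start0` is the index of the back-splice acceptor base,
`end0` is one past the donor base.  CIRCexplorer, KNIFE and find_circ are
read as 0-based; CIRI2, MapSplice and DCC as 1-based inclusive, converted
by `(s, e) → (s−1, e)`.  Records arriving donor-first (MapSplice's usual
back-splice order) are reordered by numeric value before conversion.
Half-open was chosen over 0-based fully-closed so that junction keys are
directly valid BED intervals and interval arithmetic needs no ±1 terms.
A junction must span at least two bases — a "circle" whose donor and
acceptor coincide is rejected as degenerate at parse time.  Chromosome
names are normalized to the `chr`-prefixed dialect.  Strand is carried in
every record but cross-caller matching is strand-unaware by default
(`FilterConfig.strand_aware`): find_circ infers strand without annotation
and callers disagree on it often enough that stranded matching would
fragment otherwise identical junctions; the flag exists for users whose
callers agree.

## Detection filters and consensus

Within one biofluid, per caller: detected in a sample ⇔ count ≥
`min_reads` (default 2); retained ⇔ detected in ≥ `min_samples` samples
(default 5).  The filters are applied independently per biofluid because
catalog sizes and per-sample yields are reported per fluid.  The
consensus is the strict six-caller intersection of retained sets; a
relaxed `min_tools` variant exists for sensitivity analyses but is never
the default.  Intersection-pattern tables use exclusive (UpSet)
semantics: each junction of the union is counted once, under its exact
caller-membership pattern, so pattern counts sum to the union size.

For prevalence tiers a consensus junction counts as detected in a sample
when **any** caller reports it there with ≥ `min_reads` reads
(`detection_mode="any"`); the stricter all-six rule is available.  Tier
t counts junctions detected in ≥ ⌈t·n⌉ samples ("at least t percent"),
which makes tier counts non-increasing in t by construction.

Two expression pre-filters mirror common practice before differential
analysis: drop samples detecting fewer than `min_circ_per_sample`
junctions (default 300), then drop junctions detected in fewer than half
of the remaining samples.  The synthetic demo configurations lower the
sample threshold to 100 because the simulated catalogs (≈300 junctions)
are an order of magnitude smaller than a real biofluid catalog; the
threshold should scale with catalog size, not be treated as universal.

## Quantification

`JRPM = count / (canonical + chimeric junction reads) × 10⁶`.  The
denominator comes from an explicit per-sample totals table rather than
being re-derived from alignment by-products, keeping it inspectable; a
helper can sum SJ.out.tab column 7 when no totals are available.

`CLR = count / max(linear5, linear3)`, pseudocount 1 when both flanks are
zero, so `CLR(c, 0, 0) = c`.  A linear junction belongs to the 5′ flank
when its intron ends at the base before the circle
(`intron_end1 == start0`) — same acceptor splice site — and to the 3′
flank when its intron starts just after the donor
(`intron_start1 − 1 == end0`).  Multiple linear junctions sharing a flank
splice site (alternative partners) are **summed**, since the quantity of
interest is linear spliced reads through the shared site, not the single
strongest partner; only uniquely-mapping reads (SJ.out.tab column 7)
contribute, as multi-mapper counts are unreliable for quantification.
When several callers contribute counts for a consensus junction, the
pipeline quantifies the per-sample maximum across callers — the
permissive analog of any-caller detection.

CLR summaries are computed per sample over junctions with nonzero
back-spliced counts — fraction with CLR > 1, and the (1, 5] and > 5
bands — then averaged across samples, so deep samples do not dominate.

## Annotation

Genes are assigned by ≥ 1 bp overlap between the junction interval and
transcript intervals (interval-tree lookup).  Among overlapping
transcripts, the classifier prefers the one with both junction
boundaries inside exons, then the most exons intersected, then the
lexicographically smallest name — a deterministic tie-break for
multi-isoform loci where no convention is established.  Primary classes
are mutually exclusive, assigned in order: single-exon (both boundaries
in one exon), multi-exon spanning an intron (≥ 2 exons intersected),
intronic (entirely inside one intron), boundary-outside-exon (gene
overlap but the exon model does not explain the junction), intergenic.
UTR flags are set when the junction intersects the transcript region
outside the CDS, with 5′/3′ orientation following transcript strand.

## Stability statistics

CV uses the sample (n−1) standard deviation over the mean, per junction,
restricted to junctions with nonzero mean in the scope considered.
Within-participant CVs (participants with ≥ 5 samples in the biofluid)
are pooled and compared against the global CV distribution with a
two-sided Mann–Whitney rank-sum test; the test is unnamed in common
practice for this comparison, and a distribution-free choice is
appropriate for right-skewed CV distributions.  Per-participant tests
against the global distribution are also emitted, since pooling and
per-individual testing answer slightly different questions; both outputs
are provided rather than asserting one.

Inter-caller agreement: per caller, the per-junction mean JRPM over the
union of retained junctions (zero-filled where unreported), then pairwise
Pearson correlation.  A flattened junction×sample basis is possible but
the mean-profile basis is the default.

Rank concordance consumes a table of per-item mean Ct (qRT-PCR) and mean
JRPM (RNA-Seq): Ct ranks ascending (low Ct = abundant), JRPM descending;
items missing on one platform rank last in input order; Spearman's rho is
computed over complete pairs.  The bundled validation panel
(`circfluid.datasets.validation_panel`) carries the published mean
Ct/JRPM values of the 15 most abundant circRNAs per biofluid; re-ranking
them reproduces the published rank columns exactly, and the near-zero
rho (−0.075 plasma, 0.0 urine) reflects the published observation that
the two platforms order these transcripts very differently.

## Synthetic-study generator

The generator emulates the design of a longitudinal two-biofluid cohort,
scaled to run in seconds: 12 participants, each contributing plasma and
urine, 4 sampled 6 times and the rest twice (80 samples total); 300
truth junctions per biofluid with 85% of the urine set shared with
plasma; baseline abundances log-normal on the JRPM scale
(ln-mean 1.6, ln-sd 1.2 — median ≈ 5 JRPM with a heavy upper tail);
participant effects log-normal (ln-sd 0.5) multiplying each junction's
abundance per participant; per-sample library sizes (total junction
reads) uniform on 2–8 × 10⁵; counts negative-binomial with dispersion 5,
mean `abundance × offset × library/10⁶` — overdispersion keeps the CV
analysis non-degenerate.  Truth junctions are planted at known features
of a synthetic multi-exon annotation (70% multi-exon, 2% single-exon,
8% intronic, 20% intergenic, echoing the dominance of exon-spanning
circles in real catalogs), with unique acceptor and donor coordinates so
flank splice sites never collide.  80% of junctions receive linear
flanks (NB, mean 20 reads per flank); 20% of those split the 5′ flank
across two SJ records to exercise flank summation; decoy linear
junctions are placed away from all flank splice sites.

Per-caller noise: independent dropout per (junction, sample) at rates
0.02–0.15 ordered like the observed sensitivity spread of real callers
(KNIFE most sensitive, MapSplice least), and false positives drawn
independently per caller from a shared pool of non-truth loci (rate 0.02
per locus per sample by default).  Independence across callers is the
property that makes the strict intersection suppress false positives,
and the simulation is designed to exhibit exactly that.

Counts are bumped post-hoc so that every truth junction has ≥ 2 reads in
≥ 5 samples *before* caller noise: without this, a low-abundance truth
junction can fail the detection filters for purely sampling reasons, and
noiseless-recovery tests would measure tail luck instead of pipeline
correctness.  The bump is deterministic (highest-expectation samples
first) and recorded in the manifest via the counts themselves.

What the generator does **not** emulate: read sequences and alignment
artifacts, caller-specific systematic biases (shared false positives,
annotation-driven blind spots), GC/length effects, 3′ coverage bias of
fragmented extracellular RNA, and real inter-caller correlation
structure — its caller disagreement is purely stochastic.  Passing tests
therefore demonstrate correctness of the harmonization arithmetic and
the qualitative behavior of the filters, not caller performance on real
biofluid libraries.

## Numerical choices and limitations

Ties at prevalence-tier boundaries use ≥; sample QC uses ≥ (`at least
300`), the prevalence exclusion is strict `< 50%`.  CV is undefined for
zero-mean junctions (excluded per scope) and for single samples
(participants below `min_visits` never enter the within arm).  Zero
counts yield JRPM 0 and CLR 0; zero-variance vectors yield NaN
correlations, reported as not-applicable rather than dropped silently.
Duplicate reports of one junction in one sample file are summed.
Junction matching is exact on coordinates — no ±N fuzzy merging — and no
liftover between genome builds is attempted; trans-chromosomal records
are rejected with a warning.  Problem sizes throughout (cohort, catalog,
seed counts in the acceptance script) are chosen so a full verification
run completes in well under a minute on one CPU core.
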