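# Methods

## The survey procedure

The pipeline reconstructs a genomic survey of [2Fe-2S] cluster motifs in
protoporphyrin/coproporphyrin ferrochelatases (PpfC/CpfC; the archaeal
sirohydrochlorin chelatase SirB is a different fold and out of scope).
Stages run in a fixed order: load and join sequences with genome
metadata → optionally pare genomes → apply fusion trim spans → verify
the catalytic histidine → annotate regions against the reference → scan
for cysteine motifs → call MCF status → statistics → trees. Records that
fail the His check stay in the per-record table with disposition
`dropped:no_his` (their genomes survive if a second functional copy
exists); everything downstream uses only kept records.

### Genome paring

Public genome collections oversample clinically interesting lineages.
The sampler keeps one genome per genus — preferring genomes with a
biochemically characterized ferrochelatase, then type strains, then the
lexicographically smallest genome id — and then caps each order at ten
genomes, filled round-robin over the order's families (families cycled
in ascending name order) so representation is as even as the cap allows.
The priority order makes paring a deterministic total order: it is
idempotent and independent of input ordering. Tie-breaking by genome id
is this package's convention; any fixed key would do.

### Catalytic-His verification and region annotation

Each candidate is globally aligned to a single reference ferrochelatase
(human numbering; catalytic His at 263) with an affine-gap
Needleman–Wunsch/Gotoh aligner: BLOSUM62, gap open −11, gap extend −1, a
gap of length L costing `open + (L−1)·extend`, integer arithmetic
throughout, and a fixed traceback tie-break (diagonal, then vertical,
then horizontal) so reported alignments are reproducible. A sequence is
functional iff the query column aligned to reference position 263 holds
H; a deletion at that column is reported as reason `deleted`.

The reference profile carries a core span — the conserved fold,
excluding the reference's own targeting sequence and its C-terminal
extension. Query residues aligned before the core span form the
N-terminal extension; maximal query runs aligned to reference gaps
strictly inside the core span are internal insertions when at least
`min_insertion = 15` residues long (observed insertions are 22–34
residues; 15 tolerates truncated variants); query residues aligned after
the core span form the C-terminal tail when at least `min_tail = 10`
long. Shorter runs are absorbed into the core, so the three regions plus
core always partition the query. Both thresholds are package
conventions — the original analysis read regions off a curated multiple
alignment without stating numeric cutoffs — and are configurable.

Reference mapping is pairwise by design: it avoids an external multiple
aligner, gives per-record provenance, and the one reference column
system makes coordinates comparable across records. The cost is that
query-specific insertions are invisible to downstream tree distances
(see Trees).

### Motif engine

The pattern language is the PROSITE subset the survey needs: literal
residues, `X`, `X(n)`, `X(n,m)`, optional `-` separators. The scanner
enumerates *all* matches, including overlapping ones, and collapses
alternative wildcard realizations to one hit per distinct tuple of
literal positions. `X` matches cysteine too — deliberately, so the
consensus `C-X(1,11)-C-X(1,11)-C` also matches XCCX (all four
coordinating cysteines close together, the pattern's X consuming one of
the adjacent pair) and CXC arrangements. The fourth coordinating
cysteine is *not* required by the consensus: in several proteins it lies
too far away to include without destroying specificity.

MCF calling is strict containment: a hit qualifies only if every literal
cysteine lies within a single insertion span, or every one within the
tail. Hits straddling a boundary, or anywhere else in the protein, are
recorded with location `other` and do not qualify — clusters have only
ever been confirmed in the insertion and the C-terminus. When both
locations carry hits the insertion is reported as the qualifying
location. His-rich tails are flagged at a histidine fraction of
`his_rich_threshold = 0.15` (a convention; the cyanobacterial tails this
targets are far above it), and the CAB-domain motif EXXNXR is searched
only within the tail.

### Statistics

- Binned motif likelihood: per cysteine-count bin, `p̂ = k/n` with the
  plain binomial standard error `sqrt(p̂(1−p̂)/n)` — the only formula
  consistent with ±0.27 at n = 3, p̂ = 2/3. Default bins [0–3], [4–5],
  [6–10], [11+]; the bin edges in the source narrative overlap at six,
  so the defaults are a package choice and configurable.
- Logistic regression of motif presence on cysteine count: IRLS
  (Newton–Raphson on the log-likelihood), standard errors from the
  inverse observed information at the optimum, 95% Wald interval
  reported on the odds-ratio scale. Convergence tolerance 1e-8 on the
  step, max 50 iterations; the linear predictor is clipped at ±30 so
  quasi-separated data cannot overflow — such fits are returned with
  `converged=False` rather than raised. The Wald interval is a package
  choice; the original report prints a single lower confidence bound
  without naming the method.
- Cross-tabulations are species-level: a genome is MCF-containing if
  *any* of its records is (genomes with duplicate ferrochelatases, one
  carrying the motif, count once). Percentages round to the nearest
  whole percent, halves up, matching the published tables' arithmetic.
  Two denominator conventions exist: per-row (`mcf/total` within a
  category) and MCF-share (`category mcf / all mcf`).

### Trees

The tree protocol follows the survey's stated settings: p-distances with
pairwise gap deletion, generalized b-state Jukes–Cantor correction with
b = 20 for proteins (`d = −((b−1)/b)·ln(1 − (b/(b−1))·p)`), neighbor
joining (Studier–Keppler Q-criterion, ties broken by the smallest pair
of cluster labels, negative branch lengths clamped to zero with a log
note), column bootstrap with 100 replicates, and a strict >50%
majority-rule consensus (bipartitions above a strict majority are always
mutually compatible; the builder still adds them greedily by decreasing
support so other thresholds behave sensibly). Whether the original tool
used pairwise or complete gap deletion is unknown; pairwise is the
default and saturated pairs can either raise or be capped.

When a precomputed multiple alignment is supplied the tree stage uses
it. Otherwise distances are computed on a reference-projected
pseudo-MSA: each kept query's residues at each reference column, query
insertions and tails dropped. This is a deliberate design choice — it
keeps the package free of an external multiple aligner — and means the
default tree sees core signal only; the core tree restricts further to
the reference core span. The bootstrap seed default (95549) is recorded
in output metadata for provenance; any seed may be passed.

## The synthetic-data generator

The generator is the package's ground-truth instrument. Defaults are the
survey's observed conditions: 14/497 records missing the catalytic His;
extension/insertion/tail frequencies 56/482, 63/482 and 215/482; motif
probability 60/63 given an insertion and 29/215 given (only) a tail;
insertion lengths 22–34; and metadata associations (72% of MCF species
aerobic or strictly aerobic vs 44% overall, COG0633 in 273/414 genomes,
GC means 45/56/51% for insertion-MCF, C-terminal-MCF and non-MCF
species, a mesophile-dominated temperature distribution, and an
aquatic/soil-skewed habitat distribution for MCF species).

Cysteine counts follow a class-conditional Poisson construction: motif
status is decided first from the region conditionals, then the *total*
cysteine count is drawn from Poisson(λ₀) for motif-free records and
Poisson(λ₁ = λ₀·e^{b₁}) for motif carriers, with λ₀ =
`background_cys_rate` × core length = 3.4 and b₁ = ln 2.61. By Bayes'
rule this makes motif presence *exactly* logistic in the cysteine count
with slope b₁ — the property the parameter-recovery tests rely on — and
the implied mean of ≈4.4 cysteines per sequence matches the survey. The
intercept is therefore not a free parameter; it is implied by the motif
prevalence and λ₀ (exposed as `GeneratorConfig.implied_logistic_b0`).
Motif-carrying records use three (or, with the XCCX variant at
probability 0.5, four) of their cysteines for the motif; the rest are
background.

Label exactness is enforced by construction plus verification. Background
cysteines are rejection-sampled so that no consensus triple exists
anywhere in the sequence except the planted motif (cap 1000 placements);
and each record's random content — core point mutations at rate 3%,
segment sequences — is redrawn (cap 50) until the package's own
reference alignment recovers the planted labels: His status, region
presence flags, and motif containment in the annotated qualifying
region. Exact span boundaries may still wobble by a residue or two with
alignment gap placement; presence, location and MCF status are what the
labels guarantee, and what label-recovery checks compare. Insertion,
extension and tail content is drawn from a disordered-loop-biased
composition (G/S/P/E/K-rich), like the low-complexity segments it
mimics; insertion-bearing records additionally derive their core from a
shared lineage template 12% diverged from the base, which is what makes
the insertion clade recoverable by the tree stage. The synthetic
reference (shipped as `data/synthetic_reference_fech.tsv` and
regenerable with `make_synthetic_reference()`) is a cysteine-free,
deterministic stand-in with the human reference's shape: targeting
prefix 1–62, core 63–423, His at 263, C-terminal segment 424–453.

What the generator does **not** emulate: real substitution processes
down a phylogeny (tree correctness is tested on additive matrices
instead), sequence homology between different species' tails, database
retrieval artifacts, annotation errors, and the real cohort's exact
cysteine-count distribution (the survey's binned likelihoods 0.51/0.03
are not jointly consistent with a single logistic curve; the generator
is faithful to the odds ratio, not to every bin). Passing tests
therefore demonstrate that the machinery is correct under controlled
conditions, not that the original cohort's numbers are reproduced —
those require the original curated sequence list.

## Problem sizes

The default test and acceptance runs use cohorts of 500 records for
label recovery and statistics (matching the survey's ~500 ORFs), 50
cohorts of 500 for confidence-interval coverage (coverage ≥ 42/50,
the lower binomial tolerance band around nominal 95%), 100 random
additive 6-taxon matrices for neighbor joining, 1000 random C-enriched
sequences for the scanner/oracle equivalence, and a 40-sequence cohort
for the full bootstrap tree protocol.

## Known limitations

- Region annotation inherits the reference-projection's blind spots: a
  query feature with no reference context (e.g., a tail far longer than
  the reference's) is annotated correctly but contributes nothing to
  tree distances.
- The logistic model is univariate by design; no confounder adjustment.
- The consensus builder returns topology and supports but no consensus
  branch lengths.
- Structure-based analyses (fold modeling, cluster geometry) are out of
  scope.
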