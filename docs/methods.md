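# Methods

## Streamlining traits

GC content is `100·(G+C)/(A+C+G+T)` over all contigs, case-insensitive;
ambiguity codes (including N) leave both numerator and denominator, so a
softmasked or partially ambiguous assembly is measured only on its
unambiguous bases. Coding density is the fraction of assembly length
covered by the union of CDS intervals; intervals are 1-based inclusive
(GFF3 convention), strands are merged, and overlaps are never counted
twice — density is a genomic-space fraction, not a per-strand one.
Completeness-corrected size is `assembly_length/(completeness/100)`;
completeness estimates above 100% (possible from marker-based tools) are
used as given with a warning rather than capped, because silently capping
would bias clade means invisibly. Clade summaries report the sample mean,
the n−1 standard deviation and a normal-approximation 95% CI half-width
(`1.96·sd/√n`); the normal quantile was chosen over a t-quantile for
determinism and simplicity, and at the clade sizes involved (n ≳ 6) the
difference is below the reporting precision.

## Proteome C:N ratio

Carbon and nitrogen atoms are counted per residue using the free amino
acid formulas; peptide-bond condensation removes only H₂O, so per-residue
C and N in a chain equal the free form and no terminal correction is
needed. Selenocysteine (C3/N1) and pyrrolysine (C12/N3) are counted; the
ambiguity codes X/B/Z/J are skipped and tallied rather than guessed, and
stop symbols are ignored. The ratio is reported as carbon over nitrogen:
higher values mean lower nitrogen demand.

## Paralog detection

Within-genome duplications are called from all-vs-all protein bitscores.
The two directional cross scores of a pair are reconciled by their
maximum (alignment asymmetry is a tool artifact), normalized by the
smaller of the two self scores (minbit), and edges with minbit ≥ 0.5 are
kept. Self-hits are mandatory in user-supplied tables — a length-based
self-score approximation would distort the normalization — and the
built-in scorer computes them when used.

The built-in scorer is Smith–Waterman with BLOSUM62 and BLAST-style
affine gaps (a gap of length k costs 11 + k), with raw scores converted
to bits by the gapped Karlin–Altschul parameters λ = 0.267, K = 0.041.
On mutated random protein pairs it agrees with gapped BLASTP (composition
adjustment off) to well under 1%.

Markov clustering iterates expansion (matrix squaring) and inflation
(elementwise power 2.0, the standard default, then column
renormalization) on the column-stochastic adjacency matrix, with
self-loops of weight 1 added where absent (the minbit self-edge is 1 by
construction), per-column pruning at 1e-5, convergence when the matrix
changes by less than 1e-6, and a hard cap of 100 iterations (an error,
reporting the residual, if exceeded). Clusters are the connected
components of the thresholded limit matrix — a hard partition,
deterministic for sorted node order. Edge weights are the minbit values
themselves. Only clusters with ≥ 2 members count as duplication events:
counting singletons would make every gene an event and erase the
streamlining contrast the count exists to show.

## Annotation rules

The rhodopsin residue table — D97 + E108 (proton acceptor/donor) → proton
pump; site 105 Q → blue-absorbing, L or M → green-absorbing — follows the
established spectral-tuning literature; M is mapped to green as the
methionine variant of the leucine pocket. Reference numbering is obtained
by global alignment (BLOSUM62, same gap model) against a bundled
scaffold; the scaffold is a synthetic proteorhodopsin-like sequence, not
a natural one, carrying the diagnostic residues at the correct positions
— sufficient because only column correspondence matters. Callers may
instead supply the pre-aligned 17-residue window spanning reference
positions 94–110. A gap at any diagnostic site yields an explicit
unknown call plus a warning, never a guess.

The extracellular-peptidase rule treats any positive
signal/membrane-targeting prediction as the rescue condition for
`unknown` localization; upstream tools disagree on whether such columns
denote signal peptides or transmembrane helices, so the input column is
taken at face value. CAZy rates drop subfamily models (`GH13_9`-style)
before counting so a protein hitting both a family and its subfamily is
not double counted, keep GH and CBM classes by default, and normalize by
assembly length in Mbp.

## Ecology

ANI dereplication averages the two directional values of a pair when
both exist and links pairs at ≥ 98.5% with single-linkage; the
representative is chosen by completeness, then lower contamination,
larger assembly, lexicographic id. Environmental pairing requires the
same station and a depth within 1 m (the tolerance is a parameter), and
averages duplicate casts per parameter. RPKM's denominator constant is
10⁶ bp of metagenome; relative fractions sum to ≤ 1 per sample by
construction.

CCA follows ter Braak: chi-square-standardized relative abundances
`Q̄ = (P − rcᵀ)/√(rcᵀ)`, row-weighted centering of the environmental
matrix, weighted least-squares projection of Q̄ onto it, SVD of the
fitted matrix. Eigenvalues are the squared singular values (each in
[0, 1]); site scores are the left singular vectors rescaled by 1/√r
(linear-combination scores); species scores are the right singular
vectors rescaled by 1/√c and by the singular values (scaling type 2);
biplot scores are weighted correlations of each variable with the site
axes. Variables with < 90% sample coverage are dropped first, remaining
samples with missing values are dropped listwise (no imputation), and
abundances are log(n+1)-transformed with the natural log (base-10
available via a flag; the choice only rescales the transformed matrix
slightly and does not change the [0,1] eigenvalue bounds). Constant or
collinear predictors are pruned by pivoted QR with a warning; an all-zero
row or column after transform is an error naming the offender.
Eigenvalues agree with R's `vegan::cca` to 1e-8 on random instances.

## Synthetic data

The generator encodes the study conditions the analysis is meant to
resolve. Defaults: two streamlined marine pelagic clades (8 genomes each,
true size 1.22 Mbp, 30% GC, 96.5% coding density, no paralog families,
nitrogen-poor proteomes) against an organic-carbon clade (6 genomes,
3.0 Mbp, 55% GC, 88% density, 5 families of 3 copies at 95% identity,
nitrogen-rich proteomes) and a hydrothermal clade (6 genomes, 2.5 Mbp,
45% GC, 90% density, 3 families). Completeness is simulated by truncating
the ordered contigs to a fraction drawn uniformly from 50–100% and
reporting that exact fraction, so `assembly_length/completeness` recovers
the true size sharply — a deliberate idealization that makes the
size-correction identity testable; real completeness estimators add
marker-sampling error this generator does not model.

The niche model places 6 stations × 8 depths (20–250 m, 48 samples)
around a 100 m boundary. The shallow clade's share of clade reads follows
a logistic in depth (asymptote 0.9, width 12 m) — sharp at the boundary
but monotone, as in observed profiles where the clades taper rather than
switch discontinuously; read counts are multinomial over genomes with
per-sample weight jitter, sample read depth 10⁶ at 100 bp reads.
Environmental casts carry a noise-free depth variable and depth-linear
covariates with realistic cast-level scatter (temperature sd 2 °C,
nitrate 2 µM, oxygen 15 µM), duplicate casts at ~30% of station-depths
(exercising the mean rule), and one patchily measured parameter
(chlorophyll, ~50% coverage) that the ≥ 90% coverage filter must drop.
Because covariates are noisy reflections of depth while the niche is a
function of depth itself, depth attains the largest axis-1 biplot
magnitude — the recovery the niche tests assert.

Rhodopsins are built on the synthetic scaffold with a 7:1 blue:green
residue mix at site 105, D/E fixed at 97/108, and 5% background mutation
outside the diagnostic window. All randomness derives from a single
integer seed through `numpy.random.SeedSequence`, so outputs are
byte-identical across runs and platforms. Not emulated: sequence
evolution, codon structure coupling nucleotide and protein composition,
read-level error, assembly chimerism — so passing tests demonstrate the
correctness and discriminating power of the metrics under the assumed
data structure, not robustness to real-data artifacts.

## Problem sizes

The analysis drivers and the acceptance script use the default study (28
genomes, 60 Mbp of sequence, 48 samples), 100 seeded paralog-recovery
trials at 60-residue proteins, and n = 20 genomes for size recovery;
the unit suites use smaller clades (4 genomes at 200 kbp). These sizes
resolve every contrast the defaults encode while keeping a full run in
seconds.

## Known limitations

* The built-in aligner scores pairs exhaustively; for real proteomes
  (thousands of proteins) an external prefiltering aligner's tabular
  output should be supplied instead.
* MCL is dense (O(n²) memory per genome's graph); adequate for
  within-genome paralog graphs, not for cross-genome ortholog networks.
* CCA drops samples listwise; heavily patchy environmental tables lose
  power rather than being imputed.
* The ANI representative rule (completeness → contamination → size → id)
  is one reasonable convention among several; it is deterministic and
  documented rather than canonical.
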