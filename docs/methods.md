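# Methods

This note documents the models and procedures implemented in `sglut`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Site fragments and coordinates

A candidate site is the `2n + 1` residue window centred on a cysteine,
with `n = 10` by default (one global setting). Positions in files and
reports are 1-based; window offsets run −n..+n with the cysteine at 0.
Window positions outside the protein are padded with `X`, which is also
the normalisation target for non-standard residue codes (B, Z, U, O, J,
`*`) on FASTA input. `X` never occupies the interior of a fragment.

The canonical residue order for positional encodings is
`GAVLIPFMWSTCYNQDEKRH` — glycine first, alanine second, matching the
orthogonal binary convention in which G → `10000000000000000000`.

## Feature encodings

| scheme | dim (n=10) | notes |
|---|---|---|
| binary | 420 | one-hot per position; `X` → zero block |
| aac | 20 | counts / (2n+1); `X` counts in the denominator only |
| aapc | 441 | adjacent ordered dipeptides over the 21-symbol alphabet, / 2n |
| blosum62 | 420 | per-position substitution-score rows; `X` → zeros |
| blosum62_aapc | 861 | concatenation (the default classifier feature) |
| pwm | 21 | per-position relative-frequency lookup in a training PWM |
| pssm | 400 | windowed PSI-BLAST profile collapsed 21×20 → 20×20, / (2n+1), logistic 1/(1+e^−x) |
| asa | 21 | accessibility percentage / 100, clipped to [0,1]; `X` → 0 |

Open points resolved here: "pair composition" is read as adjacent ordered
dipeptides, the standard definition consistent with the 21² = 441 count;
the hybrid feature is a plain concatenation of the two blocks; the PWM
feature dimension is one lookup per window position. AAC keeps 20 entries
with `X` absorbed by the denominator while AAPC treats `X` as a 21st
symbol — the two conventions follow the dimensionalities stated for each
feature. The BLOSUM62 matrix ships as a plain-text NCBI-layout data file
and is parsed with Biopython. PSSM profiles and ASA tables are consumed,
never computed: the package reads the PSI-BLAST ASCII dialect (a small
bespoke reader; no installed library parses it) and a TSV of per-residue
accessibility percentages.

## Maximal dependence decomposition

Residues map into five physicochemical groups; the membership table is
configurable, with default acidic {D,E}, basic {H,K,R}, aromatic {F,W,Y},
hydrophobic {A,I,L,M,P,V}, polar {C,G,N,Q,S,T} — a disjoint partition
consistent with treating K/R/H as the positively charged class. For each
ordered pair of flanking offsets a 5 × 5 contingency table of group
co-occurrence is scored with the chi-square statistic; cells with zero
expected count contribute zero. Fragments with `X` at either queried
offset are excluded from that table only.

Splitting policy:

- A node is divided only while its size exceeds `max_cluster_size`
  (default 300) **and** some pair's chi-square exceeds the threshold
  (default 34.3, kept as conventionally quoted for P ≈ 0.01 at 16 df even
  though the exact critical value is 32.0; both knobs are configurable).
  Any-pair triggering is used, not just pairs involving the argmax
  position.
- The split position is the argmax of `Score(Ai)`; ties resolve to the
  smallest |offset|, negative before positive. Offset 0 (the invariant
  cysteine) is never a candidate.
- The split group at that position is chosen by binarizing each candidate
  group into has/lacks and taking the group whose 2 × 5 chi-square summed
  over all partner positions is largest. (An earlier heuristic — the raw
  5-row chi-square contribution — systematically favours minority rows,
  whose small expected counts inflate relative deviations, and picks the
  wrong group on planted data; the binarized form directly measures how
  much dependence the actual has/lacks split explains.)
- Fragments with `X` at the split position follow the lacks branch. A
  proposed split that would leave a child empty is discarded.

Leaves partition the input and are named GSH1..GSHk in descending size;
the last subgroups may carry no conserved motif. Increasing the threshold
can only prune the tree.

## Two-layered classifier

First layer: per merged subgroup, an RBF-kernel SVM with Platt-scaled
probability outputs (scikit-learn `SVC(probability=True)`, the LIBSVM
behaviour), trained on the subgroup's positives against an equally sized
K-means-representative sample of the shared balanced negative pool
(seeded per subgroup; how negatives were apportioned per subgroup is an
open question in the original description — a shared pool is used here).
Subgroups with fewer than 10 positives are merged into the sibling group
sharing the longest split-path prefix before training. Second layer: an
SVM over each fragment's k-vector of first-layer probabilities. The meta
training vectors are **cross-fitted** (out-of-fold probabilities for the
fragments each first-layer model was trained on); training the meta model
on in-sample probabilities leaks optimistically separated inputs and
measurably degrades held-out performance. Default hyperparameters are
C = 1, gamma = "scale"; an exhaustive grid search over C ∈ 2^−5..2^15,
γ ∈ 2^−15..2^3 (powers of four, ties to the smaller values) is available.
The decision threshold on the meta probability is 0.5.

Prediction routes each query fragment down the tree by its split-path
predicates to report a matched motif; the probability itself always comes
from the full two-layer model. Cross-validation is stratified five-fold
with per-fold confusion counts pooled into a single estimate
(micro-averaging); per-fold metrics are reported alongside. MCC is
defined as 0 whenever a denominator factor vanishes.

## Dataset preparation

K-means balancing embeds fragments as one-hot vectors, making squared
Euclidean distance twice the mismatch count; the distance, initialisation
(seeded k-means++), and nearest-to-centroid representative rule are
implementation decisions, as is backfilling empty clusters with the
unchosen fragments farthest from the already-chosen set (max-min
distance), so the output size is always exactly K. Homology reduction
aligns protein pairs globally with BLOSUM62, gap open −11 / extend −1
(the BLAST defaults; the historical BL2SEQ tool is deprecated and only
the identity percentage is consumed); identity is matches over alignment
columns. "More than 30%" is exclusive. At fragment level, removal
requires exact 21-mer string equality, so no alignment is needed there.
The training set is never modified; the test set loses the duplicated
sites, reported per removal.

## Compositional bias (two-sample logo)

Per (offset, residue), occurrence proportions in two fragment sets are
compared with a two-sided pooled two-proportion z-test, falling back to
Fisher's exact test when any expected count under independence drops
below 5. `X` is excluded from numerator and denominator at its position.
No multiple-testing correction is applied by default (matching the
conventional raw p < 0.01 presentation of such logos); a Bonferroni flag
exists and is what a claim of "no difference" should use, since ~400
cells are tested per comparison.

## Synthetic proteome generator

The generator emits exactly the formats the pipeline consumes: FASTA,
sites TSV, ASA TSV, PSI-BLAST-style profile files. Defaults: 50 proteins
of 250–400 residues, 2 positive and 8 negative labelled sites per protein
(roughly the positive:negative site ratio of experimentally mapped
glutathionylomes), uniform background residue frequencies (a Swiss-Prot
frequency table is bundled as an option), sites spaced a full window
apart so planted flanks never overlap.

A planted motif models a substrate **sub-population**, not a single
column: a site carries its motif with probability `penetrance`, and a
carrier both receives a motif residue at the planted offset and draws the
rest of its window from a background tilted toward the motif's residue
pool (`context_tilt = 0.4` mixture weight). The tilt is essential to what
the benchmark can show: chi-square between two positions responds to
sub-population structure shared across positions, and a motif planted
i.i.d. at one column creates *no* inter-position dependence at any
penetrance — it would be invisible to dependence decomposition by
construction. The default weight makes a single planted motif (400
positives, penetrance 0.9) clear the 34.3 cutoff with margin, and makes
full-penetrance data strongly separable. At penetrance 0 no site carries
anything and the classes are statistically identical. With several
motifs, `exclusive` mode (default) assigns each positive one motif
uniformly — distinct subpopulations, the regime the layered classifier
targets — while `independent` plants each motif independently.

ASA values are truncated normals on [0, 100]: mean 42 background, 58 in
positive-site flanks (modified sites sit in locally exposed
neighbourhoods), 25 at the site cysteines themselves (cysteine is the
least exposed residue in either class). Profile scores echo the realised
sequence (+4 own residue, −1 otherwise, ±1 integer noise), so planted
motif residues score high at their positions.

What passing synthetic benchmarks does **not** show: real flanking
compositions are not i.i.d. mixtures, real motif subgroups overlap and
co-occur, homology structures real negative pools, and reported
cross-validation numbers on synthetic data say nothing quantitative about
performance on experimental glutathionylomes.

## Benchmark problem sizes

The shipped tests and the acceptance script use: 20 decompositions of 400
positives each for motif recovery; 300 + 300 balanced fragments for the
layered-vs-single CV comparison (two distinct residue motifs, K/R at −6
and D/E at +8, full penetrance for the headline comparison); 200 + 200
fragments for enrichment detection; and a 30-protein end-to-end CLI run
executed twice for byte-level determinism. These sizes give stable
outcomes across seeds while keeping a full run to tens of seconds on one
CPU.

## Known limitations

- PSSM and ASA features require externally produced profiles; the package
  never runs PSI-BLAST or a structure predictor.
- The fallback routing of a query fragment matching no discovered motif is
  the lacks-everything leaf; the original tool's behaviour is unspecified.
- Model archives store scikit-learn estimators via joblib and are not
  portable across major scikit-learn versions.
- With ~190 position pairs tested per node, occasional spurious splits at
  the 34.3 cutoff are expected (and observed); small spurious subgroups
  are absorbed by the merge-below-10-positives rule at training time.
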