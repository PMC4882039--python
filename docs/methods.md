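# Methods

## Problem and model

The package classifies nucleotide transcripts as long non-coding RNA
(NONCODING, the positive class) or protein-coding (CODING).  The decision
rule is two-branched:

1. **Short-ORF shortcut.** A transcript whose longest forward-frame ORF
   (MaxORF) is under 54 nt is called non-coding unconditionally, with a
   degenerate non-coding score of 1.0 and a flag.  54 nt is the minimum
   MaxORF observed in real mRNA collections; the boundary value MaxORF = 54
   goes to the forest, so the two branches partition the input space.
   Because the score is degenerate, shortcut calls are excluded from ROC/AUC
   by default.
2. **Random forest.** Everything else is scored by a 300-tree random forest
   over the 30 features selected by the feature score criterion; the
   non-coding score is the fraction of trees voting non-coding, thresholded
   at 0.5 with ties going to non-coding.  Non-coding *training* examples
   under the shortcut threshold are dropped before fitting, since the
   shortcut already answers for that region.

## Features (89, canonical order)

MaxORF, RMaxORF, SNR, Length, (G+C)%, then 4 + 16 + 64 k-mer frequencies in
lexicographic A<C<G<T order.  Conventions that the definitions leave open:

* **ORF**: ATG to the first in-frame stop (TAA/TAG/TGA), stop included, three
  forward frames only, no reverse complement.  An ATG with no downstream
  in-frame stop contributes no ORF.  Requiring a stop makes every MaxORF a
  multiple of 3 (or 0) and matches the nt-unit reading under which the
  54 nt threshold is meaningful.  A run-to-end convention would be a
  straightforward variant but is not currently exposed.
* **SNR period-3 bin**: for N not divisible by 3, k\* = round(N/3).  N/3 then
  has fractional part 1/3 or 2/3, so rounding never ties.  The spectrum mean
  Ē equals N exactly (Parseval), so SNR = P[k\*]/N; both the FFT path and a
  direct O(N²) DFT oracle are tested to 1e-8 agreement.
* **k-mers**: overlapping windows, denominator N−k+1, so each block sums
  to 1.  (G+C)% is kept as its own feature, distinct from G%, C% and the
  dinucleotide GC%.
* Features are emitted on their natural scales; tree ensembles are
  scale-invariant, and standardization happens only inside SOM sampling.

## Feature selection

FSC(g) = |μ⁺−μ⁻|/(σ⁺+σ⁻) with per-class *sample* (n−1) standard deviations.
Degenerate denominator σ⁺+σ⁻ = 0 maps to +inf when the means differ (perfect
separator, ranked first) and 0 otherwise — no epsilon tuning.  Ties break by
canonical feature order for reproducibility.  Selection runs on the full
labelled pool before SOM subsampling (the training workflow's stated order);
the top p = 30 are retained by default; a different p is one argument away.

## SOM representative sampling

One 8×8 rectangular Kohonen map per class, trained online on the
FSC-selected features z-scored with mean/SD pooled over both classes
(otherwise Length and MaxORF dominate the Euclidean distance).  Only the
schedule's monotonic decrease is prescribed by the protocol; the completions
chosen here (all exposed as arguments) are: learning rate linear 0.5 → 0.01;
Gaussian neighborhood on Euclidean grid distance with width linear
max(rows, cols)/2 → 1; epochs × n iterations with a fresh random presentation
order per epoch; weights initialized uniformly within each feature's observed
range.  The winner minimizes squared Euclidean distance (the square root
changes nothing), lowest index on ties.

Allocation: O_i = ⌈(w_i/N)·L⌉ per neuron, capped at w_i (the cap never binds
when L ≤ N but keeps without-replacement draws well-defined), then uniform
draws without replacement inside each neuron.  The ceiling bounds the drawn
total in [L, L + #non-empty neurons], which is why a target of 2000 yields
set sizes slightly above 2000.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC as a percentage, MCC with the
convention that any zero factor in the denominator gives 0.  AUC is the
Mann–Whitney rank statistic with midranks for ties, verified against
trapezoidal integration of the empirical ROC on tie-free inputs.

## Synthetic data generator

The generator emulates the single mechanism the spectral feature relies on:
coding transcripts are 5′ UTR (0–20% of the length) + ATG + sense codons
drawn i.i.d. from a strongly skewed codon-usage table (12 preferred codons
weighted 8:1 over the rest, roughly the human-preferred set) + stop + 3′ UTR,
with the ORF covering 60–85% of the sequence.  The codon bias alone creates
the period-3 peak — no sinusoid is injected.  Non-coding transcripts are
order-0 (optionally order-1 Markov) base sequences at GC 0.5 with no imposed
ORF structure; incidental long ORFs are deliberately not screened out, which
keeps the task non-trivial.  Defaults: 1000 transcripts per class, lengths
uniform on [200, 3000] nt — inside the cleaning window, long enough for a
stable spectrum, and small enough that a full pipeline run takes seconds.

What the generator does **not** emulate: splice structure, UTR composition
bias, polyA tails, GC heterogeneity between classes, pseudogenes, or
lncRNAs harbouring long protein-like ORFs.  Real lncRNA/mRNA discrimination
is much harder than this synthetic task, so passing tests demonstrate that
the machinery is implemented correctly and recovers planted structure — not
that comparable accuracy would be achieved on real lncRNA/mRNA collections.
Held-out accuracy on the synthetic task
is essentially perfect; the acceptance thresholds (ACC ≥ 0.90, AUC ≥ 0.95)
are deliberately loose lower bounds.

## Cleaning and I/O conventions

Records with any character outside {A,a,C,c,G,g,T,t,U,u} are rejected whole,
not trimmed; U→T and uppercasing normalize everything to one alphabet.  The
training length filter is the half-open window [200, 20000) — consistent
with the "> 200 nt" lncRNA definition while honouring the 20 kb cap.
"Repetitive" removal is exact duplicate removal after normalization (no
similarity threshold is defined anywhere, so none is invented).  Prediction
mode normalizes but does not drop out-of-window records — a deployed
classifier must answer for arbitrary user input — it flags them instead
(such records necessarily hit the shortcut when shorter than 54 nt).

## Determinism

Every stochastic stage (SOM fit, neuron draws, forest, permutation
importance, simulation, splitting) takes an explicit seed; the pipeline
derives per-stage seeds from one master seed via `SeedSequence` and records
them in a provenance block with the config hash and per-stage counts.
Identical config + seed reproduces byte-identical model bundles and
prediction reports.

## Known limitations

* The SOM quality contribution is modest on the synthetic task (it is nearly
  separable); the suite asserts only that SOM subsampling does not lose
  accuracy against random subsampling of the same size.
* Permutation importance is computed on a held-out set rather than literal
  per-tree out-of-bag partitions: it estimates the same quantity, is
  protocol-portable, and repeats/averages over seeded permutations.
* Scores are vote fractions, not calibrated probabilities.
* Only the forward strand is scanned for ORFs, by definition of the feature.
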