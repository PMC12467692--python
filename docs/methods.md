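# Methods

## Detector

The detector is a first-order HMM over the M = 4^k k-mer states of a
nanopore, decoded with the Viterbi algorithm. Emissions are Gaussian: state
j emits a current level with mean μ_j and standard deviation σ_j taken from
the pore model. All computation is in the natural-log domain (max-plus
algebra); a linear-domain product over a few hundred events underflows
double precision, while the log-domain recursion preserves every argmax
exactly.

Transitions encode translocation jitter. Each state j has exactly 21
nominal predecessor entries:

| category | entries | probability each | meaning |
|----------|---------|------------------|---------|
| stay     | 1 (j itself) | p_stay | the same k-mer measured again (insertion) |
| step     | 4 (overlap k−1) | p_step/4 | normal advance by one base |
| skip     | 16 (overlap k−2) | p_skip/16 | advance by two bases (one k-mer's measurement lost) |

Defaults are p_stay = 0.05, p_step = 0.90, p_skip = 0.05. No trained
transition probabilities are available for this model class, so the
defaults make the normal step dominant and give insertions and single
deletions equal, small mass; all three are exposed in the API and CLI. The
uniform split within a category reflects the absence of any
sequence-composition prior. Outgoing probability is conserved by
construction (each state is one stay, four steps' and sixteen skips'
predecessor). Longer deletions (two consecutive lost k-mers) are outside
the topology.

For low-complexity k-mers the 21 entries can name the same predecessor
state twice — a homopolymer such as AAA is its own stay *and* one of its
own step predecessors. Entries are kept separate and the Viterbi max
simply takes the heavier edge. The decoder records, per trellis cell, both
the winning predecessor state and the winning *entry's* category; decoded
paths are collapsed to bases using those recorded categories (stay → 0
bases, step → last base, skip → last two bases; the first state of a chunk
contributes all k bases). Collapsing with recorded categories rather than
by re-classifying the state pair matters exactly for homopolymers: under
the defaults the step edge (0.225) outweighs the stay edge (0.05), so a
genuine homopolymer advance is collapsed as a step and the run length is
preserved. The cost is the mirror-image error: a *re-measured* homopolymer
k-mer (a true insertion, rate p_ins·4^−k) is also collapsed as a step and
over-calls one base. For state pairs given without a decoding trellis,
`classify_transition` resolves label ambiguity by the fixed priority
stay > step > skip. Score ties anywhere are broken toward the lowest
predecessor state id (then the highest-priority category), making decoding
bit-reproducible.

Chunked decoding processes independent, non-overlapping windows (default
384 events) with a uniform −ln M prior and no carried state. Each chunk's
first state re-emits all k bases, so every boundary duplicates k−1 bases
of already-called context; this cold-start artifact is intentional (it
models a bounded memory buffer) and is included in all reported accuracy.

Supported k is 2–6, bounding the 4^k × 21 transition table and the N × M
trellis at desk scale. The full pointer matrix is retained per chunk
(384 × 4096 at worst), so no beam pruning or checkpointing is needed.

## Simulator

The simulator is generatively matched to the decoder. A uniform random
DNA sequence of length L is walked one k-mer at a time; each k-mer after
the first is dropped with probability p_del unless its predecessor was
dropped (single deletions only — the decoder's skip can bridge exactly one
lost k-mer), and each surviving k-mer emits 1 + G events with
G ~ Geometric(1 − p_ins) extra stays. Defaults p_ins = p_del = 0.05 match
the decoder's transition mass. Clean levels come from the pore model;
noise is additive i.i.d. Gaussian.

The noise scale is set by an SNR in dB defined against the *clean
event-level sequence's population variance*:
noise_std = sqrt(Var(clean) / 10^(SNR/10)). This convention is scale-free
(invariant to the model's pA range). For uniform levels on [50, 150] pA,
32 dB gives noise_std ≈ 0.72 pA. One master seed fans out to independent
substreams for sequence, jitter and noise.

The synthetic pore model draws each k-mer's level i.i.d. uniform on
[50, 150] pA — the dynamic range of published nanopore level tables — with
one shared σ. Real, trained k-mer tables differ in ways the generator
deliberately does not model: levels of overlapping k-mers are strongly
correlated (position-weighted base contributions), per-state σ varies, and
real squiggles carry drift, scaling and dwell-time structure. Passing the
simulation study therefore demonstrates the decoder's correctness and its
response to amplitude/timing noise under matched assumptions; it does not
predict accuracy on real device reads, where state confusability is much
higher. There is no read-scaling/normalisation and no parameter training
(pore models are inputs, as they are for embedded detectors in general).

## Study harness and metric

`run_study` repeats simulate → basecall → score for `reps` independent
replicates; replicate r uses seed master_seed + r, and the pore model is
drawn once per study from its own fixed seed. Decoding is *matched-model*:
the detector's σ is set to the replicate's true noise σ, since no trained
mismatched model exists in this setting. Reported accuracy is
global-alignment identity (match +1, mismatch −1, gap −1, linear gaps;
identity = matches / alignment columns, ties resolved toward more
matches). The DP packs (score, matches) into one integer per cell and
vectorises rows with a prefix-scan over the gap recurrence, so scoring a
1.8 kb read takes milliseconds; the alignment length of the chosen
alignment follows from columns = 2·matches − score. Edit-distance identity
(1 − levenshtein/max length) is available as a secondary metric and the
study records which metric produced its numbers. The study summary reports
the sample standard deviation (ddof = 1) across replicates.

At the reference study conditions (k = 3/4/5, 100 reps, L = 1800, 32 dB,
384-event chunks) the suite and `scripts/acceptance.py` measure mean
identities around 98–99%, increasing from k = 3 to the larger state
spaces with clearly diminishing returns — the k = 4 vs k = 5 gap is within
replicate noise. Embedded-detector studies on vendor-trained tables report
roughly 90–94% under the same protocol; the gap is the expected
consequence of the i.i.d. synthetic levels discussed above, so the
ballpark and the ordering, not the exact means, are what the simulation
reproduces.

## Numerical and degenerate-input choices

* Probabilities of zero are allowed in the transition distribution and map
  to −inf log weights (p_stay = p_skip = 0 yields the pure de Bruijn step
  graph).
* An event chunk must be non-empty and finite; a clean signal with zero
  variance (single repeated level) has no defined SNR and is rejected.
* Pore-model tables must enumerate every k-mer exactly once with positive
  σ; the first absent k-mer is named in the error. Text round-trips are
  exact (`%.17g` write, round-trip float parsing on read).
* The exhaustive-enumeration oracle used in tests accumulates scores in
  the same floating-point grouping as the decoder, so score agreement is
  asserted exactly rather than within tolerance; it is capped at k = 2,
  N ≤ 5 (≈10^6 paths).
* Study problem sizes (100 replicates of 1.8 kb reads; 10 replicates per
  point for SNR sweeps) keep the full suite fast on a single CPU while
  holding the mean-accuracy standard error near 0.03 points.

## Known limitations

* No dwell-time, filtering, drift or scaling effects in the simulator; no
  normalisation of real device reads — level + Gaussian noise only.
* Synthetic models ignore overlapping-k-mer level correlation, so absolute
  accuracies are optimistic relative to trained tables (see above).
* Homopolymer *insertions* over-call by one base (recorded-category
  collapse); homopolymer handling in nanopore HMMs is intrinsically
  ambiguous at the event level.
* Chunks are decoded independently; no streaming decoding, no state
  carry-over, no multi-channel multiplexing, no quality scores.
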