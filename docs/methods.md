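# Methods

## The stimulus array and its geometry

The grid models the standard colour-survey stimulus set: 330 chips
arranged as 40 hue columns × 8 lightness rows plus one achromatic
column spanning 10 lightness rows. Rows are indexed 0–9 light→dark;
hue columns 1–40 are circular (column 40 adjacent to column 1);
column 0 is achromatic. `read_chip_table` accepts any chip table in
this coordinate convention, so real survey files can be mapped in by a
thin adapter; because published charts differ in where they place the
hue origin, such an adapter should let the user choose the column
origin and direction.

Chips embed into a 3-D perceptual space: a hue circle of radius `rho`
(default 3.0, in lightness-row units) crossed with the linear lightness
axis; achromatic chips sit on the cylinder axis. With `rho = 3` the
spacing between adjacent hue columns (≈0.47) is finer than between
adjacent lightness rows (1.0), which makes hue bands easier for a
similarity-based learner to acquire than arbitrary fragments. `rho` is
exposed as a parameter everywhere the embedding is used.

### Hue anchors

Human colour naming is anchored: boundaries between categories recur
at particular hues across unrelated languages, presumably reflecting
shared perceptual structure. The synthetic study reproduces this with
a fixed set of canonical boundary columns, `DEFAULT_HUE_ANCHORS =
(2, 7, 16, 21, 28, 38)`, deliberately unevenly spaced so that no
non-trivial rotation of the hue circle maps the set onto itself. Two
components consume the anchors:

* the exemplar learner can warp the hue circle (`anchor_strength`,
  default 3.0): the angular gap just after each anchor column is
  widened by a factor `1 + anchor_strength`, so nearest-exemplar
  category boundaries preferentially settle into those gaps;
* the corpus generator places each synthetic language's band
  boundaries at a subset of the anchors (±1 column of per-language
  jitter).

This shared structure is what makes the rotation-null analysis
meaningful in the synthetic setting: without it, chains converge to
compact hue bands at arbitrary offsets, the reference corpus is
rotation-symmetric in distribution, and the expected rotation profile
is flat. `anchor_strength = 0` switches the warp off and recovers the
uniform circle (used by the geometry tests).

## Naming systems and partitions

A naming system maps chips to terms (2–6 terms for study-faithful
runs); partial labellings are supported for aggregate field data, and
all pairwise statistics are then computed over the intersection of
labelled chips. Initial partitions for chains come in three kinds:

* **hue**: k contiguous bands of near-equal width (remainder columns
  to the leftmost bands — the allocation is deterministic; the original
  procedure did not specify it); the achromatic column joins one band
  chosen uniformly at random;
* **lightness**: k contiguous row groups, largest first,
  deterministic;
* **random**: a uniform shuffle with per-term counts balanced to
  within one chip (exact equality is impossible when k does not divide
  330, e.g. k = 4).

`rotate_hue` shifts a complete system s columns rightward along the
printed array (the chip at column h takes the label from column
h − s, mod 40); achromatic chips have no hue and never rotate. A term
labelling strictly fewer than 5 % of chips is a *minority term*
(`minority_terms`), matching the display convention for converged
systems.

## Variation of information

All information quantities use natural logarithms; the base only
rescales VI and nothing constrains it. For systems C, C′ over n
common chips with contingency counts n_kk′:

    H(C)      = − Σ_k P(k) ln P(k)
    I(C, C′)  =   Σ_kk′ P(k, k′) ln [ P(k, k′) / (P(k) P(k′)) ]
    VI(C, C′) =   H(C) + H(C′) − 2 I(C, C′)

VI is a metric on partitions up to term renaming, bounded by ln n.
The implementation works on integer-coded label arrays with
`numpy.bincount` contingency tables; tests cross-check it against an
independent pure-Python contingency oracle and against
`sklearn.metrics.mutual_info_score`, and property-test the metric
axioms on random partition triples.

Comparing one system to a corpus averages in two unweighted stages —
over each language's speakers, then over languages — so languages with
many speakers do not dominate. The corpus-internal baseline
(`corpus_pairwise_vi`) averages all cross-language speaker pairs
within each unordered language pair, then averages over language
pairs. (An alternative — comparing modal per-language systems — would
also be defensible; speaker-pair averaging is implemented because it
uses all the data.) For two-sample comparisons the corpus side
contributes one value per language (its mean VI to the other
languages), giving the pooled df of n_chains + n_languages − 2; when
the corpus is a single group of speakers, one value per speaker.

## Chain simulation

A chain starts from an initial partition and iterates: sample `6·k`
distinct chips uniformly without replacement (a displayed "set" of
examples should not repeat chips), label them with the current system,
hand them to the learner, which must label all 330 chips using only
terms it observed — so inventories can shrink along a chain, matching
the fact that k is a maximum, not a quota. The full design is 30
chains: for each k in 2–6, four random-initial chains plus one hue and
one lightness chain, 13 learner generations each.

The exemplar learner scores each chip for each observed term by
`Σ_exemplars exp(−d/tau)` (d = embedding distance) and samples a term
proportionally; `tau` (default 0.3) sets label noise, and `tau → 0`
gives deterministic nearest-exemplar labelling with uniform
tie-breaking. It is an explicit stand-in for human participants, not a
model of colour cognition; its knobs (`tau`, `rho`,
`anchor_strength`) are all config-exposed. All randomness flows from
one master seed through named streams (chain id × generation ×
stage), so any chain can be regenerated independently.

## Synthetic reference corpus

Each language draws k uniformly from 2–6 and builds a template:
contiguous hue bands with boundaries at a k-subset of the anchors;
with probability 0.3 one term is spent on a lightness stripe (the two
lightest or two darkest rows) instead — colour lexicons commonly
dedicate terms to light/dark — leaving k−1 hue bands. Achromatic chips
follow the stripe when they fall in it, otherwise join a random band.
Each of the 10 speakers then flips every chip's label independently
with probability `noise_eps = 0.05` to a neighbouring category's
label, so within-language disagreement concentrates at category
boundaries, as in real naming data. Defaults (110 languages × 10
speakers) match the survey scale the analysis emulates.

What the generator does *not* emulate: uneven speaker counts, partial
or aggregate labelling, non-band category shapes (e.g. foci-centred
blobs), named focal chips, or any relationship between term frequency
and category size. Passing tests therefore show that the pipeline
detects convergence and rotation structure when they exist by
construction — they do not validate the exemplar learner as a model of
people, and quantitative VI levels here should not be read as
predictions for human data.

## Evolutionary dynamics

Population proportions x over hypotheses evolve as

    dx_i/dt = Σ_j q_ij f_j x_j − φ x_i,   φ = Σ_j f_j x_j,

with Q column-stochastic: `Q[i, j]` is the probability a learner ends
up with hypothesis i after learning from a teacher with hypothesis j.
(The literature is split on orientation; columns-as-teachers is used
throughout.) With uniform fitness the system is linear and converges
to the eigenvalue-1 eigenvector of Q, which is also the stationary
distribution of the iterated-learning Markov chain with transition
matrix Q. For learners that sample from their Bayesian posterior,
marginalizing over data shows that the prior is stationary:
Σ_j Q[i,j] p(j) = Σ_d P(i|d) P(d) = p(i).

The toy space for verifying this is the set of all 2^N binary
labellings of an N-site ring with prior ∝ exp(−β · boundary count)
and i.i.d. noisy (site, label) observations (flip probability ε).
The ring is the smallest colour-like (circular) structure; taking all
labellings rather than only contiguous ones keeps the prior genuinely
non-uniform — contiguous two-category partitions all have exactly two
boundaries, which would make a boundary-count prior flat and the
prior-convergence check vacuous. Contiguous partitions are precisely
the high-prior subset. `build_q_matrix` enumerates all data sequences
exactly (Monte-Carlo is available for larger spaces, with error
~ n_samples^(−1/2)).

Numerical choices: the ODE integrator (DOP853, rtol 1e-12, atol
1e-14) adds `− (Σ_i dx_i) · x` to the right-hand side — identically
zero on the simplex, since Σ_i dx_i = φ(1 − Σ_i x_i) — to suppress
floating-point drift of Σx. `stationary_distribution` refuses
matrices whose unit eigenvalue is not simple or that have other
eigenvalues on the unit circle (reducible/periodic chains) rather than
returning an arbitrary vector.

The equivalence checks (stationary = prior by enumeration; ODE
endpoint and a 10^5-step Markov-chain empirical distribution against
the eigenvector) run on N = 5, data size 3: with 10^5 samples the
expected multinomial sampling error of an empirical distribution over
2^N cells grows with N and would dominate the comparison already at
N = 8; N = 5 keeps it near 0.006 total variation. The larger N = 8,
data-size-4 space is still enumerated exactly for the
stationary-equals-prior identity.

## Analyses and statistics

* **Convergence**: per-iteration mean (over chains) of the two-stage
  mean VI to the reference corpus, from iteration 0 (the initial
  partitions); paired t-test (df = n − 1) on per-chain initial vs
  final VI; Spearman trend of the averaged curve; baseline =
  corpus-internal between-language VI.
* **Rotation null**: mean VI of the final systems rotated 0–20
  columns; paired tests of offset 0 against the landmark offsets
  5 / 15 / 20 (quarter, three-quarter and maximum of the tested
  range — "quarter" could alternatively mean 10 of 40 columns; the
  landmarks are configurable). Negative t means the unrotated fit is
  better.
* **Second corpus**: two-sample t (pooled variance by default, so
  df = n1 + n2 − 2; Welch available by config) between the chains'
  final VI-to-corpus values and the corpus's internal per-language
  values, asking whether chains are as close to the corpus as its own
  languages are to each other. The full study runs this against both
  the reference corpus and a control corpus built on a different
  anchor set, the analogue of checking convergence is specific to the
  reference's structure.

`run_full_study` wires these together from one config + seed and
writes TSV tables, a JSON report and plots; reruns are byte-identical
because every random draw derives from the master seed. The default
problem sizes (110 × 10 corpus, 30 × 13 chains, 0–20 rotation) are the
emulated study's own scale and complete in about two minutes on one
core.

## Known limitations

* The exemplar learner's anchor warp is the *only* source of
  cross-chain boundary universals; its strength trades convergence
  speed against within-chain drift and has not been calibrated to
  human data.
* VI between systems with very small labelled intersections is noisy;
  the package enforces only non-emptiness.
* The maximizing (MAP) learner variant of the dynamics theory — whose
  stationary distribution need not equal the prior — is not
  implemented; only posterior sampling is.
* `language_cross_vis` and `corpus_pairwise_vi` are O(speakers²) per
  language pair; survey-scale corpora are fine (seconds), but corpora
  with hundreds of speakers per language would need a modal-system
  shortcut.
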