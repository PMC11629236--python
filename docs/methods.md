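# Methods

This note records the model, the choices made where the design was open,
and what the synthetic benchmarks do and do not demonstrate.

## Imputation model

The imputer is a dense feed-forward network over pan-reactome coordinates:
`io_size → (256 rectifier units + 10% inverted dropout) × 3 → io_size`
with sigmoid outputs. Binary cross-entropy requires outputs in (0, 1), so a
sigmoid output layer is used; rectifiers are the standard hidden
nonlinearity for dense imputers. The implementation is plain numpy
(forward/backward passes and an Adam optimizer written in-package); at
pan-reactome sizes of a few hundred to a few thousand reactions this trains
in seconds to minutes on one CPU, and keeping the whole computation in one
array library makes bit-level reproducibility under a fixed seed easy to
guarantee.

### Masked, class-weighted loss

Per position: `(1 − I)·[−(1 − b0)·T·log O − b0·(1 − T)·log(1 − O)]`.

* **Mask `(1 − I)`.** Input positions contribute exactly zero loss. Without
  the mask the cheapest strategy is to echo the input; with it the network
  must model co-occurrence. (The complementary convention of masking by
  `(1 − T)` would leave deleted positions unscored, which defeats the
  purpose; the `(1 − I)` form is the one consistent with the masking's
  stated intent and is what we implement.)
* **Class weight `b0 = 0.3`.** A typical genome carries well under half of
  the pan-reactome, so absent positions dominate the sum; `b0` scales the
  absent-class term and `1 − b0` the present-class term.
* **Reduction.** The mean over positions and batch — this keeps the scale
  of gradients independent of pan-reactome size, so the same learning rate
  works across namespaces.
* **Clipping.** Outputs are clipped to `[1e−7, 1 − 1e−7]` before logs. The
  analytic gradient with respect to the logits needs no clipping (the
  `1/O` factors cancel against the sigmoid derivative).

Hyper-parameters (3 × 256 hidden, dropout 0.1, batch 50, 10 epochs, Adam
with lr 0.005, β₁ 0.9, β₂ 0.999, ε 1e−8, decay 0.01, `b0` 0.3) follow a
prior hyper-parameter search on bacterial pan-reactome data; `decay` is
implemented as step-wise learning-rate decay `lr_t = lr / (1 + decay·t)`.

## Corruption schemes

* **Uniform** deletes an exact count, `round(0.3 · n_present)`, without
  replacement — matching the "delete 30%" protocol exactly and making
  tests deterministic, rather than a Bernoulli approximation.
* **Rare-biased** deletes each present reaction independently with a
  logistic probability of its frequency. The curve is implemented
  *decreasing* in `frac_r` — `D(frac) = 1 − 1/(1 + e^{−10(frac−0.5)})` — so
  rare reactions are deleted more often, which is the stated purpose of the
  scheme (emulating the loss of accessory genes from MAGs). The opposite
  orientation (probability increasing with frequency) is available behind
  `as_printed=True`. The biased scheme does not guarantee a 30% total
  deletion; an optional rescaling (`rescale_to_target=True`) normalises the
  expected deletion to the target fraction and is off by default.
* Per-sample seeds are a 63-bit BLAKE2 hash of
  `(base_seed, genome_id, replicate_index)`: replicate streams are
  reproducible without being stored.
* A corruption that would delete every reaction retains at least one.

## Genome selection and splits

Quality score is `completeness − 5·contamination`; ties are broken by the
highest coarse consistency and, as a final deterministic tie-break that the
quality rule itself does not supply, by lexicographically smallest genome
id. The test split takes the best genome per genus; everything else trains.
Both halves keep the full input's pan-reactome so vectors stay comparable;
partition exclusion (dropping a clade) recomputes frequencies because the
excluded matrix becomes its own training collection. Pan-reactome
membership is restricted to gene-associated reactions as given in the
input reaction sets; database-only reactions are never injected into
training data.

## Gap-filling

Candidate databases are prepared by removing biomass-class reactions
(artificial constructs, not predictable from gene content) and splitting
every reversible reaction into forward/backward irreversible halves with
negated stoichiometry, bounds `[0, upper]` / `[0, |lower|]`.

The search bisects α in the LP `max α·f_b − Σ_candidates c_r·f_r` subject
to `S·v = 0`, flux bounds, and medium-limited exchange uptake:

* α = 0 is tried first (relevant for negative costs); otherwise α is
  bracketed by quadrupling and bisected to a relative tolerance of 1e−3,
  keeping the smallest α whose optimum reaches `f_b ≥ ε`. An initial
  feasibility LP (maximise `f_b` with every candidate available) detects
  hopeless instances and reports which biomass precursors are blocked.
* **ε = 1e−6** in model flux units: "biomass flux greater than zero" needs
  a strict numerical threshold for an LP; 1e−6 sits far above solver noise
  and far below any biologically meaningful flux. Shared by every
  growth call in the package (gap-fill, essentiality, carbon profiling).
* **flux_tol = 1e−9**: a candidate counts as used when its flux magnitude
  exceeds this, separating numerically-zero fluxes from real ones.
* **Greedy prune.** The flux-carrying set of the final LP can contain
  reactions that carry flux without being needed for growth (e.g. parallel
  drains). Each added reaction, costliest first, is removed if the model
  still grows without it. This keeps the output close to a minimal set at
  the price of one extra LP per added reaction.
* **Negative costs** (W4neg) would make the LP unbounded through
  zero-net-mass cycles; candidate fluxes are therefore capped
  (default 100) so the negative contribution stays finite.
* Annotation reactions are cost-free and never removed: gap-filling is
  additive only.
* LP backend: scipy's HiGHS (`linprog(method="highs")`) — deterministic
  for a fixed method, which the byte-identical-rerun contract relies on.

Costs are matched to pan-reactome entries on the reaction identifier with
direction tags stripped, so both halves of a split reversible inherit their
parent's cost, and any database reaction outside the pan-reactome gets the
default cost (50) under every scheme.

## Evaluation conventions

* Prediction confusion counts only masked (non-input) positions;
  binarisation threshold 0.5, exposed as a flag.
* Gap-fill scoring: TP = deleted ∩ added, FN = deleted − added,
  FP = added − original. TNs, when reported, use the prepared candidate
  database as the universe (reactions neither in the annotation nor
  added) — some universe must be fixed to count negatives, and the
  database after preparation is the natural one.
* Frequency-binned recall/precision pool per-reaction confusion counts in
  occurrence bins of 50 genomes; pooling then computing equals computing
  from global counts, which a test asserts.
* Balanced accuracy = (specificity + recall)/2, used for carbon-usage
  profiles; models that grow with no carbon source at all are rejected as
  uninformative.

## The synthetic study system

Defaults: 400 reactions — 100 core, 30 module chains of 8 (15 families × 2
isoenzyme variants), 60 rare paralogs — across 6 clades × 40 genomes, 90%
module gain within a clade, 1% flip noise. Sized to train the imputer in
well under a minute on one CPU while keeping every structural feature the
method exploits; the gap-fill benchmarks run on the best-per-genus test
split (6 genomes × 3 corruption replicates) in a few minutes.

The design gives each cost scheme a distinct mechanism to earn its rank,
mirroring the distinct information sources on real data:

* **Decoys** (database-only duplicates of core steps) are
  stoichiometrically indistinguishable from the real reaction. W1 ties and
  picks arbitrarily; every pan-reactome-aware scheme avoids them.
* **Rare paralogs** are in the pan-reactome at low frequency. W2 ties them
  with the frequency-1 core step they duplicate; W3 separates them.
* **Isoenzyme variant pairs** have near-equal frequencies but
  clade-specific co-occurrence. W3 ties; only the network's learned
  co-occurrence (W4) resolves which variant a genome's remaining reactions
  imply.

Every genome's stoichiometric model feeds a nutrient through the core chain
and its module chains into a genome-specific biomass reaction, so deleting
module steps genuinely abolishes growth and gap-filling has to choose among
the alternatives above.

**What passing these benchmarks does not show.** The generator plants clean
block modules and a single linear backbone; real reactomes have overlapping
pathways, promiscuous enzymes, multi-substrate stoichiometry, compartments
and annotation noise that is anything but independent flips. Absolute F1
values here therefore do not transfer to real genomes — only the *relative*
statements (scheme ordering, frequency and distance effects, bias matching)
are the claims under test. Contamination (falsely added reactions) is not
modelled at all.

## Known limitations

* The imputer is a dense network over a fixed pan-reactome: it cannot score
  reactions it never saw in training, and a model in a different namespace
  must be mapped before scoring.
* The half-interval LP relaxation does not guarantee the exact minimum-cost
  completion (solutions are verified to be within 5% of brute-force optima
  on random toys); mixed-integer exact gap-filling is out of scope.
* Essentiality scanning solves one LP per reaction — fine for hundreds of
  reactions, slow for genome-scale models with tens of thousands.
* Training streams are materialised in memory as float arrays; at very
  large collection sizes (10⁵+ samples × 10³+ reactions) a chunked loader
  would be needed.
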