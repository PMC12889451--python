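# Methods

## Model

The pipeline operates on three inputs: a compound library (identifier, name,
SMILES and/or an explicit fingerprint), a pocket library (per protein, one or
more binding-site templates, each a known-ligand fingerprint plus a site
confidence in [0, 1]), and a drug–indication mapping. Structure prediction
and binding-site detection are upstream of this package: pockets arrive as
data.

**Fingerprints.** Compounds and template ligands are encoded as ECFP4
(Morgan radius 2, i.e. diameter 4) hashed bit sets, 2048 bits by default,
computed with RDKit; the width and the bit-set (rather than count)
representation follow the de-facto ECFP4 convention. Chemical similarity is
the
Sørensen–Dice coefficient 2|A∩B|/(|A|+|B|), defined as 0 when both sets are
empty so that an unusable molecule never looks similar to anything.
Because hashed-fingerprint bit assignments differ between toolkits, tests
that need exact values operate on explicitly supplied bit sets; SMILES-derived
fingerprints are only tested for invariants (determinism, canonicalization
invariance).

**Interaction scoring.** The score of compound fingerprint F against protein
p is max over p's templates t of [confidence_t x Dice(F, ligand_t)]. The
max-over-templates and the multiplicative confidence weighting preserve the
stated score ceiling of 1.0 and make the score monotone in both ingredients;
a `score_form="dice_only"` switch retains the unweighted chemical-similarity
variant. A protein with no templates scores 0 (not missing), keeping
signatures dense. Provenance tracing returns the template attaining the
maximum, with exact ties broken toward the lexicographically smallest
template identifier for determinism.

**Similarity.** Drug–drug distance is the cosine distance between
interaction signatures, computed all-against-all; each drug's ranking lists
every other drug ascending by distance, ties broken by ascending compound
identifier, positions 0-based. An all-zero signature has no direction, so
such drugs are assigned distance 1.0 to and from every other compound and
sort last; this keeps all lists the same length (library size − 1) and is
logged.

## Benchmarking metrics

All metrics are leave-one-out against the indication mapping, skipping
indications with fewer than two ranked drugs (they are undefined, not zero).

* **IA@k**: percent of an indication's drugs whose top-k window contains at
  least one other drug of the indication. **AIA@k** is the unweighted mean
  over eligible indications (no size weighting).
* **nIA@k**: per withheld drug, the consensus prediction list is rebuilt
  from the indication's remaining drugs (top-10 windows by default); nIA is
  the percent of withheld drugs found within the top k of their own
  leave-one-out consensus list.
* **NDCG@k**: binary relevance, gain 1/log2(i+1) at 1-based position i,
  averaged over the indication's drugs. The ideal ranking places *all*
  relevant drugs at the top — the normalizer does not truncate at k. This
  choice makes NDCG monotone non-decreasing in the cutoff; the common
  min(k, |relevant|) truncation of the ideal is not monotone (a single
  relevant item at position 0 with two relevant overall gives NDCG@1 = 1 but
  NDCG@2 ≈ 0.61), which would make cross-cutoff comparisons misleading.
* **nNDCG@k**: the recovered withheld drugs are pooled into one virtual
  ranking: their achieved consensus positions are sorted ascending and a
  collision is bumped to the next free slot (e_i = max(p_i, e_{i−1}+1)),
  each contributing gain 1/log2(e_i+2); the normalizer places all m withheld
  drugs in the top m slots. Without the collision bump, m drugs each
  recovered at position 0 of their own list would sum to gain m and exceed
  the ideal; with it the metric is exactly 1 in that case, bounded in [0, 1],
  and monotone in k.

**Controls.** The analytic chance level for IA is hypergeometric: a random
length-(N−1) ranking contains at least one of the n−1 partners in its top k
with probability 1 − C(N−n, k)/C(N−1, k). The empirical control permutes
each compound's signature independently across proteins (preserving each
drug's score distribution while destroying protein identity), rebuilds all
rankings, recomputes the metrics, and averages over seeded replicates (100
by default, one spawned substream per replicate). On homogeneous null data
the two controls agree; when drugs have heterogeneous score distributions
the permuted control can fall below the hypergeometric level, because
signature flatness then dominates permuted-cosine geometry and the same few
drugs crowd every top window — the two baselines are deliberately reported
side by side.

## Consensus prediction

Candidates for an indication are all compounds appearing in at least one
top-k window (k = 10 by default) of the associated drugs' similarity lists,
ordered by descending consensus score (appearance count), then ascending
average 0-based position, then compound identifier. Associated drugs are not
excluded: recovering known drugs is informative. The attached probability is
the binomial upper tail P(X ≥ score) with X ~ Bin(n_assoc, k/(N−1)): each of
the n_assoc lists has N−1 entries, so a random list shows a given candidate
in its top k with probability k/(N−1). The choice of N−1 (not N) in the
denominator, and of the non-strict tail, is fixed by reproducing the
published seven-value probability column for the 68-drug focal indication
exactly to three significant figures; the indication size 68 is itself
recoverable as the unique integer in 2..200 consistent with that column
(`backsolve_indication_size`).

Controls: the bottom-filtered control counts appearances in the bottom-k
window of each associated drug's list after removing molecules with fewer
than 4 heavy atoms (compounds whose structure is unavailable are retained,
since the filter targets known-trivial molecules); ties order by *worse*
average position first. The random control draws positions uniformly without
replacement from a designated reference drug's list under a caller-supplied
seed. The bottom window width mirrors the top cutoff, as no separate width
is established.

## Target lists and overlap

A drug's target list is its signature sorted by descending score (ties by
protein identifier), truncated to n = 100; no score floor is applied by
default — a fixed-length window keeps lists comparable across drugs, and
weak-but-ranked interactions are themselves informative (a floor is
available). Consensus target rankings across a drug set order
proteins by appearance count over the drugs' top-n lists, then mean
position, carrying the mean interaction score for reporting. Overlap of a
target list with a gold-standard protein set is summarized by (i) relative
intersection frequencies within five fixed rank bins of width 20 over the
top-100 window, normalized by total intersections (all-zero and flagged when
none); (ii) cumulative overlap percentage |top-k ∩ gold| / |gold|; and
(iii) Jaccard |top-k ∩ gold| / |top-k ∪ gold|. Overlap percentage is
monotone in the cutoff; Jaccard need not be, since the union grows faster
than the intersection when weak predictions are added.

## Synthetic data

The generator plants known structure so recovery is measurable:

* Each indication owns a disjoint *motif* block of fingerprint bits
  (32 by default) and a set of *signal proteins* (10 per indication) whose
  first pocket template contains the motif. Every compound carries 24
  background noise bits; a drug associated with an indication additionally
  keeps each motif bit with probability `cluster_strength`. At
  `cluster_strength = 0` membership leaves no statistical trace and all
  drugs are exchangeable, so IA matches the hypergeometric control; at 1,
  same-indication drugs share whole motifs and their signatures separate
  cleanly from the background.
* Default scale is 200 compounds x 150 proteins with five indications — one
  focal indication of 68 drugs (mirroring the focal indication size the
  probability column implies) and four of 8 — chosen to keep the full
  pipeline, including 100-replicate controls, in the seconds-to-a-minute
  range while leaving meaningful rank statistics.
* The gold standard contains `gold_overlap_fraction` x `gold_size` proteins
  drawn from the focal drug set's consensus top-`gold_top_window` targets
  (window 100 by default) plus decoys from outside that window, so the
  planted overlap percentage at the window cutoff is exact by construction.
* All randomness flows from one master seed through named substreams
  (membership, fingerprints, templates, confidences, gold), and equal seeds
  produce byte-identical written studies.

What the generator does **not** emulate: real chemistry (synthetic
fingerprints are uniform random bit sets, not ECFP4 distributions of
drug-like molecules), realistic pocket-confidence profiles, overlapping
indication membership, and the heavy right tail of indication sizes in real
mappings. Passing recovery tests on synthetic data therefore demonstrates
the correctness and calibration of the machinery, not the biological
accuracy of any particular real-world ranking. A small curated SMILES set
(methane, ethanol, benzene) inside the hand-built fixture feeds the
heavy-atom-filter tests with real structures.

## Numerical and degenerate-input conventions

Cosine distances are clipped at 0 to absorb floating-point round-off;
distances of all-zero signatures are 1.0 by convention. Unparsable SMILES in
a compound table flag the record unusable (excluded from scoring, logged)
rather than aborting; a duplicated compound identifier is a hard error
naming the offender. Pocket confidences outside [0, 1] and metric
preconditions (empty relevant sets, undersized indications, oversized draws)
raise immediately. Every stochastic routine takes an explicit seed;
replicate streams are spawned from it so per-stage outputs are independently
reproducible.

## Known limitations

The confidence-weighted-maximum scoring form is one defensible reading of a
pocket-score-weighted similarity protocol; real deployments may combine
pocket scores differently, which is why `score_form` exists. Benchmarks here
quantify recovery on planted structure only; published headline recovery
percentages for real libraries depend on the full proprietary interaction
matrices and mapping and are not reproduced by this package. Consensus
probabilities assume independence of the associated drugs' lists, which is
conservative for strongly clustered indications.
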