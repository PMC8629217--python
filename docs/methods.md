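# Methods

## Setting and notation

A report is a sequence of lowercase alphabetic word tokens; `|r|` is its
token count. A test set pairs references R = {r_1, …, r_N} with candidates
C = {c_1, …, c_N}; n_R and n_C are the total token counts of each side. A
*single-report unconditioned model* outputs one fixed report c for every
input, so c_i = c for all i.

## Text normalisation

Cleaning splits raw text on every maximal run of non-alphabetic characters
and lowercases the pieces, which realises "remove all non-alphabetic
tokens" deterministically: `"5 cm,"` yields the single token `cm`, and
hyphenated words split (`x-ray` → `x`, `ray`). Stop words are retained; no
stemming or lemmatisation is applied. De-identification placeholders —
any token that is purely a run of x's — are dropped by default
(`drop_placeholders=False` retains them; note that this rule also removes
a bare `x` produced by splitting `x-ray`). Reports that clean to zero
tokens are kept so corpus sizes are stable; every metric scores such a
pair 0 and the brevity penalty is defined as 0 when n_C = 0.

## Metrics

**BLEU-K.** Clipped k-gram matches min(occ(w, r_i), occ(w, c_i)) are
pooled over the corpus. Two dialects are exposed because the summed,
token-normalised form and the conventional geometric-mean form genuinely
differ:

- `paper`: BP · Σ_{k=1..K} p_k with every p_k = (pooled clipped matches at
  order k) / n_C, i.e. normalised by total candidate *tokens*. On
  identical corpora only p_1 reaches 1 (higher orders have fewer windows
  than tokens), so the score is 1 at K = 1 and below K otherwise.
- `coco` (default): p_k normalised by the total number of candidate
  k-grams, combined as BP · exp(mean_k log p_k), zero if any p_k = 0.
  This matches the COCO-caption convention used by most published
  radiology-report numbers and scores 1 on identical corpora for any K
  (provided reports have length ≥ K).

BP = min(1, exp(1 − n_R/n_C)) in both dialects.

**ROUGE-L.** Per pair, the LCS-based F-score
((1+β²)·P·R)/(β²·P + R) with P = LCS/|c|, R = LCS/|r| and β = 1.2
(the customary weighting of recall over precision); pairs with LCS = 0
score 0; the corpus score is the mean over pairs.

**METEOR.** Exact surface-form unigram matching only (no stemming or
synonymy). The match count is the clipped count Σ_w min(occ(w,c),
occ(w,r)); chunks are found by repeatedly aligning the longest contiguous
run of still-unmatched identical tokens (each run is one chunk), a greedy
minimisation of the chunk count. Per pair:
(1 − 0.5·CP³) · (10·P·R)/(9·P + R) with CP = chunks/matches; zero matches
score 0. Identical reports with m distinct tokens score 1 − 0.5/m³; a
single-token identical pair scores 0.5 (CP = 1 — a known boundary quirk of
the formula, reproduced deliberately).

**CIDEr / CIDEr-D.** Per k ∈ 1..K (K = 4): tf-idf vectors over k-grams
with tf = count / total k-grams of the report and idf = ln(N / df) from an
index over the reference side (df floored at 1 for unseen grams, so a
k-gram appearing in *every* reference has idf exactly 0 and can never earn
credit — the structural reason single-report baselines score poorly here).
Plain CIDEr averages cosine similarities over k. CIDEr-D replaces the
inner product with the clipped form min(g(c), g(r))·g(r) (candidate
repetition beyond the reference is ignored), multiplies by a Gaussian
length penalty and by 10. The length penalty defaults to the standard
symmetric form exp(−(|c|−|r|)²/(2σ²)), σ = 6; a `literal` flag exposes the
non-squared exponent for comparison, which is asymmetric in the sign of
the length difference and is not recommended. Per-pair scores are averaged
over the corpus; zero-norm vectors (empty reports, all-idf-0 content)
contribute 0.

**Label accuracy.** A small rule lexicon (bundled YAML, fully
configurable) marks each of 14 chest-finding categories positive when a
mention phrase occurs with no negation cue (`no`, `without`, `negative`)
within the 3 tokens preceding the match, negative otherwise; no-mention is
negative. The window of 3 captures the "no …", "without …" phrasing the
synthetic templates emit. Accuracy micro-averages agreement over
(report, category) cells; a macro flag averages per category instead. The
category list follows the common 14-name chest-finding convention; the
no-finding category is ordinary and simply stays negative in synthetic
data, where normality is the all-negative state. Values are strictly
binary: the external tools this emulates also emit uncertain/blank, which
is out of scope.

## Unconditioned baselines

**Baseline 1 (retrieval).** c = argmax_{r∈R} s(r, R) over the training
references, ties broken uniformly at random under a seed; the full tie set
is reported. The exhaustive search evaluates every reference as the
universal candidate (O(N²) pair scores). Fast searches reproduce the
exhaustive result *exactly* (same floats, same tie set):

- BLEU-K: a table of per-k-gram prefix sums of Σ_i min(m, occ(w, r_i))
  makes the pooled clipped count of a candidate computable in O(|c|);
  denominators and BP depend only on |c|.
- CIDEr-D: reference tf-idf vectors and norms are computed once; the
  length penalty is a pure function of the two lengths, so it is looked up
  per reference-length bucket. Aggregation runs through the same code path
  as the plain corpus metric so results agree bit-for-bit.
- Label accuracy: with per-category positive counts p_cat over R, a
  candidate with label vector v scores
  Σ_cat [v_cat ? p_cat : N − p_cat] / (N·|categories|) in O(1).

METEOR and ROUGE-L are sequence-matching metrics with no analogous
sufficient statistics; they are served by the exhaustive search only.

**Baseline 2 (greedy construction).** Step 1 selects a multiset of
n = round-half-up(mean reference length) words; each pick maximises the
number of references in which the word still has unmatched occurrences
(#{r : occ(w, r) > occ(w, c)}), with ties broken by total corpus frequency,
then lexicographically. Because the marginal gain of an additional copy of
a word is non-increasing, this greedy attains the exact maximum of the
total clipped unigram matches Σ_r Σ_w min(occ(w,c), occ(w,r)) among all
multisets of size n (verified against brute-force enumeration at small
scale). Using at least the mean length avoids a brevity penalty when the
report is emitted once per reference. Step 2 walks the corpus 2-grams in
descending frequency (ties lexicographic) once; for each 2-gram (a, b) it
repeatedly merges the first fragment ending in `a` with the first other
fragment starting with `b`. A literal "while |c| > 1" loop cannot
terminate when no joinable pair remains, so after the single pass the
leftover fragments are concatenated in descending order of their leading
word's corpus frequency (stable within ties). Joining only reorders: the
Step 1 multiset, and hence the BLEU-1 score, is conserved.

## Permutation unconditioning

Candidates are reassigned by a uniform random permutation of positions;
references, ids and tags stay put, and the permutation is returned as an
audit record. Identity is allowed by default (the permutation is sampled
uniformly); a no-identity option resamples for m > 1, since a sampled
identity vacuously preserves scores. Any single-report candidate set is
exactly invariant under permutation — the reassigned pairs are literally
the same pairs.

## Stratified evaluation

Records are grouped by tag (normal = no positive finding, else abnormal)
and each metric is recomputed within the stratum, including corpus-level
statistics (pooled BLEU counts, BP). The CIDEr idf table defaults to the
full reference side (`idf_scope="global"`) with a per-stratum override;
per-pair-averaged metrics recombine across strata as stratum-size-weighted
means, which the tests assert numerically.

## Paired bootstrap test

The statistic is δs = s(A) − s(B) on the shared test set. Each of B
replicates (default 1000) draws N record indices with replacement and
recomputes both corpus scores from per-record sufficient statistics — so
pooled quantities (BLEU counts, BP, accuracy cell counts) are genuinely
recomputed per replicate, while per-pair-averaged metrics resample their
pair scores (the CIDEr idf table is held fixed at the original corpus; the
resampling detail is otherwise underdetermined). The null distribution is
the replicate δ distribution shifted to mean zero (shape-preserving mean
shift); the two-sided p-value is
(1 + #{b : |δ_b − mean(δ)| ≥ |δs|}) / (B + 1), add-one smoothed so p > 0.
95% percentile intervals are reported for δ and for each system's own
replicate scores. Swapping A and B negates δs and preserves the p-value
exactly under the same seed. Monte-Carlo calibration (500 repetitions,
B = 500, two identically distributed simulated systems) puts the
rejection rate at α = 0.05 in the expected band around the nominal level.

## Synthetic corpus

The generator emulates the *statistical shape* of standardised chest-X-ray
reporting, not any real corpus: four topics (heart size, lungs, pulmonary
vasculature, bony structures), one sentence each from small bundled
template banks (weights 0.6/0.25/0.15, so normal phrasing is heavily
shared), negation phrasing in normal sentences, a 0.70 normal fraction,
and per-finding abnormality probabilities (cardiomegaly 0.50, pleural
effusion 0.45, edema 0.35, fracture 0.25, conditional on the report being
abnormal; at least one positive finding is forced so tag ↔ label
consistency holds by construction). Mean report length lands near 30
tokens, controlled by template choice rather than truncation. Templates
and lexicon are co-designed so rendering followed by label extraction is
the exact identity — the basis of the ρ = 1 round-trip checks.

The simulated generator renders each candidate from the record's own true
labels with probability ρ, otherwise from labels drawn independently at
the corpus marginal rates; word-substitution noise replaces tokens with
in-vocabulary tokens at the given rate (so cleaning invariants hold). At
ρ = 0 the candidate distribution is independent of the pairing, which is
what makes the permutation comparison a true null there.

What passing tests on this generator do **not** show: real reports have
richer paraphrase variation, section structure, uncertainty hedging and
labeler disagreement; absolute metric values here (e.g. the high baseline
label accuracy driven by the 70% normal rate and four active findings)
should be read as qualitative reproductions of the evaluation-gaming
phenomena, not as estimates for any real dataset.

## Problem sizes and numerics

The test suite and the acceptance script use synthetic corpora of 40–400
reports, bootstrap sizes B = 300–1000, 50 permutation replicates and 200–
500 calibration repetitions — sizes at which every phenomenon is already
stable across seeds. Fast/exhaustive equivalence is asserted as exact
float equality, which the implementation guarantees by routing both paths
through identical arithmetic (integer count tables; shared per-pair and
aggregation code). Ties in argmax searches are exact float ties;
tie-breaking is seeded everywhere (selection rules are layered frequency →
lexicographic → random so runs are reproducible). Quantiles use linear
interpolation. Known limitations: single-reference evaluation only (no
multi-reference support), binary labels only, and no attempt to reproduce
any external labeler's behaviour on real text.
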