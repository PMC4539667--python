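# Methods

## Composition statistics

A coding sequence is normalized on load (uppercase, `U → T`) and validated
against the IUPAC nucleotide alphabet. Two per-sequence statistics form the
coordinate system of the screen:

**GC fraction.** `(G + C) / (A + C + G + T)`. Ambiguity codes are excluded
from both numerator and denominator — including `S` (G-or-C), which could
arguably count as strong. The exclusive convention keeps the statistic a
deterministic function of the unambiguous bases and avoids imputing
composition; in curated CDS sets ambiguity is rare enough that the choice
is immaterial in practice. A sequence with no unambiguous base has no GC
fraction and raises an error rather than returning a sentinel.

**G/C stretches.** A stretch is a *maximal* run of at least `k` consecutive
bases each of which is G or C (mixed runs count); the default `k = 3`. Any
other character, ambiguity codes included, terminates a run. Coordinates
are 0-based half-open everywhere. Per sequence we record the stretch count,
mean, maximum and total length. A sequence with no run of length ≥ k gets a
*missing* mean stretch length, not 0: a zero would sit far below the
smallest attainable value (k) and distort the low tail of any background
distribution built from it. Such records are excluded from the stretch axis
of the background (their count is logged) and can never be flagged on that
axis; at the default ≥ 300 nt length filter this case is vanishingly rare
in real CDS data.

Only CDS of length ≥ 300 nt are analyzed by default ("longer than 299 nt"
read literally); the threshold is configurable. Very short CDS make the
stretch mean noisy and are the conventional exclusion in this kind of
screen.

Both statistics are invariant under reverse complementation, since
complementation maps G↔C and A↔T and so preserves the strong/weak base
classes. This invariance is enforced by tests on randomized sequences, and
the stretch finder is checked exactly against a quadratic brute-force
enumerator of maximal all-G/C substrings.

## Background model and outlier rule

The background is the empirical joint behaviour of a reference gene set:
sorted value arrays for each axis plus a fixed-width histogram
(`bin_width = 0.1`, starting at `k`) of mean stretch length. At least 100
usable records are required — percentile thresholds in the 99% region are
meaningless below that.

Percentile ranks are inclusive counting ranks, `100 · #{x ≤ q} / n`; ties
count in, values above the background maximum return 100. This matches a
brute-force counting oracle exactly and involves no interpolation, so calls
are deterministic.

The outlier rule is an explicit, reproducible surrogate for a judgment that
is often made visually on a dot plot: a query is flagged when its GC and
stretch percentiles are both ≥ 99 (configurable thresholds; an `either`
mode ORs the axes instead). The rule string is recorded in every call so a
table of calls is self-describing. The joint both-axes rule keeps the
false-flag rate at or below roughly 1% by construction, since each axis
alone admits about 1% of the background and the two axes are positively
correlated.

## Group comparison

Whether two groups of genes (e.g. one species' genes vs other species')
share a composition distribution is tested with the two-sample
Kolmogorov–Smirnov statistic, `D = sup_x |F̂_a(x) − F̂_b(x)|`, evaluated
exactly over the pooled support. Internally D is computed in integer
arithmetic (`|cum_a · n_b − cum_b · n_a|`), so tied values and repeated
permutations are handled without floating-point hazards and a seeded run is
bit-reproducible.

The null is a label-permutation distribution:
`p = (1 + #{D* ≥ D}) / (1 + n_perm)` with the observed sample included in
the denominator. This is valid under exchangeability alone. Because D is a
discrete statistic, the test is slightly conservative: for two groups of
50, the attainable level nearest 0.05 is `P(D ≥ 0.28) ≈ 0.039`, and the
measured null rejection rate at α = 0.05 reflects that, not 0.05 exactly.
Groups need at least 5 non-missing values each, and `n_perm ≥ 99`;
`n_perm = 199` gives `α · (n_perm + 1)` integral at α = 0.05.

The per-gene ortholog contrast reports, per clade group, the count, mean
and range of both metrics, and runs the pairwise permutation test wherever
both groups have ≥ 5 members; smaller pairs are listed as skipped with the
reason rather than silently dropped.

## Quadruplex motif scan

The scanner implements the canonical pattern-matching convention for
putative G-quadruplexes: at least 4 tracts of ≥ 3 G separated by loops of
1–7 arbitrary bases (all parameters configurable); minus-strand motifs are
found by the same rule on C-tracts and reported in plus-strand coordinates.
It is implemented as left-greedy chain assembly over *maximal* G-runs
rather than as a single regular expression: a lazy-loop regex can consume G
bases into loops and mis-count tracts, whereas chain assembly guarantees
each reported hit contains its stated number of well-separated tracts and
hits never overlap on a strand. Chains longer than the minimum are absorbed
into one hit. This is a sequence-pattern stand-in, not a thermodynamic or
structure-based predictor, and is labelled as such in the output schema
(BED6 with the tract count in the score column).

## Synthetic sequence generator

The generator emulates the contrast between an ordinary CDS population and
GC-rich, long-stretch outliers with the simplest model in which GC content
and run structure are independently tunable: a two-state renewal process
alternating "strong" (G/C) and "weak" (A/T) runs with geometric lengths.
The strong-run mean `m_s` is set directly; the weak-run mean is derived as

    m_w = m_s · (1 − gc) / gc,

so the stationary strong-base fraction `m_s / (m_s + m_w)` equals the
target GC identically. Within a run, the two eligible letters are drawn
independently and equiprobably, which makes every composition statistic
strand-symmetric by construction. Geometric runs are memoryless, giving a
second closed form used as a test oracle: a strong run conditioned on
reaching length ≥ 3 has mean `2 + m_s`, which the measured k = 3 stretch
mean must match (at 200 kb, observed |error| ≈ 0.02 nt against 6.0 for
`m_s = 4`).

Seeding: each sequence draws from its own `numpy` generator seeded with
`spec.seed + index`, so regeneration does not depend on batch order. In a
background + spike-in panel the spike streams are offset by the background
count; two specs with identical parameters therefore still produce
independent groups, which is exactly the construction used for
null-calibration experiments.

Default study conditions used by the tests and the acceptance script:
background 2,000 sequences of 1 kb at GC 0.50 with `m_s = 3.2`; outliers
20 sequences of 1 kb at GC 0.72 with `m_s = 4.5`. Under these conditions a
single spike is flagged by the default both-axes 99th-percentile rule with
probability ≈ 0.92–1.0 depending on the draw — the stretch axis, whose
per-sequence mean carries sampling noise of ≈ 0.4 nt at 1 kb, is the
limiting axis. Calibration experiments use 1,000 replicates of two groups
of 50 GC values from 500-nt sequences with 199 permutations each; these
sizes keep the full suite fast on one CPU while leaving the binomial error
of the measured rates small.

What the generator does *not* emulate: codon structure, codon-position GC
(GC3), length variation across genes, phylogenetic correlation between
sequences, microsatellite repeats, and ambiguity codes. Passing tests on
synthetic panels therefore demonstrate the pipeline's statistical
behaviour — separation, calibration, determinism — not the biological
composition of any real gene set; real-data runs should supply their own
reference background.

## Coverage model

The coverage module demonstrates the mechanism by which GC-rich stretches
disappear from sequencing data: expected depth per fixed-width window
(default 50 nt, final partial window kept with its own GC) is

    depth(w) = base_depth · exp(−β · max(0, GC_w − GC_ref)),

uniform at `base_depth` for windows at or below the reference GC
(default 0.5) and decaying exponentially in the GC excess. β is a free
parameter with no empirically anchored value; the functional form is this
package's own one-parameter demonstrator chosen for monotonicity and
simplicity, not a fitted instrument model. The module guarantees only the
qualitative property that matters: coverage is non-increasing in window GC
for β > 0 and exactly uniform at β = 0. No read-level simulation (FASTQ,
error models, fragment sampling) is attempted.

## Pipeline determinism

Every CLI output table begins with `#` comment lines recording the tool
version and the serialized configuration; no timestamps are written.
Identical inputs, configuration and seed therefore produce byte-identical
outputs, which the test suite asserts for every subcommand. FASTA outputs
are the one exception to the header rule: the format has no portable
comment syntax, and a comment line would break downstream parsers; their
provenance lives in the sidecar metadata TSV written alongside.

## Known limitations

* The outlier rule is a percentile surrogate; it does not reproduce any
  particular published gene list, which would require the external
  databases and curated lists those analyses used.
* Percentile ranks are step functions of the background sample; with small
  backgrounds (n near the 100 minimum) the 99th-percentile threshold is
  grainy and sensitivity drops.
* The permutation test's discreteness makes it conservative at small,
  equal group sizes (see above); report the attainable level alongside α
  when group sizes are small.
* Ambiguity-heavy sequences lose information under the exclusion rule; a
  sequence of only ambiguity codes is rejected outright.
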