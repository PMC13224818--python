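# Methods

## Scope and data model

`nodufam` analyses gene superfamilies associated with root-nodule symbiosis
across 18 species: five Papilionoideae (glyma, medtr, phavu, lotja, aesev),
three Caesalpinioideae (chafa, sento, acacr), one Detarioideae (singl),
three Cercidoideae (cerca, bauva, phach), three Rosales-side relatives
(quisa, treor, paran) and three outgroups (arath, prupe, vitvi). A species
is a *legume* iff it belongs to one of the four subfamilies. Leaf labels
are `<code>.<gene_id>`; the species code is the prefix before the first
`"."`, with a first-five-characters fallback for labels without a
separator. Coordinates are 1-based inclusive (GFF3 convention); the
*ordinal* of a gene is its genome-wide rank among all annotated genes on
its chromosome sorted by start (ties broken by end, then gene id — an
arbitrary but deterministic choice). Strand is stored but ignored by all
proximity logic.

## Clade enumeration

Legume gene clades are defined on the rooted tree's leaf listing, not by
reconciliation: a clade is a maximal run of legume leaves, and in
permissive mode a single non-legume leaf whose immediate neighbours are
both legume leaves is absorbed as an intruder rather than terminating the
run. Consequences of reading "flanked" literally:

* a non-legume leaf at either end of the listing is never absorbable;
* two or more consecutive non-legume leaves always terminate a run;
* several isolated singletons may be absorbed into one clade, each
  individually flanked. `max_intruders` (default unlimited) restores the
  stricter one-intruder-per-clade reading.

Leaf order is taken exactly as written in the Newick source; no re-rooting
or ladderisation is applied, so the enumeration is a deterministic function
of the input file. Both modes satisfy: the permissive count never exceeds
the strict count (absorbing can only merge runs), and member counts sum to
the number of legume leaves. These invariants, and agreement with an
independent brute-force enumeration (rewrite isolated flanked `N`s, then
count runs), are tested on random binary leaf patterns.

## Positional paralog typing

Every unordered same-species pair in a superfamily is classified:

* **tandem** — same chromosome, |start_a − start_b| ≤ 1 Mb, and
  genome-wide ordinal difference exactly 1 (no intervening annotated gene
  of any family);
* **proximal** — same chromosome, within the window, not adjacent;
* **distal** — otherwise (including adjacent pairs that span more than
  the window, since tandem is a subdivision of the 1 Mb local class).

Distance is anchored on gene starts rather than the inter-gene gap: at the
Mb scale the difference is negligible and the start anchor is insensitive
to annotation differences in gene length. An `adjacency="within-family"`
variant treats a pair as tandem when no *family* gene lies between them,
for position tables that only cover family members.

Clade-pair origin calls test, per species shared by the two clades,
whether any cross-clade pair falls within the window on one chromosome;
with support in at least `min_local_species` species (default 1) the pair
is called local, otherwise segmental. The ancient-local rule uses strict
clades and its own threshold: at least 6 species (default) must each have
a within-window cross-strict-clade pair. Only genes that are members of
strict clades can contribute, so support is effectively restricted to
legume species; a `legume_only_support` flag makes that restriction
explicit. The rule is monotone in the threshold, which is tested.

## Expression bias

Replicates are averaged per tissue; relative expression divides each
tissue mean by the gene's total over tissues. A gene is biased toward its
top tissue when that tissue's mean is ≥ fold (default 2, inclusive) times
every other tissue's mean; exact ties and sub-threshold margins are
neutral, all-zero or absent data is NA. The fold rule is scale-invariant,
so means and relative values give identical labels. The gene-level rule
uses the same ≥ 2-fold margin as the superfamily rule (an argmax-only
gene rule would label nearly every gene); superfamily labels average
member-gene tissue means unweighted before applying the rule.

Conservation categories compare the PAP label multiset P (medtr, glyma,
phavu) with the CAE label c (chafa): category 5 when c or any PAP label is
NA or everything is neutral; 1/2 when P is unanimous and non-neutral
(c equal / different); 3/4 otherwise (c non-neutral and matching some PAP
label / not). One edge case the category definitions leave open — P
unanimously neutral with c non-neutral — falls to category 4, since there
is no non-neutral PAP pattern to be conserved within; the assignment is
total over the full 5^4 label space, which is tested exhaustively.

PCA operates on a complete-case superfamilies × (species × tissue)
relative-expression table, centered and scaled per column (constant
columns dropped); variance fractions come from the singular values.
Heatmap count matrices are capped at 50 for display only — the statistics
run on uncapped counts unless a cap is requested.

## Family-size statistics

Kruskal–Wallis H is computed on mid-ranks with the standard tie
correction (scipy), short-circuiting to H = 0, p = 1 when all observations
are identical (zero rank variance). The effect size is the rank-based
epsilon-squared, ε² = H(n+1)/(n²−1). Pairwise two-sided Wilcoxon rank-sum
tests use exact enumeration when both groups have ≤ 50 observations and no
ties, and the normal approximation with continuity and tie correction
otherwise; Benjamini–Hochberg adjustment is applied over all unordered
pairs. Note the chi-squared p-value is an approximation: on exhaustively
enumerable instances (n ≤ 8) it can differ from the exact permutation
p-value by ~0.2, while H itself matches the closed-form rank computation
exactly — the tests check both at those tolerances.

## The simulator

Families evolve down a fixed 18-taxon species tree whose planar order
places the six non-legumes first and the twelve legumes in one contiguous
block, so a duplication above the legume crown separates legume runs with
duplicated outgroup leaves while legume-internal duplications do not
split clades. Branch events: WGD copies (different chromosome, same
ordinal slot, per-leaf retention probability), tandem copies (adjacent
slot, same chromosome), proximal copies (3–11 slots away, i.e. 2–10
intervening genes) and losses; an optional planting inserts a tandem
duplication above a named pre-legume node with the copy retained in
exactly *m* legume species, giving exact control over the ≥ 6-species
ancient rule.

Positions live on an integer slot lattice per chromosome — each slot is
one annotated gene, family member or background — so ordinal rank equals
slot index. Base-pair starts accumulate i.i.d. uniform 20–90 kb
inter-gene spacings: 11 consecutive gaps stay below 990 kb, so planted
tandem and proximal copies are always within the 1 Mb window, while
distinct ancestral loci sit 20,000 slots apart and are unambiguously
distal. (A wider spacing override exists to create adjacent-but->1 Mb
edge cases.) The event log records every speciation, duplication and
loss with its placement; replaying the log reconstructs the final gene
set exactly, and ground-truth pair relations are derived from the
internal slot lattice independently of the table-driven classifier.

Expression is generated per replicate as
`base × fold^(tissue = planted label) × exp(N(0, σ))` with base
log-uniform in [1, 100]; neutral genes have fold 1. Defaults for the
recovery benchmark are planted fold 4, σ = 0.25 and 3 replicates per
tissue — a strong but realistic bias with moderate biological noise —
under which the 2-fold classifier recovers ≥ 95 % of planted labels
(measured ≈ 99.9 %), and 100 % noise-free. Recovery is monotone
non-increasing in σ and non-decreasing in fold (tested on a seeded grid).

### What the simulator does and does not emulate

It reproduces the *decision surfaces* of the pipeline: leaf-listing clade
structure under ancient vs recent duplications, the 1 Mb/adjacency
geometry, retention-count thresholds, and fold-change bias under
multiplicative noise. It does not emulate sequence evolution, gene-tree
estimation error or rooting uncertainty, real gene-density variation,
chromosome-scale synteny decay, or correlated expression across paralogs.
Passing recovery benchmarks therefore validates the inference rules and
their implementation, not robustness to tree-inference artefacts in real
data.

## Problem sizes and determinism

The standard benchmark uses 200 random leaf patterns (length ≤ 30) for
the clade oracle, 50 loss-free families (~30–70 genes each) mixing the
five regimes, and 1,000 genes for bias recovery — sizes at which every
recovery metric is stable across seeds while the whole validation run
completes in seconds. All randomness flows through
`numpy.random.default_rng` seeded from a single `--seed`, with one
substream per family index, so outputs are byte-identical across runs.
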