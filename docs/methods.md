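# Methods

This note records the modeling choices, numerical conventions and
limitations of `specmol`, in the order data flows through the pipeline.

## Peak annotation

A spectrum is reduced to its `max_peaks` (default 60) most abundant peaks —
sorted by intensity descending, ties broken by ascending m/z so the result
is independent of input order — *before* formula matching, so a spectrum
may end with fewer than 60 annotated peaks. For each retained peak, every
non-empty subformula `f` of the parent formula is enumerated exhaustively
(a bounded nested product over element counts, refused above 2·10⁶
combinations; parents at the scale this package targets have far fewer) and
the ion mass `mass(f) + adduct offset` is compared with the observed m/z.
Every peak is assumed to carry the spectrum's adduct charge. The assignment
minimizes |ppm error| within the ±`ppm_tol` window (default 20 ppm), with
ties broken by the lexicographically smallest formula string; unassignable
peaks are dropped. Surviving intensities are divided by their maximum —
"normalized intensity" is taken as per-spectrum max-normalization, the
field's default.

Adduct ion offsets are +1.007276 Da ([M+H]+) and +22.989218 Da ([M+Na]+),
the conventional proton and sodium-minus-electron values.

## Element scaling

The `ElementScaler` stores, per element of E, the maximum count observed in
the *training* annotations (floored at 1, with a warning for elements never
observed). It is frozen after fitting, serialized into the checkpoint, and
reused unchanged for validation, test and inference — refitting on
evaluation data would leak statistics across splits, and a dedicated test
asserts the pipeline does not. Counts above the training maximum scale
above 1 and are logged but never clipped; retrieval quality may degrade for
such out-of-range formulas.

## Consensus spectra

The consensus of a molecule's spectra is the union of their peak formulas
with the maximum *normalized* intensity kept per formula (merging after
per-spectrum normalization keeps the consensus in [0, 1] without a second
pass). The operation is commutative, associative and idempotent, and each
constituent spectrum's formula set is a subset of the consensus formula
set. Consensus spectra are built within each split; a single-spectrum
consensus degenerates to that spectrum's own formula map, which is also the
inference fallback when only one measurement exists.

## Encoders

All four encoders end in the shared embedding dimension (default 256;
desk-scale experiments use 64). Architectural details the model family
leaves open were fixed as follows and are all configurable:

- **Graph encoder** — 3 GCN layers over the symmetrically normalized
  adjacency with self loops (node features only; edge features are produced
  and versioned by the featurizer but a plain GCN does not consume them),
  mean pooling over nodes, then a 2-layer MLP head. Mean pooling keeps the
  scale stable across molecule sizes.
- **Spectral encoders** — a 3-layer MLP lifts each 15-dim peak vector to the
  model width, two post-norm transformer blocks with 2 attention heads mix
  the peak set, masked mean pooling collapses it, and a linear head
  projects. No positional encoding: a peak set has no order, and the
  encoders are tested to be permutation- and padding-invariant. The
  spectrum and consensus encoders share this architecture with independent
  parameters.
- **Fingerprint / binned encoders** — 3-layer MLPs. The binned variant
  replaces both spectral encoders with MLPs over fixed 0.1-Da bins
  (10 000 bins to 1000 m/z, summed then max-normalized).
- Hidden widths default to 256 (GCN, MLP, transformer FFN 2×), dropout 0.1
  between hidden layers, Glorot initialization from a seeded generator.

Embeddings are **not** L2-normalized at encoder output; normalization lives
inside the cosine of the discriminator, which is what makes the loss (and
ranking) invariant to positive rescaling of any view.

## Contrastive objective

The discriminator is `h(u, v) = exp(cos(u, v)/τ)`, τ > 0 (default 0.05).
The directed loss from view p to view q averages the InfoNCE term over the
batch anchors, with the other B−1 in-batch items of view q as negatives;
each unordered view pair contributes both directions once (six pairs,
twelve directed terms with all four views active — summed over pairs, not
averaged, while each directed term is a mean over anchors so the loss scale
is batch-size stable). Batches contain one spectrum per molecule, sampled
uniformly from the molecule's constituent spectra, so in-batch negatives
are never false negatives. The trailing partial batch of an epoch is not
emitted (its negative count would differ); the per-epoch permutation
rotates which molecules sit out.

## Training

Adam with default moments, no weight decay, no schedule. Published-recipe
defaults (lr 7.0e-5, 1500 epochs, batch 64, τ 0.05) are the `TrainConfig`
defaults; the package's small-run experiments use lr 1e-3 for 200 epochs,
appropriate for the few-hundred-step regime of a 50-molecule library.
Last-epoch parameters are kept by default; best-on-validation selection is
available behind a flag. Training with a view subset (always including
`mol` and `s`) leaves the inactive encoders exactly at initialization.
Everything is float64 numpy, single-threaded and deterministic: one seed
yields bit-identical checkpoints and result CSVs.

## Ranking and metrics

Candidates are scored by cosine similarity; ties all receive the **worst**
rank of their tie group, in metrics and in aggregation alike, so ties never
flatter the method. Average-rank aggregation stores the negated mean rank
as its score (keeping "rank 1 has the maximal score" true in every table);
reciprocal-rank aggregation sums 1/rank. The normalized rank difference of
a molecule's spectra is the range of the target's ranks divided by the
candidate count.

`mces_distance` computes |E_A| + |E_B| − 2|MCES| exactly by branch-and-bound
over edge mappings with a consistent partial vertex map; atoms match on
element and bonds on bond type (aromatic is its own type — the strictest
chemically meaningful convention, since the metric's label sensitivity is
otherwise unspecified). Exact search is exponential, so molecules above
`size_cap` (default 20) heavy atoms are refused; the approximate relaxation
used by large-scale benchmarks is out of scope, and the exact
implementation here is a stand-in for it on small molecules.

## Synthetic data

The generator emulates the statistical structure the model assumes, not
fragmentation chemistry. Molecules grow from a seeded grammar (aliphatic or
aromatic cores plus random C/O/N/S attachments, occasional carbonyls),
deduplicated by canonical SMILES, ≥4 heavy atoms. Fragments are *connected
subgraphs* of the heavy-atom graph — not random subformulas — so spectra
carry structural signal the graph view can exploit; hydrogens are those of
the fragment atoms plus one per cut bond, clamped to the parent's hydrogen
count, which guarantees every true peak is a genuine subformula. Fragment
size follows a binomial whose mean fraction `exp(−energy/40)` shrinks with
pseudo-collision-energy, mimicking harder collisions. m/z error is
Gaussian in ppm (default sd 5, clipped at ±15 so true peaks stay inside the
20 ppm window); intensities are log-normal; uniform-m/z noise peaks arrive
at a Poisson rate per true peak. Three spectra per molecule at three
energies is the default, matching the common multi-energy acquisition
pattern. Splits are disjoint by Murcko scaffold, a desk-scale proxy for
structure-disjoint benchmark splits. One seeded generator per dataset
(library first, then spectra in molecule and energy order) makes fixtures
exactly reproducible.

What passing tests on this generator do and do not show: they establish
that annotation, the encoders, the loss and ranking compose into a working
retrieval system (held-in rank@1 well above chance on 16-candidate sets,
consensus ranking at least on par with single-spectrum ranking) — they do
not demonstrate generalization to real spectra, real fragmentation
rearrangements, isotope patterns, or multiply charged ions, all of which
are explicit non-goals.

## Experiment sizes

The end-to-end experiment in `specmol.experiments` uses 50 molecules × 3
spectra, embedding dimension 64, 200 epochs at batch 32, 16-candidate
held-in sets — a size chosen so the complete pipeline (generation,
annotation, training, retrieval) runs in well under a minute on one CPU
while leaving a clear margin between learned performance (≈85–95% rank@1)
and chance (6.25%).

## Known limitations

- Query annotation requires a parent formula (ground truth in evaluation;
  an upstream assignment such as a formula-identification tool in
  production). Peaks are labeled without the adduct and assumed to carry it.
- The exact MCES is limited to small molecules by design.
- The autodiff engine implements exactly the operation set the encoders
  need; it is not a general-purpose framework.
- By-formula candidate sets on random synthetic libraries are often tiny
  (few isomers exist in a small library), so by-mass sets are the
  meaningful desk-scale retrieval benchmark.
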