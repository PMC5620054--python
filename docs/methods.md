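# Methods

## Scope and data model

The package reimplements a comparative membrane-proteome analysis as a
deterministic pipeline over four input tables plus per-species FASTA:
tabular BLAST hits (outfmt-6), Pfam-scan-style annotations, per-protein
topology/signal-peptide predictions, and a human-proxy functional table
(EC number, transporter-classification identifier, curated
receptor/other call). Sequence-level predictors (SignalP, TOPCONS-like
consensus topology, HMMER/pfam_scan, BLAST itself) are upstream tools
whose *outputs* are inputs here; the pipeline never reads residues
except through sequence lengths. The original study's manual curation is
replaced by machine-readable rules applied to these tables, which is
what makes the analysis reproducible.

## Proteome preparation

Isoforms collapse to the longest sequence per gene; equal lengths break
to the lexicographically smallest protein id so the result is
order-independent (the tie rule is this package's choice — any
deterministic rule would do). Signal peptides are excised by
bookkeeping: mature length = length − cut site, with the cut site as the
1-based last residue of the peptide (SignalP convention). A protein is
*membrane* iff its topology row reports ≥ 1 transmembrane helix;
excision precedes the membrane call, matching the order in which the
upstream predictors are normally run. Proteins with no topology row are
excluded and reported, never silently counted.

## Similarity network and MCL

Hits are thresholded at e ≤ 0.01; self-hits are dropped. Edge weight is
min(−log₁₀ e, 200); e = 0 maps to the cap, and a hit with e ≥ 1 (possible
only if the threshold is relaxed) clamps to a small positive floor
(10⁻³) because MCL requires positive weights. Duplicate directions and
HSPs resolve to the maximum weight, i.e. the best e-value — the standard
best-hit reading of network loading.

The Markov Cluster algorithm is implemented in-package against the
reference tool's contract: self-loops per node at the maximum incident
weight (1 for isolated nodes), column normalisation, then iterated
expansion (matrix squaring), inflation (entrywise power I, column
renormalisation) and pruning (entries < 10⁻⁶ zeroed, columns
renormalised), stopping when per-column chaos (max entry − Σ entries²)
falls below 10⁻⁸ or after 200 iterations (non-convergence is logged and
the current structure interpreted). Clusters are read off the converged
matrix through attractors (nonzero diagonal); attractor systems that
flow into each other merge, and a node reachable from several systems is
assigned to the smallest cluster id. The input graph is split into
connected components first — expansion cannot mix components, so
per-component dense iteration is exact and keeps the dense
representation affordable at the scales used here (thousands of nodes in
the largest component). Pruning/convergence constants are exposed in the
parameters; the published analysis relied on the reference binary's
internal defaults, so acceptance is scored on planted-structure
recovery, not byte-identity with that binary.

Inflation defaults are 1.6 (level 1) and 1.8 (level 2), the published
settings.

## Level-2 network

Only level-1 clusters with at least one Pfam annotation (any model type)
or one functionally annotated member participate. Edges connect clusters
sharing a *Family*-type Pfam model — Domain/Repeat/Motif models are
excluded to avoid clustering on promiscuous domains — weighted by the
larger of the two member fractions for that model; fractions count a
protein once per accession regardless of domain copies, with the
post-isoform-filter cluster size as denominator. Weights below 0.5 are
dropped (`≥`, matching the reference transform's greater-or-equal
semantics). When two clusters share several models, the single edge
takes the maximum weight — the least destructive reading of
"highest fraction"; the per-pair rule is applied exactly as stated, with
no chaining through distinct models. Non-participating clusters pass
through as their own units (ids prefixed `PT_`) so every membrane
protein remains traceable to exactly one level-2 unit.

## Classification

Per-protein precedence: EC → enzyme (subclass = first two EC fields,
e.g. "EC 2.4"), else TCDB → transporter, else curated receptor/other,
else DUF-only Pfam → other with a DUF flag, else no_description. A
protein carrying both EC and TCDB classifies as enzyme with the conflict
logged. Level-1 consensus: strict majority (> 50%) among classified
human-proxy members; an unresolved tie is *ambiguous*; with no
classified proxy member the cluster takes the class mapped to its
best-represented Family model (highest member fraction, smallest
accession on ties) from the shipped Pfam→class table, else
no_description. The strict-majority rule and the tie handling are this
package's declared rules — the original curation did not state one.
Level-2: unanimity wins; a majority wins with the minority logged; no
consensus sets the varied-Pfam flag and the unit is ambiguous.
Species-specific singlet clusters that still carry annotation are
flagged "annotated singlet"; bare singlets are no_description.

## Comparative quantities

From the level-2 × species count matrix (exactly two outgroup columns
enforced): the LHCA subset requires ≥ 1 protein summed over the two
outgroups **and** ≥ 1 metazoan species with a member; the ancestral size
per cluster is ⌈(c₁ + c₂)/2⌉ over the two outgroup counts, with the zero
of a non-possessing outgroup *included* in the average (so (0, 2) → 1) —
excluding zeros would systematically inflate the reconstruction; a
configuration switch provides the exclusive variant. Metazoan innovation
requires zero outgroup members and ≥ 2 metazoan species; clusters
confined to one species are species-specific (this takes precedence over
metazoan innovation, so the four categories — LHCA, metazoan innovation,
species-specific, other — partition the clusters). Heatmap matrices are
row z-scores with sample standard deviation (n − 1); zero-variance rows
are zeroed and flagged rather than dropped.

Integer percentages round half away from zero, one convention used
everywhere. Spearman ρ uses average ranks for ties (scipy's
implementation; the test suite cross-checks it against a brute-force
rank-then-Pearson oracle) and refuses fewer than three species. Two
cells of the published per-species table are internally inconsistent
with their own printed counts under any standard rounding; the package
reports its own consistent arithmetic throughout.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth. Defaults define the study conditions: 24
species (2 unicellular outgroups, 5 vertebrates of which one is the
human proxy, 17 invertebrates) and 60 planted families — 40
LHCA-conserved, 15 metazoan-novel, 5 species-specific. Per present
species, copy numbers are Poisson with a clade-multiplied mean
(base 1.8; multipliers 1.0 outgroup, 1.2 invertebrate, 2.0 vertebrate),
truncated to ≥ 1 — the simplest law producing clade expansion contrasts.
Presence probabilities are 0.9 per outgroup and 0.95 per metazoan for
conserved families (pattern minima enforced) and 0.6 per metazoan for
novel families (≥ 2 enforced). Genes carry 1–3 isoforms
(P = 0.6/0.3/0.1), the canonical isoform strictly longest. Within-family
e-values are log-uniform on [10⁻¹⁸⁰, 10⁻²⁰] — strictly below the 0.01
threshold, since only the threshold and the −log₁₀ transform matter
downstream; spurious cross-family hits occur at rate 2 × 10⁻⁵ per
ordered cross-family pair with e-values log-uniform on [10⁻⁴, 10¹], an
interval that straddles the threshold so some noise edges survive
filtering with low weight. Families receive one Pfam model (typed
"Domain" with probability 0.2, exercising the family-type-only rule),
annotated per protein at rate 0.9; class-less families carry no model at
all. Functional classes are drawn per family (enzyme 0.20, transporter
0.20, receptor 0.25, other 0.20, DUF 0.08, none 0.07). The membrane
fraction defaults to 1.0 so that every planted ancestral family is
recoverable from the membrane proteome; soluble families are exercised
in unit tests at lower fractions. All unstated distributions are
stand-ins chosen once and exposed in the configuration.

What the generator does *not* emulate: realistic residues or
evolutionary divergence along a tree, HMMER bit scores, partial-domain
hits, genuinely overlapping families sharing promiscuous domains, or
annotation biases between clades. Passing recovery tests therefore shows
the pipeline's logic is correct under the assumed noise model, not that
real proteomes would cluster this cleanly.

## Numerical and degenerate-input conventions

E-value 0 is accepted verbatim at parse time and capped at the
transform. Empty FASTA or hit files yield empty collections with a
warning. Cluster ids are assigned by smallest member, making every stage
independent of input enumeration order; reruns on identical inputs are
bit-identical (checked via manifest checksums). Dense per-component MCL
is the declared implementation; sparsity would be an optimisation, not a
contract change.

## Problem sizes

The default synthetic bundle (≈ 2 800 proteins, ≈ 190 000 hit rows) runs
end-to-end in well under a minute; unit and property tests use 6-species
bundles and small planted graphs. These sizes were chosen as the
smallest at which every presence pattern, clade contrast and noise path
is exercised with comfortable margins.

## Known limitations

The pipeline consumes predictions, so systematic upstream errors
(missed TM segments, wrong gene models) propagate untested. The LHCA
reconstruction ignores loss in both outgroups by construction — a family
lost from both unicellular lineages is invisible, so the ancestral
proteome is a lower bound. The Pfam→class fallback can only be as good
as the shipped mapping; clusters with Domain-only models and no proxy
member remain unclassified by design. MCL output for graphs with
near-tied attractors can depend on the pruning threshold; the defaults
are exposed for sensitivity analysis.
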