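# Methods

This note documents the models and procedures implemented in `psncomm`, the
parameters that matter, the synthetic ground truth used for validation, and
the numerical and design choices made where the underlying protocol is open
to interpretation.

## Protein structure network

**Contact counting.** For residues *i* and *j*, `count_atom_pairs` counts
the distinct atom pairs (*a* ∈ *i*, *b* ∈ *j*) with ‖a − b‖ ≤ 0.45 nm per
frame, over the *side-chain-heavy* selection: all non-hydrogen atoms outside
the backbone set {N, CA, C, O, OXT}. Glycine, which has no side-chain heavy
atom, is represented by its Cα so that it can still act as a network node;
both the selection policy and the glycine fallback are configurable.
Hydrogens are retained in the ensemble but flagged and excluded from
counting, since published normalization tables are heavy-atom based. Pairs
of sequence neighbours (|i − j| < 2) are excluded at the counting stage —
edges are meant to capture non-covalent interactions — and the exclusion
width is configurable. Each atom pair counts once; an atom may participate
in several pairs.

**Interaction strength.** `I_ij = 100 · n_ij / sqrt(N_i · N_j)`, with
residue-type normalization values *N*. The factor 100 puts *I* on the
percent scale of the PSN literature, where the largest-cluster transition is
scanned over [0, 40]; it can be turned off. When no literature table is
supplied, `self_normalization` derives *N* per residue type as the maximum
(over residues of that type) of the total mean contacts made, floored at 1.
Note that on sparse synthetic networks self-normalization puts the few
planted edges at *I* ≈ 50 — above the standard scan range — so validation
constructions pass an explicit uniform table on the scale of real protein
connectivities (*N* ≈ 16–64) instead.

**Edges, clusters, hubs, orphans.** An edge exists where *I*<sub>ij</sub> is
*strictly* greater than *I*<sub>min</sub>. Clusters are the connected
components of the graph restricted to nodes with at least one edge; orphans
are zero-degree nodes; hubs are nodes with degree ≥ 4 by default. The hub
threshold is deliberately configurable because the field uses "more than
three" and "more than four" interchangeably.

**I_min scan and I_crit.** The scan evaluates the largest-cluster size on
the grid 0, 0.2, …, 40. The largest-cluster size of an edgeless graph is
defined as 0 (not 1) so that the profile terminates at zero; this affects
only the tail of the profile. `detect_icrit` operationalizes the "main
transition" as the largest single-step drop and reports the grid value just
after it, with ties broken toward the smaller *I*<sub>min</sub> and the drop
magnitude returned so callers can judge significance. A 3-point smoothed
variant is available behind `method="smoothed"` for profiles where the
transition is spread over neighbouring grid points. A perfectly flat profile
raises; the pipeline then falls back to *I*<sub>min</sub> = 0 unless the
config pins `i_min` explicitly. For production-style analyses the
recommended usage mirrors the published protocol: inspect the scan, then
pin a common `i_min` across the runs being compared.

**Consensus and windows.** The consensus network keeps edges whose
persistence — the fraction of frames with *I*<sub>ij</sub> > *I*<sub>min</sub> —
is at least 0.5 (inclusive). Per-window consensus networks over
non-overlapping blocks of `frames_per_window` frames are the denominator of
path occurrence probabilities.

## Linear mutual information

Per window, frames are least-squares superposed (Kabsch, three iterations)
onto the iterated window-mean Cα structure, the per-residue 3-D displacement
covariance blocks are assembled, and the Gaussian mutual information
`MI = ½(ln det C_i + ln det C_j − ln det C_ij)` is mapped to the generalized
correlation coefficient `r = sqrt(1 − exp(−2·MI/3))`. For isotropic
equal-variance motions with per-axis correlation ρ this equals |ρ| exactly,
which is the closed form the synthetic validation relies on. Numerical
choices: 10⁻⁸ nm² is added to covariance diagonals before the determinants
(rigid planted blocks would otherwise be singular; a warning is logged if a
determinant is still non-positive); small negative MI values from round-off
are clipped to 0; the diagonal of *r* is set to 1 by definition. The window
average is the element-wise mean over windows; trailing frames not filling a
window are dropped. Windows are counted in frames because synthetic frames
carry no physical timestep; `frames_per_window` is the stand-in for a
fixed-time window (e.g. five ns) and defaults to 100.

The superposition fit removes six rigid-body degrees of freedom and
therefore induces an O(1/n_res) downward bias in recovered correlations
(and a matching spurious baseline at ρ = 0). At a realistic domain size of
100 residues the bias is below 0.02 and the validation tolerances (±0.05)
hold with margin; at 20 residues it would not. Validation ensembles are
sized accordingly.

The significance cutoff (default 0.5) is applied *inclusively* — a value of
exactly 0.5 counts as significant — and the same convention is used by the
path correlation filter.

**Frobenius comparison.** `F = sqrt(Σ_ij (a_ij − b_ij)²)` over all matrix
elements, reported together with the maximum absolute element difference
and quantiles of |a − b|. `replicate_consistency` declares a set of
replicate matrices consistent when every pairwise norm is smaller than every
replicate-to-control norm; when per-window matrices are supplied it also
reports the within-trajectory baseline (first-half vs second-half window
averages).

## Communication paths

Distances are hop counts (every edge has length 1), computed by
Floyd–Warshall. Path reconstruction returns, per pair, the canonical
**lexicographically smallest** shortest node sequence — a deterministic
representative among co-shortest paths; full enumeration is available but
bounded at 10⁴ paths per pair. The correlation filter retains a path iff at
least one *intermediate* node has r ≥ 0.5 with the first or last residue.
Direct edges (no intermediates) can never satisfy the literal rule; they are
short-range by construction, excluded from path analysis and reported
separately.

`paths_to_targets` computes, for every non-target residue, the canonical
shortest path to each target residue, de-duplicates to one path per
(source, target-set) pair — shortest first, then highest occurrence, then
lexicographic — and applies the filter cascade (correlation, occurrence
≥ 0.15, node count > 3), logging the number of paths rejected by each rule.
Occurrence is the fraction of per-window consensus networks containing all
of the path's edges; windows were chosen as the denominator (rather than
frames or replicates) because they match the correlation windowing, and a
per-replicate mode is available by passing one consensus network per
replicate. Path "length greater than three" is counted in nodes (≥ 4),
consistent with the long-range convention of "≥ 8 residues including both
ends".

The meta-graph joins the retained paths; each edge carries the fraction of
retained paths containing that connection. Mediator ranking uses
**interior** participation counts (endpoints excluded): every retained path
terminates at a target, so endpoint counts carry no information about
mediation. Ties break toward the smaller residue index.

## Synthetic ground truth

`make_reference_polymer` places one backbone carbon per residue on a gentle
helix with 1.2 nm spacing and 1–5 pseudo-side-chain heavy atoms radially
outward (glycine none), clash-free by construction. The spacing is
deliberately larger than a real Cα–Cα distance so that non-adjacent residues
have *no* background contacts at 0.45 nm: the planted chain is the only
contact signal, and recovered networks can be compared to the planted truth
edge-for-edge.

`sample_gaussian_ensemble` displaces residues rigidly per frame from a
block-equicorrelation multivariate normal (per-axis correlation ρ within a
block, independence across blocks, axes independent, common baseline
variance 0.0025 nm² — an RMSF scale of 0.5 Å typical of a folded domain
core). Rigid-residue displacement means no internal side-chain noise, so
planted contact geometry survives sampling.

`plant_contact_chain` adds `min_atom_pairs` extra pseudo-side-chain atoms
per chain edge, positioned per frame: clustered within 0.45 nm of the
partner's side-chain anchor in exactly ⌈persistence · n_frames⌉ frames
(selected by the chain's own RNG seed), parked 0.9 nm radially outward
otherwise (> 0.6 nm from the partner). Because planted atoms are *added*
rather than moved, pre-existing atoms are bit-identical and contact counts
of all pairs outside the chain are provably unchanged. The same contact
frame set is used for all edges of one chain, so a chain is present or
absent as a unit — matching the notion of a coherent communication route.

What the generator does **not** emulate: real side-chain packing and
rotamer dynamics, anisotropic and non-Gaussian fluctuations, correlated
rigid-body domain motions, solvent effects, and contact networks with
realistic density (a real domain has hundreds of edges; synthetic networks
have exactly the planted ones). Passing tests therefore demonstrate that the
estimators and the path machinery are *correct* with respect to their
definitions, not that the definitions are optimal for any particular real
protein.

## Validation problem sizes

Exhaustive graph-oracle checks cover all 1024 labelled graphs on five nodes
plus 200 seeded random graphs up to 50 nodes; correlation recovery uses a
100-residue ensemble at 5000 frames; replicate consistency uses three
600-frame replicates of a 30-residue system; the end-to-end path recovery
uses a 24-residue, 100-frame ensemble with two planted chains. These sizes
were chosen so each property is measured well inside its tolerance while the
whole suite stays interactive.

## Known limitations

* The PDB reader maps residues by sorted author numbering; exotic files with
  decreasing residue ids or insertion codes are not supported.
* Non-protein chains (DNA, solvent) are dropped with a warning; whether
  nucleic-acid atoms should contribute to contact counts in bound-state
  networks is an open interpretation question, and excluding them is this
  package's recorded choice.
* `detect_icrit` on networks whose edges all share one strength places the
  transition exactly where those edges vanish; using that value as
  `i_min` empties the network. Real ensembles have a continuum of strengths
  and do not hit this degeneracy, but synthetic single-level constructions
  must pin `i_min` explicitly.
* Only degree-based node statistics are provided (hubs); no betweenness or
  other centralities.
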