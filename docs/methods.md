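# Methods

## Model

Contact dynamics at the interface are modeled as a joint distribution over
binary variables, one per contact node (receptor residue × G-protein
residue pair). A Bayesian network — a DAG whose edges mark direct,
non-transitive dependencies — is selected by search-and-score. The score is
the Dirichlet-multinomial (BDeu) log marginal likelihood: for a binary node
X with parent set Pa (q = 2^|Pa| parent configurations, counts N_jk,
hyperparameters α_jk = ess/(2q), α_j = ess/q),

    score(X | Pa) = Σ_j [ lnΓ(α_j) − lnΓ(α_j + N_j) ]
                  + Σ_jk [ lnΓ(α_jk + N_jk) − lnΓ(α_jk) ].

The score is decomposable (total score = sum over node families) and
score-equivalent (Markov-equivalent DAGs tie), so learned edge directions
within an equivalence class are not interpreted. The scoring function is
pluggable behind `FamilyScoreCache`; BDeu was chosen because its family
score differences are exactly the "marginal likelihood with vs without the
edge" ratio that defines edge strength, and dividing by the frame count
puts all scores and strengths on a per-observation (nats/observation)
scale comparable across data sets of different length.

Frames are treated as independent samples. MD frames are autocorrelated,
so absolute scores on real trajectories overstate the effective evidence;
rankings and comparisons, which is what the pipeline reports, are less
affected. Block bootstrap is available in the sensitivity test for users
who want to respect autocorrelation.

## Search

Greedy hill climbing over single-edge add / delete / reverse moves,
acyclicity checked per move, with restarts: restart 0 from the empty graph,
restarts 1..R−1 from random DAGs (uniform order, forward-edge probability
2/(n−1), parents truncated to the cap). Equal-scoring moves resolve by
scan order, making the search deterministic given (data, seed, restarts,
ess, max_parents). Family scores are memoized across restarts. Constant
columns carry no dependency information under any score and are excluded
from move generation: they stay isolated and are flagged in the learn
metadata rather than dropped.

Defaults: 50 restarts, ess = 1.0, max_parents = 5 (tractability cap; the
contingency table grows as 2^parents). On ≤ 5 nodes an exhaustive
enumeration over all labeled DAGs (29,281 at n = 5) provides the global
optimum; the restarted search is tested to attain it.

## Contact fingerprinting

Five interaction types with the standard fingerprinting cutoffs: salt
bridge (anion–cation < 4.0 Å), hydrogen bond (donor–acceptor < 3.5 Å,
deviation from linearity < 70°), van der Waals, π-stack (centroid < 7.0 Å,
ring-normal angle < 30°), cation–π (cation–centroid < 6.0 Å, normal angle
< 60°). Decisions taken where conventions vary:

* **vdW criterion** — default: heavy-atom distance < r_i + r_j + 0.5 Å
  with Bondi radii; a literal inter-atom-gap mode (`vdw_mode="gap"`,
  gap < 2 Å) is selectable. Both the radius table and tolerance are config.
* **Hydrogens** — crystal/cryo-EM structures usually lack them. Donor
  direction is then idealized as pointing from the mean of the donor's
  bonded heavy neighbours through the donor; with explicit hydrogens the
  real D–H vectors are used. This affects static-structure contact counts
  and is therefore config-visible.
* **Atom typing** — anions Asp OD1/2, Glu OE1/2; cations Lys NZ,
  Arg NE/NH1/NH2; donors/acceptors per standard side-chain chemistry plus
  backbone N/O; aromatic rings Phe/Tyr/Trp(6-ring)/His. Exposed as module
  tables, editable without code changes elsewhere.

A contact node is *present* in a frame if any criterion fires; per-type
records are kept only to classify nodes polar (salt bridge, hydrogen bond,
cation–π dominant) vs non-polar, ties broken salt_bridge > hydrogen_bond >
cation_pi > pi_stack > vdw. Persistence filtering is strictly greater than
the threshold (default 0.20).

## Cooperativity and regions

Node strength = Σ incident edge strengths (direction ignored). Top-quartile
selection uses ceil(q·N) with label tie-breaks, so N < 4 still flags one
node. Region aggregation normalizes each G-protein region's row by that
region's number of *cooperative* (top-quartile) interactions, so the polar
and non-polar heatmaps of one complex share a denominator and sum to 1 per
region; an alternative normalization by all interactions of the region is
also emitted (`fraction_of_region_total`). The α5-tip boundary is data,
not code: region tables ship with the "last 10 residues" preset, and a
"last 11 residues" variant is a one-line table edit, because published
usage varies. Conservation flags are user data (from a subtype alignment);
the tool computes no alignments. Both Pearson and Spearman correlations
against ΔlogEC50 are reported.

## Cross-complex comparison

Moralization follows the textbook 3-step rule (identify parents; marry
unconnected co-parents; drop directions); moral graphs are unweighted. The
largest common subnetwork keeps edges whose label pair recurs in
≥ min_support moralized graphs and returns the largest connected component
(edge count, then node count, then smallest label) — connectivity is a
design choice; the support filter alone can leave scattered fragments.
Joint probabilities over the subnetwork's nodes are *full empirical
joints* (the graph contributes only the node set), guarded by a 2^20-state
cap. JSD uses natural log (bounded by ln 2 ≈ 0.693) with a default
pseudocount of 0.5 per state for stability when supports differ;
pseudocount 0 gives the unsmoothed empirical version. Anyone comparing
absolute JSD values across implementations must match both choices.

## Allostery and robustness

The distance between two contact nodes (four residues) is not uniquely
defined; the default is the minimum Cα–Cα distance over the four
cross-pairs, excluding shared residues — the most permissive "neighboring"
reading — with mean and centroid modes available. Exactly 10.0 Å classes
as neighboring ("within").

Perturbation test: per trial, 2 random add-or-remove edge moves (illegal
draws resampled, acyclicity preserved), rescored on the same data; the
report gives the fraction of trials scoring strictly below the original.
Sensitivity test: frames resampled with replacement to the original count,
fixed topology rescored per observation, empirical two-sided quantile
interval at CI 0.99. Both are bit-reproducible given seed.

## Synthetic data

The generator emulates the *statistical* shape of MD-derived fingerprints:
binary frame × contact matrices from a planted DAG with noisy-OR
conditionals (per-parent flip 0.1, roots at 0.5) — identifiable at a few
thousand frames without being deterministic — plus a hub contact with four
strong children whose planted degree is kept strictly maximal by
construction. Surrounding context (generic-id labels, round-robin region
assignments, 6 Å lattice Cα coordinates with the two chains 3.5 Å apart,
alternating conservation flags) exercises every interface of the pipeline.

It does **not** emulate frame autocorrelation, force-field realism, the
empirical frequency spectrum of real contacts, or real interface geometry
(coordinates are abstract lattice points). Passing tests therefore
demonstrate correctness of the inference machinery under known ground
truth — not that MD trajectories satisfy the independence assumptions.

Default study conditions used in tests and the acceptance script: 20
nodes × 5000 frames × 50 restarts (≈ 7 s per learn), robustness at 1000
trials, exhaustive oracles at ≤ 5 nodes. These sizes were chosen as the
smallest at which the planted structure is comfortably identifiable.

## Static-structure benchmark

The contact-detection path supports the six benchmark complexes (3SN6,
6GDG, 6D9H, 6G79, 7DFL, 7F6G; pairing per the structure-preparation
convention 6D9H = A1R:Gi2, 6GDG = A2AR:mini-Gs). Reproducing pooled
per-subtype contact counts requires downloading those entries
(`scripts/fetch_benchmarks.py`) and supplying BW/CGN mapping tables; both
are user-provided inputs, so the counts are not part of the offline test
suite. Counts are sensitive to atom-typing and numbering-table choices;
the per-criterion record output (`coopnet contacts`) is designed to make
discrepancies diagnosable contact-by-contact.

## Known limitations

* Frame independence assumed when scoring (see above).
* BDeu with small ess can, at very small n, favor attaching parents to
  near-constant columns; truly constant columns are excluded, and the
  study-condition sample sizes make this a non-issue in practice.
* Edge directions are not causal claims; only the skeleton and strengths
  are interpreted.
* No water-mediated or intra-chain contacts; unresolved loop stretches
  (e.g. ICL3) are simply absent from the analysis.
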