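# coopnet

Cooperative residue-contact networks at protein–protein interfaces.

## The problem

A protein–protein interface — the motivating case is a G-protein-coupled
receptor (GPCR) bound to its Gα subunit — is held together by dozens of
pairwise residue contacts that form and break as the complex moves. Static
structures list which contacts exist; they do not say which contacts are
*cooperative*, i.e. whose formation is statistically coupled to the
formation of others across the interface. Cooperative contacts are
candidate hotspots for coupling strength and G-protein selectivity.

`coopnet` infers that cooperativity from per-frame contact data. Each
*contact node* is one receptor-residue × G-protein-residue interaction,
named by generic numbering (Ballesteros–Weinstein on the receptor,
Common G-protein Numbering on Gα, e.g. `7×55_G.H5.24`) so the same physical
contact compares equal across complexes, and treated as a binary random
variable per trajectory frame.

## The method

1. **Fingerprinting** — contacts are detected per frame from heavy-atom
   geometry (salt bridge < 4.0 Å, hydrogen bond < 3.5 Å and < 70° off
   linear, van der Waals within Bondi-radius sum + 0.5 Å, π-stack < 7.0 Å
   and < 30°, cation–π < 6.0 Å and < 60°), filtered to persistent contacts
   (present in > 20 % of frames), and one-hot encoded into a frames ×
   contacts binary matrix **X**.
2. **Network learning** — a discrete Bayesian network over the contact
   variables is selected by hill climbing with 50 random restarts,
   maximizing the decomposable Dirichlet-multinomial marginal likelihood
   (BDeu, equivalent sample size 1). Each edge u→v carries a strength

   `s(u→v) = [ log P(x_v | Pa_v) − log P(x_v | Pa_v \ {u}) ] / N`

   — the per-observation log marginal-likelihood ratio of the network with
   the edge versus without it.
3. **Cooperativity** — the node strength (cooperativity) of a contact is
   the sum of its incident edge strengths; the top quartile is aggregated
   by structural region (TM1–7, H8, ICL1–3 × N-term, core segments,
   α5-core, α5-tip) and, restricted to unconserved G-protein residues,
   yields per-region selectivity scores comparable to experimental
   ΔlogEC50 coupling changes of chimeric G proteins.
4. **Comparison** — networks are moralized (co-parents married, directions
   dropped); edges recurring in ≥ k complexes form the largest common
   subnetwork G\*; complexes are compared by the Jensen–Shannon divergence
   (natural log, ≤ ln 2) of the empirical joint distributions of G\*'s
   nodes.
5. **Robustness & allostery** — 1000 random 2-move topology perturbations
   and 1000 frame bootstrap rescorings probe stability; edges are classed
   *neighboring* (≤ 10 Å minimum Cα–Cα cross-distance between the two
   contacts' residues) or *allosteric* (> 10 Å).

## Worked example

Real MD-derived fingerprints are large; the built-in generator plants a
known dependency structure (including a high-degree hub contact) so every
claim is checkable:

```python
import coopnet as cn

bundle = cn.make_interface_fixture(n_nodes=20, n_frames=5000, seed=1)
net = cn.learn_structure(bundle.fingerprints, restarts=50, seed=1)
print(f"learned {len(net.edges)} edges over {len(net.nodes)} contact nodes, "
      f"score {net.total_score:.1f}")

table = cn.rank_top_quartile(cn.node_strengths(net))
print("top 3 cooperative contacts:")
for text, row in table.head(3).iterrows():
    print(f"  {row['rank']}. {text}  node strength {row['node_strength']:.4f}")

rep = cn.classify_edges(net, bundle.ca_coords)
print("edge classes:", rep.counts())

pert = cn.perturbation_test(net, bundle.fingerprints, n=1000, seed=1)
print(f"perturbation test: {pert.fraction_below_original:.1%} of 1000 "
      "perturbed topologies score below the learned one")
```

prints

```
learned 12 edges over 20 contact nodes, score -50880.6
top 3 cooperative contacts:
  1. 1×50_G.H5.01  node strength 1.4708
  2. 1×57_G.H5.02  node strength 0.7150
  3. 2×51_G.H5.04  node strength 0.7032
edge classes: {'neighboring': 7, 'allosteric': 5}
perturbation test: 99.8% of 1000 perturbed topologies score below the learned one
```

`1×50_G.H5.01` is the planted hub: it tops the cooperativity ranking, its
node strength (≈ 1.47 nats/observation ≈ 4 × the ≈ 0.37-nat mutual
information of one 0.1-flip dependency) reflects its four strong edges, and
the learned topology outscores essentially all local perturbations.

The same stages are available as a CLI (`coopnet simulate | contacts |
fingerprint | learn | cooperativity | compare | robustness`); every verb
takes a YAML config and an explicit `--seed`, and networks export to
GraphML/SIF for Cytoscape.

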