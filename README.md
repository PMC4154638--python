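# psncomm

Ensemble-based analysis of long-range intramolecular communication in
proteins: **p**rotein **s**tructure **n**etworks + correlated motions →
**comm**unication paths.

## The problem

Allosteric effects — a mutation or a binding event at one site changing the
behaviour of a distant site — are carried by chains of side-chain contacts
between residues whose motions are correlated. Given a conformational
ensemble of a protein (an MD trajectory or any multi-model PDB), `psncomm`
answers: *which residues talk to a target region (say, a DNA-binding loop),
along which routes, and which residues mediate those routes?*

## The method

1. **Protein structure network (PSN).** For every residue pair *i, j*, count
   the distinct side-chain heavy-atom pairs within 0.45 nm in each frame and
   normalize by residue-type values *N*:

   *I*<sub>ij</sub> = 100 · *n*<sub>ij</sub> / √(*N*<sub>i</sub>·*N*<sub>j</sub>)

   Residues are nodes; an edge exists where *I*<sub>ij</sub> > *I*<sub>min</sub>.
   Scanning *I*<sub>min</sub> from 0 to 40 (step 0.2) and tracking the size
   of the largest connected cluster locates the critical cutoff
   *I*<sub>crit</sub> at the main transition. A **consensus network** keeps
   only edges present in at least half of the frames.

2. **Correlated motions (LMI).** Linear mutual information between the 3-D
   Cα displacement vectors of residue pairs, computed over non-overlapping
   frame windows after least-squares superposition, mapped to a generalized
   correlation coefficient *r* = √(1 − e<sup>−2·MI/3</sup>) ∈ [0, 1] that is
   invariant to the relative orientation of the fluctuations. Replicate
   matrices are compared by the Frobenius norm of their difference.

3. **Communication paths.** Floyd–Warshall shortest paths (unit edge
   distance) on the consensus network, retained only when an intermediate
   node is significantly correlated (*r* ≥ 0.5) with one of the two
   end-residues, with occurrence probability ≥ 15% across windows and more
   than three nodes. Long-range paths (≥ 8 nodes) are compared across
   conditions (e.g. free vs DNA-bound), and all retained paths are joined
   into an occurrence-weighted **meta-graph** whose interior-participation
   counts rank mediator residues.

Because public trajectories are rarely available for such studies, the
package ships a first-class synthetic-ensemble generator with *known* ground
truth — planted Gaussian correlation blocks and planted persistent contact
chains — against which every stage is validated.

## Worked example

```python
import psncomm as pc

# synthetic ensemble: 24 residues, 100 frames, a correlated block {16, 20}
# and two persistent contact chains converging on residue 12
ref = pc.make_reference_polymer(24, seed=11, sequence=["ALA"] * 24,
                                frames_per_window=25)
spec = pc.CovarianceSpec(n_residues=24, blocks=[(frozenset({16, 20}), 0.8)])
ens = pc.sample_gaussian_ensemble(ref, spec, 100, seed=11)
ens = pc.plant_contact_chain(ens, pc.PlantedChain((4, 8, 12, 16, 20),
                                                  persistence=0.9, rng_seed=12))
ens = pc.plant_contact_chain(ens, pc.PlantedChain((2, 6, 12),
                                                  persistence=0.9, rng_seed=13))

cfg = pc.AnalysisConfig(normalization={"ALA": 40.0}, i_min=7.0)
results = pc.CommunicationModel(ens, targets=[20], config=cfg).fit()
print(results.summary())
```

prints

```
Ensemble communication analysis
===============================================
frames: 100   residues: 24   atoms: 72
contact cutoff: 0.45 nm   selection: side-chain-heavy
I_min scan: 0.0..40.0 step 0.2
I_crit: 9.0 (largest-cluster drop 7)
I_min used: 7.0
consensus network: 6 edges, 1 clusters (largest 7), 17 orphans
hubs (degree >= 4): none
LMI: 4 windows of 25 frames; significant pairs (r >= 0.5): 3
paths to targets [20]: 4 retained (1 direct edges reported apart; rejected: {'unreachable': 17, 'node_count': 1, 'direct_edge': 1})
long-range (>= 8 nodes): 0 of 4
top mediator residues: [12, 16, 6, 8]
```

Reading the output: the planted chain edges all exceed the *I*<sub>min</sub>
cutoff of 7 (their mean strength is 100·3.6/40 = 9, which is exactly where
the scan detects the cluster transition); the 7-residue largest cluster is
the union of the two planted chains; the four retained paths are the routes
from residues 2, 4, 6 and 8 into the target; and residue 12 — the node the
two planted chains share — is correctly ranked as the top mediator.
`results.save("run_dir")` writes the matrices (CSV/`.dat`), networks
(GML/DOT), path lists (JSON) and a manifest; `results.compare(other)`
reports hub-degree deltas, path-set differences and the LMI Frobenius norm
between two conditions.

The same pipeline is scriptable from the shell:

```bash
psncomm generate --n-residues 24 --n-frames 100 --seed 11 \
        --chain 4,8,12,16,20:0.9 --out synthetic.pdb
psncomm run config.yaml
psncomm compare run_free/ run_bound/
```

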