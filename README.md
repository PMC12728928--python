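# tmca — transmembrane complex analysis

Analysis toolkit for molecular-dynamics trajectories of small membrane
helix bundles — specifically a receptor transmembrane helix bound to a
signaling-adaptor dimer (a TREM2–DAP12-like trimeric complex). It answers
the questions a simulator asks of such systems: which residue pairs hold
the interface together and how persistently, what kind of interactions
they form, how the helices move and tilt in the membrane, and what
discrete conformational states the complex samples.

## What it computes

**Contact persistence.** A residue pair is in contact in a frame when any
heavy-atom pair sits within 3.0 Å (minimum-image). Averaging the binary
contact matrix over frames gives a contact-frequency map; pairs held for
more than 60 % of the trajectory are classed *interacting*, more than 90 %
*important* (with 70 %/80 % intermediate tiers). Comparisons are strict, so
a pair at exactly 60 % falls below the tier.

**Geometric interaction typing**, per frame:

| type | criterion |
|---|---|
| hydrogen bond | donor–acceptor ≤ 3.0 Å and ∠D–H–A ≥ 150° |
| π–π stacking | ring-centroid distance ≤ 6.5 Å; interplanar angle ≤ 30° → parallel-displaced, 60–120° → T-shaped |
| hydrophobic | any side-chain C···C ≤ 4.5 Å (backbone N, Cα, C, O excluded) |
| salt bridge | min N···O ≤ 3.2 Å over Lys NZ / Arg NH1,NH2,NE / protonated His ND1,NE2 / N-terminal N versus Asp OD1,OD2 / Glu OE1,OE2 / C-terminal O,OXT |

Occupancy is the fraction of frames satisfying the criterion. All four
classifiers require atom-resolved input and refuse coarse-grained
backbone-bead models with a clear resolution error.

**Flexibility and positioning.** Per-residue RMSF after Kabsch alignment,

&nbsp;&nbsp;&nbsp;&nbsp;RMSF_i = √( (1/T) Σ_t ‖ r_i(t) − ⟨r_i⟩ ‖² ),

computed on Cα (or BB) atoms; mass-weighted center-of-mass traces along
the membrane normal relative to the bilayer midplane; lateral (x–y) COM
separation between helix groups; helix tilt as the angle between the
helix principal axis and the membrane normal.

**Conformational states.** Frames are featurized as flattened inter-bead
distance matrices (backbone beads every 5 residues, receptor × each
adaptor chain independently, concatenated), embedded in 2D with UMAP and
clustered with HDBSCAN — giving per-frame state labels, populations,
label-vs-time series and a medoid representative frame per state.

**Synthetic ground truth.** `tmca.synthetic_data` generates ideal-helix
bundle trajectories with planted interaction geometries on deterministic
occupancy schedules, Markov-switched metastable states, Gaussian jitter
and a dissociation scenario — so every analysis stage can be validated
against known truth without MD data.

## Worked example

Dissociation scenario: a bound receptor helix decays irreversibly into a
laterally displaced, nearly horizontal pose (the truncation-mutant
signature), and the analyses recover the planted geometry:

```python
import numpy as np
from tmca import synthetic_data as sd, contacts as ct, geometry as ge, io_model as io

spec = sd.dissociation_scenario(n_frames=500, seed=7)
top, traj, truth = sd.simulate(spec)

receptor = io.select(top, "chain A")
adaptor  = io.select(top, "chain B or chain C")

sep, _ = ge.xy_com_separation(traj, top, receptor, adaptor)
tilt = ge.helix_tilt(traj, top, receptor)
cm = ct.contact_frequency(traj, top, receptor, adaptor, cutoff=3.0, mode="heavy")
tiers = ct.classify_persistence(cm)

dissociated = truth.state_labels == 1
print(f"frames dissociated: {dissociated.mean():.1%}")
print(f"mean lateral COM separation (dissociated): {sep[dissociated].mean():.2f} A")
print(f"mean receptor tilt (dissociated): {np.nanmean(tilt[dissociated]):.1f} deg")
print(f"residue pairs at the >60% 'interacting' tier: {len(tiers.pairs_at('interacting'))}")
```

```
frames dissociated: 96.6%
mean lateral COM separation (dissociated): 11.20 A
mean receptor tilt (dissociated): 80.1 deg
residue pairs at the >60% 'interacting' tier: 0
```

The planted 11.2 Å separation and 80° tilt are recovered, and the
inter-chain contact map is empty at the interacting tier — the dissociated
complex leaves no persistent interface.

## Command line

```
tmca synth --preset dissociation --frames 2000 --seed 7 --out synthetic/
tmca run-all config.yaml      # contacts -> interactions -> geometry -> cluster
```

`run-all` is driven by a YAML config (validated before any compute, with
defaults equal to the standard analysis parameters) and writes CSV/JSON
per stage plus a manifest recording every parameter and the package
version; a rerun with the same config reproduces the outputs
byte-for-byte.

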