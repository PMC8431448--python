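# molstack

Analysis tools for **small-molecule (metabolite) self-assembly and its
inhibition by chemical chaperones**. Metabolites such as adenine can form
amyloid-like fibrils; candidate inhibitors are screened in vitro with
Thioflavin-T (ThT) kinetics and studied in silico with molecular-dynamics
simulations of monomer solutions with and without inhibitor. `molstack`
implements the downstream analysis of both arms for structural
bioinformaticians and assay scientists:

* **Trajectory post-processing** — two molecules are *in contact* when
  their centre-of-mass (COM) distance under the periodic minimum image is
  below a cutoff (default 6.0 Å = 0.6 nm); *aggregates* are connected
  components of the contact graph; the *stacking angle* of a contact pair
  is the acute angle θ = arccos|n̂₁·n̂₂| ∈ [0°, 90°] between the
  least-squares ring-plane normals (θ ≈ 0° ⇒ ordered π-stacking).
  Independent replicas are concatenated into a *metatrajectory* after
  discarding all but the final portion of each run (e.g. 4 × 200 ns =
  800 ns analyzed).
* **Hydrogen-bond occupancy** — geometric D–H⋯A detection (donor–acceptor
  ≤ 3.5 Å, angle ≥ 120°, configurable) with per-acceptor-class occupancy:
  the fraction of analyzed configurations containing at least one bond of
  that class (e.g. to an inhibitor's sulfur-bound vs intra-ring oxygens).
* **Kinetics & potency** — logistic fits of sigmoidal aggregation curves
  (lag time t½ − 2/k) and the *relative concentration* potency statistic:
  inhibitor dose divided by percent inhibition of the endpoint signal
  (default 1000 min), in mM per 1% inhibition; lower = more potent.
  Negative inhibition flags aggregation accelerators.
* **SAR** — molecular weight from formulas (IUPAC standard atomic
  weights) and Spearman rank association of drug-likeness descriptors
  (HBA, HBD, logP, TPSA, …) with potency, with permutation p-values.
* **Synthetic data with exact ground truth** — a generator that emulates
  stacked ensembles with controllable angular noise, inhibitor-"hijacked"
  disordered complexes, planted hydrogen bonds, and dose-dependent
  inhibition assays, so the whole pipeline is testable end to end without
  any simulation or plate-reader data.

## Worked example

```python
from molstack import molecular_weight, angle_distribution, occupancy
from molstack.synthetic import TrajectoryGenConfig, generate_replica_set
from molstack.trajio import build_metatrajectory

molecular_weight("C2H6OS")          # DMSO
# 78.13

cfg = TrajectoryGenConfig(n_monomer=40, n_inhibitor=5, n_frames=50,
                          stack_angle_sigma=15.0, hijack_fraction=0.2,
                          hbond_plant_rate=0.06, seed=1)
replicas, truths = generate_replica_set(cfg, 4)
meta = build_metatrajectory(replicas, retain_tail=49.0)

dist = angle_distribution(meta)      # monomer–monomer stacking angles
# mean=15.7  dispersion=22.5  stacked_fraction=0.89   (5287 samples, 200 frames)

for cls, r in sorted(occupancy(meta).items()):
    print(cls, round(r.occupancy, 3))
# intra-ring-oxygen 0.045        <- planted at rate 0.06, recovered
# sulfur-bound-oxygen 1.0        <- every hijacked complex is H-bonded
```

The mean angle and dispersion rise, and the stacked fraction falls, as
`hijack_fraction` grows: inhibitor-bound monomers adopt isotropic
orientations instead of ordered stacks, which is the mechanistic signature
the trajectory arm quantifies. The intra-ring-oxygen occupancy is the
fraction of configurations with that sporadic hydrogen bond — here 9 of
200 frames against a planted rate of 6%.

The same analyses run from the shell:

```bash
molstack simulate-traj --n-monomer 44 --n-inhibitor 5 --n-replicas 4 \
    --n-frames 125 --hijack-fraction 0.2 --seed 1 --outdir sim/
molstack analyze-traj --topology sim/topology.yaml \
    --traj sim/replica_0.xyz --traj sim/replica_1.xyz \
    --traj sim/replica_2.xyz --traj sim/replica_3.xyz --outdir results/
molstack simulate-kinetics --doses 1:60,2:45,5:35,10:25 --outdir kin/
molstack potency --curves kin/curves.csv --endpoint 1000 --outdir pot/
```

Trajectories are plain XYZ (box/time in the comment line) or multi-model
PDB (CRYST1 + MODEL/ENDMDL); topologies are YAML; curves and all reports
are CSV plus a JSON summary with a config hash for provenance.

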