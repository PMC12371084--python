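# v0scape

Conformational-landscape analysis of the Golgi V-ATPase V₀ region.

The V-ATPase proton pump is regulated by reversible assembly of its
membrane-embedded V₀ region with the cytosolic V₁ region. In the Golgi,
the a2 subunit's cytosolic *head* can engage the d1 subunit; while engaged
it sterically blocks V₁ docking, so only head-disengaged V₀ conformations
are assembly-competent. `v0scape` is a pipeline for mapping this
conformational landscape from multi-frame structure ensembles and for
quantifying how membrane lipids — PI(4)P and cholesterol — shift the
population of the assembly-promoting state:

1. **align** — Kabsch superposition removes global rotation/translation;
2. **embed** — a denoising autoencoder (input → 1024 → 128 → 2, mirrored
   decoder, ReLU, 20% dropout, L1 reconstruction + a 3×3 latent-grid L2
   term) reduces Cα configurations to 2D; trained on half the shuffled
   frames, scored by holdout mean absolute error (Å);
3. **cluster** — a Bayesian Gaussian mixture (full covariance, 9 initial
   components, Dirichlet-process prior) finds the conformational states;
   frames with max responsibility ≤ 50% sit on decision boundaries;
4. **identify** — the assembly-promoting cluster is the one whose a2 head
   forms the fewest contacts with d1;
5. **discriminate** — six-component PLS-DA separates that cluster (0/1
   labels, validation R², 0→1 structural interpolation);
6. **lipid analytics** — per-frame contact counts, salt-bridge
   frequencies (E81–R436, D76–R126), lipid occupancy density maps and
   a2/c-ring pocket occupancy;
7. **assembly fit** — each V₀ conformation is superposed onto a labeled
   holo (V₀+V₁) reference on the stable c-ring+d1 core and steric clashes
   of the a2 arm with V₁ are counted.

Because no trajectories are deposited for the membrane simulations this
analysis targets, the package ships a first-class synthetic-ensemble
generator that plants a known ground truth (four rigid-body head/arm
states, thermal noise, random global motion, leaflet lipid layouts at the
standard POPC/PI(4)P/cholesterol compositions, composition-dependent state
weights), so every stage is testable end-to-end. See `docs/methods.md`.

## Worked example

```python
from v0scape import (
    GeneratorConfig, generate_ensemble, select_atoms, kabsch_align,
    AutoencoderConfig, train_autoencoder, embed_frames,
    fit_bgmm, assign_clusters, identify_assembly_cluster, count_contacts,
)
from v0scape.synthetic import canonical_alignment_reference

ensemble, truth = generate_ensemble(GeneratorConfig(seed=7))
calpha = select_atoms(ensemble.topology, "calpha")
aligned, _ = kabsch_align(
    ensemble, canonical_alignment_reference(ensemble.topology), calpha
)
model = train_autoencoder(aligned, calpha, AutoencoderConfig(epochs=500, seed=11))
embedding = embed_frames(model, aligned)
mixture = fit_bgmm(embedding, k_max=9, seed=3)
assignment = assign_clusters(mixture, embedding)
head_d1 = count_contacts(
    aligned,
    select_atoms(aligned.topology, "region a2_head"),
    select_atoms(aligned.topology, "region d1"),
    cutoff=4.0,
)
print(f"holdout MAE: {model.holdout_mae:.3f} A")
print(f"effective clusters: {mixture.n_effective}")
print(f"assembly-promoting cluster: "
      f"{identify_assembly_cluster(assignment, head_d1.counts)}")
```

Output:

```
holdout MAE: 0.556 A
effective clusters: 4
assembly-promoting cluster: 3
```

The holdout MAE lies between the analytic floor set by the generator's
thermal noise (0.3 Å · √(2/π) ≈ 0.239 Å — the autoencoder reconstructs
state-mean structures and cannot, and should not, reproduce the noise)
and the ~1 Å scale typical of a converged model of this architecture.
The mixture recovers exactly the four planted states, and the cluster with
the fewest head–d1 contacts is the planted head-away pose. (The
assembly-promoting cluster's index depends on the mixture fit order; the
functional identification is what is stable.)

The same pipeline runs from one command:

```sh
v0scape run-all --seed 7 --outdir results/
```

which writes the embedding, cluster assignments, population tables,
contact/salt-bridge/clash tables and a provenance-stamped `report.json`.
Individual stages are exposed as `v0scape simulate|membrane-spec|embed|
cluster|plsda|contacts|saltbridges|density|clashes`.

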