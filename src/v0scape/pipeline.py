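"""End-to-end orchestration: generate -> align -> embed -> cluster ->
identify assembly cluster -> PLS-DA -> contacts / salt bridges / occupancy
-> V1 clash assessment -> report.

One master seed drives every stochastic stage through deterministically
derived sub-seeds, so re-running an identical configuration reproduces the
report bit-for-bit.  Per-composition state weights default to a landscape
in which the assembly-promoting state is suppressed by PI(4)P-rich,
cholesterol-free membranes and rescued by cholesterol.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assembly import build_toy_holo, clash_series, clashes_by_group
from .autoencoder import (
    AutoencoderConfig,
    Embedding,
    LatentModel,
    embed_frames,
    train_autoencoder,
)
from .clustering import (
    assign_clusters,
    cluster_populations,
    fit_bgmm,
    functional_order,
    identify_assembly_cluster,
)
from .contacts import (
    DEFAULT_SALT_BRIDGES,
    contacts_by_cluster,
    count_contacts,
    occupancy_map,
    salt_bridge_frequency,
)
from .discriminant import fit_plsda
from .membrane import MembraneComposition, build_membrane_spec
from .synthetic import (
    POCKET_CENTER_XY,
    POCKET_RADIUS,
    GeneratorConfig,
    canonical_alignment_reference,
    generate_ensemble,
)
from .trajio import concat_ensembles, kabsch_align, select_atoms

log = logging.getLogger("v0scape")

#: Planted per-composition weights of the four conformational states
#: (state 0 = assembly-promoting).  High PI(4)P without cholesterol
#: suppresses the assembly-promoting state; cholesterol rescues it.
DEFAULT_STATE_WEIGHTS = {
    "V0": (0.25, 0.25, 0.25, 0.25),
    "V0-20PI4": (0.08, 0.31, 0.31, 0.30),
    "V0-20PI4-10Chol": (0.24, 0.26, 0.25, 0.25),
    "V0-10PI4-20Chol": (0.40, 0.20, 0.20, 0.20),
}

DEFAULT_POCKET_BIAS = {
    "V0": "none",
    "V0-20PI4": "pi4p_in_pocket",
    "V0-20PI4-10Chol": "pi4p_in_pocket",
    "V0-10PI4-20Chol": "chol_blocks_pocket",
}


@dataclass
class CompositionRun:
    popc: float
    pi4p: float
    chol: float
    n_frames: int = 500
    state_weights: tuple[float, ...] | None = None
    pocket_bias: str | None = None


@dataclass
class PipelineConfig:
    compositions: list[CompositionRun] = field(
        default_factory=lambda: [
            CompositionRun(popc, pi4p, chol)
            for popc, pi4p, chol in (
                (100, 0, 0), (80, 20, 0), (70, 20, 10), (70, 10, 20)
            )
        ]
    )
    seed: int = 0
    noise_sigma: float = 0.3
    epochs: int = 500
    hidden2: int = 128
    lambda_grid: float = 0.1
    k_max: int = 9
    weight_threshold: float = 0.02
    pls_components: int = 6
    contact_cutoff: float = 4.0
    clash_cutoff: float = 3.0
    mobile_selector: str = "region a2_arm"

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        comps = raw.pop("compositions", None)
        cfg = cls(**raw)
        if comps is not None:
            cfg.compositions = [CompositionRun(**c) for c in comps]
        return cfg


@dataclass
class ReportBundle:
    summary: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"summary": self.summary, "provenance": self.provenance},
            indent=2, sort_keys=True,
        )


def _df_records(df) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> ReportBundle:
    """Execute all stages in dependency order and assemble the report.

    When ``outdir`` is given, intermediate artifacts (embedding, cluster
    assignments, population/contact/clash tables, the trained model and the
    report itself) are persisted there.
    """
    ss = np.random.SeedSequence(config.seed)
    gen_ss, ae_ss, bgmm_ss, pls_ss = ss.spawn(4)
    ae_seed = int(ae_ss.generate_state(1)[0] % 2**31)
    bgmm_seed = int(bgmm_ss.generate_state(1)[0] % 2**31)
    pls_seed = int(pls_ss.generate_state(1)[0] % 2**31)
    comp_seeds = [
        int(c.generate_state(1)[0] % 2**31)
        for c in gen_ss.spawn(len(config.compositions))
    ]

    # --- generate -----------------------------------------------------
    ensembles, truths = [], []
    for run, seed in zip(config.compositions, comp_seeds):
        spec = build_membrane_spec(
            MembraneComposition(run.popc, run.pi4p, run.chol)
        )
        label = spec.composition.label
        weights = run.state_weights or DEFAULT_STATE_WEIGHTS.get(label)
        bias = run.pocket_bias or DEFAULT_POCKET_BIAS.get(label, "none")
        log.info("generating %s: %d frames, weights=%s, bias=%s",
                 label, run.n_frames, weights, bias)
        ens, truth = generate_ensemble(
            GeneratorConfig(
                n_frames=run.n_frames,
                state_weights=tuple(weights) if weights else None,
                noise_sigma=config.noise_sigma,
                lipid_spec=spec,
                pocket_bias=bias,
                seed=seed,
            )
        )
        ensembles.append(ens)
        truths.append(truth)
    ensemble = concat_ensembles(ensembles)
    planted = np.concatenate([t.state_labels for t in truths])

    # --- align --------------------------------------------------------
    # Aligning onto the generator's clean pose keeps the membrane frame of
    # reference, in which the pocket region and occupancy grids are defined.
    calpha = select_atoms(ensemble.topology, "calpha", require_nonempty=True)
    reference = canonical_alignment_reference(ensemble.topology)
    aligned, fit_rmsd = kabsch_align(ensemble, reference, calpha)
    log.info("aligned %d frames (max fit RMSD %.2f A)",
             aligned.n_frames, fit_rmsd.max())

    # --- embed --------------------------------------------------------
    ae_cfg = AutoencoderConfig(
        hidden2=config.hidden2, lambda_grid=config.lambda_grid,
        epochs=config.epochs, seed=ae_seed,
    )
    model = train_autoencoder(aligned, calpha, ae_cfg)
    embedding = embed_frames(model, aligned)
    log.info("holdout MAE %.3f A", model.holdout_mae)

    # --- cluster ------------------------------------------------------
    mixture = fit_bgmm(
        embedding, k_max=config.k_max, seed=bgmm_seed,
        weight_threshold=config.weight_threshold,
    )
    assignment = assign_clusters(mixture, embedding)
    log.info("%d effective components", mixture.n_effective)

    # --- functional identification ------------------------------------
    head = select_atoms(aligned.topology, "region a2_head")
    d1 = select_atoms(aligned.topology, "region d1")
    head_d1 = count_contacts(aligned, head, d1, config.contact_cutoff)
    assembly_cluster = identify_assembly_cluster(
        assignment, head_d1.counts
    )
    order = functional_order(assignment, head_d1.counts)

    populations = cluster_populations(assignment, aligned.frame_labels)
    head_d1_by_cluster = contacts_by_cluster(
        head_d1, assignment.labels, aligned.frame_labels
    )

    # --- PLS-DA -------------------------------------------------------
    X = model.features_from(aligned)
    labels01 = (assignment.labels == assembly_cluster).astype(int)
    plsda = fit_plsda(
        X, labels01, n_components=config.pls_components, seed=pls_seed
    )

    # --- lipid analytics ----------------------------------------------
    bridges = salt_bridge_frequency(
        aligned, DEFAULT_SALT_BRIDGES, cluster_labels=assignment.labels
    )
    pi4p_present = (aligned.topology.region == "lipid_PI4P").any()
    head_pi4p_by_cluster = None
    if pi4p_present:
        pi4p = select_atoms(aligned.topology, "species PI4P")
        head_pi4p = count_contacts(aligned, head, pi4p,
                                   config.contact_cutoff)
        head_pi4p_by_cluster = contacts_by_cluster(
            head_pi4p, assignment.labels, aligned.frame_labels
        )

    pocket = {}
    for species in ("PI4P", "CHOL"):
        pocket[species] = {}
        for comp in np.unique(aligned.frame_labels.astype(str)):
            mask = np.flatnonzero(aligned.frame_labels.astype(str) == comp)
            sub = aligned.subset_frames(mask)
            if not (sub.topology.region == f"lipid_{species}").any():
                pocket[species][str(comp)] = 0.0
                continue
            omap = occupancy_map(sub, species)
            pocket[species][str(comp)] = omap.pocket_occupancy(
                POCKET_CENTER_XY, POCKET_RADIUS
            )

    # --- clashes ------------------------------------------------------
    holo = build_toy_holo()
    clashes = clash_series(
        aligned, holo, mobile_selector=config.mobile_selector,
        cutoff=config.clash_cutoff,
    )
    clash_by_cluster = clashes_by_group(clashes, assignment.labels)
    clash_by_comp = clashes_by_group(
        clashes, assignment.labels, aligned.frame_labels
    )

    # --- report -------------------------------------------------------
    summary = {
        "n_frames": int(aligned.n_frames),
        "holdout_mae_A": model.holdout_mae,
        "n_effective_clusters": int(mixture.n_effective),
        "assembly_cluster": int(assembly_cluster),
        "functional_order": [int(i) for i in order],
        "cluster_populations": populations.to_dict(orient="index"),
        "assembly_cluster_population_by_composition": {
            comp: float(populations.loc[comp, f"cluster_{assembly_cluster}"])
            for comp in populations.index
        },
        "plsda_validation_r2": plsda.validation_r2,
        "head_d1_contacts_by_cluster": _df_records(head_d1_by_cluster),
        "head_pi4p_contacts_by_cluster": (
            _df_records(head_pi4p_by_cluster)
            if head_pi4p_by_cluster is not None else None
        ),
        "salt_bridge_frequencies": _df_records(bridges),
        "pocket_occupancy_per_frame": pocket,
        "clashes_by_cluster": _df_records(clash_by_cluster),
        "clashes_by_composition": _df_records(clash_by_comp),
        "planted_state_agreement_ari": _ari(planted, assignment.labels),
    }
    provenance = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stage_seeds": {
            "generator": comp_seeds,
            "autoencoder": ae_seed,
            "bgmm": bgmm_seed,
            "plsda": pls_seed,
        },
    }
    report = ReportBundle(summary=summary, provenance=provenance)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.save(outdir / "latent_model.npz")
        np.savetxt(
            outdir / "embedding.csv",
            np.column_stack([embedding.latent,
                             embedding.is_train.astype(int)]),
            delimiter=",", header="z1,z2,is_train", comments="",
        )
        _write_assignments(outdir / "assignments.tsv", aligned, assignment)
        populations.to_csv(outdir / "populations.csv")
        head_d1_by_cluster.to_csv(outdir / "head_d1_contacts.csv",
                                  index=False)
        bridges.to_csv(outdir / "salt_bridges.csv", index=False)
        clash_by_cluster.to_csv(outdir / "clashes_by_cluster.csv",
                                index=False)
        clash_by_comp.to_csv(outdir / "clashes_by_composition.csv",
                             index=False)
        (outdir / "report.json").write_text(report.to_json())
    return report


def _write_assignments(path, ensemble, assignment):
    with open(path, "w") as fh:
        fh.write("frame\tcomposition\tcluster\tmax_responsibility\tboundary\n")
        maxr = assignment.responsibilities.max(axis=1)
        for f in range(ensemble.n_frames):
            fh.write(
                f"{f}\t{ensemble.frame_labels[f]}\t{assignment.labels[f]}"
                f"\t{maxr[f]:.6f}\t{int(assignment.boundary[f])}\n"
            )


def _ari(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))
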