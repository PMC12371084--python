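"""Conformational-state detection with a Bayesian Gaussian mixture.

A BGMM with full 2x2 covariances is fitted to the 2D embedding with a
deliberately large component budget; the Dirichlet-process concentration
prior lets superfluous components collapse, so the number of effective
components (weight above a small threshold) is regularized by the data
rather than fixed a priori.  Frames are hard-assigned by maximum posterior
responsibility, flagged as boundary frames when no component reaches 50%
responsibility, and each effective cluster is represented by the frame
whose latent point lies closest to the component mean.

Cluster indices from the fit are arbitrary; the functional identity of the
assembly-promoting cluster is established from head-d1 contact statistics
(the cluster whose a2 head forms the fewest contacts with d1), never from
fit order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.mixture import BayesianGaussianMixture

from .autoencoder import Embedding


class ParameterError(ValueError):
    pass


class AmbiguousIdentificationError(RuntimeError):
    pass


BOUNDARY_RESPONSIBILITY = 0.5
BOUNDARY_TOL = 1e-9


@dataclass
class MixtureModel:
    """A fitted 2D Gaussian mixture: weights, means, full covariances.

    Responsibilities downstream are the standard Gaussian posterior
    p(k | z) over the retained components.
    """

    weights: np.ndarray        # (K,)
    means: np.ndarray          # (K, 2)
    covariances: np.ndarray    # (K, 2, 2)
    weight_threshold: float = 0.02
    k_max: int = 0
    seed: int = 0
    converged: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ParameterError("mixture weights must sum to 1")

    @property
    def effective_components(self) -> np.ndarray:
        """Indices of components whose weight exceeds the threshold."""
        return np.flatnonzero(self.weights > self.weight_threshold)

    @property
    def n_effective(self) -> int:
        return len(self.effective_components)

    def log_responsibilities(self, Z: np.ndarray) -> np.ndarray:
        """Log posterior over the effective components, renormalized."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.means.shape[1]:
            raise ParameterError("embedding/model dimension mismatch")
        eff = self.effective_components
        covs = []
        for k in eff:
            C = 0.5 * (self.covariances[k] + self.covariances[k].T)
            # tiny ridge: near-point clusters have covariances at the
            # fitting regularization floor, which can fail strict PSD checks
            covs.append(C + 1e-12 * max(np.trace(C), 1.0) * np.eye(len(C)))
        logp = np.stack(
            [
                np.log(self.weights[k])
                + np.atleast_1d(
                    multivariate_normal.logpdf(
                        Z, self.means[k], cov, allow_singular=True,
                    )
                )
                for k, cov in zip(eff, covs)
            ],
            axis=1,
        )
        logp -= logp.max(axis=1, keepdims=True)
        logp -= np.log(np.exp(logp).sum(axis=1, keepdims=True))
        return logp


@dataclass
class ClusterAssignment:
    """Per-frame state assignment over the effective components.

    ``labels`` index the effective components 0..n_effective-1 (not the raw
    fit components).  ``responsibilities`` rows sum to 1.
    """

    responsibilities: np.ndarray   # (n_frames, n_effective)
    labels: np.ndarray             # (n_frames,)
    boundary: np.ndarray           # (n_frames,) bool
    representative_frames: np.ndarray  # (n_effective,)
    component_ids: np.ndarray      # raw fit component per effective cluster
    latent: np.ndarray             # the embedded points that were assigned

    @property
    def n_clusters(self) -> int:
        return len(self.component_ids)


def fit_bgmm(
    embedding: Embedding,
    k_max: int = 9,
    seed: int = 0,
    weight_threshold: float = 0.02,
    max_iter: int = 1000,
) -> MixtureModel:
    """Fit the Bayesian mixture with ``k_max`` initial components.

    The weight-concentration prior is ``1 / k_max`` (Dirichlet-process
    style), which lets the model empty out unneeded components.
    Non-convergence is surfaced as a warning with diagnostics, never an
    error.
    """
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    Z = np.asarray(embedding.latent, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ParameterError("embedding contains non-finite values")
    if len(Z) < 10 * k_max:
        raise ParameterError(
            f"need at least {10 * k_max} frames to fit {k_max} components"
        )
    # Covariance prior at the expected per-cluster scale (data covariance
    # over k_max^2): the library default — the covariance of ALL data —
    # inflates tight components toward data scale and can merge close,
    # well-separated clusters.
    cov_prior = np.atleast_2d(np.cov(Z.T)) / k_max**2
    cov_prior += 1e-12 * max(np.trace(cov_prior), 1.0) * np.eye(Z.shape[1])
    est = BayesianGaussianMixture(
        n_components=k_max,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1.0 / k_max,
        covariance_prior=cov_prior,
        random_state=seed,
        max_iter=max_iter,
        n_init=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Z)
    if not est.converged_:
        warnings.warn(
            f"BGMM did not converge in {max_iter} iterations "
            f"(lower bound {est.lower_bound_:.4g}); results may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    return MixtureModel(
        weights=est.weights_,
        means=est.means_,
        covariances=est.covariances_,
        weight_threshold=weight_threshold,
        k_max=k_max,
        seed=seed,
        converged=bool(est.converged_),
    )


def assign_clusters(model: MixtureModel, embedding: Embedding
                    ) -> ClusterAssignment:
    """Responsibilities, hard labels, boundary flags and representatives."""
    Z = np.asarray(embedding.latent, dtype=float)
    resp = np.exp(model.log_responsibilities(Z))
    resp /= resp.sum(axis=1, keepdims=True)
    labels = np.argmax(resp, axis=1)
    boundary = resp.max(axis=1) <= BOUNDARY_RESPONSIBILITY + BOUNDARY_TOL
    eff = model.effective_components
    reps = np.array(
        [
            int(np.argmin(np.linalg.norm(Z - model.means[c], axis=1)))
            for c in eff
        ]
    )
    return ClusterAssignment(
        responsibilities=resp,
        labels=labels,
        boundary=boundary,
        representative_frames=reps,
        component_ids=eff,
        latent=Z,
    )


def cluster_populations(
    assignment: ClusterAssignment, composition_labels
) -> pd.DataFrame:
    """Relative population of each effective cluster per composition.

    Rows are compositions, columns effective clusters; rows sum to 1.
    """
    labels = np.asarray(composition_labels, dtype=object)
    if len(labels) != len(assignment.labels):
        raise ParameterError(
            "composition labels must cover every assigned frame"
        )
    rows = {}
    for comp in pd.unique(labels):
        mask = labels == comp
        counts = np.bincount(
            assignment.labels[mask], minlength=assignment.n_clusters
        )
        rows[str(comp)] = counts / counts.sum()
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"cluster_{i}" for i in range(assignment.n_clusters)],
    )
    table.index.name = "composition"
    return table


def identify_assembly_cluster(
    assignment: ClusterAssignment,
    head_d1_counts: np.ndarray,
    tie_tolerance: float = 1e-9,
) -> int:
    """The effective cluster whose a2 head forms the fewest d1 contacts.

    ``head_d1_counts``: per-frame head-d1 contact counts aligned with the
    assignment.  Raises when the two lowest cluster means are closer than
    ``tie_tolerance`` (ambiguous identification).
    """
    counts = np.asarray(head_d1_counts, dtype=float)
    if len(counts) != len(assignment.labels):
        raise ParameterError("contact series must cover all assigned frames")
    means = np.array(
        [counts[assignment.labels == i].mean()
         for i in range(assignment.n_clusters)]
    )
    order = np.argsort(means)
    if assignment.n_clusters > 1 and (
        means[order[1]] - means[order[0]] <= tie_tolerance
    ):
        raise AmbiguousIdentificationError(
            f"clusters {order[0]} and {order[1]} tie on mean head-d1 "
            f"contacts ({means[order[0]]:.6g} vs {means[order[1]]:.6g})"
        )
    return int(order[0])


def functional_order(
    assignment: ClusterAssignment, head_d1_counts: np.ndarray
) -> np.ndarray:
    """Cluster relabeling by descending mean head-d1 contacts.

    The assembly-promoting cluster (fewest contacts) comes last, giving a
    stable, data-driven naming independent of fit order.
    """
    counts = np.asarray(head_d1_counts, dtype=float)
    means = np.array(
        [counts[assignment.labels == i].mean()
         for i in range(assignment.n_clusters)]
    )
    return np.argsort(-means)
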