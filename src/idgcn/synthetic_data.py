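"""Synthetic two-class cohorts with planted connectivity differences.

The generator emulates the statistical structure the classifier assumes:
per-subject ROI time series whose Pearson correlations differ between the
two classes on a small, known set of "informative" edges. Each informative
edge (i, j) receives its target correlation rho through a shared latent
signal: ROIs i and j both load on a common standard-normal component with
weight sqrt(rho), plus independent noise scaled so each ROI has unit
variance. A class-specific slow sinusoidal amplitude modulation of the
latent component (variance-normalised so the full-length correlation is
unchanged) makes sliding-window correlations genuinely nonstationary for
class 1, which is what the dynamic features are meant to detect.

Multi-site structure is emulated by round-robin site assignment plus a small
site-specific additive offset to every series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .connectivity import TimeSeriesMatrix

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "ground_truth_feature_indices",
]

# MNI-like bounding box for ROI centroids (mm); only relative distances matter.
_BOX_EXTENTS = (140.0, 170.0, 140.0)


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    static_effect is the between-class difference in population correlation on
    each informative edge; dynamic_effect is the class-1 amplitude of the slow
    sinusoidal modulation of the shared latent signal (class 0 is unmodulated).
    baseline_correlation is the class-0 correlation on informative edges; it
    must be large enough that modulation has something to modulate when only
    a dynamic effect is planted.
    """

    n_subjects_per_class: int
    n_rois: int = 20
    n_timepoints: int = 150
    informative_edges: list[tuple[int, int]] = field(default_factory=list)
    static_effect: float = 0.0
    dynamic_effect: float = 0.0
    n_sites: int = 3
    noise_sd: float = 1.0
    seed: int = 0
    baseline_correlation: float = 0.35
    modulation_period: float = 64.0
    site_offset_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be positive")
        if self.n_rois < 2:
            raise ValueError("n_rois must be at least 2")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dynamic_effect < 0:
            raise ValueError("dynamic_effect must be non-negative")
        edges = []
        for i, j in self.informative_edges:
            if i == j:
                raise ValueError(f"informative edge ({i},{j}) is a self-loop")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(
                    f"informative edge ({i},{j}) outside [0, {self.n_rois})"
                )
            edges.append((min(i, j), max(i, j)))
        if len(set(edges)) != len(edges):
            raise ValueError("informative edges must be distinct")
        self.informative_edges = edges
        # Feasibility: per class, the latent loadings on each node must leave
        # positive residual variance, and every target correlation must be in (-1, 1).
        for cls in (0, 1):
            load = np.zeros(self.n_rois)
            for (i, j), rho in zip(edges, self._edge_rhos(cls)):
                if not (-1.0 < rho < 1.0):
                    raise ValueError(
                        f"infeasible correlation target {rho:.3f} on edge ({i},{j})"
                    )
                if rho < 0:
                    raise ValueError(
                        f"negative correlation target {rho:.3f} on edge ({i},{j}) "
                        "is not representable by shared-latent mixing"
                    )
                load[i] += rho
                load[j] += rho
            bad = np.flatnonzero(load >= 1.0)
            if bad.size:
                raise ValueError(
                    f"node {bad[0]}: summed edge correlations >= 1, reduce effects "
                    "or spread informative edges over more nodes"
                )

    def _edge_rhos(self, cls: int) -> list[float]:
        rho = self.baseline_correlation + (self.static_effect if cls == 1 else 0.0)
        return [rho] * len(self.informative_edges)


@dataclass
class SyntheticCohort(Cohort):
    """Cohort plus the generating spec (ground truth kept for recovery tests)."""

    spec: CohortSpec | None = None


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a seeded synthetic cohort under ``spec``.

    Subjects alternate class 0/1 and are assigned to sites round-robin. The
    same seed always yields a bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rois
    coords = rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(_BOX_EXTENTS)
    roi_ids = [f"roi{i:03d}" for i in range(n)]

    n_sub = 2 * spec.n_subjects_per_class
    labels = np.tile([0, 1], spec.n_subjects_per_class)
    sites = np.arange(n_sub) % spec.n_sites
    subject_ids = [f"sub{idx:04d}" for idx in range(n_sub)]

    T = spec.n_timepoints
    t = np.arange(T)
    series: list[TimeSeriesMatrix] = []
    for idx in range(n_sub):
        cls = labels[idx]
        rhos = spec._edge_rhos(cls)
        x = np.zeros((T, n))
        resid = np.ones(n)
        for (i, j), rho in zip(spec.informative_edges, rhos):
            latent = rng.standard_normal(T)
            if cls == 1 and spec.dynamic_effect > 0:
                phase = rng.uniform(0.0, 2 * np.pi)
                w = 1.0 + spec.dynamic_effect * np.sin(
                    2 * np.pi * t / spec.modulation_period + phase
                )
                # normalise E[w^2] = 1 so the full-length correlation is unchanged
                w /= np.sqrt(1.0 + 0.5 * spec.dynamic_effect**2)
                latent = latent * w
            amp = np.sqrt(rho)
            x[:, i] += amp * latent
            x[:, j] += amp * latent
            resid[i] -= rho
            resid[j] -= rho
        x += np.sqrt(resid) * rng.standard_normal((T, n))
        x *= spec.noise_sd
        x += spec.site_offset_scale * spec.noise_sd * sites[idx]
        series.append(TimeSeriesMatrix(x, list(roi_ids)))

    return SyntheticCohort(
        subject_ids=subject_ids,
        labels=labels,
        sites=sites,
        coords=coords,
        roi_ids=roi_ids,
        timeseries=series,
        informative_edges=list(spec.informative_edges),
        spec=spec,
    )


def ground_truth_feature_indices(cohort: Cohort) -> list[tuple[int, int]]:
    """(node, feature-column) pairs that screening should be able to recover.

    Correlation features are symmetric, so each informative edge (i, j)
    contributes both (i, j) — edge seen from node i's feature row — and (j, i).
    """
    pairs: list[tuple[int, int]] = []
    for i, j in cohort.informative_edges:
        pairs.append((i, j))
        pairs.append((j, i))
    return pairs
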