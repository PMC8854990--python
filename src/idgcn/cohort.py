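"""In-memory cohort container shared by the generator, readers and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix, TimeSeriesMatrix

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """A two-class study cohort.

    Subjects are represented either by ROI time series (preferred; dynamic
    features computable) or by precomputed connectivity matrices. Labels are
    binary diagnoses, sites are integer acquisition-site codes, and coords are
    ROI centroid coordinates in mm.
    """

    subject_ids: list[str]
    labels: np.ndarray
    sites: np.ndarray
    coords: np.ndarray
    roi_ids: list[str]
    timeseries: list[TimeSeriesMatrix] | None = None
    connectivity: list[ConnectivityMatrix] | None = None
    informative_edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sites = np.asarray(self.sites, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n_sub = len(self.subject_ids)
        if self.labels.shape != (n_sub,) or self.sites.shape != (n_sub,):
            raise ValueError("labels/sites must have one entry per subject")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        if self.coords.shape != (len(self.roi_ids), 3):
            raise ValueError("coords must be an N x 3 table matching roi_ids")
        if self.timeseries is None and self.connectivity is None:
            raise ValueError("cohort needs time series or connectivity matrices")
        data = self.timeseries if self.timeseries is not None else self.connectivity
        if len(data) != n_sub:
            raise ValueError("one data matrix required per subject")
        for sid, m in zip(self.subject_ids, data):
            if m.n_rois != len(self.roi_ids):
                raise ValueError(
                    f"subject {sid}: {m.n_rois} ROIs, expected {len(self.roi_ids)}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_sites(self) -> int:
        return int(self.sites.max()) + 1 if len(self.sites) else 0
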