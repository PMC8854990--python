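"""Plain-text on-disk formats for cohorts, selections and reports.

Layout of a cohort directory:

    manifest.tsv          subject_id, label, site
    coords.tsv            roi_id, x, y, z (mm)
    timeseries/<id>.tsv   rows = time points, columns = ROIs (header = roi ids)
    ground_truth.tsv      optional sidecar: planted informative edges

All tables are tab-delimited with headers so they are diffable and readable
by any standard tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .connectivity import ConnectivityMatrix, TimeSeriesMatrix
from .interpret import ImportanceReport
from .model import CVResult, IDGCNParams
from .screening import FeatureSelection

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_selection",
    "read_selection",
    "write_connectivity",
    "read_connectivity",
    "save_checkpoint",
    "load_checkpoint",
    "write_metrics_table",
    "write_edge_report",
    "write_node_report",
]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort (time series form) to the directory layout the CLI reads."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"subject_id": cohort.subject_ids, "label": cohort.labels, "site": cohort.sites}
    ).to_csv(out / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "roi_id": cohort.roi_ids,
            "x": cohort.coords[:, 0],
            "y": cohort.coords[:, 1],
            "z": cohort.coords[:, 2],
        }
    ).to_csv(out / "coords.tsv", sep="\t", index=False, float_format="%.17g")
    if cohort.timeseries is None:
        raise ValueError("write_cohort expects a time-series cohort")
    for sid, ts in zip(cohort.subject_ids, cohort.timeseries):
        pd.DataFrame(ts.values, columns=ts.roi_ids).to_csv(
            out / "timeseries" / f"{sid}.tsv", sep="\t", index=False, float_format="%.17g"
        )
    if cohort.informative_edges:
        pd.DataFrame(cohort.informative_edges, columns=["roi_i", "roi_j"]).to_csv(
            out / "ground_truth.tsv", sep="\t", index=False
        )
    return out


def read_cohort(
    manifest_path: str | Path,
    data_dir: str | Path,
    coords_path: str | Path,
) -> Cohort:
    """Load and validate a cohort from disk.

    Errors name the offending subject (missing file, ROI-count mismatch,
    non-binary label).
    """
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "label", "site"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing column {col!r}")
    bad = manifest[~manifest["label"].isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"subject {bad['subject_id'].iloc[0]}: non-binary label {bad['label'].iloc[0]!r}"
        )
    coords_tab = pd.read_csv(coords_path, sep="\t", float_precision="round_trip")
    roi_ids = [str(r) for r in coords_tab["roi_id"]]
    coords = coords_tab[["x", "y", "z"]].to_numpy(dtype=float)

    data_dir = Path(data_dir)
    series = []
    for sid in manifest["subject_id"]:
        f = data_dir / f"{sid}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"subject {sid}: data file {f} not found")
        tab = pd.read_csv(f, sep="\t", float_precision="round_trip")
        if list(tab.columns) != roi_ids:
            raise ValueError(
                f"subject {sid}: {len(tab.columns)} ROIs do not match the "
                f"{len(roi_ids)}-ROI coordinates table"
            )
        series.append(TimeSeriesMatrix(tab.to_numpy(dtype=float), roi_ids))

    sites_raw = manifest["site"].to_numpy()
    _, sites = np.unique(sites_raw, return_inverse=True)

    gt_path = Path(manifest_path).parent / "ground_truth.tsv"
    edges = []
    if gt_path.exists():
        gt = pd.read_csv(gt_path, sep="\t")
        edges = [(int(i), int(j)) for i, j in zip(gt["roi_i"], gt["roi_j"])]

    return Cohort(
        subject_ids=list(manifest["subject_id"]),
        labels=manifest["label"].to_numpy(dtype=int),
        sites=sites,
        coords=coords,
        roi_ids=roi_ids,
        timeseries=series,
        informative_edges=edges,
    )


def write_connectivity(mat: ConnectivityMatrix, path: str | Path) -> None:
    """Connectivity matrix as delimited text with ROI-id header row/column."""
    pd.DataFrame(mat.values, index=mat.roi_ids, columns=mat.roi_ids).to_csv(
        path, sep="\t", index_label="roi_id", float_format="%.17g"
    )


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    tab = pd.read_csv(path, sep="\t", index_col="roi_id", float_precision="round_trip")
    return ConnectivityMatrix(tab.to_numpy(dtype=float), [str(c) for c in tab.columns])


def write_selection(sel: FeatureSelection, path: str | Path) -> None:
    """Selection as a diffable table (roi, slot, source, selected_roi)."""
    rows = []
    for r in range(sel.n_rois):
        rid = sel.roi_ids[r] if sel.roi_ids else str(r)
        for slot, j in enumerate(sel.static_indices[r]):
            rows.append((rid, r, slot, "static", int(j)))
        for slot, j in enumerate(sel.dynamic_indices[r]):
            rows.append((rid, r, slot, "dynamic", int(j)))
    pd.DataFrame(
        rows, columns=["roi_id", "roi_index", "slot", "source", "selected_roi_index"]
    ).to_csv(path, sep="\t", index=False)


def read_selection(path: str | Path, M: int, J: int, fit_seed: int = 0) -> FeatureSelection:
    tab = pd.read_csv(path, sep="\t")
    n = tab["roi_index"].max() + 1
    static = [
        tab.query("roi_index == @r and source == 'static'")
        .sort_values("slot")["selected_roi_index"]
        .to_numpy(dtype=int)
        for r in range(n)
    ]
    dynamic = [
        tab.query("roi_index == @r and source == 'dynamic'")
        .sort_values("slot")["selected_roi_index"]
        .to_numpy(dtype=int)
        for r in range(n)
    ]
    roi_ids = [str(tab.query("roi_index == @r")["roi_id"].iloc[0]) for r in range(n)]
    return FeatureSelection(
        static_indices=static, dynamic_indices=dynamic, M=M, J=J,
        fit_seed=fit_seed, roi_ids=roi_ids,
    )


def save_checkpoint(
    params: IDGCNParams, path: str | Path, meta: dict | None = None
) -> None:
    """All weights in one structured .npz container (+ JSON metadata inside)."""
    arrays = {
        "fc_weights": params.fc_weights,
        "fc_bias": params.fc_bias,
        "meta": np.frombuffer(
            json.dumps(
                {
                    "n_rois": params.n_rois,
                    "n_sites": params.n_sites,
                    "n_blocks": len(params.blocks.blocks),
                    **(meta or {}),
                }
            ).encode(),
            dtype=np.uint8,
        ),
    }
    for i, blk in enumerate(params.blocks.blocks):
        arrays[f"block{i}_phi"] = blk.phi.weights
        arrays[f"block{i}_omega"] = blk.omega.weights
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[IDGCNParams, dict]:
    from .gcn_core import ChebGCNLayerParams
    from .invertible import IDGCNBlocks, InvertibleBlockParams

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        blocks = [
            InvertibleBlockParams(
                phi=ChebGCNLayerParams(z[f"block{i}_phi"]),
                omega=ChebGCNLayerParams(z[f"block{i}_omega"]),
            )
            for i in range(meta["n_blocks"])
        ]
        params = IDGCNParams(
            blocks=IDGCNBlocks(blocks),
            fc_weights=z["fc_weights"],
            fc_bias=z["fc_bias"],
            n_rois=meta["n_rois"],
            n_sites=meta["n_sites"],
        )
    return params, meta


def write_metrics_table(cv: CVResult, path: str | Path, header_comment: str = "") -> None:
    names = ("accuracy", "auc", "precision", "recall", "f1")
    rows = []
    for i, fold in enumerate(cv.folds):
        m = fold.metrics
        rows.append([f"fold{i}", *[getattr(m, name) for name in names], m.n])
    rows.append(["mean", *[cv.mean[name] for name in names], ""])
    rows.append(["sd", *[cv.sd[name] for name in names], ""])
    df = pd.DataFrame(rows, columns=["split", *names, "n_test"])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_edge_report(report: ImportanceReport, path: str | Path, header_comment: str = "") -> None:
    rows = [
        (report.roi_ids[i], report.roi_ids[j], score)
        for i, j, score in report.top_edges
    ]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows, columns=["roi_i_label", "roi_j_label", "score"]).to_csv(
            fh, sep="\t", index=False, float_format="%.6g"
        )


def write_node_report(report: ImportanceReport, path: str | Path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(
            {"roi_label": report.roi_ids, "accuracy_drop": report.node_scores}
        ).to_csv(fh, sep="\t", index=False, float_format="%.6g")
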