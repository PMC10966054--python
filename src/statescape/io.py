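"""Plain-text readers and writers for time series, labels, and graphs."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .mapper import ShapeGraph
from .synthetic import LabeledTimeSeries, PsychometricTable

__all__ = [
    "save_timeseries",
    "load_timeseries",
    "load_nifti_timeseries",
    "save_psychometrics",
    "load_psychometrics",
    "graph_to_graphml",
    "graph_from_graphml",
    "graph_to_json",
    "graph_from_json",
]


def save_timeseries(series: LabeledTimeSeries, directory: str | Path) -> tuple[Path, Path]:
    """Write ``<subject>_matrix.tsv`` and ``<subject>_labels.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix_path = directory / f"{series.subject_id}_matrix.tsv"
    labels_path = directory / f"{series.subject_id}_labels.csv"
    # %.17g round-trips float64 exactly; Mapper decisions (bin boundaries,
    # epsilon thresholds) are discontinuous, so lossy text would not do.
    np.savetxt(matrix_path, series.values, delimiter="\t", fmt="%.17g")
    pd.DataFrame(
        {"frame_index": np.arange(series.n_frames), "label": series.labels}
    ).to_csv(labels_path, index=False)
    return matrix_path, labels_path


def load_timeseries(
    matrix_path: str | Path,
    labels_path: str | Path,
    subject_id: str,
    group: str,
) -> LabeledTimeSeries:
    values = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    labels_df = pd.read_csv(labels_path)
    if "label" not in labels_df.columns:
        raise ValidationError("labels CSV must have a 'label' column")
    labels = labels_df.sort_values("frame_index")["label"].to_numpy(dtype=object) \
        if "frame_index" in labels_df.columns else labels_df["label"].to_numpy(dtype=object)
    return LabeledTimeSeries(values=values, labels=labels,
                             subject_id=subject_id, group=group)


def load_nifti_timeseries(path: str | Path, mask_path: str | Path) -> np.ndarray:
    """Frames x voxels matrix from a 4-D NIfTI image and a binary mask."""
    import nibabel as nib  # optional dependency, only needed for NIfTI input

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError("expected a 4-D NIfTI time series")
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValidationError("mask shape must match the image's spatial grid")
    return data[mask].T.astype(float)  # (frames, voxels)


def save_psychometrics(table: PsychometricTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    coef_path = path.with_suffix(".coefficients.json")
    with open(coef_path, "w") as fh:
        json.dump(table.coefficients, fh, indent=2, sort_keys=True)
    return path


def load_psychometrics(path: str | Path) -> PsychometricTable:
    path = Path(path)
    frame = pd.read_csv(path)
    coef_path = path.with_suffix(".coefficients.json")
    coefficients = {}
    if coef_path.exists():
        with open(coef_path) as fh:
            coefficients = json.load(fh)
    return PsychometricTable(frame=frame, coefficients=coefficients)


def graph_to_graphml(sg: ShapeGraph, path: str | Path) -> Path:
    """GraphML export with scalar node attributes.

    ``members`` is serialized as a semicolon-joined string and label counts
    as ``count_<label>`` integers, since GraphML values must be scalar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = nx.Graph()
    for v in sg.node_order:
        counts = sg.label_counts(v)
        g.add_node(
            v,
            size=int(sg.graph.nodes[v]["size"]),
            members=";".join(str(i) for i in sg.members(v)),
            **{f"count_{k}": int(c) for k, c in sorted(counts.items())},
        )
    g.add_edges_from(sg.graph.edges)
    nx.write_graphml(g, path)
    return path


def graph_from_graphml(path: str | Path) -> ShapeGraph:
    raw = nx.read_graphml(path)
    g = nx.Graph()
    max_frame = -1
    for v, attrs in raw.nodes(data=True):
        members = tuple(int(i) for i in str(attrs["members"]).split(";") if i != "")
        counts = {k[len("count_"):]: int(c) for k, c in attrs.items()
                  if k.startswith("count_")}
        node = int(v)
        g.add_node(node, members=members, size=len(members))
        if counts:
            g.nodes[node]["label_counts"] = counts
        if members:
            max_frame = max(max_frame, max(members))
    g.add_edges_from((int(u), int(v)) for u, v in raw.edges)
    return ShapeGraph(graph=g, n_frames=max_frame + 1)


def graph_to_json(sg: ShapeGraph, path: str | Path) -> Path:
    """JSON dump: node -> member frame indices + label counts, edge list."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_frames": sg.n_frames,
        "nodes": {
            str(v): {
                "members": list(sg.members(v)),
                "label_counts": dict(sorted(sg.label_counts(v).items())),
            }
            for v in sg.node_order
        },
        "edges": sorted([int(u), int(v)] for u, v in sg.graph.edges),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path


def graph_from_json(path: str | Path) -> ShapeGraph:
    with open(path) as fh:
        payload = json.load(fh)
    g = nx.Graph()
    for v, attrs in payload["nodes"].items():
        members = tuple(int(i) for i in attrs["members"])
        g.add_node(int(v), members=members, size=len(members))
        if attrs.get("label_counts"):
            g.nodes[int(v)]["label_counts"] = dict(attrs["label_counts"])
    g.add_edges_from((int(u), int(v)) for u, v in payload["edges"])
    return ShapeGraph(graph=g, n_frames=int(payload["n_frames"]))
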