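"""Plain-text IO: trace tables, truth sidecars, manifests, fit artifacts.

All tabular formats are UTF-8 tab-separated values; structured artifacts
(models, decompositions, manifests) are JSON.  Every writer accepts an
optional provenance dict that is embedded in JSON outputs and prefixed as
``#key=value`` comment lines on TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm import GaussianHmm, IdealizedTrace
from .synthetic import FoldingModel, SimulatedDataset
from .traces import IntensityTrace

__all__ = [
    "write_trace_table",
    "read_trace_table",
    "write_truth",
    "read_truth",
    "write_manifest",
    "read_manifest",
    "write_json",
    "read_json",
    "write_tsv",
    "write_segments",
    "read_segments",
]


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj: dict, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if provenance:
        payload["provenance"] = provenance
    path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_trace_table(
    traces: Sequence[IntensityTrace], path, provenance: dict | None = None
) -> Path:
    """Long-format TSV: molecule_id, frame, donor, acceptor."""
    frames = [
        pd.DataFrame(
            {
                "molecule_id": tr.molecule_id,
                "frame": np.arange(len(tr)),
                "donor": tr.donor,
                "acceptor": tr.acceptor,
            }
        )
        for tr in traces
    ]
    return write_tsv(pd.concat(frames, ignore_index=True), path, provenance)


def read_trace_table(path, frame_interval_s: float = 0.1) -> list[IntensityTrace]:
    df = read_tsv(path)
    traces = []
    for mol, g in df.groupby("molecule_id", sort=True):
        g = g.sort_values("frame")
        traces.append(
            IntensityTrace(
                molecule_id=str(mol),
                donor=g["donor"].to_numpy(),
                acceptor=g["acceptor"].to_numpy(),
                frame_interval_s=frame_interval_s,
            )
        )
    return traces


def write_truth(dataset: SimulatedDataset, tsv_path, header_path) -> tuple[Path, Path]:
    """Truth sidecar: per-frame true state TSV + generating-model JSON."""
    frames = [
        pd.DataFrame(
            {
                "molecule_id": tr.molecule_id,
                "frame": np.arange(path.size),
                "true_state": path,
            }
        )
        for tr, path in zip(dataset.traces, dataset.truth_paths)
    ]
    tsv = write_tsv(pd.concat(frames, ignore_index=True), tsv_path)
    header = write_json(
        {
            "model": dataset.truth_model.to_dict(),
            "seed": dataset.seed,
            "condition": dataset.condition,
            "n_molecules": dataset.n_molecules,
            "frame_interval_s": dataset.phys.frame_interval_s,
            "bleach_frames": [
                {"donor": b.donor_frame, "acceptor": b.acceptor_frame}
                for b in dataset.bleach_events
            ],
        },
        header_path,
    )
    return tsv, header


def read_truth(tsv_path, header_path) -> tuple[dict[str, np.ndarray], FoldingModel, dict]:
    df = read_tsv(tsv_path)
    paths = {
        str(mol): g.sort_values("frame")["true_state"].to_numpy()
        for mol, g in df.groupby("molecule_id", sort=True)
    }
    header = read_json(header_path)
    return paths, FoldingModel.from_dict(header["model"]), header


def write_manifest(conditions: dict[str, dict], path, provenance: dict | None = None) -> Path:
    """Condition label -> {trace_file, kcl_mM / protein condition, ...}."""
    return write_json({"conditions": conditions}, path, provenance)


def read_manifest(path) -> dict[str, dict]:
    return read_json(path)["conditions"]


def write_fret_traces(fret_traces, path, provenance: dict | None = None) -> Path:
    """Accepted FRET traces as TSV: molecule_id, frame, efficiency."""
    frames = []
    for ft in fret_traces:
        if not ft.is_accepted:
            continue
        lo, hi = ft.accepted
        sl = slice(lo, hi)
        idx = np.arange(lo, hi)[ft.valid[sl]]
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": ft.molecule_id,
                    "frame": idx,
                    "efficiency": ft.efficiency[idx],
                }
            )
        )
    if not frames:
        raise ValueError("no accepted traces to write")
    return write_tsv(pd.concat(frames, ignore_index=True), path, provenance)


def write_density(density, path, provenance: dict | None = None) -> Path:
    """Transition density matrix as TSV with the grid in the header row."""
    edges = density.grid_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    df = pd.DataFrame(density.density, columns=[f"{c:.4f}" for c in centers])
    df.insert(0, "e_before", [f"{c:.4f}" for c in centers])
    prov = dict(provenance or {})
    prov["total_transitions"] = density.total_transitions
    prov["normalized"] = density.normalized
    return write_tsv(df, path, prov)


def write_segments(
    idealized: Sequence[IdealizedTrace], path, provenance: dict | None = None
) -> Path:
    """Idealized traces as a segments TSV."""
    rows = []
    for tr in idealized:
        for s, e, k in tr.segments:
            rows.append(
                {
                    "molecule_id": tr.molecule_id,
                    "start_frame": s,
                    "end_frame": e,
                    "state": k,
                    "state_mean": tr.state_means[k],
                }
            )
    return write_tsv(pd.DataFrame(rows), path, provenance)


def read_segments(path, frame_interval_s: float = 0.1) -> list[IdealizedTrace]:
    df = read_tsv(path)
    out = []
    for mol, g in df.groupby("molecule_id", sort=True):
        g = g.sort_values("start_frame")
        n_states = int(g["state"].max()) + 1
        means = np.full(n_states, np.nan)
        for _, row in g.iterrows():
            means[int(row["state"])] = row["state_mean"]
        # fill means of states unseen in this molecule from the grid midpoint
        if np.any(np.isnan(means)):
            means = np.where(np.isnan(means), np.nanmean(means), means)
        segs = tuple(
            (int(r.start_frame), int(r.end_frame), int(r.state))
            for r in g.itertuples()
        )
        out.append(
            IdealizedTrace(
                molecule_id=str(mol),
                segments=segs,
                state_means=means,
                frame_interval_s=frame_interval_s,
            )
        )
    return out
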