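"""Plain-text on-disk layouts for recordings, matrices and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .pipeline import ExperimentResult
from .synthetic import ContinuousRecording

__all__ = [
    "channel_names",
    "write_recording",
    "read_recording",
    "write_matrix",
    "read_matrix",
    "write_results",
]


def channel_names(n_channels: int) -> list:
    return [f"ch{i + 1:02d}" for i in range(n_channels)]


def write_recording(recording: ContinuousRecording, outdir) -> Path:
    """One numeric matrix file per segment plus a manifest table.

    Layout: ``<outdir>/sub<id>_ses<id>/segment<k>.tsv`` (channels x
    samples, tab-separated) and a ``manifest.tsv`` listing subject,
    session, segment index, duration and sampling rate.
    """
    outdir = Path(outdir)
    sub = outdir / f"sub{recording.subject_id:03d}_ses{recording.session_id}"
    sub.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, seg in enumerate(recording.segments):
        fname = f"segment{k:03d}.tsv"
        np.savetxt(sub / fname, seg, delimiter="\t", fmt="%.6g")
        rows.append(dict(subject=recording.subject_id,
                         session=recording.session_id, segment=k,
                         n_samples=seg.shape[1],
                         duration_s=seg.shape[1] / recording.sampling_rate,
                         sampling_rate=recording.sampling_rate, file=fname))
    manifest = outdir / "manifest.tsv"
    df = pd.DataFrame(rows)
    if manifest.exists():
        prev = pd.read_csv(manifest, sep="\t")
        mask = ~((prev.subject == recording.subject_id)
                 & (prev.session == recording.session_id))
        df = pd.concat([prev[mask], df], ignore_index=True)
    df.to_csv(manifest, sep="\t", index=False)
    return sub


def read_recording(outdir, subject_id: int,
                   session_id: int) -> ContinuousRecording:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    rows = manifest[(manifest.subject == subject_id)
                    & (manifest.session == session_id)]
    if rows.empty:
        raise FileNotFoundError(
            f"no recording for subject {subject_id} session {session_id}")
    sub = outdir / f"sub{subject_id:03d}_ses{session_id}"
    segments = [np.atleast_2d(np.loadtxt(sub / r.file, delimiter="\t"))
                for r in rows.sort_values("segment").itertuples()]
    return ContinuousRecording(subject_id=subject_id, session_id=session_id,
                               segments=segments,
                               sampling_rate=float(rows.sampling_rate.iloc[0]))


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Square TSV with a channel-name header row plus a JSON sidecar."""
    path = Path(path)
    names = channel_names(matrix.n_channels)
    pd.DataFrame(matrix.weights, index=names, columns=names) \
        .to_csv(path, sep="\t", float_format="%.10g")
    meta = dict(method=matrix.method, band=list(matrix.band),
                n_epochs_used=matrix.n_epochs_used)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2))


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ConnectivityMatrix(weights=df.to_numpy(), method=meta["method"],
                              band=tuple(meta["band"]),
                              n_epochs_used=meta["n_epochs_used"])


def write_results(result: ExperimentResult, outdir) -> Path:
    """Tidy CSV tables plus a JSON manifest capturing the full run config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.scores.to_csv(outdir / "scores.csv", index=False)
    result.icc_table.to_csv(outdir / "icc_table.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str))
    return outdir
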