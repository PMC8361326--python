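"""Readers and writers for the package's on-disk formats.

Connectivity matrices are plain whitespace- or comma-delimited n x n numeric
text files, one file per weight kind.  A cohort is described by a manifest CSV
with columns ``subject_id, group, fn_path, fa_path, md_path``; relative paths
are resolved against the manifest's directory.  Phantoms travel either as a
JSON document (schema below) or as NIfTI label/FA/MD volumes plus a TRK/TCK
streamline file.

Phantom JSON schema::

    {
      "shape": [nx, ny, nz],
      "labels": [...nested int lists...],   # 0 = background, 1..R regions
      "fa": [...nested float lists...],
      "md": [...nested float lists...],
      "streamlines": [[[x, y, z], ...], ...]  # ordered voxel indices
    }
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import MultiWeightConnectome, StreamlinePhantom

MANIFEST_COLUMNS = ("subject_id", "group", "fn_path", "fa_path", "md_path")


# -- matrices ---------------------------------------------------------------

def read_matrix(path) -> np.ndarray:
    """Read a square numeric matrix from delimited text (whitespace or comma)."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    m = np.loadtxt(path, delimiter=delimiter)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: not a square matrix (shape {m.shape})")
    return m


def write_matrix(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%.10g")


def read_connectome(fn_path, fa_path, md_path,
                    node_labels: Sequence[str] | None = None) -> MultiWeightConnectome:
    kwargs = {"node_labels": tuple(node_labels)} if node_labels else {}
    return MultiWeightConnectome(
        fn=read_matrix(fn_path), fa=read_matrix(fa_path), md=read_matrix(md_path),
        **kwargs,
    )


def write_connectome(conn: MultiWeightConnectome, prefix) -> dict[str, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, m in conn.matrices().items():
        p = prefix.parent / f"{prefix.name}_{kind.lower()}.txt"
        write_matrix(p, m)
        paths[kind] = p
    return paths


# -- manifests --------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    return df


def load_cohort(manifest_path, positive_group: str | None = None
                ) -> tuple[list[tuple[MultiWeightConnectome, int]], list[str]]:
    """Load (connectome, label) pairs from a manifest CSV.

    ``group`` values of -1/+1 are used directly; otherwise ``positive_group``
    names the group mapped to +1 (the patient group by convention) and every
    other group maps to -1.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    groups = df["group"]
    numeric = set(str(g) for g in groups.unique()) <= {"-1", "1", "+1"}
    cohort = []
    ids = []
    for _, row in df.iterrows():
        if numeric:
            y = int(row["group"])
        else:
            if positive_group is None:
                raise ValueError(
                    "manifest has named groups; positive_group must be given"
                )
            y = 1 if str(row["group"]) == positive_group else -1
        paths = []
        for col in ("fn_path", "fa_path", "md_path"):
            p = Path(row[col])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"matrix file not found: {p}")
            paths.append(p)
        cohort.append((read_connectome(*paths), y))
        ids.append(str(row["subject_id"]))
    return cohort, ids


def write_cohort(cohort, subject_ids, out_dir,
                 group_names: dict[int, str] | None = None) -> Path:
    """Write per-subject matrix files plus a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (conn, y), sid in zip(cohort, subject_ids):
        paths = write_connectome(conn, out_dir / sid)
        group = group_names[y] if group_names else y
        rows.append({
            "subject_id": sid, "group": group,
            "fn_path": paths["FN"].name, "fa_path": paths["FA"].name,
            "md_path": paths["MD"].name,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


# -- phantoms ---------------------------------------------------------------

def read_phantom_json(path) -> StreamlinePhantom:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["shape"])
    lab = np.asarray(doc["labels"], dtype=int).reshape(shape)
    fa = np.asarray(doc["fa"], dtype=float).reshape(shape)
    md = np.asarray(doc["md"], dtype=float).reshape(shape)
    streams = [np.asarray(s, dtype=int) for s in doc["streamlines"]]
    return StreamlinePhantom(label_volume=lab, fa_volume=fa, md_volume=md,
                             streamlines=streams)


def write_phantom_json(phantom: StreamlinePhantom, path) -> None:
    doc = {
        "shape": list(phantom.shape),
        "labels": phantom.label_volume.tolist(),
        "fa": phantom.fa_volume.tolist(),
        "md": phantom.md_volume.tolist(),
        "streamlines": [s.tolist() for s in phantom.streamlines],
    }
    Path(path).write_text(json.dumps(doc))


def read_phantom_niftis(label_path, fa_path, md_path,
                        streamline_path) -> StreamlinePhantom:
    """Assemble a phantom from NIfTI volumes and a TRK/TCK streamline file.

    Streamline points (world mm, RAS) are mapped to voxel indices through the
    inverse of the label volume's affine and rounded to the nearest voxel.
    """
    import nibabel as nib

    label_img = nib.load(str(label_path))
    lab = np.asarray(label_img.dataobj).astype(int)
    fa = np.asarray(nib.load(str(fa_path)).dataobj).astype(float)
    md = np.asarray(nib.load(str(md_path)).dataobj).astype(float)

    tractogram = nib.streamlines.load(str(streamline_path))
    inv = np.linalg.inv(label_img.affine)
    streams = []
    for pts in tractogram.streamlines:
        homog = np.c_[pts, np.ones(len(pts))]
        vox = np.rint((homog @ inv.T)[:, :3]).astype(int)
        vox = np.clip(vox, 0, np.array(lab.shape) - 1)
        # collapse consecutive duplicates from rounding
        keep = np.ones(len(vox), dtype=bool)
        keep[1:] = np.any(vox[1:] != vox[:-1], axis=1)
        vox = vox[keep]
        if len(vox) >= 2:
            streams.append(vox)
    return StreamlinePhantom(label_volume=lab, fa_volume=fa, md_volume=md,
                             streamlines=streams)
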