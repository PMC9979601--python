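"""Delimited-text artifact formats: feature tables, label tables, moment
tables, manifests.

Every artifact starts with a ``# alfgp-<kind> v<major>.<minor>`` schema line;
readers reject unknown kinds and unknown major versions.  All atom indices in
files are 0-based, stated in each header.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .active_learning import LabeledPoint
from .multipoles import MOMENT_CONVENTION, MultipoleSet, component_index

__all__ = [
    "write_features",
    "read_features",
    "write_labels",
    "read_labels",
    "FileOracle",
    "write_moments",
    "read_moments",
    "write_manifest",
    "SchemaError",
]


class SchemaError(ValueError):
    """Artifact header missing, of unknown kind, or of unsupported major."""


def _header(kind: str, extra: list[str] | None = None) -> str:
    lines = [f"# alfgp-{kind} v1.0", "# indices are 0-based"]
    lines += extra or []
    return "\n".join(lines) + "\n"


def _check_schema(path: Path, kind: str) -> None:
    first = path.read_text().splitlines()[0].strip()
    prefix = f"# alfgp-{kind} v"
    if not first.startswith(prefix):
        raise SchemaError(f"{path}: expected a '{prefix}…' header, got {first!r}")
    major = first[len(prefix) :].split(".")[0]
    if major != "1":
        raise SchemaError(f"{path}: unsupported major version {major}")


def _read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    _check_schema(path, kind)
    return pd.read_csv(path, sep="\t", comment="#")


# --------------------------------------------------------------------------- #
def write_features(
    path: str | Path, features: np.ndarray, cyclic_mask: np.ndarray,
    atom_index: int, unit: str = "angstrom",
) -> None:
    """n_frames × D feature matrix for one atom, TSV."""
    F = np.atleast_2d(np.asarray(features, float))
    mask = "".join("1" if c else "0" for c in np.asarray(cyclic_mask, bool))
    df = pd.DataFrame(F, columns=[f"f{d}" for d in range(F.shape[1])])
    df.insert(0, "frame", np.arange(F.shape[0]))
    with open(path, "w") as fh:
        fh.write(
            _header(
                "features",
                [f"# atom_index {atom_index}", f"# unit {unit}",
                 f"# cyclic_mask {mask}"],
            )
        )
        df.to_csv(fh, sep="\t", index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, int]:
    """Returns (features, cyclic_mask, atom_index)."""
    path = Path(path)
    _check_schema(path, "features")
    mask = atom_index = None
    for line in path.read_text().splitlines():
        if line.startswith("# cyclic_mask "):
            mask = np.array([c == "1" for c in line.split()[-1]])
        elif line.startswith("# atom_index "):
            atom_index = int(line.split()[-1])
        elif not line.startswith("#"):
            break
    df = pd.read_csv(path, sep="\t", comment="#").sort_values("frame")
    F = df.drop(columns="frame").to_numpy(float)
    if mask is None or mask.size != F.shape[1]:
        raise SchemaError(f"{path}: missing or mismatched cyclic_mask header")
    return F, mask, int(atom_index or 0)


def write_labels(path: str | Path, points: list[LabeledPoint],
                 atom_tag: str = "atom0", property_tag: str = "iqa") -> None:
    """Label table: frame, atom_tag, property, value, integration_error."""
    df = pd.DataFrame(
        {
            "frame": [p.source_frame for p in points],
            "atom_tag": atom_tag,
            "property": property_tag,
            "value": [p.label for p in points],
            "integration_error": [p.integration_error for p in points],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header("labels", ["# value and integration_error in a.u."]))
        df.to_csv(fh, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return _read_table(path, "labels")


class FileOracle:
    """Oracle-contract labeller backed by a precomputed label table.

    Pairs a feature matrix (one row per frame) with a label table keyed by
    frame index; raises on frames the table does not cover.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: pd.DataFrame,
        atom_tag: str | None = None,
        property_tag: str | None = None,
    ) -> None:
        df = labels
        if atom_tag is not None:
            df = df[df["atom_tag"] == atom_tag]
        if property_tag is not None:
            df = df[df["property"] == property_tag]
        self.features = np.atleast_2d(np.asarray(features, float))
        self._by_frame = {
            int(r.frame): (float(r.value), float(r.integration_error))
            for r in df.itertuples()
        }

    def __call__(self, frame_indices) -> list[LabeledPoint]:
        out = []
        for f in frame_indices:
            f = int(f)
            if f not in self._by_frame:
                raise KeyError(f"no label for frame {f}")
            value, err = self._by_frame[f]
            out.append(
                LabeledPoint(self.features[f], value, err, source_frame=f)
            )
        return out


def write_moments(
    path: str | Path, moments: dict[tuple[str, int], MultipoleSet]
) -> None:
    """Moment table keyed by (atom_tag, frame): one row per (l, m) value."""
    rows = []
    for (atom_tag, frame), ms in moments.items():
        for l in range(5):
            for m in range(-l, l + 1):
                rows.append(
                    (atom_tag, frame, l, m, ms[(l, m)], ms.frame)
                )
    df = pd.DataFrame(
        rows, columns=["atom_tag", "frame", "l", "m", "value", "frame_tag"]
    )
    with open(path, "w") as fh:
        fh.write(_header("moments", [f"# convention: {MOMENT_CONVENTION}"]))
        df.to_csv(fh, sep="\t", index=False)


def read_moments(path: str | Path) -> dict[tuple[str, int], MultipoleSet]:
    df = _read_table(path, "moments")
    out: dict[tuple[str, int], MultipoleSet] = {}
    for (atom_tag, frame), grp in df.groupby(["atom_tag", "frame"]):
        vec = np.zeros(25)
        frame_tags = set(grp["frame_tag"])
        if len(frame_tags) != 1:
            raise SchemaError(f"{path}: mixed frame tags for {atom_tag}/{frame}")
        for r in grp.itertuples():
            vec[component_index(int(r.l), int(r.m))] = float(r.value)
        out[(str(atom_tag), int(frame))] = MultipoleSet(
            vec, frame_tags.pop(), str(atom_tag)
        )
    return out


def write_manifest(path: str | Path, config: dict, seeds: dict[str, int]) -> None:
    """Run provenance: config hash, seeds, package and platform versions."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "schema_version": "1.0",
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config,
        "seeds": seeds,
        "alfgp_version": __version__,
        "python_version": platform.python_version(),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
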