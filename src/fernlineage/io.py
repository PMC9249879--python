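"""Readers and writers for the pipeline's text formats.

Every table written here carries a one-line schema comment
(``# fernlineage schema: <name> v1``) so a run's outputs are
self-describing; the readers skip comment lines.  Supplementary
spreadsheet exports are loaded with header-name matching that tolerates
case, spacing and punctuation differences.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, mapping as shapely_mapping, shape as shapely_shape

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "v1"


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """CSV with a schema-version header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fernlineage schema: {schema} {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Annotations (notch points, archegonium tracks, manual centers)
# ---------------------------------------------------------------------------


def write_annotations(path: str | Path, notches=None, tracks=None) -> Path:
    """Notch-per-frame and archegonium-track annotations as JSON."""
    payload: dict = {"schema": f"fernlineage/annotations {SCHEMA_VERSION}"}
    if notches is not None:
        payload["notches"] = {str(t): list(map(float, p)) for t, p in notches.points.items()}
    if tracks is not None:
        payload["archegonia"] = [
            {
                "arch_id": tr.arch_id,
                "initiation_t": tr.initiation_t,
                "centers": {str(t): list(map(float, c)) for t, c in tr.centers.items()},
                "member_ids": {str(t): list(map(int, ids)) for t, ids in tr.member_ids.items()},
            }
            for tr in tracks
        ]
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_annotations(path: str | Path):
    """Read annotations JSON; returns (NotchAnnotation | None, tracks)."""
    from .geometry import ArchegoniumTrack, NotchAnnotation

    payload = json.loads(Path(path).read_text())
    notches = None
    if "notches" in payload:
        notches = NotchAnnotation(
            points={int(t): tuple(p) for t, p in payload["notches"].items()}
        )
    tracks = []
    for tr in payload.get("archegonia", []):
        tracks.append(
            ArchegoniumTrack(
                arch_id=int(tr["arch_id"]),
                initiation_t=int(tr["initiation_t"]),
                centers={int(t): tuple(c) for t, c in tr["centers"].items()},
                member_ids={int(t): list(ids) for t, ids in tr.get("member_ids", {}).items()},
            )
        )
    return notches, tracks


# ---------------------------------------------------------------------------
# ROI polygons (GeoJSON) and edit scripts (YAML)
# ---------------------------------------------------------------------------


def write_roi(path: str | Path, polygon: Polygon, properties: Mapping | None = None) -> Path:
    feature = {
        "type": "Feature",
        "properties": dict(properties or {}),
        "geometry": shapely_mapping(polygon),
    }
    payload = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(payload))
    return Path(path)


def read_roi(path: str | Path) -> Polygon:
    payload = json.loads(Path(path).read_text())
    geom = payload["features"][0]["geometry"]
    return shapely_shape(geom)


def write_edit_script(path: str | Path, script) -> Path:
    items = [
        {
            "op": d.op,
            "t": d.t_index,
            "ids": list(d.ids),
            **({"seeds": [list(s) for s in d.seeds]} if d.seeds else {}),
        }
        for d in script.directives
    ]
    Path(path).write_text(yaml.safe_dump(items))
    return Path(path)


def read_edit_script(path: str | Path):
    from .segmentation import EditScript

    return EditScript.from_obj(yaml.safe_load(Path(path).read_text()) or [])


# ---------------------------------------------------------------------------
# Supplementary spreadsheet exports
# ---------------------------------------------------------------------------

#: canonical column -> recognised header aliases (after normalisation)
_SUPP_SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "division_counts": {
        "t_index": ("t_index", "time_index", "frame"),
        "id": ("id", "cell_id", "nucleus_id", "cell"),
        "root_id": ("root_id", "lineage", "lineage_id", "progenitor", "progenitor_id"),
        "zone": ("zone", "position", "cell_position", "layer"),
        "n_events": (
            "n_events",
            "n_division_events",
            "division_events",
            "divisions",
            "number_of_division_events",
            "number_of_cell_division_events",
        ),
    },
    "distance_series": {
        "arch_id": ("arch_id", "archegonium", "archegonium_id"),
        "hours_since_initiation": (
            "hours_since_initiation",
            "hours",
            "time_h",
            "h_since_initiation",
            "time_point_h",
        ),
        "distance_um": ("distance_um", "distance", "distance_m", "distance_micron",
                        "distance_microns"),
    },
}


def _normalise(header: str) -> str:
    h = header.strip().lower()
    h = h.replace("μ", "u").replace("µ", "u")
    h = re.sub(r"[^\w]+", "_", h)
    return h.strip("_")


def read_supplementary_table(path: str | Path, schema_hint: str) -> pd.DataFrame:
    """Load a spreadsheet-exported delimited text file onto a known schema.

    Header names are matched case/space/punctuation-tolerantly against the
    aliases of ``schema_hint`` ("division_counts" or "distance_series");
    matched columns are renamed to the canonical names, unmapped columns are
    preserved verbatim.  Raises if no recognisable column is found.
    """
    if schema_hint not in _SUPP_SCHEMAS:
        raise ValueError(f"unknown schema_hint {schema_hint!r}; "
                         f"expected one of {sorted(_SUPP_SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    aliases = _SUPP_SCHEMAS[schema_hint]
    rename: dict[str, str] = {}
    for col in df.columns:
        norm = _normalise(str(col))
        for canonical, names in aliases.items():
            if norm == canonical or norm in names:
                rename[col] = canonical
                break
    if not rename:
        raise ValueError(
            f"no recognisable {schema_hint} columns in {path.name}; "
            f"found headers: {list(df.columns)}"
        )
    return df.rename(columns=rename)


# ---------------------------------------------------------------------------
# Label maps and image stacks
# ---------------------------------------------------------------------------


def write_label_map(path: str | Path, lm) -> Path:
    import tifffile

    if lm.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label image")
    tifffile.imwrite(Path(path), lm.labels.astype(np.uint16))
    return Path(path)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (T, rows, cols) array."""
    import tifffile

    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr


def write_forest_json(path: str | Path, forest) -> Path:
    Path(path).write_text(json.dumps(
        {"schema": f"fernlineage/forest {SCHEMA_VERSION}", **forest.to_json_obj()}
    ))
    return Path(path)


def write_forest_newick(path: str | Path, forest) -> Path:
    """All lineage trees, one Newick per line (branch length = steps)."""
    lines = [forest.to_newick(rk) for rk in sorted(forest.roots)]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def parameter_echo(path: str | Path, params: Mapping) -> Path:
    """Machine-readable record of a run's parameters (reproducibility)."""
    import fernlineage

    payload = {
        "schema": f"fernlineage/run {SCHEMA_VERSION}",
        "fernlineage_version": fernlineage.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "parameters": _jsonify(dict(params)),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "__dataclass_fields__"):
        import dataclasses

        return _jsonify(dataclasses.asdict(obj))
    return obj
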