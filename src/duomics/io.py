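"""Reading and writing the pipeline's plain-text formats.

Matrices travel as TSV with a leading ``feature_id`` column and one column
per sample; blank or NA cells are missing values (only permitted outside
raw-count layers).  Annotation collections use standard GMT lines
(name, description, then members).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .datatypes import (
    AnnotationCollection,
    FeatureAnnotation,
    FormatError,
    OmicsLayer,
    SampleMeta,
)

log = logging.getLogger("duomics")

_NA = ["", "NA", "NaN", "nan"]


def read_matrix(path, layer_id: str, scale: str, orientation: str = "features_rows") -> OmicsLayer:
    """Read a delimited feature x sample matrix into an :class:`OmicsLayer`.

    ``orientation='samples_rows'`` transposes after reading.  Duplicate row or
    column names raise :class:`FormatError`; scale contracts (non-negative
    complete integers for counts) are enforced by the container.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA, keep_default_na=False,
                     float_precision="round_trip")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"duplicate feature or sample ids in {path}")
    if orientation == "samples_rows":
        df = df.T
    elif orientation != "features_rows":
        raise FormatError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    df.columns = df.columns.astype(str)
    return OmicsLayer(layer_id, df, scale)


def write_matrix(layer: OmicsLayer, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = layer.values.copy()
    df.index.name = "feature_id"
    if layer.scale == "raw_count":
        df = df.astype(int)
        df.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")
    else:
        # %.17g guarantees bit-exact float round-trips through text
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g", lineterminator="\n")


def read_samples(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleMeta(df)


def write_samples(meta: SampleMeta, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.table.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_features(path) -> FeatureAnnotation:
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    if "kegg_present" in df.columns:
        df["kegg_present"] = df["kegg_present"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    return FeatureAnnotation(df)


def write_features(ann: FeatureAnnotation, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ann.table.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_gmt(path, name: str | None = None) -> AnnotationCollection:
    """Read a GMT file: each line ``set_name<TAB>description<TAB>member...``.

    Duplicate members within a line are dropped with a warning; duplicate set
    names and lines with fewer than three fields are format errors.  An empty
    file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_name = fields[0]
            if set_name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            members = fields[2:]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                log.warning("GMT set %s: %d duplicate members dropped", set_name, len(members) - len(uniq))
            sets[set_name] = frozenset(uniq)
    return AnnotationCollection(name or path.stem, sets)


def write_gmt(collection: AnnotationCollection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for set_name in sorted(collection.sets):
            members = sorted(collection.sets[set_name])
            fh.write("\t".join([set_name, collection.name] + members) + "\n")


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a stage output table; provenance (stage name, thresholds) goes
    into ``# key=value`` header comment lines so every artifact declares the
    parameters that produced it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key in sorted(provenance or {}):
            fh.write(f"# {key}={(provenance or {})[key]}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=_NA, keep_default_na=False,
                       float_precision="round_trip")
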