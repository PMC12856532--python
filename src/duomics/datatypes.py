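"""Core in-memory containers shared by every pipeline stage.

All matrices are feature-rows x sample-columns pandas DataFrames; joins are
always by identifier, never by position.  Missing values are explicit NaN and
are distinct from zero; raw-count layers must be complete and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("transcriptome", "proteome", "metabolome", "lipidome")
SCALES = ("raw_count", "linear_peak", "log2")
TISSUES = ("liver", "muscle")
GROUPS = ("control", "alcohol")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad GMT line, ...)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain contract."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent configuration of a stage."""


@dataclass
class OmicsLayer:
    """One feature x sample abundance matrix with its scale and layer tag.

    Parameters
    ----------
    layer_id : str
        One of :data:`LAYERS`.
    values : pandas.DataFrame
        Feature rows, sample columns.  NaN marks a missing measurement.
    scale : str
        ``raw_count`` (complete non-negative integers), ``linear_peak``
        (positive peak areas, NaN allowed) or ``log2``.
    """

    layer_id: str
    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.layer_id not in LAYERS:
            raise ValidationError(f"unknown layer_id {self.layer_id!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        self.values = self.values.astype(float)
        self.values.index.name = "feature_id"
        if self.scale == "raw_count":
            arr = self.values.to_numpy()
            if np.isnan(arr).any():
                raise ValidationError("count layer contains missing values")
            if (arr < 0).any():
                raise ValidationError("count layer contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("count layer contains non-integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "OmicsLayer":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in layer: {missing[:5]}")
        return OmicsLayer(self.layer_id, self.values[list(sample_ids)].copy(), self.scale)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "OmicsLayer":
        return OmicsLayer(self.layer_id, values, scale or self.scale)


@dataclass
class SampleMeta:
    """Per-sample metadata table.

    Columns: ``sample_id``, ``tissue``, ``group`` (NaN for QC injections),
    ``role`` (``experimental`` | ``qc``), ``injection_order``, ``batch``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "tissue", "group", "role", "injection_order", "batch")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"sample metadata missing column {col!r}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        qc = t["role"] == "qc"
        if t.loc[qc, "group"].notna().any():
            raise ValidationError("QC samples must not carry a group label")
        bad = t.loc[~qc, "group"].isin(GROUPS)
        if not bad.all():
            raise ValidationError("experimental samples need group in {control, alcohol}")
        orders = t.dropna(subset=["injection_order"])
        for (_, _), sub in orders.groupby(["tissue", "batch"], dropna=False):
            if sub["injection_order"].duplicated().any():
                raise ValidationError("injection_order not unique within a batch")
        self.table = t.set_index("sample_id", drop=False)

    def for_samples(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing[:5]}")
        return self.table.loc[list(sample_ids)]

    def experimental(self, tissue: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["role"] == "experimental"]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return t

    def qc(self, tissue: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["role"] == "qc"]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return t


@dataclass
class FeatureAnnotation:
    """Per-feature annotations: display name, lipid main class, metabolite
    pathway labels, KEGG-ID flag, and the gene-symbol mapping key."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "feature_id" not in self.table.columns:
            raise FormatError("feature annotation needs a feature_id column")
        if self.table["feature_id"].duplicated().any():
            raise FormatError("duplicate feature ids in annotation")
        t = self.table.copy()
        if "gene_symbol" in t.columns:
            # mapping keys are case-normalized
            t["gene_symbol"] = t["gene_symbol"].astype("string").str.upper()
        self.table = t.set_index("feature_id", drop=False)

    def lipid_classes(self) -> pd.Series:
        sub = self.table[self.table["layer_id"] == "lipidome"]
        return sub["lipid_class"].dropna()

    def gene_symbols(self, layer_id: str) -> pd.Series:
        sub = self.table[self.table["layer_id"] == layer_id]
        return sub["gene_symbol"].dropna()

    def kegg_flags(self) -> pd.Series:
        sub = self.table[self.table["layer_id"] == "metabolome"]
        return sub["kegg_present"].map(bool, na_action="ignore").fillna(False)


@dataclass
class AnnotationCollection:
    """A named collection of annotation sets (GMT semantics)."""

    name: str
    sets: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"empty set {set_name!r} in collection {self.name!r}")
            self.sets[set_name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def member_universe(self) -> frozenset:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)
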