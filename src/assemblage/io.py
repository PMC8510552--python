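"""Core data containers and I/O: OTU tables, metadata, trees, rarefaction,
prevalence filtering, and geographic distances.

Tables are stored samples x OTUs in memory; on disk the TSV layout is
OTU ids x sample ids (one row per OTU), the layout most OTU-table tooling
emits. BIOM support targets the JSON-based BIOM 1.0 spec so that files stay
plain text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

HABITAT_CLASSES = ("nearshore", "offshore")
DEPTH_LAYERS = ("surface", "DCM", "bottom")


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with unique string ids."""

    data: pd.DataFrame  # index = sample ids, columns = OTU ids

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError(f"duplicate sample ids: "
                              f"{sorted(df.index[df.index.duplicated()])}")
        if df.columns.has_duplicates:
            raise FormatError(f"duplicate OTU ids: "
                              f"{sorted(df.columns[df.columns.duplicated()])}")
        values = df.to_numpy()
        if not np.isfinite(values).all():
            raise FormatError("counts must be finite")
        if (values < 0).any():
            bad = df.index[(values < 0).any(axis=1)][0]
            raise FormatError(f"negative count in sample {bad!r}")
        self.data = df.astype(np.int64, copy=False)

    # -- basic accessors ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)].copy())

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.data.sum(axis=0) > 0
        return OtuTable(self.data.loc[:, keep].copy())

    # -- serialisation -----------------------------------------------------

    def to_tsv(self, path) -> None:
        self.data.T.to_csv(path, sep="\t", index_label="#OTU ID")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001 - rewrap parser errors
            raise FormatError(f"cannot parse OTU table {path}: {exc}") from exc
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)][0]
            raise FormatError(f"ragged or missing values at row {bad!r}")
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str).rename(None)
        return cls(df.T)

    def to_biom(self, path, table_id: str = "otu-table") -> None:
        """Write a dense BIOM 1.0 (JSON) file."""
        obj = {
            "id": table_id,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "assemblage",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [self.n_otus, self.n_samples],
            "rows": [{"id": o, "metadata": None} for o in self.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": self.data.T.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_biom(cls, path) -> "OtuTable":
        with open(path) as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"cannot parse BIOM file {path}: {exc}") from exc
        otu_ids = [r["id"] for r in obj["rows"]]
        sample_ids = [c["id"] for c in obj["columns"]]
        n_otus, n_samples = obj["shape"]
        mat = np.zeros((n_otus, n_samples))
        if obj["matrix_type"] == "dense":
            mat = np.asarray(obj["data"], dtype=float)
        else:
            for i, j, v in obj["data"]:
                mat[i, j] = v
        df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
        return cls(df)


def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from TSV or BIOM (JSON) format."""
    if format == "tsv":
        return OtuTable.from_tsv(path)
    if format == "biom":
        return OtuTable.from_biom(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.to_tsv(path)
    elif format == "biom":
        table.to_biom(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


@dataclass
class SampleMetadata:
    """Per-sample covariates: station, habitat class, depth layer, position
    and environmental measurements."""

    data: pd.DataFrame  # index = sample ids

    REQUIRED = ("station", "habitat_class", "layer", "latitude", "longitude",
                "depth", "temperature")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        bad_hab = set(df["habitat_class"]) - set(HABITAT_CLASSES)
        if bad_hab:
            raise FormatError(f"unknown habitat_class values: {sorted(bad_hab)}")
        bad_layer = set(df["layer"]) - set(DEPTH_LAYERS)
        if bad_layer:
            raise FormatError(f"unknown layer values: {sorted(bad_layer)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def numeric(self, variable: str) -> pd.Series:
        if variable not in self.data.columns:
            raise KeyError(f"no metadata variable {variable!r}")
        series = pd.to_numeric(self.data[variable])
        return series

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        df.index = df.index.astype(str)
        return cls(df)


def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums[sums >= depth].index
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    out = {}
    for sid in keep:
        row = table.data.loc[sid].to_numpy()
        total = int(row.sum())
        if total == depth:
            out[sid] = row.copy()
            continue
        # hypergeometric draw: choose `depth` of the `total` reads uniformly
        chosen = rng.choice(total, size=depth, replace=False)
        bounds = np.cumsum(row)
        otu_of_read = np.searchsorted(bounds, chosen, side="right")
        out[sid] = np.bincount(otu_of_read, minlength=table.n_otus)
    df = pd.DataFrame.from_dict(out, orient="index", dtype=np.int64)
    df = df.set_axis(table.otu_ids, axis=1)
    df = df.loc[[s for s in table.sample_ids if s in keep]]
    return OtuTable(df)


def filter_prevalence(table: OtuTable, min_fraction: float) -> OtuTable:
    """Keep OTUs detected in strictly more than ``min_fraction`` of samples."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    occ = (table.counts > 0).mean(axis=0)
    keep = occ > min_fraction
    return OtuTable(table.data.loc[:, keep].copy())


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-normalised proportions (each sample sums to 1)."""
    sums = table.data.sum(axis=1)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise DegenerateInputError(f"sample {bad!r} has zero total count")
    return table.data.div(sums, axis=0)


def geographic_distance(metadata: SampleMetadata) -> pd.DataFrame:
    """Pairwise great-circle (haversine) distances between samples, in km."""
    lat = metadata.numeric("latitude").to_numpy(dtype=float)
    lon = metadata.numeric("longitude").to_numpy(dtype=float)
    if not (np.isfinite(lat).all() and np.isfinite(lon).all()):
        raise ValueError("missing or non-finite coordinates")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2.0) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    ids = metadata.sample_ids
    return pd.DataFrame(d, index=ids, columns=ids)


def align_table_tree(table: OtuTable, tip_names) -> OtuTable:
    """Check every OTU in the table is a tree tip; return the table unchanged."""
    missing = sorted(set(table.otu_ids) - set(tip_names))
    if missing:
        raise ConsistencyError(
            f"{len(missing)} OTUs absent from the tree, e.g. {missing[:5]}")
    return table
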