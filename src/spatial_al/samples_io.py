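"""Georeferenced NDVI point samples: domain types, I/O and the parcel split.

A :class:`Sample` is a point in a projected (metric) coordinate system with a
parcel id, an ordered vector of monthly NDVI features and a class label (or
the sentinel ``"unlabeled"``). A :class:`SampleSet` is an ordered collection
of such points sharing a feature length; Euclidean distance on (x, y) is the
metric used everywhere downstream (variograms, spatial admissibility).

Coordinates are assumed to be already projected in meters; the package never
reprojects. CSV files are comma-separated with a header row and columns
``id, x, y, parcel_id, label, ndvi_01..ndvi_12`` (months are ordinal
positions, not dates). GeoJSON files are FeatureCollections of Point
features whose properties mirror the CSV columns.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: Label sentinel for samples whose class is not (yet) known.
UNLABELED = "unlabeled"

DEFAULT_MONTH_LABELS = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)


class SchemaError(ValueError):
    """A file or record does not match the documented sample schema."""


def ndvi(nir, red):
    """Normalized Difference Vegetation Index, (NIR − red) / (NIR + red).

    Accepts scalars or numpy arrays of non-negative reflectances; the result
    lies in [−1, 1]. Raises :class:`ValueError` when both inputs are zero
    anywhere (the index is undefined there).
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectances must be non-negative")
    total = nir + red
    if np.any(total == 0):
        raise ValueError("NDVI undefined where nir + red == 0")
    out = (nir - red) / total
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Sample:
    """One georeferenced point sample with monthly NDVI features."""

    id: str
    x: float
    y: float
    parcel_id: str
    features: tuple  # ordered monthly NDVI values
    label: str = UNLABELED

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(float(v) for v in self.features))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"sample {self.id!r}: non-finite coordinates")
        for v in self.features:
            if not math.isfinite(v) or not (-1.0 <= v <= 1.0):
                raise SchemaError(
                    f"sample {self.id!r}: NDVI value {v} outside [-1, 1]"
                )

    @property
    def labeled(self) -> bool:
        return self.label != UNLABELED


@dataclass
class SampleSet:
    """An ordered collection of samples sharing one feature length.

    Distances between samples are Euclidean distances of their projected
    (x, y) coordinates in meters — the metric used by the spatial filter.
    """

    samples: list = field(default_factory=list)
    crs_note: str = "projected, meters"
    month_labels: tuple = DEFAULT_MONTH_LABELS

    def __post_init__(self):
        self.samples = list(self.samples)
        self.month_labels = tuple(self.month_labels)
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate sample ids: {dup[:5]}")
        lengths = {len(s.features) for s in self.samples}
        if len(lengths) > 1:
            raise SchemaError(f"inconsistent feature lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __getitem__(self, key):
        return self.samples[key]

    @property
    def n_features(self) -> int:
        return len(self.samples[0].features) if self.samples else len(self.month_labels)

    @property
    def ids(self) -> list:
        return [s.id for s in self.samples]

    def by_id(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, ids: Iterable[str]) -> "SampleSet":
        wanted = set(ids)
        return SampleSet(
            [s for s in self.samples if s.id in wanted],
            crs_note=self.crs_note,
            month_labels=self.month_labels,
        )

    def coords(self) -> np.ndarray:
        """(n, 2) array of projected coordinates in meters."""
        return np.array([(s.x, s.y) for s in self.samples], dtype=float).reshape(-1, 2)

    def feature_matrix(self) -> np.ndarray:
        """(n, p) array of NDVI features."""
        return np.array([s.features for s in self.samples], dtype=float)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=object)

    def classes(self) -> list:
        return sorted({s.label for s in self.samples if s.label != UNLABELED})

    def to_frame(self) -> pd.DataFrame:
        p = self.n_features
        cols = {f"ndvi_{m + 1:02d}": [s.features[m] for s in self.samples] for m in range(p)}
        return pd.DataFrame(
            {
                "id": [s.id for s in self.samples],
                "x": [s.x for s in self.samples],
                "y": [s.y for s in self.samples],
                "parcel_id": [s.parcel_id for s in self.samples],
                "label": [s.label for s in self.samples],
                **cols,
            }
        )


_MANDATORY = ("id", "x", "y", "parcel_id")


def _samples_from_frame(df: pd.DataFrame) -> list:
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    ndvi_cols = sorted(c for c in df.columns if c.startswith("ndvi_"))
    if not ndvi_cols:
        raise SchemaError("no ndvi_* feature columns found")
    for c in ("x", "y", *ndvi_cols):
        if not pd.api.types.is_numeric_dtype(pd.to_numeric(df[c], errors="coerce")):
            raise SchemaError(f"non-numeric values in column {c!r}")
        if pd.to_numeric(df[c], errors="coerce").isna().any():
            raise SchemaError(f"non-numeric or missing values in column {c!r}")
    labels = (
        df["label"].astype(object).where(df["label"].notna(), UNLABELED)
        if "label" in df.columns
        else pd.Series([UNLABELED] * len(df))
    )
    samples = []
    for row, lab in zip(df.itertuples(index=False), labels):
        rec = row._asdict()
        lab = UNLABELED if (lab is None or str(lab).strip() == "") else str(lab)
        samples.append(
            Sample(
                id=str(rec["id"]),
                x=float(rec["x"]),
                y=float(rec["y"]),
                parcel_id=str(rec["parcel_id"]),
                features=tuple(float(rec[c]) for c in ndvi_cols),
                label=lab,
            )
        )
    return samples


def read_samples(path, format: str | None = None) -> SampleSet:
    """Read a :class:`SampleSet` from CSV or GeoJSON.

    ``format`` is inferred from the file suffix when omitted. Rows with a
    missing/empty label become ``"unlabeled"``. Schema violations (missing
    columns, non-numeric coordinates, duplicate ids, NDVI outside [−1, 1])
    raise :class:`SchemaError` naming the offending field.
    """
    path = Path(path)
    fmt = format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"id": str, "parcel_id": str})
        return SampleSet(_samples_from_frame(df))
    if fmt == "geojson":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise SchemaError("GeoJSON root must be a FeatureCollection")
        rows = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise SchemaError("only Point geometries are supported")
            props = dict(feat.get("properties") or {})
            props["x"], props["y"] = geom["coordinates"][:2]
            rows.append(props)
        df = pd.DataFrame(rows)
        return SampleSet(_samples_from_frame(df))
    raise ValueError(f"unknown format {fmt!r}")


def write_samples(sample_set: SampleSet, path, format: str | None = None) -> Path:
    """Write a :class:`SampleSet` to CSV or GeoJSON; inverse of
    :func:`read_samples` up to floating-point round-trip."""
    path = Path(path)
    fmt = format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")
    df = sample_set.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "geojson":
        feats = []
        for rec in df.to_dict(orient="records"):
            x, y = rec.pop("x"), rec.pop("y")
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [x, y]},
                    "properties": rec,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _largest_remainder_train_count(n_parcels: int, train_fraction: float) -> int:
    """Parcels assigned to train for one class: floor plus the leftover parcel
    going to the side with the larger fractional remainder; both sides keep at
    least one parcel when the class has ≥ 2."""
    exact_train = n_parcels * train_fraction
    exact_test = n_parcels * (1 - train_fraction)
    n_train = math.floor(exact_train)
    n_test = math.floor(exact_test)
    if n_train + n_test < n_parcels:  # one leftover parcel
        if (exact_train - n_train) >= (exact_test - n_test):
            n_train += 1
    if n_parcels >= 2:
        n_train = min(max(n_train, 1), n_parcels - 1)
    return n_train


def split_by_parcel(
    sample_set: SampleSet, train_fraction: float = 0.7, seed: int = 0
) -> tuple:
    """Parcel-disjoint, class-stratified train/test split.

    All points of a parcel move together so that the two sides are spatially
    independent at the parcel level. Per class, the fraction of parcels
    assigned to train approximates ``train_fraction`` (largest-remainder
    rounding, at least one parcel on each side when the class has ≥ 2
    parcels). A class with a single parcel goes entirely to train with a
    warning. Reproducible under ``seed``.
    """
    if not sample_set.samples:
        raise ValueError("cannot split an empty SampleSet")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie strictly between 0 and 1")

    # parcel -> majority class (synthetic parcels are single-class)
    by_parcel: dict = {}
    for s in sample_set:
        by_parcel.setdefault(s.parcel_id, []).append(s.label)
    parcel_class = {
        pid: max(set(labels), key=labels.count) for pid, labels in by_parcel.items()
    }
    by_class: dict = {}
    for pid, cls in parcel_class.items():
        by_class.setdefault(cls, []).append(pid)

    rng = np.random.default_rng(seed)
    train_parcels: set = set()
    for cls in sorted(by_class):
        parcels = sorted(by_class[cls])
        if len(parcels) == 1:
            warnings.warn(
                f"class {cls!r} has a single parcel; assigning it to train",
                stacklevel=2,
            )
            train_parcels.update(parcels)
            continue
        n_train = _largest_remainder_train_count(len(parcels), train_fraction)
        order = rng.permutation(len(parcels))
        train_parcels.update(parcels[i] for i in order[:n_train])

    train = [s for s in sample_set if s.parcel_id in train_parcels]
    test = [s for s in sample_set if s.parcel_id not in train_parcels]
    mk = lambda ss: SampleSet(ss, crs_note=sample_set.crs_note, month_labels=sample_set.month_labels)
    return mk(train), mk(test)
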