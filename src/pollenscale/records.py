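"""Pollen-record containers, CSV I/O, compositional transforms and filtering.

A pollen record is one site's time-ordered matrix of pollen counts: ``n``
dated sediment samples by ``p`` harmonized taxa, plus coordinates and
optional land-cover class labels.  Ages are calendar years BP (present =
1950 CE, larger = older; post-1950 samples carry negative ages).

Counts become an assemblage matrix of proportions (rows sum to 1) and are
square-root transformed before ordination, which damps the dominance of
abundant taxa and the interdependence of proportions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

#: Analysis window of the main variability analysis, years BP (closed).
ANALYSIS_WINDOW = (2000.0, 8000.0)

#: Longitude (degrees E) separating western from eastern Eurasia.
EURASIA_SPLIT_LON = 60.0


def infer_region(lon: float) -> str:
    """Coarse continental region from longitude.

    ``N_America`` for lon < -30, ``W_Eurasia`` for -30 <= lon < 60,
    ``E_Eurasia`` for lon >= 60.
    """
    if lon < -30.0:
        return "N_America"
    if lon < EURASIA_SPLIT_LON:
        return "W_Eurasia"
    return "E_Eurasia"


@dataclass
class PollenRecord:
    """One site's dated pollen count matrix with coordinates and metadata.

    Parameters
    ----------
    site_id : str
    lat, lon : float
        Decimal degrees; ``abs(lat) <= 90``.
    times : ndarray, shape (n,)
        Sample ages in years BP, strictly increasing.
    taxa : list of str
        Harmonized taxon names (length p).
    counts : ndarray, shape (n, p)
        Non-negative integer pollen counts; every row total positive.
    class_labels : dict, optional
        Site-level class labels, e.g. ``{"olson_class": ..., "cci_class": ...}``.
    meta : dict, optional
        Free-form metadata (synthetic ground truth lives here).
    """

    site_id: str
    lat: float
    lon: float
    times: np.ndarray
    taxa: list[str]
    counts: np.ndarray
    class_labels: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.ndim != 1 or self.times.size < 1:
            raise FormatError(f"{self.site_id}: need at least one sample")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError(f"{self.site_id}: ages must be strictly increasing")
        if self.counts.shape != (self.times.size, len(self.taxa)):
            raise FormatError(
                f"{self.site_id}: counts shape {self.counts.shape} does not match "
                f"{self.times.size} samples x {len(self.taxa)} taxa"
            )
        if np.any(self.counts < 0):
            raise FormatError(f"{self.site_id}: negative counts")
        totals = self.counts.sum(axis=1)
        if np.any(totals <= 0):
            bad = self.times[totals <= 0]
            raise FormatError(
                f"{self.site_id}: zero total count at age(s) {bad.tolist()}"
            )
        if abs(self.lat) > 90:
            raise FormatError(f"{self.site_id}: latitude {self.lat} out of range")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def region(self) -> str:
        return infer_region(self.lon)

    def subset_window(self, window: tuple[float, float]) -> "PollenRecord | None":
        """Samples with age in the closed window, or None if empty."""
        lo, hi = sorted(window)
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            return None
        return replace(self, times=self.times[mask], counts=self.counts[mask])

    def equals(self, other: "PollenRecord") -> bool:
        return (
            self.site_id == other.site_id
            and np.isclose(self.lat, other.lat)
            and np.isclose(self.lon, other.lon)
            and list(self.taxa) == list(other.taxa)
            and np.allclose(self.times, other.times)
            and np.array_equal(np.asarray(self.counts), np.asarray(other.counts))
            and self.class_labels == other.class_labels
        )


@dataclass
class AssemblageMatrix:
    """n x p compositional matrix with an explicit transform state."""

    values: np.ndarray
    transform_state: str  # "proportion" | "sqrt_proportion"
    taxa: list[str]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.transform_state not in ("proportion", "sqrt_proportion"):
            raise FormatError(f"unknown transform_state {self.transform_state!r}")
        if np.any(self.values < 0):
            raise FormatError("assemblage values must be non-negative")


REQUIRED_COUNT_COLS = ("site_id", "age_bp", "taxon", "count")
REQUIRED_META_COLS = ("site_id", "lat", "lon")


def load_records(
    counts_path,
    meta_path,
    taxon_map: dict[str, str] | None = None,
) -> list[PollenRecord]:
    """Read long-format counts and site metadata CSVs into records.

    ``counts_path`` columns: site_id, age_bp, taxon, count.
    ``meta_path`` columns: site_id, lat, lon, plus optional class-label
    columns that are attached verbatim to ``class_labels``.

    Duplicate (site, age, taxon) rows are summed with a logged warning.
    When ``taxon_map`` is given, counts of synonyms are summed under the
    harmonized name before pivoting.
    """
    counts = pd.read_csv(counts_path)
    meta = pd.read_csv(meta_path)
    for col in REQUIRED_COUNT_COLS:
        if col not in counts.columns:
            raise FormatError(f"counts table missing required column {col!r}")
    for col in REQUIRED_META_COLS:
        if col not in meta.columns:
            raise FormatError(f"metadata table missing required column {col!r}")

    counts = counts.copy()
    counts["site_id"] = counts["site_id"].astype(str)
    meta = meta.copy()
    meta["site_id"] = meta["site_id"].astype(str)

    if taxon_map:
        counts["taxon"] = counts["taxon"].map(lambda t: taxon_map.get(t, t))

    dup = counts.duplicated(subset=["site_id", "age_bp", "taxon"])
    if dup.any():
        logger.warning("summed %d duplicate (site, age, taxon) rows", int(dup.sum()))
    counts = (
        counts.groupby(["site_id", "age_bp", "taxon"], sort=True)["count"]
        .sum()
        .reset_index()
    )

    missing = sorted(set(counts["site_id"]) - set(meta["site_id"]))
    if missing:
        raise FormatError(f"sites present in counts but absent from metadata: {missing}")

    meta_idx = meta.set_index("site_id")
    class_cols = [c for c in meta.columns if c not in REQUIRED_META_COLS]

    records = []
    for site_id, grp in counts.groupby("site_id", sort=True):
        wide = (
            grp.pivot_table(index="age_bp", columns="taxon", values="count",
                            aggfunc="sum", fill_value=0)
            .sort_index()
        )
        row = meta_idx.loc[site_id]
        labels = {c: row[c] for c in class_cols if pd.notna(row[c])}
        records.append(
            PollenRecord(
                site_id=str(site_id),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                times=wide.index.to_numpy(dtype=float),
                taxa=[str(t) for t in wide.columns],
                counts=wide.to_numpy(),
                class_labels=labels,
            )
        )
    return records


def write_records(records: list[PollenRecord], counts_path, meta_path) -> None:
    """Emit the same long-format schema :func:`load_records` consumes."""
    count_rows, meta_rows = [], []
    for rec in records:
        for i, age in enumerate(rec.times):
            for j, taxon in enumerate(rec.taxa):
                c = rec.counts[i, j]
                if c > 0:
                    count_rows.append((rec.site_id, age, taxon, c))
        meta_rows.append({"site_id": rec.site_id, "lat": rec.lat, "lon": rec.lon,
                          **rec.class_labels})
    pd.DataFrame(count_rows, columns=list(REQUIRED_COUNT_COLS)).to_csv(
        counts_path, index=False
    )
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


def to_proportions(record: PollenRecord) -> AssemblageMatrix:
    """Divide each sample's counts by its total so rows sum to 1."""
    totals = record.counts.sum(axis=1, dtype=float)
    if np.any(totals <= 0):
        bad = record.times[totals <= 0]
        raise DegenerateInputError(
            f"{record.site_id}: zero total count at age(s) {bad.tolist()}"
        )
    return AssemblageMatrix(
        values=record.counts / totals[:, None],
        transform_state="proportion",
        taxa=list(record.taxa),
        times=record.times.copy(),
    )


def sqrt_transform(assemblage: AssemblageMatrix) -> AssemblageMatrix:
    """Element-wise square root of a proportion matrix.

    Squared row sums remain 1; applying the transform twice is an error.
    """
    if assemblage.transform_state != "proportion":
        raise FormatError(
            f"sqrt_transform expects proportions, got {assemblage.transform_state!r}"
        )
    return AssemblageMatrix(
        values=np.sqrt(assemblage.values),
        transform_state="sqrt_proportion",
        taxa=list(assemblage.taxa),
        times=assemblage.times.copy(),
    )


@dataclass
class FilterReport:
    n_input: int
    n_fail_lat: int
    n_fail_min_samples: int
    n_kept: int


def filter_records(
    records: list[PollenRecord],
    min_samples: int = 6,
    min_lat: float = 25.0,
    window: tuple[float, float] = ANALYSIS_WINDOW,
) -> tuple[list[PollenRecord], FilterReport]:
    """Record-selection rules of the main analysis.

    Samples outside the closed age window are dropped first; a record is
    then kept when it retains at least ``min_samples`` samples and lies
    strictly north of ``min_lat``.  Failure counts per rule are tallied
    independently (a record can fail both).
    """
    kept = []
    n_fail_lat = n_fail_samples = 0
    for rec in records:
        trimmed = rec.subset_window(window)
        fail_lat = rec.lat <= min_lat
        fail_samples = trimmed is None or trimmed.n_samples < min_samples
        n_fail_lat += fail_lat
        n_fail_samples += fail_samples
        if not fail_lat and not fail_samples:
            kept.append(trimmed)
    report = FilterReport(
        n_input=len(records),
        n_fail_lat=n_fail_lat,
        n_fail_min_samples=n_fail_samples,
        n_kept=len(kept),
    )
    logger.info(
        "filter_records: %d in, %d fail latitude, %d fail min-samples, %d kept",
        report.n_input, report.n_fail_lat, report.n_fail_min_samples, report.n_kept,
    )
    return kept, report


def align_on_union(vectors: dict[str, pd.Series]) -> pd.DataFrame:
    """Align per-key taxon vectors on the union taxon list, zero-filled."""
    return pd.DataFrame(vectors).T.fillna(0.0)
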