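"""Turn raw fossil occurrence tables into per-class capture histories.

The raw inputs are (a) an occurrence table in the Paleobiology Database
download dialect — one row per fossil occurrence with genus, class, an
early/late interval assignment and modern plus palaeo coordinates — and
(b) a genus trait table with log10 biovolume (mm^3).  The pipeline:

1. resolve each occurrence to a single geologic stage (rows whose early
   and late intervals name the same stage in the stage table);
2. elevate subgenera to genus rank;
3. filter: keep occurrences of genera that have a body-size trait and at
   least one stage-resolved occurrence inside the analysis window
   (Ordovician or younger; Cambrian data are excluded), then keep only
   classes with at least ``min_genera`` such genera;
4. per genus x stage, compute the maximum great-circle distance (km)
   between its occurrences (the time-varying geographical-range proxy);
   stages in the genus's stratigraphic range with <= 1 occurrence get a
   nominal 1 km range before the log10 transform;
5. standardize: body size to a z-score within class, log10 range to a
   z-score within class x stage;
6. encode each genus as a binary detection vector over its class's stage
   window, with the size and range covariates alongside.

All operations work on pandas DataFrames with the canonical columns
``genus, subgenus, class_name, stage_name, stage_index, lng, lat,
paleo_lng, paleo_lat``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .timescale import StageTable

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "CaptureHistory",
    "CaptureHistorySet",
    "read_occurrences",
    "elevate_subgenera",
    "apply_study_filters",
    "max_great_circle_km",
    "build_stage_ranges",
    "standardize",
    "build_capture_histories",
    "prepare_class_histories",
]

EARTH_RADIUS_KM = 6371.0

#: default column mapping for PBDB occurrence downloads
DEFAULT_COLUMN_MAP = {
    "genus": "genus",
    "subgenus": "subgenus",
    "class_name": "class",
    "early_interval": "early_interval",
    "late_interval": "late_interval",
    "lng": "lng",
    "lat": "lat",
    "paleo_lng": "paleolng",
    "paleo_lat": "paleolat",
}

_SUBGENUS_RE = re.compile(r"^\s*(\S+)\s*\(\s*([^)]+?)\s*\)\s*$")


@dataclass(frozen=True)
class CaptureHistory:
    """Detection vector plus covariates for one genus.

    ``detections`` is 0/1 over the class's analysis stages; ``z_size`` is
    the class-standardized log10 biovolume; ``z_range_series`` gives the
    class-x-stage-standardized log10 geographical range at every occasion
    (outside the observed span it carries the standardized 1 km value).
    """

    genus: str
    class_name: str
    detections: np.ndarray
    z_size: float
    z_range_series: np.ndarray

    def __post_init__(self) -> None:
        if self.detections.sum() < 1:
            raise ValueError(f"{self.genus}: capture history has no detections")
        if len(self.detections) != len(self.z_range_series):
            raise ValueError(f"{self.genus}: covariate/detection length mismatch")


@dataclass
class CaptureHistorySet:
    """All capture histories of one class over a shared stage window.

    Array layout used by the likelihood: ``detections`` (n, T) 0/1,
    ``z_size`` (n,), ``z_range`` (n, T).  ``stage_table`` is the window's
    (re-indexed) stage table; ``window_start`` is the 1-based index of the
    window's first stage in the full table.
    """

    class_name: str
    genera: list[str]
    detections: np.ndarray
    z_size: np.ndarray
    z_range: np.ndarray
    stage_table: StageTable
    window_start: int = 1

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    @property
    def n_occasions(self) -> int:
        return self.detections.shape[1]

    def __iter__(self):
        for i, g in enumerate(self.genera):
            yield CaptureHistory(
                genus=g,
                class_name=self.class_name,
                detections=self.detections[i],
                z_size=float(self.z_size[i]),
                z_range_series=self.z_range[i],
            )


def read_occurrences(
    path,
    stage_table: StageTable,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a PBDB-dialect occurrence CSV into canonical columns.

    ``stage_name`` is set only when the early and late intervals name the
    same stage present in ``stage_table`` (a blank late interval counts as
    equal to the early one, as in PBDB downloads).  Unresolved rows are
    kept with an empty ``stage_name`` and counted in a log summary.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["genus", "class_name", "early_interval", "lng", "lat"]
    missing = [k for k in required if cmap[k] not in raw.columns]
    if missing:
        raise ValueError(
            f"occurrence file {path}: unmapped required columns "
            f"{[cmap[k] for k in missing]}"
        )
    return _canonicalize(raw, cmap, stage_table)


def occurrences_from_frame(
    raw: pd.DataFrame,
    stage_table: StageTable,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """As :func:`read_occurrences` but from an in-memory PBDB-dialect frame."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    return _canonicalize(raw.astype(str), cmap, stage_table)


def _canonicalize(
    raw: pd.DataFrame, cmap: dict[str, str], stage_table: StageTable
) -> pd.DataFrame:
    df = pd.DataFrame()
    for canon in (
        "genus",
        "subgenus",
        "class_name",
        "early_interval",
        "late_interval",
    ):
        src = cmap.get(canon)
        df[canon] = (
            raw[src].astype(str).str.strip() if src in raw.columns else ""
        )
    for canon in ("lng", "lat", "paleo_lng", "paleo_lat"):
        src = cmap.get(canon)
        if src in raw.columns:
            df[canon] = pd.to_numeric(raw[src], errors="coerce")
        else:
            df[canon] = np.nan
    bad_lng = df["lng"].abs() > 180
    bad_lat = df["lat"].abs() > 90
    if (bad_lng | bad_lat).any():
        raise ValueError(
            f"{int((bad_lng | bad_lat).sum())} rows with coordinates outside "
            "[-180,180]x[-90,90]"
        )

    late = df["late_interval"].where(df["late_interval"] != "", df["early_interval"])
    known = set(stage_table.names)
    resolved = (df["early_interval"] == late) & df["early_interval"].isin(known)
    df["stage_name"] = df["early_interval"].where(resolved, "")
    idx_map = {name: stage_table.index_of(name) for name in known}
    df["stage_index"] = df["stage_name"].map(idx_map).astype("Int64")
    n_unresolved = int((~resolved).sum())
    if n_unresolved:
        logger.info(
            "read_occurrences: %d of %d rows not resolved to a single stage "
            "in the table (will drop at filtering)",
            n_unresolved,
            len(df),
        )
    return df.drop(columns=["early_interval", "late_interval"])


def elevate_subgenera(records: pd.DataFrame) -> pd.DataFrame:
    """Elevate subgenera to genus rank.

    Accepts either a populated ``subgenus`` column or the
    ``"Genus (Subgenus)"`` pattern in the genus name; the operating genus
    name becomes the subgenus name.  Distinct names may merge; merges are
    logged, not prevented.
    """
    df = records.copy()
    genus = df["genus"].astype(str)
    m = genus.str.extract(_SUBGENUS_RE, expand=True)
    from_pattern = m[1].fillna("")
    sub = df["subgenus"].astype(str).str.strip() if "subgenus" in df else ""
    sub = pd.Series(sub, index=df.index).where(lambda s: s != "", from_pattern)
    new_genus = sub.where(sub != "", genus.where(m[0].isna(), m[0]))
    # rows with the parenthetical pattern but no usable subgenus keep the
    # outer genus name (m[0]); plain names pass through untouched
    n_changed = int((new_genus != genus).sum())
    before, after = genus.nunique(), new_genus.nunique()
    if n_changed:
        logger.info(
            "elevate_subgenera: %d rows renamed; %d -> %d distinct genera",
            n_changed,
            before,
            after,
        )
    df["genus"] = new_genus
    return df


def apply_study_filters(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    stage_table: StageTable,
    min_genera: int = 500,
) -> pd.DataFrame:
    """Apply the analysis filters; tallies per rule are logged.

    Keeps occurrences that are stage-resolved within the table's window and
    belong to a genus with a body-size trait; then keeps only classes whose
    surviving genus count is at least ``min_genera``.  The end state is
    independent of rule order.  Raises when nothing survives.
    """
    tally: dict[str, int] = {}
    df = records
    n0 = len(df)

    has_stage = df["stage_index"].notna()
    tally["not_stage_resolved"] = int((~has_stage).sum())
    df = df[has_stage]

    trait_genera = set(traits["genus"])
    has_trait = df["genus"].isin(trait_genera)
    tally["no_body_size_trait"] = int((~has_trait).sum())
    df = df[has_trait]

    counts = df.groupby("class_name")["genus"].nunique()
    small = set(counts[counts < min_genera].index)
    in_small = df["class_name"].isin(small)
    tally[f"class_below_{min_genera}_genera"] = int(in_small.sum())
    df = df[~in_small]

    for rule, n in tally.items():
        logger.info("filter %-28s removed %d occurrences", rule, n)
    logger.info("filters: %d of %d occurrences retained", len(df), n0)
    if df.empty:
        raise ValueError(
            "no occurrences survive the study filters; review min_genera, "
            "the trait table, and the stage-table window"
        )
    return df.reset_index(drop=True)


def max_great_circle_km(points: np.ndarray) -> float:
    """Maximum pairwise great-circle distance (km) between (lng, lat) points.

    Spherical Earth of radius 6371.0 km.  Callers handle the degenerate
    <2-distinct-points case (the 1 km rule); here it is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (m, 2) array of (lng, lat)")
    if np.any(np.abs(pts[:, 0]) > 180) or np.any(np.abs(pts[:, 1]) > 90):
        raise ValueError("coordinates outside [-180,180]x[-90,90]")
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need at least 2 distinct points")
    latlng_rad = np.radians(pts[:, ::-1])
    d = haversine_distances(latlng_rad) * EARTH_RADIUS_KM
    return float(d.max())


def _distinct_points(pts: np.ndarray, decimals: int = 4) -> np.ndarray:
    """Distinct coordinates after rounding to PBDB precision (4 decimals)."""
    pts = pts[~np.isnan(pts).any(axis=1)]
    if len(pts) == 0:
        return pts
    return np.unique(np.round(pts, decimals), axis=0)


def _pairwise_max_km(pts: np.ndarray) -> float:
    """Batch-path maximum pairwise haversine distance (km).

    Lightweight equivalent of :func:`max_great_circle_km` for the inner
    loop over thousands of genus-stage cells; equality with the public
    routine is property-tested.
    """
    lng = np.radians(pts[:, 0])
    lat = np.radians(pts[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlng = lng[:, None] - lng[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlng / 2.0) ** 2
    )
    return float(
        2.0 * EARTH_RADIUS_KM * np.max(np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))
    )


def build_stage_ranges(
    records: pd.DataFrame,
    stage_table: StageTable,
    coord_mode: str = "paleo",
) -> pd.DataFrame:
    """Per genus x stage geographic range over each genus's observed span.

    For every stage from a genus's first to last detected stage inclusive:
    the maximum great-circle distance when the stage holds >= 2 distinct
    occurrence points, else the nominal 1 km (so log10 range = 0).
    ``coord_mode`` selects palaeocoordinates (with modern fallback where
    missing) or modern coordinates.
    """
    if coord_mode not in ("paleo", "modern"):
        raise ValueError("coord_mode must be 'paleo' or 'modern'")
    df = records.copy()
    if coord_mode == "paleo":
        df["x"] = df["paleo_lng"].fillna(df["lng"])
        df["y"] = df["paleo_lat"].fillna(df["lat"])
    else:
        df["x"] = df["lng"]
        df["y"] = df["lat"]
    df["stage_index"] = df["stage_index"].astype(int)

    # numpy-side cell loop: sort once, slice per (class, genus, stage)
    order = df.sort_values(["class_name", "genus", "stage_index"], kind="mergesort")
    cls_arr = order["class_name"].to_numpy()
    gen_arr = order["genus"].to_numpy()
    stg_arr = order["stage_index"].to_numpy()
    xy = order[["x", "y"]].to_numpy(float)

    keys = pd.MultiIndex.from_arrays([cls_arr, gen_arr, stg_arr])
    starts = np.flatnonzero(np.r_[True, keys[1:] != keys[:-1]])
    bounds = np.r_[starts, len(order)]

    occ_cells: dict[tuple, tuple[int, float]] = {}
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        pts = _distinct_points(xy[b0:b1])
        gcd = _pairwise_max_km(pts) if len(pts) >= 2 else 1.0
        occ_cells[(cls_arr[b0], gen_arr[b0], int(stg_arr[b0]))] = (
            int(b1 - b0),
            gcd,
        )

    spans = df.groupby(["class_name", "genus"])["stage_index"].agg(["min", "max"])
    rows = []
    for (cls, genus), (first, last) in spans.iterrows():
        for s in range(int(first), int(last) + 1):
            n_occ, gcd = occ_cells.get((cls, genus, s), (0, 1.0))
            rows.append((cls, genus, s, n_occ, gcd, np.log10(gcd)))
    return pd.DataFrame(
        rows,
        columns=["class_name", "genus", "stage_index", "n_occ", "gcd_km", "log_range"],
    )


def standardize(
    traits: pd.DataFrame, ranges: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add z-scores: size within class, log range within class x stage.

    Standard deviations use denominator n-1.  A class x stage cell with
    zero variance (or a single row) gets z = 0 for all its rows, with a
    warning in the log.
    """
    traits = traits.copy()

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(0.0, index=x.index)
        return (x - x.mean()) / sd

    traits["z_size"] = traits.groupby("class_name")["log_size"].transform(_z)

    ranges = ranges.copy()
    n_degenerate = 0

    def _z_cell(x: pd.Series) -> pd.Series:
        nonlocal n_degenerate
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            n_degenerate += 1
            return pd.Series(0.0, index=x.index)
        return (x - x.mean()) / sd

    ranges["z_range"] = ranges.groupby(["class_name", "stage_index"])[
        "log_range"
    ].transform(_z_cell)
    if n_degenerate:
        logger.warning(
            "standardize: %d class x stage cells with zero variance; their "
            "z_range set to 0",
            n_degenerate,
        )
    return traits, ranges


def build_capture_histories(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    ranges: pd.DataFrame,
    stage_table: StageTable,
    per_class_window: bool = True,
) -> dict[str, CaptureHistorySet]:
    """Assemble per-class capture-history sets from filtered inputs.

    Detection is 1 iff the genus has >= 1 stage-resolved occurrence in the
    stage.  ``z_range`` is defined at every occasion: inside the observed
    span from the standardized stage ranges (which apply the nominal-1 km
    rule to unsampled span stages); outside the span, the neutral class x
    stage mean (z = 0).  A genus carries no range information before its
    first or after its last record, and the likelihood's origination and
    ascertainment terms do evaluate survival odds there — carrying the
    1 km minimum into those occasions would paint every pre-appearance
    interval as survived-at-minimum-range and systematically distort the
    range coefficient.  The window is the class's observed stage span
    when ``per_class_window``, else the full table.
    """
    trait_z = traits.set_index(["class_name", "genus"])["z_size"]
    out: dict[str, CaptureHistorySet] = {}
    for cls, cls_rec in records.groupby("class_name", sort=True):
        s_min = int(cls_rec["stage_index"].min()) if per_class_window else 1
        s_max = (
            int(cls_rec["stage_index"].max())
            if per_class_window
            else len(stage_table)
        )
        T = s_max - s_min + 1
        window = stage_table.subset(s_min, s_max)

        genera = sorted(cls_rec["genus"].unique())
        det = np.zeros((len(genera), T), dtype=np.int8)
        zr = np.zeros((len(genera), T))
        zs = np.zeros(len(genera))
        gidx = {g: i for i, g in enumerate(genera)}
        for (g, s), _ in cls_rec.groupby(["genus", "stage_index"]):
            det[gidx[g], int(s) - s_min] = 1
        cls_ranges = ranges[ranges["class_name"] == cls]
        for row in cls_ranges.itertuples():
            i = gidx.get(row.genus)
            t = int(row.stage_index) - s_min
            if i is not None and 0 <= t < T:
                zr[i, t] = row.z_range
        for g, i in gidx.items():
            zs[i] = trait_z.loc[(cls, g)]

        keep = det.sum(axis=1) >= 1
        if not keep.all():
            logger.info(
                "class %s: %d genera with zero detections excluded",
                cls,
                int((~keep).sum()),
            )
        out[cls] = CaptureHistorySet(
            class_name=cls,
            genera=[g for g, k in zip(genera, keep) if k],
            detections=det[keep],
            z_size=zs[keep],
            z_range=zr[keep],
            stage_table=window,
            window_start=s_min,
        )
    return out


def prepare_class_histories(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    stage_table: StageTable,
    min_genera: int = 500,
    coord_mode: str = "paleo",
    per_class_window: bool = True,
) -> dict[str, CaptureHistorySet]:
    """Full preparation pipeline: filters -> ranges -> z-scores -> histories."""
    rec = elevate_subgenera(records)
    traits = traits.copy()
    if "log_size" not in traits.columns:
        traits = traits.rename(columns={"log10_volume_mm3": "log_size"})
    if "class_name" not in traits.columns:
        traits = traits.rename(columns={"class": "class_name"})
    rec = apply_study_filters(rec, traits, stage_table, min_genera=min_genera)
    kept = rec[["class_name", "genus"]].drop_duplicates()
    traits = traits.merge(kept, on=["class_name", "genus"])
    ranges = build_stage_ranges(rec, stage_table, coord_mode=coord_mode)
    traits, ranges = standardize(traits, ranges)
    return build_capture_histories(
        rec, traits, ranges, stage_table, per_class_window=per_class_window
    )
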