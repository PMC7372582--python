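"""Per-cell features -> normalized, feature-selected, well-level profiles.

The pipeline order is fixed and mirrors standard image-based-profiling
practice:

1. aggregate cells to images (median per feature per image site);
2. QC-filter images (cell count below threshold, or flagged low quality);
3. normalize plate-by-plate by dividing each feature by the plate's
   median DMSO response;
4. feature selection: drop features with missing values, with zero or
   near-zero variance, then greedily eliminate one member of every feature
   pair correlated above the cutoff;
5. scale globally to zero mean and unit SD per feature;
6. aggregate images to wells (median over a well's surviving images) and
   join compound / concentration / role metadata from the plate map.

Steps 3-5 are exposed as sklearn-style transformers so they can be fitted
on one set of profiles and applied to another; the module-level functions
are thin wrappers for the common fit-and-transform-in-place case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler

from phenoscreen.synth import META_COLUMNS

__all__ = [
    "feature_columns",
    "aggregate_cells_to_images",
    "qc_filter_images",
    "DmsoNormalizer",
    "normalize_to_dmso",
    "FeatureSelector",
    "select_features",
    "GlobalScaler",
    "scale_features",
    "aggregate_images_to_wells",
    "profile_cell_line",
    "PreprocessReport",
]


def feature_columns(df: pd.DataFrame) -> list[str]:
    """All columns of ``df`` that are not known metadata columns."""
    return [c for c in df.columns if c not in META_COLUMNS]


@dataclass
class PreprocessReport:
    """Per-stage bookkeeping for one preprocessing run."""

    n_cells: int = 0
    n_images: int = 0
    n_images_removed: int = 0
    removed_images: list[dict] = field(default_factory=list)
    dropped_features: list[tuple[str, str]] = field(default_factory=list)
    empty_wells: list[tuple[str, str]] = field(default_factory=list)
    n_wells: int = 0

    def to_text(self) -> str:
        lines = [
            f"cells: {self.n_cells}",
            f"images: {self.n_images} ({self.n_images_removed} removed by QC)",
            f"features dropped: {len(self.dropped_features)}",
            f"wells: {self.n_wells} ({len(self.empty_wells)} wells lost all images)",
        ]
        for feat, reason in self.dropped_features:
            lines.append(f"- dropped {feat}: {reason}")
        for rec in self.removed_images:
            lines.append(f"- removed image {rec}")
        return "\n".join(lines) + "\n"


def _grouped_median(df: pd.DataFrame, keys: list[str], feats: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-group median over feature columns (NaN-ignoring), plus group sizes."""
    codes, key_frame = pd.factorize(pd.MultiIndex.from_frame(df[keys]), sort=True)
    order = np.argsort(codes, kind="stable")
    values = df[feats].to_numpy()[order]
    bounds = np.searchsorted(codes[order], np.arange(len(key_frame) + 1))
    median = np.nanmedian if np.isnan(values).any() else np.median
    medians = np.empty((len(key_frame), len(feats)))
    for g in range(len(key_frame)):
        medians[g] = median(values[bounds[g] : bounds[g + 1]], axis=0)
    sizes = np.diff(bounds)
    out = key_frame.to_frame(index=False)
    out.columns = keys
    return pd.concat([out, pd.DataFrame(medians, columns=feats)], axis=1), sizes


def aggregate_cells_to_images(cells: pd.DataFrame) -> pd.DataFrame:
    """Median of every feature over the cells of each image site.

    Returns one row per (plate, well, site) — plus cell_line when present —
    with ``n_cells`` set to the number of aggregated rows.  Missing values
    are ignored by the median.
    """
    if cells.empty:
        raise ValueError("cell feature table is empty")
    keys = [k for k in ("cell_line", "plate", "well", "site") if k in cells.columns]
    feats = feature_columns(cells)
    out, sizes = _grouped_median(cells, keys, feats)
    out.insert(len(keys), "n_cells", sizes)
    return out


def qc_filter_images(
    images: pd.DataFrame,
    min_cells: int = 20,
    quality_flags: set[tuple] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove image profiles failing QC; returns (kept, removal log).

    An image is removed when its cell count is strictly below ``min_cells``
    (a count of exactly ``min_cells`` is kept) or when its
    (plate, well, site) key appears in ``quality_flags``.  Removing every
    image of a well is permitted; the loss surfaces at well aggregation.
    """
    flags = quality_flags or set()
    removed: list[dict] = []
    keep = np.ones(len(images), dtype=bool)
    for i, row in enumerate(images.itertuples(index=False)):
        key = (row.plate, row.well, row.site)
        if row.n_cells < min_cells:
            keep[i] = False
            removed.append({"plate": row.plate, "well": row.well, "site": row.site, "reason": f"n_cells={row.n_cells} < {min_cells}"})
        elif key in flags:
            keep[i] = False
            removed.append({"plate": row.plate, "well": row.well, "site": row.site, "reason": "quality flag"})
    return images.loc[keep].reset_index(drop=True), removed


class DmsoNormalizer(BaseEstimator, TransformerMixin):
    """Plate-wise division of each feature by the plate's median DMSO response.

    Fitting computes, per plate, the median of every feature over that
    plate's surviving DMSO image profiles.  A plate without surviving DMSO
    images is a hard error.  Features whose DMSO median is zero on any
    plate cannot be safely divided and are dropped (recorded in
    ``dropped_features_``).

    Parameters
    ----------
    platemap : DataFrame with plate, well, compound, concentration, role.
    """

    def __init__(self, platemap: pd.DataFrame):
        self.platemap = platemap

    def fit(self, X: pd.DataFrame, y=None):
        feats = feature_columns(X)
        pm = self.platemap
        dmso_wells = pm.loc[pm["role"] == "vehicle_control", ["plate", "well"]]
        dmso_keys = set(map(tuple, dmso_wells.to_numpy()))
        is_dmso = [(p, w) in dmso_keys for p, w in zip(X["plate"], X["well"])]
        dmso = X.loc[is_dmso]
        medians = {}
        for plate in X["plate"].unique():
            sub = dmso[dmso["plate"] == plate]
            if sub.empty:
                raise ValueError(f"plate {plate} has no surviving DMSO image profiles; cannot normalize")
            medians[plate] = sub[feats].median()
        med = pd.DataFrame(medians).T
        med.index.name = "plate"
        zero = med.columns[(med == 0).any(axis=0)]
        self.dropped_features_ = [(f, "zero DMSO median") for f in zero]
        self.feature_names_ = [f for f in feats if f not in set(zero)]
        self.medians_ = med[self.feature_names_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        unknown = set(X["plate"]) - set(self.medians_.index)
        if unknown:
            raise ValueError(f"plates not seen at fit time: {sorted(unknown)}")
        meta = [c for c in X.columns if c in META_COLUMNS]
        denom = self.medians_.loc[X["plate"]].to_numpy()
        values = X[self.feature_names_].to_numpy(dtype=np.float64) / denom
        out = X[meta].reset_index(drop=True)
        return pd.concat([out, pd.DataFrame(values, columns=self.feature_names_)], axis=1)


def normalize_to_dmso(images: pd.DataFrame, platemap: pd.DataFrame) -> tuple[pd.DataFrame, DmsoNormalizer]:
    norm = DmsoNormalizer(platemap).fit(images)
    return norm.transform(images), norm


class FeatureSelector(BaseEstimator, TransformerMixin):
    """Missing-value, near-zero-variance and pairwise-correlation filtering.

    Drops, in order:

    1. features with any missing value;
    2. features with exactly zero variance, or near-zero variance — the
       ratio of the most frequent value's count to the second-most
       frequent's is >= ``nzv_freq_cut`` AND the fraction of distinct
       values is <= ``nzv_unique_cut`` (the conventional 95/5 and 10%
       defaults);
    3. one member of every remaining feature pair with |Pearson r| >
       ``corr_cutoff``: repeatedly take the most-correlated violating
       pair and discard its member with the larger mean absolute
       correlation to all remaining features, ties broken by reverse
       lexicographic feature name for determinism.

    The fitted ``report_`` lists every dropped feature with its reason.
    Selection is idempotent: transforming already-selected data and
    refitting yields the same feature set.
    """

    def __init__(self, nzv_freq_cut: float = 95.0 / 5.0, nzv_unique_cut: float = 0.1, corr_cutoff: float = 0.95):
        self.nzv_freq_cut = nzv_freq_cut
        self.nzv_unique_cut = nzv_unique_cut
        self.corr_cutoff = corr_cutoff

    def fit(self, X: pd.DataFrame, y=None):
        feats = feature_columns(X)
        data = X[feats]
        report: list[tuple[str, str]] = []

        has_na = data.columns[data.isna().any(axis=0)]
        report += [(f, "missing values") for f in has_na]
        data = data.drop(columns=list(has_na))

        nzv = [f for f in data.columns if self._near_zero_variance(data[f].to_numpy())]
        report += [(f, "zero or near-zero variance") for f in nzv]
        data = data.drop(columns=nzv)

        kept, corr_dropped = self._correlation_filter(data)
        report += [(f, f"|r| > {self.corr_cutoff} with {partner}") for f, partner in corr_dropped]

        if len(kept) < 2:
            raise ValueError(f"feature selection left {len(kept)} features; need at least 2")
        self.feature_names_ = kept
        self.report_ = report
        return self

    def _near_zero_variance(self, x: np.ndarray) -> bool:
        values, counts = np.unique(x[~np.isnan(x)], return_counts=True)
        if len(values) <= 1:
            return True  # constant (zero variance)
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_fraction = len(values) / len(x)
        return freq_ratio >= self.nzv_freq_cut and unique_fraction <= self.nzv_unique_cut

    def _correlation_filter(self, data: pd.DataFrame) -> tuple[list[str], list[tuple[str, str]]]:
        names = list(data.columns)
        if len(names) < 2:
            return names, []
        corr = np.abs(np.corrcoef(data.to_numpy(dtype=np.float64), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        alive = dict.fromkeys(names, True)
        idx = {f: i for i, f in enumerate(names)}
        dropped: list[tuple[str, str]] = []
        while True:
            live = [f for f in names if alive[f]]
            li = [idx[f] for f in live]
            sub = corr[np.ix_(li, li)]
            if sub.size == 0 or sub.max() <= self.corr_cutoff:
                break
            a, b = np.unravel_index(np.argmax(sub), sub.shape)
            fa, fb = live[a], live[b]
            mean_a = sub[a].sum() / (len(live) - 1)
            mean_b = sub[b].sum() / (len(live) - 1)
            if mean_a > mean_b:
                victim, partner = fa, fb
            elif mean_b > mean_a:
                victim, partner = fb, fa
            else:  # deterministic tie-break on the name
                victim, partner = (fb, fa) if fb > fa else (fa, fb)
            alive[victim] = False
            dropped.append((victim, partner))
        return [f for f in names if alive[f]], dropped

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.feature_names_ if f not in X.columns]
        if missing:
            raise ValueError(f"input lacks selected features: {missing}")
        meta = [c for c in X.columns if c in META_COLUMNS]
        return X[meta + self.feature_names_].copy()


def select_features(
    profiles: pd.DataFrame,
    nzv_freq_cut: float = 95.0 / 5.0,
    nzv_unique_cut: float = 0.1,
    corr_cutoff: float = 0.95,
) -> tuple[pd.DataFrame, FeatureSelector]:
    sel = FeatureSelector(nzv_freq_cut, nzv_unique_cut, corr_cutoff).fit(profiles)
    return sel.transform(profiles), sel


class GlobalScaler(BaseEstimator, TransformerMixin):
    """Global z-transform: subtract each feature's mean, divide by its SD.

    SD is the population standard deviation over the fitted profiles.  A
    zero-variance feature reaching this stage is a hard error — it should
    have been removed by :class:`FeatureSelector`.
    """

    def fit(self, X: pd.DataFrame, y=None):
        feats = feature_columns(X)
        values = X[feats].to_numpy(dtype=np.float64)
        sd = values.std(axis=0, ddof=0)
        zero = [f for f, s in zip(feats, sd) if s == 0]
        if zero:
            raise ValueError(f"zero-variance features reached scaling (filter upstream): {zero}")
        self._scaler = StandardScaler().fit(values)
        self.feature_names_ = feats
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        meta = [c for c in X.columns if c in META_COLUMNS]
        values = self._scaler.transform(X[self.feature_names_].to_numpy(dtype=np.float64))
        out = X[meta].reset_index(drop=True)
        return pd.concat([out, pd.DataFrame(values, columns=self.feature_names_)], axis=1)


def scale_features(profiles: pd.DataFrame) -> tuple[pd.DataFrame, GlobalScaler]:
    scaler = GlobalScaler().fit(profiles)
    return scaler.transform(profiles), scaler


def aggregate_images_to_wells(images: pd.DataFrame, platemap: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Median over each well's surviving images, joined with plate-map metadata.

    Wells that lost all their images upstream are absent from the result
    and returned in the second element.  A well present in the image data
    but missing from the plate map is a hard error.
    """
    feats = feature_columns(images)
    keys = [k for k in ("cell_line", "plate", "well") if k in images.columns]
    wells, _ = _grouped_median(images, keys, feats)

    pm = platemap.drop(columns=[c for c in ("cell_line",) if c in platemap.columns])
    pm = pm.drop_duplicates(subset=["plate", "well"])
    merged = wells.merge(pm[["plate", "well", "compound", "concentration", "role"]], on=["plate", "well"], how="left")
    orphan = merged["compound"].isna()
    if orphan.any():
        bad = merged.loc[orphan, ["plate", "well"]].to_records(index=False).tolist()
        raise ValueError(f"wells present in features but absent from plate map: {bad[:10]}")

    expected = set(map(tuple, platemap.loc[platemap["plate"].isin(images["plate"].unique()), ["plate", "well"]].to_numpy()))
    present = set(map(tuple, wells[["plate", "well"]].to_numpy()))
    empty = sorted(expected - present)

    meta = keys + ["compound", "concentration", "role"]
    return merged[meta + feats], empty


def profile_cell_line(
    cells: pd.DataFrame,
    platemap: pd.DataFrame,
    min_cells: int = 20,
    quality_flags: set[tuple] | None = None,
    nzv_freq_cut: float = 95.0 / 5.0,
    nzv_unique_cut: float = 0.1,
    corr_cutoff: float = 0.95,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full fixed-order pipeline for one cell line.

    Returns well-level profiles (normalized, feature-selected, scaled) and
    a report of per-stage counts.  Feature selection statistics are
    computed on this cell line's own data, so feature sets can differ
    across lines; harmonize with :func:`phenoscreen.moa.harmonize_features`
    before cross-line model transfer.
    """
    report = PreprocessReport(n_cells=len(cells))
    images = aggregate_cells_to_images(cells)
    report.n_images = len(images)
    kept, removed = qc_filter_images(images, min_cells=min_cells, quality_flags=quality_flags)
    report.removed_images = removed
    report.n_images_removed = len(removed)
    if kept.empty:
        raise ValueError("all images removed by QC; nothing to profile")

    normalized, normalizer = normalize_to_dmso(kept, platemap)
    report.dropped_features += normalizer.dropped_features_

    selected, selector = select_features(
        normalized, nzv_freq_cut=nzv_freq_cut, nzv_unique_cut=nzv_unique_cut, corr_cutoff=corr_cutoff
    )
    report.dropped_features += selector.report_

    scaled, _ = scale_features(selected)
    wells, empty = aggregate_images_to_wells(scaled, platemap)
    report.empty_wells = empty
    report.n_wells = len(wells)
    if empty:
        warnings.warn(f"{len(empty)} wells lost all images during QC", stacklevel=2)
    return wells, report
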