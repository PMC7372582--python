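"""Phenotypic and viability hit calling with cancer-vs-control selectivity.

Phenotypic activity is scored as the squared Mahalanobis distance of a
well's profile from the DMSO control distribution in PCA space:

    D^2(x) = (x - mu)' Sigma^{-1} (x - mu)

with mu and Sigma the mean and covariance of the DMSO wells over the
first ``n_components`` (default 15) principal components.  The covariance
normalisation gives elliptic decision boundaries and makes the score
comparable across correlated feature sets.  A well is a phenotypic hit
when its distance exceeds a threshold — either a fixed value (the
screen-scale convention is 1500) or a percentile of the DMSO null
distribution; a compound is *selective* when it hits in at least
``min_eac_lines`` cancer (EAC) lines and in no control line.

Viability is scored per well as the nuclei-count z-score against the
plate's DMSO wells, summarised per compound by the median over replicate
wells.  A line-level hit (z <= -3 by default) counts toward selectivity
only if at least one control line responds weaker by at least the margin
(z_control - z_eac >= 2, e.g. an EAC z of -3 requires a control z >= -1).

The union of the two selective sets, with per-source provenance, is the
screen's hit list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from phenoscreen.preprocess import feature_columns

__all__ = [
    "DmsoReference",
    "PhenotypicDistance",
    "mahalanobis_to_dmso",
    "null_distance_threshold",
    "call_phenotypic_hits",
    "compute_zscores",
    "call_viability_hits",
    "combine_hits",
    "assemble_hit_table",
]


@dataclass
class DmsoReference:
    """Mean and covariance of DMSO well scores in PC space."""

    mean: np.ndarray
    cov: np.ndarray
    n_dmso: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")


def _cholesky_or_error(cov: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "DMSO covariance is singular; enable shrinkage (shrinkage='lw' or a float) or add DMSO wells"
        ) from exc


def mahalanobis_to_dmso(scores: np.ndarray, ref: DmsoReference, squared: bool = True) -> np.ndarray:
    """Squared Mahalanobis distance of each score row to the DMSO reference.

    Computed via a Cholesky solve, never an explicit inverse.  With
    ``squared=False`` the square root (the classical distance) is
    returned.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    chol = _cholesky_or_error(ref.cov)
    centered = scores - ref.mean
    z = linalg.solve_triangular(chol, centered.T, lower=True)
    d2 = np.einsum("ij,ij->j", z, z)
    d2 = np.maximum(d2, 0.0)
    return d2 if squared else np.sqrt(d2)


def null_distance_threshold(
    ref: DmsoReference, n_components: int, alpha: float = 0.001, method: str = "f"
) -> float:
    """Distance threshold at the (1 - alpha) quantile of the DMSO null.

    ``method='f'`` accounts for mu/Sigma being estimated from ``n_dmso``
    wells: for an independent Gaussian point,
    D^2 ~ p (n-1)(n+1) / (n (n-p)) * F(p, n-p).  ``method='chi2'`` uses the
    large-sample chi-square with ``n_components`` degrees of freedom.
    """
    p, n = n_components, ref.n_dmso
    if method == "chi2":
        return float(stats.chi2.ppf(1 - alpha, df=p))
    if method == "f":
        if n <= p + 2:
            raise ValueError("too few DMSO wells for the F-calibrated null; add wells or use chi2")
        scale = p * (n - 1) * (n + 1) / (n * (n - p))
        return float(scale * stats.f.ppf(1 - alpha, p, n - p))
    raise ValueError(f"unknown calibration method {method!r}")


class PhenotypicDistance(BaseEstimator):
    """PCA reduction plus Mahalanobis distance to the DMSO controls.

    Fitting runs standard PCA on the well profiles, then estimates the
    DMSO reference (mean, covariance) from the scores of the wells marked
    as vehicle controls.  ``score_samples`` returns squared distances.

    Parameters
    ----------
    n_components : PCs retained (default 15).  When ``variance_target`` is
        set instead, the smallest number of PCs explaining that fraction
        of variance is used.
    shrinkage : None, ``'lw'`` (Ledoit-Wolf) or a float in [0, 1] blending
        the empirical covariance toward its scaled identity; useful when
        DMSO wells are scarce relative to the dimensionality.
    squared : report squared distances (the default convention) or their
        square roots.
    """

    def __init__(
        self,
        n_components: int = 15,
        variance_target: float | None = None,
        shrinkage: str | float | None = None,
        squared: bool = True,
    ):
        self.n_components = n_components
        self.variance_target = variance_target
        self.shrinkage = shrinkage
        self.squared = squared

    def fit(self, X: pd.DataFrame, dmso_mask: np.ndarray | None = None):
        feats = feature_columns(X) if isinstance(X, pd.DataFrame) else None
        values = X[feats].to_numpy(dtype=np.float64) if feats else np.asarray(X, dtype=np.float64)
        if dmso_mask is None:
            if not isinstance(X, pd.DataFrame) or "role" not in X.columns:
                raise ValueError("provide dmso_mask or a 'role' column")
            dmso_mask = (X["role"] == "vehicle_control").to_numpy()
        dmso_mask = np.asarray(dmso_mask, dtype=bool)

        n_comp = self.n_components
        if self.variance_target is not None:
            full = PCA().fit(values)
            n_comp = int(np.searchsorted(np.cumsum(full.explained_variance_ratio_), self.variance_target) + 1)
        max_rank = min(values.shape[0] - 1, values.shape[1])
        if n_comp > max_rank:
            warnings.warn(f"rank {max_rank} < requested {n_comp} components; reducing", stacklevel=2)
            n_comp = max_rank
        self.n_components_ = n_comp
        self.pca_ = PCA(n_components=n_comp, svd_solver="full").fit(values)
        self.feature_names_ = feats
        scores = self.pca_.transform(values)

        dmso_scores = scores[dmso_mask]
        if dmso_scores.shape[0] <= n_comp:
            warnings.warn("fewer DMSO wells than components + 1; covariance will need shrinkage", stacklevel=2)
        cov = np.cov(dmso_scores, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        cov = self._shrink(cov, dmso_scores)
        self.reference_ = DmsoReference(mean=dmso_scores.mean(axis=0), cov=cov, n_dmso=dmso_scores.shape[0])
        return self

    def _shrink(self, cov: np.ndarray, dmso_scores: np.ndarray) -> np.ndarray:
        if self.shrinkage is None:
            return cov
        if self.shrinkage == "lw":
            from sklearn.covariance import LedoitWolf

            return LedoitWolf().fit(dmso_scores).covariance_
        lam = float(self.shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage float must lie in [0, 1]")
        target = np.eye(cov.shape[0]) * np.trace(cov) / cov.shape[0]
        return (1 - lam) * cov + lam * target

    def transform(self, X) -> np.ndarray:
        """Scores on the retained principal components."""
        check_is_fitted(self, "pca_")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_ or [] if f not in X.columns]
            if missing:
                raise ValueError(f"profiles lack model features: {missing}")
            X = X[self.feature_names_].to_numpy(dtype=np.float64)
        return self.pca_.transform(np.asarray(X, dtype=np.float64))

    def score_samples(self, X) -> np.ndarray:
        """(Squared) Mahalanobis distance of each profile to the DMSO reference."""
        return mahalanobis_to_dmso(self.transform(X), self.reference_, squared=self.squared)

    def null_threshold(self, alpha: float = 0.001, method: str = "f") -> float:
        check_is_fitted(self, "reference_")
        return null_distance_threshold(self.reference_, self.n_components_, alpha=alpha, method=method)


def _to_wide(values: pd.DataFrame, value_col: str) -> pd.DataFrame:
    if {"compound", "cell_line", value_col} <= set(values.columns):
        return values.pivot_table(index="compound", columns="cell_line", values=value_col, aggfunc="median")
    return values


def call_phenotypic_hits(
    distances: pd.DataFrame,
    eac_lines: tuple[str, ...],
    control_lines: tuple[str, ...],
    threshold: float | dict[str, float] = 1500.0,
    min_eac_lines: int = 2,
) -> pd.DataFrame:
    """Per-line and selective phenotypic hit flags from a distance table.

    ``distances`` is either long (compound, cell_line, mahalanobis) or a
    wide compound x cell-line table.  A line-level hit requires a distance
    strictly greater than the threshold (a scalar, or a per-line mapping
    when thresholds are calibrated on each line's own DMSO null).  A
    compound is selective iff it hits in >= ``min_eac_lines`` EAC lines
    and in no control line; compounds missing any line's distance are
    excluded and flagged incomplete.
    """
    wide = _to_wide(distances, "mahalanobis")
    lines = list(eac_lines) + list(control_lines)
    wide = wide.reindex(columns=lines)  # wholly missing lines become NaN -> incomplete
    thr = pd.Series({l: threshold[l] if isinstance(threshold, dict) else threshold for l in lines})
    hits = wide.gt(thr, axis=1)
    complete = wide.notna().all(axis=1)
    n_eac_hits = hits[list(eac_lines)].sum(axis=1)
    any_control = hits[list(control_lines)].any(axis=1)
    out = hits.add_prefix("hit_")
    out["incomplete"] = ~complete
    out["n_eac_hits"] = n_eac_hits
    out["selective"] = complete & (n_eac_hits >= min_eac_lines) & ~any_control
    return out


def compute_zscores(
    nuclei_counts: pd.DataFrame,
    platemap: pd.DataFrame,
    per_plate: bool = True,
) -> pd.DataFrame:
    """Nuclei-count z-scores versus DMSO, median over replicate wells.

    z = (count - mean of DMSO counts) / SD of DMSO counts, computed per
    plate by default (``per_plate=False`` pools the whole screen's DMSO
    wells).  Returns one row per (compound, cell_line) with the median z
    over that compound's wells.  A plate whose DMSO counts have zero SD is
    a hard error.
    """
    pm_cols = ["plate", "well", "compound", "role"]
    pm = platemap.drop_duplicates(subset=["plate", "well"])[
        [c for c in pm_cols + ["cell_line"] if c in platemap.columns]
    ]
    df = nuclei_counts.merge(pm, on=[c for c in ("cell_line", "plate", "well") if c in nuclei_counts.columns and c in pm.columns], how="left")
    df = df.dropna(subset=["nuclei_count"]).reset_index(drop=True)
    if df["compound"].isna().any():
        bad = df.loc[df["compound"].isna(), ["plate", "well"]].head()
        raise ValueError(f"nuclei counts for wells absent from plate map:\n{bad}")

    group_cols = ["plate"] if per_plate else (["cell_line"] if "cell_line" in df.columns else [None])
    z = np.empty(len(df))
    grouping = df.groupby(group_cols) if group_cols != [None] else [(None, df)]
    for key, grp in grouping:
        dmso = grp.loc[grp["role"] == "vehicle_control", "nuclei_count"]
        if len(dmso) < 2:
            raise ValueError(f"group {key} has fewer than 2 DMSO wells; z-scores undefined")
        sd = dmso.std(ddof=1)
        if sd == 0:
            raise ValueError(f"DMSO nuclei-count SD is zero in group {key}; z-scores undefined")
        z[grp.index] = (grp["nuclei_count"] - dmso.mean()) / sd
    df["z"] = z
    keys = [c for c in ("compound", "cell_line") if c in df.columns]
    out = df.loc[df["role"] == "treatment"].groupby(keys, as_index=False)["z"].median()
    return out


def call_viability_hits(
    zscores: pd.DataFrame,
    eac_lines: tuple[str, ...],
    control_lines: tuple[str, ...],
    eac_threshold: float = -3.0,
    margin: float = 2.0,
    min_eac_lines: int = 2,
) -> pd.DataFrame:
    """Selective viability hits from a compound x cell-line z-score table.

    A line-level hit is z <= ``eac_threshold``.  The hit *qualifies*
    toward selectivity iff in at least one control line the control z
    exceeds the EAC z by at least ``margin`` (z_control - z_eac >= margin;
    for z_eac = -3 and margin 2 the control must be >= -1, boundary
    included).  A compound is selective iff >= ``min_eac_lines`` EAC lines
    qualify.  Compounds missing a control-line z are excluded and flagged.
    """
    wide = _to_wide(zscores, "z")
    lines = list(eac_lines) + list(control_lines)
    wide = wide.reindex(columns=lines)  # wholly missing lines become NaN -> incomplete
    ctrl = wide[list(control_lines)]
    missing_ctrl = ctrl.isna().any(axis=1)

    out = pd.DataFrame(index=wide.index)
    qualifying = pd.DataFrame(index=wide.index)
    for line in eac_lines:
        z_eac = wide[line]
        is_hit = z_eac <= eac_threshold
        has_margin = ctrl.sub(z_eac, axis=0).ge(margin).any(axis=1)
        out[f"hit_{line}"] = is_hit.fillna(False)
        qualifying[line] = (is_hit & has_margin).fillna(False)
    out["n_qualifying"] = qualifying.sum(axis=1)
    out["incomplete"] = missing_ctrl
    out["selective"] = (~missing_ctrl) & (out["n_qualifying"] >= min_eac_lines)
    return out


def combine_hits(phenotypic: set[str], viability: set[str]) -> pd.DataFrame:
    """Union of the two selective hit sets with per-source provenance.

    |union| = |A| + |B| - |A intersect B| by construction; each compound is
    tagged phenotypic_only, viability_only or both.
    """
    phenotypic, viability = set(phenotypic), set(viability)
    rows = []
    for c in sorted(phenotypic | viability):
        in_p, in_v = c in phenotypic, c in viability
        category = "both" if (in_p and in_v) else ("phenotypic_only" if in_p else "viability_only")
        rows.append((c, in_p, in_v, category))
    return pd.DataFrame(rows, columns=["compound", "phenotypic", "viability", "category"])


def assemble_hit_table(
    distances: pd.DataFrame,
    zscores: pd.DataFrame,
    phenotypic_calls: pd.DataFrame,
    viability_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Tidy per-(compound, cell line) hit table with all scores and flags."""
    d = distances.rename(columns={"mahalanobis": "mahalanobis"})
    z = zscores.rename(columns={"z": "z_nuclei"})
    merged = d.merge(z, on=["compound", "cell_line"], how="outer")
    merged["phenotypic_hit"] = [
        bool(phenotypic_calls.at[c, f"hit_{l}"]) if c in phenotypic_calls.index else False
        for c, l in zip(merged["compound"], merged["cell_line"])
    ]
    merged["viability_hit"] = [
        bool(viability_calls.at[c, f"hit_{l}"])
        if c in viability_calls.index and f"hit_{l}" in viability_calls.columns
        else False
        for c, l in zip(merged["compound"], merged["cell_line"])
    ]
    merged["selective_phenotypic"] = merged["compound"].map(phenotypic_calls["selective"]).fillna(False).astype(bool)
    merged["selective_viability"] = merged["compound"].map(viability_calls["selective"]).fillna(False).astype(bool)
    merged["selective_any"] = merged["selective_phenotypic"] | merged["selective_viability"]
    return merged
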