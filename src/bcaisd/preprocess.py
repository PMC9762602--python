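"""Missing-value imputation and design-matrix construction.

Three imputers, each fitted on a training set only and reusable on held-out
data so cross-validation folds never leak:

* **median** — per-feature median (mode for categorical features);
* **knn** — mean (majority for categorical) of the k nearest complete donors
  under a missing-aware Euclidean distance that averages over co-observed
  coordinates and rescales;
* **mice** — chained equations: initialize with medians, then cycle the
  columns in fixed order, regressing each incomplete column on all others
  (linear for numeric targets, one-vs-rest linear scores with argmax for
  categorical) and overwriting the imputed cells with predictions.

``encode_and_scale`` then one-hot encodes categorical features and z-scores
numeric ones into a :class:`DesignMatrix` whose fitted transform (medians,
means/sds, category lists) can be replayed on new data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .cohort_sim import CohortTable, FeatureMeta

__all__ = ["PreprocessConfig", "DesignMatrix", "MedianImputer", "KNNImputer",
           "MiceImputer", "impute_median", "impute_knn", "impute_mice",
           "encode_and_scale", "make_imputer"]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    method: str = "mice"          # median | knn | mice
    k: int = 2
    mice_iters: int = 10
    seed: int = 0
    scale: bool = True

    def __post_init__(self):
        if self.method not in ("median", "knn", "mice"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mice_iters < 1:
            raise ValueError("mice_iters must be >= 1")


def make_imputer(config: PreprocessConfig):
    if config.method == "median":
        return MedianImputer()
    if config.method == "knn":
        return KNNImputer(k=config.k)
    return MiceImputer(iters=config.mice_iters, seed=config.seed)


# ---------------------------------------------------------------------------
# helpers

def _feature_frame(table: CohortTable) -> pd.DataFrame:
    return table.features().copy()


def _rebuild(table: CohortTable, feats: pd.DataFrame) -> CohortTable:
    df = table.data.copy()
    for c in feats.columns:
        df[c] = feats[c].values
    return CohortTable(df, table.metadata)


def _dtype_map(metadata) -> dict[str, str]:
    return {m.name: m.dtype for m in metadata}


def _median_mode(feats: pd.DataFrame, dtypes) -> dict:
    fills = {}
    for c in feats.columns:
        obs = feats[c].dropna()
        if len(obs) == 0:
            raise ValueError(f"column {c!r} has no observed values in the fitting set")
        if dtypes[c] == "numeric":
            fills[c] = float(obs.median())
        else:
            counts = obs.value_counts()
            top = counts[counts == counts.max()]
            fills[c] = sorted(top.index)[0]      # deterministic mode tie-break
    return fills


def _encode_numeric(feats: pd.DataFrame, dtypes, stats=None):
    """Encode a mixed frame to a float matrix for distance computation.

    Numeric columns are z-scored (fit-set mean/sd), categorical columns are
    expanded to one-hot indicators.  Missing cells become NaN across the
    feature's encoded columns.  Returns (matrix, column ownership map, stats).
    """
    if stats is None:
        stats = {}
        for c in feats.columns:
            if dtypes[c] == "numeric":
                obs = feats[c].astype(float)
                sd = float(obs.std(ddof=0))
                stats[c] = (float(obs.mean()), sd if sd > 0 else 1.0)
            else:
                stats[c] = sorted(feats[c].dropna().unique())
    blocks, owner = [], []
    for c in feats.columns:
        if dtypes[c] == "numeric":
            mu, sd = stats[c]
            blocks.append(((feats[c].astype(float) - mu) / sd).to_numpy()[:, None])
            owner.append([c])
        else:
            levels = stats[c]
            col = feats[c]
            mat = np.full((len(feats), len(levels)), np.nan)
            notna = col.notna().to_numpy()
            codes = pd.Categorical(col[notna], categories=levels).codes
            hot = np.zeros((int(notna.sum()), len(levels)))
            ok = codes >= 0
            hot[np.arange(len(codes))[ok], codes[ok]] = 1.0
            mat[notna] = hot
            blocks.append(mat)
            owner.append([c] * len(levels))
    X = np.hstack(blocks) if blocks else np.zeros((len(feats), 0))
    owner_flat = [c for grp in owner for c in grp]
    return X, owner_flat, stats


# ---------------------------------------------------------------------------
# median / mode

class MedianImputer:
    """Median imputation for numeric features, mode for categorical ones."""

    def fit(self, table: CohortTable):
        feats = _feature_frame(table)
        self.fills_ = _median_mode(feats, _dtype_map(table.metadata))
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        feats = _feature_frame(table)
        for c, v in self.fills_.items():
            if feats[c].isna().any():
                if isinstance(feats[c].dtype, pd.CategoricalDtype):
                    feats[c] = feats[c].cat.add_categories(
                        [v]) if v not in feats[c].cat.categories else feats[c]
                feats[c] = feats[c].fillna(v)
        return _rebuild(table, feats)

    def fit_transform(self, table):
        return self.fit(table).transform(table)


# ---------------------------------------------------------------------------
# k-nearest-neighbour

class KNNImputer:
    """Donor-based imputation from the k nearest complete neighbours.

    Distances are Euclidean over the remaining features (the target feature
    is excluded), averaged over co-observed coordinates and rescaled, on the
    z-scored/one-hot encoding of the fitting set.  Numeric targets receive
    the donor mean; categorical targets the donor majority (ties broken by
    category order).  Distance ties are broken by donor row order.
    """

    def __init__(self, k=2):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, table: CohortTable):
        self.dtypes_ = _dtype_map(table.metadata)
        feats = _feature_frame(table)
        _median_mode(feats, self.dtypes_)   # validates every column has data
        self.donor_feats_ = feats
        self.X_, self.owner_, self.stats_ = _encode_numeric(feats, self.dtypes_)
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        feats = _feature_frame(table)
        Xq, _, _ = _encode_numeric(feats, self.dtypes_, stats=self.stats_)
        out = feats.copy()
        owner = np.array(self.owner_)
        for c in feats.columns:
            miss = feats[c].isna().to_numpy()
            if not miss.any():
                continue
            donors_mask = self.donor_feats_[c].notna().to_numpy()
            if donors_mask.sum() < self.k:
                raise ValueError(
                    f"feature {c!r}: only {int(donors_mask.sum())} usable donors "
                    f"for k={self.k}")
            keep_cols = owner != c
            D = nan_euclidean_distances(Xq[np.ix_(miss, keep_cols)],
                                        self.X_[np.ix_(donors_mask, keep_cols)])
            D = np.where(np.isnan(D), np.inf, D)
            # stable argsort -> distance ties resolved by donor row order
            nn = np.argsort(D, axis=1, kind="stable")[:, : self.k]
            donor_vals = self.donor_feats_[c][donors_mask].reset_index(drop=True)
            if self.dtypes_[c] == "numeric":
                vals = donor_vals.to_numpy(float)[nn].mean(axis=1)
            else:
                levels = self.stats_[c]
                codes = pd.Categorical(donor_vals, categories=levels).codes[nn]
                vals = []
                for row in codes:
                    counts = np.bincount(row[row >= 0], minlength=len(levels))
                    vals.append(levels[int(np.argmax(counts))])
                vals = np.array(vals, dtype=object)
            col = out[c]
            if isinstance(col.dtype, pd.CategoricalDtype):
                out[c] = col.astype(object)
            out.loc[miss, c] = vals
            if isinstance(col.dtype, pd.CategoricalDtype):
                out[c] = pd.Categorical(out[c], categories=col.cat.categories)
        return _rebuild(table, out)

    def fit_transform(self, table):
        return self.fit(table).transform(table)


# ---------------------------------------------------------------------------
# chained equations

class _LinearModel:
    """Minimum-norm least squares with intercept (single- or multi-target)."""

    __slots__ = ("coef",)

    def __init__(self, coef):
        self.coef = coef

    @classmethod
    def fit(cls, X, y):
        A = np.hstack([np.ones((len(X), 1)), X])
        G = A.T @ A
        # tiny ridge keeps one-hot collinearity solvable without biasing
        G[np.diag_indices_from(G)] += 1e-8 * max(1.0, np.trace(G) / len(G))
        try:
            coef = np.linalg.solve(G, A.T @ y)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(coef)):
            return None
        return cls(coef)

    def predict(self, X):
        return np.hstack([np.ones((len(X), 1)), X]) @ self.coef


class MiceImputer:
    """Deterministic chained-equations imputation.

    The sweep is fitted on the training set: after median initialization the
    columns are cycled in table order for ``iters`` rounds, each incomplete
    column regressed on the encoding of all the others; imputed cells are
    overwritten with the (deterministic) predictions.  The per-column models
    from the final sweep are stored and replayed, with the same
    initialization and number of rounds, on held-out data — no statistic of
    the apply-set enters the transform.  ``seed`` is a hook for stochastic
    variants and does not affect the deterministic path.
    """

    def __init__(self, iters=10, seed=0):
        if iters < 1:
            raise ValueError("iters must be >= 1")
        self.iters = iters
        self.seed = seed

    def _sweep(self, feats, filled, fit_models: bool):
        dtypes = self.dtypes_
        # encode the current completed frame once; columns of a feature are
        # refreshed in place as the sweep updates it (chained equations)
        X_full, owner, _ = _encode_numeric(filled, dtypes, stats=self.enc_stats_)
        owner = np.array(owner)
        for c in self.incomplete_:
            miss = feats[c].isna().to_numpy()
            if not miss.any() and fit_models is False:
                continue
            X = X_full[:, owner != c]
            if fit_models:
                obs = feats[c].notna().to_numpy()
                if dtypes[c] == "numeric":
                    y = feats[c].to_numpy(float)[obs]
                else:
                    levels = self.enc_stats_[c]
                    y = (pd.Categorical(feats[c][obs], categories=levels)
                         .codes[:, None] == np.arange(len(levels))[None, :]).astype(float)
                model = _LinearModel.fit(X[obs], y)
                if model is None:   # pragma: no cover - degenerate designs
                    log.warning("mice: regression failed for %s; median fallback", c)
                self.models_[c] = model
            model = self.models_.get(c)
            if not miss.any():
                continue
            if model is None:
                continue            # stays at the median initialization
            pred = model.predict(X[miss])
            if dtypes[c] == "numeric":
                filled.loc[miss, c] = pred
                mu, sd = self.enc_stats_[c]
                X_full[miss, np.nonzero(owner == c)[0][0]] = (pred - mu) / sd
            else:
                levels = self.enc_stats_[c]
                picks = np.argmax(pred, axis=1)
                pick = [levels[int(i)] for i in picks]
                col = filled[c]
                if isinstance(col.dtype, pd.CategoricalDtype):
                    filled[c] = col.astype(object)
                filled.loc[miss, c] = pick
                if isinstance(col.dtype, pd.CategoricalDtype):
                    filled[c] = pd.Categorical(filled[c], categories=col.cat.categories)
                cols_c = np.nonzero(owner == c)[0]
                X_full[np.ix_(miss, cols_c)] = np.eye(len(levels))[picks]
        return filled

    def _init_fill(self, feats):
        filled = feats.copy()
        for c, v in self.fills_.items():
            if filled[c].isna().any():
                filled[c] = filled[c].fillna(v)
        return filled

    def fit(self, table: CohortTable):
        feats = _feature_frame(table)
        if feats.shape[1] < 2:
            raise ValueError("chained equations need at least two columns")
        for c in feats.columns:
            if feats[c].notna().sum() < 2:
                raise ValueError(f"column {c!r} has fewer than 2 observed values")
        self.dtypes_ = _dtype_map(table.metadata)
        self.fills_ = _median_mode(feats, self.dtypes_)
        _, _, self.enc_stats_ = _encode_numeric(feats, self.dtypes_)
        self.incomplete_ = [c for c in feats.columns if feats[c].isna().any()]
        self.models_ = {}
        filled = self._init_fill(feats)
        # refit the column models every sweep; the final sweep's models are
        # what transform() replays on held-out data
        for _ in range(self.iters):
            filled = self._sweep(feats, filled, fit_models=True)
        self.fitted_fill_ = filled
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        feats = _feature_frame(table)
        filled = self._init_fill(feats)
        for _ in range(self.iters):
            filled = self._sweep(feats, filled, fit_models=False)
        return _rebuild(table, filled)

    def fit_transform(self, table):
        self.fit(table)
        return self.transform(table)


# functional wrappers -------------------------------------------------------

def impute_median(table, fitted_on=None):
    """Median/mode imputation; learned on ``fitted_on`` (default: ``table``)."""
    return MedianImputer().fit(fitted_on or table).transform(table)


def impute_knn(table, k=2, fitted_on=None):
    return KNNImputer(k=k).fit(fitted_on or table).transform(table)


def impute_mice(table, mice_iters=10, seed=0, fitted_on=None):
    return MiceImputer(iters=mice_iters, seed=seed).fit(fitted_on or table).transform(table)


# ---------------------------------------------------------------------------
# design matrix

@dataclass
class DesignMatrix:
    """Model-ready numeric matrix with a replayable fitted transform."""

    X: np.ndarray
    columns: list[str]
    source: dict[str, list[str]]                 # feature -> its encoded columns
    numeric_stats: dict[str, tuple[float, float]]
    categories: dict[str, list]
    scale: bool = True
    dtypes: dict[str, str] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)

    def subset(self, cols: list[str]) -> "DesignMatrix":
        idx = [self.columns.index(c) for c in cols]
        return DesignMatrix(self.X[:, idx], list(cols), self.source,
                            self.numeric_stats, self.categories, self.scale,
                            self.dtypes)

    def apply(self, table_or_frame) -> "DesignMatrix":
        """Replay the fitted transform on new (already imputed) data."""
        feats = (table_or_frame.features()
                 if isinstance(table_or_frame, CohortTable) else table_or_frame)
        blocks = []
        for name in self.source:
            if self.dtypes[name] == "numeric":
                col = feats[name].astype(float).to_numpy()
                if np.isnan(col).any():
                    raise ValueError(f"missing values in {name!r}: impute first")
                if self.scale:
                    mu, sd = self.numeric_stats[name]
                    col = (col - mu) / sd
                blocks.append(col[:, None])
            else:
                levels = self.categories[name]
                vals = feats[name]
                if vals.isna().any():
                    raise ValueError(f"missing values in {name!r}: impute first")
                codes = pd.Categorical(vals, categories=levels).codes
                if (codes < 0).any():
                    log.warning("unseen categories in %s mapped to all-zero indicators", name)
                hot = np.zeros((len(feats), len(levels)))
                ok = codes >= 0
                hot[np.arange(len(feats))[ok], codes[ok]] = 1.0
                blocks.append(hot)
        X = np.hstack(blocks) if blocks else np.zeros((len(feats), 0))
        return DesignMatrix(X, self.columns, self.source, self.numeric_stats,
                            self.categories, self.scale, self.dtypes)


def encode_and_scale(table: CohortTable, scale: bool = True) -> DesignMatrix:
    """One-hot encode categorical and z-score numeric features.

    Must be called on imputed data.  Categorical features with L observed
    levels expand to L indicator columns named ``feature=level``; numeric
    features are standardized with the fitting set's mean and (population)
    standard deviation.  The returned object replays the identical transform
    on held-out data via :meth:`DesignMatrix.apply`.
    """
    feats = table.features()
    dtypes = _dtype_map(table.metadata)
    columns, source = [], {}
    numeric_stats, categories = {}, {}
    blocks = []
    for m in table.metadata:
        name = m.name
        if dtypes[name] == "numeric":
            col = feats[name].astype(float).to_numpy()
            if np.isnan(col).any():
                raise ValueError(f"missing values in {name!r}: impute first")
            mu = float(col.mean())
            sd = float(col.std(ddof=0))
            if sd == 0:
                sd = 1.0
            numeric_stats[name] = (mu, sd)
            blocks.append(((col - mu) / sd if scale else col)[:, None])
            columns.append(name)
            source[name] = [name]
        else:
            vals = feats[name]
            if vals.isna().any():
                raise ValueError(f"missing values in {name!r}: impute first")
            levels = (list(vals.cat.categories)
                      if isinstance(vals.dtype, pd.CategoricalDtype)
                      else sorted(vals.unique()))
            categories[name] = levels
            codes = pd.Categorical(vals, categories=levels).codes
            hot = np.zeros((len(feats), len(levels)))
            hot[np.arange(len(feats)), codes] = 1.0
            blocks.append(hot)
            enc = [f"{name}={lv}" for lv in levels]
            columns.extend(enc)
            source[name] = enc
    X = np.hstack(blocks) if blocks else np.zeros((len(feats), 0))
    return DesignMatrix(X, columns, source, numeric_stats, categories, scale, dtypes)
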