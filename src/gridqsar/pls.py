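"""Partial least squares on grid-field descriptors, with the statistics
customarily reported for field-based QSAR models.

The descriptor matrix is wide (thousands of lattice-point columns, tens of
compounds), so columns are first filtered by a minimum-standard-deviation
rule, centred, and scaled block-wise (every column of a field block shares
one scale, the pooled standard deviation of the block — the conventional
"CoMFA standard" scaling that balances fields of different units).  The
latent-variable fit itself is NIPALS PLS (scikit-learn); everything around
it — leave-one-out cross-validation (q2 = 1 - PRESS/SS), the predictive
r2 on an external test set (r2_pred = 1 - PRESS/SD with SD taken about the
training-set mean), standard errors, F, and per-field contribution
fractions — is computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .fields import FieldBlock

__all__ = [
    "FilteredBlock",
    "Descriptors",
    "PLSModel",
    "LOOResult",
    "ModelStats",
    "RankError",
    "filter_columns",
    "combine_blocks",
    "fit",
    "loo_cv",
    "evaluate",
    "r2_pred",
    "flag_outliers",
    "DEFAULT_MIN_SD",
]

#: default minimum-standard-deviation column filters per field family
DEFAULT_MIN_SD = {"comfa": 2.0, "comsia": 0.05}


class RankError(ValueError):
    """More latent components requested than the descriptor rank supports."""


@dataclass
class FilteredBlock:
    """A field block reduced to its informative columns."""

    field_kind: str
    matrix: np.ndarray
    column_indices: np.ndarray  # into the parent block's lattice columns
    compound_ids: List[int]
    column_sds: np.ndarray  # raw (unscaled) standard deviations


def filter_columns(block: FieldBlock, min_sd: float) -> FilteredBlock:
    """Drop columns whose standard deviation falls below ``min_sd``.

    ``min_sd = 0`` keeps every column.  Raises if nothing survives.
    """
    sds = block.matrix.std(axis=0, ddof=0)
    keep = np.flatnonzero(sds >= min_sd) if min_sd > 0 else np.arange(sds.size)
    if keep.size == 0:
        raise ValueError(
            f"column filter min_sd={min_sd} removed every column of "
            f"{block.field_kind}"
        )
    return FilteredBlock(
        field_kind=block.field_kind,
        matrix=block.matrix[:, keep],
        column_indices=keep,
        compound_ids=list(block.compound_ids),
        column_sds=sds[keep],
    )


@dataclass
class Descriptors:
    """Concatenated filtered blocks ready for PLS.

    ``column_scales`` hold the block-level scale of each column; dividing
    the centred matrix by them gives the modelling space.
    """

    X: np.ndarray
    compound_ids: List[int]
    column_field_kinds: np.ndarray  # str per column
    column_grid_indices: np.ndarray  # lattice column index per column
    column_scales: np.ndarray
    column_raw_sds: np.ndarray

    def rows_for(self, ids: Sequence[int]) -> np.ndarray:
        pos = {cid: i for i, cid in enumerate(self.compound_ids)}
        return self.X[[pos[i] for i in ids]]


def combine_blocks(blocks: Sequence[FilteredBlock]) -> Descriptors:
    """Concatenate filtered blocks column-wise with block-level scaling."""
    if not blocks:
        raise ValueError("no descriptor blocks given")
    ids0 = blocks[0].compound_ids
    for b in blocks[1:]:
        if b.compound_ids != ids0:
            raise ValueError(
                f"blocks disagree on compounds ({b.field_kind} vs {blocks[0].field_kind})"
            )
    mats, kinds, gidx, scales, raw_sds = [], [], [], [], []
    for b in blocks:
        centred = b.matrix - b.matrix.mean(axis=0)
        pooled = float(np.sqrt(np.mean(centred ** 2)))
        if pooled <= 0:
            pooled = 1.0
        mats.append(b.matrix)
        kinds.append(np.full(b.matrix.shape[1], b.field_kind, dtype=object))
        gidx.append(b.column_indices)
        scales.append(np.full(b.matrix.shape[1], pooled))
        raw_sds.append(b.column_sds)
    return Descriptors(
        X=np.hstack(mats),
        compound_ids=list(ids0),
        column_field_kinds=np.concatenate(kinds),
        column_grid_indices=np.concatenate(gidx),
        column_scales=np.concatenate(scales),
        column_raw_sds=np.concatenate(raw_sds),
    )


@dataclass
class PLSModel:
    """A fitted PLS regression in preprocessed (centred, scaled) space."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    column_scales: np.ndarray
    coef_scaled: np.ndarray  # per preprocessed column
    column_field_kinds: Optional[np.ndarray] = None
    column_grid_indices: Optional[np.ndarray] = None

    @property
    def coef_raw(self) -> np.ndarray:
        """Coefficients in the original descriptor units."""
        return self.coef_scaled / self.column_scales

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        Z = (X - self.x_mean) / self.column_scales
        return Z @ self.coef_scaled + self.y_mean


def _preprocess(
    X: np.ndarray, column_scales: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, float)
    x_mean = X.mean(axis=0)
    scales = (
        np.ones(X.shape[1]) if column_scales is None else np.asarray(column_scales, float)
    )
    return (X - x_mean) / scales, x_mean, scales


def fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    column_scales: Optional[np.ndarray] = None,
    column_field_kinds: Optional[np.ndarray] = None,
    column_grid_indices: Optional[np.ndarray] = None,
) -> PLSModel:
    """Fit a PLS model with the given number of latent components.

    ``X`` is the raw (unfiltered-units) descriptor matrix; centring and the
    optional block scaling are applied internally and recorded on the model.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of compounds")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if X.shape[0] < n_components + 1:
        raise RankError(
            f"{n_components} components need at least {n_components + 1} rows, "
            f"got {X.shape[0]}"
        )
    Z, x_mean, scales = _preprocess(X, column_scales)
    rank = np.linalg.matrix_rank(Z @ Z.T)
    if rank < n_components:
        raise RankError(
            f"descriptor rank {rank} below the requested {n_components} components"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NIPALS convergence chatter on toys
        pls.fit(Z, y - y.mean())
    coef = np.asarray(pls.coef_, float).reshape(-1)
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=float(y.mean()),
        column_scales=scales,
        coef_scaled=coef,
        column_field_kinds=column_field_kinds,
        column_grid_indices=column_grid_indices,
    )


@dataclass
class LOOResult:
    """Leave-one-out cross-validation summary."""

    q2_by_components: Dict[int, float]
    press_by_components: Dict[int, float]
    n_components: int  # selected
    q2: float
    press: float
    sep: float

    @property
    def best_q2(self) -> float:
        return max(self.q2_by_components.values())


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    column_scales: Optional[np.ndarray] = None,
    selection: str = "parsimony",
    parsimony_tol: float = 0.05,
) -> LOOResult:
    """Leave-one-out q2 for every component count up to ``max_components``.

    Each left-out sample is predicted by a model refitted on the remaining
    n-1 rows; q2(c) = 1 - PRESS(c)/SS with SS about the full-sample mean.
    The selected component count is either the smallest count whose q2 lies
    within ``parsimony_tol`` (relative) of the maximum ("parsimony", the
    default) or the argmax ("argmax").
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    feasible = min(max_components, n - 2)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if feasible > rank:
        feasible = rank
    if feasible < max_components:
        warnings.warn(
            f"max_components truncated from {max_components} to {feasible} "
            "(sample size or rank limit)",
            stacklevel=2,
        )
    if feasible < 1:
        raise RankError("descriptors have no usable rank for cross-validation")

    ss = float(np.sum((y - y.mean()) ** 2))
    press = {c: 0.0 for c in range(1, feasible + 1)}
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        for c in range(1, feasible + 1):
            try:
                m = fit(X[mask], y[mask], c, column_scales=column_scales)
            except RankError:
                press[c] = np.inf
                continue
            pred = float(m.predict(X[i : i + 1])[0])
            press[c] += (y[i] - pred) ** 2
    q2 = {c: 1.0 - press[c] / ss for c in press}

    best_c = max(q2, key=lambda c: (q2[c], -c))
    if selection == "parsimony":
        threshold = q2[best_c] - parsimony_tol * abs(q2[best_c])
        chosen = min(c for c in q2 if q2[c] >= threshold)
    elif selection == "argmax":
        chosen = best_c
    else:
        raise ValueError(f"unknown selection rule {selection!r}")
    sep = float(np.sqrt(press[chosen] / max(n - chosen - 1, 1)))
    return LOOResult(
        q2_by_components=q2,
        press_by_components=press,
        n_components=chosen,
        q2=q2[chosen],
        press=press[chosen],
        sep=sep,
    )


@dataclass
class ModelStats:
    """The statistics suite customarily tabulated for one model."""

    q2: float
    sep: float
    r2ncv: float
    see: float
    f_stat: float
    f_ratio: float
    n_components: int
    field_fractions: Dict[str, float] = field(default_factory=dict)
    press: float = float("nan")
    sd: float = float("nan")
    r2pred: float = float("nan")
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> Dict[str, object]:
        return {
            "q2": self.q2,
            "sep": self.sep,
            "r2ncv": self.r2ncv,
            "see": self.see,
            "f_stat": self.f_stat,
            "f_ratio": self.f_ratio,
            "n_components": self.n_components,
            "field_fractions": dict(sorted(self.field_fractions.items())),
            "press": self.press,
            "sd": self.sd,
            "r2pred": self.r2pred,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def r2_pred(
    y_test: np.ndarray, predictions: np.ndarray, train_mean: float
) -> Tuple[float, float, float]:
    """Predictive r2 on an external test set: ``1 - PRESS/SD``.

    PRESS is the squared deviation of predictions from the observed test
    activities; SD is the squared deviation of the observed test activities
    from the training-set mean.  Returns ``(r2pred, press, sd)``.
    """
    y_test = np.asarray(y_test, float).ravel()
    predictions = np.asarray(predictions, float).ravel()
    if y_test.shape != predictions.shape:
        raise ValueError("test activities and predictions are not conformable")
    press = float(np.sum((y_test - predictions) ** 2))
    sd = float(np.sum((y_test - train_mean) ** 2))
    if sd == 0.0:
        raise ZeroDivisionError(
            "SD about the training mean is zero; r2_pred is undefined"
        )
    return 1.0 - press / sd, press, sd


def flag_outliers(
    y_test: np.ndarray, predictions: np.ndarray, threshold: float = 1.0
) -> np.ndarray:
    """True where the absolute residual strictly exceeds ``threshold`` log units."""
    res = np.abs(np.asarray(y_test, float) - np.asarray(predictions, float))
    return res > threshold


def field_contribution_fractions(
    model: PLSModel, X_train: np.ndarray
) -> Dict[str, float]:
    """Per-field fractions of sum(|coefficient| * column sd), computed in the
    preprocessed modelling space and normalised to 1."""
    if model.column_field_kinds is None:
        return {}
    Z = (np.asarray(X_train, float) - model.x_mean) / model.column_scales
    contrib = np.abs(model.coef_scaled) * Z.std(axis=0, ddof=0)
    total = contrib.sum()
    if total <= 0:
        return {k: 0.0 for k in np.unique(model.column_field_kinds)}
    out: Dict[str, float] = {}
    for kind in np.unique(model.column_field_kinds):
        out[str(kind)] = float(contrib[model.column_field_kinds == kind].sum() / total)
    return out


def evaluate(
    model: PLSModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    train_mean: Optional[float] = None,
    loo: Optional[LOOResult] = None,
    exclude_test: Optional[np.ndarray] = None,
) -> ModelStats:
    """Assemble the full statistics suite for a fitted model.

    ``exclude_test`` masks test compounds (e.g. flagged outliers) out of the
    predictive-r2 computation; they are still predicted and reported
    elsewhere.  ``train_mean`` defaults to the mean of ``y_train``.
    """
    y_train = np.asarray(y_train, float).ravel()
    y_test = np.asarray(y_test, float).ravel()
    n, c = y_train.size, model.n_components
    pred_train = model.predict(X_train)
    rss = float(np.sum((y_train - pred_train) ** 2))
    ss = float(np.sum((y_train - y_train.mean()) ** 2))
    r2ncv = 1.0 - rss / ss
    dof = n - c - 1
    if dof < 1:
        raise RankError(f"no residual degrees of freedom (n={n}, components={c})")
    see = float(np.sqrt(rss / dof))
    f_ratio = r2ncv / (1.0 - r2ncv) if r2ncv < 1.0 else float("inf")
    f_stat = f_ratio * dof / c

    if y_test.size == 0:
        raise ValueError("test set is empty")
    keep = (
        np.ones(y_test.size, bool)
        if exclude_test is None
        else ~np.asarray(exclude_test, bool)
    )
    pred_test = model.predict(X_test)
    mean = float(y_train.mean()) if train_mean is None else float(train_mean)
    r2p, press, sd = r2_pred(y_test[keep], pred_test[keep], mean)

    return ModelStats(
        q2=loo.q2 if loo else float("nan"),
        sep=loo.sep if loo else float("nan"),
        r2ncv=r2ncv,
        see=see,
        f_stat=f_stat,
        f_ratio=f_ratio,
        n_components=c,
        field_fractions=field_contribution_fractions(model, X_train),
        press=press,
        sd=sd,
        r2pred=r2p,
        n_train=n,
        n_test=int(keep.sum()),
    )
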