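"""Blocked cross-validation, CC / RMSE metrics, and paired tests.

The session is split into 10 non-overlapping contiguous blocks of
(near-)equal size.  Fold f uses block f as the test set, block
(f+1) mod 10 as the validation set, and the remaining 8 blocks as the
training set.  The validation block exists for API parity with
decoders that tune hyperparameters; plain OLS never touches it.

Standardization parameters (per-column mean/sd) are estimated on the
training rows of each fold only and applied to the test rows, so test
data can never leak into the fit.  CC and RMSE are computed on the
standardized target scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import TargetMatrix, standardize
from .inference import MLRModel, fit_mlr, predict_mlr


@dataclass(frozen=True)
class Fold:
    index: int
    train_rows: np.ndarray
    val_rows: np.ndarray
    test_rows: np.ndarray


@dataclass(frozen=True)
class BlockPartition:
    """Contiguous equal-size blocks; remainder spread over leading blocks."""

    n_rows: int
    n_blocks: int
    block_bounds: tuple[tuple[int, int], ...]

    def block_rows(self, b: int) -> np.ndarray:
        s, e = self.block_bounds[b]
        return np.arange(s, e)

    def folds(self) -> list[Fold]:
        out = []
        for f in range(self.n_blocks):
            val = (f + 1) % self.n_blocks
            train = np.concatenate(
                [self.block_rows(b) for b in range(self.n_blocks) if b not in (f, val)]
            )
            out.append(
                Fold(
                    index=f,
                    train_rows=train,
                    val_rows=self.block_rows(val),
                    test_rows=self.block_rows(f),
                )
            )
        return out


def partition_blocks(n_rows: int, n_blocks: int = 10) -> BlockPartition:
    """Split ``n_rows`` into contiguous blocks whose sizes differ by <= 1."""
    if n_rows < n_blocks:
        raise ValueError(f"cannot split {n_rows} rows into {n_blocks} blocks")
    base, rem = divmod(n_rows, n_blocks)
    sizes = [base + 1] * rem + [base] * (n_blocks - rem)
    bounds = []
    start = 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s
    return BlockPartition(n_rows=n_rows, n_blocks=n_blocks, block_bounds=tuple(bounds))


def pearson_cc(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation between actual and inferred series.

    Returns NaN with a warning when either input is constant (the
    correlation is undefined there).
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("series lengths differ")
    if y.size < 2:
        raise ValueError("need at least two samples")
    yc = y - y.mean()
    hc = y_hat - y_hat.mean()
    denom = np.sqrt((yc**2).sum()) * np.sqrt((hc**2).sum())
    if denom == 0:
        warnings.warn("constant input; correlation undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((yc * hc).sum() / denom)


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error between actual and inferred series."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("series lengths differ")
    if y.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(((y_hat - y) ** 2).mean()))


def _cc_columns(Y: np.ndarray, Y_hat: np.ndarray) -> np.ndarray:
    """Column-wise Pearson CC; NaN where a column is constant."""
    yc = Y - Y.mean(axis=0)
    hc = Y_hat - Y_hat.mean(axis=0)
    denom = np.sqrt((yc**2).sum(axis=0)) * np.sqrt((hc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (yc * hc).sum(axis=0) / denom
    out = np.where(denom == 0, np.nan, out)
    return out


@dataclass
class CrossValResult:
    """Per-(fold, output) CC/RMSE records plus pooled aggregates.

    ``records`` has columns fold, output, cc, rmse and -- when target
    descriptors are available -- signal_type, channel, unit_id.
    Aggregates pool all (output, fold) pairs; SEM is the ddof-1 standard
    deviation over that pool divided by sqrt(count).
    """

    records: pd.DataFrame
    partition: BlockPartition
    models: list[MLRModel] | None = None

    @property
    def mean_cc(self) -> float:
        return float(self.records["cc"].mean())

    @property
    def sem_cc(self) -> float:
        v = self.records["cc"]
        return float(v.std(ddof=1) / np.sqrt(v.count()))

    @property
    def mean_rmse(self) -> float:
        return float(self.records["rmse"].mean())

    @property
    def sem_rmse(self) -> float:
        v = self.records["rmse"]
        return float(v.std(ddof=1) / np.sqrt(v.count()))


def cross_validate(
    X,
    Y,
    partition: BlockPartition,
    return_models: bool = False,
) -> CrossValResult:
    """Blocked cross-validation of an MLR decoder.

    Per fold: standardize X and Y with training-fold statistics, fit on
    the training rows, predict the test rows, and score every output
    with CC and RMSE on the standardized scale.
    """
    from .features import FeatureMatrix  # local to avoid cycle at import time

    Xv = X.values if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, float))
    if isinstance(Y, TargetMatrix):
        Yv, ycols = Y.values, Y.columns
    else:
        Yv = np.asarray(Y, dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        ycols = None
    if Xv.shape[0] != partition.n_rows or Yv.shape[0] != partition.n_rows:
        raise ValueError("X/Y rows do not match the partition")

    m = Yv.shape[1]
    rec_fold, rec_out, rec_cc, rec_rmse = [], [], [], []
    models: list[MLRModel] = []
    for fold in partition.folds():
        zX, _ = standardize(Xv, fold.train_rows)
        zY, _ = standardize(Yv, fold.train_rows)
        model = fit_mlr(zX[fold.train_rows], zY[fold.train_rows])
        pred = predict_mlr(model, zX[fold.test_rows])
        truth = zY[fold.test_rows]
        cc = _cc_columns(truth, pred)
        err = np.sqrt(((pred - truth) ** 2).mean(axis=0))
        rec_fold.extend([fold.index] * m)
        rec_out.extend(range(m))
        rec_cc.extend(cc.tolist())
        rec_rmse.extend(err.tolist())
        if return_models:
            models.append(model)

    records = pd.DataFrame(
        {"fold": rec_fold, "output": rec_out, "cc": rec_cc, "rmse": rec_rmse}
    )
    if ycols is not None:
        records["signal_type"] = [ycols[k].signal_type for k in records["output"]]
        records["channel"] = [ycols[k].channel for k in records["output"]]
        records["unit_id"] = [
            np.nan if ycols[k].unit_id is None else float(ycols[k].unit_id)
            for k in records["output"]
        ]
    return CrossValResult(
        records=records,
        partition=partition,
        models=models if return_models else None,
    )


def paired_comparison(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Two-tailed paired test between matched samples.

    The difference distribution is screened with Shapiro-Wilk at
    alpha = 0.05: normal-looking differences go to the paired t-test,
    anything else to the Wilcoxon signed-rank test.  All-zero
    differences return p = 1 with a warning (nothing to test).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero", RuntimeWarning, stacklevel=2)
        return 1.0, "degenerate"
    if np.ptp(d) == 0:
        # constant non-zero shift: normality is untestable, rank test is exact
        res = stats.wilcoxon(d, alternative="two-sided")
        return float(res.pvalue), "wilcoxon signed-rank"
    _, p_norm = stats.shapiro(d)
    if p_norm >= 0.05:
        res = stats.ttest_rel(a, b)
        return float(res.pvalue), "paired t-test"
    res = stats.wilcoxon(d, alternative="two-sided")
    return float(res.pvalue), "wilcoxon signed-rank"
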