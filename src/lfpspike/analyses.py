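"""Secondary analyses: feature informativeness, channel-count curves,
interchannel correlation, channel-importance maps and distance trends.

Two complementary importance metrics appear throughout:

* ``cc``   -- cross-validated CC of a decoder fit on a single input
  channel (p = 1 per feature type): how well does this channel alone
  predict the output?
* ``coef`` -- mean absolute coefficient of one decoder fit on all
  channels simultaneously: how much weight does the joint model assign
  to this channel?

Importance rows are annotated with the interelectrode distance between
the input (LFP) electrode and the output (spiking) electrode, which
feeds the distance-trend regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_geometry import ElectrodeArrayMap, distance_matrix
from .evaluation import BlockPartition, cross_validate
from .features import FeatureMatrix, TargetMatrix
from .signals import ContinuousSignal

IMPORTANCE_METRICS = ("cc", "coef")


# ---------------------------------------------------------------------------
# feature informativeness


def feature_informativeness(
    features_by_type: Mapping[str, FeatureMatrix],
    Y: TargetMatrix,
    partition: BlockPartition,
    expected_types: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank LFP feature types by predictive power and by model weight.

    Returns ``(cc_table, coef_table)``:

    * cc_table: one cross-validated decoder per feature type
      (feature_type, mean_cc, sem_cc);
    * coef_table: one decoder on all feature types combined,
      |coefficients| averaged per type over inputs, outputs and folds
      (feature_type, mean_abs_coef).
    """
    if expected_types is not None:
        missing = [t for t in expected_types if t not in features_by_type]
        if missing:
            raise ValueError(f"missing feature types: {missing}")
    types = list(features_by_type)
    if not types:
        raise ValueError("no feature types given")

    cc_rows = []
    for t in types:
        res = cross_validate(features_by_type[t], Y, partition)
        cc_rows.append({"feature_type": t, "mean_cc": res.mean_cc, "sem_cc": res.sem_cc})
    cc_table = pd.DataFrame(cc_rows)

    combined = np.hstack([features_by_type[t].values for t in types])
    col_type = np.concatenate(
        [np.full(features_by_type[t].p, i) for i, t in enumerate(types)]
    )
    res_all = cross_validate(combined, Y.values, partition, return_models=True)
    abs_coef = np.mean([np.abs(m.coefficients) for m in res_all.models], axis=0)
    coef_table = pd.DataFrame(
        {
            "feature_type": types,
            "mean_abs_coef": [
                float(abs_coef[col_type == i].mean()) for i in range(len(types))
            ],
        }
    )
    return cc_table, coef_table


# ---------------------------------------------------------------------------
# channel-count curves


@dataclass
class SubsetCurve:
    """Mean CC as a function of the number of input channels."""

    p_values: np.ndarray
    mean_cc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    per_iteration: np.ndarray  # (len(p_values), iterations)
    iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_channels": self.p_values,
                "mean_cc": self.mean_cc,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def channel_subset_curve(
    X: FeatureMatrix,
    Y: TargetMatrix,
    partition: BlockPartition,
    p_grid: Sequence[int] | None = None,
    iterations: int = 30,
    seed: int = 0,
) -> SubsetCurve:
    """Inference performance vs number of randomly drawn input channels.

    For every channel count p and iteration, p distinct channels are
    sampled without replacement (one named substream per (p, iteration)
    pair), the decoder is cross-validated on their columns, and the
    pooled mean CC recorded.  The 95% CI is the 2.5/97.5 percentile
    band over iterations.  p equal to the full channel count is
    deterministic (single possible subset) and computed once.
    """
    channels = np.array(X.channels)
    n_avail = channels.size
    if p_grid is None:
        p_grid = [1] + [p for p in range(5, n_avail, 5)]
    p_grid = list(p_grid)
    cols_by_channel = {
        ch: [j for j, c in enumerate(X.columns) if c.channel == ch] for ch in channels
    }
    per_iter = np.empty((len(p_grid), iterations))
    for pi, p in enumerate(p_grid):
        if not 1 <= p <= n_avail:
            raise ValueError(f"subset size {p} outside [1, {n_avail}]")
        if p == n_avail:
            res = cross_validate(X.values, Y.values, partition)
            per_iter[pi, :] = res.mean_cc
            continue
        for it in range(iterations):
            rng = np.random.default_rng([seed, p, it])
            subset = rng.choice(channels, size=p, replace=False)
            cols = np.concatenate([cols_by_channel[ch] for ch in subset])
            res = cross_validate(X.values[:, cols], Y.values, partition)
            per_iter[pi, it] = res.mean_cc
    lo, hi = np.percentile(per_iter, [2.5, 97.5], axis=1)
    return SubsetCurve(
        p_values=np.array(p_grid),
        mean_cc=per_iter.mean(axis=1),
        ci_low=lo,
        ci_high=hi,
        per_iteration=per_iter,
        iterations=iterations,
        seed=seed,
    )


def channels_to_fraction(curve: SubsetCurve, fraction: float = 0.9) -> int:
    """Smallest channel count reaching ``fraction`` of the curve maximum.

    The mean-CC curve is linearly interpolated between grid points and
    the crossing rounded up to an integer channel count (the plateau
    points reported in the literature, e.g. 35, lie off the 5-channel
    sampling grid, so some interpolation is implied).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    m = np.asarray(curve.mean_cc, dtype=float)
    p = np.asarray(curve.p_values, dtype=float)
    if m.size == 0:
        raise ValueError("empty curve")
    target = fraction * m.max()
    reached = m >= target
    idx = int(np.argmax(reached))
    if idx == 0:
        return int(p[0])
    p0, p1 = p[idx - 1], p[idx]
    m0, m1 = m[idx - 1], m[idx]
    crossing = p0 + (target - m0) * (p1 - p0) / (m1 - m0)
    return int(np.ceil(crossing))


# ---------------------------------------------------------------------------
# interchannel correlation


def interchannel_correlation(
    lfp: ContinuousSignal | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Pairwise Pearson correlation of LFP channels and its average.

    Returns the symmetric channels x channels matrix (unit diagonal)
    and the mean of the upper-triangle off-diagonal entries -- a scalar
    measure of array-wide redundancy.  Constant channels produce NaN
    rows/columns with a warning.
    """
    v = lfp.signal if isinstance(lfp, ContinuousSignal) else np.atleast_2d(np.asarray(lfp, float))
    if v.shape[1] < 2:
        raise ValueError("need at least two samples per channel")
    sd = v.std(axis=1)
    vc = v - v.mean(axis=1, keepdims=True)
    cov = vc @ vc.T / v.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} constant channel(s); correlation undefined there",
            RuntimeWarning,
            stacklevel=2,
        )
        corr[const, :] = np.nan
        corr[:, const] = np.nan
    iu = np.triu_indices(v.shape[0], k=1)
    return corr, float(corr[iu].mean())


# ---------------------------------------------------------------------------
# channel importance


def channel_importance(
    X: FeatureMatrix,
    Y: TargetMatrix,
    partition: BlockPartition,
    amap: ElectrodeArrayMap,
    metric: str = "cc",
    average_units: bool = True,
) -> pd.DataFrame:
    """Importance of every input channel for every output.

    Returns an ImportanceTable DataFrame with columns ``output_type``,
    ``output_channel``, ``input_channel``, ``metric``, ``score`` and
    ``distance_um``.  With ``average_units`` (default), scores of
    multiple units recorded on the same output channel (SUA) are
    averaged into one row per (input, output channel) pair.
    """
    if metric not in IMPORTANCE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {IMPORTANCE_METRICS}")
    in_channels = list(X.channels)
    out_channels = [c.channel for c in Y.columns]
    out_types = [c.signal_type for c in Y.columns]

    scores = np.empty((len(in_channels), Y.m))
    if metric == "cc":
        for i, ch in enumerate(in_channels):
            Xc = X.select(channels=[ch])
            res = cross_validate(Xc.values, Y.values, partition)
            scores[i] = res.records.groupby("output")["cc"].mean().to_numpy()
    else:
        res = cross_validate(X.values, Y.values, partition, return_models=True)
        abs_coef = np.mean([np.abs(m.coefficients) for m in res.models], axis=0)
        for i, ch in enumerate(in_channels):
            rows = [j for j, c in enumerate(X.columns) if c.channel == ch]
            scores[i] = abs_coef[rows].mean(axis=0)

    dist = distance_matrix(amap, in_channels, out_channels)
    table = pd.DataFrame(
        {
            "output_type": np.repeat([out_types], len(in_channels), axis=0).ravel(),
            "output_channel": np.tile(out_channels, len(in_channels)),
            "input_channel": np.repeat(in_channels, Y.m),
            "metric": metric,
            "score": scores.ravel(),
            "distance_um": dist.ravel(),
        }
    )
    if average_units:
        table = (
            table.groupby(
                ["output_type", "output_channel", "input_channel", "metric"],
                as_index=False,
            )
            .agg(score=("score", "mean"), distance_um=("distance_um", "first"))
        )
    return table


def distance_trend(table: pd.DataFrame) -> tuple[float, float]:
    """Linear trend of importance score against interelectrode distance.

    OLS of score on distance; returns (slope in score per um, two-tailed
    p-value of the slope-is-zero t-test).  Constant scores short-circuit
    to (0, 1).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a trend")
    d = table["distance_um"].to_numpy(dtype=float)
    s = table["score"].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("zero distance variance")
    if np.ptp(s) == 0:
        return 0.0, 1.0
    res = stats.linregress(d, s)
    return float(res.slope), float(res.pvalue)


def importance_heatmap(
    table: pd.DataFrame, amap: ElectrodeArrayMap
) -> tuple[np.ndarray, np.ndarray]:
    """Map one output's importance scores onto the electrode grid.

    Returns ``(grid, connected)``: a rows x cols float grid with scores
    at each input channel's site and NaN at unconnected sites, plus the
    boolean connectivity mask distinguishing "unconnected" from a true
    score of 0.  Expects rows for exactly one output.
    """
    keys = table[["output_type", "output_channel"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("heatmap expects rows for exactly one output")
    grid = np.full((amap.grid_rows, amap.grid_cols), np.nan)
    connected = np.zeros((amap.grid_rows, amap.grid_cols), dtype=bool)
    for r, c in amap.connected_sites:
        connected[r, c] = True
    seen = set()
    for ch, score in zip(table["input_channel"], table["score"]):
        r, c = amap.site(int(ch))
        grid[r, c] = score
        seen.add(int(ch))
    missing = set(amap.channel_ids) - seen
    if missing:
        raise ValueError(f"scores missing for channels {sorted(missing)[:5]}...")
    return grid, connected


def heatmap_to_table(
    grid: np.ndarray, amap: ElectrodeArrayMap
) -> pd.DataFrame:
    """Inverse of :func:`importance_heatmap` (input channel, score)."""
    rows = [
        {"input_channel": ch, "score": grid[r, c]}
        for ch, (r, c) in sorted(amap.site_of_channel.items())
    ]
    return pd.DataFrame(rows)
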