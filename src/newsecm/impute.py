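"""Pre-filtering, log2 transform, and QRILC left-censored imputation.

Label-free proteomics matrices are missing-not-at-random: low-abundance
proteins drop below the detection limit, so zeros concentrate in the
left tail of each sample's intensity distribution. The QRILC approach
(quantile regression imputation of left-censored data) estimates, per
sample, the mean and standard deviation of the *complete* log2
distribution from the observed upper-tail order statistics, then draws
each missing value from a normal with those parameters truncated above
at the sample's minimum observed value.

Parameter estimation here regresses the observed sorted values y_(i) on
standard-normal quantiles evaluated at Blom-type plotting positions
(r - 0.375)/(n + 0.25), where the rank r of the smallest observed value
starts *after* the censored count — i.e. the observed values are treated
as the top k of n order statistics. The least-squares slope estimates
sigma and the intercept estimates mu of the complete distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtri

from .matrix import IntensityMatrix

__all__ = ["LogMatrix", "ImputedMatrix", "prefilter_min_nonzero",
           "log2_transform", "qrilc_impute", "delog"]


@dataclass
class LogMatrix:
    """Log2 intensities with NaN marking not-observed entries."""

    values: pd.DataFrame
    proteins: pd.DataFrame = None
    samples: pd.DataFrame = None

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class ImputedMatrix:
    """Complete log2 matrix plus the imputation audit trail."""

    values: pd.DataFrame
    imputed_mask: pd.DataFrame
    params: pd.DataFrame  # per sample: mu, sigma, truncation, tune_sigma, seed
    proteins: pd.DataFrame = None
    samples: pd.DataFrame = None


def prefilter_min_nonzero(matrix: IntensityMatrix, group_labels,
                          min_nonzero: int = 2) -> IntensityMatrix:
    """Keep proteins with >= min_nonzero nonzero values in *every* group.

    ``group_labels`` maps each sample id to its treatment group (a dict
    or a Series). Protein order is preserved.
    """
    labels = pd.Series(group_labels)
    unknown = set(matrix.values.columns) - set(labels.index)
    if unknown:
        raise ValueError(f"samples without a group label: {sorted(unknown)}")
    labels = labels[matrix.values.columns]
    nonzero = matrix.values > 0
    keep = pd.Series(True, index=matrix.values.index)
    for _, cols in nonzero.T.groupby(labels, sort=False):
        keep &= cols.sum(axis=0) >= min_nonzero
    return matrix.select_proteins(accessions=matrix.values.index[keep])


def log2_transform(matrix: IntensityMatrix) -> LogMatrix:
    """Log2 of positive intensities; zeros become missing (NaN)."""
    arr = matrix.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    with np.errstate(divide="ignore"):
        logged = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    values = pd.DataFrame(logged, index=matrix.values.index,
                          columns=matrix.values.columns)
    return LogMatrix(values, matrix.proteins.copy(), matrix.samples.copy())


def _estimate_censored_normal(observed: np.ndarray, n_total: int) -> tuple[float, float]:
    """(mu, sigma) of the complete distribution from top-k order stats."""
    y = np.sort(observed)
    k = y.size
    ranks = np.arange(n_total - k + 1, n_total + 1)
    pp = (ranks - 0.375) / (n_total + 0.25)
    x = ndtri(pp)
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def qrilc_impute(logmat: LogMatrix, tune_sigma: float = 1.0,
                 seed: int | None = None) -> ImputedMatrix:
    """Impute missing log2 values column-wise from a truncated normal.

    Per sample: estimate (mu, sigma) of the complete distribution by
    quantile regression on the observed order statistics, then draw each
    missing entry from Normal(mu, sigma * tune_sigma) truncated above at
    the sample's minimum observed value. Observed entries pass through
    bit-identical. Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If any sample has fewer than 3 observed values, or a sigma
        estimate is non-positive.
    """
    rng = np.random.default_rng(seed)
    values = logmat.values.copy()
    imputed_mask = logmat.values.isna()
    rows: list[dict] = []
    for col in values.columns:
        v = values[col].to_numpy(copy=True)
        miss = np.isnan(v)
        obs = v[~miss]
        if obs.size < 3:
            raise ValueError(
                f"sample {col!r} has only {obs.size} observed values; "
                "QRILC needs at least 3")
        if miss.any():
            mu, sigma = _estimate_censored_normal(obs, v.size)
            if sigma <= 0:
                raise ValueError(f"non-positive sigma estimate for sample {col!r}")
            trunc = float(obs.min())
            sd = sigma * tune_sigma
            b = (trunc - mu) / sd
            draws = sps.truncnorm.rvs(-np.inf, b, loc=mu, scale=sd,
                                      size=int(miss.sum()), random_state=rng)
            v[miss] = draws
            values[col] = v
        else:
            mu, sigma, trunc = np.nan, np.nan, np.nan
        rows.append({"sample_id": col, "mu": mu, "sigma": sigma,
                     "truncation": trunc, "tune_sigma": tune_sigma,
                     "n_imputed": int(miss.sum())})
    params = pd.DataFrame(rows).set_index("sample_id")
    params["seed"] = seed
    return ImputedMatrix(values, imputed_mask, params,
                         logmat.proteins, logmat.samples)


def delog(imputed: ImputedMatrix) -> pd.DataFrame:
    """Back-transform log2 values to the decimal scale (2**x)."""
    return np.power(2.0, imputed.values)
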