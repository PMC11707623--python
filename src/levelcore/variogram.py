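"""Empirical semivariograms of habitat covariates at relocation points.

gamma(h) = (1 / (2 N(h))) * sum over point pairs in lag bin h of
(z_i - z_j)^2.  Used as a diagnostic: covariates measured at animal
locations inherit the landscape's spatial autocorrelation, so gamma rises
with lag and plateaus near the field's practical range.  Omnidirectional
only; no variogram model is fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist


class VariogramError(ValueError):
    pass


@dataclass
class Semivariogram:
    lag_centers: np.ndarray
    gamma: np.ndarray              # NaN where a bin holds no pairs
    pair_counts: np.ndarray
    max_lag: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_m": self.lag_centers, "gamma": self.gamma,
                             "n_pairs": self.pair_counts})


def empirical_semivariogram(points: np.ndarray, values: np.ndarray,
                            n_bins: int = 15,
                            max_lag: float | None = None) -> Semivariogram:
    """Equal-width binned semivariogram on (0, max_lag].

    Default max_lag is half the maximum pairwise distance (beyond that,
    pair support thins and the estimate is unstable).
    """
    pts = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(pts) < 2:
        raise VariogramError("need >= 2 points")
    d = pdist(pts)
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if max_lag > d.max():
        raise VariogramError("max_lag exceeds the maximum pairwise distance")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges[1:], right=True)       # bin index per pair
    valid = d <= max_lag
    counts = np.bincount(which[valid], minlength=n_bins)[:n_bins]
    sums = np.bincount(which[valid], weights=sq[valid],
                       minlength=n_bins)[:n_bins]
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Semivariogram(lag_centers=centers, gamma=gamma,
                         pair_counts=counts, max_lag=float(max_lag))
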