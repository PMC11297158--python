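"""Paired p38-NFkB correlation structure and coefficients of variation.

Spearman rank correlations between p38 and NFkB dynamic features (or
half-hour activity integrals) of the same cells quantify how much of the
cell-to-cell heterogeneity is shared between the two pathways.  A
correlation is flagged significant when p < 0.05 AND |CC| > 0.15.  Shuffling
one pathway's cell assignments within a condition is the negative control:
it destroys pairing, so all correlations collapse to ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_THRESHOLD = 0.05
CC_THRESHOLD = 0.15
EXACT_PERMUTATIONS = 10_000
EXACT_N_MAX = 30


@dataclass
class CorrelationReport:
    cc: pd.DataFrame       # rows: p38 columns, cols: nfkb columns
    p_values: pd.DataFrame
    mask: pd.DataFrame     # significant AND |CC| above threshold
    n_cells: int
    condition: str = ""

    def corresponding_pairs(self) -> pd.Series:
        """Diagonal of the matrix for features sharing a base name."""
        out = {}
        for a in self.cc.index:
            base = a.split("_", 1)[1] if "_" in a else a
            for b in self.cc.columns:
                if (b.split("_", 1)[1] if "_" in b else b) == base:
                    out[base] = self.cc.loc[a, b]
        return pd.Series(out)


def _spearman(a: np.ndarray, b: np.ndarray, seed: int = 0) -> tuple[float, float]:
    n = a.size
    if np.all(a == a[0]) or np.all(b == b[0]):
        # a constant column carries no rank information
        return float("nan"), float("nan")
    if n > EXACT_N_MAX:
        rho, p = stats.spearmanr(a, b)
        return float(rho), float(p)
    # small n: permutation p-value for the rank correlation
    res = stats.permutation_test(
        (a,), lambda x: stats.spearmanr(x, b).statistic,
        permutation_type="pairings", n_resamples=EXACT_PERMUTATIONS,
        alternative="two-sided", rng=np.random.default_rng(seed))
    rho, _ = stats.spearmanr(a, b)
    return float(rho), float(res.pvalue)


def spearman_paired(features: pd.DataFrame, set_a: list, set_b: list,
                    condition: str = "", seed: int = 0) -> CorrelationReport:
    """Rank-correlation matrix between paired p38 and NFkB columns.

    Rows with a missing value in either column of a pair are dropped pairwise.
    Ties receive average ranks (scipy convention); p-values are two-sided
    (t approximation above n = 30, permutation below).
    """
    if len(features) < 10:
        raise ValueError("need at least 10 paired cells")
    cc = pd.DataFrame(index=set_a, columns=set_b, dtype=float)
    pv = pd.DataFrame(index=set_a, columns=set_b, dtype=float)
    for a in set_a:
        for b in set_b:
            pair = features[[a, b]].dropna()
            if len(pair) < 10:
                cc.loc[a, b], pv.loc[a, b] = np.nan, np.nan
                continue
            rho, p = _spearman(pair[a].to_numpy(), pair[b].to_numpy(), seed)
            cc.loc[a, b], pv.loc[a, b] = rho, p
    mask = (pv < P_THRESHOLD) & (cc.abs() > CC_THRESHOLD)
    return CorrelationReport(cc=cc, p_values=pv, mask=mask,
                             n_cells=len(features), condition=condition)


def shuffle_control(features: pd.DataFrame, set_a: list, set_b: list,
                    shuffle: str = "nfkb", seed: int = 0,
                    condition_column: str = "condition") -> CorrelationReport:
    """Correlations after permuting one pathway's rows within each condition."""
    rng = np.random.default_rng(seed)
    cols = set_b if shuffle == "nfkb" else set_a
    shuffled = features.copy()
    if condition_column in features.columns:
        groups = features.groupby(condition_column, sort=False).indices.values()
    else:
        groups = [np.arange(len(features))]
    for idx in groups:
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        shuffled.iloc[idx, [features.columns.get_loc(c) for c in cols]] = \
            features.iloc[idx[perm]][cols].to_numpy()
    condition = (features[condition_column].iloc[0]
                 if condition_column in features.columns and len(features) else "")
    return spearman_paired(shuffled, set_a, set_b, condition=str(condition), seed=seed)


def coefficient_of_variation(values) -> float:
    """Sample SD divided by the mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / mean)
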