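"""Condition-level aggregation of per-cell measurements.

Single-cell FCS yields one (D, c) pair per cell, compartment and channel;
distributions over >= 40 cells per condition are summarized by medians with
robust dispersions (MAD and IQR — published "+-" spreads are often neither
labeled nor normal, so both are emitted).  Pairwise condition comparisons
use the two-sided Mann-Whitney U test with the conventional star notation
(*** p<0.001, ** p<0.01, * p<0.05, NS otherwise).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CellMeasurement", "MannWhitneyResult", "mann_whitney",
           "stars_for_p", "summarize", "compare_groups"]

#: exact null enumeration up to this product of group sizes, normal
#: approximation (tie- and continuity-corrected) beyond
_EXACT_LIMIT = 10_000


@dataclass
class CellMeasurement:
    """One channel of one 120 s-style acquisition in one cell."""

    cell_id: str
    compartment: str          # cytosol | nucleus
    condition: str
    channel: str              # G | R
    D: float                  # um^2/s
    c: float                  # nM
    N_apparent: float = np.nan
    N_corrected: float = np.nan
    tau_D: float = np.nan     # s
    chi2_reduced: float = np.nan
    mean_rate: float = np.nan  # Hz
    cross_amplitude: float = np.nan
    cross_se: float = np.nan
    qc_flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def qc_pass(self) -> bool:
        return len(self.qc_flags) == 0


class MannWhitneyResult(NamedTuple):
    U: float
    p: float
    stars: str


def stars_for_p(p: float) -> str:
    if not np.isfinite(p) or not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test between two per-cell value sets.

    Small, tie-free problems (n_a * n_b <= 10^4) use the exact null
    distribution; larger or tied ones the normal approximation with tie and
    continuity corrections.  Two fully tied groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(U=a.size * b.size / 2.0, p=1.0, stars="NS")
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size * b.size <= _EXACT_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return MannWhitneyResult(U=float(res.statistic), p=p, stars=stars_for_p(p))


def _to_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    rows = []
    for m in measurements:
        d = dict(vars(m))
        d["qc_flags"] = ";".join(m.qc_flags)
        rows.append(d)
    return pd.DataFrame(rows)


def _mad(x: np.ndarray) -> float:
    return float(stats.median_abs_deviation(x, nan_policy="omit"))


def _iqr(x: np.ndarray) -> float:
    return float(stats.iqr(x, nan_policy="omit"))


def summarize(measurements, group_keys=("condition", "compartment", "channel"),
              values=("D", "c"), min_n: int = 10) -> pd.DataFrame:
    """Medians and robust dispersions per group of cell measurements.

    Groups smaller than ``min_n`` are kept but flagged; empty groups cannot
    arise from a groupby and all-NaN value columns are summarized as NaN
    with a warning.
    """
    df = _to_frame(measurements)
    if df.empty:
        raise ValueError("no measurements to summarize")
    group_keys = list(group_keys)
    out = []
    for keys, grp in df.groupby(group_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_keys, keys))
        row["n"] = len(grp)
        for v in values:
            x = grp[v].to_numpy(dtype=float)
            if np.all(np.isnan(x)):
                warnings.warn(f"group {keys}: all {v} values missing")
            row[f"median_{v}"] = float(np.nanmedian(x)) if np.isfinite(x).any() else np.nan
            row[f"mad_{v}"] = _mad(x)
            row[f"iqr_{v}"] = _iqr(x)
        row["small_group"] = len(grp) < min_n
        out.append(row)
    return pd.DataFrame(out)


def compare_groups(measurements, value: str = "D", group_key: str = "condition",
                   within=("compartment", "channel")) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of one value column across groups.

    Comparisons are made separately inside each combination of the
    ``within`` keys (e.g. per compartment and channel).  Unadjusted p-values
    by design; multiplicity handling is the caller's decision.
    """
    df = _to_frame(measurements)
    within = [w for w in within if w in df.columns]
    rows = []
    strata = df.groupby(within, sort=True) if within else [((), df)]
    for wkeys, stratum in strata:
        if not isinstance(wkeys, tuple):
            wkeys = (wkeys,)
        names = sorted(stratum[group_key].unique())
        for ga, gb in itertools.combinations(names, 2):
            xa = stratum.loc[stratum[group_key] == ga, value].dropna().to_numpy()
            xb = stratum.loc[stratum[group_key] == gb, value].dropna().to_numpy()
            if xa.size < 3 or xb.size < 3:
                warnings.warn(f"skipping {ga} vs {gb}: fewer than 3 values")
                continue
            res = mann_whitney(xa, xb)
            row = dict(zip(within, wkeys))
            row.update({"group_a": ga, "group_b": gb, "value": value,
                        "n_a": xa.size, "n_b": xb.size,
                        "U": res.U, "p": res.p, "stars": res.stars})
            rows.append(row)
    return pd.DataFrame(rows)
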