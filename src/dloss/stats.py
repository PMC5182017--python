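"""Comparative damage statistics.

* Atom-type ranking: atom types ordered per dataset by mean D_loss (rank 0 =
  most damaged); across datasets, the products of per-dataset ranks are
  ranked again, which mitigates dose-scale miscalibration between datasets.
* Damage signatures: the distribution of Cα-normalized D_loss values over all
  heavy atoms of a residue type, compared between topologically similar
  residue pairs with the two-sample Kolmogorov–Smirnov statistic and
  summarized with Gaussian KDEs.
* Hotelling T² for comparing the multivariate (per-dose) D_loss vectors of
  two atom groups, and ordinary linear R² for covariate correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .structures import AtomTypeKey

__all__ = [
    "RankTable",
    "TestResult",
    "rank_atom_types",
    "ks_statistic",
    "signature_kde",
    "hotelling_t2",
    "linear_r2",
    "OXYGEN_TYPE_KEYS",
]

log = logging.getLogger(__name__)

# Side-chain oxygen species compared against Tyr OH (equal electron counts):
# the carboxylate oxygens of Glu/Asp plus the control group of amide/hydroxyl
# oxygens not suspected to be cleaved.
OXYGEN_TYPE_KEYS: tuple[AtomTypeKey, ...] = (
    AtomTypeKey("GLU", "OE1"), AtomTypeKey("GLU", "OE2"),
    AtomTypeKey("ASP", "OD1"), AtomTypeKey("ASP", "OD2"),
    AtomTypeKey("GLN", "OE1"), AtomTypeKey("ASN", "OD1"),
    AtomTypeKey("SER", "OG"), AtomTypeKey("THR", "OG1"),
    AtomTypeKey("TYR", "OH"),
)

CONTROL_OXYGEN_KEYS: tuple[AtomTypeKey, ...] = (
    AtomTypeKey("GLN", "OE1"), AtomTypeKey("ASN", "OD1"),
    AtomTypeKey("SER", "OG"), AtomTypeKey("THR", "OG1"),
)


@dataclass
class TestResult:
    statistic: float
    p_value: float | None
    n_a: int
    n_b: int
    method: str


@dataclass
class RankTable:
    """Per-type mean D_loss, per-dataset ranks and the across-dataset rank.

    ``table`` is indexed by atom-type string (e.g. "GLU-OE1") with columns
    ``mean_<label>``, ``rank_<label>`` per dataset plus ``rank_product`` and
    ``rank_overall`` (0 = most damaged).  ``missing`` lists requested types
    absent from the structure.
    """

    table: pd.DataFrame
    datasets: list[str]
    missing: list[AtomTypeKey]

    def rank_of(self, key: AtomTypeKey) -> int:
        return int(self.table.loc[str(key), "rank_overall"])

    def __contains__(self, key: AtomTypeKey) -> bool:
        return str(key) in self.table.index


def rank_atom_types(dloss_table: pd.DataFrame,
                    keys: Sequence[AtomTypeKey] = OXYGEN_TYPE_KEYS,
                    value_column: str = "dloss_raw") -> RankTable:
    """Rank atom types by mean D_loss per dataset, then by rank product.

    Ranks start at 0 for the most damaged type in each dataset.  Ties (in
    per-dataset means or in rank products) are broken by the mean of
    per-dataset ranks, then lexicographically by atom-type key; the policy is
    logged whenever it fires.
    """
    datasets = list(dict.fromkeys(dloss_table["dataset"]))
    if not datasets:
        raise ValueError("D_loss table contains no datasets")
    present, missing = [], []
    means: dict[AtomTypeKey, np.ndarray] = {}
    for key in keys:
        sub = dloss_table[(dloss_table["residue_name"] == key.residue_name)
                          & (dloss_table["atom_name"] == key.atom_name)]
        if sub.empty:
            missing.append(key)
            continue
        present.append(key)
        means[key] = np.array([sub[sub["dataset"] == d][value_column].mean()
                               for d in datasets])
    if missing:
        log.info("atom types absent from structure, excluded from ranking: %s",
                 ", ".join(map(str, missing)))
    if not present:
        raise ValueError("none of the requested atom types is present")
    mean_mat = np.array([means[k] for k in present])          # (n_types, n_datasets)
    names = [str(k) for k in present]
    rank_mat = np.empty_like(mean_mat, dtype=int)
    for j in range(mean_mat.shape[1]):
        col = mean_mat[:, j]
        if len(np.unique(col)) < len(col):
            log.info("tied per-dataset means in dataset %s: lexicographic tie-break",
                     datasets[j])
        order = sorted(range(len(col)), key=lambda i: (-col[i], names[i]))
        for r, i in enumerate(order):
            rank_mat[i, j] = r
    products = rank_mat.astype(float).prod(axis=1)
    mean_ranks = rank_mat.mean(axis=1)
    if len(np.unique(products)) < len(products):
        log.info("tied rank products: mean-of-ranks then lexicographic tie-break")
    overall_order = sorted(range(len(present)),
                           key=lambda i: (products[i], mean_ranks[i], names[i]))
    overall = np.empty(len(present), dtype=int)
    for r, i in enumerate(overall_order):
        overall[i] = r
    data = {}
    for j, d in enumerate(datasets):
        data[f"mean_{d}"] = mean_mat[:, j]
        data[f"rank_{d}"] = rank_mat[:, j]
    data["rank_product"] = products
    data["rank_overall"] = overall
    return RankTable(pd.DataFrame(data, index=names), datasets, missing)


def ks_statistic(sample_a: Sequence[float], sample_b: Sequence[float],
                 method: str = "auto") -> TestResult:
    """Two-sample Kolmogorov–Smirnov statistic sup|ECDF_a − ECDF_b| with p-value.

    ``method="auto"`` uses the exact finite-sample null distribution for the
    sample sizes that arise here; the asymptotic formula is known to be
    conservative at n of a few tens and is available via ``method="asymp"``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = sps.ks_2samp(a, b, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), a.size, b.size, "KS")


def signature_kde(sample: Sequence[float],
                  bandwidth: float | str = "scott",
                  n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of a damage signature on a grid spanning data ± 3 bandwidths.

    Scott's rule is the default bandwidth; the returned densities integrate to
    1 within ~1e-3 on the grid.
    """
    x = np.asarray(sample, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("degenerate sample (all values equal); use a histogram")
    bw_method = bandwidth if isinstance(bandwidth, str) else bandwidth / x.std(ddof=1)
    kde = sps.gaussian_kde(x, bw_method=bw_method)
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, max(n_grid, 256))
    return grid, kde(grid)


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-sample Hotelling T² with pooled covariance and the F transform.

    Rows are members (atoms), columns the p doses.  The statistic is referred
    to F(p, n_a + n_b − p − 1) via F = T²·(n_a+n_b−p−1) / (p·(n_a+n_b−2)).
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the dose dimension")
    na, nb, p = A.shape[0], B.shape[0], A.shape[1]
    if na + nb - 2 <= p:
        raise ValueError("need n_a + n_b − 2 > p observations for Hotelling T²")
    d = A.mean(axis=0) - B.mean(axis=0)
    S = (((na - 1) * np.cov(A, rowvar=False, ddof=1).reshape(p, p)
          + (nb - 1) * np.cov(B, rowvar=False, ddof=1).reshape(p, p))
         / (na + nb - 2))
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; consider dropping collinear doses") from exc
    t2 = float(na * nb / (na + nb) * d @ sol)
    df2 = na + nb - p - 1
    f_stat = t2 * df2 / (p * (na + nb - 2))
    p_value = float(sps.f.sf(f_stat, p, df2))
    return TestResult(t2, p_value, na, nb, "HotellingT2")


def linear_r2(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Ordinary least-squares R² (with intercept) of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; R² undefined")
    if np.ptp(y) == 0:
        warnings.warn("y is constant; defining R² = 0", stacklevel=2)
        return TestResult(0.0, None, x.size, x.size, "R2")
    fit = sps.linregress(x, y)
    return TestResult(float(fit.rvalue**2), float(fit.pvalue), x.size, x.size, "R2")
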