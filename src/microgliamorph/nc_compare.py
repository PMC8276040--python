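"""Nearest-centroid classification and CNN-vs-NC conformity analysis.

Centroids are per-class componentwise medians over a training table; cells
are assigned the class of the Euclidean-nearest centroid in the selected
parameter subspace. Agreement between the CNN and NC labelings is summarized
as a 4x4 cross-tabulation, its degree of conformity (trace over total) and an
exact symmetry test for paired contingency tables (pairwise two-sided
binomial tests, multiplicity-adjusted).

The SRI parameter is excluded from all of this because it is undefined for
cells without processes; the 17 remaining parameters are enumerated in
``morphometry.NC_PARAM_NAMES``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import PHENOTYPES
from .morphometry import NC_PARAM_NAMES


@dataclass
class ClassCentroids:
    centroids: dict[str, np.ndarray]  # class -> vector over parameter_subset
    parameter_subset: tuple[str, ...]
    scaling: str = "raw"  # or "zscore"
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None


@dataclass
class ConformityResult:
    matrix: np.ndarray  # rows = CNN class, cols = NC class
    conformity: float
    symmetry_p: float
    subset: tuple[str, ...] = ()


@dataclass
class SweepResult:
    records: pd.DataFrame  # columns: subset, k, conformity, symmetry_p
    per_k_summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def _check_table(table: pd.DataFrame, subset) -> None:
    missing = [p for p in subset if p not in table.columns]
    if missing:
        raise KeyError(f"missing parameter columns: {missing}")


def compute_centroids(
    training_table: pd.DataFrame,
    subset=NC_PARAM_NAMES,
    scaling: str = "raw",
    label_column: str = "label",
) -> ClassCentroids:
    """Per-class componentwise medians (even counts use midpoint interpolation)."""
    subset = tuple(subset)
    _check_table(training_table, subset)
    mean = sd = None
    values = training_table.loc[:, list(subset)].to_numpy(dtype=float)
    if scaling == "zscore":
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    elif scaling != "raw":
        raise ValueError(f"unknown scaling {scaling!r}")
    centroids = {}
    for cls in PHENOTYPES:
        sel = training_table[label_column] == cls
        if not sel.any():
            raise ValueError(f"no training cells for class {cls!r}")
        centroids[cls] = np.median(values[sel.to_numpy()], axis=0)
    return ClassCentroids(
        centroids=centroids, parameter_subset=subset, scaling=scaling,
        scale_mean=mean, scale_sd=sd,
    )


def nc_classify(table: pd.DataFrame, centroids: ClassCentroids) -> list[str]:
    """Euclidean nearest-centroid labels; distance ties use fixed class order."""
    _check_table(table, centroids.parameter_subset)
    x = table.loc[:, list(centroids.parameter_subset)].to_numpy(dtype=float)
    c = np.stack([centroids.centroids[cls] for cls in PHENOTYPES])
    if centroids.scaling == "zscore":
        x = (x - centroids.scale_mean) / centroids.scale_sd
        c = (c - centroids.scale_mean) / centroids.scale_sd
    d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    return [PHENOTYPES[int(i)] for i in d2.argmin(axis=1)]  # argmin: first min wins


def _cross_tab(cnn_labels, nc_labels) -> np.ndarray:
    k = len(PHENOTYPES)
    idx = {cls: i for i, cls in enumerate(PHENOTYPES)}
    m = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(cnn_labels, nc_labels, strict=True):
        m[idx[a], idx[b]] += 1
    return m


def exact_symmetry_test(matrix: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Exact symmetry test for a paired contingency table.

    Each off-diagonal pair (i, j) gets a two-sided exact binomial test of
    n_ij successes in n_ij + n_ji trials at p = 1/2; the per-pair p-values
    are Benjamini-Hochberg adjusted and the global p is their minimum.
    Pairs with no discordant observations contribute p = 1.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    rows = []
    for i, j in itertools.combinations(range(m.shape[0]), 2):
        nij, nji = int(m[i, j]), int(m[j, i])
        if nij + nji == 0:
            p = 1.0
        else:
            p = stats.binomtest(nij, nij + nji, 0.5).pvalue
        rows.append((i, j, nij, nji, p))
    raw = np.array([r[4] for r in rows])
    adjusted = np.minimum(stats.false_discovery_control(raw, method="bh"), 1.0)
    pairs = pd.DataFrame(rows, columns=["i", "j", "n_ij", "n_ji", "p_raw"])
    pairs["p_adjusted"] = adjusted
    return float(adjusted.min()), pairs


def conformity(cnn_labels, nc_labels, subset=()) -> ConformityResult:
    """Degree of conformity between two labelings over the 4 classes."""
    if len(cnn_labels) == 0:
        raise ValueError("empty label vectors")
    m = _cross_tab(cnn_labels, nc_labels)
    sym_p, _ = exact_symmetry_test(m)
    return ConformityResult(
        matrix=m,
        conformity=float(np.trace(m)) / float(m.sum()),
        symmetry_p=sym_p,
        subset=tuple(subset),
    )


def enumerate_subsets(parameters=NC_PARAM_NAMES, k_min: int = 2, k_max: int | None = None):
    """Lexicographic, duplicate-free subsets of sizes k_min..k_max."""
    parameters = tuple(parameters)
    if k_max is None:
        k_max = len(parameters)
    if not 1 <= k_min <= k_max <= len(parameters):
        raise ValueError("invalid subset size bounds")
    for k in range(k_min, k_max + 1):
        yield from itertools.combinations(parameters, k)


def count_subsets(n: int, k_min: int = 2, k_max: int | None = None) -> int:
    if k_max is None:
        k_max = n
    return sum(math.comb(n, k) for k in range(k_min, k_max + 1))


def sweep(
    table: pd.DataFrame,
    cnn_labels,
    training_table: pd.DataFrame | None = None,
    k_min: int = 2,
    k_max: int | None = None,
    parameters=NC_PARAM_NAMES,
    scaling: str = "raw",
    label_column: str = "label",
    symmetry: bool = True,
) -> SweepResult:
    """Conformity of NC vs CNN labels for every parameter subset.

    Medians are componentwise, so full-space class centroids are computed
    once and sliced per subset. ``training_table`` defaults to ``table``
    labeled with ``cnn_labels`` (centroids from the compared cells).
    """
    parameters = tuple(parameters)
    if training_table is None:
        training_table = table.copy()
        training_table[label_column] = list(cnn_labels)
    cents = compute_centroids(training_table, parameters, scaling, label_column)
    x = table.loc[:, list(parameters)].to_numpy(dtype=float)
    c = np.stack([cents.centroids[cls] for cls in PHENOTYPES])
    if scaling == "zscore":
        x = (x - cents.scale_mean) / cents.scale_sd
        c = (c - cents.scale_mean) / cents.scale_sd
    # per-parameter squared differences, reused across subsets
    d2 = (x[:, None, :] - c[None, :, :]) ** 2  # (cells, 4, params)
    y_true = np.array([PHENOTYPES.index(l) for l in cnn_labels])
    k_classes = len(PHENOTYPES)
    records = []
    col_index = {p: i for i, p in enumerate(parameters)}
    for subset in enumerate_subsets(parameters, k_min, k_max):
        cols = [col_index[p] for p in subset]
        pred = d2[:, :, cols].sum(axis=2).argmin(axis=1)
        m = np.zeros((k_classes, k_classes), dtype=np.int64)
        np.add.at(m, (y_true, pred), 1)
        conf = float(np.trace(m)) / float(m.sum())
        sym_p = exact_symmetry_test(m)[0] if symmetry else float("nan")
        records.append(("+".join(subset), len(subset), conf, sym_p))
    df = pd.DataFrame(records, columns=["subset", "k", "conformity", "symmetry_p"])
    per_k = (
        df.groupby("k")["conformity"]
        .agg(["min", "median", "max"])
        .reset_index()
        .rename(columns={"min": "conformity_min", "median": "conformity_median",
                         "max": "conformity_max"})
    )
    return SweepResult(records=df, per_k_summary=per_k)


def top_parameters(sweep_result: SweepResult, top_fraction: float = 0.05) -> pd.DataFrame:
    """Per-parameter representation among the top-conformity subsets."""
    df = sweep_result.records
    n_top = max(1, int(len(df) * top_fraction))
    top = df.nlargest(n_top, "conformity")
    counts: dict[str, int] = {}
    for s in top["subset"]:
        for p in s.split("+"):
            counts[p] = counts.get(p, 0) + 1
    out = pd.DataFrame(sorted(counts.items(), key=lambda kv: -kv[1]),
                       columns=["parameter", "count"])
    out["fraction_of_top"] = out["count"] / n_top
    return out


def correlation_analysis(
    table: pd.DataFrame,
    cnn_labels,
    parameters=NC_PARAM_NAMES,
    training_table: pd.DataFrame | None = None,
) -> dict:
    """Spearman correlations of all parameter pairs and the relationship
    between two-parameter conformity and |rho|.

    Returns a dict with the full correlation matrix (DataFrame), a per-pair
    table (rho, |rho|, conformity) and the least-squares regression of
    conformity on |rho| (slope, intercept, Pearson r). Pairs involving a
    constant column get NaN correlations and are dropped from the regression.
    """
    parameters = tuple(parameters)
    _check_table(table, parameters)
    if len(table) < 3:
        raise ValueError("need at least 3 cells")
    values = table.loc[:, list(parameters)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_mat = stats.spearmanr(values).statistic
    rho = pd.DataFrame(rho_mat, index=parameters, columns=parameters)
    two = sweep(table, cnn_labels, training_table, k_min=2, k_max=2,
                parameters=parameters, symmetry=False).records
    pair_rho = []
    for s in two["subset"]:
        a, b = s.split("+")
        pair_rho.append(rho.loc[a, b])
    two = two.assign(rho=pair_rho, abs_rho=np.abs(pair_rho))
    ok = two.dropna(subset=["abs_rho"])
    if len(ok) >= 2 and ok["abs_rho"].nunique() > 1:
        slope, intercept = np.polyfit(ok["abs_rho"], ok["conformity"], 1)
        r = float(np.corrcoef(ok["abs_rho"], ok["conformity"])[0, 1])
    else:
        slope = intercept = r = float("nan")
    return {
        "correlation_matrix": rho,
        "pairs": two,
        "regression": {"slope": float(slope), "intercept": float(intercept), "r": r},
    }
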