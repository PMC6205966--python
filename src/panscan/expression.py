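"""Probe-level microarray normalization and per-gene developmental profiles.

The pipeline implements the two summarization steps of RMA that operate on
the probe matrix: quantile normalization across arrays and Tukey median
polish within each probeset, both on the log2 scale.  (The convolution
background-correction step of full RMA is not part of this pipeline.)
Per-gene developmental profiles are the arithmetic means of the biological
replicates at each time point, reported as log2.

Conventions, stated once for determinism:

* log2 is taken before both normalization steps;
* quantile-normalization ties within a column receive the mean of the
  reference values at their tied ranks;
* the polish is run per probeset; a probeset's expression on an array is
  the fitted overall effect plus that array's column effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ProbeMatrix:
    """Raw probe intensities with probe->probeset and array->design maps."""

    intensities: pd.DataFrame  # probes x arrays, positive
    probe_map: dict[str, str]  # probe id -> probeset/gene id
    design: dict[str, tuple[float, int]]  # array id -> (time point, replicate)

    def __post_init__(self) -> None:
        if (self.intensities <= 0).any().any():
            raise ValueError("intensities must be positive")
        unmapped = set(self.intensities.index) - set(self.probe_map)
        if unmapped:
            raise ValueError(f"unmapped probes: {sorted(unmapped)[:5]}")


@dataclass(frozen=True)
class ExpressionProfile:
    gene: str
    time_points: tuple[float, ...]
    values: tuple[float, ...]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common empirical distribution: the
    across-column mean of sorted values.  Ties within a column receive the
    mean of the reference values at their tied ranks."""
    if matrix.isna().any().any():
        raise ValueError("matrix has missing cells")
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average assigned reference values over tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(
    matrix: pd.DataFrame | np.ndarray,
    tol: float = 0.01,
    max_iter: int = 10,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish: decompose a (log-scale) matrix into
    overall + row effects + column effects + residuals.

    Iterates row- and column-median sweeps until the change in the total
    absolute residual is below ``tol`` or ``max_iter`` is reached.  The
    decomposition reconstructs the input exactly at every iteration.
    """
    Z = np.asarray(matrix, dtype=float).copy()
    if Z.ndim != 2 or Z.shape[0] < 1 or Z.shape[1] < 1:
        raise ValueError("need a 2-D matrix")
    nr, nc = Z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    last = None
    for _ in range(max_iter):
        rmed = np.median(Z, axis=1)
        Z -= rmed[:, None]
        row += rmed
        cm = np.median(col)
        col -= cm
        overall += cm

        cmed = np.median(Z, axis=0)
        Z -= cmed[None, :]
        col += cmed
        rm = np.median(row)
        row -= rm
        overall += rm

        total = np.abs(Z).sum()
        if last is not None and abs(last - total) < tol:
            break
        last = total
    return overall, row, col, Z


def summarize_probesets(pm: ProbeMatrix) -> pd.DataFrame:
    """log2 -> quantile normalization (whole matrix) -> per-probeset median
    polish; returns gene x array log2 expression (overall + column effect).

    A single-probe probeset degenerates to its normalized probe row.
    """
    log2 = np.log2(pm.intensities)
    norm = quantile_normalize(log2)
    genes = sorted(set(pm.probe_map.values()))
    arrays = list(norm.columns)
    out = pd.DataFrame(np.nan, index=genes, columns=arrays)
    by_gene: dict[str, list[str]] = {}
    for probe, gene in pm.probe_map.items():
        if probe in norm.index:
            by_gene.setdefault(gene, []).append(probe)
    for gene in genes:
        probes = sorted(by_gene.get(gene, []))
        if not probes:
            continue
        sub = norm.loc[probes]
        if len(probes) == 1:
            out.loc[gene] = sub.iloc[0].to_numpy()
        else:
            overall, _row, col, _res = median_polish(sub)
            out.loc[gene] = overall + col
    return out.dropna(how="all")


def mean_replicate_profile(
    expression: pd.DataFrame,
    design: dict[str, tuple[float, int]],
    genes: list[str] | None = None,
) -> list[ExpressionProfile]:
    """Average expression over biological replicates per time point.

    ``design`` maps array id -> (time point, replicate).  Raises on genes
    absent from the expression table, listing all of them.
    """
    genes = list(genes) if genes is not None else list(expression.index)
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    times = sorted({t for t, _ in design.values()})
    by_time = {
        t: [a for a in expression.columns if design[a][0] == t] for t in times
    }
    for t, arrays in by_time.items():
        if not arrays:
            raise ValueError(f"time point {t} has no arrays")
    profiles = []
    for g in genes:
        vals = tuple(float(expression.loc[g, by_time[t]].mean()) for t in times)
        profiles.append(
            ExpressionProfile(gene=g, time_points=tuple(times), values=vals)
        )
    return profiles


def profiles_to_frame(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    """Gene x time-point table of mean log2 expression."""
    if not profiles:
        return pd.DataFrame()
    times = profiles[0].time_points
    return pd.DataFrame(
        {p.gene: p.values for p in profiles}, index=list(times)
    ).T


def plot_profiles(profiles: list[ExpressionProfile], path: str) -> None:
    """Line plot of per-gene developmental expression profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    for p in profiles:
        ax.plot(p.time_points, p.values, marker="o", label=p.gene)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("mean log2 expression")
    ax.legend(fontsize=6, ncols=2)
    fig.savefig(path, dpi=150)
    plt.close(fig)
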