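"""Kitome-corrected community analysis on the spatial sampling grid.

Workflow for the 16S rRNA amplicon data of the reactor post-mortems:
subtract the reagent-blank ("kitome") reads per ASV, renormalize to
relative abundances, confirm taxon presence against the blank, ordinate
with a Hellinger-transformed PCA, compare 16S copies/gram across the five
radial sampling columns (variance-gated t-tests, off-center vs center),
and interpolate grid values into dense spatial maps.

Raw read processing (denoising, chimera removal, taxonomy assignment)
happens upstream and is out of scope here; this module starts from an ASV
count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator, griddata

from .reactor_sim import ASVTable, GRID_COLUMNS, GRID_ROWS

__all__ = [
    "CorrectedTable",
    "ColumnTest",
    "RelativeAbundance",
    "kitome_correct",
    "relative_abundance",
    "pooled_relative_abundance",
    "confirm_presence",
    "hellinger",
    "pca_ordination",
    "column_biomass_tests",
    "spatial_map",
]

OFF_CENTER = ("OL", "CL", "CR", "OR")


@dataclass
class CorrectedTable:
    """Kitome-subtracted counts with provenance of clamped cells.

    ``counts`` = max(0, raw - kitome) per ASV per sample; ``clamped`` marks
    cells where the subtraction hit the zero floor (raw < kitome).
    """

    counts: pd.DataFrame
    clamped: pd.DataFrame
    raw: pd.DataFrame
    kitome: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("corrected counts must be non-negative")
        if (self.counts.to_numpy() > self.raw.to_numpy()).any():
            raise ValueError("corrected counts cannot exceed raw counts")


@dataclass(frozen=True)
class ColumnTest:
    """One off-center vs center biomass comparison.

    ``variant`` is "pooled" when the preliminary two-sided variance-ratio
    test does not reject equal variances at ``alpha_var``, else
    "unequal-variance" (Welch).  ``p_value`` is one-sided for the
    alternative "off-center < center"; no multiplicity correction is
    applied.
    """

    column: str
    variance_p: float
    variant: str
    t_stat: float
    p_value: float
    direction: str

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1) or not (0 <= self.variance_p <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.variant not in ("pooled", "unequal-variance"):
            raise ValueError(f"unknown test variant {self.variant!r}")


class RelativeAbundance(NamedTuple):
    proportions: pd.DataFrame
    excluded: list[str]


def kitome_correct(table: ASVTable) -> CorrectedTable:
    """Subtract the kitome reads of each ASV from every sample, clamped at 0."""
    if table.kitome is None or len(table.kitome) != table.counts.shape[1]:
        raise ValueError("ASV table has no usable kitome vector")
    raw = table.counts
    sub = raw.sub(table.kitome, axis=1)
    clamped = sub < 0
    corrected = sub.where(~clamped, 0)
    n_clamped = int(clamped.to_numpy().sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} cells clamped at zero during kitome "
                      "subtraction", stacklevel=2)
    return CorrectedTable(counts=corrected, clamped=clamped, raw=raw,
                          kitome=table.kitome)


def relative_abundance(corrected: CorrectedTable) -> RelativeAbundance:
    """Per-sample proportions of the corrected counts.

    Each retained sample's proportions sum to 1 (normalized by the
    post-subtraction total); samples whose corrected reads are all zero
    are excluded and reported in ``excluded``.
    """
    counts = corrected.counts
    if counts.size == 0:
        raise ValueError("empty table")
    totals = counts.sum(axis=1)
    excluded = list(totals.index[totals == 0])
    if excluded:
        warnings.warn(f"{len(excluded)} all-zero samples excluded after "
                      "kitome correction", stacklevel=2)
    kept = counts.loc[totals > 0]
    props = kept.div(kept.sum(axis=1), axis=0)
    return RelativeAbundance(proportions=props, excluded=excluded)


def pooled_relative_abundance(table: ASVTable,
                              samples: Sequence[str] | None = None) -> pd.Series:
    """Reactor-level relative abundance: average reads FIRST, then correct.

    Mean raw reads per ASV over the selected samples, minus the kitome
    (clamped at zero), normalized to the corrected total.  This reads-first
    order is not the same as averaging per-sample proportions.
    """
    counts = table.counts if samples is None else table.counts.loc[list(samples)]
    if counts.shape[0] == 0:
        raise ValueError("no samples selected")
    mean_reads = counts.mean(axis=0)
    corrected = (mean_reads - table.kitome).clip(lower=0.0)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("all ASVs fall below the kitome after averaging")
    return corrected / total


def confirm_presence(table: ASVTable, taxon: str,
                     group: Sequence[str]) -> bool:
    """Presence of a taxon in a sample group, judged against the kitome.

    True iff the mean RAW reads of the taxon over the group STRICTLY
    exceed its kitome reads; ties mean presence cannot be confirmed.
    """
    if taxon not in table.counts.columns:
        raise ValueError(f"unknown taxon {taxon!r}")
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    mean_reads = float(table.counts.loc[group, taxon].mean())
    return mean_reads > float(table.kitome[taxon])


def hellinger(proportions: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Hellinger transform: elementwise square root of proportions.

    Rows that sum to 1 acquire unit sum of squares, making Euclidean
    distances (and hence PCA) composition-appropriate.
    """
    arr = proportions.to_numpy() if isinstance(proportions, pd.DataFrame) \
        else np.asarray(proportions, dtype=float)
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    root = np.sqrt(arr)
    if isinstance(proportions, pd.DataFrame):
        return pd.DataFrame(root, index=proportions.index,
                            columns=proportions.columns)
    return root


def pca_ordination(x: pd.DataFrame | np.ndarray,
                   n_components: int = 2
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of a (samples x features) matrix by SVD.

    Columns are centered (not scaled); returns (scores, loadings,
    explained-variance fractions).  Fractions are non-increasing and sum
    to <= 1; a request beyond the matrix rank is truncated with a warning.
    Degenerate input (all rows identical) yields zero scores and zero
    fractions.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    centered = arr - arr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(arr.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank == 0:
        k = min(n_components, arr.shape[1])
        warnings.warn("matrix has zero variance; all component fractions are 0",
                      stacklevel=2)
        return (np.zeros((arr.shape[0], k)), np.zeros((k, arr.shape[1])),
                np.zeros(k))
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; "
                      "truncated", stacklevel=2)
        n_components = rank
    total_var = (s ** 2).sum()
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    evr = (s[:n_components] ** 2) / total_var
    return scores, loadings, evr


def _two_sided_variance_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio (F) test p-value for equal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(min(p, 1.0))


def column_biomass_tests(copies_per_g: pd.Series,
                         grid_col: pd.Series,
                         alpha_var: float = 0.05) -> list[ColumnTest]:
    """Compare 16S copies/g of each off-center column against the center.

    For each of OL, CL, CR, OR vs C: a two-sided variance-ratio test at
    ``alpha_var`` chooses between the pooled and the Welch two-sample
    t-test, then the t-test is run one-sided for "off-center < center".
    Raw p-values are reported without multiplicity correction.  Columns
    with fewer than 2 values are skipped with a warning.
    """
    if not (0 < alpha_var < 1):
        raise ValueError("alpha_var must be in (0, 1)")
    copies_per_g, grid_col = copies_per_g.align(grid_col, join="inner")
    center = copies_per_g[grid_col == "C"].to_numpy(dtype=float)
    results: list[ColumnTest] = []
    if len(center) < 2:
        warnings.warn("center column has fewer than 2 values; no tests run",
                      stacklevel=2)
        return results
    for col in OFF_CENTER:
        off = copies_per_g[grid_col == col].to_numpy(dtype=float)
        if len(off) < 2:
            warnings.warn(f"column {col} has fewer than 2 values; skipped",
                          stacklevel=2)
            continue
        p_var = _two_sided_variance_test(off, center)
        pooled = p_var >= alpha_var
        res = stats.ttest_ind(off, center, equal_var=pooled,
                              alternative="less")
        results.append(ColumnTest(
            column=col, variance_p=p_var,
            variant="pooled" if pooled else "unequal-variance",
            t_stat=float(res.statistic), p_value=float(res.pvalue),
            direction="lower" if off.mean() < center.mean() else "higher"))
    return results


def spatial_map(grid_values: pd.DataFrame | np.ndarray,
                refine: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear interpolation of a 7x5 (rows x columns) grid of values.

    Missing nodes (NaN) are tolerated up to 50% of the grid and filled by
    nearest-neighbor before interpolating.  Returns (field, row_coords,
    col_coords) on a dense grid that contains the 35 node coordinates, at
    which the node values are reproduced exactly.
    """
    arr = np.asarray(grid_values, dtype=float)
    if arr.shape != (len(GRID_ROWS), len(GRID_COLUMNS)):
        raise ValueError(f"expected a {len(GRID_ROWS)}x{len(GRID_COLUMNS)} "
                         "(rows x columns) grid")
    missing = np.isnan(arr)
    if missing.mean() > 0.5:
        raise ValueError("more than 50% of the grid is missing")
    rows = np.asarray(GRID_ROWS, dtype=float)
    cols = np.arange(len(GRID_COLUMNS), dtype=float)
    if missing.any():
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        known = ~missing
        arr = arr.copy()
        arr[missing] = griddata(
            np.column_stack([rr[known], cc[known]]), arr[known],
            np.column_stack([rr[missing], cc[missing]]), method="nearest")
    interp = RegularGridInterpolator((rows, cols), arr, method="linear")
    dense_rows = np.linspace(rows[0], rows[-1], (len(rows) - 1) * refine + 1)
    dense_cols = np.linspace(cols[0], cols[-1], (len(cols) - 1) * refine + 1)
    rr, cc = np.meshgrid(dense_rows, dense_cols, indexing="ij")
    field = interp(np.column_stack([rr.ravel(), cc.ravel()])).reshape(rr.shape)
    return field, dense_rows, dense_cols
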