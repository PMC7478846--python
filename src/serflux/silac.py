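"""Serine-incorporation estimation and proteome ratio outliers from SILAC data.

Cells grown on isotope-labeled serine incorporate the heavy amino acid into
newly made proteins; for a peptide carrying exactly one serine the
heavy/light intensity ratio reflects the fraction of serine pools that are
labeled.  The per-strain incorporation level is estimated as the maximum of
a Gaussian kernel density over per-peptide incorporation values, which is
robust to the long tails that ratio noise produces.

Two per-peptide formulas are available: the as-printed form
``1 - 1/(ratio - 1)`` (the default) and the standard incorporation-check
identity ``ratio/(ratio + 1)``.  Both are strictly increasing in the ratio
with limit 1; they differ at low ratios, and the as-printed form is
undefined at ratio 1 (such records are flagged and excluded downstream).

For whole-proteome comparisons, intensity-dependent outliers are called with
a binned robust z-score: log2 ratios are grouped into equal-count intensity
bins, a robust spread per bin is derived from the 15.87/84.13 percentile
distances to the median (the +-1 sigma quantiles of a normal), and two-sided
normal tail p-values are assigned, tiered at 1e-11, 1e-4 and 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeptideRecord",
    "IncorporationEstimate",
    "read_peptide_table",
    "filter_single_serine",
    "incorporation_from_ratio",
    "incorporation_values",
    "incorporation_level",
    "labeled_peptide_fraction",
    "incorporation_change",
    "intensity_dependent_outliers",
]

FORMULAS = ("as-printed", "ratio-over-ratio-plus-one")

#: outlier significance tiers, most to least stringent
OUTLIER_TIERS = (1e-11, 1e-4, 0.05)


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    ratio_hl: float | None
    intensity: float | None = None
    protein: str = ""

    @property
    def serine_count(self) -> int:
        return self.sequence.upper().count("S")


@dataclass
class IncorporationEstimate:
    """Density-maximum incorporation level for one strain.

    ``level`` is a fraction in [0, 1]-ish units (the KDE grid point of
    maximal density); multiply by 100 to report percent.
    """

    strain: str
    values: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    level: float
    bandwidth: float
    tied: bool = False

    @property
    def level_percent(self) -> float:
        return 100.0 * self.level


def read_peptide_table(
    path: str | Path,
    sheet: str | int = 0,
    columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a peptide table (TSV, or XLSX for supplementary-style files).

    ``columns`` optionally maps source column names onto the expected
    ``sequence`` / ``ratio_hl`` / ``intensity`` / ``protein`` names, e.g.
    ``{"Sequence": "sequence", "Ratio H/L": "ratio_hl"}``; ``sheet`` selects
    the worksheet for XLSX input.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, sep="\t")
    if columns:
        df = df.rename(columns=columns)
    required = {"sequence", "ratio_hl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table {path} is missing columns {sorted(missing)}")
    return df


def _as_frame(peptides) -> pd.DataFrame:
    if isinstance(peptides, pd.DataFrame):
        return peptides
    return pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptides],
            "ratio_hl": [p.ratio_hl for p in peptides],
            "intensity": [p.intensity for p in peptides],
            "protein": [p.protein for p in peptides],
        }
    )


def filter_single_serine(peptides) -> pd.DataFrame:
    """Keep peptides with exactly one serine and a finite, positive H/L ratio.

    Accepts a DataFrame (columns ``sequence``, ``ratio_hl``) or a sequence of
    :class:`PeptideRecord`; order is preserved.
    """
    df = _as_frame(peptides)
    ratio = pd.to_numeric(df["ratio_hl"], errors="coerce")
    n_ser = df["sequence"].astype(str).str.upper().str.count("S")
    keep = (n_ser == 1) & np.isfinite(ratio) & (ratio > 0)
    return df.loc[keep].copy()


def incorporation_from_ratio(ratio_hl, formula: str = "as-printed"):
    """Per-peptide incorporation fraction from a heavy/light ratio.

    ``as-printed`` computes ``1 - 1/(ratio - 1)`` and is undefined (NaN) at
    ratio 1; ``ratio-over-ratio-plus-one`` computes ``ratio/(ratio + 1)``.
    Values outside [0, 1] are returned as computed (callers may flag them).
    Vectorized over array input.
    """
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; choose from {FORMULAS}")
    r = np.asarray(ratio_hl, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r[np.isfinite(r)] <= 0):
        raise ValueError("ratio_hl must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        if formula == "as-printed":
            out = np.where(r == 1.0, np.nan, 1.0 - 1.0 / (r - 1.0))
        else:
            out = r / (r + 1.0)
    out = np.where(np.isfinite(r), out, np.nan)
    return float(out[0]) if scalar else out


def incorporation_values(peptides, formula: str = "as-printed") -> np.ndarray:
    """Filtered single-serine peptides -> finite per-peptide incorporation values."""
    df = filter_single_serine(peptides)
    vals = incorporation_from_ratio(df["ratio_hl"].to_numpy(float), formula=formula)
    return vals[np.isfinite(vals)]


def incorporation_level(
    values: Sequence[float],
    bandwidth: float | str | None = None,
    strain: str = "",
    grid_points: int = 512,
) -> IncorporationEstimate:
    """Estimate the incorporation level as the maximum of a kernel density.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on a fixed
    grid spanning [min - 3h, max + 3h]; the level is the grid point of
    maximal density.  Exact ties resolve to the lowest grid point and set
    ``tied``.  Requires at least 10 finite values (the mode of a KDE over
    fewer points is unstable).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise ValueError(f"need at least 10 finite values, got {vals.size}")
    if np.ptp(vals) == 0:
        # degenerate: all identical; density maximum is that value
        level = float(vals[0])
        grid = np.full(grid_points, level)
        dens = np.full(grid_points, np.inf)
        return IncorporationEstimate(strain, vals, grid, dens, level, 0.0)
    kde = stats.gaussian_kde(vals, bw_method=bandwidth if bandwidth else "silverman")
    h = kde.factor * vals.std(ddof=1)
    grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, grid_points)
    dens = kde(grid)
    imax = int(np.argmax(dens))  # argmax returns the first (lowest) maximum
    tied = bool(np.sum(dens == dens[imax]) > 1)
    return IncorporationEstimate(strain, vals, grid, dens, float(grid[imax]), float(h), tied)


def labeled_peptide_fraction(values: Sequence[float], threshold: float = 0.5) -> float:
    """Fraction of peptides whose incorporation exceeds the threshold.

    The alternative headline statistic to the density maximum: the share of
    analyzed peptides that carry the labeled serine (incorporation > 0.5,
    i.e. the heavy form dominates).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values")
    return float(np.mean(vals > threshold))


def incorporation_change(
    test: IncorporationEstimate | float, reference: IncorporationEstimate | float
) -> float:
    """Percent decrease of the test level relative to the reference level.

    Returns ``100 * (reference - test) / reference``; positive = decrease.
    """
    t = test.level if isinstance(test, IncorporationEstimate) else float(test)
    r = reference.level if isinstance(reference, IncorporationEstimate) else float(reference)
    if r == 0:
        raise ValueError("reference level must be nonzero")
    return 100.0 * (r - t) / r


def intensity_dependent_outliers(
    proteins: pd.DataFrame,
    bin_size: int = 300,
    percentiles: tuple[float, float] = (15.87, 84.13),
    tiers: Sequence[float] = OUTLIER_TIERS,
) -> pd.DataFrame:
    """Call intensity-dependent ratio outliers with a binned robust z-score.

    Input columns: ``protein`` (optional), ``ratio`` (H/L, linear scale) and
    ``intensity``.  Proteins are sorted by intensity into equal-count bins of
    about ``bin_size``; within each bin the median log2 ratio and a robust
    sigma (half the distance between the given percentiles, the normal
    +-1 sigma quantiles) yield a z-score and a two-sided normal p-value.
    The returned frame adds ``log2_ratio``, ``z``, ``p_value`` and ``tier``
    (most stringent tier passed, or ``"ns"``).  Tiers are nested by
    construction.  Requires >= 50 proteins with finite ratio and intensity.
    """
    df = proteins.copy()
    ratio = pd.to_numeric(df["ratio"], errors="coerce")
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    ok = np.isfinite(ratio) & (ratio > 0) & np.isfinite(intensity)
    df = df.loc[ok].copy()
    if len(df) < 50:
        raise ValueError(f"need at least 50 proteins with finite ratio/intensity, got {len(df)}")
    df["log2_ratio"] = np.log2(df["ratio"].astype(float))

    order = np.argsort(df["intensity"].to_numpy(), kind="stable")
    n = len(df)
    n_bins = max(1, round(n / bin_size))
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    z = np.full(n, np.nan)
    lo_q, hi_q = percentiles
    vals = df["log2_ratio"].to_numpy()
    for b in range(n_bins):
        idx = order[edges[b]: edges[b + 1]]
        x = vals[idx]
        med = np.median(x)
        lo, hi = np.percentile(x, [lo_q, hi_q])
        sigma = (hi - lo) / 2.0
        if sigma <= 0:
            z[idx] = 0.0  # all ratios identical in the bin: nothing is an outlier
        else:
            z[idx] = (x - med) / sigma
    df["z"] = z
    df["p_value"] = 2.0 * stats.norm.sf(np.abs(z))
    tiers = sorted(tiers)
    labels = []
    for p in df["p_value"]:
        tier = "ns"
        for t in tiers:  # ascending: first tier passed is the most stringent
            if p < t:
                tier = f"p<{t:g}"
                break
        labels.append(tier)
    df["tier"] = labels
    return df
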