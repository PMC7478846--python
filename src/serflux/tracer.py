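"""Quantification of tracer assays: radiolabel uptake, amino acids, lipids.

Covers the arithmetic downstream of instrument output:

* scintillation-count uptake time courses -> background-subtracted uptake in
  nmol per mg protein and an initial uptake rate (the 5-min point by
  default, or a linear fit through the origin over all points);
* LC-MS amino-acid peak tables -> concentrations in nmol per 1e8 cells via
  the norleucine internal standard and per-analyte calibration factors;
* lipid-species tables -> mol% of a (class, label channel) cell per all
  detected lipids;
* long-chain-base (LCB) tables -> absolute pmol per mg protein via a spiked
  LCB 17:0 internal standard, and fold changes versus a reference sample.

Replicates are aggregated as arithmetic mean +- sd with n reported;
two-condition comparisons use Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UptakeTimecourse",
    "UptakeResult",
    "AminoAcidPeakTable",
    "LcbTable",
    "uptake_rate",
    "summarize_uptake",
    "percent_reduction",
    "amino_acid_concentration",
    "compare_conditions",
    "lipid_label_molpercent",
    "lipid_molpercent_table",
    "lcb_amounts",
    "lcb_fold_change",
]


@dataclass
class UptakeTimecourse:
    """One replicate of a radiolabeled-substrate uptake assay."""

    strain: str
    times: np.ndarray  # minutes, strictly increasing
    counts: np.ndarray  # scintillation counts per time point
    background: float  # counts of the substrate-only filter
    protein_mg: float
    specific_activity: float  # counts per nmol of labeled substrate
    replicate: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValueError("times and counts must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.protein_mg <= 0:
            raise ValueError("protein mass must be positive")
        if self.specific_activity <= 0:
            raise ValueError("specific activity must be positive")


@dataclass
class UptakeResult:
    strain: str
    times: np.ndarray
    uptake: np.ndarray  # nmol per mg protein at each time
    initial_rate: float  # nmol per mg protein per minute
    replicate: str = ""


def uptake_rate(
    tc: UptakeTimecourse, initial: str = "first-point"
) -> UptakeResult:
    """Background-subtracted uptake per time point and an initial rate.

    Per-time uptake is ``max(counts - background, 0) / specific_activity /
    protein_mg`` (negative differences clamp to zero with a warning:
    transported amounts are physically nonnegative).  ``initial="first-point"``
    divides the first time point's uptake by its time; ``initial="fit"``
    fits a least-squares line through the origin over all points.
    """
    diff = tc.counts - tc.background
    if np.any(diff < 0):
        if np.all(diff <= 0):
            warnings.warn(
                f"{tc.strain}: background exceeds counts at every time point; "
                "uptake is all zero",
                stacklevel=2,
            )
        else:
            warnings.warn(
                f"{tc.strain}: background exceeds counts at some time points; "
                "clamping to zero",
                stacklevel=2,
            )
        diff = np.clip(diff, 0, None)
    uptake = diff / tc.specific_activity / tc.protein_mg
    if initial == "first-point":
        rate = float(uptake[0] / tc.times[0])
    elif initial == "fit":
        # least squares through the origin: rate = <t,u>/<t,t>
        rate = float(np.dot(tc.times, uptake) / np.dot(tc.times, tc.times))
    else:
        raise ValueError(f"unknown initial-rate method {initial!r}")
    return UptakeResult(tc.strain, tc.times.copy(), uptake, rate, tc.replicate)


def summarize_uptake(
    timecourses: Sequence[UptakeTimecourse], initial: str = "first-point"
) -> pd.DataFrame:
    """Replicate mean +- sd of uptake per strain and time, plus initial rates.

    Returns a long-format frame with columns strain, time_min,
    mean_uptake, sd_uptake, n, mean_initial_rate, sd_initial_rate.
    """
    rows = []
    for tc in timecourses:
        res = uptake_rate(tc, initial=initial)
        for t, u in zip(res.times, res.uptake):
            rows.append(
                {"strain": tc.strain, "time_min": t, "uptake": u, "rate": res.initial_rate}
            )
    long = pd.DataFrame(rows)
    out = (
        long.groupby(["strain", "time_min"], sort=True)
        .agg(
            mean_uptake=("uptake", "mean"),
            sd_uptake=("uptake", "std"),
            n=("uptake", "size"),
            mean_initial_rate=("rate", "mean"),
            sd_initial_rate=("rate", "std"),
        )
        .reset_index()
    )
    return out


def percent_reduction(test: float, reference: float) -> float:
    """``100 * (reference - test) / reference``; positive = reduction."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - test) / reference


# ---------------------------------------------------------------------------
# amino acids
# ---------------------------------------------------------------------------


@dataclass
class AminoAcidPeakTable:
    """One sample's LC-MS peak areas with internal-standard normalization.

    ``calibration`` maps analyte -> factor converting an area ratio
    (analyte / norleucine) into nmol, from a measured standard mixture.
    ``cell_count`` is in units of 1e8 cells.
    """

    sample: str
    areas: Mapping[str, float]
    internal_standard_area: float
    calibration: Mapping[str, float]
    cell_count: float  # in 1e8 cells

    def __post_init__(self) -> None:
        if self.internal_standard_area <= 0:
            raise ValueError("internal standard area must be positive")
        if self.cell_count <= 0:
            raise ValueError("cell count must be positive")
        bad = [a for a, f in self.calibration.items() if f <= 0]
        if bad:
            raise ValueError(f"nonpositive calibration factors for {bad}")


def amino_acid_concentration(table: AminoAcidPeakTable, analyte: str) -> float:
    """Concentration of one analyte in nmol per 1e8 cells."""
    if analyte not in table.areas:
        raise KeyError(f"analyte {analyte!r} not in sample {table.sample!r}")
    if analyte not in table.calibration:
        raise KeyError(f"no calibration factor for analyte {analyte!r}")
    return (
        table.areas[analyte]
        / table.internal_standard_area
        * table.calibration[analyte]
        / table.cell_count
    )


def compare_conditions(
    test: Sequence[float], reference: Sequence[float]
) -> dict[str, float]:
    """Two-condition comparison: percent change and Welch's t-test.

    Returns mean/sd/n per group, percent change of the test mean relative to
    the reference mean (positive = increase), and the Welch t statistic and
    two-sided p-value.
    """
    t_arr = np.asarray(test, float)
    r_arr = np.asarray(reference, float)
    if r_arr.mean() == 0:
        raise ValueError("reference mean must be nonzero")
    tt = stats.ttest_ind(t_arr, r_arr, equal_var=False)
    return {
        "mean_test": float(t_arr.mean()),
        "sd_test": float(t_arr.std(ddof=1)) if t_arr.size > 1 else float("nan"),
        "n_test": int(t_arr.size),
        "mean_reference": float(r_arr.mean()),
        "sd_reference": float(r_arr.std(ddof=1)) if r_arr.size > 1 else float("nan"),
        "n_reference": int(r_arr.size),
        "percent_change": float(100.0 * (t_arr.mean() - r_arr.mean()) / r_arr.mean()),
        "t_statistic": float(tt.statistic),
        "p_value": float(tt.pvalue),
    }


# ---------------------------------------------------------------------------
# lipids
# ---------------------------------------------------------------------------


def lipid_label_molpercent(
    table: pd.DataFrame, lipid_class: str, channel: str
) -> pd.DataFrame:
    """mol% of one (lipid class, label channel) cell per all detected lipids.

    ``table`` holds rows (sample, lipid_class, channel, amount) with amounts
    in mol.  Returns per-sample mol% (100 * class/channel sum over the
    sample's total) plus the replicate mean in an extra summary attribute-free
    row-less form: columns sample, molpercent, with the mean available via
    ``.molpercent.mean()``.
    """
    required = {"sample", "lipid_class", "channel", "amount"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"lipid table is missing columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("lipid table is empty")
    if (table["amount"] < 0).any():
        raise ValueError("lipid amounts must be nonnegative")
    out = []
    for sample, grp in table.groupby("sample", sort=True):
        total = grp["amount"].sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total lipid amount")
        sel = grp[(grp["lipid_class"] == lipid_class) & (grp["channel"] == channel)]
        out.append({"sample": sample, "molpercent": 100.0 * sel["amount"].sum() / total})
    return pd.DataFrame(out)


def lipid_molpercent_table(table: pd.DataFrame) -> pd.DataFrame:
    """mol% for every (sample, class, channel) cell; sums to 100 per sample."""
    out = []
    for sample, grp in table.groupby("sample", sort=True):
        total = grp["amount"].sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total lipid amount")
        cell = (
            grp.groupby(["lipid_class", "channel"], sort=True)["amount"].sum() / total * 100.0
        )
        for (cls, ch), v in cell.items():
            out.append(
                {"sample": sample, "lipid_class": cls, "channel": ch, "molpercent": v}
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# long chain bases
# ---------------------------------------------------------------------------


@dataclass
class LcbTable:
    """Per-species LCB intensities for one sample, with the spiked standard."""

    sample: str
    intensities: Mapping[str, float]  # species -> intensity
    standard_intensity: float  # LCB 17:0 internal standard
    standard_pmol: float  # spiked amount
    protein_mg: float

    def __post_init__(self) -> None:
        if self.standard_intensity <= 0:
            raise ValueError("standard intensity must be positive")
        if self.protein_mg <= 0:
            raise ValueError("protein mass must be positive")


def lcb_amounts(table: LcbTable) -> dict[str, float]:
    """Absolute amounts in pmol per mg protein for every species."""
    return {
        sp: inten / table.standard_intensity * table.standard_pmol / table.protein_mg
        for sp, inten in table.intensities.items()
    }


def lcb_fold_change(
    samples: Sequence[LcbTable], reference_sample: str
) -> pd.DataFrame:
    """Per-species pmol/mg and fold change versus a reference sample.

    Fold change is sample amount over the reference amount; a zero reference
    amount yields NaN with the row flagged ``undefined``.
    """
    by_name = {t.sample: t for t in samples}
    if reference_sample not in by_name:
        raise KeyError(f"reference sample {reference_sample!r} not present")
    ref = lcb_amounts(by_name[reference_sample])
    rows = []
    for t in samples:
        amounts = lcb_amounts(t)
        for sp, amt in amounts.items():
            r = ref.get(sp)
            undefined = r is None or r == 0
            rows.append(
                {
                    "sample": t.sample,
                    "species": sp,
                    "pmol_per_mg": amt,
                    "fold_change": float("nan") if undefined else amt / r,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)
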