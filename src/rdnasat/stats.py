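"""Cross-species summary tables and rank statistics.

The headline analysis is the relationship between intergenic-spacer size
and total 45S unit length across species: variables are first screened with
the Shapiro-Wilk normality test and the association is then quantified with
Spearman's rank correlation (midranks for ties), significance at alpha =
0.05. Scipy provides the underlying test statistics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpeciesSummary",
    "normality_test",
    "spearman_correlation",
    "build_summary",
    "write_summary_tsv",
    "plot_length_boxplot",
]

ALPHA = 0.05


@dataclass
class SpeciesSummary:
    """One row of the per-species report table (missing fields are None)."""

    species: str
    unit_consensus_length: int | None = None
    igs_length: int | None = None
    genomic_proportion: float | None = None
    n_sat_annotations: int | None = None
    identity_min: float | None = None
    identity_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("unit_consensus_length", "igs_length"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("genomic_proportion", "identity_min", "identity_max"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} out of [0, 100]")


def normality_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p).

    Requires 3 <= n <= 5000. A constant vector has no defined W and is
    reported as degenerate (NaN, NaN) with a warning.
    """
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        warnings.warn("constant input; Shapiro-Wilk W undefined")
        return (math.nan, math.nan)
    res = sps.shapiro(x)
    return (float(res.statistic), float(res.pvalue))


def _rho_midranks(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t-approx",
) -> tuple[float, float]:
    """Spearman's rho with midranks for ties; returns (rho, p).

    ``method='t-approx'`` uses the large-sample t approximation with n-2
    degrees of freedom; ``method='exact'`` enumerates all permutations
    (two-sided, available for n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    rho = _rho_midranks(x, y)
    if math.isnan(rho):
        return (math.nan, math.nan)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rho_midranks(x, y[list(perm)])
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return (rho, count / total)
    if method != "t-approx":
        raise ValueError("method must be 't-approx' or 'exact'")
    if abs(rho) >= 1.0:
        return (rho, 0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return (rho, float(p))


_COLUMNS = [
    "species",
    "unit_consensus_length",
    "igs_length",
    "genomic_proportion",
    "n_sat_annotations",
    "identity_min",
    "identity_max",
]


def build_summary(per_species: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Assemble the per-species report table; missing fields stay blank."""
    labels = [s.species for s in per_species]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate species labels: {dupes}")
    rows = [{c: getattr(s, c) for c in _COLUMNS} for s in per_species]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_summary_tsv(df: pd.DataFrame, path: str | Path, correlate: bool = True) -> None:
    """Write the summary TSV, appending a Spearman block when possible.

    The correlation between IGS length and unit length is appended as
    comment lines when at least 4 species carry both values; with fewer it
    is suppressed with a warning.
    """
    df.to_csv(path, sep="\t", index=False)
    if not correlate:
        return
    sub = df.dropna(subset=["igs_length", "unit_consensus_length"]) if len(df) else df
    with open(path, "a") as fh:
        if len(sub) >= 4:
            sw_igs = normality_test(sub["igs_length"])
            sw_unit = normality_test(sub["unit_consensus_length"])
            rho, p = spearman_correlation(sub["igs_length"], sub["unit_consensus_length"])
            fh.write(f"# shapiro_igs_W={sw_igs[0]:.4f}\tp={sw_igs[1]:.4g}\n")
            fh.write(f"# shapiro_unit_W={sw_unit[0]:.4f}\tp={sw_unit[1]:.4g}\n")
            fh.write(f"# spearman_rho={rho:.4f}\tp={p:.4g}\tn={len(sub)}\talpha={ALPHA}\n")
        elif len(df):
            warnings.warn("fewer than 4 species with IGS and unit lengths; correlation suppressed")


def plot_length_boxplot(df: pd.DataFrame, path: str | Path) -> None:
    """Boxplots of unit and IGS lengths across species."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    data = [
        df["unit_consensus_length"].dropna().to_numpy(),
        df["igs_length"].dropna().to_numpy(),
    ]
    ax.boxplot(data, tick_labels=["45S unit", "IGS"])
    ax.set_ylabel("length (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
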