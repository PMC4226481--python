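"""Evaluation statistics: ERP component windows, sign tests,
Bonferroni correction, two-sample t-tests, two-way repeated-measures
ANOVA, the TTI accuracy profile and the centered error topography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .paradigm import LetterMatrix
from .preprocessing import EpochSet

#: Component analysis windows (name -> (channel, (start_ms, end_ms))).
COMPONENT_WINDOWS: dict[str, tuple[str, tuple[float, float]]] = {
    "N170": ("PO7", (130.0, 200.0)),
    "P300": ("Cz", (280.0, 370.0)),
    "N400f": ("Cz", (400.0, 550.0)),
}


@dataclass(frozen=True)
class ComponentWindow:
    name: str
    channel: str
    window_ms: tuple[float, float]

    @classmethod
    def standard(cls, name: str) -> "ComponentWindow":
        channel, window = COMPONENT_WINDOWS[name]
        return cls(name=name, channel=channel, window_ms=window)


def component_window_mean(epochs: EpochSet, win: ComponentWindow,
                          ) -> np.ndarray:
    """Per-epoch mean amplitude of the window's channel over its span."""
    ch = epochs.channel_index(win.channel)
    lo, hi = win.window_ms
    mask = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {win.window_ms} has no samples")
    return epochs.data[:, ch, mask].mean(axis=1)


def paired_sign_test(a, b) -> float:
    """Exact two-sided sign test on paired samples; ties are dropped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff != 0
    n = int(nz.sum())
    if n == 0:
        raise ValueError("all pairs are tied; sign test undefined")
    k = int((diff[nz] > 0).sum())
    return float(sp_stats.binomtest(k, n, 0.5,
                                    alternative="two-sided").pvalue)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p); ``m`` defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample t-test; returns (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least 2 observations")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0 and var_b == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sp_stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class AnovaTable:
    """F, dfs and p per within-subject effect."""

    table: pd.DataFrame  # index: effect; columns: F, df1, df2, p

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def repeated_measures_anova_2way(data: np.ndarray,
                                 factor_names: tuple[str, str] =
                                 ("speller", "sequences")) -> AnovaTable:
    """Two-way fully within-subject ANOVA on a subjects x a x b array.

    Error terms are the effect-by-subject interactions; dfs are
    (a-1, (a-1)(s-1)) and (b-1, (b-1)(s-1)) for the main effects and
    ((a-1)(b-1), (a-1)(b-1)(s-1)) for the interaction.  No sphericity
    correction is applied.  A zero effect with zero error (constant
    data) yields F = 0 by convention.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be subjects x factorA x factorB")
    if np.isnan(data).any():
        raise ValueError("missing cells: the design must be complete")
    s, a, b = data.shape
    if min(s, a, b) < 2:
        raise ValueError("each dimension needs at least 2 levels")

    m = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_a = s * b * np.sum((m_a - m) ** 2)
    ss_b = s * a * np.sum((m_b - m) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    resid = (data - m_sa[:, :, None] - m_sb[:, None, :]
             - m_ab[None, :, :] + m_s[:, None, None]
             + m_a[None, :, None] + m_b[None, None, :] - m)
    ss_abs = np.sum(resid**2)

    rows = []
    for name, ss_eff, ss_err, df1, df2 in (
            (factor_names[0], ss_a, ss_as, a - 1, (a - 1) * (s - 1)),
            (factor_names[1], ss_b, ss_bs, b - 1, (b - 1) * (s - 1)),
            (f"{factor_names[0]}x{factor_names[1]}", ss_ab, ss_abs,
             (a - 1) * (b - 1), (a - 1) * (b - 1) * (s - 1))):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = 0.0 if ms_eff == 0 else ms_eff / ms_err
        p = float(sp_stats.f.sf(F, df1, df2))
        rows.append({"effect": name, "F": float(F), "df1": df1,
                     "df2": df2, "p": p})
    table = pd.DataFrame(rows).set_index("effect")
    return AnovaTable(table=table)


#: TTI histogram bins: 0..4 singletons plus a ">=5" overflow bin.
TTI_BINS: tuple[str, ...] = ("0", "1", "2", "3", "4", ">=5")


def tti_accuracy_profile(correct, tti) -> dict[str, float | None]:
    """Fraction of correct outcomes per TTI bin among target flashes.

    ``correct`` is a boolean outcome per target flash and ``tti`` its
    target-to-target interval; entries with undefined TTI (NaN/None,
    i.e. a trial's first target flash) are ignored.  Empty bins map to
    None rather than 0.
    """
    correct = np.asarray(correct, dtype=float)
    tti = np.asarray(tti, dtype=float)
    if correct.shape != tti.shape:
        raise ValueError("correct and tti must align")
    valid = ~np.isnan(tti)
    out: dict[str, float | None] = {}
    for bin_name in TTI_BINS:
        if bin_name == ">=5":
            mask = valid & (tti >= 5)
        else:
            mask = valid & (tti == int(bin_name))
        out[bin_name] = float(correct[mask].mean()) if mask.any() else None
    return out


def adjacency_error_map(decoded, truth, matrix: LetterMatrix) -> np.ndarray:
    """11x11 histogram of decoding offsets, target centered at (5, 5).

    Cell (dr + 5, dc + 5) counts trials whose decoded symbol sat dr rows
    and dc columns away from the target; the center cell counts correct
    selections and the matrix total equals the number of trials.
    """
    if len(decoded) != len(truth):
        raise ValueError("decoded and truth must align")
    grid = np.zeros((11, 11), dtype=int)
    for d, t in zip(decoded, truth):
        dr = matrix.position(d)[0] - matrix.position(t)[0]
        dc = matrix.position(d)[1] - matrix.position(t)[1]
        grid[dr + 5, dc + 5] += 1
    return grid
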