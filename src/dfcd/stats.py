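"""Peak extraction and within-subject factorial statistics.

The event-averaged percent-change curves show an early response peak
(around the HRF maximum, searched in [0, 10) s by default) and a later
second peak (searched in [10, 20] s).  Peak amplitude and latency per
subject / TR / window feed a 4 x 3 fully within-subject repeated-measures
ANOVA (factors TR and window length), with Greenhouse-Geisser
degrees-of-freedom correction per effect, followed by Bonferroni-corrected
paired t-tests over the cell pairs that differ in exactly one factor
(30 such pairs in a 4 x 3 design, corrected threshold 0.05/30).

The ANOVA is the classical sums-of-squares univariate approach: each
effect is tested against its own effect-by-subject interaction, and the
Greenhouse-Geisser epsilon is computed per effect from the covariance of
the subjects' cell scores projected onto an orthonormal contrast basis
(for a main effect this equals the textbook epsilon of the factor's level
covariance after collapsing over the other factor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["PeakResult", "find_peaks", "rm_anova", "posthoc_paired",
           "single_factor_pairs"]


@dataclass
class PeakResult:
    """Amplitude and latency of the curve maximum within one search band."""

    amplitude: float
    latency: float
    is_local_max: bool


def find_peaks(offsets: np.ndarray, curve: np.ndarray,
               band1: tuple[float, float] = (0.0, 10.0),
               band2: tuple[float, float] = (10.0, 20.0),
               ) -> tuple[PeakResult, PeakResult]:
    """Maximum (amplitude, latency) of the curve within two search bands.

    Band 1 is half-open [lo, hi), band 2 closed [lo, hi].  The maxima are
    returned even when they sit on a band edge (flagged as non-local).
    """
    if not band1[1] <= band2[0]:
        raise ValueError("band1 must end before band2 starts")
    offsets = np.asarray(offsets, float)
    curve = np.asarray(curve, float)
    results = []
    for (lo, hi), closed in ((band1, False), (band2, True)):
        sel = (offsets >= lo) & ((offsets <= hi) if closed else (offsets < hi))
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            raise ValueError(f"no samples inside band [{lo}, {hi}]")
        if not np.any(np.isfinite(curve[idx])):
            raise ValueError(f"no finite curve values inside band [{lo}, {hi}]")
        k = idx[np.nanargmax(curve[idx])]
        local = 0 < k < offsets.size - 1 and curve[k] >= curve[k - 1] \
            and curve[k] >= curve[k + 1]
        results.append(PeakResult(amplitude=float(curve[k]),
                                  latency=float(offsets[k]),
                                  is_local_max=bool(local)))
    return results[0], results[1]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space of level differences."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_epsilon(cell_scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one effect.

    ``cell_scores`` is subjects x cells; ``contrasts`` maps cells onto the
    effect's orthonormal contrast space.  Epsilon is tr(M)^2 / (d tr(M^2))
    for M the contrast-space covariance, clipped to [1/d, 1].
    """
    d = contrasts.shape[0]
    sigma = np.cov(cell_scores, rowvar=False)
    m = contrasts @ sigma @ contrasts.T
    tr_m = np.trace(m)
    tr_m2 = np.trace(m @ m)
    if tr_m2 <= 0:
        return 1.0
    eps = tr_m ** 2 / (d * tr_m2)
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(table: pd.DataFrame, dv: str, subject: str = "subject",
             factors: tuple[str, str] = ("tr", "window")) -> pd.DataFrame:
    """Two-way fully within-subject repeated-measures ANOVA.

    Requires a complete balanced design (every subject observed in every
    factor-level cell exactly once; missing cells raise).  Returns one row
    per effect (two main effects and the interaction) with the uncorrected
    and the Greenhouse-Geisser-corrected test.
    """
    fa, fb = factors
    a_levels = np.array(sorted(table[fa].unique()))
    b_levels = np.array(sorted(table[fb].unique()))
    subjects = np.array(sorted(table[subject].unique()))
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least 2 levels")
    pivot = table.pivot_table(index=subject, columns=[fa, fb], values=dv,
                              aggfunc="count")
    if pivot.isna().any().any() or not (pivot == 1).all().all() \
            or len(table) != n * a * b:
        raise ValueError("design is not complete and balanced")
    y = np.empty((n, a, b))
    lut = {(row[subject], row[fa], row[fb]): row[dv]
           for row in table.to_dict("records")}
    for i, s in enumerate(subjects):
        for j, av in enumerate(a_levels):
            for k, bv in enumerate(b_levels):
                y[i, j, k] = lut[(s, av, bv)]

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_abs = np.sum((y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
                     + m_s[:, None, None] + m_a[None, :, None]
                     + m_b[None, None, :] - grand) ** 2)

    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    cells = y.reshape(n, a * b)  # cell order: A-major, matching the krons below
    mean_b = np.ones(b) / b
    mean_a = np.ones(a) / a
    eps_a = _gg_epsilon(cells, np.kron(c_a, mean_b[None, :]) * np.sqrt(b))
    eps_b = _gg_epsilon(cells, np.kron(mean_a[None, :], c_b) * np.sqrt(a))
    eps_ab = _gg_epsilon(cells, np.kron(c_a, c_b))

    rows = []
    for name, ss_eff, ss_err, df1, df2, eps in (
        (fa, ss_a, ss_as, a - 1, (a - 1) * (n - 1), eps_a),
        (fb, ss_b, ss_bs, b - 1, (b - 1) * (n - 1), eps_b),
        (f"{fa} * {fb}", ss_ab, ss_abs, (a - 1) * (b - 1),
         (a - 1) * (b - 1) * (n - 1), eps_ab),
    ):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f_val = ms_eff / ms_err if ms_err > 0 else np.nan
        p_unc = float(sstats.f.sf(f_val, df1, df2)) if np.isfinite(f_val) else np.nan
        p_gg = float(sstats.f.sf(f_val, eps * df1, eps * df2)) \
            if np.isfinite(f_val) else np.nan
        rows.append(dict(effect=name, ss=ss_eff, ss_error=ss_err,
                         df1=df1, df2=df2, F=f_val, p_unc=p_unc,
                         epsilon=eps, df1_gg=eps * df1, df2_gg=eps * df2,
                         p_gg=p_gg))
    return pd.DataFrame(rows)


def single_factor_pairs(a_levels, b_levels) -> list[tuple[tuple, tuple]]:
    """All cell pairs of an AxB design differing in exactly one factor.

    For a 4 x 3 design this enumerates 30 pairs (3 window pairs per TR is
    12, 6 TR pairs per window is 18).
    """
    pairs = []
    for b in b_levels:
        for a1, a2 in itertools.combinations(sorted(a_levels), 2):
            pairs.append(((a1, b), (a2, b)))
    for a in a_levels:
        for b1, b2 in itertools.combinations(sorted(b_levels), 2):
            pairs.append(((a, b1), (a, b2)))
    return pairs


def posthoc_paired(table: pd.DataFrame, dv: str, subject: str = "subject",
                   factors: tuple[str, str] = ("tr", "window"),
                   family: list[tuple[tuple, tuple]] | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests over a family of cell pairs.

    The default family is every pair of design cells differing in exactly
    one factor; the correction count m is always the size of the family
    actually tested, and the corrected significance threshold is alpha/m.
    Zero-variance differences are flagged (t undefined, p set to 1).
    """
    fa, fb = factors
    if family is None:
        family = single_factor_pairs(table[fa].unique(), table[fb].unique())
    m = len(family)
    rows = []
    for (a1, b1), (a2, b2) in family:
        c1 = table[(table[fa] == a1) & (table[fb] == b1)].set_index(subject)[dv]
        c2 = table[(table[fa] == a2) & (table[fb] == b2)].set_index(subject)[dv]
        common = c1.index.intersection(c2.index)
        d = c1.loc[common].to_numpy() - c2.loc[common].to_numpy()
        label = f"({a1},{b1}) vs ({a2},{b2})"
        if d.size < 2 or np.allclose(d, d[0]):
            rows.append(dict(comparison=label, t=np.nan, df=d.size - 1,
                             p_raw=1.0, p_bonferroni=1.0, significant=False,
                             degenerate=True))
            continue
        t_val, p_raw = sstats.ttest_rel(c1.loc[common], c2.loc[common])
        p_bonf = min(1.0, m * float(p_raw))
        rows.append(dict(comparison=label, t=float(t_val), df=d.size - 1,
                         p_raw=float(p_raw), p_bonferroni=p_bonf,
                         significant=bool(p_raw < alpha / m), degenerate=False))
    out = pd.DataFrame(rows)
    out.attrs["m"] = m
    out.attrs["alpha_corrected"] = alpha / m
    return out
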