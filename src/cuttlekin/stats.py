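"""Nonparametric rank statistics for the attack analysis.

Two tests are used: the Wilcoxon matched-pairs signed-rank test (paired
cuttlefish speeds during slow vs fast prey motion) and the Mann-Whitney
U test (attention durations of episodes with vs without a strike
attempt). Both are implemented with an exact enumeration null for small
samples — 2^n sign assignments for the signed-rank test, all C(n, n1)
group labelings for Mann-Whitney — which handles midrank ties without
approximation, and a normal approximation with tie and continuity
corrections otherwise. The switchover sizes (n <= 15 signed-rank,
n1 + n2 <= 20 Mann-Whitney) mirror common statistical-package defaults.

Two-sided p-values are defined as the null probability of a statistic
at least as far from its null mean as observed; both enumeration nulls
are symmetric, so this coincides with doubling the smaller tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from cuttlekin.errors import DegenerateSampleError, ParameterError
from cuttlekin.pose_io import Table1Fixture
from cuttlekin.segmentation import StrikeEvent

EXACT_MAX_N_WILCOXON = 15
EXACT_MAX_N_MANNWHITNEY = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test."""

    method: str  # wilcoxon_signed_rank | mann_whitney_u
    statistic: float
    p_value: float
    n1: int
    n2: int
    approximation: str  # exact | normal_cc

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _two_sided_from_null(null: np.ndarray, observed: float) -> float:
    """P(|T - E| >= |observed - E|) under a (symmetric) enumeration null."""
    center = null.mean()
    dev = abs(observed - center)
    return float(np.mean(np.abs(null - center) >= dev - 1e-12))


def wilcoxon_signed_rank(pairs) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    ``pairs`` is a sequence of (a, b); differences b - a equal to zero
    are dropped before ranking. Exact sign-flip enumeration when the
    effective n is at most 15, otherwise normal approximation with tie
    and continuity corrections. The statistic is W+, the rank sum of
    positive differences.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) == 0:
        raise ParameterError("pairs must be a non-empty sequence of (a, b)")
    d = arr[:, 1] - arr[:, 0]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_MAX_N_WILCOXON:
        # all 2^n sign assignments of the observed midranks
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        null = signs @ ranks
        p = _two_sided_from_null(null, w_plus)
        approx = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        if var <= 0:
            raise DegenerateSampleError("zero variance (all |differences| tied at one value)")
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(2 * _norm.sf(abs(z)))
        approx = "normal_cc"
    return TestResult("wilcoxon_signed_rank", w_plus, min(p, 1.0), len(arr), len(arr), approx)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact labeling enumeration when n1 + n2 <= 20, otherwise normal
    approximation with tie and continuity corrections. The statistic is
    U for the first sample; the p-value is invariant to swapping x and
    y.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n = n1 + n2

    if n <= EXACT_MAX_N_MANNWHITNEY:
        m = min(n1, n2)
        idx = np.array(list(combinations(range(n), m)))
        null = ranks[idx].sum(axis=1) - m * (m + 1) / 2.0
        u_obs = u1 if m == n1 else n1 * n2 - u1  # U of the smaller group
        p = _two_sided_from_null(null, u_obs)
        approx = "exact"
    else:
        mean = n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            raise DegenerateSampleError("zero variance (all observations identical)")
        z = (u1 - mean - 0.5 * np.sign(u1 - mean)) / np.sqrt(var)
        p = float(2 * _norm.sf(abs(z)))
        approx = "normal_cc"
    return TestResult("mann_whitney_u", u1, min(p, 1.0), n1, n2, approx)


def sign_flip_location_test(sample, norm_value: float) -> TestResult:
    """One-sample location test against a stated norm.

    A reconstruction of the published "spread vs norm" comparisons
    (strike length vs one mantle length; strike angle vs perpendicular):
    a Wilcoxon signed-rank test of the sample against the constant norm.
    The original variant is not documented, so this is the package's own
    documented choice, not a certified reproduction.
    """
    sample = np.asarray(list(sample), dtype=float)
    return wilcoxon_signed_rank(np.column_stack([np.full(len(sample), norm_value), sample]))


def summarize_attention(episodes: Table1Fixture | pd.DataFrame) -> pd.DataFrame:
    """Attention durations split by whether the episode preceded a strike.

    Returns one row per group (pre_strike / no_strike) with the
    durations, their min, max and count; the total episode count is in
    ``result.attrs['total']``.
    """
    df = episodes.episodes if isinstance(episodes, Table1Fixture) else episodes
    if len(df) == 0:
        raise ParameterError("need at least one episode")
    rows = []
    for name, flag in (("pre_strike", True), ("no_strike", False)):
        dur = df.loc[df["pre_strike"] == flag, "duration_s"].to_numpy()
        if dur.size:
            rows.append(
                dict(group=name, durations=tuple(dur), min_s=dur.min(), max_s=dur.max(), n=dur.size)
            )
    out = pd.DataFrame(rows)
    out.attrs["total"] = len(df)
    return out


def attention_mann_whitney(episodes: Table1Fixture | pd.DataFrame) -> TestResult:
    """Mann-Whitney U: pre-strike vs other attention durations."""
    df = episodes.episodes if isinstance(episodes, Table1Fixture) else episodes
    pre = df.loc[df["pre_strike"], "duration_s"]
    other = df.loc[~df["pre_strike"], "duration_s"]
    return mann_whitney_u(pre, other)


def summarize_strike_geometry(strikes: list[StrikeEvent]) -> dict[str, pd.DataFrame]:
    """Tidy distribution tables for strike geometry and timing.

    Four tables: normalized strike lengths (ML); body-axis angle
    relative to the prey at onset (deg); per-eye delta-beta excursions
    (deg); and (prey phase, time since last reversal) timing pairs.
    """
    if not strikes:
        raise ParameterError("need at least one strike")
    return {
        "length_ml": pd.DataFrame({"peak_extension_ml": [s.peak_extension_ml for s in strikes]}),
        "angle_deg": pd.DataFrame({"strike_angle_deg": [s.strike_angle_deg for s in strikes]}),
        "delta_beta_deg": pd.DataFrame(
            {
                "side": ["left"] * len(strikes) + ["right"] * len(strikes),
                "delta_beta_deg": [s.delta_beta_left_deg for s in strikes]
                + [s.delta_beta_right_deg for s in strikes],
            }
        ),
        "timing": pd.DataFrame(
            {
                "prey_phase_at_onset": [s.prey_phase_at_onset for s in strikes],
                "time_since_reversal_s": [s.time_since_reversal_s for s in strikes],
            }
        ),
    }
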