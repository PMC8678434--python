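"""Paired and Welch t-tests and the table-style reports built from them.

The paired test operates on per-participant difference features (flare-on
mean minus flare-off mean) and reports the mean estimated difference with
its two-sided 95% CI; a negative estimate means the symptom scores worse
during flare (scores run 1 = least healthy to 5 = most healthy). Cluster
contrasts use Welch's unequal-variance t-test with Satterthwaite degrees of
freedom, applied to continuous covariates and to 0/1 indicators alike. Raw
p-values are reported with a P < 0.01 significance convention and no
multiple-testing correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .catalogue import REPORT_VARIABLE_ORDER
from .data import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    BaselineRecord,
)
from .features import FeatureRow


@dataclass(frozen=True)
class PairedTestResult:
    variable: str
    n: int
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    t_stat: float | None
    df: int | None
    p_value: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class WelchTestResult:
    name: str
    mean_a: float | None
    mean_b: float | None
    sd_a: float | None
    sd_b: float | None
    n_a: int
    n_b: int
    t_stat: float | None
    df: float | None
    p_value: float | None
    degenerate: bool = False
    reason: str | None = None


def paired_t_test(
    diffs: Sequence[float], variable: str = "", confidence: float = 0.95
) -> PairedTestResult:
    """One-sample t-test of per-participant differences against zero.

    t = mean / (sd/√n) with the n−1 sample S.d.; two-sided p from the t
    distribution on n−1 df; CI = mean ± t_{1−α/2, n−1}·sd/√n. Fewer than two
    differences, or zero spread, yields a degenerate result (p = 1 when the
    mean is also zero, p → 0 otherwise).
    """
    values = np.asarray([d for d in diffs if d is not None and np.isfinite(d)], dtype=float)
    n = len(values)
    if n < 2:
        est = float(values[0]) if n == 1 else None
        return PairedTestResult(variable, n, est, None, None, None, None, None, True)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(variable, n, 0.0, 0.0, 0.0, 0.0, df, 1.0, True)
        return PairedTestResult(
            variable, n, mean, mean, mean, math.copysign(math.inf, mean), df, 0.0, True
        )
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    half = float(_sps.t.ppf(0.5 + confidence / 2.0, df)) * se
    return PairedTestResult(variable, n, mean, mean - half, mean + half, t, df, p, False)


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float], name: str = ""
) -> WelchTestResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Missing values are dropped per group. Either group having fewer than two
    finite observations gives a degenerate result carrying whatever moments
    are computable; both groups having zero variance gives p = 1 when the
    means agree and p → 0 otherwise.
    """
    a = np.asarray([x for x in group_a if x is not None and np.isfinite(x)], dtype=float)
    b = np.asarray([x for x in group_b if x is not None and np.isfinite(x)], dtype=float)
    na, nb = len(a), len(b)
    mean_a = float(a.mean()) if na else None
    mean_b = float(b.mean()) if nb else None
    sd_a = float(a.std(ddof=1)) if na >= 2 else None
    sd_b = float(b.std(ddof=1)) if nb >= 2 else None
    if na < 2 or nb < 2:
        return WelchTestResult(
            name, mean_a, mean_b, sd_a, sd_b, na, nb, None, None, None,
            True, "group with fewer than 2 observations",
        )
    va, vb = sd_a**2 / na, sd_b**2 / nb
    delta = mean_a - mean_b
    if va + vb == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
        t = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        return WelchTestResult(
            name, mean_a, mean_b, sd_a, sd_b, na, nb, t, float(na + nb - 2), p,
            True, "zero variance in both groups",
        )
    t = delta / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return WelchTestResult(name, mean_a, mean_b, sd_a, sd_b, na, nb, t, df, p, False)


def _nan(value: float | None) -> float:
    """Missing results become NaN so report columns stay numeric."""
    return np.nan if value is None else float(value)


def build_table1(
    rows: Sequence[FeatureRow],
    variable_order: Sequence[str] = REPORT_VARIABLE_ORDER,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-variable paired tests of flare-on vs flare-off mean scores.

    One row per variable over the participants with both a flare-on and a
    flare-off mean for it (hence the varying n); variables nobody observed
    on both sides get an NA row rather than an error. Rows are flagged
    significant at the raw P < ``alpha`` convention.
    """
    records = []
    for variable in variable_order:
        diffs = [d for r in rows if (d := r.diff(variable)) is not None]
        res = paired_t_test(diffs, variable)
        records.append(
            {
                "variable": variable,
                "estimated_difference": _nan(res.estimate),
                "p_value": _nan(res.p_value),
                "ci_low": _nan(res.ci_low),
                "ci_high": _nan(res.ci_high),
                "n": res.n,
                "significant": (
                    bool(res.p_value < alpha) if res.p_value is not None else False
                ),
            }
        )
    return pd.DataFrame.from_records(records).set_index("variable")


def _split(values: Mapping[str, float | None], labels: Mapping[str, int], cluster: int):
    return [v for pid, v in values.items() if labels.get(pid) == cluster]


def compare_cluster_features(
    rows: Sequence[FeatureRow],
    labels: Mapping[str, int],
    variable_order: Sequence[str] = REPORT_VARIABLE_ORDER,
    clusters: tuple[int, int] = (0, 1),
    min_n_for_p: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-cluster contrasts of the difference features (one table) and
    of the raw flare-on / flare-off means (a second, stacked table).

    Welch p-values are reported only when both clusters contribute at least
    ``min_n_for_p`` participants for the variable; otherwise NA, mirroring
    the tiny-n optional petals.
    """
    a, b = clusters
    by_pid = {r.participant_id: r for r in rows}
    diff_records = []
    for variable in variable_order:
        diffs = {pid: r.diff(variable) for pid, r in by_pid.items()}
        ga = [v for v in _split(diffs, labels, a) if v is not None]
        gb = [v for v in _split(diffs, labels, b) if v is not None]
        res = welch_t_test(ga, gb, variable)
        diff_records.append(
            {
                "variable": variable,
                "diff_group1": _nan(res.mean_a),
                "n_group1": res.n_a,
                "diff_group2": _nan(res.mean_b),
                "n_group2": res.n_b,
                "p_value": _nan(
                    res.p_value
                    if res.n_a >= min_n_for_p and res.n_b >= min_n_for_p
                    else None
                ),
            }
        )
    table2 = pd.DataFrame.from_records(diff_records).set_index("variable")

    mean_records = []
    for phase, attr in (("flare_on", "mean_on"), ("flare_off", "mean_off")):
        for variable in variable_order:
            means = {pid: getattr(r, attr).get(variable) for pid, r in by_pid.items()}
            ga = [v for v in _split(means, labels, a) if v is not None]
            gb = [v for v in _split(means, labels, b) if v is not None]
            res = welch_t_test(ga, gb, variable)
            mean_records.append(
                {
                    "phase": phase,
                    "variable": variable,
                    "mean_group1": _nan(res.mean_a),
                    "sd_group1": _nan(res.sd_a),
                    "n_group1": res.n_a,
                    "mean_group2": _nan(res.mean_b),
                    "sd_group2": _nan(res.sd_b),
                    "n_group2": res.n_b,
                    "p_value": _nan(
                        res.p_value
                        if res.n_a >= min_n_for_p and res.n_b >= min_n_for_p
                        else None
                    ),
                }
            )
    table3 = pd.DataFrame.from_records(mean_records).set_index(["phase", "variable"])
    return table2, table3


def compare_cluster_baselines(
    records: Sequence[BaselineRecord],
    labels: Mapping[str, int],
    clusters: tuple[int, int] = (0, 1),
    min_n_for_p: int = 2,
) -> pd.DataFrame:
    """Between-cluster Welch contrasts of baseline covariates.

    Binary covariates are compared as 0/1 indicators through the same Welch
    machinery (unpooled two-proportion comparison); covariates entirely
    missing in a cluster, or observed in fewer than ``min_n_for_p``
    members, get an NA p-value.
    """
    a, b = clusters
    by_pid = {r.participant_id: r for r in records}
    rows = []
    for kind, names in (("continuous", CONTINUOUS_COVARIATES), ("binary", BINARY_COVARIATES)):
        for name in names:
            values = {
                pid: (
                    r.continuous.get(name) if kind == "continuous" else r.binary.get(name)
                )
                for pid, r in by_pid.items()
            }
            ga = [float(v) for v in _split(values, labels, a) if v is not None]
            gb = [float(v) for v in _split(values, labels, b) if v is not None]
            res = welch_t_test(ga, gb, name)
            rows.append(
                {
                    "covariate": name,
                    "kind": kind,
                    "mean_group1": _nan(res.mean_a),
                    "sd_group1": _nan(res.sd_a),
                    "n_group1": res.n_a,
                    "mean_group2": _nan(res.mean_b),
                    "sd_group2": _nan(res.sd_b),
                    "n_group2": res.n_b,
                    "p_value": _nan(
                        res.p_value
                        if res.n_a >= min_n_for_p and res.n_b >= min_n_for_p
                        else None
                    ),
                }
            )
    return pd.DataFrame.from_records(rows).set_index("covariate")


def two_proportion_chi2(
    successes: tuple[int, int], totals: tuple[int, int]
) -> tuple[float, float]:
    """Chi-square alternative for binary covariate contrasts (2x2 table,
    no continuity correction). Returns (statistic, p)."""
    s1, s2 = successes
    n1, n2 = totals
    table = np.array([[s1, n1 - s1], [s2, n2 - s2]], dtype=float)
    if table.min() < 0 or n1 == 0 or n2 == 0:
        raise ValueError("invalid 2x2 table")
    chi2, p, _, _ = _sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
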