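"""One-way fixed-effects ANOVA, from raw values or summary statistics.

Used to test whether mean K2P distances differ among species-pair groups.
The classic decomposition is computed explicitly (it is also exactly
recoverable from per-group n/mean/sd, which published results often are);
the p-value comes from the F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    ss_between: float
    ss_within: float


def anova_oneway(values, groups) -> AnovaResult:
    """Classic one-way ANOVA of ``values`` grouped by ``groups`` labels."""
    values = np.asarray(values, dtype=float)
    labels = list(groups)
    if values.size != len(labels):
        raise InvalidInputError("values and groups differ in length")
    by_group: dict[str, list[float]] = {}
    for v, g in zip(values, labels):
        by_group.setdefault(g, []).append(float(v))
    if len(by_group) < 2:
        raise InvalidInputError("ANOVA needs at least two groups")
    if any(len(v) < 2 for v in by_group.values()):
        raise InvalidInputError("every group needs at least two values")
    ns = [len(v) for v in by_group.values()]
    means = [float(np.mean(v)) for v in by_group.values()]
    sds = [float(np.std(v, ddof=1)) for v in by_group.values()]
    res = anova_from_summary(ns, means, sds)
    return AnovaResult(
        F=res.F, p_value=res.p_value, df_between=res.df_between,
        df_within=res.df_within,
        group_means={g: float(np.mean(v)) for g, v in by_group.items()},
        ss_between=res.ss_between, ss_within=res.ss_within)


def anova_from_summary(ns, means, sds) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, sample sd).

    The F statistic depends on the data only through these sufficient
    statistics: SSB = sum n_i (mean_i - grand)^2, SSW = sum (n_i - 1) sd_i^2.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.size == means.size == sds.size):
        raise InvalidInputError("ns, means and sds differ in length")
    if ns.size < 2:
        raise InvalidInputError("ANOVA needs at least two groups")
    if (ns < 2).any():
        raise InvalidInputError("every group needs at least two values")
    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    df_b = int(ns.size - 1)
    df_w = int(n_total - ns.size)
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else float("inf")
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(
        F=f, p_value=p, df_between=df_b, df_within=df_w,
        group_means={str(i): float(m) for i, m in enumerate(means)},
        ss_between=ssb, ss_within=ssw)
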