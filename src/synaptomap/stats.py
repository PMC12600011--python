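"""Replicate-level group statistics.

Eye-specific measurements are summarized per biological replicate and
compared across arms (eye or input class) with two-tailed paired t-tests;
cumulative distributions are compared with two-sample Kolmogorov-Smirnov
tests.  Effect sizes are Cohen's d for parametric tests and the rank-based
epsilon squared for nonparametric ones; confidence intervals are reported
at the 5/95% level.  p-values are corrected with the Benjamini-Hochberg
step-up procedure at alpha = 0.05, separately within each experimental
condition family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "paired_t",
    "ks_two_sample",
    "bh_fdr",
    "replicate_summary",
    "paired_family_tests",
]


@dataclass
class StatResult:
    measurement_name: str
    test: str  # "paired_t" | "ks"
    statistic: float
    p: float
    effect_size: float
    effect_name: str
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_adj: float = float("nan")
    n: int = 0


def paired_t(
    arm1: np.ndarray, arm2: np.ndarray, name: str = ""
) -> StatResult:
    """Two-tailed paired t-test on within-replicate differences.

    Cohen's d = mean(diff) / sd(diff); the confidence interval is the
    5/95% interval of the mean difference.
    """
    arm1 = np.asarray(arm1, dtype=float)
    arm2 = np.asarray(arm2, dtype=float)
    if arm1.shape != arm2.shape or arm1.size < 2:
        raise ValueError("paired test needs >= 2 paired replicates")
    diff = arm1 - arm2
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate pairs")
    t, p = sps.ttest_rel(arm1, arm2)
    n = diff.size
    se = sd / np.sqrt(n)
    tq = sps.t.ppf(0.95, df=n - 1)
    mean = diff.mean()
    return StatResult(
        measurement_name=name,
        test="paired_t",
        statistic=float(t),
        p=float(p),
        effect_size=float(mean / sd),
        effect_name="cohens_d",
        ci_low=float(mean - tq * se),
        ci_high=float(mean + tq * se),
        n=n,
    )


def _epsilon_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-based epsilon squared for a two-group comparison.

    epsilon^2 = H / ((n^2 - 1) / (n + 1)) with H the Kruskal-Wallis
    statistic and n the pooled sample size.
    """
    n = len(x) + len(y)
    if len(np.unique(np.concatenate([x, y]))) < 2:
        return 0.0
    h, _ = sps.kruskal(x, y)
    return float(h / ((n * n - 1) / (n + 1)))


def ks_two_sample(x: np.ndarray, y: np.ndarray, name: str = "") -> StatResult:
    """Two-sample Kolmogorov-Smirnov test with epsilon-squared effect size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp" if min(x.size, y.size) > 25 else "auto")
    return StatResult(
        measurement_name=name,
        test="ks",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_size=_epsilon_squared(x, y),
        effect_name="epsilon_squared",
        n=x.size + y.size,
    )


def bh_fdr(
    p_values: list[float] | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment within one condition family.

    Returns (adjusted p-values, rejection flags at ``alpha``).  Adjusted
    values are the cumulative minimum of p(i) * m / i from the largest
    rank, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def replicate_summary(
    replicates: list[dict],
) -> pd.DataFrame:
    """Long-format replicate measurement table.

    Each entry of ``replicates`` describes one biological replicate:
    ``replicate_id``, ``condition``, an ``inputs`` DataFrame (as written by
    the classification stage), optionally a ``records`` DataFrame (spatial
    stage) and ``neuropil_volume_um3``.  Emitted measurements per eye arm
    mirror the figure families: class densities, mAZ input fraction,
    median vesicle volume, mean AZ count, mean volume per AZ, and (when
    spatial records are present) clustered fractions and mean nearby-sAZ
    counts per input class.
    """
    rows = []
    for rep in replicates:
        rid = rep["replicate_id"]
        cond = rep.get("condition", "default")
        df = rep["inputs"]
        vol = rep.get("neuropil_volume_um3")
        records = rep.get("records")
        if df is None or len(df) == 0:
            continue

        def emit(name: str, arm: str, value: float) -> None:
            rows.append(
                dict(
                    replicate_id=rid,
                    condition=cond,
                    measurement_name=name,
                    arm=arm,
                    value=float(value),
                )
            )

        for eye, g in df.groupby("eye"):
            if vol:
                for klass, gg in g.groupby("input_class"):
                    emit(f"density_{klass}", eye, len(gg) / vol)
            emit("maz_fraction", eye, (g.input_class == "mAZ").mean())
            emit("median_vesicle_volume_um3", eye, g.vesicle_volume_um3.median())
            emit("mean_az_count", eye, g.az_count.mean())
            emit("mean_volume_per_az_um3", eye, g.volume_per_az.mean())
            if "mean_docked_volume_um3" in g:
                emit("mean_docked_volume_um3", eye, g.mean_docked_volume_um3.mean())
        if records is not None and len(records):
            for (eye, klass), g in records.groupby(["eye", "input_class"]):
                if g.clustered.notna().any():
                    emit(f"clustered_fraction_{klass}", eye, g.clustered.mean())
                    gg = g[g.clustered == True]  # noqa: E712
                    if len(gg):
                        emit(f"mean_nearby_saz_{klass}", eye, gg.n_nearby_saz.mean())
    return pd.DataFrame(
        rows,
        columns=["replicate_id", "condition", "measurement_name", "arm", "value"],
    )


def paired_family_tests(
    summary: pd.DataFrame,
    arm_pair: tuple[str, str] = ("dominant", "non_dominant"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired eye comparisons per measurement, BH-corrected within condition.

    For every (condition, measurement) with both arms present in every
    replicate, runs a two-tailed paired t-test across replicates; p-values
    are BH-adjusted within each condition family.  Measurements with a
    missing arm or zero difference variance are skipped (logged in the
    ``skipped`` column of the attrs).
    """
    out_rows = []
    skipped = []
    for cond, fam in summary.groupby("condition"):
        results = []
        for name, g in fam.groupby("measurement_name"):
            wide = g.pivot_table(
                index="replicate_id", columns="arm", values="value"
            )
            if not set(arm_pair).issubset(wide.columns):
                skipped.append((cond, name, "missing arm"))
                continue
            wide = wide.dropna(subset=list(arm_pair))
            if len(wide) < 2:
                skipped.append((cond, name, "too few replicates"))
                continue
            try:
                res = paired_t(
                    wide[arm_pair[0]].to_numpy(),
                    wide[arm_pair[1]].to_numpy(),
                    name=name,
                )
            except ValueError:
                skipped.append((cond, name, "degenerate pairs"))
                continue
            results.append(res)
        if not results:
            continue
        p_adj, reject = bh_fdr([r.p for r in results], alpha=alpha)
        for r, pa, rj in zip(results, p_adj, reject):
            out_rows.append(
                dict(
                    condition=cond,
                    measurement_name=r.measurement_name,
                    test=r.test,
                    statistic=r.statistic,
                    p=r.p,
                    p_adj=float(pa),
                    reject=bool(rj),
                    effect_size=r.effect_size,
                    effect_name=r.effect_name,
                    ci_low=r.ci_low,
                    ci_high=r.ci_high,
                    n=r.n,
                )
            )
    out = pd.DataFrame(
        out_rows,
        columns=[
            "condition", "measurement_name", "test", "statistic", "p",
            "p_adj", "reject", "effect_size", "effect_name", "ci_low",
            "ci_high", "n",
        ],
    )
    out.attrs["skipped"] = skipped
    return out
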