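"""Method-agreement statistics: difference indices, Bland-Altman, tests.

Compares a gold-standard (GS) set of manual measurements against
depth-camera (DC) estimates of the same subjects:

* absolute difference index ``d`` — the mean per-subject difference,
  reported with the sign convention that an underestimating DC gives
  ``d < 0`` (i.e. ``d = mean(DC - GS)``);
* relative difference ``Δ = 100 · d / mean(GS)`` in percent;
* Bland-Altman quantities — sample standard deviation of the paired
  differences (``sd_diff``), the coefficient of repeatability
  ``CR = 2 · sd_diff``, the coefficient of variance
  ``CV = 100 · sd_diff / mean_pooled`` (the denominator is the mean of the
  pooled GS and DC values), limits of agreement ``mean ± 1.96·sd_diff``, and
  per-subject ``((GS+DC)/2, DC-GS)`` pairs for plotting;
* a two-sided Mann-Whitney U test of GS vs DC (unpaired, normal
  approximation with tie and continuity corrections);
* the Pearson correlation between GS and DC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "absolute_difference",
    "relative_difference",
    "bland_altman",
    "pearson_correlation",
    "mann_whitney_test",
    "evaluate_parameters",
    "read_paired_table",
    "write_report",
    "write_bland_altman_data",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-subject gold-standard and estimated values for one parameter."""

    gs: np.ndarray
    dc: np.ndarray

    def __post_init__(self) -> None:
        gs = np.asarray(self.gs, dtype=np.float64).ravel()
        dc = np.asarray(self.dc, dtype=np.float64).ravel()
        if gs.size != dc.size:
            raise ValidationError("gs and dc must have the same length")
        if gs.size < 1:
            raise ValidationError("need at least one paired measurement")
        if not (np.isfinite(gs).all() and np.isfinite(dc).all()):
            raise ValidationError("paired measurements must be finite")
        object.__setattr__(self, "gs", gs)
        object.__setattr__(self, "dc", dc)

    @property
    def n(self) -> int:
        return int(self.gs.size)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement summary for one parameter across subjects."""

    n: int
    d: float  # mean(DC - GS), m
    delta_pct: float  # 100 * d / mean(GS)
    r: float  # Pearson correlation
    sd_diff: float  # sample sd (n-1) of DC - GS, m
    CR: float  # 2 * sd_diff, m
    CV_pct: float  # 100 * sd_diff / mean_pooled
    p: float  # Mann-Whitney two-sided p
    mean_pooled: float  # mean of all GS and DC values, m
    loa_low: float  # d - 1.96 * sd_diff
    loa_high: float  # d + 1.96 * sd_diff
    ba_means: np.ndarray  # per-subject (GS + DC) / 2
    ba_diffs: np.ndarray  # per-subject DC - GS


def absolute_difference(pm: PairedMeasurements) -> float:
    """Mean paired difference, negative when DC underestimates GS."""
    return float(np.mean(pm.dc - pm.gs))


def relative_difference(d: float, pm: PairedMeasurements) -> float:
    """Relative difference in percent: ``100 * d / mean(GS)``."""
    mean_gs = float(np.mean(pm.gs))
    if mean_gs == 0:
        raise ValidationError("mean gold-standard value is zero")
    return 100.0 * d / mean_gs


def _sd_diff(pm: PairedMeasurements) -> float:
    if pm.n < 2:
        raise ValidationError("need at least 2 pairs for a standard deviation")
    return float(np.std(pm.dc - pm.gs, ddof=1))


def bland_altman(pm: PairedMeasurements) -> AgreementReport:
    """Full agreement report (see module docstring for definitions)."""
    if pm.n < 2:
        raise ValidationError("Bland-Altman analysis needs at least 2 pairs")
    diffs = pm.dc - pm.gs
    d = float(diffs.mean())
    sd = _sd_diff(pm)
    pooled = float(np.concatenate([pm.gs, pm.dc]).mean())
    if pooled == 0:
        raise ValidationError("pooled mean is zero; CV undefined")
    return AgreementReport(
        n=pm.n,
        d=d,
        delta_pct=relative_difference(d, pm),
        r=pearson_correlation(pm) if pm.n >= 3 and _has_variance(pm) else np.nan,
        sd_diff=sd,
        CR=2.0 * sd,
        CV_pct=100.0 * sd / pooled,
        p=mann_whitney_test(pm),
        mean_pooled=pooled,
        loa_low=d - 1.96 * sd,
        loa_high=d + 1.96 * sd,
        ba_means=(pm.gs + pm.dc) / 2.0,
        ba_diffs=diffs,
    )


def _has_variance(pm: PairedMeasurements) -> bool:
    return float(np.std(pm.gs)) > 0 and float(np.std(pm.dc)) > 0


def pearson_correlation(pm: PairedMeasurements) -> float:
    """Sample Pearson correlation between GS and DC."""
    if pm.n < 3:
        raise ValidationError("Pearson correlation needs at least 3 pairs")
    if not _has_variance(pm):
        raise ValidationError("correlation undefined: a sample has zero variance")
    r, _ = stats.pearsonr(pm.gs, pm.dc)
    return float(r)


def mann_whitney_test(pm: PairedMeasurements) -> float:
    """Two-sided Mann-Whitney U p-value of GS vs DC (unpaired).

    Normal approximation with tie correction and continuity correction.
    When every pooled value is identical the statistic carries no
    information and p = 1 is returned.
    """
    pooled = np.concatenate([pm.gs, pm.dc])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = stats.mannwhitneyu(
        pm.gs, pm.dc, alternative="two-sided", method="asymptotic",
        use_continuity=True,
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Tabular report


_QUART = dict(q=(25, 50, 75), method="linear")


def _describe(vals: np.ndarray, prefix: str) -> dict[str, float]:
    q1, med, q3 = np.percentile(vals, _QUART["q"], method=_QUART["method"])
    return {
        f"{prefix}_mean": float(vals.mean()),
        f"{prefix}_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        f"{prefix}_median": float(med),
        f"{prefix}_q1": float(q1),
        f"{prefix}_q3": float(q3),
    }


def evaluate_parameters(
    per_parameter: dict[str, PairedMeasurements],
) -> pd.DataFrame:
    """One row per parameter with descriptive, difference and agreement columns.

    Columns: parameter, n, gs_mean/sd/median/q1/q3, dc_mean/sd/median/q1/q3,
    d, delta_pct, p, r, sd_diff, CR, CV_pct, mean_pooled, loa_low, loa_high.
    Values are kept at full precision; round only for presentation.
    """
    if not per_parameter:
        raise ValidationError("no parameters to evaluate")
    rows = []
    for name, pm in per_parameter.items():
        rep = bland_altman(pm)
        row: dict[str, float | str | int] = {"parameter": name, "n": pm.n}
        row.update(_describe(pm.gs, "gs"))
        row.update(_describe(pm.dc, "dc"))
        row.update(
            d=rep.d, delta_pct=rep.delta_pct, p=rep.p, r=rep.r,
            sd_diff=rep.sd_diff, CR=rep.CR, CV_pct=rep.CV_pct,
            mean_pooled=rep.mean_pooled, loa_low=rep.loa_low,
            loa_high=rep.loa_high,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text interfaces


def read_paired_table(path: str) -> dict[str, PairedMeasurements]:
    """Read a paired table: columns subject, parameter, gs_m, dc_m."""
    df = pd.read_csv(path, sep=None, engine="python")
    needed = {"subject", "parameter", "gs_m", "dc_m"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"paired table lacks columns: {sorted(missing)}")
    bad = df[~np.isfinite(df["gs_m"]) | ~np.isfinite(df["dc_m"])]
    if len(bad):
        lines = (bad.index + 2).tolist()  # 1-based incl. header
        raise ValidationError(f"non-numeric gs_m/dc_m values on lines {lines}")
    out = {}
    for name, grp in df.groupby("parameter", sort=False):
        out[str(name)] = PairedMeasurements(
            gs=grp["gs_m"].to_numpy(), dc=grp["dc_m"].to_numpy()
        )
    return out


def write_report(report: pd.DataFrame, path: str) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bland_altman_data(rep: AgreementReport, path: str) -> None:
    """Per-subject (mean, diff) pairs plus the bias and limit-of-agreement lines."""
    df = pd.DataFrame({"mean_m": rep.ba_means, "diff_m": rep.ba_diffs})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# bias: {rep.d:.6g}\n")
        fh.write(f"# loa_low: {rep.loa_low:.6g}\n")
        fh.write(f"# loa_high: {rep.loa_high:.6g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
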