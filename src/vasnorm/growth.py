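"""Tumour growth-delay and survival endpoint analysis.

Calliper measurements (length, width, height, three times a week) are
converted to ellipsoid volumes V = π/6·l·w·h.  Animals are treated at
100–120 mm³ and followed to a 400 mm³ endpoint; the analysis endpoints are

* time to endpoint (first threshold crossing, linearly interpolated between
  bracketing measurements; censored at last observation when never reached),
* regrowth interval between two volume thresholds (e.g. 150 → 400 mm³),
* group comparisons: ordinary one-way ANOVA with Tukey's HSD multiple
  comparisons, preceded by Brown–Forsythe's test, plus Kaplan–Meier survival
  to endpoint and pairwise log-rank (Mantel–Cox) tests versus control.

Animals that never reach the endpoint (e.g. cured) are censored in the
survival analysis and excluded, flagged, from the delay means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ENDPOINT_MM3 = 400.0
DEFAULT_TREATMENT_WINDOW = (100.0, 120.0)

MEASUREMENT_COLUMNS = ["animal_id", "group", "day", "length_mm", "width_mm", "height_mm"]


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class GrowthStudy:
    """Longitudinal calliper records for a treatment study.

    ``records`` must carry columns animal_id, group, day, length_mm,
    width_mm, height_mm; days must be non-decreasing within each animal.
    """

    records: pd.DataFrame
    endpoint_volume: float = DEFAULT_ENDPOINT_MM3
    treatment_window: tuple[float, float] = DEFAULT_TREATMENT_WINDOW

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        dims = self.records[["length_mm", "width_mm", "height_mm"]].to_numpy()
        if (dims < 0).any():
            raise ValueError("calliper dimensions must be non-negative")
        for animal, sub in self.records.groupby("animal_id"):
            if (np.diff(sub.day.to_numpy()) < 0).any():
                raise ValueError(f"days not sorted for animal {animal!r}")

    def with_volumes(self) -> pd.DataFrame:
        df = self.records.copy()
        df["volume_mm3"] = calliper_volume(
            df.length_mm.to_numpy(), df.width_mm.to_numpy(), df.height_mm.to_numpy()
        )
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records[MEASUREMENT_COLUMNS].to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "GrowthStudy":
        return cls(records=pd.read_csv(path), **kwargs)


@dataclass
class SurvivalRecord:
    """Time to reach the endpoint volume; ``event=False`` marks censoring."""

    animal_id: str
    group: str
    time: float
    event: bool


# --------------------------------------------------------------------------
# volumes and threshold crossings
# --------------------------------------------------------------------------

def calliper_volume(length, width, height):
    """Ellipsoid tumour volume V = π/6 · l · w · h (mm³)."""
    length = np.asarray(length, float)
    width = np.asarray(width, float)
    height = np.asarray(height, float)
    if (length < 0).any() or (width < 0).any() or (height < 0).any():
        raise ValueError("calliper dimensions must be non-negative")
    out = np.pi / 6.0 * length * width * height
    return float(out) if out.ndim == 0 else out


def time_to_threshold(
    days: Sequence[float],
    volumes: Sequence[float],
    threshold: float,
) -> tuple[float, bool]:
    """First crossing time of ``threshold``, linearly interpolated.

    Returns ``(time, event)``; when the threshold is never reached the last
    observation day is returned with ``event=False`` (censored).  If the
    first measurement is already at or above the threshold, its day is the
    crossing time.
    """
    days = np.asarray(days, float)
    volumes = np.asarray(volumes, float)
    if days.size == 0:
        raise ValueError("empty trajectory")
    if days.size != volumes.size:
        raise ValueError("days and volumes must have equal length")
    if (np.diff(days) < 0).any():
        raise ValueError("trajectory must be sorted by day")
    if volumes[0] >= threshold:
        return float(days[0]), True
    above = np.flatnonzero(volumes >= threshold)
    if above.size == 0:
        return float(days[-1]), False
    i = above[0]
    v0, v1 = volumes[i - 1], volumes[i]
    t = days[i - 1] + (days[i] - days[i - 1]) * (threshold - v0) / (v1 - v0)
    return float(t), True


def regrowth_interval(
    days: Sequence[float],
    volumes: Sequence[float],
    from_volume: float = 150.0,
    to_volume: float = DEFAULT_ENDPOINT_MM3,
) -> tuple[float, bool]:
    """Days between the (interpolated) crossings of two volume thresholds.

    Raises if ``from_volume`` is never reached; returns a censored interval
    (to the last observation) when ``to_volume`` is never reached.
    """
    t_from, reached = time_to_threshold(days, volumes, from_volume)
    if not reached:
        raise ValueError(f"trajectory never reaches from_volume={from_volume:g}")
    t_to, event = time_to_threshold(days, volumes, to_volume)
    return float(t_to - t_from), event


def survival_records(study: GrowthStudy) -> pd.DataFrame:
    """Per-animal time-to-endpoint table (animal_id, group, time, event)."""
    df = study.with_volumes()
    rows = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("day")
        t, event = time_to_threshold(
            sub.day.to_numpy(), sub.volume_mm3.to_numpy(), study.endpoint_volume
        )
        rows.append({"animal_id": animal, "group": group, "time": t, "event": event})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# group-comparison statistics
# --------------------------------------------------------------------------

@dataclass
class AnovaTukeyResult:
    f: float
    p: float
    tukey: pd.DataFrame  # group_a, group_b, mean_diff, p_adj


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        out[name] = arr
    return out


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """Ordinary one-way ANOVA with Tukey's HSD all-pairs comparisons.

    The adjusted p-values use the studentised-range distribution with the
    pooled within-group variance (classic HSD).  With zero within- and
    between-group variance the convention F = 0, p = 1 is returned.
    """
    arrs = _validate_groups(groups)
    names = list(arrs)
    data = list(arrs.values())
    pooled = np.concatenate(data)
    within_ss = sum(((a - a.mean()) ** 2).sum() for a in data)
    between_ss = sum(a.size * (a.mean() - pooled.mean()) ** 2 for a in data)
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    if within_ss == 0:
        if between_ss == 0:
            f, p = 0.0, 1.0
            p_adj = np.ones(len(pairs))
        else:
            f, p = float("inf"), 0.0
            p_adj = np.array([
                0.0 if data[i].mean() != data[j].mean() else 1.0 for i, j in pairs
            ])
        rows = [{
            "group_a": names[i], "group_b": names[j],
            "mean_diff": data[j].mean() - data[i].mean(), "p_adj": pa,
        } for (i, j), pa in zip(pairs, p_adj)]
        return AnovaTukeyResult(f=f, p=p, tukey=pd.DataFrame(rows))
    f, p = stats.f_oneway(*data)
    hsd = stats.tukey_hsd(*data)
    rows = [{
        "group_a": names[i],
        "group_b": names[j],
        "mean_diff": data[j].mean() - data[i].mean(),
        "p_adj": float(hsd.pvalue[i, j]),
    } for i, j in pairs]
    return AnovaTukeyResult(f=float(f), p=float(p), tukey=pd.DataFrame(rows))


@dataclass
class BrownForsytheResult:
    statistic: float
    p: float
    kind: str
    df: tuple[float, float] | None = None


def brown_forsythe(
    groups: Mapping[str, Sequence[float]],
    kind: str = "means",
) -> BrownForsytheResult:
    """Brown–Forsythe test, in either of its two standard senses.

    ``kind="means"`` (default): the Brown–Forsythe robust one-way ANOVA for
    equality of group means under unequal variances,
    F* = Σ nᵢ(x̄ᵢ − x̄)² / Σ (1 − nᵢ/N) sᵢ², with Satterthwaite denominator
    degrees of freedom.  ``kind="variances"``: the median-centred Levene
    test, i.e. a one-way ANOVA on absolute deviations from group medians.
    """
    arrs = _validate_groups(groups)
    data = list(arrs.values())
    if kind == "variances":
        stat, p = stats.levene(*data, center="median")
        return BrownForsytheResult(statistic=float(stat), p=float(p), kind=kind)
    if kind != "means":
        raise ValueError("kind must be 'means' or 'variances'")
    n = np.array([a.size for a in data], float)
    means = np.array([a.mean() for a in data])
    var = np.array([a.var(ddof=1) for a in data])
    grand = np.concatenate(data).mean()
    num = float(np.sum(n * (means - grand) ** 2))
    c = (1 - n / n.sum()) * var
    denom = float(c.sum())
    if denom == 0:
        if num == 0:
            return BrownForsytheResult(0.0, 1.0, kind, (len(data) - 1, float("inf")))
        return BrownForsytheResult(float("inf"), 0.0, kind, (len(data) - 1, float("inf")))
    f_star = num / denom
    df1 = len(data) - 1
    rel = c / denom
    df2 = 1.0 / np.sum(rel**2 / (n - 1))
    p = float(stats.f.sf(f_star, df1, df2))
    return BrownForsytheResult(statistic=float(f_star), p=p, kind=kind, df=(df1, float(df2)))


# --------------------------------------------------------------------------
# survival: Kaplan-Meier and log-rank
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve with risk-set bookkeeping."""

    table: pd.DataFrame  # time, n_risk, n_events, n_censored, survival
    label: str | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        tab = self.table
        past = tab[tab.time <= t]
        return float(past.survival.iloc[-1]) if len(past) else 1.0

    def plot(self, ax=None, **kwargs):
        """Draw the step curve; censored times are marked with ticks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.table.time.to_numpy()])
        s = np.concatenate([[1.0], self.table.survival.to_numpy()])
        ax.step(t, s, where="post", label=self.label, **kwargs)
        cens = self.table[self.table.n_censored > 0]
        if len(cens):
            ax.plot(cens.time, cens.survival, "|", color=ax.lines[-1].get_color())
        ax.set_xlabel("days")
        ax.set_ylabel("survival to endpoint")
        ax.set_ylim(-0.02, 1.02)
        return ax


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    label: str | None = None,
) -> KMCurve:
    """Kaplan–Meier product-limit estimate S(t) = Π (1 − dᵢ/nᵢ).

    Censored records reduce the risk set without producing a step.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("need at least one record")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label or "KM")
    et = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    table = pd.DataFrame({
        "time": et.index.to_numpy(float),
        "n_risk": et.at_risk.to_numpy(int),
        "n_events": et.observed.to_numpy(int),
        "n_censored": et.censored.to_numpy(int),
        "survival": surv.reindex(et.index).to_numpy(float),
    }).reset_index(drop=True)
    return KMCurve(table=table, label=label)


@dataclass
class LogrankResult:
    statistic: float
    p: float
    note: str = ""


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> LogrankResult:
    """Two-group log-rank (Mantel–Cox) test; chi-square with 1 df."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return LogrankResult(float("nan"), float("nan"), note="no events in either group")
    from lifelines.statistics import logrank_test as _lr

    res = _lr(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(statistic=float(res.test_statistic), p=float(res.p_value))


# --------------------------------------------------------------------------
# study-level report
# --------------------------------------------------------------------------

@dataclass
class GrowthDelayReport:
    """All endpoint statistics of a growth study, against a control group."""

    survival: pd.DataFrame            # animal_id, group, time, event
    group_summary: pd.DataFrame       # group, n, n_events, mean_days, sem_days
    anova: AnovaTukeyResult
    brown_forsythe: BrownForsytheResult
    km_curves: dict[str, KMCurve]
    logrank_vs_control: pd.DataFrame  # group, statistic, p
    control: str
    endpoint_volume: float
    censored_excluded: list[str] = field(default_factory=list)

    def plot_km(self, ax=None):
        """Overlay the Kaplan-Meier curves of all groups."""
        for label, curve in sorted(self.km_curves.items()):
            ax = curve.plot(ax=ax)
        ax.legend()
        return ax

    def delay_vs_control(self, group: str) -> float:
        """Mean extra days to endpoint relative to the control group."""
        s = self.group_summary.set_index("group").mean_days
        return float(s[group] - s[self.control])

    def summary(self) -> str:
        lines = [
            f"Growth delay to {self.endpoint_volume:g} mm3 "
            f"(control group: {self.control!r})",
            "",
            self.group_summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
            "",
            f"One-way ANOVA: F = {self.anova.f:.3f}, p = {self.anova.p:.4g}",
            f"Brown-Forsythe ({self.brown_forsythe.kind}): "
            f"stat = {self.brown_forsythe.statistic:.3f}, p = {self.brown_forsythe.p:.4g}",
            "",
            "Tukey HSD (all pairs):",
            self.anova.tukey.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "Log-rank vs control:",
            self.logrank_vs_control.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.censored_excluded:
            lines.append("")
            lines.append(
                "Censored (excluded from delay means, kept in KM/log-rank): "
                + ", ".join(self.censored_excluded)
            )
        return "\n".join(lines)


def growth_delay_report(
    study: GrowthStudy,
    control: str = "control",
    bf_kind: str = "means",
) -> GrowthDelayReport:
    """Full endpoint analysis: delay means ± SEM, ANOVA/Tukey, KM, log-rank.

    Censored animals (endpoint never reached) enter the Kaplan–Meier and
    log-rank analyses but are excluded — and flagged — from the delay means
    and the ANOVA.
    """
    surv = survival_records(study)
    if control not in set(surv.group):
        raise ValueError(f"control group {control!r} not present in study")
    censored_ids = surv.loc[~surv.event, "animal_id"].tolist()
    if censored_ids:
        warnings.warn(
            f"{len(censored_ids)} censored animal(s) excluded from delay means: "
            f"{censored_ids}",
            stacklevel=2,
        )
    events_only = surv[surv.event]
    rows = []
    for group, sub in surv.groupby("group"):
        ev = sub[sub.event]
        rows.append({
            "group": group,
            "n": len(sub),
            "n_events": len(ev),
            "n_censored": len(sub) - len(ev),
            "mean_days": ev.time.mean() if len(ev) else float("nan"),
            "sem_days": ev.time.sem() if len(ev) > 1 else float("nan"),
        })
    group_summary = pd.DataFrame(rows)
    delay_groups = {
        g: sub.time.to_numpy() for g, sub in events_only.groupby("group")
    }
    anova = anova_tukey(delay_groups)
    bf = brown_forsythe(delay_groups, kind=bf_kind)
    km_curves = {
        g: km_estimate(sub.time.to_numpy(), sub.event.to_numpy(), label=g)
        for g, sub in surv.groupby("group")
    }
    ctrl = surv[surv.group == control]
    lr_rows = []
    for group, sub in surv.groupby("group"):
        if group == control:
            continue
        res = logrank_test(
            sub.time.to_numpy(), sub.event.to_numpy(),
            ctrl.time.to_numpy(), ctrl.event.to_numpy(),
        )
        lr_rows.append({"group": group, "statistic": res.statistic, "p": res.p})
    return GrowthDelayReport(
        survival=surv,
        group_summary=group_summary,
        anova=anova,
        brown_forsythe=bf,
        km_curves=km_curves,
        logrank_vs_control=pd.DataFrame(lr_rows),
        control=control,
        endpoint_volume=study.endpoint_volume,
        censored_excluded=censored_ids,
    )
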