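"""Field-potential analysis for microelectrode-array (MEA) recordings.

Spontaneously beating cardiomyocyte monolayers yield per-beat field-potential
durations (FPD, the cellular surrogate of the QT interval) and inter-beat
intervals (IBI).  FPD depends on beating rate, so it is adjusted with a power
law aFPD = rawFPD / (IBI/1000)^α where the exponent α is re-estimated from the
baseline data themselves rather than fixed at Bazett's 1/2 (which
over-corrects) or Fridericia's 1/3.  Dose-response curves of the
baseline-normalised aFPD change are then summarised with a Hill fit, lines are
screened for arrhythmic beating, QC-filtered and classified by their response
at a reference drug concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BeatSeries",
    "RateCorrection",
    "DoseResponse",
    "HillFit",
    "ArrhythmiaCall",
    "AnovaTable",
    "fit_rate_correction",
    "adjust_fpd",
    "dose_response",
    "fit_hill",
    "hill_curve",
    "detect_arrhythmia",
    "qc_filter_lines",
    "classify_lines",
    "two_way_rm_anova",
]


@dataclass(frozen=True)
class BeatSeries:
    """One 2-minute recording: aligned IBI and raw FPD sequences (ms).

    ``concentration`` is the cumulative drug concentration in mol/L; 0 denotes
    the vehicle baseline.
    """

    line_id: str
    concentration: float
    ibi: np.ndarray
    raw_fpd: np.ndarray
    drug: str = "sotalol"

    def __post_init__(self):
        ibi = np.asarray(self.ibi, dtype=float)
        fpd = np.asarray(self.raw_fpd, dtype=float)
        object.__setattr__(self, "ibi", ibi)
        object.__setattr__(self, "raw_fpd", fpd)
        if ibi.shape != fpd.shape:
            raise ValueError("ibi and raw_fpd must be aligned (same length)")
        if ibi.size and (np.any(ibi <= 0) or np.any(fpd <= 0)):
            raise ValueError("IBI and FPD values must be positive (ms)")


@dataclass(frozen=True)
class RateCorrection:
    """Fitted rate-correction law log(FPD) = intercept + α·log(IBI/1000)."""

    alpha: float
    intercept: float  # log-ms
    residual_slope: float  # ms per ms, corrected FPD vs IBI
    residual_slope_p: float
    n_points: int


def fit_rate_correction(baseline_series) -> RateCorrection:
    """Estimate the correction exponent α from baseline recordings.

    Pools all (IBI, FPD) pairs of the given :class:`BeatSeries` collection and
    fits ``log(FPD) = intercept + α·log(IBI/1000)`` by least squares.  The
    over-correction diagnostic regresses the adjusted FPD on IBI: a slope near
    zero means the fitted exponent removed the rate dependence (an exponent
    that is too large, e.g. Bazett on data generated with a smaller true α,
    leaves a positive slope).
    """
    if isinstance(baseline_series, BeatSeries):
        baseline_series = [baseline_series]
    ibi = np.concatenate([s.ibi for s in baseline_series])
    fpd = np.concatenate([s.raw_fpd for s in baseline_series])
    if ibi.size < 3:
        raise ValueError("need at least 3 (IBI, FPD) pairs")
    if np.unique(ibi).size < 2:
        raise ValueError("degenerate IBI spread: all inter-beat intervals equal")
    x = np.log(ibi / 1000.0)
    y = np.log(fpd)
    alpha, intercept = np.polyfit(x, y, 1)
    afpd = adjust_fpd(fpd, ibi, alpha)
    res = stats.linregress(ibi, afpd)
    return RateCorrection(
        alpha=float(alpha),
        intercept=float(intercept),
        residual_slope=float(res.slope),
        residual_slope_p=float(res.pvalue),
        n_points=int(ibi.size),
    )


def adjust_fpd(raw_fpd, ibi, alpha: float):
    """Rate-adjust FPD: aFPD = rawFPD / (IBI/1000)^α (all ms)."""
    ibi = np.asarray(ibi, dtype=float)
    if np.any(ibi <= 0):
        raise ValueError("IBI must be positive (ms)")
    return np.asarray(raw_fpd, dtype=float) / (ibi / 1000.0) ** alpha


@dataclass
class DoseResponse:
    """Baseline-normalised aFPD change per concentration for one line."""

    line_id: str
    concentrations: np.ndarray  # mol/L, ascending, incl. 0 (vehicle)
    afpd_mean: np.ndarray  # ms, per concentration
    afpd_change: np.ndarray  # fraction relative to vehicle
    max_change: float
    arrhythmia_flags: np.ndarray  # bool per concentration

    def change_at(self, concentration: float) -> float:
        i = np.flatnonzero(np.isclose(self.concentrations, concentration))
        if i.size == 0:
            raise KeyError(f"concentration {concentration!r} not recorded for {self.line_id}")
        return float(self.afpd_change[i[0]])


def dose_response(series_list, correction: RateCorrection) -> DoseResponse:
    """Assemble the dose-response of one line from its recordings.

    Each recording is rate-adjusted with ``correction`` and summarised by the
    mean aFPD over its beats; changes are expressed relative to the vehicle
    (concentration 0) recording.  Arrhythmia flags are computed per
    concentration against the vehicle recording.
    """
    series_list = sorted(series_list, key=lambda s: s.concentration)
    lines = {s.line_id for s in series_list}
    if len(lines) != 1:
        raise ValueError(f"dose_response expects one line, got {sorted(lines)}")
    conc = np.array([s.concentration for s in series_list])
    if not np.any(conc == 0):
        raise ValueError("missing vehicle baseline (concentration 0)")
    baseline = next(s for s in series_list if s.concentration == 0)
    means = np.array(
        [float(np.mean(adjust_fpd(s.raw_fpd, s.ibi, correction.alpha))) for s in series_list]
    )
    base = means[conc == 0][0]
    change = (means - base) / base
    flags = np.array(
        [detect_arrhythmia(s, baseline).flag if s.concentration > 0 else False for s in series_list]
    )
    return DoseResponse(
        line_id=baseline.line_id,
        concentrations=conc,
        afpd_mean=means,
        afpd_change=change,
        max_change=float(change.max()),
        arrhythmia_flags=flags,
    )


def hill_curve(c, emax: float, ec50: float, h: float):
    """Hill response r(c) = Emax·c^h / (c^h + EC50^h)."""
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    out[pos] = emax * c[pos] ** h / (c[pos] ** h + ec50**h)
    return out


@dataclass(frozen=True)
class HillFit:
    ec50: float  # mol/L
    emax: float  # fraction
    hill_coef: float
    rss: float


def fit_hill(concentrations, responses, h_bounds=(0.5, 4.0)) -> HillFit:
    """Least-squares Hill fit with multistart initialisation.

    EC50 is parameterised on the log scale and started from a grid spanning
    the tested concentration range; the Hill coefficient is bounded (default
    [0.5, 4]).  A warning is raised when the fitted EC50 falls outside the
    tested span (extrapolated potency).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    order = np.argsort(c)
    c, r = c[order], r[order]
    pos = c > 0
    if pos.sum() < 4:
        raise ValueError("need at least 4 non-zero concentration levels")
    if np.allclose(r, r[0]):
        raise ValueError("constant response: nothing to fit")

    lo, hi = np.log10(c[pos].min()), np.log10(c[pos].max())
    emax0 = max(float(np.max(np.abs(r))), 1e-3)
    best = None
    failures = []
    for log_ec50 in np.linspace(lo - 1, hi + 1, 7):
        for h0 in (0.7, 1.0, 2.0):
            x0 = np.array([emax0, log_ec50, h0])

            def resid(x):
                return hill_curve(c, x[0], 10.0 ** x[1], x[2]) - r

            try:
                sol = optimize.least_squares(
                    resid,
                    x0,
                    bounds=([0.0, lo - 4, h_bounds[0]], [np.inf, hi + 4, h_bounds[1]]),
                )
            except Exception as exc:  # pragma: no cover - scipy rarely raises here
                failures.append(str(exc))
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError(f"Hill fit failed for all starts: {failures}")
    rss, (emax, log_ec50, h) = best
    ec50 = float(10.0**log_ec50)
    if not (c[pos].min() <= ec50 <= c[pos].max()):
        warnings.warn(
            f"fitted EC50 {ec50:.3g} M lies outside the tested span "
            f"[{c[pos].min():.3g}, {c[pos].max():.3g}] M",
            stacklevel=2,
        )
    return HillFit(ec50=ec50, emax=float(emax), hill_coef=float(h), rss=rss)


@dataclass(frozen=True)
class ArrhythmiaCall:
    flag: bool
    ectopic: bool  # any IBI < short_fraction × median IBI
    irregular: bool  # CV(IBI) above threshold
    cv: float
    baseline_cv: float
    min_ibi_ratio: float


# Repo-defined constants realising the qualitative "ectopic beats or irregular
# beating" rule; overridable via keyword arguments / PipelineConfig.
SHORT_BEAT_FRACTION = 0.8
CV_FLOOR = 0.10
CV_BASELINE_FACTOR = 2.0


def detect_arrhythmia(
    series: BeatSeries,
    baseline_series: BeatSeries,
    short_fraction: float = SHORT_BEAT_FRACTION,
    cv_floor: float = CV_FLOOR,
    cv_factor: float = CV_BASELINE_FACTOR,
) -> ArrhythmiaCall:
    """Flag arrhythmic beating: ectopic (short) beats or irregular rate.

    A recording is flagged when any IBI drops below ``short_fraction`` × its
    median (ectopic beat) or when the IBI coefficient of variation exceeds
    max(``cv_floor``, ``cv_factor`` × baseline CV).
    """
    if series.ibi.size < 10 or baseline_series.ibi.size < 10:
        raise ValueError("need at least 10 beats in each series")
    med = float(np.median(series.ibi))
    min_ratio = float(series.ibi.min() / med)
    ectopic = bool(min_ratio < short_fraction)
    cv = float(np.std(series.ibi) / np.mean(series.ibi))
    base_cv = float(np.std(baseline_series.ibi) / np.mean(baseline_series.ibi))
    irregular = bool(cv > max(cv_floor, cv_factor * base_cv))
    return ArrhythmiaCall(
        flag=ectopic or irregular,
        ectopic=ectopic,
        irregular=irregular,
        cv=cv,
        baseline_cv=base_cv,
        min_ibi_ratio=min_ratio,
    )


def qc_filter_lines(
    line_metadata: pd.DataFrame,
    responsiveness_floor: float = 0.05,
) -> pd.DataFrame:
    """Line-level quality control.

    Drops lines whose maximal FPD change under the reference hERG blocker
    (E4031) stays below ``responsiveness_floor`` and lines with an abnormal
    karyotype.  Requires columns ``line_id, karyotype_ok, e4031_max_change``.
    Returns the metadata with ``retained`` and ``exclusion_reason`` columns.
    """
    required = {"line_id", "karyotype_ok", "e4031_max_change"}
    missing = required - set(line_metadata.columns)
    if missing:
        raise ValueError(f"line metadata missing columns: {sorted(missing)}")
    if line_metadata[["karyotype_ok", "e4031_max_change"]].isna().any().any():
        raise ValueError("line metadata must be complete (no missing QC fields)")
    out = line_metadata.copy()
    reasons = []
    for _, row in out.iterrows():
        why = []
        if row["e4031_max_change"] < responsiveness_floor:
            why.append("e4031_non_responder")
        if not row["karyotype_ok"]:
            why.append("abnormal_karyotype")
        reasons.append(";".join(why))
    out["exclusion_reason"] = reasons
    out["retained"] = [r == "" for r in reasons]
    return out


def classify_lines(
    dose_responses,
    labels: pd.Series | dict,
    threshold: float = 0.25,
    at_concentration: float = 3e-5,
) -> pd.DataFrame:
    """Classify lines by their aFPD change at a reference concentration.

    A change strictly above ``threshold`` (default 25%) at
    ``at_concentration`` (default 30 µM) predicts a high-sensitivity donor;
    ties at the threshold go to low.  Returns per-line predictions joined with
    the provided labels and a ``correct`` flag.
    """
    labels = dict(labels)
    rows = []
    for dr in dose_responses:
        change = dr.change_at(at_concentration)
        pred = "high" if change > threshold else "low"
        truth = labels.get(dr.line_id)
        rows.append(
            {
                "line_id": dr.line_id,
                "change": change,
                "predicted": pred,
                "label": truth,
                "correct": (pred == truth) if truth is not None else None,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaTable:
    """Mixed-design (split-plot) ANOVA decomposition.

    Between-subjects factor: group (error term: lines within groups).
    Within-subjects factor: concentration, and its interaction with group
    (error term: concentration × lines-within-groups).
    """

    table: pd.DataFrame  # rows: group, subjects_within, concentration, interaction, error_within
    f_group: float
    p_group: float
    f_concentration: float
    p_concentration: float
    f_interaction: float
    p_interaction: float
    ss_total: float


def two_way_rm_anova(response: pd.DataFrame, groups: pd.Series | dict) -> AnovaTable:
    """Two-way repeated-measures ANOVA on a line × concentration matrix.

    ``response`` holds one row per line and one column per within-subject
    level (concentration); ``groups`` maps line id → group label.  Missing
    cells are an error (no imputation).  Classical sums-of-squares
    decomposition for the split-plot design.
    """
    if response.isna().any().any():
        raise ValueError("missing cells in the response matrix (no imputation)")
    groups = pd.Series(dict(groups)).loc[response.index]
    counts = groups.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 lines each")

    y = response.to_numpy(dtype=float)
    n_lines, b = y.shape
    a = len(counts)
    grand = y.mean()

    ss_total = float(((y - grand) ** 2).sum())
    line_means = y.mean(axis=1)
    ss_subjects = float(b * ((line_means - grand) ** 2).sum())
    group_means = {g: y[groups.to_numpy() == g].mean() for g in counts.index}
    ss_group = float(
        b * sum(counts[g] * (group_means[g] - grand) ** 2 for g in counts.index)
    )
    ss_subj_within = ss_subjects - ss_group
    conc_means = y.mean(axis=0)
    # concentration means weighted by group size (every line has every level)
    ss_conc = float(n_lines * ((conc_means - grand) ** 2).sum())
    ss_cells = 0.0
    for g in counts.index:
        sub = y[groups.to_numpy() == g]
        ss_cells += counts[g] * ((sub.mean(axis=0) - grand) ** 2).sum()
    ss_inter = float(ss_cells - ss_group - ss_conc)
    ss_err = ss_total - ss_subjects - ss_conc - ss_inter

    df_group = a - 1
    df_sw = n_lines - a
    df_conc = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = (n_lines - a) * (b - 1)

    ms = lambda ss, df: ss / df if df > 0 else np.nan
    f_group = ms(ss_group, df_group) / ms(ss_subj_within, df_sw)
    f_conc = ms(ss_conc, df_conc) / ms(ss_err, df_err)
    f_inter = ms(ss_inter, df_inter) / ms(ss_err, df_err)
    p_group = float(stats.f.sf(f_group, df_group, df_sw))
    p_conc = float(stats.f.sf(f_conc, df_conc, df_err))
    p_inter = float(stats.f.sf(f_inter, df_inter, df_err))

    table = pd.DataFrame(
        {
            "source": ["group", "subjects_within", "concentration", "interaction", "error_within"],
            "ss": [ss_group, ss_subj_within, ss_conc, ss_inter, ss_err],
            "df": [df_group, df_sw, df_conc, df_inter, df_err],
        }
    )
    return AnovaTable(
        table=table,
        f_group=float(f_group),
        p_group=p_group,
        f_concentration=float(f_conc),
        p_concentration=p_conc,
        f_interaction=float(f_inter),
        p_interaction=p_inter,
        ss_total=ss_total,
    )
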