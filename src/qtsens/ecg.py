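"""Rate-corrected QT phenotyping and extreme-responder selection.

The clinical sensitivity phenotype is the change in Fridericia-corrected QT
(ΔQTcf, ms) between a pre-drug baseline (mean of replicate ECGs) and a single
post-drug recording.  Subjects in the tails of the ΔQTcf distribution are
labelled high- or low-sensitivity; the two arms are later contrasted in vitro.

RR intervals are stored in ms throughout but normalised to seconds inside the
rate-law denominators, so QT in ms yields a corrected QT in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correct_qt_fridericia",
    "correct_qt_bazett",
    "phenotype_subject",
    "phenotype_cohort",
    "select_extremes",
    "power_two_sample",
    "compare_groups",
    "SubjectPhenotype",
    "SelectionResult",
    "PowerResult",
]


def _check_rr(rr) -> np.ndarray:
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR interval must be positive (ms)")
    return rr


def correct_qt_fridericia(qt, rr):
    """Fridericia cube-root correction: QTcf = QT / (RR/1000)^(1/3).

    Parameters are in ms; RR is converted to seconds inside the power law.
    Accepts scalars or arrays.
    """
    rr = _check_rr(rr)
    return np.asarray(qt, dtype=float) / (rr / 1000.0) ** (1.0 / 3.0)


def correct_qt_bazett(qt, rr):
    """Bazett square-root correction: QTc = QT / (RR/1000)^(1/2)."""
    rr = _check_rr(rr)
    return np.asarray(qt, dtype=float) / (rr / 1000.0) ** 0.5


@dataclass(frozen=True)
class SubjectPhenotype:
    """Per-subject phenotype: baseline/post QTcf (ms) and their difference."""

    subject_id: str
    qtcf_baseline: float
    qtcf_post: float
    delta_qtcf: float
    sensitivity: str = "unselected"


def phenotype_subject(records: pd.DataFrame) -> SubjectPhenotype:
    """Collapse one subject's ECG records into a :class:`SubjectPhenotype`.

    ``records`` needs columns ``subject_id, phase, rr_ms, qt_ms`` with phase in
    {"baseline", "post_drug"}.  Each record is rate-corrected first and the
    baseline replicates are then averaged; ΔQTcf = post − mean(baseline).
    """
    subjects = records["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"expected records for one subject, got {list(subjects)}")
    qtcf = correct_qt_fridericia(records["qt_ms"].to_numpy(), records["rr_ms"].to_numpy())
    phase = records["phase"].to_numpy()
    base = qtcf[phase == "baseline"]
    post = qtcf[phase == "post_drug"]
    if base.size == 0 or post.size == 0:
        raise ValueError(f"subject {subjects[0]}: need >=1 baseline and >=1 post_drug record")
    qtcf_baseline = float(base.mean())
    qtcf_post = float(post.mean())
    return SubjectPhenotype(
        subject_id=str(subjects[0]),
        qtcf_baseline=qtcf_baseline,
        qtcf_post=qtcf_post,
        delta_qtcf=qtcf_post - qtcf_baseline,
    )


def phenotype_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`phenotype_subject` per subject; returns a tidy table."""
    rows = [
        phenotype_subject(g)
        for _, g in records.groupby("subject_id", sort=True)
    ]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "qtcf_baseline": [r.qtcf_baseline for r in rows],
            "qtcf_post": [r.qtcf_post for r in rows],
            "delta_qtcf": [r.delta_qtcf for r in rows],
        }
    )


@dataclass
class SelectionResult:
    """Extreme-arm selection outcome."""

    phenotypes: pd.DataFrame  # with a "sensitivity" column
    high_threshold: float
    low_threshold: float
    n_high: int
    n_low: int
    shortfall_high: int
    shortfall_low: int

    @property
    def implied_separation(self) -> float:
        """Minimal ΔQTcf separation implied by the two thresholds (ms)."""
        return self.high_threshold - self.low_threshold


def select_extremes(
    phenotypes: pd.DataFrame,
    high_threshold: float = 35.0,
    low_threshold: float = 5.0,
    n_per_arm: int = 10,
) -> SelectionResult:
    """Label extreme responders: ΔQTcf strictly above/below the thresholds.

    The high arm takes the largest ΔQTcf values strictly above
    ``high_threshold`` (at most ``n_per_arm``); the low arm the smallest values
    strictly below ``low_threshold``.  Exact-threshold ties belong to neither
    arm.  If fewer subjects are eligible than requested, all eligible are
    labelled and the shortfall reported.
    """
    if high_threshold <= low_threshold:
        raise ValueError("high_threshold must exceed low_threshold")
    out = phenotypes.copy()
    delta = out["delta_qtcf"]
    high_pool = out.index[delta > high_threshold]
    low_pool = out.index[delta < low_threshold]
    high_idx = delta.loc[high_pool].sort_values(ascending=False).index[:n_per_arm]
    low_idx = delta.loc[low_pool].sort_values(ascending=True).index[:n_per_arm]
    out["sensitivity"] = "unselected"
    out.loc[high_idx, "sensitivity"] = "high"
    out.loc[low_idx, "sensitivity"] = "low"
    return SelectionResult(
        phenotypes=out,
        high_threshold=high_threshold,
        low_threshold=low_threshold,
        n_high=len(high_idx),
        n_low=len(low_idx),
        shortfall_high=max(0, n_per_arm - len(high_idx)),
        shortfall_low=max(0, n_per_arm - len(low_idx)),
    )


@dataclass(frozen=True)
class PowerResult:
    mc_power: float
    analytic_power: float
    n_sim: int
    mc_se: float


def power_two_sample(
    diff: float,
    sd: float,
    alpha: float = 0.05,
    n_per_group: int = 10,
    n_sim: int = 50_000,
    seed: int = 0,
) -> PowerResult:
    """Power of the two-sided two-sample t-test, Monte-Carlo plus closed form.

    The closed form uses the noncentral t distribution with noncentrality
    δ = diff / (sd·√(2/n)) and df = 2n − 2.  ``sd`` is interpreted as the
    common within-group standard deviation.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    df = 2 * n_per_group - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ncp = diff / (sd * np.sqrt(2.0 / n_per_group))
    analytic = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)

    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_sim, n_per_group))
    b = rng.normal(diff, sd, size=(n_sim, n_per_group))
    t, p = stats.ttest_ind(b, a, axis=1)
    mc = float(np.mean(p < alpha))
    se = float(np.sqrt(mc * (1 - mc) / n_sim))
    return PowerResult(mc_power=mc, analytic_power=float(analytic), n_sim=n_sim, mc_se=se)


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "sensitivity",
    exact_max_n: int = 12,
) -> pd.DataFrame:
    """Per-variable two-group comparison.

    Continuous columns are compared with the Mann-Whitney U test (exact
    enumeration when the combined sample size is ≤ ``exact_max_n``, normal
    approximation above); binary columns with Fisher's exact test.  Returns
    one row per variable with the statistic and two-sided p.
    """
    groups = [g for g in table[group_col].unique()]
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    for col in table.columns:
        if col == group_col:
            continue
        a = ga[col].dropna()
        b = gb[col].dropna()
        vals = pd.concat([a, b]).unique()
        if set(vals) <= {0, 1, False, True}:
            tab = [
                [int((a == 1).sum()), int((a != 1).sum())],
                [int((b == 1).sum()), int((b != 1).sum())],
            ]
            stat, p = stats.fisher_exact(tab, alternative="two-sided")
            test = "fisher"
        else:
            method = "exact" if len(a) + len(b) <= exact_max_n else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
            test = f"mannwhitney_{method}"
        rows.append({"variable": col, "test": test, "statistic": stat, "p": p})
    return pd.DataFrame(rows)
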