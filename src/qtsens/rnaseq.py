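"""Depth-equalised differential expression and the netto-count confound check.

Libraries are first equalised to the smallest total by uniform read removal
(multivariate hypergeometric downsampling), so that detection sensitivity is
comparable across samples.  Expression is summarised as FPKM; differential
genes between the high- and low-sensitivity groups are called with a Welch t
test on log2(FPKM+1), Benjamini-Hochberg FDR control at 5% and a minimum fold
change |log2((FPKM_A+1)/(FPKM_B+1))| ≥ log2(1.3).

Because the two sensitivity arms are gender-imbalanced, a gender-confound
statistic is computed: same-gender (high, low) pairs are formed, every
female-pair × male-pair combination is tested female-vs-male, and each gene's
netto count = (up detections − down detections) / number of combinations.  A
gene whose group fold change is driven by gender shows a netto count of the
same sign (gender-consistent quadrant); a genuine group effect does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "equalize_depth",
    "fpkm",
    "deg_test",
    "build_same_gender_pairs",
    "netto_counts",
    "gender_quadrant",
    "DEFAULT_FDR",
    "DEFAULT_FOLD",
]

DEFAULT_FDR = 0.05
DEFAULT_FOLD = 1.3
NETTO_ZERO_BAND = 0.1


@dataclass
class ExpressionMatrix:
    """Gene × sample counts with sample metadata and gene lengths.

    ``counts``: DataFrame, genes × samples, non-negative integers.
    ``meta``: DataFrame indexed by sample id with ``group`` (high/low) and
    ``gender`` (M/F) columns.  ``lengths``: Series of gene lengths in bp.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.lengths = pd.Series(self.lengths).loc[self.counts.index]
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    def fpkm(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return fpkm(self.counts, self.lengths, totals)


def equalize_depth(counts: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Downsample every library to the smallest column total.

    Reads are removed uniformly without replacement, i.e. each retained
    library is a multivariate-hypergeometric draw over its genes with the
    minimum total as sample size.  Deterministic under ``seed``.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total libraries: {bad}")
    target = int(totals.min())
    rng = np.random.default_rng(seed)
    out = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=np.int64)
        if col.sum() == target:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, target, method="marginals")
    return pd.DataFrame(out, index=counts.index)


def fpkm(counts, gene_length, library_total):
    """FPKM = counts × 10⁹ / (gene length [bp] × library total)."""
    counts = np.asarray(counts, dtype=float) if not isinstance(counts, pd.DataFrame) else counts
    if isinstance(counts, pd.DataFrame):
        lengths = pd.Series(gene_length).loc[counts.index]
        totals = pd.Series(library_total).loc[counts.columns]
        if (lengths <= 0).any() or (totals <= 0).any():
            raise ValueError("gene lengths and library totals must be positive")
        return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    gene_length = np.asarray(gene_length, dtype=float)
    library_total = np.asarray(library_total, dtype=float)
    if np.any(gene_length <= 0) or np.any(library_total <= 0):
        raise ValueError("gene lengths and library totals must be positive")
    return counts * 1e9 / (gene_length * library_total)


def _welch_t(log_a: np.ndarray, log_b: np.ndarray, var_floor: float | None,
             normal_ref: bool = False):
    """Vectorised per-gene Welch t on pre-logged expression (genes × samples).

    With ``normal_ref`` the statistic is referred to a standard normal rather
    than the Welch t distribution.  This is the moderated small-n mode: when
    the variance floor is pooled across thousands of genes it is treated as
    known, so the df-starved t reference (df ≈ 2 at n = 2 per side) is
    replaced by z.
    """
    na, nb = log_a.shape[1], log_b.shape[1]
    ma, mb = log_a.mean(axis=1), log_b.mean(axis=1)
    va = log_a.var(axis=1, ddof=1)
    vb = log_b.var(axis=1, ddof=1)
    if var_floor is not None:
        va = np.maximum(va, var_floor)
        vb = np.maximum(vb, var_floor)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        if normal_ref:
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = 2 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1))
    p = np.where(se2 > 0, p, 1.0)
    p = np.where(np.isfinite(p), p, 1.0)
    return t, p


def deg_test(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    fdr: float = DEFAULT_FDR,
    min_fold: float = DEFAULT_FOLD,
    var_floor: float | None = None,
) -> pd.DataFrame:
    """Differential expression of group A vs group B.

    Per gene: Welch t on log2(FPKM+1); BH adjustment across genes; fold change
    lfc = log2((mean FPKM_A + 1) / (mean FPKM_B + 1)).  A gene is differential
    when q ≤ ``fdr`` and |lfc| ≥ log2(``min_fold``).  ``var_floor`` clips
    per-group gene variances from below (used for 2-vs-2 comparisons where a
    sample variance can degenerate to 0); pass ``"auto"`` to use the pooled
    10th-percentile gene variance.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    unknown = (set(group_a) | set(group_b)) - set(matrix.counts.columns)
    if unknown:
        raise ValueError(f"unknown samples: {sorted(unknown)}")
    fp = matrix.fpkm()
    log_all = np.log2(fp.to_numpy() + 1.0)
    cols = {s: i for i, s in enumerate(fp.columns)}
    log_a = log_all[:, [cols[s] for s in group_a]]
    log_b = log_all[:, [cols[s] for s in group_b]]

    if var_floor == "auto":
        pooled = np.concatenate([log_a, log_b], axis=1).var(axis=1, ddof=1)
        var_floor = float(np.quantile(pooled, 0.10))
    if min(len(group_a), len(group_b)) < 2:
        # fold-change-only mode: no variance estimate is possible
        t = np.full(fp.shape[0], np.nan)
        p = np.ones(fp.shape[0])
        q = np.ones(fp.shape[0])
        fold_only = True
    else:
        # pooled floor + z reference for df-starved designs (n = 2 per side)
        normal_ref = var_floor is not None and min(len(group_a), len(group_b)) < 3
        t, p = _welch_t(log_a, log_b, var_floor, normal_ref=normal_ref)
        q = multipletests(p, method="fdr_bh")[1]
        fold_only = False

    mean_a = fp[group_a].mean(axis=1)
    mean_b = fp[group_b].mean(axis=1)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    thresh = np.log2(min_fold)
    if fold_only:
        is_de = np.abs(lfc) >= thresh
    else:
        is_de = (q <= fdr) & (np.abs(lfc).to_numpy() >= thresh)
    out = pd.DataFrame(
        {
            "gene": fp.index,
            "lfc": lfc.to_numpy(),
            "t": t,
            "p": p,
            "q": q,
            "is_de": np.asarray(is_de, dtype=bool),
        }
    ).set_index("gene")
    out.attrs["fold_only"] = fold_only
    out.attrs["var_floor"] = var_floor
    return out


def build_same_gender_pairs(meta: pd.DataFrame):
    """All (high, low) sample pairs within each gender.

    Returns ``(female_pairs, male_pairs)`` as lists of ``(high_id, low_id)``
    tuples, ordered deterministically.  ``meta`` is indexed by sample id with
    ``group`` and ``gender`` columns.
    """
    pairs = {"F": [], "M": []}
    for gender in ("F", "M"):
        sub = meta[meta["gender"] == gender]
        highs = sorted(sub.index[sub["group"] == "high"])
        lows = sorted(sub.index[sub["group"] == "low"])
        pairs[gender] = [(h, l) for h in highs for l in lows]
    return pairs["F"], pairs["M"]


def netto_counts(
    matrix: ExpressionMatrix,
    female_pairs,
    male_pairs,
    fdr: float = DEFAULT_FDR,
    min_fold: float = DEFAULT_FOLD,
    var_floor="auto",
) -> pd.DataFrame:
    """Gender-confound statistic over all female-pair × male-pair combinations.

    For every combination, the 2-sample female group (one high-S + one low-S
    female) is tested against the 2-sample male group with :func:`deg_test`
    ("up" = higher in the female group).  Per gene,
    netto = (up detections − down detections) / n_combinations ∈ [−1, 1].
    """
    female_pairs, male_pairs = list(female_pairs), list(male_pairs)
    if not female_pairs or not male_pairs:
        raise ValueError("need at least one female and one male pair")
    known = set(matrix.counts.columns)
    for h, l in female_pairs + male_pairs:
        if h not in known or l not in known:
            raise ValueError(f"pair ({h}, {l}) references unknown sample")
    up = np.zeros(matrix.counts.shape[0], dtype=int)
    down = np.zeros_like(up)
    n_comb = 0
    for fh, fl in female_pairs:
        for mh, ml in male_pairs:
            res = deg_test(
                matrix, [fh, fl], [mh, ml], fdr=fdr, min_fold=min_fold, var_floor=var_floor
            )
            de = res["is_de"].to_numpy()
            lfc = res["lfc"].to_numpy()
            up += de & (lfc > 0)
            down += de & (lfc < 0)
            n_comb += 1
    return pd.DataFrame(
        {
            "gene": matrix.counts.index,
            "up_count": up,
            "down_count": down,
            "netto": (up - down) / n_comb,
        }
    ).set_index("gene").assign(n_comparisons=n_comb)


def gender_quadrant(
    lfc: pd.Series,
    netto: pd.Series,
    zero_band: float = NETTO_ZERO_BAND,
) -> pd.Series:
    """Quadrant reading of group fold change vs netto count.

    Same nonzero sign of group lfc and netto ⇒ ``gender-consistent`` (the
    group difference is suspected to be a gender effect); opposite signs or
    |netto| < ``zero_band`` ⇒ ``gender-independent``.
    """
    genes = lfc.index.intersection(netto.index)
    lfc = lfc.loc[genes]
    netto = netto.loc[genes]
    consistent = (np.sign(lfc) == np.sign(netto)) & (netto.abs() >= zero_band) & (lfc != 0)
    return pd.Series(
        np.where(consistent, "gender-consistent", "gender-independent"),
        index=genes,
        name="quadrant",
    )
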