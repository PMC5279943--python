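"""Minor-allele-frequency imbalance screening over the LQTS gene panel.

Diploid minor-allele dosages ({0,1,2}, missing allowed) per subject per SNP
are summarised as per-group minor-allele frequencies and compared between the
two sensitivity arms with Fisher's exact test on the 2×2 allele-count table.
No multiplicity correction is applied; the screen is an exploratory ranking
of candidate predisposing variants, not a confirmatory test.

Genomic intervals use the 0-based half-open convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GenotypeMatrix", "maf", "allelic_fisher", "imbalance_screen", "restrict_to_genes"]


@dataclass
class GenotypeMatrix:
    """Subject × SNP dosage matrix with SNP annotations and group labels.

    ``dosage``: DataFrame, subjects as rows, SNP ids as columns, values in
    {0, 1, 2} or NaN (missing).  ``snp_info``: DataFrame indexed by SNP id
    with at least a ``gene`` column (``chrom``/``pos`` needed for interval
    restriction).  ``groups``: Series mapping subject id → group label.
    """

    dosage: pd.DataFrame
    snp_info: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        self.groups = pd.Series(self.groups).loc[self.dosage.index]

    def subset(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = [s for s in snp_ids]
        return GenotypeMatrix(
            dosage=self.dosage[snp_ids],
            snp_info=self.snp_info.loc[snp_ids],
            groups=self.groups,
        )


def maf(dosages) -> float:
    """Minor-allele frequency: Σ dosage / (2 × non-missing subjects)."""
    d = np.asarray(pd.Series(dosages).dropna(), dtype=float)
    if d.size == 0:
        raise ValueError("no non-missing genotypes")
    return float(d.sum() / (2 * d.size))


def _allele_counts(dosages) -> tuple[int, int]:
    d = np.asarray(pd.Series(dosages).dropna(), dtype=float)
    if d.size == 0:
        raise ValueError("no non-missing genotypes in group")
    minor = int(d.sum())
    return minor, 2 * d.size - minor


def allelic_fisher(dosages_a, dosages_b) -> float:
    """Two-sided Fisher exact p on the 2×2 minor/major allele-count table."""
    a_min, a_maj = _allele_counts(dosages_a)
    b_min, b_maj = _allele_counts(dosages_b)
    _, p = stats.fisher_exact([[a_min, a_maj], [b_min, b_maj]], alternative="two-sided")
    return float(p)


def imbalance_screen(matrix: GenotypeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP MAF by group and allelic Fisher test; flag p < alpha.

    Returns one row per SNP (snp_id, gene, maf_low, maf_high, p, significant).
    No multiple-testing correction is applied.
    """
    labels = sorted(matrix.groups.unique())
    if set(labels) != {"high", "low"}:
        raise ValueError(f"expected groups {{'high', 'low'}}, got {labels}")
    low_ids = matrix.groups.index[matrix.groups == "low"]
    high_ids = matrix.groups.index[matrix.groups == "high"]
    if len(low_ids) < 2 or len(high_ids) < 2:
        raise ValueError("need >=2 subjects per group")
    rows = []
    for snp in matrix.dosage.columns:
        d_low = matrix.dosage.loc[low_ids, snp]
        d_high = matrix.dosage.loc[high_ids, snp]
        p = allelic_fisher(d_low, d_high)
        rows.append(
            {
                "snp_id": snp,
                "gene": matrix.snp_info.loc[snp, "gene"] if "gene" in matrix.snp_info else "",
                "maf_low": maf(d_low),
                "maf_high": maf(d_high),
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def restrict_to_genes(matrix: GenotypeMatrix, intervals: pd.DataFrame) -> GenotypeMatrix:
    """Keep SNPs falling in any of the gene intervals (0-based half-open).

    ``intervals`` needs columns ``chrom, start, end, gene``; ``snp_info``
    needs ``chrom`` and ``pos``.  A SNP at ``start`` is retained, one at
    ``end`` is not.  Retained SNPs get their ``gene`` annotation (first
    matching interval wins).
    """
    for col in ("chrom", "pos"):
        if col not in matrix.snp_info.columns:
            raise ValueError(f"snp_info needs a {col!r} column for interval restriction")
    keep = []
    gene_of = {}
    for snp, row in matrix.snp_info.iterrows():
        hits = intervals[
            (intervals["chrom"] == row["chrom"])
            & (intervals["start"] <= row["pos"])
            & (row["pos"] < intervals["end"])
        ]
        if len(hits):
            keep.append(snp)
            gene_of[snp] = hits.iloc[0]["gene"]
    sub = matrix.subset(keep)
    sub.snp_info = sub.snp_info.assign(gene=[gene_of[s] for s in keep])
    return sub
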