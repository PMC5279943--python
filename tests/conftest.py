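import numpy as np
import pandas as pd
import pytest

import qtsens as q


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Default-calibrated synthetic cohort: records, truth, phenotypes."""
    records, truth = q.simulate_cohort(q.CohortSpec(seed=11))
    phen = q.phenotype_cohort(records)
    return records, truth, phen


@pytest.fixture(scope="session")
def mea_panel():
    """14-line default MEA panel with per-line dose responses."""
    series, truth = q.simulate_mea(q.MeaSpec(seed=7))
    by_line = {}
    for s in series:
        by_line.setdefault(s.line_id, []).append(s)
    responses = {}
    corrections = {}
    for lid, ss in by_line.items():
        corr = q.fit_rate_correction([s for s in ss if s.concentration == 0])
        corrections[lid] = corr
        responses[lid] = q.dose_response(ss, corr)
    return series, truth, corrections, responses


@pytest.fixture(scope="session")
def small_expression():
    """1000-gene default-panel expression matrix, depth-equalised."""
    em, truth = q.simulate_expression(q.ExpressionSpec(n_genes=1000, seed=13))
    em = q.ExpressionMatrix(
        counts=q.equalize_depth(em.counts, seed=13), meta=em.meta, lengths=em.lengths
    )
    return em, truth
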