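import numpy as np
import pytest
from scipy import stats

from rubrwatch import CategorySpec, TrialDesign


@pytest.fixture
def adore_design() -> TrialDesign:
    """Design shaped like a large two-category trial: n=1355, T=48, P=0.3."""
    return TrialDesign(
        n_target=1355,
        horizon_T=48.0,
        confidence_P=0.3,
        categories=(CategorySpec("NW", 0.45), CategorySpec("H", 0.15)),
        rubr_target=0.6,
    )


@pytest.fixture
def flat_design() -> TrialDesign:
    """Flat-prior design (P = 0), two categories."""
    return TrialDesign(
        n_target=200,
        horizon_T=20.0,
        confidence_P=0.0,
        categories=(CategorySpec("NW", 0.5), CategorySpec("H", 0.5)),
    )


def chisquare_gof_pvalue(draws: np.ndarray, pmf_dist, min_expected: float = 5.0) -> float:
    """Goodness-of-fit p-value of integer draws against a discrete scipy
    distribution, with sparse tail cells pooled."""
    draws = np.asarray(draws)
    s = draws.size
    hi = int(draws.max())
    support = np.arange(hi + 1)
    probs = pmf_dist.pmf(support)
    tail = 1.0 - probs.sum()
    observed = np.bincount(draws, minlength=hi + 1).astype(float)
    f_obs = np.append(observed, 0.0)
    f_exp = np.append(probs, max(tail, 0.0)) * s
    # pool cells with small expectation into their neighbor
    keep_obs, keep_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(f_obs, f_exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            keep_obs.append(acc_o)
            keep_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and keep_exp:
        keep_obs[-1] += acc_o
        keep_exp[-1] += acc_e
    f_obs = np.array(keep_obs)
    f_exp = np.array(keep_exp) * (f_obs.sum() / np.sum(keep_exp))
    return float(stats.chisquare(f_obs, f_exp).pvalue)


def two_sample_pvalue(a: np.ndarray, b: np.ndarray, min_expected: float = 5.0) -> float:
    """Homogeneity chi-square p-value for two integer samples."""
    hi = int(max(a.max(), b.max()))
    ca = np.bincount(a, minlength=hi + 1).astype(float)
    cb = np.bincount(b, minlength=hi + 1).astype(float)
    # pool cells so every expected count is adequate
    rows_a, rows_b = [], []
    acc_a = acc_b = 0.0
    for x, y in zip(ca, cb):
        acc_a += x
        acc_b += y
        if acc_a + acc_b >= 2 * min_expected:
            rows_a.append(acc_a)
            rows_b.append(acc_b)
            acc_a = acc_b = 0.0
    if (acc_a + acc_b) > 0 and rows_a:
        rows_a[-1] += acc_a
        rows_b[-1] += acc_b
    table = np.array([rows_a, rows_b])
    table = table[:, table.sum(axis=0) > 0]
    return float(stats.chi2_contingency(table).pvalue)
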