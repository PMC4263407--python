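"""Statistical primitives: per-region means, the named tests, BH correction
and the passive (replication-dependent) demethylation model.

Conventions: methylation levels are percentages in [0, 100]; an undefined
mean is NaN, not an exception.  All p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import logger


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# means
# ---------------------------------------------------------------------------

def region_mean_level(meth, total, weighted: bool = False) -> float:
    """Mean methylation (%) of a set of CpGs.

    Default is the unweighted mean of per-CpG levels (each CpG's
    meth/total averaged across CpGs); ``weighted=True`` pools reads
    instead.  Returns NaN when no CpG has coverage.
    """
    meth = np.asarray(meth, float)
    total = np.asarray(total, float)
    ok = total > 0
    if not ok.any():
        return float("nan")
    if weighted:
        return 100.0 * meth[ok].sum() / total[ok].sum()
    return 100.0 * float(np.mean(meth[ok] / total[ok]))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def student_t_test(levels_a, levels_b, mode: str = "unpaired") -> TestResult:
    """Two-sided Student's t-test on per-CpG level vectors.

    ``mode='unpaired'`` is the classical equal-variance two-sample test;
    ``mode='paired'`` tests the per-CpG differences (vectors must already
    be restricted to CpGs covered in both samples).  Windows where both
    groups are constant but the means differ get p = 0 (the limit of the t
    statistic), with a logged flag; fewer than 2 values per group (or <2
    pairs) yields an undefined (NaN) result.
    """
    a = np.asarray(levels_a, float)
    b = np.asarray(levels_b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired mode requires equal-length vectors")
        if len(a) < 2:
            return TestResult(float("nan"), float("nan"), "t_paired", len(a), len(b))
        d = a - b
        if np.ptp(d) == 0.0:
            if d[0] == 0.0:
                return TestResult(0.0, 1.0, "t_paired", len(a), len(b))
            logger.debug("paired t-test: constant nonzero differences, p set to 0")
            return TestResult(math.inf if d[0] > 0 else -math.inf, 0.0,
                              "t_paired", len(a), len(b))
        t, p = sps.ttest_rel(a, b)
        return TestResult(float(t), float(p), "t_paired", len(a), len(b))
    if mode != "unpaired":
        raise ValueError(f"unknown t-test mode {mode!r}")
    if len(a) < 2 or len(b) < 2:
        return TestResult(float("nan"), float("nan"), "t_unpaired", len(a), len(b))
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return TestResult(0.0, 1.0, "t_unpaired", len(a), len(b))
        logger.debug("t-test: both groups constant with unequal means, p set to 0")
        return TestResult(math.inf if a[0] > b[0] else -math.inf, 0.0,
                          "t_unpaired", len(a), len(b))
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(p), "t_unpaired", len(a), len(b))


def t_test_from_summary(mean_a, var_a, n_a, mean_b, var_b, n_b):
    """Vectorized equal-variance two-sample t-test from summary statistics.

    ``var`` is the unbiased (ddof=1) sample variance.  Returns (t, p)
    arrays; entries with n < 2 in either group are NaN, and zero pooled
    variance with unequal means yields p = 0.
    """
    mean_a, var_a, mean_b, var_b = map(lambda x: np.asarray(x, float),
                                       (mean_a, var_a, mean_b, var_b))
    n_a = np.asarray(n_a, float)
    n_b = np.asarray(n_b, float)
    df = n_a + n_b - 2
    valid = (n_a >= 2) & (n_b >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        t = (mean_a - mean_b) / se
    p = np.full(t.shape, np.nan)
    ok = valid & (se > 0)
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])
    degen = valid & (se == 0)
    same = degen & (mean_a == mean_b)
    diff = degen & ~same
    t[same], p[same] = 0.0, 1.0
    t[diff] = np.where(mean_a[diff] > mean_b[diff], np.inf, -np.inf)
    p[diff] = 0.0
    t[~valid] = np.nan
    return t, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   correction: str = "none") -> TestResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]] with 1 df.

    Default is the uncorrected statistic; ``correction='yates'`` applies
    the continuity correction.  A zero marginal total is an error.
    """
    table = np.array([[a, b], [c, d]], float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    if correction not in {"none", "yates"}:
        raise ValueError(f"unknown correction {correction!r}")
    stat, p, _, _ = sps.chi2_contingency(table, correction=(correction == "yates"))
    return TestResult(float(stat), float(p), f"chi2_{correction}",
                      int(a + b), int(c + d))


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration for small samples without ties (both n <= 20)
    and the tie-corrected normal approximation otherwise.  Fully tied data
    (zero rank variance) gives p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty vector")
    n1, n2 = len(x), len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    if max(n1, n2) <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "mwu_exact", n1, n2)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult(float(u1), 1.0, "mwu_normal", n1, n2)
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(float(u1), float(p), "mwu_normal", n1, n2)


def pearson_r(x, y) -> float:
    """Pearson correlation with listwise deletion of undefined pairs.

    Returns NaN for n < 3 or zero variance in either vector.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# passive demethylation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemethylationModel:
    """Replication-dependent dilution of the maternally contributed
    methylation after fertilization.

    ``m_maternal``/``m_paternal`` are allele methylation fractions in
    [0, 1]; ``rounds`` is the number of replication-dependent global
    demethylation events (each halves the maternal contribution; the
    paternal contribution is held at its input value unless
    ``codilute_paternal`` is set).
    """

    m_maternal: float
    m_paternal: float
    rounds: int = 1
    codilute_paternal: bool = False

    def __post_init__(self):
        if not (0.0 <= self.m_maternal <= 1.0 and 0.0 <= self.m_paternal <= 1.0):
            raise ValueError("allele methylation fractions must be in [0, 1]")
        if self.rounds < 0:
            raise ValueError("rounds must be non-negative")


def passive_demethylation_expectation(model: DemethylationModel) -> float:
    """Expected zygotic methylation (%) under passive dilution.

    The zygote averages the two alleles; each replication-dependent
    demethylation event halves the diluted contribution(s).  A fully
    maternally methylated, paternally unmethylated region after one event
    evaluates to exactly 25%.
    """
    dilution = 0.5 ** model.rounds
    maternal = model.m_maternal * dilution
    paternal = model.m_paternal * (dilution if model.codilute_paternal else 1.0)
    return 100.0 * (maternal + paternal) / 2.0
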