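"""Statistical comparison of model fits across subjects.

Fisher z-transformation of R-values (r = sqrt(R^2)), two-sided paired
t-tests, and one-way within-subject (repeated-measures) ANOVA with
Bonferroni-corrected post-hoc paired t-tests. No sphericity correction is
applied. Alpha is 0.05 throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTestError, IncompleteDesignError

ALPHA = 0.05


@dataclass
class ComparisonResult:
    test: str  # paired_t | rm_anova
    statistic: float
    p: float
    transformed: bool  # Fisher z applied
    correction: str = "none"  # none | bonferroni
    contrast: tuple = ()
    df: object = None
    posthoc: dict = field(default_factory=dict)  # (i, j) -> corrected p

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def fisher_z(r: float) -> float:
    """z = atanh(r); domain |r| < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return math.atanh(r)


def _to_z(values) -> np.ndarray:
    """R^2 values -> Fisher z of r = sqrt(R^2). Negative R^2 is untransformable."""
    values = np.asarray(values, dtype=float)
    return np.array([fisher_z(math.sqrt(v)) for v in values])


def _drop_negative_pairs(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = (a >= 0) & (b >= 0)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} pair(s) with negative R^2 "
            "(Fisher z undefined)", stacklevel=3,
        )
    return a[keep], b[keep]


def paired_model_test(per_subject_a, per_subject_b, on_r: bool = False) -> ComparisonResult:
    """Two-sided paired t-test of per-subject fit statistics.

    With ``on_r`` both vectors are taken as uncentered R^2 values and Fisher
    z-transformed (r = sqrt(R^2)) first; pairs where either value is negative
    are dropped with a warning. RMSE comparisons use ``on_r=False``.
    """
    a = np.asarray(per_subject_a, dtype=float)
    b = np.asarray(per_subject_b, dtype=float)
    if a.shape != b.shape:
        raise IncompleteDesignError("paired vectors must have equal length")
    if on_r:
        a, b = _drop_negative_pairs(a, b)
        if len(a) < 3:
            raise DegenerateTestError(
                f"only {len(a)} transformable pairs remain (need >= 3)"
            )
        a, b = _to_z(a), _to_z(b)
    if len(a) < 3:
        raise DegenerateTestError(f"need >= 3 pairs, got {len(a)}")
    d = a - b
    if np.allclose(d, d[0]) and np.std(d, ddof=1) == 0:
        if d[0] == 0:
            return ComparisonResult(test="paired_t", statistic=0.0, p=1.0,
                                    transformed=on_r, df=len(d) - 1)
        raise DegenerateTestError("zero variance of non-zero differences")
    t, p = sps.ttest_rel(a, b)
    return ComparisonResult(test="paired_t", statistic=float(t), p=float(p),
                            transformed=on_r, df=len(d) - 1)


def rm_anova_bonferroni(per_subject_by_condition, on_r: bool = False,
                        conditions=None) -> ComparisonResult:
    """One-way within-subject ANOVA with Bonferroni post-hoc paired t-tests.

    ``per_subject_by_condition`` is a complete (n_subjects x n_conditions)
    matrix. F is computed from the within-subject sums-of-squares
    decomposition; post-hoc pairwise paired t-tests have their p-values
    multiplied by the number of comparisons (capped at 1).
    """
    M = np.asarray(per_subject_by_condition, dtype=float)
    if M.ndim != 2:
        raise IncompleteDesignError("matrix must be subjects x conditions")
    n, k = M.shape
    if n < 3 or k < 2:
        raise IncompleteDesignError(f"need >= 3 subjects and >= 2 conditions, got {n}x{k}")
    if not np.isfinite(M).all():
        raise IncompleteDesignError("missing cells in the repeated-measures design")
    if on_r:
        if (M < 0).any():
            bad = int((M < 0).any(axis=1).sum())
            warnings.warn(
                f"dropping {bad} subject(s) with negative R^2 (Fisher z undefined)",
                stacklevel=2,
            )
            M = M[(M >= 0).all(axis=1)]
            n = M.shape[0]
            if n < 3:
                raise DegenerateTestError(
                    f"only {n} transformable subjects remain (need >= 3)"
                )
        M = np.arctanh(np.sqrt(M))

    grand = M.mean()
    cond_means = M.mean(axis=0)
    subj_means = M.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    resid = M - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = float(np.sum(resid ** 2))
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    if ss_err == 0:
        if ss_cond == 0:
            return ComparisonResult(test="rm_anova", statistic=0.0, p=1.0,
                                    transformed=on_r, correction="bonferroni",
                                    df=(df_cond, df_err),
                                    contrast=tuple(conditions or range(k)))
        raise DegenerateTestError("zero error sum of squares with non-zero effect")
    F = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_cond, df_err))
    if ss_cond == 0:
        p = 1.0

    labels = list(conditions) if conditions is not None else list(range(k))
    n_comp = k * (k - 1) // 2
    posthoc = {}
    for i in range(k):
        for j in range(i + 1, k):
            d = M[:, i] - M[:, j]
            if np.std(d, ddof=1) == 0:
                p_ij = 1.0 if np.allclose(d, 0) else 0.0
            else:
                _, p_ij = sps.ttest_rel(M[:, i], M[:, j])
            posthoc[(labels[i], labels[j])] = min(1.0, float(p_ij) * n_comp)
    return ComparisonResult(test="rm_anova", statistic=float(F), p=p,
                            transformed=on_r, correction="bonferroni",
                            contrast=tuple(labels), df=(df_cond, df_err),
                            posthoc=posthoc)


def comparison_to_csv(results, path) -> None:
    """Serialize ComparisonResults side-by-side (Table 1/2 style layout)."""
    import pandas as pd

    records = []
    for res in results:
        base = dict(test=res.test, statistic=res.statistic, p=res.p,
                    transformed=res.transformed, correction=res.correction,
                    contrast="|".join(str(c) for c in res.contrast))
        if res.posthoc:
            for (a, b), p in res.posthoc.items():
                rec = dict(base)
                rec.update(pair=f"{a} vs {b}", p_posthoc=p)
                records.append(rec)
        else:
            records.append(base)
    pd.DataFrame.from_records(records).to_csv(path, index=False)
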