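"""Cohort comparison machinery: stratified bootstrap, chi-square, K-S.

A test cohort's feature statistic is compared against a null
distribution built by repeatedly drawing, without replacement, sets
from a control pool of the same size and stratum composition as the
test set (strata typically match consequence class and binned junction
distance). If the null distribution passes a Shapiro-Wilk normality
gate the comparison is reported as a Z score with a normal P-value,
otherwise as an add-one empirical P-value. Significance uses a
stringent default alpha of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BootstrapResult",
    "bootstrap_compare",
    "chi2_yates",
    "ks_compare",
    "significance_gate",
    "junction_distance_bin",
    "DEFAULT_JUNCTION_BINS",
]

_STATISTICS = {"mean", "proportion", "sum"}

# default binned minimum-junction-distance strata (exonic bases)
DEFAULT_JUNCTION_BINS: tuple[int, ...] = (10, 25, 50)


def junction_distance_bin(distance: int, edges: Sequence[int] = DEFAULT_JUNCTION_BINS) -> str:
    """Bin a minimum junction distance for stratified sampling."""
    prev = None
    for edge in edges:
        if distance <= edge:
            lo = 4 if prev is None else prev + 1
            return f"{lo}-{edge}"
        prev = edge
    return f">{edges[-1]}"


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of one stratified bootstrap comparison."""

    observed: float
    null_mean: float
    null_sd: float
    z: float | None
    p_normal: float | None
    p_empirical: float
    p: float  # the reported P: normal when the gate passes, else empirical
    normality_p: float | None
    gate_passed: bool
    iterations: int
    seed: int
    statistic: str
    n_test: int
    strata: dict[Hashable, int]
    alternative: str = "two-sided"

    @property
    def effect(self) -> float:
        """Observed minus null mean, in feature units."""
        return self.observed - self.null_mean


def _stat_reduce(statistic: str, total: np.ndarray, n: int) -> np.ndarray:
    if statistic in ("mean", "proportion"):
        return total / n
    return total


def _dedup_exons(values: np.ndarray, exon_ids: Sequence[Hashable] | None, label: str):
    if exon_ids is None:
        raise ValueError(f"unit='exon' requires {label} exon ids")
    seen: set[Hashable] = set()
    keep = []
    for i, eid in enumerate(exon_ids):
        if eid not in seen:
            seen.add(eid)
            keep.append(i)
    return keep


def bootstrap_compare(
    test_values,
    control_values,
    *,
    test_strata: Sequence[Hashable] | None = None,
    control_strata: Sequence[Hashable] | None = None,
    statistic: str = "mean",
    n_iter: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
    unit: str = "variant",
    test_exon_ids: Sequence[Hashable] | None = None,
    control_exon_ids: Sequence[Hashable] | None = None,
    shapiro_cap: int = 5000,
    normality_alpha: float = 0.05,
) -> BootstrapResult:
    """Compare a test cohort statistic against stratified resamples.

    Parameters
    ----------
    test_values, control_values
        Per-record feature values. The observed statistic is computed
        on the test values; each bootstrap iteration draws, without
        replacement and per stratum, exactly the test set's stratum
        counts from the control pool and computes the same statistic.
    test_strata, control_strata
        Optional per-record stratum labels (e.g. consequence class, or
        a (consequence, junction-distance-bin) tuple). Omitted = one
        stratum.
    statistic
        "mean", "proportion" (mean of 0/1 indicators) or "sum".
    unit
        "variant" uses every record; "exon" first deduplicates both
        cohorts to unique exon ids (first record per exon wins), since
        several variants can share an exon.
    alternative
        Sidedness of the reported P ("two-sided", "greater", "less").

    Notes
    -----
    The normality gate applies a Shapiro-Wilk test to (a capped
    subsample of) the null distribution; when it passes (P > 0.05) the
    Z-based normal P-value is reported, otherwise the add-one empirical
    P-value ``(1 + tail count) / (1 + iterations)``. Identical seed
    and inputs give bit-identical results.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    test = np.asarray(test_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    t_strata = list(test_strata) if test_strata is not None else [0] * len(test)
    c_strata = list(control_strata) if control_strata is not None else [0] * len(control)
    if len(t_strata) != len(test) or len(c_strata) != len(control):
        raise ValueError("strata must align with values")

    if unit == "exon":
        keep_t = _dedup_exons(test, test_exon_ids, "test")
        keep_c = _dedup_exons(control, control_exon_ids, "control")
        test, t_strata = test[keep_t], [t_strata[i] for i in keep_t]
        control, c_strata = control[keep_c], [c_strata[i] for i in keep_c]
    elif unit != "variant":
        raise ValueError(f"unit must be 'variant' or 'exon', got {unit!r}")
    if len(test) == 0:
        raise ValueError("empty test cohort")

    stratum_counts: dict[Hashable, int] = {}
    for s in t_strata:
        stratum_counts[s] = stratum_counts.get(s, 0) + 1
    pools: dict[Hashable, np.ndarray] = {}
    for s, k in stratum_counts.items():
        pool = control[np.fromiter((cs == s for cs in c_strata), bool, len(c_strata))]
        if len(pool) < k:
            raise ValueError(
                f"stratum {s!r}: control pool has {len(pool)} records, test needs {k}"
            )
        pools[s] = pool

    rng = np.random.default_rng(seed)
    totals = np.zeros(n_iter)
    n_test = len(test)
    for s in sorted(stratum_counts, key=repr):  # deterministic stratum order
        k = stratum_counts[s]
        pool = pools[s]
        keys = rng.random((n_iter, len(pool)))
        if k < len(pool):
            idx = np.argpartition(keys, k, axis=1)[:, :k]
        else:
            idx = np.tile(np.arange(len(pool)), (n_iter, 1))
        totals += pool[idx].sum(axis=1)
    null = _stat_reduce(statistic, totals, n_test)
    observed = float(_stat_reduce(statistic, np.array([test.sum()]), n_test)[0])

    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if n_iter > 1 else 0.0

    # empirical tail probabilities with add-one correction
    ge = float((1 + np.count_nonzero(null >= observed)) / (1 + n_iter))
    le = float((1 + np.count_nonzero(null <= observed)) / (1 + n_iter))
    if alternative == "greater":
        p_emp = ge
    elif alternative == "less":
        p_emp = le
    else:
        p_emp = min(1.0, 2.0 * min(ge, le))

    if sd > 0:
        z = (observed - mu) / sd
        if alternative == "greater":
            p_norm = float(stats.norm.sf(z))
        elif alternative == "less":
            p_norm = float(stats.norm.cdf(z))
        else:
            p_norm = float(2.0 * stats.norm.sf(abs(z)))
        sample = null
        if len(sample) > shapiro_cap:
            sample = rng.choice(null, size=shapiro_cap, replace=False)
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                normality_p = float(stats.shapiro(sample).pvalue)
        except ValueError:
            normality_p = None
        gate = normality_p is not None and normality_p > normality_alpha
    else:
        z = None
        p_norm = None
        normality_p = None
        gate = False

    return BootstrapResult(
        observed=observed,
        null_mean=mu,
        null_sd=sd,
        z=z,
        p_normal=p_norm,
        p_empirical=p_emp,
        p=p_norm if gate and p_norm is not None else p_emp,
        normality_p=normality_p,
        gate_passed=gate,
        iterations=n_iter,
        seed=seed,
        statistic=statistic,
        n_test=n_test,
        strata=dict(sorted(stratum_counts.items(), key=lambda kv: repr(kv[0]))),
        alternative=alternative,
    )


def chi2_yates(table) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(stat), float(p)


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (D statistic and P-value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp" if min(len(a), len(b)) > 25 else "auto")
    return float(res.statistic), float(res.pvalue)


def significance_gate(p: float, alpha: float = 0.01) -> bool:
    """Strict significance flag: p < alpha (default stringent 0.01)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    return p < alpha
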