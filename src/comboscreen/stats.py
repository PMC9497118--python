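"""Statistical primitives shared by every screening stage.

Cox proportional-hazards fits (lifelines, Efron tie handling) with per-term
Wald p-values, the Wilcoxon rank-sum test, Fisher's product method with a
missing-term policy, Benjamini–Hochberg FDR, and Kaplan–Meier estimation.

Conventions
-----------
* A p-value of ``None`` (or NaN) marks *unavailable* evidence — a term whose
  model could not be estimated, e.g. a drug with no mutated target gene.
  :func:`fishers_product` handles these via its ``missing`` policy.
* A failed or separated Cox fit is reported with ``converged=False`` and all
  p-values set to 1.0: a failed fit must never promote a candidate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: floor applied to p-values before taking logs in Fisher's product method
P_FLOOR = 1e-300

#: minimum number of events required to attempt a Cox fit
MIN_EVENTS = 2


def _is_missing(p) -> bool:
    return p is None or (isinstance(p, float) and math.isnan(p))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFitResult:
    """Outcome of one Cox PH fit.

    ``p_values`` maps each *retained* term to its two-sided Wald p-value.
    Terms dropped before fitting (zero variance) are listed in
    ``dropped_terms`` and are absent from ``p_values`` — downstream treats
    them as unavailable evidence, not as p = 1.
    """

    term_names: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    converged: bool
    n_events: int
    dropped_terms: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def p_for(self, term: str) -> float | None:
        """p-value for ``term``; None if the term was dropped or never fit."""
        return self.p_values.get(term)


#: binary covariates whose minority class is smaller than this are treated
#: as quasi-constant and dropped before fitting (monotone-likelihood guard)
MIN_MINORITY = 3


def _degenerate_columns(X: pd.DataFrame) -> list[str]:
    """Constant columns, plus binary columns with < MIN_MINORITY in the
    minority class — both carry no estimable information and routinely
    break the partial-likelihood Newton iteration."""
    out = []
    for c in X.columns:
        v = X[c].to_numpy(dtype=float)
        uniq = np.unique(v)
        if uniq.size == 1:
            out.append(c)
        elif uniq.size == 2:
            minority = min((v == uniq[0]).sum(), (v == uniq[1]).sum())
            if minority < MIN_MINORITY:
                out.append(c)
    return out


def _sparsest_binary(X: pd.DataFrame, candidates: list[str]) -> str | None:
    best, best_n = None, None
    for c in candidates:
        v = X[c].to_numpy(dtype=float)
        uniq = np.unique(v)
        if uniq.size == 2:
            minority = int(min((v == uniq[0]).sum(), (v == uniq[1]).sum()))
            if best_n is None or minority < best_n:
                best, best_n = c, minority
    return best


def cox_fit(
    time: Sequence[float],
    event: Sequence[int],
    covariates: pd.DataFrame,
    protected: Sequence[str] = (),
) -> CoxFitResult:
    """Fit a Cox proportional-hazards model and extract per-term Wald p-values.

    Ties are handled by Efron's approximation (the lifelines default).
    Zero-variance and quasi-constant binary covariates are dropped before
    fitting and recorded in ``dropped_terms``. If the Newton iteration still
    fails (monotone likelihood / separation), the sparsest *unprotected*
    binary adjustment covariate is dropped and the fit retried; ``protected``
    names the primary terms that must never be auto-dropped this way.
    Fewer than two events, or failure with nothing left to drop, yield a
    flagged result with ``converged=False`` and p = 1 for every retained
    term (conservative: failed fits never look significant).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = covariates.reset_index(drop=True).astype(float)
    n_events = int(event.sum())

    dropped = _degenerate_columns(X)
    kept = [c for c in X.columns if c not in dropped]
    flags = []
    if dropped:
        flags.append("dropped_degenerate:" + ",".join(dropped))

    def _failed(reason: str) -> CoxFitResult:
        return CoxFitResult(
            term_names=kept,
            coefficients={c: 0.0 for c in kept},
            p_values={c: 1.0 for c in kept},
            converged=False,
            n_events=n_events,
            dropped_terms=dropped,
            flags=flags + [reason],
        )

    if n_events < MIN_EVENTS:
        return _failed("non_estimable:too_few_events")
    if not kept:
        return _failed("non_estimable:no_covariates")

    last_reason = "fit_failed"
    while kept:
        df = X[kept].copy()
        df["_time"] = time
        df["_event"] = event
        cph = CoxPHFitter()
        ok = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                warnings.simplefilter("ignore", category=RuntimeWarning)
                cph.fit(df, duration_col="_time", event_col="_event")
            coefs = cph.params_
            ses = cph.standard_errors_
            ok = (np.all(np.isfinite(coefs)) and np.all(np.isfinite(ses))
                  and not np.any(np.abs(coefs) > 50) and not np.any(ses > 100))
            last_reason = "fit_failed:separation" if not ok else last_reason
        except Exception as exc:  # noqa: BLE001 - any fit failure
            last_reason = f"fit_failed:{type(exc).__name__}"
        if ok:
            pvals = cph.summary["p"]
            p_values = {c: float(min(max(pvals[c], P_FLOOR), 1.0)) for c in kept}
            return CoxFitResult(
                term_names=kept,
                coefficients={c: float(coefs[c]) for c in kept},
                p_values=p_values,
                converged=True,
                n_events=n_events,
                dropped_terms=dropped,
                flags=flags,
            )
        candidate = _sparsest_binary(
            X, [c for c in kept if c not in protected])
        if candidate is None:
            break
        kept.remove(candidate)
        dropped.append(candidate)
        flags.append(f"dropped_on_retry:{candidate}")
    return _failed(last_reason)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(values_group0, values_group1) -> float | None:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null enumeration when both groups have <= 10 observations and there
    are no ties; otherwise the tie-corrected normal approximation with
    continuity correction. Returns None (unavailable) if either group is
    empty or all values are identical.
    """
    x = np.asarray(values_group0, dtype=float)
    y = np.asarray(values_group1, dtype=float)
    if x.size == 0 or y.size == 0:
        return None
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Fisher's product method
# ---------------------------------------------------------------------------

@dataclass
class FpmResult:
    """Fisher's product combination of k independent p-values.

    chi2 = -2 * sum(ln p) over the terms actually used; under the null
    chi2 ~ chi-square with df = 2k. ``terms_missing`` lists the labels of
    unavailable terms handled by the ``missing`` policy.
    """

    chi2: float
    df: int
    p_combined: float
    terms_used: list[tuple[str, float]]
    terms_missing: list[str]
    available: bool = True

    def __post_init__(self):
        if self.available:
            assert self.df == 2 * len(self.terms_used)


def fishers_product(
    labeled_p_values: Iterable[tuple[str, float | None]] | Mapping[str, float | None],
    missing: str = "drop",
) -> FpmResult:
    """Combine labeled p-values by Fisher's product method.

    Parameters
    ----------
    labeled_p_values
        ``(label, p)`` pairs; ``p`` of None/NaN marks unavailable evidence.
    missing
        ``"drop"`` (default): exclude unavailable terms and reduce df by 2
        each — the standard meta-analytic treatment of an unavailable study.
        ``"impute_one"``: include them as p = 1 (contributing 0 to chi2).

    p-values are clamped to [1e-300, 1] before the log.
    """
    if missing not in ("drop", "impute_one"):
        raise ValueError(f"unknown missing policy: {missing!r}")
    if isinstance(labeled_p_values, Mapping):
        items = list(labeled_p_values.items())
    else:
        items = list(labeled_p_values)

    used: list[tuple[str, float]] = []
    missing_labels: list[str] = []
    for label, p in items:
        if _is_missing(p):
            if missing == "impute_one":
                used.append((label, 1.0))
            else:
                missing_labels.append(label)
        else:
            used.append((label, float(min(max(p, P_FLOOR), 1.0))))

    if not used:
        return FpmResult(0.0, 0, float("nan"), [], missing_labels, available=False)

    # fsum: exactly-rounded summation, so the result is permutation-invariant
    chi2 = -2.0 * math.fsum(math.log(p) for _, p in used)
    df = 2 * len(used)
    p_combined = float(min(max(sps.chi2.sf(chi2, df), P_FLOOR), 1.0))
    return FpmResult(chi2, df, p_combined, used, missing_labels)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (same order as input)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def km_estimate(
    time: Sequence[float],
    event: Sequence[int],
    group_labels: Sequence[str],
    groups: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns, per group, a DataFrame with columns ``time`` (event/censor
    times, ascending), ``survival`` (S(t), right-continuous step function)
    and ``n_at_risk``. Survival is 1 before the first event; censoring does
    not drop the curve.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(group_labels, dtype=object)
    present = pd.unique(labels)
    if groups is None:
        groups = sorted(present)
    else:
        unknown = set(present) - set(groups)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")

    out: dict[str, pd.DataFrame] = {}
    for g in groups:
        mask = labels == g
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        tab = kmf.event_table
        df = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "n_at_risk": tab["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        )
        out[g] = df.reset_index(drop=True)
    return out
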