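"""Seed-anchored doublet enumeration and the three combination scores.

Every unordered pair of drugs containing at least one seed therapy is
scored in each cohort with eight evidence terms:

* mutation Cox model — main effects of the two gene-set mutation
  indicators and their interaction (pM1, pM2, pM3), adjusted for age and
  the two treatment flags;
* expression Cox model — main effects of the two gene-set PC1 scores and
  their interaction (pE1, pE2, pE3), same adjustment;
* eQTL — per drug, Wilcoxon rank-sum of its PC1 score split by its own
  mutation indicator (pQ1, pQ2).

Three evidence-combination schemes rank the pairs:

* Method 1: Fisher's product over all sixteen terms from both cohorts.
* Method 2: Fisher's product over the four expression main effects
  (pE1, pE2 in each cohort), with an additional per-cohort filter that
  every one of the four be < alpha.
* Method 3: per cohort, take the single most significant term; if both
  cohorts' minima come from the same Cox model family, substitute that
  family's interaction-term p-value; combine the two by Fisher's product.

Degenerate inputs (a drug with no mutated target gene, a constant
indicator within a subgroup, ...) yield missing terms, which shrink the
chi-square degrees of freedom rather than being imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortBundle, DrugTargetLibrary
from .preprocess import TherapySetSummary, summarize_therapy_set
from .single_screen import ADJUST_COVARIATES
from .stats import FpmResult, cox_fit, fishers_product, wilcoxon_rank_sum

log = logging.getLogger(__name__)

TERM_NAMES = ("pM1", "pM2", "pM3", "pE1", "pE2", "pE3", "pQ1", "pQ2")
#: model family of each term; tie-breaks use this fixed order
TERM_FAMILY = {
    "pM1": "mutation", "pM2": "mutation", "pM3": "mutation",
    "pE1": "expression", "pE2": "expression", "pE3": "expression",
    "pQ1": "eqtl", "pQ2": "eqtl",
}
FAMILY_ORDER = {"mutation": 0, "expression": 1, "eqtl": 2}
FAMILY_INTERACTION = {"mutation": "pM3", "expression": "pE3"}
SUBGROUPS = ("All", "BRAF", "NRAS", "TripleWT")


@dataclass
class DoubletConfig:
    method2_filter_alpha: float = 0.05
    fpm_missing: str = "drop"
    method3_families: str = "all"   # "all" | "cox_only"
    min_subgroup_patients: int = 10


@dataclass
class DoubletPool:
    pairs: list[tuple[str, str]]
    n_seed_seed: int
    n_seed_other: int


@dataclass
class DoubletScore:
    drug1: str
    drug2: str
    subgroup: str
    terms: dict[str, dict[str, float | None]]   # cohort -> term -> p
    method1: FpmResult
    method2: FpmResult
    method2_pass_filter: bool
    method3: FpmResult
    flags: list[str] = field(default_factory=list)


def enumerate_doublets(seeds: list[str], pool: list[str]) -> DoubletPool:
    """All unordered pairs {a, b}, a != b, with at least one seed.

    Seed–seed pairs are included exactly once; pairs are stored in
    lexicographic canonical order (drug1 < drug2).
    """
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("empty seed set")
    missing = seed_set - set(pool)
    if missing:
        raise ValueError(f"seeds not in candidate pool: {sorted(missing)}")
    others = sorted(set(pool) - seed_set)
    pairs = [tuple(sorted(p)) for p in itertools.combinations(sorted(seed_set), 2)]
    n_ss = len(pairs)
    for s in sorted(seed_set):
        for o in others:
            pairs.append(tuple(sorted((s, o))))
    pairs = sorted(set(pairs))
    return DoubletPool(pairs=pairs, n_seed_seed=n_ss,
                       n_seed_other=len(pairs) - n_ss)


# ---------------------------------------------------------------------------
# Per-cohort model fits
# ---------------------------------------------------------------------------

class SummaryCache:
    """Per-(cohort, drug) cache of gene-set summaries to avoid recomputation
    across the thousands of pairs that share a seed."""

    def __init__(self, library: DrugTargetLibrary):
        self.library = library
        self._cache: dict[tuple[str, str], TherapySetSummary] = {}

    def get(self, bundle: CohortBundle, drug: str) -> TherapySetSummary:
        key = (bundle.name, drug)
        if key not in self._cache:
            self._cache[key] = summarize_therapy_set(
                bundle, drug, self.library.targets(drug))
        return self._cache[key]


def _two_drug_cox(
    bundle: CohortBundle,
    v1: pd.Series | None, v2: pd.Series | None,
    names: tuple[str, str, str],
) -> dict[str, float | None]:
    """Cox fit with two primary covariates and their interaction.

    Either primary may be unavailable (None): its main-effect and the
    interaction terms come back missing. Constant columns are dropped by
    the fitter (also yielding missing terms). A failed fit reports p = 1
    for the terms that entered the model.
    """
    n1, n2, n12 = names
    out: dict[str, float | None] = {n1: None, n2: None, n12: None}
    cols = {}
    if v1 is not None:
        cols[n1] = v1.loc[bundle.patients].astype(float).to_numpy()
    if v2 is not None:
        cols[n2] = v2.loc[bundle.patients].astype(float).to_numpy()
    if n1 in cols and n2 in cols:
        cols[n12] = cols[n1] * cols[n2]
    if not cols:
        return out
    X = pd.DataFrame(cols, index=bundle.patients)
    for c in ADJUST_COVARIATES:
        X[c] = bundle.clinical[c].astype(float)
    fit = cox_fit(bundle.clinical["os_time"].to_numpy(),
                  bundle.clinical["os_event"].to_numpy(), X,
                  protected=tuple(cols))
    for term in (n1, n2, n12):
        if term not in cols:
            continue
        if term in fit.dropped_terms:
            out[term] = None
        elif not fit.converged:
            out[term] = 1.0
        else:
            out[term] = fit.p_for(term)
    return out


def fit_doublet_models(
    pair: tuple[str, str],
    bundle: CohortBundle,
    library: DrugTargetLibrary,
    cache: SummaryCache | None = None,
) -> tuple[dict[str, float | None], list[str]]:
    """The eight per-cohort term p-values for one drug pair.

    Returns (terms, flags); a term is None when its model was not
    estimable in this cohort.
    """
    d1, d2 = sorted(pair)
    cache = cache or SummaryCache(library)
    s1 = cache.get(bundle, d1)
    s2 = cache.get(bundle, d2)
    flags: list[str] = []

    x1 = s1.mut.values if s1.mut.usable else None
    x2 = s2.mut.values if s2.mut.usable else None
    e1 = s1.pc1.scores if s1.pc1.available else None
    e2 = s2.pc1.scores if s2.pc1.available else None

    terms: dict[str, float | None] = {t: None for t in TERM_NAMES}
    terms.update(_two_drug_cox(bundle, x1, x2, ("pM1", "pM2", "pM3")))
    terms.update(_two_drug_cox(bundle, e1, e2, ("pE1", "pE2", "pE3")))
    for x, e, key in ((x1, e1, "pQ1"), (x2, e2, "pQ2")):
        if x is not None and e is not None:
            terms[key] = wilcoxon_rank_sum(e[x == 0], e[x == 1])

    t1, t2 = library.targets(d1), library.targets(d2)
    overlap = len(t1 & t2) / min(len(t1), len(t2))
    if overlap > 0:
        flags.append(f"target_overlap:{overlap:.2f}")
    if all(v is None for v in terms.values()):
        flags.append("cohort_unobservable")
    return terms, flags


# ---------------------------------------------------------------------------
# Combination methods
# ---------------------------------------------------------------------------

def _labeled(terms: dict[str, dict[str, float | None]],
             names: tuple[str, ...] = TERM_NAMES) -> list[tuple[str, float | None]]:
    return [(f"{t}{c}", terms[c][t]) for c in ("t", "m") for t in names]


def combine_method1(terms: dict[str, dict[str, float | None]],
                    config: DoubletConfig | None = None) -> FpmResult:
    """Fisher's product over all sixteen terms from both cohorts."""
    config = config or DoubletConfig()
    return fishers_product(_labeled(terms), missing=config.fpm_missing)


def combine_method2(
    terms: dict[str, dict[str, float | None]],
    config: DoubletConfig | None = None,
) -> tuple[FpmResult, bool]:
    """Fisher's product over the four expression main effects, plus the
    per-cohort filter: pass iff all four are available and each < alpha."""
    config = config or DoubletConfig()
    labeled = _labeled(terms, ("pE1", "pE2"))
    fpm = fishers_product(labeled, missing=config.fpm_missing)
    pass_filter = all(
        p is not None and p < config.method2_filter_alpha for _, p in labeled)
    return fpm, pass_filter


def _cohort_min(terms_c: dict[str, float | None],
                families: str) -> tuple[str, float] | None:
    """Most significant available term in one cohort.

    Ties are broken by the fixed family order (mutation < expression <
    eqtl), then by term name, so results are deterministic.
    """
    candidates = []
    for t in TERM_NAMES:
        if families == "cox_only" and TERM_FAMILY[t] == "eqtl":
            continue
        p = terms_c.get(t)
        if p is not None and not (isinstance(p, float) and np.isnan(p)):
            candidates.append((p, FAMILY_ORDER[TERM_FAMILY[t]], t))
    if not candidates:
        return None
    p, _, t = min(candidates)
    return t, p


def combine_method3(
    terms: dict[str, dict[str, float | None]],
    config: DoubletConfig | None = None,
) -> FpmResult:
    """Minimum-p rule with the same-family interaction substitution.

    Per cohort the minimum available p is found and its model family
    recorded. If both cohorts' minima come from the same Cox model family
    (mutation or expression), both are replaced by that family's
    interaction-term p-value where available. The two resulting values are
    combined by Fisher's product (df <= 4; df = 2 if one cohort has no
    available term).
    """
    config = config or DoubletConfig()
    mins = {c: _cohort_min(terms[c], config.method3_families)
            for c in ("t", "m")}
    chosen: dict[str, float | None] = {}
    fams = {c: (TERM_FAMILY[m[0]] if m else None) for c, m in mins.items()}
    same_cox = (fams["t"] is not None and fams["t"] == fams["m"]
                and fams["t"] in FAMILY_INTERACTION)
    for c in ("t", "m"):
        if mins[c] is None:
            chosen[f"min_{c}"] = None
            continue
        term, p = mins[c]
        if same_cox:
            inter = terms[c].get(FAMILY_INTERACTION[fams[c]])
            if inter is not None:
                term, p = FAMILY_INTERACTION[fams[c]], inter
        chosen[f"{term}{c}"] = p
    return fishers_product(list(chosen.items()), missing=config.fpm_missing)


# ---------------------------------------------------------------------------
# Scoring driver
# ---------------------------------------------------------------------------

def filter_subgroup(bundle: CohortBundle, subgroup: str) -> CohortBundle:
    """Restrict a cohort to one genotype subgroup (``All`` keeps everyone)."""
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup: {subgroup!r}")
    if subgroup == "All":
        return bundle
    keep = [p for p, g in bundle.clinical["genotype_group"].items()
            if g == subgroup]
    return bundle.subset(keep, name=f"{bundle.name}:{subgroup}")


def score_doublet(
    pair: tuple[str, str],
    bundle_t: CohortBundle,
    bundle_m: CohortBundle,
    library: DrugTargetLibrary,
    subgroup: str = "All",
    config: DoubletConfig | None = None,
    caches: dict[str, SummaryCache] | None = None,
) -> DoubletScore:
    """Score one unordered pair in both cohorts under Methods 1, 2, 3."""
    config = config or DoubletConfig()
    d1, d2 = sorted(pair)
    terms: dict[str, dict[str, float | None]] = {}
    flags: list[str] = []
    for c, bundle in (("t", bundle_t), ("m", bundle_m)):
        if bundle.n_patients < config.min_subgroup_patients:
            log.warning("cohort %s has %d (<%d) patients in subgroup %s; "
                        "terms set missing", bundle.name, bundle.n_patients,
                        config.min_subgroup_patients, subgroup)
            terms[c] = {t: None for t in TERM_NAMES}
            flags.append(f"too_few_patients_{c}")
            continue
        cache = caches[c] if caches else None
        terms[c], cohort_flags = fit_doublet_models(
            (d1, d2), bundle, library, cache)
        for f in cohort_flags:
            flags.append(f"{f}_{c}" if f == "cohort_unobservable" else f)
    m1 = combine_method1(terms, config)
    m2, m2_pass = combine_method2(terms, config)
    m3 = combine_method3(terms, config)
    return DoubletScore(d1, d2, subgroup, terms, m1, m2, m2_pass, m3,
                        flags=sorted(set(flags)))


def run_subgroup(
    pairs: list[tuple[str, str]],
    bundle_t: CohortBundle,
    bundle_m: CohortBundle,
    library: DrugTargetLibrary,
    subgroup: str = "All",
    config: DoubletConfig | None = None,
) -> list[DoubletScore]:
    """Score a list of pairs within one genotype subgroup.

    Patients are filtered by genotype; covariates that become constant in
    the subgroup (e.g. BRAF-inhibitor treatment among TripleWT patients)
    are dropped automatically by the Cox fitter.
    """
    config = config or DoubletConfig()
    sub_t = filter_subgroup(bundle_t, subgroup)
    sub_m = filter_subgroup(bundle_m, subgroup)
    caches = {"t": SummaryCache(library), "m": SummaryCache(library)}
    return [score_doublet(p, sub_t, sub_m, library, subgroup, config, caches)
            for p in pairs]


def doublet_table(scores: list[DoubletScore]) -> pd.DataFrame:
    """Flat ranked export of doublet scores (ascending Method-2 p, then
    Method-1, ties broken lexicographically for determinism)."""
    rows = []
    for s in scores:
        row = {"drug1": s.drug1, "drug2": s.drug2, "subgroup": s.subgroup}
        for c in ("t", "m"):
            for t in TERM_NAMES:
                v = s.terms[c][t]
                row[f"{t}_{c}"] = np.nan if v is None else v
        row["method1_p"] = s.method1.p_combined if s.method1.available else np.nan
        row["method2_p"] = s.method2.p_combined if s.method2.available else np.nan
        row["method2_pass"] = s.method2_pass_filter
        row["method3_p"] = s.method3.p_combined if s.method3.available else np.nan
        row["flags"] = ";".join(s.flags)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["method2_p", "method1_p", "drug1", "drug2"],
                            na_position="last").reset_index(drop=True)
    return df
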