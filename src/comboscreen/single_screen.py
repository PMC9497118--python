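"""Single-therapy screen and seed selection.

For every candidate drug, three lines of evidence are collected per cohort:

* mutation–survival: Cox PH of overall survival on the gene-set mutation
  indicator, adjusting for age and the BRAF-inhibitor and
  checkpoint-inhibitor treatment flags;
* expression–survival: the same Cox model with the gene-set PC1 score as
  the primary covariate;
* eQTL: a Wilcoxon rank-sum test of the PC1 score split by the mutation
  indicator (does mutation in the set shift its expression summary?).

The three p-values are combined by Fisher's product method within each
cohort, then the two cohort-level combined p-values are combined again
across cohorts. Drugs are ranked by that overall combined p, BH-FDR
adjusted, and those with q below a threshold — plus any forced clinical
inclusions — become the seed therapies that anchor the doublet pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortBundle, DrugTargetLibrary
from .preprocess import summarize_therapy_set
from .stats import FpmResult, bh_fdr, cox_fit, fishers_product, wilcoxon_rank_sum

log = logging.getLogger(__name__)

#: adjustment covariates in every survival model
ADJUST_COVARIATES = ("age", "braf_tx", "ipi_nivo_tx")


@dataclass
class CohortEvidence:
    """The three per-cohort evidence p-values for one drug."""

    p_mut: float | None
    p_expr: float | None
    p_eqtl: float | None
    fpm: FpmResult
    flags: list[str] = field(default_factory=list)


@dataclass
class SingleTherapyScore:
    drug_name: str
    cohorts: dict[str, CohortEvidence]
    fpm_overall: FpmResult
    q_value: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def available(self) -> bool:
        return self.fpm_overall.available


@dataclass
class SeedSet:
    seeds: list[str]
    selection_rule: dict


def _adjusted_design(bundle: CohortBundle, primary: pd.Series,
                     primary_name: str) -> pd.DataFrame:
    X = bundle.clinical[list(ADJUST_COVARIATES)].astype(float).copy()
    X.insert(0, primary_name, primary.loc[bundle.patients].astype(float).values)
    return X


def _survival_p(bundle: CohortBundle, primary: pd.Series,
                primary_name: str) -> float | None:
    """Wald p of the primary term in the adjusted Cox model; None if dropped."""
    fit = cox_fit(
        bundle.clinical["os_time"].to_numpy(),
        bundle.clinical["os_event"].to_numpy(),
        _adjusted_design(bundle, primary, primary_name),
        protected=(primary_name,),
    )
    if not fit.converged:
        # conservative policy: failed fit reports p = 1 for the primary term
        return 1.0 if primary_name in fit.term_names else None
    return fit.p_for(primary_name)


def score_cohort_evidence(
    bundle: CohortBundle, drug: str, library: DrugTargetLibrary,
) -> CohortEvidence:
    """Mutation, expression and eQTL evidence for one drug in one cohort."""
    summary = summarize_therapy_set(bundle, drug, library.targets(drug))
    flags = list(summary.flags)

    p_mut = p_expr = p_eqtl = None
    if summary.mut.usable:
        p_mut = _survival_p(bundle, summary.mut.values, "mut_indicator")
    if summary.pc1.available:
        p_expr = _survival_p(bundle, summary.pc1.scores, "pc1_score")
    if summary.mut.usable and summary.pc1.available:
        ind = summary.mut.values
        scores = summary.pc1.scores
        p_eqtl = wilcoxon_rank_sum(scores[ind == 0], scores[ind == 1])

    fpm = fishers_product(
        [("p_mut", p_mut), ("p_expr", p_expr), ("p_eqtl", p_eqtl)])
    return CohortEvidence(p_mut, p_expr, p_eqtl, fpm, flags)


def score_single_therapy(
    drug: str,
    bundle_t: CohortBundle,
    bundle_m: CohortBundle,
    library: DrugTargetLibrary,
) -> SingleTherapyScore:
    """Score one drug across both cohorts (hierarchical FPM)."""
    if drug not in library:
        raise KeyError(f"drug not in library: {drug}")
    cohorts = {
        "t": score_cohort_evidence(bundle_t, drug, library),
        "m": score_cohort_evidence(bundle_m, drug, library),
    }
    labeled = [(c, ev.fpm.p_combined if ev.fpm.available else None)
               for c, ev in cohorts.items()]
    fpm_overall = fishers_product(labeled)
    flags = []
    n_avail = sum(1 for _, p in labeled if p is not None)
    if n_avail == 1:
        flags.append("single_cohort_evidence")
    elif n_avail == 0:
        flags.append("unavailable")
    return SingleTherapyScore(drug, cohorts, fpm_overall, flags=flags)


def attach_fdr(scores: list[SingleTherapyScore]) -> list[SingleTherapyScore]:
    """BH-FDR over the drugs with available overall evidence (in place)."""
    avail = [s for s in scores if s.available]
    if avail:
        q = bh_fdr([s.fpm_overall.p_combined for s in avail])
        for s, qv in zip(avail, q):
            s.q_value = float(qv)
    return scores


def screen_single_therapies(
    bundle_t: CohortBundle,
    bundle_m: CohortBundle,
    library: DrugTargetLibrary,
    drugs: list[str] | None = None,
) -> list[SingleTherapyScore]:
    """Score every drug (or a subset) and attach BH-FDR q-values."""
    drugs = drugs if drugs is not None else library.drugs
    scores = [score_single_therapy(d, bundle_t, bundle_m, library)
              for d in drugs]
    return attach_fdr(scores)


def select_seeds(
    scores: list[SingleTherapyScore],
    fdr_threshold: float = 0.05,
    forced_inclusions: tuple[str, ...] | list[str] = (),
    library: DrugTargetLibrary | None = None,
) -> SeedSet:
    """Seed therapies: drugs with q < threshold, union forced inclusions.

    Forced drugs absent from the library (when one is given) are a fatal
    error. The result is de-duplicated and alphabetically ordered.
    """
    if library is not None:
        for d in forced_inclusions:
            if d not in library:
                raise KeyError(f"forced seed not in library: {d}")
    passing = {s.drug_name for s in scores
               if s.q_value is not None and s.q_value < fdr_threshold}
    seeds = sorted(passing | set(forced_inclusions))
    return SeedSet(
        seeds=seeds,
        selection_rule={
            "fdr_threshold": fdr_threshold,
            "forced_inclusions": sorted(set(forced_inclusions)),
            "n_passing_fdr": len(passing),
        },
    )


def assemble_candidate_pool(library: DrugTargetLibrary) -> list[str]:
    """All library drugs, deduplicated and sorted; per-source counts logged."""
    pool = library.drugs
    for src, n in sorted(library.source_counts().items()):
        log.info("candidate pool: %d drugs from %s", n, src)
    log.info("candidate pool: %d drugs total", len(pool))
    return pool


def scores_table(scores: list[SingleTherapyScore]) -> pd.DataFrame:
    """Flat export table of the single-therapy screen."""
    rows = []
    for s in scores:
        row = {"drug": s.drug_name}
        for c in ("t", "m"):
            ev = s.cohorts.get(c)
            row[f"p_mut_{c}"] = ev.p_mut if ev else np.nan
            row[f"p_expr_{c}"] = ev.p_expr if ev else np.nan
            row[f"p_eqtl_{c}"] = ev.p_eqtl if ev else np.nan
            row[f"fpm_{c}"] = (ev.fpm.p_combined
                               if ev and ev.fpm.available else np.nan)
        row["fpm_overall"] = (s.fpm_overall.p_combined
                              if s.available else np.nan)
        row["q_value"] = s.q_value if s.q_value is not None else np.nan
        row["flags"] = ";".join(s.flags)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["fpm_overall", "drug"],
                          na_position="last").reset_index(drop=True)
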