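"""Cohort summary, app-facing table exports, and the end-to-end pipeline.

Exports are plain TSV/JSON: the ranked doublet tables, Kaplan–Meier curve
data by gene-set mutation status and by median-dichotomized PC1, eQTL
box-plot summaries, TME tables, and a run manifest with checksums so that
identical config + seed provably yields identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (CohortBundle, DrugTargetLibrary, read_cohort,
                        read_drug_library, read_single_cell)
from .doublets import (DoubletConfig, doublet_table, enumerate_doublets,
                       run_subgroup)
from .preprocess import batch_adjust_bundles, summarize_therapy_set
from .simulate import (SimulationConfig, SingleCellConfig, simulate_cohorts,
                       simulate_single_cell)
from .single_screen import (assemble_candidate_pool, scores_table,
                            screen_single_therapies, select_seeds)
from .stats import km_estimate
from .tme import profile_drug_tme, tme_heatmap_table, tme_violin_table

log = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the printed precision (table style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, n: int) -> float:
    return round_half_up(100.0 * count / n, 1)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    n: int
    genotype: dict[str, tuple[int, float]]   # group -> (count, pct)
    age_mean: float
    age_sd: float
    treatment: dict[str, tuple[int, float]]
    sex: dict[str, tuple[int, float]]

    def to_frame(self, cohort: str = "") -> pd.DataFrame:
        rows = [{"cohort": cohort, "section": "n", "item": "n",
                 "count": self.n, "percent": np.nan}]
        for sec, d in (("genotype", self.genotype),
                       ("treatment", self.treatment), ("sex", self.sex)):
            for item, (c, p) in d.items():
                rows.append({"cohort": cohort, "section": sec, "item": item,
                             "count": c, "percent": p})
        rows.append({"cohort": cohort, "section": "age", "item": "mean",
                     "count": np.nan, "percent": self.age_mean})
        rows.append({"cohort": cohort, "section": "age", "item": "sd",
                     "count": np.nan, "percent": self.age_sd})
        return pd.DataFrame(rows)


def summarize_cohort(clinical: pd.DataFrame) -> CohortSummary:
    """Table-1-style cohort summary: counts and half-up percentages."""
    if len(clinical) == 0:
        raise ValueError("empty clinical table")
    n = len(clinical)
    geno = {}
    for g in ("BRAF", "NRAS", "TripleWT", "other"):
        c = int((clinical["genotype_group"] == g).sum())
        if g != "other" or c > 0:
            geno[g] = (c, percent(c, n))
    treat = {}
    for flag in ("ipi_nivo_tx", "braf_tx"):
        c = int(clinical[flag].sum())
        treat[flag] = (c, percent(c, n))
    sex = {}
    for s in ("female", "male"):
        c = int((clinical["sex"] == s).sum())
        sex[s] = (c, percent(c, n))
    return CohortSummary(
        n=n, genotype=geno,
        age_mean=round_half_up(clinical["age"].mean(), 1),
        age_sd=round_half_up(clinical["age"].std(ddof=1), 1),
        treatment=treat, sex=sex,
    )


# ---------------------------------------------------------------------------
# KM and eQTL exports
# ---------------------------------------------------------------------------

def _km_frame(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for g, df in groups.items():
        d = df.copy()
        d.insert(0, "group", g)
        rows.append(d)
    return (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["group", "time", "survival", "n_at_risk"]))


def export_km_data(
    pair: tuple[str, str],
    bundles: dict[str, CohortBundle],
    library: DrugTargetLibrary,
) -> dict[str, pd.DataFrame]:
    """KM curve data per cohort, by mutation status and by PC1 median split.

    Mutation groups: neither / drug1_only / drug2_only / both (empty groups
    omitted with a logged note). PC1 dichotomized at the median per drug;
    values >= median go to the high group.
    """
    d1, d2 = sorted(pair)
    out: dict[str, pd.DataFrame] = {}
    for c, bundle in bundles.items():
        time = bundle.clinical["os_time"].to_numpy()
        event = bundle.clinical["os_event"].to_numpy()
        s1 = summarize_therapy_set(bundle, d1, library.targets(d1))
        s2 = summarize_therapy_set(bundle, d2, library.targets(d2))
        if s1.mut.available and s2.mut.available:
            x1 = s1.mut.values.to_numpy()
            x2 = s2.mut.values.to_numpy()
            names = np.array(["neither", f"{d2}_only", f"{d1}_only", "both"])
            labels = names[x1 * 2 + x2]
            counts = pd.Series(labels).value_counts()
            for g in names:
                if g not in counts:
                    log.info("KM export %s/%s: group %s empty, omitted", c, d1, g)
            out[f"{c}_mutation"] = _km_frame(km_estimate(time, event, labels))
        for drug, summ in ((d1, s1), (d2, s2)):
            if not summ.pc1.available:
                continue
            v = summ.pc1.scores.to_numpy()
            med = np.median(v)
            labels = np.where(v >= med, "PC1_high", "PC1_low")
            out[f"{c}_pc1_{drug}"] = _km_frame(km_estimate(time, event, labels))
    return out


def _quartile_row(values: np.ndarray) -> dict:
    if values.size == 0:
        return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan}
    return {"n": int(values.size),
            "median": float(np.percentile(values, 50)),
            "q1": float(np.percentile(values, 25)),
            "q3": float(np.percentile(values, 75))}


def export_eqtl_data(
    pair: tuple[str, str],
    bundles: dict[str, CohortBundle],
    library: DrugTargetLibrary,
) -> pd.DataFrame:
    """Box-plot summaries: PC1 and per-gene expression by mutation status.

    Expression values are taken from the bundles as given — run this on
    batch-adjusted bundles to match the de-batched app display.
    """
    rows = []
    for c, bundle in bundles.items():
        for drug in sorted(pair):
            s = summarize_therapy_set(bundle, drug, library.targets(drug))
            if not s.mut.available:
                continue
            ind = s.mut.values
            variables = {}
            if s.pc1.available:
                variables["pc1"] = s.pc1.scores
            for g in s.pc1.genes_used:
                variables[g] = bundle.expression.loc[g]
            for var, series in variables.items():
                for grp in (0, 1):
                    vals = series[ind == grp].to_numpy(dtype=float)
                    rows.append({"cohort": c, "drug": drug, "variable": var,
                                 "mut_group": grp, **_quartile_row(vals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "seeds_fdr_threshold": 0.05,
    "forced_seeds": ["Panobinostat", "Trametinib"],
    "method2_filter_alpha": 0.05,
    "fpm_missing": "drop",
    "method3_families": "all",
    "subgroups": ["All"],
    "max_pairs": None,
    "with_tme": True,
}


def load_config(config_path: str | Path | None, **overrides) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config_path is not None:
        with open(config_path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _load_inputs(cfg: dict):
    """Either simulate inputs or read them from the configured paths."""
    if "clinical_t" in cfg:
        bt = read_cohort(cfg["clinical_t"], cfg["mutations_t"],
                         cfg["expression_t"], name="t")
        bm = read_cohort(cfg["clinical_m"], cfg["mutations_m"],
                         cfg["expression_m"], name="m")
        library = read_drug_library(cfg["library_gmt"])
        sc = None
        if cfg.get("sc_mtx"):
            sc = read_single_cell(cfg["sc_mtx"], cfg["sc_genes"],
                                  cfg["sc_barcodes"], cfg["sc_labels"])
        return bt, bm, library, sc
    sim_keys = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
    sim_cfg = SimulationConfig(
        **{k: v for k, v in cfg.items() if k in sim_keys})
    bt, bm, library, _ = simulate_cohorts(sim_cfg)
    sc = simulate_single_cell(SingleCellConfig(seed=cfg.get("seed", 0)))
    return bt, bm, library, sc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config_path: str | Path | None, outdir: str | Path,
                 **overrides) -> Path:
    """Execute read -> batch-adjust -> screen -> seeds -> doublets -> exports.

    Writes all output tables plus a manifest (config hash, version, seed,
    per-file checksum and row count) under ``outdir``.
    """
    cfg = load_config(config_path, **overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written[name] = path

    bundle_t, bundle_m, library, sc = _load_inputs(cfg)
    bundle_t, bundle_m = batch_adjust_bundles(bundle_t, bundle_m)
    bundles = {"t": bundle_t, "m": bundle_m}

    emit("cohort_summary.tsv", pd.concat(
        [summarize_cohort(b.clinical).to_frame(c) for c, b in bundles.items()],
        ignore_index=True))

    pool = assemble_candidate_pool(library)
    scores = screen_single_therapies(bundle_t, bundle_m, library, pool)
    emit("single_therapy_scores.tsv", scores_table(scores))

    forced = [d for d in cfg["forced_seeds"] if d in library]
    missing_forced = sorted(set(cfg["forced_seeds"]) - set(forced))
    if missing_forced:
        log.warning("forced seeds absent from library, skipped: %s",
                    missing_forced)
    seed_set = select_seeds(scores, cfg["seeds_fdr_threshold"], forced, library)
    emit("seeds.tsv", pd.DataFrame({"seed": seed_set.seeds}))

    dconfig = DoubletConfig(
        method2_filter_alpha=cfg["method2_filter_alpha"],
        fpm_missing=cfg["fpm_missing"],
        method3_families=cfg["method3_families"],
    )
    pairs = enumerate_doublets(seed_set.seeds, pool).pairs
    if cfg.get("max_pairs") is not None:
        pairs = pairs[: int(cfg["max_pairs"])]

    top_pair = None
    for subgroup in cfg["subgroups"]:
        sub_scores = run_subgroup(pairs, bundle_t, bundle_m, library,
                                  subgroup, dconfig)
        table = doublet_table(sub_scores)
        emit(f"doublets_{subgroup}.tsv", table)
        if subgroup == "All" and len(table):
            top_pair = (table.iloc[0]["drug1"], table.iloc[0]["drug2"])

    if top_pair is not None:
        for name, df in export_km_data(top_pair, bundles, library).items():
            emit(f"km_{name}.tsv", df)
        emit("eqtl_top_pair.tsv", export_eqtl_data(top_pair, bundles, library))
        if cfg.get("with_tme") and sc is not None:
            profiles = [profile_drug_tme(d, sc, library) for d in top_pair
                        if set(g.upper() for g in library.targets(d))
                        & set(sc.genes)]
            heat = tme_heatmap_table(profiles)
            if len(heat):
                emit("tme_heatmap.tsv", heat)
                emit("tme_violin.tsv", pd.concat(
                    [tme_violin_table(p.drug_name, sc, library)
                     for p in profiles], ignore_index=True))

    cfg_canon = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": cfg.get("seed", 0),
        "config_sha256": hashlib.sha256(cfg_canon.encode()).hexdigest(),
        "config": cfg,
        "n_patients": {c: b.n_patients for c, b in bundles.items()},
        "n_drugs": len(library),
        "n_seeds": len(seed_set.seeds),
        "n_pairs": len(pairs),
        "files": {
            name: {"sha256": _sha256(p),
                   "rows": max(sum(1 for _ in open(p)) - 1, 0)}
            for name, p in sorted(written.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return outdir
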