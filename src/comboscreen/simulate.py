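"""Synthetic two-cohort generator with the structure the pipeline assumes.

The generator emulates the study design the screen targets: two independent
melanoma-like cohorts (a large discovery cohort ``t`` of 459 patients and a
smaller validation cohort ``m`` of 135) with, per patient, somatic mutation
calls, log-scale expression, overall survival and the clinical covariates,
plus a drug -> target-gene library.

Generative model
----------------
* Genes are partitioned into co-expression modules; each gene's expression
  is ``base + lambda * module_factor + noise``, so the target genes of a
  drug (drawn within one module) are correlated and PC1 recovers the
  latent factor.
* Mutations are Bernoulli per gene with gene-level prevalences shared
  across cohorts.
* Survival follows a Cox–Weibull model: the linear predictor contains a
  mild age effect plus any configured drug effects (mutation-indicator
  hazard, latent-factor "expression" hazard, pairwise mutation-interaction
  hazard). eQTL effects shift the target genes' expression in mutated
  patients without touching the hazard.
* Cohort ``m`` receives an additive per-gene batch offset.
* Censoring is an independent uniform–exponential mixture whose scale is
  calibrated so the realized censoring fraction matches the configured
  rate.

The seed fully determines the output; the truth record stores every
injected effect for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .cohort_io import CohortBundle, DrugEntry, DrugTargetLibrary, SingleCellMatrix


@dataclass
class EffectSpec:
    """One injected ground-truth effect.

    channel:
      mutation_hazard     — log-HR on the drug's mutation indicator
      expression_hazard   — log-HR on the drug's latent module factor
      interaction_hazard  — log-HR on x1*x2 of a drug pair (target = (d1, d2))
      eqtl_shift          — additive expression shift of the drug's target
                            genes in mutated patients (no hazard)
    """

    target: str | tuple[str, str]
    channel: str
    magnitude: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: dict = field(default_factory=lambda: {"t": 459, "m": 135})
    n_genes: int = 300
    module_size: int = 5
    module_loading: float = 0.7
    genotype_fractions: dict = field(default_factory=lambda: {
        "t": {"BRAF": 0.514, "NRAS": 0.272, "TripleWT": 0.192},
        "m": {"BRAF": 0.437, "NRAS": 0.252, "TripleWT": 0.207},
    })
    treatment_flag_rates: dict = field(default_factory=lambda: {
        "t": {"braf_tx": 0.011, "ipi_nivo_tx": 0.033},
        "m": {"braf_tx": 0.215, "ipi_nivo_tx": 0.378},
    })
    drug_library_spec: dict = field(default_factory=lambda: {
        "dsigdb": 50, "hdac_panel": 7, "checkpoint": 3})
    named_drugs: dict = field(default_factory=lambda: {
        "Panobinostat": "hdac_panel", "Trametinib": "dsigdb"})
    target_set_mean_extra: float = 2.0   # set size = 1 + Poisson(this)
    mutation_prevalence: tuple = (0.02, 0.25)
    effect_spec: list = field(default_factory=list)
    batch_shift: float = 1.0             # sd of the per-gene cohort-m offset
    expression_base_mean: float = 6.0
    expression_base_sd: float = 1.0
    baseline_shape: float = 1.2          # Weibull shape (PH holds exactly)
    baseline_scale: float = 1500.0       # days
    age_log_hr: float = 0.1              # per standardized-age unit
    age_mean: float = 61.5
    age_sd: float = 15.0
    male_fraction: float = 0.62
    censoring_rate: float = 0.45

    def validate(self) -> "SimulationConfig":
        for c, frac in self.genotype_fractions.items():
            if sum(frac.values()) > 1.0 + 1e-9:
                raise ValueError(f"genotype fractions for {c} sum above 1")
        for c, n in self.n_patients.items():
            if n < 20:
                raise ValueError(f"n_patients[{c}] must be >= 20")
        lo, hi = self.mutation_prevalence
        if not (0 < lo <= hi < 1):
            raise ValueError("mutation prevalence bounds must be in (0, 1)")
        return self


def _build_library(cfg: SimulationConfig, rng: np.random.Generator,
                   genes: list[str], gene_module: np.ndarray,
                   ) -> tuple[DrugTargetLibrary, dict[str, int]]:
    n_modules = int(gene_module.max()) + 1
    entries: dict[str, DrugEntry] = {}
    drug_module: dict[str, int] = {}

    def add_drug(name: str, source: str):
        m = int(rng.integers(n_modules))
        members = [g for g, mm in zip(genes, gene_module) if mm == m]
        k = min(1 + int(rng.poisson(cfg.target_set_mean_extra)), len(members))
        k = max(k, 1)
        targets = frozenset(
            str(g) for g in rng.choice(members, size=k, replace=False))
        entries[name] = DrugEntry(targets, source)
        drug_module[name] = m

    for source, count in sorted(cfg.drug_library_spec.items()):
        for i in range(count):
            add_drug(f"{source}_drug_{i:04d}", source)
    for name, source in sorted(cfg.named_drugs.items()):
        add_drug(name, source)
    return DrugTargetLibrary(entries), drug_module


def _simulate_clinical(cfg: SimulationConfig, rng: np.random.Generator,
                       cohort: str) -> pd.DataFrame:
    n = cfg.n_patients[cohort]
    pids = [f"{cohort}_P{i:04d}" for i in range(n)]
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18, 95)
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    frac = cfg.genotype_fractions[cohort]
    probs = [frac["BRAF"], frac["NRAS"], frac["TripleWT"]]
    probs.append(max(0.0, 1.0 - sum(probs)))
    geno = rng.choice(["BRAF", "NRAS", "TripleWT", "other"], size=n, p=probs)
    rates = cfg.treatment_flag_rates[cohort]
    # BRAF-inhibitor treatment is only given to BRAF-mutant patients;
    # the conditional rate is inflated so the marginal matches the config
    braf_tx = np.zeros(n, dtype=int)
    is_braf = geno == "BRAF"
    if is_braf.any():
        cond = min(1.0, rates["braf_tx"] / max(frac["BRAF"], 1e-9))
        braf_tx[is_braf] = (rng.random(is_braf.sum()) < cond).astype(int)
    ipi = (rng.random(n) < rates["ipi_nivo_tx"]).astype(int)
    return pd.DataFrame({
        "age": age, "sex": sex, "braf_tx": braf_tx, "ipi_nivo_tx": ipi,
        "genotype_group": geno,
    }, index=pd.Index(pids, name="patient_id"))


def _calibrate_censoring(event_times: np.ndarray, c_base: np.ndarray,
                         rate: float) -> float:
    """Scale for the censoring draw so that P(C < T) ~= rate."""
    if rate <= 0:
        return np.inf
    lo, hi = 1e-6, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = np.mean(mid * c_base < event_times)
        if frac > rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_cohorts(config: SimulationConfig
                     ) -> tuple[CohortBundle, CohortBundle,
                                DrugTargetLibrary, dict]:
    """Generate both cohort bundles, the drug library and the truth record."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    gene_module = np.arange(cfg.n_genes) // cfg.module_size
    library, drug_module = _build_library(cfg, rng, genes, gene_module)

    lo, hi = cfg.mutation_prevalence
    prevalence = rng.uniform(lo, hi, cfg.n_genes)
    base_mean = rng.normal(cfg.expression_base_mean, cfg.expression_base_sd,
                           cfg.n_genes)
    batch_offset = rng.normal(0.0, cfg.batch_shift, cfg.n_genes)

    # feasibility: a mutation-channel effect needs mutable targets
    for eff in cfg.effect_spec:
        names = eff.target if isinstance(eff.target, tuple) else (eff.target,)
        for d in names:
            if d not in library:
                raise ValueError(f"effect on unknown drug: {d}")

    bundles = {}
    truth_factors = {}
    for cohort in ("t", "m"):
        n = cfg.n_patients[cohort]
        clinical = _simulate_clinical(cfg, rng, cohort)
        pids = list(clinical.index)

        mut = (rng.random((cfg.n_genes, n)) < prevalence[:, None]).astype(np.int8)
        mutations = pd.DataFrame(mut, index=genes, columns=pids)

        n_modules = int(gene_module.max()) + 1
        factors = rng.standard_normal((n_modules, n))
        lam = cfg.module_loading
        noise = rng.standard_normal((cfg.n_genes, n))
        expr = (base_mean[:, None] + lam * factors[gene_module, :]
                + np.sqrt(1 - lam ** 2) * noise)
        if cohort == "m":
            expr = expr + batch_offset[:, None]
        expression = pd.DataFrame(expr, index=genes, columns=pids)

        def indicator(drug: str) -> np.ndarray:
            tg = sorted(library.targets(drug))
            return mutations.loc[tg].to_numpy().any(axis=0).astype(float)

        lp = cfg.age_log_hr * (clinical["age"].to_numpy() - cfg.age_mean) / cfg.age_sd
        for eff in cfg.effect_spec:
            if eff.channel == "mutation_hazard":
                lp = lp + eff.magnitude * indicator(eff.target)
            elif eff.channel == "expression_hazard":
                lp = lp + eff.magnitude * factors[drug_module[eff.target]]
            elif eff.channel == "interaction_hazard":
                d1, d2 = eff.target
                lp = lp + eff.magnitude * indicator(d1) * indicator(d2)
            elif eff.channel == "eqtl_shift":
                tg = sorted(set(library.targets(eff.target)) & set(genes))
                ind = indicator(eff.target).astype(bool)
                expression.loc[tg, expression.columns[ind]] += eff.magnitude
            else:
                raise ValueError(f"unknown effect channel: {eff.channel}")

        E = rng.exponential(1.0, n)
        T = cfg.baseline_scale * (E / np.exp(lp)) ** (1.0 / cfg.baseline_shape)
        # censoring: independent uniform-exponential mixture, scale calibrated
        c_base = np.where(rng.random(n) < 0.5,
                          rng.uniform(0.0, 2.0, n), rng.exponential(1.0, n))
        c_base = np.maximum(c_base, 1e-9)
        s = _calibrate_censoring(T, c_base, cfg.censoring_rate)
        C = s * c_base
        os_time = np.maximum(np.minimum(T, C), 1e-3)
        os_event = (T <= C).astype(int)
        clinical["os_time"] = os_time
        clinical["os_event"] = os_event
        clinical = clinical[["age", "sex", "os_time", "os_event",
                             "braf_tx", "ipi_nivo_tx", "genotype_group"]]

        bundles[cohort] = CohortBundle(
            name=cohort, clinical=clinical,
            mutations=mutations, expression=expression).validate()
        truth_factors[cohort] = factors

    truth = {
        "seed": cfg.seed,
        "effects": [asdict(e) for e in cfg.effect_spec],
        "drug_module": drug_module,
        "gene_module": {g: int(m) for g, m in zip(genes, gene_module)},
        "prevalence": dict(zip(genes, prevalence.tolist())),
        "batch_offset": dict(zip(genes, batch_offset.tolist())),
        "module_factors": truth_factors,
    }
    return bundles["t"], bundles["m"], library, truth


# ---------------------------------------------------------------------------
# Single-cell simulation
# ---------------------------------------------------------------------------

@dataclass
class SingleCellConfig:
    seed: int = 0
    n_cells: int = 300
    n_genes: int = 60
    cell_types: tuple = ("T_NK", "myeloid", "malignant")
    markers: dict | None = None          # cell_type -> list of gene names
    marker_mean: float = 5.0
    base_mean: float = 0.3
    dispersion: float = 2.0              # NB size parameter theta


def simulate_single_cell(config: SingleCellConfig) -> SingleCellMatrix:
    """Negative-binomial counts with cell-type-specific marker means."""
    cfg = config
    if len(cfg.cell_types) < 2:
        raise ValueError("need >= 2 cell types")
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    markers = cfg.markers
    if markers is None:
        # first len(cell_types)*3 genes become type-exclusive markers
        markers = {ct: genes[3 * i: 3 * i + 3]
                   for i, ct in enumerate(cfg.cell_types)}
    labels = [cfg.cell_types[i % len(cfg.cell_types)]
              for i in range(cfg.n_cells)]
    barcodes = [f"cell_{i:05d}" for i in range(cfg.n_cells)]

    mean = np.full((cfg.n_cells, cfg.n_genes), cfg.base_mean)
    gidx = {g: j for j, g in enumerate(genes)}
    for i, ct in enumerate(labels):
        for g in markers.get(ct, []):
            if g in gidx:
                mean[i, gidx[g]] = cfg.marker_mean
    theta = cfg.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean))
    return SingleCellMatrix(
        values=sparse.csr_matrix(counts),
        cells=barcodes, genes=genes,
        cell_type=pd.Series(labels, index=barcodes, name="cell_type"),
    )


# ---------------------------------------------------------------------------
# File export (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_simulation(config: SimulationConfig, outdir: str | Path,
                     sc_config: SingleCellConfig | None = None) -> dict:
    """Write the full synthetic input file set + truth JSON; returns paths."""
    from .cohort_io import write_cohort, write_drug_library

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bt, bm, library, truth = simulate_cohorts(config)
    paths = {}
    for b in (bt, bm):
        paths.update({f"{b.name}_{k}": str(v)
                      for k, v in write_cohort(b, outdir).items()})
    paths["library"] = str(write_drug_library(library, outdir / "drug_library.gmt"))

    sc = simulate_single_cell(sc_config or SingleCellConfig(seed=config.seed))
    spio.mmwrite(str(outdir / "sc_matrix.mtx"), sparse.coo_matrix(sc.values))
    pd.Series(sc.genes).to_csv(outdir / "sc_genes.tsv", sep="\t",
                               index=False, header=False)
    pd.Series(sc.cells).to_csv(outdir / "sc_barcodes.tsv", sep="\t",
                               index=False, header=False)
    sc.cell_type.rename_axis("barcode").reset_index().to_csv(
        outdir / "sc_labels.tsv", sep="\t", index=False, header=False)
    paths.update({"sc_matrix": str(outdir / "sc_matrix.mtx"),
                  "sc_genes": str(outdir / "sc_genes.tsv"),
                  "sc_barcodes": str(outdir / "sc_barcodes.tsv"),
                  "sc_labels": str(outdir / "sc_labels.tsv")})

    truth_out = {k: v for k, v in truth.items() if k != "module_factors"}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_out, fh, indent=1)
    paths["truth"] = str(outdir / "truth.json")
    return paths
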