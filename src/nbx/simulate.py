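"""Synthetic data generators with known ground truth.

These emulate the inputs of a hypoxia/prognosis gene-discovery study in
neuroblastoma so every downstream stage (differential expression, overlap
testing, survival scanning, qPCR quantification) can be exercised end-to-end
without any external download:

* patient cohorts: log2 expression matrices with a planted set of
  outcome-associated genes (partially confounded with MYCN amplification)
  and right-censored overall-survival times whose hazard depends on the
  planted genes through a threshold (high/low expression group) effect;
* cell-line hypoxia experiments: normoxia/hypoxia pairs across cell lines
  with planted hypoxia-responsive genes and a between-line random intercept;
* triplicate qPCR Ct plates with a housekeeping reference gene;
* BED fixtures of gene TSSs and differential peaks planted in the promoter
  windows of a chosen gene subset.

Reproducibility: every generator derives its RNG from
``numpy.random.default_rng([seed, STREAM])`` where ``STREAM`` is a fixed
per-generator constant, so the same seed can be shared across generators
without coupling their draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import (
    ExpressionDataset,
    write_clinical_tsv,
    write_expression_tsv,
)

__all__ = [
    "CohortSimConfig",
    "CellLineSimConfig",
    "QPCRSimConfig",
    "simulate_patient_cohort",
    "simulate_cellline_experiment",
    "simulate_qpcr_plate",
    "simulate_peak_fixtures",
    "simulate_proportional_hazards",
    "write_cohort",
    "write_cellline",
]

# per-generator RNG stream constants (arbitrary, fixed)
_STREAM_COHORT = 101
_STREAM_CELLLINE = 202
_STREAM_QPCR = 303
_STREAM_PEAKS = 404
_STREAM_COXSIM = 505

#: INSS stage frequencies of a 478-patient diagnostic cohort
_STAGE_LEVELS = ["1", "2", "3", "4", "4S"]
_STAGE_PROBS = np.array([119, 80, 69, 148, 62]) / 478.0


@dataclass
class CohortSimConfig:
    """Parameters of a simulated diagnostic patient cohort.

    Defaults mirror a 478-patient cohort: ~19% deaths during follow-up,
    ~15% MYCN-amplified tumors, stage frequencies as above, log2-scale
    expression with residual SD 0.5 and a one-unit (2-fold) planted effect.

    ``expression_link`` chooses how planted prognostic genes couple to
    survival:

    * ``"latent"`` (default): a latent high-risk group of size
      ``1 - threshold_quantile`` both shifts planted-gene expression by
      ``effect_size`` and multiplies the hazard by
      ``exp(log_hazard_ratio)`` — the threshold model a cutpoint scan is
      meant to recover. The deceased-vs-survivor expression contrast is
      then an attenuated version of ``effect_size``.
    * ``"event"``: planted-gene expression is shifted by ``effect_size``
      in patients who die, so two-group differential expression recovers
      ``effect_size`` exactly; the threshold location then tracks the
      event fraction rather than ``threshold_quantile``.
    """

    n_patients: int = 478
    n_genes: int = 2000
    n_prognostic: int = 25
    effect_size: float = 1.0
    mycn_fraction: float = 74 / 478
    mycn_confound: float = 1.0
    n_mycn_genes: int = 25
    baseline_hazard: float = 0.05
    log_hazard_ratio: float = float(np.log(3.0))
    threshold_quantile: float = 0.6
    censor_rate: float = 1 - 91 / 478
    noise_sd: float = 0.5
    stage4_log_hr: float = 0.7
    age_log_hr: float = 0.3
    expression_link: str = "latent"
    seed: int = 0

    def validate(self) -> None:
        if self.n_prognostic > self.n_genes:
            raise ValueError("n_prognostic exceeds n_genes")
        if not (0 < self.threshold_quantile < 1):
            raise ValueError("threshold_quantile must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("mycn_fraction", "censor_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("effect_size", "mycn_confound", "log_hazard_ratio"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.expression_link not in ("latent", "event"):
            raise ValueError("expression_link must be 'latent' or 'event'")


@dataclass
class CellLineSimConfig:
    """Parameters of a simulated normoxia/hypoxia cell-line experiment.

    Defaults mirror an 11-line panel assayed in both 21% and 1% oxygen,
    with a between-line random intercept and a subset of MYCN-amplified
    lines.
    """

    n_lines: int = 11
    n_replicates_per_condition: int = 2
    n_genes: int = 2000
    n_hypoxia_responsive: int = 25
    hypoxia_effect: float = 2.0
    line_sd: float = 1.0
    noise_sd: float = 0.5
    mycn_lines: tuple[int, ...] | None = None  # default: roughly half the lines
    mycn_effect: float = 0.5
    growth_effect: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.line_sd < 0:
            raise ValueError("line_sd must be >= 0")
        if self.n_hypoxia_responsive > self.n_genes:
            raise ValueError("n_hypoxia_responsive exceeds n_genes")
        if not np.isfinite(self.hypoxia_effect):
            raise ValueError("hypoxia_effect must be finite")


@dataclass
class QPCRSimConfig:
    """Parameters of a simulated qRT-PCR Ct plate (triplicates by default)."""

    genes: tuple[str, ...] = ("HK2", "PGK1", "ENO1")
    true_log2_fold: tuple[float, ...] = (3.0, 2.0, 1.5)
    reference_gene: str = "ACTB"
    n_replicates: int = 3
    ct_noise_sd: float = 0.2
    plate_offset_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.genes) != len(self.true_log2_fold):
            raise ValueError("genes and true_log2_fold lengths differ")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.reference_gene in self.genes:
            idx = self.genes.index(self.reference_gene)
            if self.true_log2_fold[idx] != 0:
                raise ValueError("reference gene must have true_log2_fold = 0")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _calibrate_censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Horizon u of Uniform(0, u) censoring achieving the target censoring
    fraction for exponential event times with the given per-patient rates.

    P(censored | rate r) = E[exp(-r C)] = (1 - exp(-r u)) / (r u).
    """
    if censor_rate <= 0:
        return np.inf

    def mean_censored(u: float) -> float:
        x = rates * u
        return float(np.mean(np.where(x > 1e-12, (1 - np.exp(-x)) / x, 1.0)))

    lo, hi = 1e-9, 1e9
    if mean_censored(hi) > censor_rate:  # pragma: no cover - pathological rates
        return hi
    return brentq(lambda u: mean_censored(u) - censor_rate, lo, hi)


def simulate_patient_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionDataset, dict]:
    """Simulate one patient cohort.

    Returns the dataset and a ground-truth dict with the planted prognostic
    gene IDs, their directions, the true expression cutpoints, the MYCN-only
    gene IDs and the latent risk-group labels.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    n, m = config.n_patients, config.n_genes
    genes = _gene_ids(m)
    samples = [f"P{i:04d}" for i in range(n)]

    prognostic = genes[: config.n_prognostic]
    # directions alternate so both tails of the fold-change distribution
    # carry planted genes
    directions = np.where(np.arange(config.n_prognostic) % 2 == 0, 1.0, -1.0)
    n_mycn_genes = min(config.n_mycn_genes, m - config.n_prognostic)
    mycn_genes = genes[config.n_prognostic : config.n_prognostic + n_mycn_genes]

    mycn = rng.random(n) < config.mycn_fraction
    stage = rng.choice(_STAGE_LEVELS, size=n, p=_STAGE_PROBS)
    age = rng.gamma(shape=2.0, scale=12.0, size=n)  # months at diagnosis

    # latent high-risk group: the top (1 - threshold_quantile) of patients
    high_risk = rng.random(n) < (1 - config.threshold_quantile)

    age_z = (age - age.mean()) / max(age.std(), 1e-12)
    log_hazard = (
        np.log(config.baseline_hazard)
        + config.log_hazard_ratio * high_risk
        + config.stage4_log_hr * (stage == "4")
        + config.age_log_hr * age_z
    )
    rates = np.exp(log_hazard)
    event_times = rng.exponential(1.0 / rates)
    horizon = _calibrate_censor_horizon(rates, config.censor_rate)
    censor_times = (
        rng.uniform(0, horizon, size=n) if np.isfinite(horizon) else np.full(n, np.inf)
    )
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)
    os_time = np.maximum(os_time, 1e-6)

    baseline = rng.normal(8.0, 1.0, size=m)  # per-gene log2 baseline intensity
    X = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(m, n))

    link = high_risk if config.expression_link == "latent" else os_event.astype(bool)
    X[: config.n_prognostic, :] += (
        config.effect_size * directions[:, None] * link[None, :]
    )
    lo = config.n_prognostic
    X[lo : lo + n_mycn_genes, :] += config.mycn_confound * mycn[None, :]

    matrix = pd.DataFrame(X, index=genes, columns=samples)
    annotations = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "mycn": mycn.astype(int),
            "stage": stage,
            "age": age,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    dataset = ExpressionDataset(matrix, annotations, dataset_id="sim_cohort")

    true_cutpoints = {
        g: float(baseline[i] + (config.effect_size / 2 if directions[i] > 0 else -config.effect_size / 2))
        for i, g in enumerate(prognostic)
    }
    truth = {
        "prognostic_genes": list(prognostic),
        "directions": {
            g: ("up" if d > 0 else "down") for g, d in zip(prognostic, directions)
        },
        "true_cutpoints": true_cutpoints,
        "threshold_quantile": config.threshold_quantile,
        "mycn_genes": list(mycn_genes),
        "high_risk": dict(zip(samples, high_risk.astype(int).tolist())),
    }
    return dataset, truth


def simulate_cellline_experiment(
    config: CellLineSimConfig,
) -> tuple[ExpressionDataset, dict]:
    """Simulate a normoxia/hypoxia experiment across cell lines.

    Expression = gene baseline + line random intercept + hypoxia effect for
    responsive genes + small MYCN / growth-pattern fixed effects + noise.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_CELLLINE])
    m = config.n_genes
    genes = _gene_ids(m)
    responsive = genes[: config.n_hypoxia_responsive]
    directions = np.where(
        np.arange(config.n_hypoxia_responsive) % 2 == 0, 1.0, -1.0
    )

    lines = [f"LINE{i:02d}" for i in range(config.n_lines)]
    if config.mycn_lines is None:
        # every third line, deliberately out of phase with the alternating
        # growth pattern so MYCN and growth are not collinear
        mycn_lines = set(range(0, config.n_lines, 3))
    else:
        mycn_lines = set(config.mycn_lines)
    growth = ["N" if i % 2 == 0 else "S" for i in range(config.n_lines)]

    rows = []
    for i, line in enumerate(lines):
        for cond in ("normoxia", "hypoxia"):
            for rep in range(config.n_replicates_per_condition):
                rows.append(
                    {
                        "sample_id": f"{line}_{cond}_{rep}",
                        "condition": cond,
                        "line": line,
                        "mycn": int(i in mycn_lines),
                        "growth_pattern": growth[i],
                    }
                )
    annotations = pd.DataFrame(rows).set_index("sample_id")
    n = len(annotations)

    baseline = rng.normal(8.0, 1.0, size=m)
    line_intercepts = rng.normal(0.0, config.line_sd, size=(m, config.n_lines))
    line_idx = np.array([lines.index(l) for l in annotations["line"]])
    hyp = (annotations["condition"] == "hypoxia").to_numpy()
    mycn = annotations["mycn"].to_numpy()
    growth_s = (annotations["growth_pattern"] == "S").to_numpy()

    X = baseline[:, None] + line_intercepts[:, line_idx]
    X += rng.normal(0.0, config.noise_sd, size=(m, n))
    X[: config.n_hypoxia_responsive, :] += (
        config.hypoxia_effect * directions[:, None] * hyp[None, :]
    )
    X += config.mycn_effect * mycn[None, :]
    X += config.growth_effect * growth_s[None, :]

    matrix = pd.DataFrame(X, index=genes, columns=annotations.index)
    dataset = ExpressionDataset(matrix, annotations, dataset_id="sim_cellline")
    truth = {
        "hypoxia_genes": list(responsive),
        "directions": {
            g: ("up" if d > 0 else "down") for g, d in zip(responsive, directions)
        },
        "hypoxia_effect": config.hypoxia_effect,
    }
    return dataset, truth


def simulate_qpcr_plate(config: QPCRSimConfig) -> pd.DataFrame:
    """Simulate a Ct table (gene, condition, replicate, ct).

    The expected ΔΔCt of gene g equals −true_log2_fold(g); the reference
    gene's Ct is unaffected by the oxygen condition. An optional per-(condition,
    replicate) plate offset shifts every gene including the reference, which
    replicate-paired ΔCt normalization cancels exactly.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_QPCR])
    all_genes = list(config.genes)
    if config.reference_gene not in all_genes:
        all_genes = all_genes + [config.reference_gene]
    folds = dict(zip(config.genes, config.true_log2_fold))
    folds[config.reference_gene] = 0.0
    base_ct = {g: float(rng.uniform(20, 28)) for g in all_genes}
    base_ct[config.reference_gene] = 16.0

    rows = []
    for cond in ("normoxia", "hypoxia"):
        for rep in range(config.n_replicates):
            offset = (
                rng.normal(0, config.plate_offset_sd)
                if config.plate_offset_sd > 0
                else 0.0
            )
            for g in all_genes:
                ct = base_ct[g] + offset
                if cond == "hypoxia":
                    ct -= folds[g]  # higher expression -> fewer cycles
                if config.ct_noise_sd > 0:
                    ct += rng.normal(0, config.ct_noise_sd)
                rows.append(
                    {"gene": g, "condition": cond, "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows)


def simulate_peak_fixtures(
    n_genes: int,
    flagged: set[str] | list[str],
    promoter_window: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BED fixtures: one TSS per gene, and differential peaks planted inside
    the promoter windows of exactly the flagged genes.

    Returns (gene_bed, peak_bed) DataFrames in 6-column BED layout with
    0-based half-open coordinates.
    """
    if promoter_window < 0:
        raise ValueError("promoter_window must be non-negative")
    genes = _gene_ids(n_genes)
    flagged = set(flagged)
    unknown = flagged - set(genes)
    if unknown:
        raise ValueError(f"flagged genes not in gene universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng([seed, _STREAM_PEAKS])

    spacing = max(10 * promoter_window, 10000)
    gene_rows = []
    for i, g in enumerate(genes):
        strand = "+" if i % 2 == 0 else "-"
        tss = spacing * (i + 1)
        # BED row is a 1-bp interval marking the TSS
        gene_rows.append(
            {
                "chrom": "chr1",
                "start": tss,
                "end": tss + 1,
                "name": g,
                "score": "0",
                "strand": strand,
            }
        )
    gene_bed = pd.DataFrame(gene_rows)

    peak_rows = []
    half_w = max(promoter_window // 2, 1)
    for j, g in enumerate(sorted(flagged)):
        row = gene_bed.loc[gene_bed["name"] == g].iloc[0]
        tss = int(row["start"])
        offset = int(rng.integers(-half_w, half_w)) if promoter_window > 0 else 0
        center = tss + offset
        width = int(rng.integers(100, 300))
        start = max(center - width // 2, 0)
        peak_rows.append(
            {
                "chrom": "chr1",
                "start": start,
                "end": start + width,
                "name": f"peak_{j}",
                "score": "0",
                "strand": ".",
            }
        )
    peak_bed = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return gene_bed, peak_bed


def simulate_proportional_hazards(
    n: int,
    log_hr: float = 0.7,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with a continuous covariate acting linearly on
    the log hazard: h(t | x) = baseline_hazard * exp(log_hr * x).

    Used to check Cox partial-likelihood estimation against a known truth.
    Returns columns x, os_time, os_event.
    """
    rng = np.random.default_rng([seed, _STREAM_COXSIM])
    x = rng.normal(0.0, 1.0, size=n)
    rates = baseline_hazard * np.exp(log_hr * x)
    t = rng.exponential(1.0 / rates)
    horizon = _calibrate_censor_horizon(rates, censor_rate)
    c = rng.uniform(0, horizon, size=n) if np.isfinite(horizon) else np.full(n, np.inf)
    return pd.DataFrame(
        {
            "x": x,
            "os_time": np.maximum(np.minimum(t, c), 1e-9),
            "os_event": (t <= c).astype(int),
        }
    )


def simulate_study(
    seed: int = 0,
    n_genes: int = 2000,
    n_planted: int = 25,
    effect_size: float = 1.0,
    hypoxia_effect: float = 2.0,
    expression_link: str = "event",
) -> tuple[dict[str, ExpressionDataset], dict]:
    """Simulate the full four-dataset study design with one shared set of
    planted hypoxia + prognosis genes.

    Two patient cohorts (n = 478 and n = 88, with the corresponding death
    fractions) and two cell-line experiments (a single-line RNA-seq-like
    triplicate design and an 11-line panel) share a gene universe; the
    first ``n_planted`` genes are planted as outcome-associated in both
    cohorts and hypoxia-responsive in both cell-line experiments with the
    same direction pattern. Cohorts default to the ``"event"`` expression
    link so the planted deceased-vs-survivor contrast equals
    ``effect_size``.

    Returns ({dataset_id: ExpressionDataset}, ground truth).
    """
    sub = np.random.SeedSequence(seed).generate_state(8) % (2**31 - 1)
    cohort1, truth1 = simulate_patient_cohort(
        CohortSimConfig(
            n_genes=n_genes, n_prognostic=n_planted, effect_size=effect_size,
            expression_link=expression_link, seed=int(sub[0]),
        )
    )
    cohort2, truth2 = simulate_patient_cohort(
        CohortSimConfig(
            n_patients=88, censor_rate=1 - 33 / 88, mycn_fraction=16 / 88,
            n_genes=n_genes, n_prognostic=n_planted, effect_size=effect_size,
            expression_link=expression_link, seed=int(sub[1]),
        )
    )
    # experiment 1 emulates deep RNA-seq of a single homogeneous cell line:
    # far lower residual noise than heterogeneous tumor arrays, and enough
    # replicates that per-gene OLS has the effective degrees of freedom a
    # dispersion-sharing RNA-seq caller achieves with triplicates
    cell1, ctruth1 = simulate_cellline_experiment(
        CellLineSimConfig(
            n_lines=1, n_replicates_per_condition=6, line_sd=0.0,
            noise_sd=0.15, n_genes=n_genes, n_hypoxia_responsive=n_planted,
            hypoxia_effect=hypoxia_effect, seed=int(sub[2]),
        )
    )
    cell2, ctruth2 = simulate_cellline_experiment(
        CellLineSimConfig(
            n_genes=n_genes, n_hypoxia_responsive=n_planted,
            hypoxia_effect=hypoxia_effect, seed=int(sub[3]),
        )
    )
    cohort1.dataset_id, cohort2.dataset_id = "cohort1", "cohort2"
    cell1.dataset_id, cell2.dataset_id = "cellline1", "cellline2"
    datasets = {
        "cohort1": cohort1,
        "cohort2": cohort2,
        "cellline1": cell1,
        "cellline2": cell2,
    }
    truth = {
        "planted_genes": truth1["prognostic_genes"],
        "directions": truth1["directions"],
        "cohort_truths": {"cohort1": truth1, "cohort2": truth2},
        "cellline_truths": {"cellline1": ctruth1, "cellline2": ctruth2},
    }
    return datasets, truth


def write_cohort(
    dataset: ExpressionDataset, truth: dict, outdir: str | Path, prefix: str
) -> dict[str, Path]:
    """Write expression TSV, clinical TSV and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / f"{prefix}_expression.tsv",
        "clinical": outdir / f"{prefix}_clinical.tsv",
        "truth": outdir / f"{prefix}_truth.json",
    }
    write_expression_tsv(dataset.matrix, paths["expression"])
    write_clinical_tsv(dataset.sample_annotations, paths["clinical"])
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def write_cellline(
    dataset: ExpressionDataset, truth: dict, outdir: str | Path, prefix: str
) -> dict[str, Path]:
    return write_cohort(dataset, truth, outdir, prefix)
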