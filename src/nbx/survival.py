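"""Sliding-window survival cutpoint scanning, Cox modeling, and the
DEG-prognosis permutation test.

For each gene, patients are dichotomized into high/low expression at every
admissible threshold: thresholds step one patient at a time over the order
statistics of expression, and a threshold is admissible only if both arms
retain at least a minimum fraction of patients (default 2%). A two-group
log-rank test is evaluated at every threshold. Because the per-gene minimum
p over thresholds is anti-conservative, multiple-testing correction pools
*all* (gene, threshold) p-values from the dataset into a single q-value
computation; the per-gene minimum q is the reported value and the threshold
achieving it is the best cutpoint.

The log-rank statistic is computed in closed form over suffix sums of
at-risk and event indicator matrices, which makes the full scan of every
threshold for every gene a handful of matrix operations per gene.

Cox proportional-hazards fits (univariate, and multivariate with MYCN
status, INSS stage and age at diagnosis) delegate to lifelines.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset
from .diffexpr import compute_qvalues
from .integrate import PermutationResult

__all__ = [
    "logrank_test",
    "cutpoint_scan",
    "scan_all_genes",
    "cox_fit",
    "cox_scan",
    "deg_survival_permutation",
    "CoxFit",
]

log = logging.getLogger(__name__)

STAGE_LEVELS = ["1", "2", "3", "4", "4S"]


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(
    times1, events1, times2, events2
) -> tuple[float, float]:
    """Standard two-group log-rank test (1 df chi-square).

    At every distinct event time the observed group-1 events are compared to
    their hypergeometric expectation given the at-risk counts; ties use the
    conditional (hypergeometric) variance. Returns (statistic, p).
    """
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be nonempty")
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group1 = np.concatenate([np.ones(len(t1), bool), np.zeros(len(t2), bool)])
    if events.sum() == 0:
        warnings.warn("no events in either group; log-rank p = 1")
        return 0.0, 1.0

    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        d_j = int(((times == t) & (events == 1)).sum())
        n1_j = int((at_risk & group1).sum())
        d1_j = int(((times == t) & (events == 1) & group1).sum())
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += (
                d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
            )
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# cutpoint scan
# ---------------------------------------------------------------------------

def _scan_one_gene(
    x: np.ndarray, times: np.ndarray, events: np.ndarray, min_per_side: int
) -> pd.DataFrame:
    """All admissible cutpoints for one gene with log-rank p at each.

    Samples with expression equal to a threshold go to the low group (high
    means expression strictly above the threshold; thresholds are midpoints
    between consecutive distinct order statistics).
    """
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    xs, ts, es = x[order], times[order], events[order]

    cand = [
        r
        for r in range(min_per_side, n - min_per_side + 1)
        if xs[r - 1] < xs[r]
    ]
    empty = pd.DataFrame(columns=["cutpoint", "p", "statistic", "n_low", "n_high"])
    if not cand:
        return empty
    if events.sum() == 0:
        warnings.warn("no events; all log-rank p = 1")
        return pd.DataFrame(
            {
                "cutpoint": [(xs[r - 1] + xs[r]) / 2 for r in cand],
                "p": 1.0,
                "statistic": 0.0,
                "n_low": cand,
                "n_high": [n - r for r in cand],
            }
        )

    event_times = np.unique(ts[es == 1])
    A = ts[None, :] >= event_times[:, None]  # at-risk (J x n)
    D = (es[None, :] == 1) & (ts[None, :] == event_times[:, None])
    n_j = A.sum(axis=1).astype(float)
    d_j = D.sum(axis=1).astype(float)
    # suffix sums over expression rank: col r = contribution of high group
    suffA = np.cumsum(A[:, ::-1], axis=1)[:, ::-1].astype(float)
    suffD = np.cumsum(D[:, ::-1], axis=1)[:, ::-1].astype(float)

    ranks = np.array(cand)
    n1 = suffA[:, ranks]  # J x R at-risk in high group
    d1 = suffD[:, ranks]
    frac = n1 / n_j[:, None]
    O = d1.sum(axis=0)
    E = (d_j[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = (
            d_j[:, None]
            * frac
            * (1 - frac)
            * ((n_j - d_j) / np.maximum(n_j - 1, 1.0))[:, None]
        )
    V = v_terms.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        statistic = np.where(V > 0, (O - E) ** 2 / V, 0.0)
    p = np.where(V > 0, stats.chi2.sf(statistic, df=1), 1.0)
    return pd.DataFrame(
        {
            "cutpoint": (xs[ranks - 1] + xs[ranks]) / 2,
            "p": p,
            "statistic": statistic,
            "n_low": ranks,
            "n_high": n - ranks,
        }
    )


def cutpoint_scan(
    expression,
    survival: pd.DataFrame,
    min_fraction: float = 0.02,
) -> pd.DataFrame:
    """Sliding-window dichotomization of one gene.

    Every threshold that leaves at least ``ceil(min_fraction * n)`` patients
    in each arm is evaluated with a log-rank test. Returns a DataFrame of
    (cutpoint, p, statistic, n_low, n_high); empty (gene not scannable) for
    constant expression.
    """
    x = np.asarray(expression, dtype=float)
    if not (0 < min_fraction < 0.5):
        raise ValueError("min_fraction must lie in (0, 0.5)")
    n = len(x)
    if n != len(survival):
        raise ValueError("expression and survival lengths differ")
    min_per_side = max(int(math.ceil(min_fraction * n)), 1)
    return _scan_one_gene(
        x,
        survival["os_time"].to_numpy(dtype=float),
        survival["os_event"].to_numpy(dtype=int),
        min_per_side,
    )


def scan_all_genes(
    data: ExpressionDataset,
    min_fraction: float = 0.02,
    genes: list[str] | None = None,
    pi0: float = 1.0,
    keep_details: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Cutpoint-scan every gene and q-correct jointly across all
    (gene, window) tests.

    All per-window p-values from all genes are pooled into one q-value
    computation (pi0 = 1 by default: minimum-p selection invalidates
    smoother-based pi0 estimates on the pooled set). Per gene the minimum q
    and the threshold achieving it are reported; output is ranked by min_q.

    Returns a summary DataFrame (gene, n_windows, best_cutpoint, min_p,
    min_q, n_low, n_high) and, when ``keep_details`` is set, a dict of the
    per-gene window tables with their q column.
    """
    ann = data.sample_annotations
    for col in ("os_time", "os_event"):
        if col not in ann.columns:
            raise ValueError(f"survival annotations need {col!r}")
    surv = ann[["os_time", "os_event"]]
    gene_list = list(genes) if genes is not None else list(data.matrix.index)
    missing = set(gene_list) - set(data.matrix.index)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}")

    tables: dict[str, pd.DataFrame] = {}
    for g in gene_list:
        tables[g] = cutpoint_scan(
            data.matrix.loc[g].to_numpy(dtype=float), surv, min_fraction
        )

    all_p = np.concatenate(
        [t["p"].to_numpy() for t in tables.values() if len(t)] or [np.array([])]
    )
    all_q = compute_qvalues(all_p, pi0=pi0) if len(all_p) else np.array([])
    pos = 0
    rows = []
    for g in gene_list:
        t = tables[g]
        if len(t) == 0:
            rows.append(
                {
                    "gene": g,
                    "n_windows": 0,
                    "best_cutpoint": np.nan,
                    "min_p": np.nan,
                    "min_q": np.nan,
                    "n_low": np.nan,
                    "n_high": np.nan,
                    "flag": "not_scannable",
                }
            )
            continue
        q = all_q[pos : pos + len(t)]
        pos += len(t)
        t = t.assign(q=q)
        tables[g] = t
        best = t["p"].idxmin()  # first minimum -> deterministic
        rows.append(
            {
                "gene": g,
                "n_windows": len(t),
                "best_cutpoint": float(t.loc[best, "cutpoint"]),
                "min_p": float(t.loc[best, "p"]),
                "min_q": float(t["q"].min()),
                "n_low": int(t.loc[best, "n_low"]),
                "n_high": int(t.loc[best, "n_high"]),
                "flag": "",
            }
        )
    summary = (
        pd.DataFrame(rows)
        .sort_values(["min_q", "gene"], kind="mergesort", na_position="last")
        .reset_index(drop=True)
    )
    if keep_details:
        return summary, tables
    return summary


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    gene: str
    model: str  # "univariate" | "multivariate"
    hazard_ratio: float
    log_hr: float
    se: float
    p: float
    converged: bool
    flag: str = ""
    covariate_estimates: dict | None = None


def _cox_design(
    expression, survival: pd.DataFrame, covariates: list[str] | None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "expression": np.asarray(expression, dtype=float),
            "os_time": survival["os_time"].to_numpy(dtype=float),
            "os_event": survival["os_event"].to_numpy(dtype=int),
        }
    )
    if covariates:
        if "mycn" in covariates:
            df["mycn"] = survival["mycn"].to_numpy(dtype=float)
        if "age" in covariates:
            df["age"] = survival["age"].to_numpy(dtype=float)
        if "stage" in covariates:
            stage = pd.Categorical(
                survival["stage"].astype(str), categories=STAGE_LEVELS
            )
            dummies = pd.get_dummies(stage, prefix="stage", dtype=float)
            # stage 1 is the reference level
            df = pd.concat(
                [df, dummies.drop(columns="stage_1").set_index(df.index)], axis=1
            )
    return df


def cox_fit(
    expression,
    survival: pd.DataFrame,
    covariates: list[str] | None = None,
    gene: str = "gene",
    min_events: int = 10,
) -> CoxFit:
    """Cox proportional-hazards fit for one gene's expression.

    ``covariates=None`` fits the univariate model; ``["mycn", "stage",
    "age"]`` the multivariate model with stage as unordered categorical
    (stage 1 reference). Efron tie handling, convergence by lifelines'
    Newton-Raphson. Non-convergence or a non-identifiable design yields a
    flagged result rather than an exception.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    n_events = int(np.asarray(survival["os_event"]).sum())
    if n_events < min_events:
        raise ValueError(
            f"only {n_events} events; need at least {min_events} for a Cox fit"
        )
    model = "multivariate" if covariates else "univariate"
    df = _cox_design(expression, survival, covariates)
    if float(np.std(df["expression"])) == 0.0:
        return CoxFit(gene, model, np.nan, np.nan, np.nan, np.nan, False,
                      flag="constant_expression")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_time", event_col="os_event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        return CoxFit(
            gene, model, np.nan, np.nan, np.nan, np.nan, False,
            flag=f"non_identifiable_or_divergent: {type(exc).__name__}",
        )
    beta = float(cph.params_["expression"])
    se = float(cph.standard_errors_["expression"])
    p = float(cph.summary.loc["expression", "p"])
    covar = {
        k: float(v) for k, v in cph.params_.items() if k != "expression"
    }
    flag = ""
    if se > 100 or abs(beta) > 50:  # effectively separated / unstable
        flag = "unstable_fit"
    return CoxFit(
        gene=gene,
        model=model,
        hazard_ratio=float(np.exp(beta)),
        log_hr=beta,
        se=se,
        p=p,
        converged=True,
        flag=flag,
        covariate_estimates=covar,
    )


def cox_scan(
    data: ExpressionDataset,
    genes: list[str] | None = None,
    covariates: list[str] | None = None,
    min_events: int = 10,
    pi0: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Cox fits with q-values across genes.

    Non-converged fits are flagged and excluded from the q computation
    (logged count). Returns gene, hazard_ratio, log_hr, se, p, q, flag.
    """
    gene_list = list(genes) if genes is not None else list(data.matrix.index)
    surv = data.sample_annotations
    fits = [
        cox_fit(
            data.matrix.loc[g].to_numpy(dtype=float),
            surv,
            covariates=covariates,
            gene=g,
            min_events=min_events,
        )
        for g in gene_list
    ]
    df = pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "hazard_ratio": [f.hazard_ratio for f in fits],
            "log_hr": [f.log_hr for f in fits],
            "se": [f.se for f in fits],
            "p": [f.p for f in fits],
            "converged": [f.converged for f in fits],
            "flag": [f.flag for f in fits],
        }
    )
    ok = df["converged"] & df["p"].notna()
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("excluding %d non-converged Cox fits from q computation", n_bad)
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = compute_qvalues(df.loc[ok, "p"].to_numpy(), pi0=pi0)
    df["q"] = q
    return df


# ---------------------------------------------------------------------------
# DEG-prognosis permutation test
# ---------------------------------------------------------------------------

def deg_survival_permutation(
    deg_lists: tuple[list[str], list[str]],
    prognostic_sets: tuple[set[str], set[str]],
    observed: tuple[int, int],
    draw_sizes: tuple[int, int] = (8, 9),
    n_permutations: int = 100_000,
    seed: int = 0,
) -> tuple[PermutationResult, PermutationResult]:
    """Can candidate-gene prognosis arise by chance among DEGs?

    For each cohort, a replicate draws ``draw_sizes[c]`` genes without
    replacement from that cohort's DEG list and counts how many are
    prognostic (survival FDR < 1%) in *both* cohorts. The upper-tail
    p-value against the observed count is reported separately per cohort,
    following the count / n_permutations rule.
    """
    prog_both = set(prognostic_sets[0]) & set(prognostic_sets[1])
    results = []
    for c, (deg_list, k, obs) in enumerate(
        zip(deg_lists, draw_sizes, observed)
    ):
        deg_list = list(deg_list)
        if k > len(deg_list):
            raise ValueError(
                f"draw size {k} exceeds cohort {c + 1} DEG list ({len(deg_list)})"
            )
        indicator = np.array([g in prog_both for g in deg_list], dtype=np.int64)
        rng = np.random.default_rng([seed, c])
        counts_hist = np.zeros(k + 1, dtype=np.int64)
        done = 0
        while done < n_permutations:
            chunk = min(4096, n_permutations - done)
            keys = rng.random((chunk, len(deg_list)))
            chosen = np.argpartition(keys, k - 1, axis=1)[:, :k]
            counts = indicator[chosen].sum(axis=1)
            counts_hist += np.bincount(counts, minlength=k + 1)
            done += chunk
        if obs <= 0:
            n_extreme = n_permutations  # every replicate overlap is >= 0
        elif obs > k:
            n_extreme = 0
        else:
            n_extreme = int(counts_hist[obs:].sum())
        results.append(
            PermutationResult(
                observed=obs,
                n_permutations=n_permutations,
                n_as_extreme=n_extreme,
                p=n_extreme / n_permutations,
                p_add_one=(n_extreme + 1) / (n_permutations + 1),
                seed=seed,
                null_distribution={
                    int(i): int(v) for i, v in enumerate(counts_hist) if v
                },
            )
        )
    return tuple(results)
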