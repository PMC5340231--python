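"""Covariate-adjusted differential expression and the dual DEG filter.

Patient cohorts: per-feature ordinary least squares of log2 expression on
outcome status with MYCN amplification as a fixed effect
(``y ~ status + MYCN``), vectorized across features since the design matrix
is shared. Cell-line experiments: per-feature Gaussian linear mixed model
with fixed effects for oxygen condition, MYCN status and N/S growth pattern
and a random intercept per cell line
(``y ~ hypoxia + MYCN + growth + (1 | line)``).

Features are collapsed probe -> gene by most significant p-value, false
discovery rates come from Storey q-values, and a gene is called
differentially expressed when its q-value is below the FDR ceiling *and*
its log2 fold change lies in the top or bottom decile of the fold-change
distribution (both thresholds configurable; defaults FDR < 0.01, decile 10%).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DEGTable, ExpressionDataset

__all__ = [
    "fit_survivor_model",
    "fit_hypoxia_model",
    "collapse_probes",
    "compute_qvalues",
    "estimate_pi0",
    "select_degs",
    "build_deg_table",
    "ingest_external_deg_table",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shared vectorized OLS
# ---------------------------------------------------------------------------

def _vectorized_ols(Y: np.ndarray, X: np.ndarray, coef_index: int):
    """OLS of every row of Y on the shared design X.

    Returns (coef, se, p, flags). Zero-variance rows get coef 0, p 1 and a
    ``zero_variance`` flag so downstream filters behave deterministically.
    A rank-deficient design yields flagged rows rather than a crash.
    """
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    m = Y.shape[0]
    if rank < k:
        return (
            np.zeros(m),
            np.full(m, np.nan),
            np.ones(m),
            np.array(["singular_design"] * m, dtype=object),
        )
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # k x n
    beta = Y @ H.T  # m x k
    resid = Y - beta @ X.T
    dof = n - k
    s2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(s2, 0.0)[:, None] * np.diag(XtX_inv)[None, :])

    coef = beta[:, coef_index]
    coef_se = se[:, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / coef_se
    p = 2 * stats.t.sf(np.abs(t), dof)

    flags = np.array([""] * m, dtype=object)
    degenerate = s2 < 1e-24
    if degenerate.any():
        coef = coef.copy()
        coef[degenerate] = 0.0
        p[degenerate] = 1.0
        flags[degenerate] = "zero_variance"
    p = np.where(np.isnan(p), 1.0, p)
    return coef, coef_se, p, flags


def _check_binary_levels(series: pd.Series, name: str, min_per_level: int = 2):
    counts = series.value_counts()
    for level, count in counts.items():
        if count < min_per_level:
            raise ValueError(
                f"annotation {name!r} level {level!r} has {count} sample(s); "
                f"need at least {min_per_level}"
            )


def fit_survivor_model(data: ExpressionDataset) -> pd.DataFrame:
    """Per-feature OLS of expression on outcome status adjusting for MYCN.

    The status coefficient is the log2 fold change (deceased - survivor)
    because the inputs are log2-scale. Returns a DataFrame indexed by
    feature with columns ``log2fc``, ``se``, ``p``, ``flag``.
    """
    ann = data.sample_annotations
    if "os_event" not in ann.columns or "mycn" not in ann.columns:
        raise ValueError("cohort annotations need os_event and mycn columns")
    status = ann["os_event"].astype(float).to_numpy()
    mycn = ann["mycn"].astype(float).to_numpy()
    _check_binary_levels(ann["os_event"], "os_event")

    if np.std(mycn) > 0:
        X = np.column_stack([np.ones_like(status), status, mycn])
    else:
        log.warning("MYCN status is constant; dropping it from the model")
        X = np.column_stack([np.ones_like(status), status])
    Y = data.matrix.to_numpy(dtype=float)
    coef, se, p, flags = _vectorized_ols(Y, X, coef_index=1)
    return pd.DataFrame(
        {"log2fc": coef, "se": se, "p": p, "flag": flags}, index=data.matrix.index
    )


def _mixedlm_single_feature(y, X, groups, df_t):
    """One REML random-intercept fit; returns (coef, se, p, flag)."""
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        coef, se = float(fit.fe_params[1]), float(fit.bse_fe[1])
        if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
            raise ValueError("non-finite mixed-model estimate")
        p = 2 * stats.t.sf(abs(coef / se), df_t)
        flag = "" if fit.converged else "not_converged"
        return coef, se, p, flag
    except Exception:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        s2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(max(s2 * xtx_inv[1, 1], 0.0)))
        if se == 0:
            return 0.0, np.nan, 1.0, "fallback_ols_zero_variance"
        t = beta[1] / se
        return beta[1], se, 2 * stats.t.sf(abs(t), dof), "fallback_ols"


def fit_hypoxia_model(data: ExpressionDataset) -> pd.DataFrame:
    """Per-feature mixed model: hypoxia + MYCN + growth pattern fixed,
    random intercept per cell line.

    The response is normalized log intensity, so the model is a Gaussian
    linear mixed model (identity link). With a single cell line the random
    intercept is unidentifiable and the fit falls back to fixed-effects OLS
    with a logged warning. Wald p-values use a t reference with
    within-cluster (containment) degrees of freedom
    ``n - rank(X) - (n_lines - 1)``.

    Returns a DataFrame indexed by feature with ``log2fc`` (hypoxia
    coefficient), ``se``, ``p``, ``flag``.
    """
    ann = data.sample_annotations
    for col in ("condition", "line"):
        if col not in ann.columns:
            raise ValueError(f"cell-line annotations need a {col!r} column")
    conditions = set(ann["condition"])
    if len(conditions) < 2:
        raise ValueError(f"need both oxygen conditions, found only {conditions}")

    hyp = (ann["condition"] == "hypoxia").astype(float).to_numpy()
    cols = [np.ones_like(hyp), hyp]
    names = ["intercept", "hypoxia"]
    for col, make in (
        ("mycn", lambda s: s.astype(float).to_numpy()),
        ("growth_pattern", lambda s: (s == "S").astype(float).to_numpy()),
    ):
        if col in ann.columns:
            v = make(ann[col])
            if np.std(v) > 0:  # drop constant covariates
                cols.append(v)
                names.append(col)
    X = np.column_stack(cols)
    # prune collinear covariates (keep intercept + hypoxia) so the fixed
    # design is full rank
    while np.linalg.matrix_rank(X) < X.shape[1] and X.shape[1] > 2:
        log.warning("dropping collinear covariate %r from hypoxia model",
                    names[-1])
        X = X[:, :-1]
        names.pop()
    Y = data.matrix.to_numpy(dtype=float)
    lines = ann["line"].to_numpy()
    n_lines = len(set(lines))

    if n_lines < 2:
        log.warning(
            "only one cell line present; falling back to fixed-effects OLS"
        )
        coef, se, p, flags = _vectorized_ols(Y, X, coef_index=1)
        flags = np.where(flags == "", "single_line_ols", flags)
        return pd.DataFrame(
            {"log2fc": coef, "se": se, "p": p, "flag": flags},
            index=data.matrix.index,
        )

    df_t = max(Y.shape[1] - np.linalg.matrix_rank(X) - (n_lines - 1), 1)
    out = np.empty((Y.shape[0], 3))
    flags = []
    for i in range(Y.shape[0]):
        coef, se, p, flag = _mixedlm_single_feature(Y[i], X, lines, df_t)
        out[i] = (coef, se, p)
        flags.append(flag)
    n_fallback = sum(1 for f in flags if f.startswith("fallback"))
    if n_fallback:
        log.warning("mixed model fell back to OLS for %d features", n_fallback)
    return pd.DataFrame(
        {"log2fc": out[:, 0], "se": out[:, 1], "p": out[:, 2], "flag": flags},
        index=data.matrix.index,
    )


# ---------------------------------------------------------------------------
# probe collapse, q-values, DEG selection
# ---------------------------------------------------------------------------

def collapse_probes(table: pd.DataFrame, feature_map: pd.Series) -> pd.DataFrame:
    """Collapse per-probe results to per-gene: keep the probe with the most
    significant p-value.

    Ties break by smallest p, then largest \\|log2fc\\|, then lexicographically
    smallest probe ID. Probes absent from the map are dropped with a logged
    count. Returns a DataFrame indexed by gene with a ``source_probe`` column.
    """
    if feature_map is None or len(feature_map) == 0:
        raise ValueError("empty feature map")
    df = table.copy()
    df["source_probe"] = df.index.astype(str)
    mapped = df.index.isin(feature_map.index)
    n_dropped = int((~mapped).sum())
    if n_dropped:
        log.info("dropping %d probes without a gene mapping", n_dropped)
    df = df.loc[mapped]
    df["gene"] = feature_map.reindex(df.index).to_numpy()
    df = df.sort_values(
        by=["p", "log2fc", "source_probe"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
    )
    best = df.groupby("gene", sort=True).head(1).set_index("gene").sort_index()
    return best


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a lambda
    grid, smoothed with a cubic spline, and read off at the largest lambda;
    the result is clamped to (0, 1]. With fewer than 100 p-values, or an
    unstable estimate, returns the conservative pi0 = 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m < 100:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array(
        [(p > lam).sum() / (m * (1 - lam)) for lam in lambdas]
    )
    try:
        from scipy.interpolate import UnivariateSpline

        spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:  # pragma: no cover - spline failure
        pi0 = float(pi0_lambda[-1])
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def compute_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    q(i) = min_{j >= i} pi0 * m * p(j) / j over p sorted ascending, returned
    in the input order. With ``pi0=1`` this reduces exactly to
    Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_degs(
    table: pd.DataFrame,
    universe_size: int | None = None,
    dataset_id: str = "dataset",
    fdr_max: float = 0.01,
    fc_decile: float = 0.10,
    fc_decile_scope: str = "universe",
    universe: list[str] | None = None,
) -> DEGTable:
    """Dual-criterion DEG selection: q below ``fdr_max`` AND log2 fold
    change in the top or bottom ``fc_decile`` of the fold-change
    distribution.

    ``fc_decile_scope`` chooses whether the decile thresholds are computed
    over all tested genes (``"universe"``, default) or only over the
    FDR-significant subset (``"significant"``). Deciles are of signed
    log2fc: the top decile and the bottom decile are thresholded separately.

    ``table`` must be indexed by gene with columns log2fc, p, q.
    """
    if not (0 < fc_decile < 0.5):
        raise ValueError("fc_decile must lie in (0, 0.5)")
    if fc_decile_scope not in ("universe", "significant"):
        raise ValueError("fc_decile_scope must be 'universe' or 'significant'")
    required = {"log2fc", "p", "q"}
    if not required <= set(table.columns):
        raise ValueError(f"table missing columns: {sorted(required - set(table.columns))}")

    sig = table["q"] < fdr_max
    scope = table if fc_decile_scope == "universe" else table.loc[sig]
    if len(scope) == 0:
        selected = table.iloc[0:0]
    else:
        fc = scope["log2fc"].to_numpy()
        hi = np.quantile(fc, 1 - fc_decile)
        lo = np.quantile(fc, fc_decile)
        in_tail = (table["log2fc"] >= hi) | (table["log2fc"] <= lo)
        selected = table.loc[sig & in_tail]

    records = selected.reset_index(names="gene").copy()
    zero_fc = records["log2fc"] == 0
    if zero_fc.any():
        log.warning("%d selected genes have log2fc == 0; direction set to 'up'",
                    int(zero_fc.sum()))
    records["direction"] = np.where(records["log2fc"] < 0, "down", "up")
    cols = ["gene", "log2fc", "p", "q", "direction"]
    if "source_probe" in records.columns:
        cols.append("source_probe")
    return DEGTable(
        records=records[cols].sort_values("q", kind="mergesort").reset_index(drop=True),
        universe_size=universe_size if universe_size is not None else len(table),
        dataset_id=dataset_id,
        universe=universe if universe is not None else list(table.index.astype(str)),
    )


def build_deg_table(
    data: ExpressionDataset,
    kind: str = "cohort",
    fdr_max: float = 0.01,
    fc_decile: float = 0.10,
    pi0: float | None = None,
    fc_decile_scope: str = "universe",
) -> DEGTable:
    """Full per-dataset DE pass: model fit, optional probe collapse,
    q-values, dual-criterion selection."""
    if kind == "cohort":
        fits = fit_survivor_model(data)
    elif kind == "cellline":
        fits = fit_hypoxia_model(data)
    else:
        raise ValueError("kind must be 'cohort' or 'cellline'")
    if data.feature_map is not None:
        fits = collapse_probes(fits, data.feature_map)
    fits = fits.copy()
    fits["q"] = compute_qvalues(fits["p"].to_numpy(), pi0=pi0)
    return select_degs(
        fits,
        universe_size=len(fits),
        dataset_id=data.dataset_id,
        fdr_max=fdr_max,
        fc_decile=fc_decile,
        fc_decile_scope=fc_decile_scope,
        universe=list(fits.index.astype(str)),
    )


def ingest_external_deg_table(
    path: str | Path,
    dataset_id: str | None = None,
    column_map: dict[str, str] | None = None,
    universe_size: int | None = None,
    fdr_max: float = 0.01,
    fc_decile: float = 0.10,
) -> DEGTable:
    """Ingest a pre-made differential-expression table (e.g. an RNA-seq DE
    caller's output) and apply the same dual selection criterion.

    The file must be tab-delimited with at least gene, log2fc and p (or q)
    columns; ``column_map`` renames source columns to these names. When a q
    column is present it is used verbatim; otherwise q-values are computed
    from p.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    if "gene" not in df.columns or "log2fc" not in df.columns:
        missing = {"gene", "log2fc"} - set(df.columns)
        raise ValueError(f"external DEG table missing columns: {sorted(missing)}")
    if "p" not in df.columns and "q" not in df.columns:
        raise ValueError("external DEG table missing columns: ['p' (or 'q')]")
    if "q" not in df.columns:
        df["q"] = compute_qvalues(df["p"].to_numpy())
    if "p" not in df.columns:
        df["p"] = df["q"]
    table = df.set_index("gene")[["log2fc", "p", "q"]]
    return select_degs(
        table,
        universe_size=universe_size if universe_size is not None else len(table),
        dataset_id=dataset_id or path.stem,
        fdr_max=fdr_max,
        fc_decile=fc_decile,
    )
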