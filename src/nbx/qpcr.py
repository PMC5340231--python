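"""Relative qRT-PCR quantification by the 2^-ddCt rule.

Each gene's cycle threshold (Ct) is normalized to a housekeeping reference
(beta-Actin in the validation experiments this emulates) within the same
replicate: dCt = Ct_gene - Ct_reference. The condition contrast is
ddCt = dCt_treated - dCt_control, the fold change is 2^-ddCt and the log2
fold is -ddCt. Significance of the condition contrast is a Welch t-test on
the per-replicate dCt values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RelativeExpression", "delta_delta_ct", "replicate_significance",
           "quantify_plate"]

log = logging.getLogger(__name__)

_REQUIRED = ["gene", "condition", "replicate", "ct"]


@dataclass
class RelativeExpression:
    gene: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float
    log2_fold: float
    p: float | None = None
    significant_up: bool | None = None


def _check_table(measurements: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in measurements.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = measurements["ct"].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and positive")


def _paired_delta_ct(
    measurements: pd.DataFrame, gene: str, reference_gene: str, condition: str
) -> np.ndarray:
    """Per-replicate dCt for one gene in one condition, pairing gene and
    reference within the same replicate index.

    Falls back to the condition-mean reference Ct (with a warning) when the
    replicate indices do not align; errors when the reference is missing
    for the condition entirely.
    """
    sub = measurements[measurements["condition"] == condition]
    g = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    r = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
    if len(g) == 0:
        raise ValueError(f"no measurements for gene {gene!r} in {condition!r}")
    if len(r) == 0:
        raise ValueError(
            f"missing reference {reference_gene!r} measurements in {condition!r}"
        )
    unmatched = g.index.difference(r.index)
    if len(unmatched) == 0:
        return (g - r.loc[g.index]).to_numpy(dtype=float)
    log.warning(
        "reference %r missing for (%s, replicate %s); using condition-mean "
        "reference Ct",
        reference_gene,
        condition,
        list(unmatched),
    )
    return (g - float(r.mean())).to_numpy(dtype=float)


def delta_delta_ct(
    measurements: pd.DataFrame,
    gene: str,
    reference_gene: str = "ACTB",
    treated: str = "hypoxia",
    control: str = "normoxia",
) -> RelativeExpression:
    """2^-ddCt relative quantification of one gene.

    dCt per condition is the mean over replicates of (Ct_gene - Ct_reference)
    paired by replicate; ddCt = dCt_treated - dCt_control;
    fold change = 2^-ddCt exactly.
    """
    _check_table(measurements)
    d_treated = _paired_delta_ct(measurements, gene, reference_gene, treated)
    d_control = _paired_delta_ct(measurements, gene, reference_gene, control)
    ddct = float(d_treated.mean() - d_control.mean())
    return RelativeExpression(
        gene=gene,
        delta_ct_treated=float(d_treated.mean()),
        delta_ct_control=float(d_control.mean()),
        delta_delta_ct=ddct,
        fold_change=float(2.0 ** (-ddct)),
        log2_fold=-ddct,
    )


def replicate_significance(
    measurements: pd.DataFrame,
    gene: str,
    reference_gene: str = "ACTB",
    treated: str = "hypoxia",
    control: str = "normoxia",
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Welch t-test on per-replicate dCt between conditions.

    Returns (p, significant_up); significant_up is true iff p < alpha and
    the log2 fold (treated vs control) is positive. Zero variance in both
    groups is guarded: identical dCt yields p = 1.
    """
    _check_table(measurements)
    d_treated = _paired_delta_ct(measurements, gene, reference_gene, treated)
    d_control = _paired_delta_ct(measurements, gene, reference_gene, control)
    if len(d_treated) < 2 or len(d_control) < 2:
        raise ValueError("need at least 2 replicates per condition for testing")
    if np.var(d_treated) == 0 and np.var(d_control) == 0:
        p = 1.0 if d_treated.mean() == d_control.mean() else 0.0
    else:
        p = float(stats.ttest_ind(d_treated, d_control, equal_var=False).pvalue)
    log2_fold = -(d_treated.mean() - d_control.mean())
    return p, bool(p < alpha and log2_fold > 0)


def quantify_plate(
    measurements: pd.DataFrame,
    reference_gene: str = "ACTB",
    treated: str = "hypoxia",
    control: str = "normoxia",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene relative quantification for every non-reference gene.

    Returns columns gene, delta_delta_ct, fold_change, log2_fold, p,
    significant_up, sorted by gene.
    """
    _check_table(measurements)
    genes = sorted(set(measurements["gene"]) - {reference_gene})
    rows = []
    for g in genes:
        rel = delta_delta_ct(measurements, g, reference_gene, treated, control)
        p, sig = replicate_significance(
            measurements, g, reference_gene, treated, control, alpha
        )
        rows.append(
            {
                "gene": g,
                "delta_delta_ct": rel.delta_delta_ct,
                "fold_change": rel.fold_change,
                "log2_fold": rel.log2_fold,
                "p": p,
                "significant_up": sig,
            }
        )
    return pd.DataFrame(rows)
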