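"""Multi-dataset signature integration.

Gene signatures from independent datasets (patient cohorts, cell-line
hypoxia experiments) are intersected by symbol with per-gene direction
bookkeeping; the size of the intersection is compared against a Monte-Carlo
null in which each dataset's signature is replaced by a uniform random
subset of the same size drawn from that dataset's own tested universe. For
two datasets on a common universe the null overlap is hypergeometric, which
serves as an analytic oracle. A generic hypergeometric over-representation
test covers gene-set (GO/pathway) enrichment, and a strand-aware promoter
window annotates genes with differential peaks from a BED file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import compute_qvalues

__all__ = [
    "SignatureSet",
    "OverlapReport",
    "PermutationResult",
    "intersect_signatures",
    "permutation_overlap_test",
    "exact_overlap_pvalue",
    "ora_enrichment",
    "annotate_genes_with_peaks",
]

log = logging.getLogger(__name__)

_CHUNK = 2048  # permutation replicates per vectorized batch


@dataclass
class SignatureSet:
    """A dataset's selected genes with directions, plus its tested universe."""

    dataset_id: str
    genes: dict[str, str]  # gene -> "up" | "down"
    universe: set[str]

    def __post_init__(self) -> None:
        bad = set(self.genes.values()) - {"up", "down"}
        if bad:
            raise ValueError(f"invalid directions: {sorted(bad)}")
        outside = set(self.genes) - self.universe
        if outside:
            raise ValueError(
                f"{len(outside)} signature genes outside the universe "
                f"(e.g. {sorted(outside)[:3]})"
            )

    @classmethod
    def from_deg_table(cls, table) -> "SignatureSet":
        universe = (
            set(table.universe)
            if table.universe is not None
            else set(table.records["gene"])
        )
        return cls(
            dataset_id=table.dataset_id,
            genes=table.directions(),
            universe=universe,
        )


@dataclass
class OverlapReport:
    member_sets: list[str]
    shared_genes: set[str]
    n_shared: int
    consistent_genes: set[str]
    n_direction_consistent: int
    directions: dict[str, str] = field(default_factory=dict)


@dataclass
class PermutationResult:
    """Monte-Carlo overlap null.

    ``p`` follows the count/n rule (number of permuted overlaps at least as
    large as observed, divided by the number of permutations), which can
    return exactly 0; ``p_add_one`` is the bias-guarded (count+1)/(n+1)
    companion estimator.
    """

    observed: int
    n_permutations: int
    n_as_extreme: int
    p: float
    p_add_one: float
    seed: int
    null_distribution: dict[int, int]

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "n_permutations": self.n_permutations,
            "n_as_extreme": self.n_as_extreme,
            "p": self.p,
            "p_add_one": self.p_add_one,
            "seed": self.seed,
            "null_mean": float(
                sum(k * v for k, v in self.null_distribution.items())
                / max(self.n_permutations, 1)
            ),
        }


def intersect_signatures(sets: list[SignatureSet]) -> OverlapReport:
    """Intersect k signatures by gene symbol.

    A shared gene is direction-consistent iff its direction is identical in
    every member set. Any empty signature empties the intersection (with a
    logged warning).
    """
    if len(sets) < 2:
        raise ValueError("need at least two signature sets")
    for s in sets:
        if not s.genes:
            log.warning("signature %s is empty; intersection is empty", s.dataset_id)
    shared = set.intersection(*(set(s.genes) for s in sets))
    consistent = {
        g for g in shared if len({s.genes[g] for s in sets}) == 1
    }
    directions = {g: sets[0].genes[g] for g in consistent}
    return OverlapReport(
        member_sets=[s.dataset_id for s in sets],
        shared_genes=shared,
        n_shared=len(shared),
        consistent_genes=consistent,
        n_direction_consistent=len(consistent),
        directions=directions,
    )


def _random_subset_membership(
    rng: np.random.Generator, n_reps: int, universe_idx: np.ndarray,
    size: int, n_union: int,
) -> np.ndarray:
    """Boolean (n_reps, n_union) membership of uniform random subsets of
    ``size`` drawn without replacement from universe_idx."""
    u = len(universe_idx)
    if size == 0:
        return np.zeros((n_reps, n_union), dtype=bool)
    keys = rng.random((n_reps, u))
    chosen = np.argpartition(keys, size - 1, axis=1)[:, :size] if size < u else (
        np.tile(np.arange(u), (n_reps, 1))
    )
    member = np.zeros((n_reps, n_union), dtype=bool)
    rows = np.repeat(np.arange(n_reps), chosen.shape[1])
    member[rows, universe_idx[chosen].ravel()] = True
    return member


def permutation_overlap_test(
    set_sizes: list[int],
    universes: list[set[str]],
    observed: int,
    n_permutations: int = 100_000,
    seed: int = 0,
    common_universe: bool = False,
) -> PermutationResult:
    """Monte-Carlo null for a k-way signature overlap.

    Each replicate draws, for every dataset, a uniform random gene subset of
    the observed signature size from that dataset's tested universe (without
    replacement), and counts the k-way intersection by symbol. The p-value is
    the fraction of replicates whose overlap is at least the observed count.

    ``common_universe=True`` first intersects the universes and samples all
    datasets from the shared gene space.
    """
    if len(set_sizes) != len(universes):
        raise ValueError("set_sizes and universes length mismatch")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if common_universe:
        shared = set.intersection(*[set(u) for u in universes])
        universes = [shared for _ in universes]
    for size, uni in zip(set_sizes, universes):
        if size > len(uni):
            raise ValueError(
                f"set size {size} exceeds universe size {len(uni)}"
            )

    union = sorted(set.union(*[set(u) for u in universes]))
    index = {g: i for i, g in enumerate(union)}
    n_union = len(union)
    universe_idx = [
        np.array(sorted(index[g] for g in uni), dtype=np.int64) for uni in universes
    ]

    rng = np.random.default_rng(seed)
    counts = np.zeros(min(set_sizes) + 1, dtype=np.int64)
    done = 0
    while done < n_permutations:
        chunk = min(_CHUNK, n_permutations - done)
        inter = np.ones((chunk, n_union), dtype=bool)
        for size, uidx in zip(set_sizes, universe_idx):
            inter &= _random_subset_membership(rng, chunk, uidx, size, n_union)
        overlap = inter.sum(axis=1)
        counts += np.bincount(overlap, minlength=len(counts))[: len(counts)]
        done += chunk

    n_as_extreme = int(counts[observed:].sum()) if observed <= min(set_sizes) else 0
    return PermutationResult(
        observed=observed,
        n_permutations=n_permutations,
        n_as_extreme=n_as_extreme,
        p=n_as_extreme / n_permutations,
        p_add_one=(n_as_extreme + 1) / (n_permutations + 1),
        seed=seed,
        null_distribution={int(k): int(v) for k, v in enumerate(counts) if v},
    )


def exact_overlap_pvalue(
    universe_size: int, k1: int, k2: int, observed: int
) -> float:
    """Exact hypergeometric upper tail P(X >= observed) for the overlap of
    two independent uniform random subsets of sizes k1 and k2 drawn from a
    common universe.

    The analytic two-set oracle for :func:`permutation_overlap_test`.
    """
    if k1 > universe_size or k2 > universe_size:
        raise ValueError("subset size exceeds universe size")
    if observed > min(k1, k2):
        warnings.warn("observed overlap exceeds min(k1, k2); returning p = 0")
        return 0.0
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, universe_size, k1, k2))


def ora_enrichment(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set against a
    named collection (e.g. a GMT of GO terms).

    Collection sets are intersected with the universe before testing; the
    query must lie within the universe. Returns a DataFrame with columns
    set_name, set_size, overlap, p, q sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    outside = set(query) - set(universe)
    if outside:
        raise ValueError(
            f"query genes outside the universe (e.g. {sorted(outside)[:3]})"
        )
    n = len(universe)
    k = len(query)
    rows = []
    for name, genes in collection.items():
        genes_in = set(genes) & set(universe)
        ov = len(genes_in & set(query))
        p = (
            float(stats.hypergeom.sf(ov - 1, n, len(genes_in), k))
            if ov > 0
            else 1.0
        )
        rows.append(
            {
                "set_name": name,
                "set_size": len(genes_in),
                "overlap": ov,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = compute_qvalues(df["p"].to_numpy())
        df = df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return df


def annotate_genes_with_peaks(
    gene_bed: pd.DataFrame,
    peak_bed: pd.DataFrame,
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Flag genes whose promoter window contains at least one peak.

    The promoter window is [TSS - w, TSS + w) in 0-based half-open
    coordinates, with the TSS taken strand-aware (interval start on '+',
    end - 1 on '-'). Returns per-gene rows: gene, flagged, peaks
    (comma-joined overlapping peak names).
    """
    if promoter_window < 0:
        raise ValueError("promoter_window must be non-negative")
    rows = []
    for _, g in gene_bed.iterrows():
        tss = int(g["start"]) if g["strand"] != "-" else int(g["end"]) - 1
        win_lo, win_hi = tss - promoter_window, tss + promoter_window
        hits = peak_bed[
            (peak_bed["chrom"] == g["chrom"])
            & (peak_bed["start"] < win_hi)
            & (peak_bed["end"] > win_lo)
        ]
        rows.append(
            {
                "gene": g["name"],
                "flagged": len(hits) > 0,
                "peaks": ",".join(hits["name"].astype(str)),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "flagged", "peaks"])
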