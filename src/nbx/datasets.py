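"""Core data containers and plain-text I/O.

Expression matrices are features x samples (rows = probes or genes, columns =
sample IDs) of normalized, log2-scale intensities, mirroring the layout of
normalized microarray exports. Sample annotations carry either clinical fields
(overall-survival time and event, MYCN amplification, INSS stage, age at
diagnosis) or experimental fields (oxygen condition, cell line, MYCN status,
N/S growth pattern).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "DEGTable",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_feature_map_tsv",
    "read_gmt",
    "read_bed",
    "write_bed",
]

#: clinical annotation columns expected for patient cohorts
CLINICAL_COLUMNS = ["os_time", "os_event", "mycn", "stage", "age"]

#: experimental annotation columns expected for cell-line experiments
CELLLINE_COLUMNS = ["condition", "line", "mycn", "growth_pattern"]


@dataclass
class ExpressionDataset:
    """A features x samples expression matrix with per-sample annotations.

    Parameters
    ----------
    matrix
        DataFrame of normalized log2-scale intensities, index = feature
        (probe or gene) IDs, columns = sample IDs.
    sample_annotations
        DataFrame indexed by sample ID. For cohorts: ``os_time``,
        ``os_event``, ``mycn``, ``stage``, ``age``. For cell-line
        experiments: ``condition``, ``line``, ``mycn``, ``growth_pattern``.
    feature_map
        Optional Series mapping probe ID -> gene symbol.
    dataset_id
        Free-text label used in reports.
    """

    matrix: pd.DataFrame
    sample_annotations: pd.DataFrame
    feature_map: pd.Series | None = None
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            dupes = self.matrix.columns[self.matrix.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs in matrix: {dupes}")
        if self.sample_annotations.index.duplicated().any():
            raise ValueError("duplicate sample IDs in annotations")
        missing = self.matrix.columns.difference(self.sample_annotations.index)
        if len(missing):
            raise ValueError(f"samples missing annotations: {list(missing)[:5]}")
        # align annotation order to matrix column order
        self.sample_annotations = self.sample_annotations.loc[self.matrix.columns]
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(
            matrix=self.matrix[ids],
            sample_annotations=self.sample_annotations.loc[ids],
            feature_map=self.feature_map,
            dataset_id=self.dataset_id,
        )


@dataclass
class DEGTable:
    """Per-gene differential-expression results for one dataset.

    ``records`` columns: gene, log2fc, p, q, direction ("up"/"down"),
    source_probe. ``universe_size`` is the number of genes tested in the
    dataset, which downstream overlap permutation tests sample from.
    """

    records: pd.DataFrame
    universe_size: int
    dataset_id: str = "dataset"
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        required = {"gene", "log2fc", "p", "q", "direction"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"DEGTable records missing columns: {sorted(missing)}")
        if self.records["gene"].duplicated().any():
            raise ValueError("DEGTable must hold one record per gene")
        if self.universe_size < len(self.records):
            raise ValueError("universe_size smaller than number of records")

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])

    def directions(self) -> dict[str, str]:
        return dict(zip(self.records["gene"], self.records["direction"]))

    def write(self, path: str | Path) -> None:
        """Write records as TSV plus a JSON sidecar with universe metadata."""
        import json

        path = Path(path)
        cols = ["gene", "log2fc", "p", "q", "direction"]
        if "source_probe" in self.records.columns:
            cols.append("source_probe")
        self.records[cols].to_csv(path, sep="\t", index=False)
        sidecar = {
            "dataset_id": self.dataset_id,
            "universe_size": int(self.universe_size),
        }
        if self.universe is not None:
            sidecar["universe"] = sorted(self.universe)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def read(cls, path: str | Path) -> "DEGTable":
        import json

        path = Path(path)
        records = pd.read_csv(path, sep="\t")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
        else:
            sidecar = {"dataset_id": path.stem, "universe_size": len(records)}
        return cls(
            records=records,
            universe_size=sidecar["universe_size"],
            dataset_id=sidecar["dataset_id"],
            universe=sidecar.get("universe"),
        )


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV (rows = features, header row = sample IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample annotations; first column is the sample ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "stage" in df.columns:
        df["stage"] = df["stage"].astype(str)
    return df


def write_clinical_tsv(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample_id")


def read_feature_map_tsv(path: str | Path) -> pd.Series:
    """Read a probe_id -> gene_symbol map (two tab-separated columns)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("feature map needs probe_id and gene_symbol columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        collection[parts[0]] = set(g for g in parts[2:] if g)
    return collection


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end/name/score/strand.

    Raises ValueError naming the offending line number on malformed input.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed BED line {lineno}: {exc}") from None
        if end < start:
            raise ValueError(f"malformed BED line {lineno}: end < start")
        rows.append(
            {
                "chrom": parts[0],
                "start": start,
                "end": end,
                "name": parts[3] if len(parts) > 3 else f"feature_{lineno}",
                "score": parts[4] if len(parts) > 4 else "0",
                "strand": parts[5] if len(parts) > 5 else "+",
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )
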