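"""Delimited-text I/O for expression tables, labels and score reports."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, LabelVector
from .exceptions import ValidationError
from .selection import SelectionResult


@dataclass(frozen=True)
class TableSpec:
    """Where and how to read an expression table.

    ``orientation`` is ``"samples-by-features"`` (canonical) or
    ``"features-by-samples"`` (transposed on read). Labels come either
    from a named column of the table (``label_column``) or from a separate
    single-column file (``label_file``); the minority/positive mark is
    declared explicitly with ``positive_label`` when known.
    """

    path: str
    delimiter: str = "\t"
    orientation: str = "samples-by-features"
    label_column: Optional[str] = None
    label_file: Optional[str] = None
    positive_label: Optional[str] = None

    def __post_init__(self):
        if self.orientation not in ("samples-by-features", "features-by-samples"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if (self.label_column is None) == (self.label_file is None):
            raise ValidationError(
                "exactly one of label_column / label_file must be given"
            )


def read_expression_table(spec: TableSpec) -> tuple[ExpressionMatrix, LabelVector]:
    """Parse a delimited expression table plus labels into validated types."""
    df = pd.read_csv(spec.path, sep=spec.delimiter, index_col=0)
    if spec.orientation == "features-by-samples":
        df = df.T

    if spec.label_column is not None:
        if spec.label_column not in df.columns:
            raise ValidationError(
                f"label column {spec.label_column!r} not found in {spec.path}"
            )
        raw_labels = df[spec.label_column].astype(str).to_numpy()
        df = df.drop(columns=[spec.label_column])
    else:
        lab = pd.read_csv(spec.label_file, header=None).iloc[:, 0]
        raw_labels = lab.astype(str).to_numpy()
        if raw_labels.shape[0] != df.shape[0]:
            raise ValidationError(
                f"{raw_labels.shape[0]} labels in {spec.label_file} for "
                f"{df.shape[0]} samples in {spec.path}"
            )

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"non-numeric or missing cell at sample {df.index[r]!r}, "
            f"feature {df.columns[c]!r} in {spec.path}"
        )
    fids = [str(c) for c in df.columns]
    if len(set(fids)) != len(fids):
        raise ValidationError(f"duplicate feature ids in {spec.path}")

    X = ExpressionMatrix(
        numeric.to_numpy(float),
        sample_ids=tuple(str(i) for i in df.index),
        feature_ids=tuple(fids),
    )
    labels = LabelVector(raw_labels, positive_label=spec.positive_label)
    return X, labels


def write_score_report(result: SelectionResult, path) -> Path:
    """Write the per-feature score report as TSV plus a JSON sidecar.

    One row per feature: id, 1-based Psi rank, phi, omega, psi, beta (NaN
    outside the candidate pool) and the final-set / backfilled flags. The
    sidecar ``<path>.json`` records config, seed, tau and lambda.
    """
    path = Path(path)
    ranked = result.ranked
    p = len(ranked.feature_ids)
    rank = np.empty(p, dtype=int)
    rank[ranked.order] = np.arange(1, p + 1)

    beta = np.full(p, np.nan)
    if result.refinement is not None:
        idx = {f: i for i, f in enumerate(ranked.feature_ids)}
        for f, b in zip(result.refinement.candidate_ids, result.refinement.beta):
            beta[idx[f]] = b

    final = set(result.final_set)
    backfilled = set(result.backfilled)
    df = pd.DataFrame(
        {
            "feature_id": ranked.feature_ids,
            "rank": rank,
            "phi": result.phi.scores if result.phi is not None else np.nan,
            "omega": result.margin.omega if result.margin is not None else np.nan,
            "psi": result.psi.scores if result.psi is not None else np.nan,
            "beta": beta,
            "in_final_set": [f in final for f in ranked.feature_ids],
            "backfilled": [f in backfilled for f in ranked.feature_ids],
        }
    ).sort_values("rank")
    df.to_csv(path, sep="\t", index=False)

    config = result.provenance.get("config")
    sidecar = {
        "config": config.__dict__ if config is not None else None,
        "seed": result.provenance.get("seed"),
        "tau": result.provenance.get("tau"),
        "lambda_used": result.provenance.get("lambda_used"),
        "final_set": list(result.final_set),
        "backfilled": list(result.backfilled),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def write_dataset(X: ExpressionMatrix, labels: LabelVector, path,
                  extra: Optional[dict] = None) -> Path:
    """Write a samples-by-features TSV with a trailing ``class`` column.

    An optional JSON manifest ``<path>.json`` carries e.g. the planted
    informative feature ids of a simulated dataset.
    """
    path = Path(path)
    df = pd.DataFrame(X.values, index=list(X.sample_ids), columns=list(X.feature_ids))
    df["class"] = labels.labels
    df.to_csv(path, sep="\t", index_label="sample_id")
    if extra is not None:
        Path(str(path) + ".json").write_text(json.dumps(extra, indent=2, default=str))
    return path
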