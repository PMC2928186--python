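"""File I/O: TSV matrices, ortholog maps, Newick trees, reports, configs.

TSV dialect everywhere: tab-separated, UTF-8, '.' decimal point, one
header row, no quoting.  Expression matrices have the gene identifier in
the first column (header ``gene_id``) and one column per tissue.
Write/read round-trips are identities on values and labels to within
float-formatting precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, OrthologPairSet
from .distances import PairDistanceVector
from .errors import ValidationError
from .simulate import GroundTruth, SyntheticConfig

__all__ = [
    "write_expression",
    "read_expression",
    "write_matrix",
    "write_orthologs",
    "read_orthologs",
    "write_ground_truth",
    "write_newick",
    "read_newick",
    "write_distances",
    "write_json",
    "read_synthetic_config",
]

_FLOAT_FMT = "%.10g"


def write_expression(mat, path) -> None:
    """Write any gene x tissue matrix as TSV (first column ``gene_id``)."""
    frame = mat.data.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


#: Alias covering relative and binary matrices, which share the dialect.
write_matrix = write_expression


def _read_table(path, n_min_cols: int) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc
    if frame.shape[1] < n_min_cols:
        raise ValidationError(f"{path}: expected at least {n_min_cols} tab-separated columns")
    return frame


def read_expression(path, species: str) -> ExpressionMatrix:
    """Read a linear-scale expression TSV written by :func:`write_expression`."""
    frame = _read_table(path, 3)
    gene_ids = frame.iloc[:, 0]
    if gene_ids.duplicated().any():
        dup = gene_ids[gene_ids.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    body = frame.iloc[:, 1:]
    try:
        values = body.astype(float)
    except ValueError as exc:
        for line_no, (_, row) in enumerate(body.iterrows(), start=2):
            try:
                row.astype(float)
            except ValueError:
                raise ValidationError(f"{path}: non-numeric value on line {line_no}") from exc
        raise
    values.index = pd.Index(gene_ids, name="gene_id")
    return ExpressionMatrix(values, species=species)


def write_orthologs(pairs: OrthologPairSet, path, columns=("species1", "species2")) -> None:
    pd.DataFrame(
        {columns[0]: pairs.species1_ids, columns[1]: pairs.species2_ids}
    ).to_csv(path, sep="\t", index=False)


def read_orthologs(path) -> OrthologPairSet:
    frame = _read_table(path, 2)
    return OrthologPairSet(frame.iloc[:, 0].tolist(), frame.iloc[:, 1].tolist())


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", na_rep="NA")


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick file; returns a :class:`dendropy.Tree` for inspection."""
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_distances(d: PairDistanceVector, path, excluded_path=None) -> None:
    """Distance vector as TSV; excluded (undefined) pairs go to a side-car."""
    params = json.dumps(d.params) if d.params else ""
    pd.DataFrame(
        {
            "species1_gene": [p[0] for p in d.pair_ids],
            "species2_gene": [p[1] for p in d.pair_ids],
            "distance": d.values,
            "measure": d.measure,
            "params": params,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if excluded_path is not None:
        pd.DataFrame(
            {
                "species1_gene": [p[0] for p in d.excluded_ids],
                "species2_gene": [p[1] for p in d.excluded_ids],
            }
        ).to_csv(excluded_path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        if math.isnan(f):
            return None
        return f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def _parse_lambda(value):
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("inf", "+inf", "infinity"):
            return math.inf
        if v in ("-inf", "-infinity"):
            return -math.inf
        return float(value)
    return float(value)


def read_synthetic_config(path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML mapping.

    Keys mirror the dataclass fields; unknown keys are rejected so typos
    fail loudly rather than silently falling back to defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    allowed = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "species_names" in raw:
        raw["species_names"] = tuple(raw["species_names"])
    return SyntheticConfig(**raw)
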