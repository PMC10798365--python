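"""Readers and writers for the pipeline's plain-text formats.

Count tables and phenotype tables are TSV with samples in rows (first column
is the sample ID, header row holds feature names); trees are newick;
distance matrices are square TSV with sample IDs on both margins; candidate
sets, reports and configs are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .cohort import QualVar, QuantVar, SyntheticSpec
from .diversity import Ordination

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_phenotypes",
    "write_phenotypes",
    "read_tree",
    "write_tree",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_ordination",
    "spec_to_json",
    "spec_from_json",
]


class TableFormatError(ValueError):
    """A tabular input violates the expected format (message carries the line)."""


def read_feature_table(path) -> pd.DataFrame:
    """Read a samples x taxa TSV of nonnegative integer counts.

    Rejects ragged rows, non-integer or negative cells, and duplicate sample
    IDs, reporting the 1-based line number of the offence.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TableFormatError(f"{path}: empty file")
        cols = header.split("\t")
        taxa = cols[1:]
        if len(set(taxa)) != len(taxa):
            raise TableFormatError(f"{path}: line 1: duplicate taxon names")
        rows: list[list[int]] = []
        ids: list[str] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, "
                    f"got {len(parts)}"
                )
            sid = parts[0]
            if sid in seen:
                raise TableFormatError(
                    f"{path}: line {lineno}: duplicate sample ID {sid!r}"
                )
            seen.add(sid)
            vals = []
            for taxon, cell in zip(taxa, parts[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise TableFormatError(
                        f"{path}: line {lineno}: non-integer count {cell!r} "
                        f"for taxon {taxon!r}"
                    ) from None
                if v < 0:
                    raise TableFormatError(
                        f"{path}: line {lineno}: negative count {v} for "
                        f"taxon {taxon!r}"
                    )
                vals.append(v)
            ids.append(sid)
            rows.append(vals)
    if not rows:
        raise TableFormatError(f"{path}: no data rows")
    return pd.DataFrame(rows, index=pd.Index(ids, name=cols[0] or "sample"),
                        columns=taxa)


def write_feature_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample")


def read_phenotypes(path, schema: dict[str, str]) -> pd.DataFrame:
    """Read a phenotype TSV with a declared column typing.

    ``schema`` maps column name -> "quantitative" | "qualitative".  Columns in
    the schema must exist in the file; quantitative columns must parse as
    numbers (empty cells become missing values); qualitative columns are kept
    as strings with empty cells missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: schema columns absent from file: {missing}")
    bad_kind = {c: k for c, k in schema.items()
                if k not in ("quantitative", "qualitative")}
    if bad_kind:
        raise ValueError(f"invalid schema kinds: {bad_kind}")
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        raw = df[col].replace("", np.nan)
        if kind == "quantitative":
            try:
                out[col] = raw.astype(float)
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: column {col!r} declared quantitative but holds "
                    f"non-numeric data ({exc})"
                ) from None
        else:
            out[col] = raw.astype(object)
    return out


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="sample")


def phenotype_schema(phenotypes: pd.DataFrame) -> dict[str, str]:
    """Derive the quantitative/qualitative schema from column dtypes."""
    return {
        c: ("quantitative" if pd.api.types.is_numeric_dtype(phenotypes[c])
            else "qualitative")
        for c in phenotypes.columns
    }


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.to_csv(path, sep="\t", index_label="sample")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))


def write_ordination(ord_: Ordination, path) -> None:
    """Coordinates TSV with a one-line eigenvalue/percent-variance header."""
    with Path(path).open("w") as fh:
        eig = ",".join(f"{v:.10g}" for v in ord_.eigenvalues)
        pct = ",".join(f"{v:.6f}" for v in ord_.proportion_explained)
        fh.write(f"# eigenvalues={eig} percent_explained={pct}\n")
        ord_.coordinates.to_csv(fh, sep="\t", index_label="sample")


def spec_to_json(spec: SyntheticSpec, path=None) -> str:
    payload = {
        "group_sizes": dict(spec.group_sizes),
        "n_taxa": spec.n_taxa,
        "planted_taxa": {
            g: [[int(i), float(l)] for i, l in eff]
            for g, eff in spec.planted_taxa.items()
        },
        "base_concentration": list(map(float, spec.base_concentration)),
        "library_size_range": list(spec.library_size_range),
        "quant_vars": [
            {"name": q.name, "control_mean": q.control_mean,
             "control_sd": q.control_sd, "shifts": dict(q.shifts)}
            for q in spec.quant_vars
        ],
        "qual_vars": [
            {"name": q.name, "levels": list(q.levels),
             "control_probs": list(q.control_probs),
             "group_probs": {g: list(p) for g, p in q.group_probs.items()}}
            for q in spec.qual_vars
        ],
        "seed": spec.seed,
        "control": spec.control,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def spec_from_json(source) -> SyntheticSpec:
    if isinstance(source, (str, Path)) and Path(source).exists():
        payload = json.loads(Path(source).read_text())
    else:
        payload = json.loads(source)
    return SyntheticSpec(
        group_sizes=payload["group_sizes"],
        n_taxa=int(payload["n_taxa"]),
        planted_taxa={
            g: [(int(i), float(l)) for i, l in eff]
            for g, eff in payload["planted_taxa"].items()
        },
        base_concentration=tuple(payload["base_concentration"]),
        library_size_range=tuple(payload["library_size_range"]),
        quant_vars=tuple(
            QuantVar(q["name"], q["control_mean"], q["control_sd"],
                     dict(q.get("shifts", {})))
            for q in payload["quant_vars"]
        ),
        qual_vars=tuple(
            QualVar(q["name"], tuple(q["levels"]), tuple(q["control_probs"]),
                    {g: tuple(p) for g, p in q.get("group_probs", {}).items()})
            for q in payload["qual_vars"]
        ),
        seed=int(payload["seed"]),
        control=payload.get("control", "CT"),
    )
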