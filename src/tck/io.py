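"""Readers and writers for the pipeline's plain-text formats.

Matrices, designs and result tables are TSV; gene sets are GMT.  Every file
written here carries leading ``#``-comment header lines recording the tool
version and, when supplied, the run's config hash and seed; readers skip
and parse those lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import CohortDesign, ExpressionMatrix, SchemaError, STAGES
from .enrichment import GeneSetCollection

logger = logging.getLogger(__name__)


def _write_header(handle, meta: dict | None) -> None:
    meta = dict(meta or {})
    meta.setdefault("tck_version", __version__)
    for key in sorted(meta):
        handle.write(f"# {key}: {meta[key]}\n")


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta, n


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None,
                index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _, skip = _read_header(path)
    return pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")


def write_matrix(matrix: ExpressionMatrix, path: str | Path,
                 meta: dict | None = None) -> Path:
    meta = dict(meta or {})
    meta["stage"] = matrix.stage
    df = matrix.data.copy()
    df.index.name = "feature_id"
    return write_table(df, path, meta=meta, index=True)


def read_matrix(path: str | Path, stage: str | None = None) -> ExpressionMatrix:
    """Read a features x samples TSV; stage comes from the header if present."""
    path = Path(path)
    meta, skip = _read_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicate feature ids {dupes[:5]}")
    eff_stage = stage or meta.get("stage", "raw")
    if eff_stage not in STAGES:
        raise SchemaError(f"{path}: unknown stage {eff_stage!r}")
    return ExpressionMatrix(df, stage=eff_stage)


def write_design(design: CohortDesign, path: str | Path,
                 meta: dict | None = None) -> Path:
    df = design.table.copy()
    df.index.name = "sample_id"
    return write_table(df, path, meta=meta, index=True)


def read_design(path: str | Path) -> CohortDesign:
    path = Path(path)
    _, skip = _read_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"donor": str, "batch": str}, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: first column must be sample_id")
    return CohortDesign(df.set_index("sample_id"))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member genes, tab-separated."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, _desc, *members = parts
            if name in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [m for m in members if m]
    return GeneSetCollection(sets, source_tag=path.stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source_tag or "na", *members]) + "\n")
    return path


def read_targets(path: str | Path) -> pd.DataFrame:
    """Read a validated-target TSV (mirna_id, gene_id, evidence)."""
    df = read_table(path)
    required = {"mirna_id", "gene_id", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: target table missing columns {sorted(missing)}")
    return df


def read_reference(path: str | Path) -> set[str]:
    """Read a reference gene universe, one identifier per line."""
    path = Path(path)
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    if not out:
        raise SchemaError(f"{path}: empty reference list")
    return out
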