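"""Readers and writers for the pipeline's external text formats.

Everything is delimited text or JSON: expression matrices with an id
header row and id first column (canonical orientation cohorts-in-rows),
two-column label and annotation tables, a line-oriented filtration
format (``value<TAB>v0,v1,...``), an interval TSV and cycle/cover/
metrics JSON.  Delimiters are auto-detected from the first line with
an override.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .complex_core import Filtration, PersistenceInterval
from .gene_curation import AnnotationMap
from .rep_cycles import RepCycle

__all__ = [
    "RunConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_annotations",
    "write_annotations",
    "dump_filtration",
    "load_filtration",
    "dump_intervals",
    "load_intervals",
    "cycles_to_json",
    "cycles_from_json",
    "write_meta",
]


def _detect_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_expression_matrix(
    path,
    orientation: str = "cohorts_in_rows",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a matrix with an id header row and id first column.

    Returns a float DataFrame in the canonical cohorts-in-rows
    orientation (``genes_in_rows`` inputs are transposed on read).
    """
    if orientation not in ("cohorts_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    delim = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, index_col=0, comment="#")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column identifiers")
    try:
        out = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any() or df[col].isna().any():
                row = df.index[bad.argmax() if bad.any() else df[col].isna().argmax()]
                raise ValueError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise
    if out.isna().any().any():
        j = out.isna().any(axis=0).argmax()
        i = out.iloc[:, j].isna().argmax()
        raise ValueError(
            f"{path}: non-numeric cell at row {out.index[i]!r}, "
            f"column {out.columns[j]!r}"
        )
    if orientation == "genes_in_rows":
        out = out.T
    return out


def write_expression_matrix(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    pd.DataFrame(df).to_csv(path, sep=delimiter)


def read_labels(path, delimiter: str | None = None) -> dict:
    """Read a two-column (cohort id, integer label) table."""
    path = Path(path)
    delim = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, header=None, comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty label file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, label)")
    # tolerate a header line
    try:
        int(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no label rows")
    labels = {}
    for _, (cid, lab) in df.iloc[:, :2].iterrows():
        labels[str(cid)] = int(lab)
    return labels


def write_labels(labels: dict, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for cid, lab in labels.items():
            fh.write(f"{cid}{delimiter}{int(lab)}\n")


def read_annotations(path, delimiter: str | None = None) -> AnnotationMap:
    """Read a two-column many-to-many (gene id, term) table."""
    path = Path(path)
    delim = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, header=None, comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty annotation file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, term)")
    return AnnotationMap.from_pairs(
        (str(g), str(t)) for g, t in df.iloc[:, :2].itertuples(index=False)
    )


def write_annotations(ann: AnnotationMap, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for g in sorted(ann.terms, key=str):
            for t in sorted(ann.terms[g]):
                fh.write(f"{g}{delimiter}{t}\n")


def dump_filtration(filt: Filtration, path) -> None:
    """One simplex per line: ``value<TAB>v0,v1,...`` in filtration order."""
    with open(path, "w") as fh:
        if filt.is_pseudo_manifold:
            fh.write("# pseudo_manifold\n")
        for s, v in zip(filt.simplices, filt.values):
            fh.write(f"{float(v)!r}\t{','.join(map(str, s))}\n")


def load_filtration(path) -> Filtration:
    simplices, values = [], []
    pm = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                pm = pm or "pseudo_manifold" in line
                continue
            v, verts = line.split("\t")
            simplices.append(tuple(int(x) for x in verts.split(",")))
            values.append(float(v))
    return Filtration(simplices, values, is_pseudo_manifold=pm)


_IV_COLS = [
    "dim", "birth_index", "death_index", "birth_value", "death_value",
    "creator", "destroyer",
]


def dump_intervals(intervals: list[PersistenceInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_IV_COLS) + "\n")
        for iv in intervals:
            dest = ",".join(map(str, iv.destroyer)) if iv.destroyer else ""
            death_i = "inf" if not iv.finite else str(iv.death_index)
            death_v = "inf" if not iv.finite else repr(float(iv.death_value))
            fh.write(
                f"{iv.dim}\t{iv.birth_index}\t{death_i}\t{float(iv.birth_value)!r}\t"
                f"{death_v}\t{','.join(map(str, iv.creator))}\t{dest}\n"
            )


def load_intervals(path) -> list[PersistenceInterval]:
    out = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != _IV_COLS:
            raise ValueError(f"{path}: unexpected interval header {header}")
        for line in fh:
            d, bi, di, bv, dv, cr, de = line.rstrip("\n").split("\t")
            out.append(
                PersistenceInterval(
                    dim=int(d),
                    birth_index=int(bi),
                    death_index=math.inf if di == "inf" else int(di),
                    birth_value=float(bv),
                    death_value=float(dv),
                    creator=tuple(int(x) for x in cr.split(",")),
                    destroyer=tuple(int(x) for x in de.split(",")) if de else None,
                )
            )
    return out


def cycles_to_json(cycles: list[RepCycle]) -> list[dict]:
    recs = []
    for c in cycles:
        iv = c.interval
        recs.append(
            {
                "dim": c.dim,
                "birth_index": iv.birth_index,
                "death_index": iv.death_index if iv.finite else "inf",
                "birth_value": iv.birth_value,
                "death_value": iv.death_value if iv.finite else "inf",
                "simplices": sorted(list(s) for s in c.simplices),
                "vertex_set": sorted(c.vertex_set),
            }
        )
    return recs


def cycles_from_json(recs: list[dict]) -> list[RepCycle]:
    out = []
    for r in recs:
        simplices = frozenset(tuple(s) for s in r["simplices"])
        creator = min(simplices)  # placeholder witness; intervals lack provenance
        iv = PersistenceInterval(
            dim=r["dim"],
            birth_index=r["birth_index"],
            death_index=math.inf if r["death_index"] == "inf" else r["death_index"],
            birth_value=r["birth_value"],
            death_value=math.inf if r["death_value"] == "inf" else r["death_value"],
            creator=creator,
        )
        out.append(RepCycle(dim=r["dim"], simplices=simplices, interval=iv))
    return out


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run (YAML-serialisable)."""

    filtration: dict = field(
        default_factory=lambda: {"max_dim": 3, "max_scale": None, "sparsity": None}
    )
    curation: dict = field(
        default_factory=lambda: {
            "k": 100, "mode": "h1+h2", "kappa_max": 3, "scaling": "none",
        }
    )
    evaluation: dict = field(
        default_factory=lambda: {
            "model": "decision_tree", "reps": 10, "test_frac": 0.2,
            "cnn": {"n_filters": 32, "kernel_size": 16, "dropout_prob": 0.25,
                    "dense_units": [128, 64], "epochs": 50},
        }
    )
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, val in raw.items():
            default = getattr(cfg, key)
            if isinstance(default, dict):
                extra = set(val) - set(default)
                if extra:
                    raise ValueError(f"unknown keys under {key!r}: {sorted(extra)}")
                default.update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_meta(path, config: dict, seed: int) -> None:
    """Reproducibility sidecar: the resolved config and seed of an artifact."""
    meta = {"config": config, "seed": seed}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))
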