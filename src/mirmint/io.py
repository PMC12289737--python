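"""Readers and writers for the pipeline's plain-text formats.

Canonical dialect is TSV, UTF-8, "." decimal separator (CSV accepted on
read for matrices).  Matrices are features-in-rows, samples-in-columns
with two header rows: sample ids, then group labels.  Undetermined Ct
cells are written as the literal token "Undetermined" and mapped back
to the ceiling on read.  Gene sets and target maps use the standard GMT
dialect (name, description, members).  Graphs are 3-column edge lists
(source, interaction, target).  Every CLI run writes a two-column TSV
manifest (config snapshot JSON-encoded, seed, stage counts, version).
"""
from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .mirna_de import CtMatrix, DEFAULT_CEILING
from .mrna_de import ExpressionMatrix, FLAG_TOKENS
from .synthetic import GroundTruth

logger = logging.getLogger(__name__)

UNDETERMINED = "Undetermined"


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_two_header_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    sep = _sep(path)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: expected two header rows and at least one feature row")
    header = lines[0].rstrip("\n").split(sep)
    group_row = lines[1].rstrip("\n").split(sep)
    samples = header[1:]
    if group_row[0].lower() != "group":
        raise ValueError(f"{path}: second header row must start with 'group'")
    if len(group_row) != len(header):
        raise ValueError(f"{path}: group row has {len(group_row)} fields, header {len(header)}")
    groups = pd.Series(group_row[1:], index=samples)
    ids, rows = [], []
    for ln_no, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        fields = line.split(sep)
        if len(fields) != len(header):
            raise ValueError(f"{path}:{ln_no}: ragged row ({len(fields)} fields, "
                             f"expected {len(header)})")
        ids.append(fields[0])
        rows.append(fields[1:])
    df = pd.DataFrame(rows, index=ids, columns=samples)
    return df, groups


def read_ct_matrix(path: str | Path, ceiling: float = DEFAULT_CEILING) -> CtMatrix:
    """Read a Ct matrix; the "Undetermined" token maps to the ceiling."""
    df, groups = _read_two_header_matrix(path)
    def conv(x: str) -> float:
        if x.strip().lower() == UNDETERMINED.lower():
            return ceiling
        try:
            return float(x)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric Ct value {x!r}") from exc
    vals = df.map(conv).astype(float)
    return CtMatrix(vals, groups, ceiling=ceiling)


def write_ct_matrix(ct: CtMatrix, path: str | Path) -> None:
    sep = _sep(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["id", *ct.sample_ids]) + "\n")
        fh.write(sep.join(["group", *ct.groups.tolist()]) + "\n")
        und = ct.undetermined_mask()
        for fid in ct.values.index:
            cells = [
                UNDETERMINED if und.at[fid, s] else format(ct.values.at[fid, s], "g")
                for s in ct.sample_ids
            ]
            fh.write(sep.join([str(fid), *cells]) + "\n")


def read_expression_matrix(values_path: str | Path, flags_path: str | Path) -> ExpressionMatrix:
    df, groups = _read_two_header_matrix(values_path)
    try:
        vals = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{values_path}: non-numeric intensity") from exc
    fdf, fgroups = _read_two_header_matrix(flags_path)
    if not fgroups.equals(groups):
        raise ValueError("flags file group row differs from values file")
    bad = set(np.unique(fdf.to_numpy())) - FLAG_TOKENS
    if bad:
        raise ValueError(f"{flags_path}: unknown flag tokens {sorted(bad)}")
    return ExpressionMatrix(vals, fdf, groups)


def write_expression_matrix(
    expr: ExpressionMatrix, values_path: str | Path, flags_path: str | Path
) -> None:
    for df, path in ((expr.values, values_path), (expr.flags, flags_path)):
        sep = _sep(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(sep.join(["id", *map(str, df.columns)]) + "\n")
            fh.write(sep.join(["group", *expr.groups.tolist()]) + "\n")
            for fid in df.index:
                row = [
                    format(v, "g") if isinstance(v, float) else str(v)
                    for v in df.loc[fid].tolist()
                ]
                fh.write(sep.join([str(fid), *row]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, set[str]] = {}
    for ln_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln_no}: GMT line needs name, description, >=1 member")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{ln_no}: duplicate set name {name!r}")
        sets[name] = {f for f in fields[2:] if f}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            members = sorted(sets[name])
            fh.write("\t".join([str(name), description, *members]) + "\n")


def read_edge_list(path: str | Path) -> nx.DiGraph:
    """3-column TSV (source, interaction, target); duplicates deduplicated."""
    g = nx.DiGraph()
    n_dup = 0
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    start = 1 if lines and lines[0].lower().startswith("source\t") else 0
    for ln_no, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{ln_no}: expected 3 columns, got {len(fields)}")
        src, interaction, tgt = fields
        if g.has_edge(src, tgt):
            n_dup += 1
            continue
        g.add_edge(src, tgt, interaction=interaction)
    if n_dup:
        logger.warning("%s: %d duplicate edges dropped", path, n_dup)
    return g


def write_edge_list(graph: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\tinteraction\ttarget\n")
        for src, tgt, data in sorted(graph.edges(data=True)):
            fh.write(f"{src}\t{data.get('interaction', 'na')}\t{tgt}\n")


def read_directions(path: str | Path) -> dict[str, str]:
    """Two-column TSV: id <tab> up|down."""
    out: dict[str, str] = {}
    for ln_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lower().startswith("id\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or fields[1] not in ("up", "down"):
            raise ValueError(f"{path}:{ln_no}: expected 'id<TAB>up|down'")
        out[fields[0]] = fields[1]
    return out


def write_directions(directions: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tdirection\n")
        for k in sorted(directions):
            fh.write(f"{k}\t{directions[k]}\n")


def read_id_list(path: str | Path) -> set[str]:
    return {ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip()}


def write_id_list(ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n", encoding="utf-8")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep(path))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for s, kind, direction in (
        (truth.de_mirnas_up, "mirna", "up"),
        (truth.de_mirnas_down, "mirna", "down"),
        (truth.de_genes_up, "gene", "up"),
        (truth.de_genes_down, "gene", "down"),
    ):
        for fid in sorted(s):
            rows.append((fid, kind, direction, truth.planted_effects.get(fid, float("nan"))))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tkind\tdirection\teffect\n")
        for fid, kind, direction, eff in rows:
            fh.write(f"{fid}\t{kind}\t{direction}\t{eff:g}\n")


def write_manifest(
    path: str | Path,
    *,
    command: str,
    config: dict | None = None,
    seed: int | None = None,
    stage_counts: dict[str, int] | None = None,
) -> None:
    from . import __version__

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"command\t{command}\n")
        fh.write(f"version\t{__version__}\n")
        fh.write(f"timestamp\t{datetime.datetime.now().isoformat()}\n")
        if seed is not None:
            fh.write(f"seed\t{seed}\n")
        if config is not None:
            fh.write(f"config\t{json.dumps(config, sort_keys=True)}\n")
        for name, count in (stage_counts or {}).items():
            fh.write(f"count_{name}\t{count}\n")
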