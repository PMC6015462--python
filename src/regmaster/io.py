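"""Readers and writers for every on-disk artifact the pipeline touches.

All files are plain UTF-8 text with LF line endings:

* expression matrices as TSV (first column gene ids, header row sample ids)
  or GCT 1.2 (two header lines, Description column ignored on read);
* phenotype tables as two-column TSV ``sample_id<TAB>group``;
* signed regulons as a GMT dialect with two records per TF, ``<TF>|pos``
  and ``<TF>|neg``, whose description field carries the MI weights as a
  comma-separated list aligned with the member genes (a deliberate
  extension of the GMT description slot);
* compound signature databases as TSV with columns instance_id, compound,
  cell_line, rank_1..rank_n (rank 1 = most up-regulated gene).

Every reader/writer pair is an exact round trip on valid files, and
readers never hand back objects violating the type invariants.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CompoundSignatureDB,
    SignedRegulon,
    validate_expression,
    validate_phenotype,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_regulon_gmt",
    "write_regulon_gmt",
    "read_signature_db",
    "write_signature_db",
]


def _check_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~df.isna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(f"{path}: non-numeric value at gene {gene!r}, sample {sample!r}")
    return out


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    *,
    na_policy: str = "reject",
) -> pd.DataFrame:
    """Load a genes x samples expression matrix.

    Parameters
    ----------
    dialect : {"tsv", "gct"}
    na_policy : {"reject", "row_mean"}
        ``reject`` raises on any missing cell; ``row_mean`` imputes the
        gene's mean across the remaining samples.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"{path}: expected GCT 1.2 header, got {version!r}")
            fh.readline()  # row/column counts; shape is validated from the body
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        df = df.drop(columns=["Description"], errors="ignore")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    numeric = _check_numeric(df.replace("", np.nan), path)
    if numeric.isna().any().any():
        if na_policy == "row_mean":
            n_imputed = int(numeric.isna().sum().sum())
            numeric = numeric.apply(lambda row: row.fillna(row.mean()), axis=1)
            log.warning("%s: imputed %d missing values with row means", path, n_imputed)
        else:
            gene = numeric.index[numeric.isna().any(axis=1)][0]
            raise ValueError(f"{path}: missing value at gene {gene!r} (na_policy='reject')")
    numeric.index.name = df.index.name or "gene_id"
    return validate_expression(numeric)


def write_expression_matrix(expr: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    expr = validate_expression(expr)
    out = expr.copy()
    out.index.name = out.index.name or "gene_id"
    if dialect == "tsv":
        out.to_csv(path, sep="\t", lineterminator="\n")
    elif dialect == "gct":
        body = out.reset_index()
        body.insert(1, "Description", out.index.astype(str))
        body.columns = ["Name", "Description", *out.columns]
        with open(path, "w", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{out.shape[0]}\t{out.shape[1]}\n")
            body.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_phenotype_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: phenotype table must have exactly 2 columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    ser.index.name = "sample_id"
    if ser.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id {ser.index[ser.index.duplicated()][0]!r}")
    return validate_phenotype(ser)


def write_phenotype_table(pheno: pd.Series, path: str | Path) -> None:
    validate_phenotype(pheno)
    out = pheno.rename("group")
    out.index.name = "sample_id"
    out.to_frame().to_csv(path, sep="\t", lineterminator="\n")


def _fmt_weights(targets: dict[str, float]) -> str:
    return ",".join(repr(float(w)) for w in targets.values())


def write_regulon_gmt(regulons: dict[str, SignedRegulon], path: str | Path) -> None:
    """Write regulons in the signed GMT dialect (two lines per TF)."""
    with open(Path(path), "w", newline="\n") as fh:
        for tf in regulons:
            reg = regulons[tf]
            for tag, members in (("pos", reg.positive), ("neg", reg.negative)):
                fields = [f"{tf}|{tag}", _fmt_weights(dict(members)), *members]
                fh.write("\t".join(fields) + "\n")


def read_regulon_gmt(path: str | Path) -> dict[str, SignedRegulon]:
    path = Path(path)
    halves: dict[str, dict[str, dict[str, float]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, desc, members = fields[0], fields[1], fields[2:]
            if "|" not in name:
                raise ValueError(f"{path}:{lineno}: record {name!r} lacks |pos / |neg suffix")
            tf, tag = name.rsplit("|", 1)
            if tag not in ("pos", "neg"):
                raise ValueError(f"{path}:{lineno}: unknown mode tag {tag!r}")
            weights = [float(w) for w in desc.split(",")] if desc else []
            if len(weights) != len(members):
                raise ValueError(f"{path}:{lineno}: {len(weights)} weights for {len(members)} members")
            if tf not in halves:
                halves[tf] = {}
                order.append(tf)
            if tag in halves[tf]:
                raise ValueError(f"{path}:{lineno}: duplicate {tag!r} record for TF {tf!r}")
            halves[tf][tag] = dict(zip(members, weights))
    out: dict[str, SignedRegulon] = {}
    for tf in order:
        rec = halves[tf]
        if set(rec) != {"pos", "neg"}:
            missing = ({"pos", "neg"} - set(rec)).pop()
            raise ValueError(f"{path}: TF {tf!r} is missing its {missing!r} record")
        out[tf] = SignedRegulon(tf=tf, positive=rec["pos"], negative=rec["neg"])
    return out


def write_signature_db(db: CompoundSignatureDB, path: str | Path) -> None:
    n = db.n_genes
    genes = np.asarray(db.rank_of.index)
    rows = []
    for _, meta in db.meta.iterrows():
        inst = meta["instance_id"]
        ranks = db.rank_of[inst].to_numpy()
        ordered = genes[np.argsort(ranks)]  # rank 1 first
        rows.append([inst, meta["compound"], meta["cell_line"], *ordered])
    header = ["instance_id", "compound", "cell_line", *[f"rank_{i}" for i in range(1, n + 1)]]
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_signature_db(path: str | Path) -> CompoundSignatureDB:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["instance_id", "compound", "cell_line"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    rank_cols = df.columns[3:]
    if len(rank_cols) == 0:
        raise ValueError(f"{path}: no rank columns")
    universe = sorted(df.iloc[0, 3:].astype(str))
    uni_index = pd.Index(universe)
    pos = {g: i for i, g in enumerate(universe)}
    ranks = {}
    for _, row in df.iterrows():
        inst = row["instance_id"]
        ordered = row.iloc[3:].astype(str).to_list()
        if sorted(ordered) != universe:
            raise ValueError(f"{path}: instance {inst!r} list is not a permutation of the universe")
        vec = np.empty(len(universe), dtype=np.int64)
        for r, g in enumerate(ordered, start=1):
            vec[pos[g]] = r
        ranks[inst] = vec
    meta = df[required].reset_index(drop=True)
    rank_of = pd.DataFrame(ranks, index=uni_index)
    return CompoundSignatureDB(meta=meta, rank_of=rank_of)
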