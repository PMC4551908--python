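"""Readers and writers for the plain-text formats the package speaks.

Paired matrices are TSV (first column the feature id, remaining columns
named ``<subject>_<early|late>``) with a sidecar metadata TSV (subject,
age_early, age_late).  Ranked lists are Broad RNK (symbol TAB metric),
gene sets are Broad GMT (name, description, members), probe tracks are
BED4-like TSV and CpG islands BED3.  Floats are written at 6 significant
digits; reads validate and report offending lines/columns by name.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .core import PairedMatrix

__all__ = [
    "read_paired_matrix", "write_paired_matrix",
    "read_score_table", "write_score_table",
    "read_gmt", "write_gmt",
    "read_rnk", "write_rnk",
    "read_bed", "write_window_track",
]

_FLOAT_FMT = "%.6g"
_COL_RE = re.compile(r"^(?P<subject>.+)_(?P<tp>early|late)$")


def read_paired_matrix(path, metadata_path) -> PairedMatrix:
    """Read a feature x paired-sample TSV plus its pair-metadata sidecar."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    early_cols, late_cols = {}, {}
    for col in df.columns:
        m = _COL_RE.match(col)
        if m is None:
            raise ValueError(
                f"malformed sample column {col!r} in {path}: expected "
                "'<subject>_early' or '<subject>_late'")
        (early_cols if m["tp"] == "early" else late_cols)[m["subject"]] = col
    subjects = sorted(early_cols)
    if sorted(late_cols) != subjects:
        odd = sorted(set(early_cols) ^ set(late_cols))
        raise ValueError(f"subjects missing one time point: {odd}")
    meta = pd.read_csv(metadata_path, sep="\t")
    for c in ("subject", "age_early", "age_late"):
        if c not in meta.columns:
            raise ValueError(f"metadata {metadata_path} missing column {c!r}")
    meta = meta.set_index(meta["subject"].astype(str))
    meta.index.name = "pair_id"
    missing = [s for s in subjects if s not in meta.index]
    if missing:
        raise ValueError(f"subjects absent from metadata: {missing}")
    meta = meta.loc[subjects]
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, feature {bad.index[0]!r}")
    early = df[[early_cols[s] for s in subjects]].to_numpy(dtype=float)
    late = df[[late_cols[s] for s in subjects]].to_numpy(dtype=float)
    return PairedMatrix(feature_ids=df.index.to_numpy(dtype=object),
                        pair_ids=np.array(subjects, dtype=object),
                        early=early, late=late, scale="linear", meta=meta)


def write_paired_matrix(m: PairedMatrix, path, metadata_path) -> None:
    cols = {}
    for j, s in enumerate(m.pair_ids):
        cols[f"{s}_early"] = m.early[:, j]
        cols[f"{s}_late"] = m.late[:, j]
    df = pd.DataFrame(cols, index=pd.Index(m.feature_ids, name="feature"))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    if m.meta is not None:
        m.meta.to_csv(metadata_path, sep="\t", index=False,
                      float_format=_FLOAT_FMT)


def write_score_table(st: pd.DataFrame, path, full_precision: bool = False,
                      ) -> None:
    out = st.copy()
    out.index.name = out.index.name or "feature"
    out.to_csv(path, sep="\t",
               float_format=None if full_precision else _FLOAT_FMT)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection: name TAB description TAB members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has no members "
                    f"(name={parts[0]!r})")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_rnk(path) -> pd.Series:
    """Read a two-column RNK ranked list (symbol TAB signed metric)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, "
                                 f"got {len(parts)}")
            try:
                rows.append((parts[0], float(parts[1])))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric metric {parts[1]!r}") from None
    if not rows:
        raise ValueError(f"{path}: empty ranked list")
    genes = [g for g, _ in rows]
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"{path}: duplicate symbols {dup[:5]}")
    from .gsea import make_ranked_list
    return make_ranked_list(genes, [v for _, v in rows])


def write_rnk(rl: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for gene, metric in rl.items():
            fh.write(f"{gene}\t{_FLOAT_FMT % metric}\n")


def read_bed(path, score_col: str | None = "ratio") -> pd.DataFrame:
    """Read BED3 (score_col=None) or BED4-like TSV with a numeric 4th column."""
    names = ["chrom", "start", "end"] + ([score_col] if score_col else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names, usecols=range(len(names)))
    if df.isna().any().any():
        lineno = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}:{lineno}: missing or malformed field")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_window_track(wt, path) -> None:
    """Write binned windows as BED5 + kept flag."""
    df = wt.windows if hasattr(wt, "windows") else wt
    out = df[["chrom", "start", "end", "mean_log2", "n_probes", "kept"]].copy()
    out["kept"] = out["kept"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format=_FLOAT_FMT)
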