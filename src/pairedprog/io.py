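"""Readers and writers for the tabular formats shared across the pipeline.

All tables are tab-separated with a one-line header. The expression matrix
convention is genes in rows (first column ``gene_id``) and samples in
columns. Gene sets use the GMT dialect (set name, description, then member
genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

EXPRESSION_INDEX = "gene_id"

PAIRING_COLUMNS = [
    "patient_id",
    "initial_sample_id",
    "recurrent_sample_id",
    "tumor_status",
    "histology",
]

CLINICAL_COLUMNS = ["sample_id", "patient_id", "tumor_status", "histology"]

MAF_COLUMNS = [
    "sample_id",
    "hugo_symbol",
    "variant_classification",
    "protein_change",
    "is_hotspot",
]

BREAKPOINT_COLUMNS = ["sample_id", "chrom", "pos_1based", "sv_type"]

ANNOTATION_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "role",
    "cosmic",
    "sv_association_sign",
    "hotspot_residues",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV into a float DataFrame."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index.name = EXPRESSION_INDEX
    return m.astype(float)


def write_expression(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label=EXPRESSION_INDEX, float_format="%.6g")


def read_pairing(path: str | Path) -> pd.DataFrame:
    p = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PAIRING_COLUMNS) - set(p.columns)
    if missing:
        raise ValueError(f"pairing table {path} missing columns: {sorted(missing)}")
    return p


def write_pairing(pairing: pd.DataFrame, path: str | Path) -> None:
    pairing.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    c = pd.read_csv(path, sep="\t")
    missing = set(CLINICAL_COLUMNS) - set(c.columns)
    if missing:
        raise ValueError(f"clinical table {path} missing columns: {sorted(missing)}")
    return c


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> pd.DataFrame:
    v = pd.read_csv(path, sep="\t")
    missing = set(MAF_COLUMNS) - set(v.columns)
    if missing:
        raise ValueError(f"variant table {path} missing columns: {sorted(missing)}")
    v["is_hotspot"] = v["is_hotspot"].astype(bool)
    return v


def read_cna(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix of thresholded copy-number calls in {-2..2}."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index.name = EXPRESSION_INDEX
    return m.astype(int)


def read_breakpoints(path: str | Path) -> pd.DataFrame:
    b = pd.read_csv(path, sep="\t")
    missing = set(BREAKPOINT_COLUMNS) - set(b.columns)
    if missing:
        raise ValueError(f"breakpoint table {path} missing columns: {sorted(missing)}")
    b["pos_1based"] = b["pos_1based"].astype(int)
    return b


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation: coordinates, role, COSMIC flag, SV sign, hotspots.

    ``hotspot_residues`` is serialized as a semicolon-joined list of integer
    protein positions (empty string for none); it is parsed into a frozenset.
    """
    a = pd.read_csv(path, sep="\t", dtype={"hotspot_residues": str})
    missing = set(ANNOTATION_COLUMNS) - set(a.columns)
    if missing:
        raise ValueError(f"annotation table {path} missing columns: {sorted(missing)}")
    a["hotspot_residues"] = [
        frozenset(int(x) for x in str(s).split(";") if x not in ("", "nan"))
        for s in a["hotspot_residues"].fillna("")
    ]
    return a.set_index("gene_id", drop=False)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["hotspot_residues"] = [
        ";".join(str(p) for p in sorted(s)) for s in out["hotspot_residues"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_gene_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index_label=EXPRESSION_INDEX)


def read_rnk(path: str | Path) -> pd.Series:
    """Read a two-column .rnk-style file (gene, statistic), sorted descending."""
    r = pd.read_csv(path, sep="\t", header=None, names=["gene", "stat"], comment="#")
    s = pd.Series(r["stat"].astype(float).values, index=r["gene"].astype(str))
    return s.sort_values(ascending=False, kind="stable")


def write_rnk(ranking: pd.Series, path: str | Path) -> None:
    ranking.to_csv(path, sep="\t", header=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of set name -> member genes.

    Duplicate genes within a set are dropped (first occurrence kept).
    Raises on lines with fewer than three fields, naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    if hasattr(x, "item"):  # numpy scalar
        return x.item()
    if hasattr(x, "tolist"):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
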