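"""Plain-text readers and writers for every pipeline artefact.

All formats are TSV with documented headers (study-scale data are tiny and
reviewability matters); positions are cM decimals, haplotype calls are the
literal symbols Q/q/x.  Every writer/reader pair round-trips exactly:
floats are serialized with ``repr`` precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import MarkerMap
from .haplotypes import HaplotypeTable, haplotype_table
from .linkage import QTLScanResult, TransmissionProfile

__all__ = [
    "write_marker_map", "read_marker_map",
    "write_inheritance", "read_inheritance",
    "write_phenotypes", "read_phenotypes",
    "write_expression", "read_expression",
    "write_haplotype_table", "read_haplotype_table",
    "write_scan", "read_scan",
    "check_consistency",
]

def _FLOAT_FMT(v):
    # shortest exact decimal representation; round-trips bit-for-bit
    return repr(float(v))


def _to_tsv(df: pd.DataFrame, path, index_label):
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def write_marker_map(mm: MarkerMap, path):
    mm.to_dataframe().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise ValueError(f"{path}: duplicate marker identifier {dup!r}")
    return MarkerMap.from_dataframe(df)


def write_inheritance(inherit: pd.DataFrame, path):
    out = inherit.copy()
    _to_tsv(out, path, index_label="animal")


def read_inheritance(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("animal")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate animal identifiers")
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 1.0) | (vals == 2.0)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"{path}: line {i + 2}: inheritance value {vals[i, j]!r} for animal "
            f"{df.index[i]!r} at marker {df.columns[j]!r} is not 1, 2 or NA"
        )
    return df.astype(float)


def write_phenotypes(pheno: pd.DataFrame, path):
    _to_tsv(pheno, path, index_label="animal")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("animal")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate animal identifiers")
    required = {"trait", "hatch", "dam", "body_weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    return df


def write_expression(expr: pd.DataFrame, path):
    _to_tsv(expr, path, index_label="gene")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("gene")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene identifiers")
    return df.astype(float)


def write_haplotype_table(table: HaplotypeTable, path):
    table.table.to_csv(path, sep="\t", index_label="animal")


def read_haplotype_table(path) -> HaplotypeTable:
    df = pd.read_csv(path, sep="\t").set_index("animal")
    subgroup = df["subgroup"] if "subgroup" in df.columns else None
    return haplotype_table(df["proximal"], df["distal"], subgroup)


def write_scan(scan: QTLScanResult, path, sidecar: str | Path | None = None):
    """Scan curve as TSV (pos_cM, lrt, lod); summary numbers in a JSON sidecar."""
    import json

    scan.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if sidecar is not None:
        meta = {
            "model": scan.model,
            "n": scan.n,
            "max_pos": scan.max_pos,
            "max_lrt": scan.max_lrt,
            "effect": scan.effect,
            "effect_sd": scan.effect_sd,
            "ci": list(scan.ci) if scan.ci else None,
            "fixed_pos": scan.fixed_pos,
            "threshold": scan.threshold.value if scan.threshold else None,
            "threshold_level": scan.threshold.level if scan.threshold else None,
        }
        Path(sidecar).write_text(json.dumps(meta, indent=1))


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def check_consistency(inherit: pd.DataFrame | None = None,
                      pheno: pd.DataFrame | None = None,
                      expr: pd.DataFrame | None = None,
                      marker_map: MarkerMap | None = None):
    """Cross-file identifier consistency; raises naming the offender."""
    sets = {}
    if inherit is not None:
        sets["inherit"] = set(inherit.index)
    if pheno is not None:
        sets["pheno"] = set(pheno.index)
    if expr is not None:
        sets["expr"] = set(expr.columns)
    names = list(sets)
    for a in names:
        for b in names:
            if a < b and sets[a] != sets[b]:
                diff = sorted(sets[a] ^ sets[b])
                raise ValueError(
                    f"animal sets differ between {a} and {b}: {diff[:10]}"
                )
    if inherit is not None and marker_map is not None:
        if list(inherit.columns) != list(marker_map.names):
            raise ValueError("inheritance markers do not match the marker map")
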