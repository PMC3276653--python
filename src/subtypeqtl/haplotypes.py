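"""Per-animal paternal Q/q haplotype calls at QTL regions.

A region call uses only the markers inside the region of interest: the
posterior transmission probability is computed at the region center from
those markers alone, and the call is Q (or q) when it exceeds the
determination threshold (0.99 by default), "x" otherwise.

The published haplotype table of the 45-bird study family ships with the
package as a plain-text reference dataset and is exposed through
:func:`load_study_haplotype_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .genmap import MarkerMap
from .linkage import transmission_probabilities

__all__ = [
    "HaplotypeTable",
    "call_haplotype",
    "haplotype_table",
    "subtype_haplotype_summary",
    "load_study_haplotype_table",
]


def call_haplotype(
    inherit: pd.DataFrame,
    marker_map: MarkerMap,
    region_center: float,
    region_halfwidth: float,
    threshold: float = 0.99,
    q_homolog: int = 1,
    at: str = "center",
) -> pd.Series:
    """Q/q/x call per animal at one QTL region.

    Parameters
    ----------
    inherit : animals x markers transmitted-homolog matrix (1/2/NaN)
    region_center, region_halfwidth : cM; markers outside
        ``center +- halfwidth`` are ignored.
    threshold : determination probability (call made when P > threshold)
    at : "center" calls at the region center; "max" calls at the in-region
        position (center or a marker) where the posterior is most extreme.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError("threshold must lie in (0.5, 1)")
    sub_map = marker_map.restrict(region_center - region_halfwidth, region_center + region_halfwidth)
    if sub_map is None:
        warnings.warn(
            f"no marker within {region_center}+-{region_halfwidth} cM; all calls are 'x'",
            stacklevel=2,
        )
        return pd.Series("x", index=inherit.index, name="call")
    sub_inherit = inherit[list(sub_map.names)]
    if at == "center":
        grid = np.array([region_center])
    elif at == "max":
        grid = np.unique(np.concatenate([[region_center], sub_map.positions]))
    else:
        raise ValueError("at must be 'center' or 'max'")
    profile = transmission_probabilities(sub_inherit, sub_map, grid=grid, q_homolog=q_homolog)
    p = profile.pi.to_numpy(dtype=float)
    if at == "center":
        p_q = p[:, 0]
    else:
        extreme = np.argmax(np.abs(p - 0.5), axis=1)
        p_q = p[np.arange(p.shape[0]), extreme]
    calls = np.where(p_q > threshold, "Q", np.where(1.0 - p_q > threshold, "q", "x"))
    return pd.Series(calls, index=inherit.index, name="call")


@dataclass
class HaplotypeTable:
    """Per-animal haplotype calls at the proximal and distal QTL."""

    table: pd.DataFrame  # columns: subgroup, proximal, distal, both

    @property
    def n_proximal_determined(self) -> int:
        return int((self.table["proximal"] != "x").sum())

    @property
    def n_distal_determined(self) -> int:
        return int((self.table["distal"] != "x").sum())

    @property
    def n_both_determined(self) -> int:
        return int((self.table["both"] != "X").sum())

    @property
    def counts(self) -> tuple:
        return (self.n_proximal_determined, self.n_distal_determined, self.n_both_determined)

    def determined(self) -> pd.DataFrame:
        """Rows with both loci determined (the animals the two-way ANOVA uses)."""
        return self.table[self.table["both"] != "X"]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def haplotype_table(
    calls_proximal: pd.Series,
    calls_distal: pd.Series,
    subtypes: pd.Series | None = None,
) -> HaplotypeTable:
    """Combine per-locus calls into a study-style haplotype table.

    The joint column is "<prox>-<dist>" when both calls are determined and
    "X" otherwise.
    """
    if set(calls_proximal.index) != set(calls_distal.index):
        raise ValueError("proximal and distal calls cover different animal sets")
    idx = calls_proximal.index
    for name, calls in (("proximal", calls_proximal), ("distal", calls_distal)):
        bad = set(calls.unique()) - {"Q", "q", "x"}
        if bad:
            raise ValueError(f"{name} calls contain invalid symbols {bad}")
    distal = calls_distal.reindex(idx)
    both = np.where(
        (calls_proximal == "x") | (distal == "x"),
        "X",
        calls_proximal.astype(str) + "-" + distal.astype(str),
    )
    df = pd.DataFrame(
        {
            "subgroup": subtypes.reindex(idx) if subtypes is not None else "",
            "proximal": calls_proximal,
            "distal": distal,
            "both": both,
        },
        index=idx,
    )
    df.index.name = "animal"
    return HaplotypeTable(table=df)


def subtype_haplotype_summary(table: HaplotypeTable, subgroup: str, locus: str):
    """(n_in_group, n_determined, count_Q, count_q) for one subgroup/locus."""
    if locus not in ("proximal", "distal"):
        raise ValueError("locus must be 'proximal' or 'distal'")
    known = set(table.table["subgroup"].unique())
    if subgroup not in known:
        raise KeyError(f"unknown subgroup {subgroup!r}; have {sorted(known)}")
    rows = table.table[table.table["subgroup"] == subgroup]
    calls = rows[locus]
    return (
        len(rows),
        int((calls != "x").sum()),
        int((calls == "Q").sum()),
        int((calls == "q").sum()),
    )


def load_study_haplotype_table() -> HaplotypeTable:
    """The published haplotype table of the 45-bird study family.

    Static reference data (a transcription, not a computation): subgroup
    membership and Q/q/x calls at the proximal and distal fatness QTL.
    """
    with resources.files("subtypeqtl.data").joinpath("study_haplotypes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("animal")
    return haplotype_table(df["proximal"], df["distal"], df["subgroup"])
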