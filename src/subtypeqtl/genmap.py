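"""Genetic map containers and map functions.

All positions are genetic distances in centimorgan (cM) on a single
chromosome; there are no physical coordinates anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "haldane_recombination",
    "kosambi_recombination",
    "MarkerMap",
    "STUDY_MICROSATELLITE_CM",
    "STUDY_SNP_CM",
]

# The half-sib study family's chromosome-5 marker panel: ten microsatellites
# spanning the distal QTL region, plus six SNPs later added to fine-map the
# proximal region.
STUDY_MICROSATELLITE_CM = (83.0, 100.0, 125.0, 151.0, 162.0, 166.0, 175.0, 187.0, 190.0, 192.0)
STUDY_SNP_CM = (67.0, 77.0, 80.0, 86.0, 89.0, 95.0)


def haldane_recombination(d_cm):
    """Recombination fraction for a genetic distance under Haldane's map.

    No crossover interference: ``c = (1 - exp(-2d/100)) / 2``.  Vectorized.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distances must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def kosambi_recombination(d_cm):
    """Recombination fraction under Kosambi's map, ``c = tanh(2d/100)/2``.

    Offered for interpreting externally supplied maps; the simulator and the
    transmission chain use Haldane throughout (no interference).
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distances must be non-negative")
    return 0.5 * np.tanh(2.0 * d / 100.0)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker positions on one chromosome.

    Parameters
    ----------
    names : sequence of str
        Unique marker identifiers.
    positions : sequence of float
        Strictly increasing positions in cM.
    chromosome : str
        Chromosome label (cosmetic; the package is single-chromosome).
    """

    names: tuple = field(default_factory=tuple)
    positions: np.ndarray = field(default_factory=lambda: np.array([]))
    chromosome: str = "5"

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.names) != pos.size:
            raise ValueError("names and positions must have equal length")
        if pos.size == 0:
            raise ValueError("a marker map needs at least one marker")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate marker names")

    def __len__(self):
        return self.positions.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.names, "chrom": self.chromosome, "pos_cM": self.positions}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerMap":
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        chroms = df["chrom"].astype(str).unique()
        if len(chroms) != 1:
            raise ValueError("marker map must cover a single chromosome")
        order = np.argsort(df["pos_cM"].to_numpy())
        if not np.array_equal(order, np.arange(len(df))):
            raise ValueError("marker map rows must be sorted by position")
        return cls(
            names=tuple(df["marker"].astype(str)),
            positions=df["pos_cM"].to_numpy(dtype=float),
            chromosome=str(chroms[0]),
        )

    def restrict(self, low_cm: float, high_cm: float) -> "MarkerMap | None":
        """Sub-map of markers with ``low_cm <= pos <= high_cm`` (None if empty)."""
        keep = (self.positions >= low_cm) & (self.positions <= high_cm)
        if not keep.any():
            return None
        return MarkerMap(
            names=tuple(n for n, k in zip(self.names, keep) if k),
            positions=self.positions[keep],
            chromosome=self.chromosome,
        )


def study_marker_map(include_fine_mapping_snps: bool = False) -> MarkerMap:
    """The study family's chromosome-5 marker map.

    With ``include_fine_mapping_snps`` the six proximal-region SNPs are merged
    in, reproducing the map used to localise the proximal QTL.
    """
    pos = list(STUDY_MICROSATELLITE_CM)
    names = [f"MS{int(p)}" for p in pos]
    if include_fine_mapping_snps:
        pos = list(STUDY_SNP_CM) + pos
        names = [f"SNP{int(p)}" for p in STUDY_SNP_CM] + names
    order = np.argsort(pos)
    return MarkerMap(
        names=tuple(names[i] for i in order),
        positions=np.asarray(pos, dtype=float)[order],
    )
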