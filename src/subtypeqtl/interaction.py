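"""QTL x QTL interaction testing and the candidate-gene filter.

Three complementary views of epistasis between the proximal and distal
fatness QTL:

1. a two-way ANOVA of the trait on the 2 x 2 paternal haplotype classes
   (Type-II sums of squares; only animals with both haplotypes determined),
2. a "fixed-QTL interaction" scan -- no QTL versus one QTL in interaction
   with a second QTL fixed at a known position (2 extra df), and
3. a two-QTL additive scan -- one QTL versus two, no product term (1 df).

Plus the three-condition candidate-gene filter: genes whose distal eQTL
colocalizes with the distal trait QTL, whose proximal signal under the
interaction model colocalizes with the proximal trait QTL, and which are
differentially expressed between the two lean subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import HaplotypeTable
from .linkage import (
    EmpiricalThreshold,
    QTLScanResult,
    TransmissionProfile,
    _build_scan,
    _lrt_matrix,
    empirical_threshold,
)

__all__ = [
    "InteractionAnova",
    "two_way_anova_interaction",
    "interaction_scan",
    "two_qtl_additive_scan",
    "eqtl_candidate_filter",
    "intervals_overlap",
]


@dataclass
class InteractionAnova:
    """Two-way ANOVA of the trait on the proximal x distal haplotype classes."""

    anova: pd.DataFrame  # rows proximal/distal/interaction/residual
    cell_means: pd.DataFrame  # proximal (rows) x distal (columns)
    cell_counts: pd.DataFrame
    diff_given_distal_Q: float  # proximal Q - q difference on the distal-Q background
    diff_given_distal_q: float
    n: int

    @property
    def p_interaction(self) -> float:
        return float(self.anova.loc["proximal:distal", "PR(>F)"])

    @property
    def p_proximal(self) -> float:
        return float(self.anova.loc["proximal", "PR(>F)"])

    @property
    def p_distal(self) -> float:
        return float(self.anova.loc["distal", "PR(>F)"])

    def summary(self) -> str:
        lines = [
            f"Two-way haplotype ANOVA (n = {self.n} animals with both calls)",
            "=" * 56,
            self.anova.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "trait means by haplotype class:",
            self.cell_means.to_string(float_format=lambda v: f"{v:.2f}"),
            "",
            f"proximal Q-q difference | distal Q: {self.diff_given_distal_Q:+.2f}",
            f"proximal Q-q difference | distal q: {self.diff_given_distal_q:+.2f}",
        ]
        return "\n".join(lines)


def two_way_anova_interaction(
    adjusted_trait: pd.Series, table: HaplotypeTable, ss_type: int = 2
) -> InteractionAnova:
    """Trait ~ proximal + distal + proximal:distal on the haplotype classes.

    Only animals with both calls determined enter.  Type-II sums of squares
    by default (the design is unbalanced); Type-III available via
    ``ss_type=3``.  An empty haplotype cell makes the interaction
    inestimable and raises.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    det = table.determined()
    df = pd.DataFrame(
        {
            "trait": adjusted_trait.reindex(det.index),
            "proximal": det["proximal"],
            "distal": det["distal"],
        }
    )
    if df["trait"].isna().any():
        raise ValueError("trait missing for some haplotype-determined animals")
    counts = df.pivot_table(index="proximal", columns="distal", values="trait", aggfunc="size").reindex(
        index=["Q", "q"], columns=["Q", "q"]
    )
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError(
            "empty haplotype cell; the interaction is inestimable:\n" + counts.to_string()
        )
    fit = smf.ols("trait ~ C(proximal) + C(distal) + C(proximal):C(distal)", data=df).fit()
    an = anova_lm(fit, typ=ss_type)
    an = an.rename(
        index={
            "C(proximal)": "proximal",
            "C(distal)": "distal",
            "C(proximal):C(distal)": "proximal:distal",
            "Residual": "residual",
        }
    )
    means = df.pivot_table(index="proximal", columns="distal", values="trait", aggfunc="mean").reindex(
        index=["Q", "q"], columns=["Q", "q"]
    )
    return InteractionAnova(
        anova=an,
        cell_means=means,
        cell_counts=counts.astype(int),
        diff_given_distal_Q=float(means.loc["Q", "Q"] - means.loc["q", "Q"]),
        diff_given_distal_q=float(means.loc["Q", "q"] - means.loc["q", "q"]),
        n=len(df),
    )


def _nested_scan(adjusted_trait, profile, fixed_pos, model, n_sim, h2, level, rng, design=None):
    y = adjusted_trait.reindex(profile.animals)
    if y.isna().any():
        raise ValueError("trait missing for some animals in the profile")
    y = y.to_numpy(dtype=float)
    w_fixed = 2.0 * profile.column(fixed_pos) - 1.0
    if np.allclose(np.std(w_fixed), 0.0) and model == "interaction":
        warnings.warn(
            "transmission at the conditioning position is uninformative; the "
            "interaction model collapses to the plain one-QTL scan",
            stacklevel=3,
        )
    lrt, slope = _lrt_matrix(y[:, None], profile.w(), model=model, w_fixed=w_fixed)
    scan = _build_scan(y, profile, model, fixed_pos, lrt[:, 0], slope[:, 0])
    if n_sim:
        scan.threshold = empirical_threshold(
            profile, n_sim=n_sim, h2=h2, level=level, rng=rng, model=model,
            fixed_pos=fixed_pos, design=design,
        )
    return scan


def interaction_scan(
    adjusted_trait: pd.Series,
    profile: TransmissionProfile,
    fixed_pos: float,
    n_sim: int = 2000,
    h2: float = 0.5,
    level: float = 0.05,
    rng=None,
    design=None,
) -> QTLScanResult:
    """No QTL versus one QTL in interaction with a QTL fixed at ``fixed_pos``.

    H0: y = mu + a_f w(fixed);  H1: y = mu + a_f w(fixed) + a_x w(x)
    + g w(x) w(fixed).  Two df are added; the empirical threshold is
    recomputed under H0 by polygenic simulation.  Pass ``n_sim=0`` to skip
    the threshold.
    """
    return _nested_scan(
        adjusted_trait, profile, fixed_pos, "interaction", n_sim, h2, level, rng, design
    )


def two_qtl_additive_scan(
    adjusted_trait: pd.Series,
    profile: TransmissionProfile,
    fixed_pos: float,
    n_sim: int = 2000,
    h2: float = 0.5,
    level: float = 0.05,
    rng=None,
    design=None,
) -> QTLScanResult:
    """One QTL versus two QTL, additive (no product term; 1 extra df)."""
    return _nested_scan(
        adjusted_trait, profile, fixed_pos, "additive", n_sim, h2, level, rng, design
    )


def intervals_overlap(a: tuple, b: tuple) -> bool:
    """Closed-interval overlap (symmetric, reflexive)."""
    return a[0] <= b[1] and b[0] <= a[1]


def eqtl_candidate_filter(
    expr: pd.DataFrame,
    profile: TransmissionProfile,
    distal_trait_ci: tuple,
    proximal_trait_ci: tuple,
    subtypes: pd.Series,
    fixed_pos: float = 168.0,
    alpha_interaction: float = 0.1,
    alpha_de: float = 0.1,
    n_sim: int = 500,
    h2: float = 0.5,
    rng=None,
) -> pd.DataFrame:
    """Candidate genes whose expression is controlled by both regions in
    interaction, the way the trait is.

    A gene is kept when all three hold:

    1. its classical (no-vs-one eQTL) scan peaks with a one-LOD support
       interval overlapping the distal trait-QTL interval,
    2. its interaction-model scan (distal eQTL fixed at ``fixed_pos``) has an
       empirical chromosome-wide p-value < ``alpha_interaction`` and a
       support interval overlapping the proximal trait-QTL interval, and
    3. it is differentially expressed between the two lean subtypes
       (equal-variance t-test p < ``alpha_de``).

    Gene expression is used unadjusted for hatch/dam (small-family
    convention); the caller chooses raw or factor-adjusted expression.
    Returns a diagnostic DataFrame for all genes with a boolean
    ``candidate`` column.
    """
    rng = np.random.default_rng(rng)
    animals = profile.animals
    Y = expr[animals].to_numpy(dtype=float).T  # n x genes
    Y = Y - Y.mean(axis=0, keepdims=True)
    W = profile.w()
    w_fixed = 2.0 * profile.column(fixed_pos) - 1.0

    lrt_cls, slope_cls = _lrt_matrix(Y, W, model="single")
    lrt_int, slope_int = _lrt_matrix(Y, W, model="interaction", w_fixed=w_fixed)
    thr_int = empirical_threshold(
        profile, n_sim=n_sim, h2=h2, level=alpha_interaction, rng=rng,
        model="interaction", fixed_pos=fixed_pos,
    )

    lean1 = [a for a in animals if subtypes.get(a) == "lean1"]
    lean2 = [a for a in animals if subtypes.get(a) == "lean2"]
    have_lean = bool(lean1) and bool(lean2)
    if not have_lean:
        warnings.warn("lean1/lean2 subgroups unavailable; the differential-expression "
                      "condition is skipped", stacklevel=2)

    grid = profile.grid
    records = []
    for j, gene in enumerate(expr.index):
        rec = {"gene": gene}
        scan_c = _build_scan(Y[:, j], profile, "single", None, lrt_cls[:, j], slope_cls[:, j])
        rec["classical_max_pos"] = scan_c.max_pos
        rec["classical_max_lrt"] = scan_c.max_lrt
        rec["distal_colocalized"] = intervals_overlap(scan_c.ci, distal_trait_ci)
        scan_i = _build_scan(Y[:, j], profile, "interaction", fixed_pos, lrt_int[:, j], slope_int[:, j])
        rec["interaction_max_pos"] = scan_i.max_pos
        rec["interaction_max_lrt"] = scan_i.max_lrt
        rec["interaction_p"] = thr_int.pvalue(scan_i.max_lrt)
        rec["proximal_colocalized"] = intervals_overlap(scan_i.ci, proximal_trait_ci)
        if have_lean:
            _, p_de = stats.ttest_ind(
                expr.loc[gene, lean1].to_numpy(dtype=float),
                expr.loc[gene, lean2].to_numpy(dtype=float),
                equal_var=True,
            )
            rec["lean_de_p"] = float(p_de)
        else:
            rec["lean_de_p"] = np.nan
        rec["candidate"] = bool(
            rec["distal_colocalized"]
            and rec["proximal_colocalized"]
            and rec["interaction_p"] < alpha_interaction
            and (not have_lean or rec["lean_de_p"] < alpha_de)
        )
        records.append(rec)
    out = pd.DataFrame.from_records(records).set_index("gene")
    return out
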