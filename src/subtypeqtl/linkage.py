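"""Half-sib interval mapping.

Paternal transmission probabilities by a two-state forward-backward pass
along the chromosome, approximate-LRT scans by within-family regression on
expected transmission (Haley-Knott style), chromosome-wide empirical
thresholds from polygenic-only simulation, one-LOD-drop confidence
intervals, and leave-one-subtype-out scans.

The statistical test at position x is

    H0: y_i = mu + e_i
    H1: y_i = mu + a * w_i(x) + e_i,    w_i(x) = 2 * pi_i(x) - 1,

with Gaussian residuals, giving LRT(x) = n * ln(RSS0 / RSS1).  The Q-q
substitution effect is 2a.  LOD(x) = LRT(x) / (2 ln 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import MarkerMap, haldane_recombination

__all__ = [
    "TransmissionProfile",
    "QTLScanResult",
    "EmpiricalThreshold",
    "LOD_PER_LRT",
    "adjust_phenotype",
    "transmission_probabilities",
    "scan_chromosome",
    "empirical_threshold",
    "lod_drop_ci",
    "leave_one_subtype_out_scans",
]

# One LOD unit equals 2 ln 10 units of the LRT statistic.
LRT_PER_LOD = 2.0 * np.log(10.0)
LOD_PER_LRT = 1.0 / LRT_PER_LOD


# ---------------------------------------------------------------------------
# phenotype pre-adjustment
# ---------------------------------------------------------------------------

def adjustment_design(pheno: pd.DataFrame) -> pd.DataFrame:
    """Design matrix of the nuisance model: intercept, hatch and dam
    dummies, body weight.

    Factor levels carried by a single animal are pooled into the largest
    level (with a warning) so the design stays estimable.  The same design
    must be applied to simulated null traits when computing empirical
    thresholds, so observed and simulated scans lose the same degrees of
    freedom.
    """
    df = pheno.copy()
    for col in ("hatch", "dam"):
        counts = df[col].value_counts()
        singletons = counts.index[counts < 2]
        if len(singletons):
            warnings.warn(
                f"{col} level(s) {list(singletons)} have a single animal; pooled",
                stacklevel=2,
            )
            df.loc[df[col].isin(singletons), col] = counts.idxmax()
    cols = {"intercept": np.ones(len(df))}
    for col in ("hatch", "dam"):
        dummies = pd.get_dummies(df[col], drop_first=True)
        for c in dummies:
            cols[f"{col}_{c}"] = dummies[c].to_numpy(dtype=float)
    cols["body_weight"] = df["body_weight"].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _project_out(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def adjust_phenotype(pheno: pd.DataFrame, trait_col: str = "trait") -> pd.Series:
    """Residuals of ``trait ~ C(hatch) + C(dam) + body_weight``, centered."""
    X = adjustment_design(pheno).to_numpy(dtype=float)
    y = pheno[trait_col].to_numpy(dtype=float)
    resid = _project_out(y[:, None], X)[:, 0]
    resid = resid - resid.mean()
    return pd.Series(resid, index=pheno.index, name="adjusted_trait")


# ---------------------------------------------------------------------------
# transmission probabilities
# ---------------------------------------------------------------------------

@dataclass
class TransmissionProfile:
    """P(Q-bearing homolog transmitted) per offspring on a cM grid."""

    grid: np.ndarray  # positions (cM)
    pi: pd.DataFrame  # animals x positions

    @property
    def animals(self):
        return list(self.pi.index)

    def w(self) -> np.ndarray:
        """Transmission coding ``w = 2 pi - 1 = P(Q) - P(q)``, animals x grid."""
        return 2.0 * self.pi.to_numpy(dtype=float) - 1.0

    def column(self, pos_cm: float) -> np.ndarray:
        """pi at the grid position nearest ``pos_cm``."""
        j = int(np.argmin(np.abs(self.grid - pos_cm)))
        return self.pi.iloc[:, j].to_numpy(dtype=float)

    def subset(self, animals) -> "TransmissionProfile":
        return TransmissionProfile(grid=self.grid, pi=self.pi.loc[list(animals)])


def _forward_backward(obs_states, distances_cm):
    """Posterior P(state 1) for one offspring along ordered positions.

    obs_states: array over positions; 1 or 2 where the transmitted homolog
    was observed, 0 where unknown.  Transitions are Haldane.  Returns an
    array of P(homolog 1) per position.  A zero-likelihood path (conflicting
    observations at zero distance) is flagged and yields 0.5 everywhere.
    """
    P = len(obs_states)
    c = haldane_recombination(distances_cm)
    alpha = np.zeros((P, 2))
    like = np.array([0.5, 0.5])
    for j in range(P):
        if j > 0:
            cj = c[j - 1]
            like = np.array(
                [like[0] * (1 - cj) + like[1] * cj, like[0] * cj + like[1] * (1 - cj)]
            )
        if obs_states[j] == 1:
            like = like * np.array([1.0, 0.0])
        elif obs_states[j] == 2:
            like = like * np.array([0.0, 1.0])
        s = like.sum()
        if s == 0.0:
            warnings.warn(
                "marker observations inconsistent with the map (zero-likelihood "
                "origin path); posterior set to 0.5",
                stacklevel=3,
            )
            return np.full(P, 0.5)
        like = like / s
        alpha[j] = like
    beta = np.ones((P, 2))
    back = np.array([1.0, 1.0])
    for j in range(P - 2, -1, -1):
        nxt = back.copy()
        if obs_states[j + 1] == 1:
            nxt = nxt * np.array([1.0, 0.0])
        elif obs_states[j + 1] == 2:
            nxt = nxt * np.array([0.0, 1.0])
        cj = c[j]
        back = np.array(
            [nxt[0] * (1 - cj) + nxt[1] * cj, nxt[0] * cj + nxt[1] * (1 - cj)]
        )
        back = back / back.sum()
        beta[j] = back
    post = alpha * beta
    post = post / post.sum(axis=1, keepdims=True)
    return post[:, 0]


def transmission_probabilities(
    inherit: pd.DataFrame,
    marker_map: MarkerMap,
    grid=None,
    q_homolog: int = 1,
    step_cm: float = 1.0,
    chromosome_length: float | None = None,
) -> TransmissionProfile:
    """Posterior transmission probabilities by forward-backward.

    Parameters
    ----------
    inherit : DataFrame, animals x markers with values 1, 2 or NaN (unknown).
        Columns must match ``marker_map.names``.
    marker_map : MarkerMap (sire phase: ``q_homolog`` carries Q everywhere)
    grid : optional positions; default a ``step_cm`` grid over the chromosome
        (0 .. chromosome_length, which defaults to the last marker position).
    """
    if list(inherit.columns) != list(marker_map.names):
        raise ValueError("inheritance columns must match the marker map")
    if q_homolog not in (1, 2):
        raise ValueError("q_homolog must be 1 or 2")
    if grid is None:
        L = chromosome_length if chromosome_length is not None else marker_map.positions[-1]
        grid = np.arange(0.0, L + step_cm / 2, step_cm)
    grid = np.asarray(grid, dtype=float)
    grid_order = np.argsort(grid, kind="mergesort")
    grid_sorted = grid[grid_order]
    all_pos = np.concatenate([grid_sorted, marker_map.positions])
    order = np.argsort(all_pos, kind="mergesort")
    sorted_pos = all_pos[order]
    is_grid = order < grid.size
    marker_slot = np.empty(len(marker_map), dtype=int)
    inv = np.argsort(order, kind="mergesort")
    for k in range(len(marker_map)):
        marker_slot[k] = inv[grid.size + k]
    distances = np.diff(sorted_pos)
    obs_template = np.zeros(sorted_pos.size, dtype=np.int8)

    vals = inherit.to_numpy(dtype=float)
    post = np.empty((inherit.shape[0], grid.size))
    for i in range(inherit.shape[0]):
        obs = obs_template.copy()
        row = vals[i]
        known = ~np.isnan(row)
        obs[marker_slot[known]] = row[known].astype(np.int8)
        p1 = _forward_backward(obs, distances)
        p_q = p1 if q_homolog == 1 else 1.0 - p1
        # a grid point may coincide with a marker; the zero-distance
        # transition makes the posteriors identical there
        post[i, grid_order] = p_q[is_grid]
    pi = pd.DataFrame(post, index=inherit.index, columns=grid)
    return TransmissionProfile(grid=grid, pi=pi)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

@dataclass
class QTLScanResult:
    """An approximate-LRT scan along the chromosome."""

    positions: np.ndarray
    lrt: np.ndarray
    max_pos: float
    max_lrt: float
    effect: float  # Q-q substitution effect in trait units
    effect_sd: float  # same, in phenotypic SD
    n: int
    model: str = "single"
    fixed_pos: float | None = None
    threshold: "EmpiricalThreshold | None" = None
    ci: tuple | None = None
    flat: bool = False

    @property
    def lod(self) -> np.ndarray:
        return self.lrt * LOD_PER_LRT

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return bool(self.max_lrt > self.threshold.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos_cM": self.positions, "lrt": self.lrt, "lod": self.lod})

    def summary(self) -> str:
        lines = [
            f"QTL scan ({self.model} model, n = {self.n})",
            "=" * 44,
            f"max LRT {self.max_lrt:.2f} at {self.max_pos:.1f} cM",
            f"Q-q substitution effect: {self.effect:+.3f} trait units"
            f" ({self.effect_sd:+.2f} phenotypic SD)",
        ]
        if self.ci is not None:
            lines.append(f"one-LOD support interval: {self.ci[0]:.1f} - {self.ci[1]:.1f} cM")
        if self.threshold is not None:
            verdict = "significant" if self.significant else "not significant"
            lines.append(
                f"chromosome-wide {100 * (1 - self.threshold.level):.0f}% threshold: "
                f"{self.threshold.value:.2f} ({verdict})"
            )
        if self.fixed_pos is not None:
            lines.append(f"conditioning QTL fixed at {self.fixed_pos:.0f} cM")
        return "\n".join(lines)


@dataclass
class EmpiricalThreshold:
    """Chromosome-wide empirical significance threshold."""

    value: float
    level: float
    n_sim: int
    h2: float
    maxima: np.ndarray = field(repr=False, default=None)

    def pvalue(self, observed_max_lrt: float) -> float:
        """Empirical chromosome-wide p-value of an observed maximum LRT."""
        return float((np.sum(self.maxima >= observed_max_lrt) + 1) / (self.n_sim + 1))


def _lrt_matrix(Y: np.ndarray, W: np.ndarray, model: str = "single", w_fixed: np.ndarray | None = None):
    """LRT for every (position, trait) pair.

    Y: n x R trait matrix; W: n x P transmission coding.  Returns (P x R
    LRT array, P x R slope array for the scanned position).  ``model``:

    - "single":      H0 mean-only            vs H1 + a w(x)
    - "additive":    H0 mu + a_f w_fixed     vs H1 + a_x w(x)
    - "interaction": H0 mu + a_f w_fixed     vs H1 + a_x w(x) + g w(x) w_fixed

    Rank-deficient designs (e.g. w(x) collinear with w_fixed) are handled by
    least squares on the reduced column space, so a degenerate conditioning
    collapses gracefully to the nested model.
    """
    n, R = Y.shape
    P = W.shape[1]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    if model == "single":
        Wc = W - W.mean(axis=0, keepdims=True)
        rss0 = (Yc ** 2).sum(axis=0)  # R
        den = (Wc ** 2).sum(axis=0)  # P
        num = Wc.T @ Yc  # P x R
        safe = den > 1e-12
        slope = np.zeros((P, R))
        slope[safe] = num[safe] / den[safe, None]
        rss1 = rss0[None, :] - np.where(safe[:, None], num ** 2 / np.where(safe, den, 1.0)[:, None], 0.0)
        rss1 = np.maximum(rss1, 1e-300)
        lrt = n * np.log(np.maximum(rss0[None, :], 1e-300) / rss1)
        return np.maximum(lrt, 0.0), slope
    if w_fixed is None:
        raise ValueError("w_fixed required for nested two-QTL models")
    X0 = np.column_stack([np.ones(n), w_fixed])
    b0, *_ = np.linalg.lstsq(X0, Y, rcond=None)
    rss0 = ((Y - X0 @ b0) ** 2).sum(axis=0)
    lrt = np.zeros((P, R))
    slope = np.zeros((P, R))
    for p in range(P):
        wp = W[:, p]
        if model == "interaction":
            X1 = np.column_stack([np.ones(n), w_fixed, wp, wp * w_fixed])
        elif model == "additive":
            X1 = np.column_stack([np.ones(n), w_fixed, wp])
        else:
            raise ValueError(f"unknown model {model!r}")
        b1, *_ = np.linalg.lstsq(X1, Y, rcond=None)
        rss1 = np.maximum(((Y - X1 @ b1) ** 2).sum(axis=0), 1e-300)
        lrt[p] = n * np.log(np.maximum(rss0, 1e-300) / rss1)
        slope[p] = b1[2]
    return np.maximum(lrt, 0.0), slope


def _build_scan(y, profile, model, fixed_pos, lrt_col, slope_col, drop_lod=1.0):
    i_max = int(np.argmax(lrt_col))  # argmax takes the leftmost tie
    max_pos = float(profile.grid[i_max])
    a_hat = float(slope_col[i_max])
    sd = float(np.std(y, ddof=1))
    res = QTLScanResult(
        positions=profile.grid.copy(),
        lrt=lrt_col.copy(),
        max_pos=max_pos,
        max_lrt=float(lrt_col[i_max]),
        effect=2.0 * a_hat,
        effect_sd=2.0 * a_hat / sd if sd > 0 else np.nan,
        n=y.size,
        model=model,
        fixed_pos=fixed_pos,
    )
    res.ci = lod_drop_ci(res, drop_lod=drop_lod)
    return res


def scan_chromosome(adjusted_trait: pd.Series, profile: TransmissionProfile) -> QTLScanResult:
    """No-QTL versus one-QTL approximate-LRT scan.

    ``adjusted_trait`` must be indexed by the same animals as the profile
    (hatch/dam/body-weight adjustment, when wanted, happens upstream).
    """
    y = adjusted_trait.reindex(profile.animals)
    if y.isna().any():
        raise ValueError("trait missing for some animals in the profile")
    y = y.to_numpy(dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 offspring for a scan")
    if np.isclose(y.std(), 0.0):
        raise ValueError("trait has zero variance")
    lrt, slope = _lrt_matrix(y[:, None], profile.w(), model="single")
    return _build_scan(y, profile, "single", None, lrt[:, 0], slope[:, 0])


def empirical_threshold(
    profile: TransmissionProfile,
    n_sim: int = 2000,
    h2: float = 0.5,
    level: float = 0.05,
    rng=None,
    model: str = "single",
    fixed_pos: float | None = None,
    design: pd.DataFrame | None = None,
) -> EmpiricalThreshold:
    """Chromosome-wide threshold from polygenic-only trait simulation.

    Traits are simulated with no QTL as polygenic + residual deviations
    (variances h2 and 1 - h2 of a unit phenotypic variance; the family-wide
    sire contribution is a constant absorbed by the model mean, and the LRT
    is scale-invariant), each simulated family is scanned on the observed
    transmission profile, and the threshold is the (1 - level) quantile of
    the maximum LRT.

    When the observed trait was pre-adjusted (hatch/dam/body-weight
    residuals), pass the same ``design`` (see :func:`adjustment_design`):
    the simulated traits are residualized on it too, so observed and null
    scans lose identical degrees of freedom and the threshold stays
    calibrated.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(rng)
    n = len(profile.animals)
    Y = np.sqrt(h2) * rng.standard_normal((n, n_sim)) + np.sqrt(1 - h2) * rng.standard_normal((n, n_sim))
    if design is not None:
        X = design.reindex(profile.animals).to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("design rows missing for some animals in the profile")
        Y = _project_out(Y, X)
    W = profile.w()
    w_fixed = None
    if model != "single":
        if fixed_pos is None:
            raise ValueError("fixed_pos required for nested models")
        w_fixed = 2.0 * profile.column(fixed_pos) - 1.0
    lrt, _ = _lrt_matrix(Y, W, model=model, w_fixed=w_fixed)
    maxima = lrt.max(axis=0)
    value = float(np.quantile(maxima, 1.0 - level))
    return EmpiricalThreshold(value=value, level=level, n_sim=n_sim, h2=h2, maxima=maxima)


def lod_drop_ci(scan: QTLScanResult, drop_lod: float = 1.0) -> tuple:
    """One-LOD-drop support interval, clamped to the scanned range.

    The outermost positions whose LOD is within ``drop_lod`` of the maximum.
    A flat scan yields the full range and sets ``scan.flat``.
    """
    lod = scan.lrt * LOD_PER_LRT
    cutoff = lod.max() - drop_lod
    if np.ptp(scan.lrt) < 1e-12:
        scan.flat = True
        return (float(scan.positions[0]), float(scan.positions[-1]))
    inside = np.where(lod >= cutoff)[0]
    return (float(scan.positions[inside[0]]), float(scan.positions[inside[-1]]))


def leave_one_subtype_out_scans(
    adjusted_trait: pd.Series,
    profile: TransmissionProfile,
    subtypes: pd.Series,
    n_sim: int = 2000,
    h2: float = 0.5,
    level: float = 0.05,
    rng=None,
    group_names=None,
    design: pd.DataFrame | None = None,
) -> dict:
    """Full-family scan plus one scan per omitted subgroup.

    Each condition gets its own empirical threshold recomputed on the
    reduced family.  Keys: "full" and "without_<name>".  ``group_names``
    overrides the set of groups to omit (a name without members yields the
    full-family scan unchanged).
    """
    subtypes = subtypes.reindex(profile.animals)
    if subtypes.isna().any():
        raise ValueError("every animal needs a subgroup label")
    rng = np.random.default_rng(rng)
    out = {}
    full = scan_chromosome(adjusted_trait, profile)
    full.threshold = empirical_threshold(
        profile, n_sim=n_sim, h2=h2, level=level, rng=rng, design=design
    )
    out["full"] = full
    n = len(profile.animals)
    if group_names is None:
        group_names = list(pd.unique(subtypes))
    for name in group_names:
        keep = [a for a, s in subtypes.items() if s != name]
        if len(keep) == n:
            out[f"without_{name}"] = full
            continue
        if n - len(keep) > n / 2:
            warnings.warn(f"omitted subgroup {name!r} is larger than half the family", stacklevel=2)
        sub_profile = profile.subset(keep)
        scan = scan_chromosome(adjusted_trait.loc[keep], sub_profile)
        sub_design = design.loc[keep] if design is not None else None
        scan.threshold = empirical_threshold(
            sub_profile, n_sim=n_sim, h2=h2, level=level, rng=rng, design=sub_design
        )
        out[f"without_{name}"] = scan
    return out
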