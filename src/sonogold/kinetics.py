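"""ICP-AES uptake post-processing and first-order absorption kinetics.

Inductively coupled plasma atomic emission spectroscopy (ICP-AES) reports a
gold mass concentration ``C_m`` (mg/L) in the digested, diluted sample.  The
per-cell particle count follows from the molar mass of gold, the number of
gold atoms in one nanoparticle, Avogadro's number, the effective sample
volume and the cell count:

    N_np per cell = C_m [g/L] * V_sample [L] * N_A / (M_Au * N_Au * N_C)

reported here on the x10^4-particles-per-cell scale the field prints.

Uptake time courses are modelled by a first-order absorption law with a
fixed asymptote,

    Y(t) = A_max * (1 - exp(-k t)),

where ``A_max`` is pinned to the observed late-time plateau so the rate
constant ``k`` is the sole free parameter.  With the zero-uptake origin
anchored at t = 0 h, a 4-point group-mean series leaves n - 1 = 3 degrees of
freedom for inference on ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "KineticConstants",
    "UptakeMeasurement",
    "UptakeSeries",
    "KineticFit",
    "GroupComparison",
    "adjust_dilution",
    "concentration_to_particles",
    "fit_first_order",
    "fold_change",
    "compare_groups",
    "first_order_model",
]

#: Number of gold atoms in one ~50 nm gold nanoparticle.
ATOMS_PER_50NM_GNP = 3_849_991


@dataclass(frozen=True)
class KineticConstants:
    """Physical constants for the gold-mass -> particle-count conversion.

    ``v_sample_L`` is the effective sample volume: 2 mL of digested cell
    sample diluted 5-fold to 10 mL, so the gold mass is the diluted
    concentration times 0.010 L.
    """

    m_au_g_mol: float = 196.966657
    n_atoms_per_particle: float = ATOMS_PER_50NM_GNP
    n_cells: float = 1e6
    n_avogadro: float = 6.022e23
    v_sample_L: float = 0.010
    dilution_factor: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "m_au_g_mol", "n_atoms_per_particle", "n_cells",
            "n_avogadro", "v_sample_L", "dilution_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class UptakeMeasurement:
    """One ICP-AES reading and its derived per-cell particle count."""

    group_min: float
    time_h: float
    replicate: int
    c_m_mgL: float
    c_eq_1e4: float = float("nan")

    def __post_init__(self) -> None:
        if self.c_m_mgL < 0:
            raise ValueError("c_m must be nonnegative")
        if self.time_h < 0:
            raise ValueError("time must be nonnegative")


@dataclass
class UptakeSeries:
    """Ordered uptake measurements for one exposure group.

    ``data`` has columns ``time_h``, ``replicate``, ``c_m_mgL``.  When
    ``include_origin`` is set, kinetic fitting prepends the (0 h, 0 mg/L)
    anchor expressing the assumption that no intracellular nanoparticles are
    present before treatment.
    """

    group_min: float
    data: pd.DataFrame
    include_origin: bool = True

    def __post_init__(self) -> None:
        required = {"time_h", "replicate", "c_m_mgL"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"uptake table needs columns {sorted(required)}")
        if (self.data["time_h"] < 0).any():
            raise ValueError("times must be nonnegative")
        self.data = self.data.sort_values(["time_h", "replicate"]).reset_index(drop=True)

    def group_means(self) -> pd.DataFrame:
        """Mean and SD of ``c_m`` per sampling time."""
        g = self.data.groupby("time_h")["c_m_mgL"]
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)}).reset_index()


@dataclass(frozen=True)
class KineticFit:
    """Fixed-asymptote first-order fit: the rate constant and its inference."""

    a_max: float
    k: float
    se_k: float
    df: int
    r_squared: float
    p_model: float
    p_k: float
    sse: float
    n_points: int
    converged: bool = True


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise follow-up."""

    f_statistic: float
    p_anova: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adjusted


def first_order_model(t: np.ndarray, a_max: float, k: float) -> np.ndarray:
    """Saturating uptake curve ``A_max * (1 - exp(-k t))``."""
    return a_max * -np.expm1(-k * np.asarray(t, dtype=float))


def adjust_dilution(measured_c: float, constants: KineticConstants = KineticConstants()) -> float:
    """Scale a diluted-sample concentration back to the original volume."""
    if measured_c < 0:
        raise ValueError("concentration must be nonnegative")
    return measured_c * constants.dilution_factor


def concentration_to_particles(
    c_m: float | np.ndarray,
    constants: KineticConstants = KineticConstants(),
) -> float | np.ndarray:
    """Convert gold mass concentration (mg/L) to x10^4 particles per cell.

    Exactly linear in ``c_m``; with the default constants the slope is
    ~0.7941 x10^4 particles per cell per mg/L.
    """
    c = np.asarray(c_m, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    n_per_cell = (
        c * 1e-3 * constants.v_sample_L * constants.n_avogadro
        / (constants.m_au_g_mol * constants.n_atoms_per_particle * constants.n_cells)
    )
    out = n_per_cell / 1e4
    return float(out) if np.isscalar(c_m) else out


def _series_points(
    series: UptakeSeries, use_group_means: bool
) -> tuple[np.ndarray, np.ndarray]:
    if use_group_means:
        gm = series.group_means()
        t = gm["time_h"].to_numpy(dtype=float)
        y = gm["mean"].to_numpy(dtype=float)
    else:
        t = series.data["time_h"].to_numpy(dtype=float)
        y = series.data["c_m_mgL"].to_numpy(dtype=float)
    if series.include_origin and not np.any(t == 0):
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
    return t, y


def fit_first_order(
    series: UptakeSeries,
    a_max: float | None = None,
    use_group_means: bool = True,
) -> KineticFit:
    """Least-squares estimate of the sole rate constant ``k`` (bounded k >= 0).

    ``a_max`` defaults to the observed mean at the latest sampling time of the
    same series (the late-time plateau taken as the maximum uptake capacity).
    Standard error of ``k`` comes from the linearized Jacobian at the optimum
    with residual variance ``sse / df`` and ``df = n - 1``; R-squared is
    centered on the mean of all fitted observations (origin included when
    anchored).  ``p_k`` is a two-sided t-test of k = 0; ``p_model`` is the
    F-test of the fit against the constant-mean model with (1, df) df.
    """
    t, y = _series_points(series, use_group_means)
    if a_max is None:
        a_max = float(y[np.argmax(t)])
    if a_max <= 0:
        raise ValueError("a_max must be positive")
    if np.count_nonzero(t > 0) < 2 or len(np.unique(t[t > 0])) < 2:
        raise ValueError("need >= 2 distinct positive sampling times")
    if np.allclose(y, 0):
        raise ValueError("degenerate fit: all observations are zero")

    def sse_of(k: float) -> float:
        return float(np.sum((y - first_order_model(t, a_max, k)) ** 2))

    # The SSE is unimodal in k but flattens to a plateau once exp(-k t) has
    # saturated at every sample time, which starves golden-section searches
    # of signal; bracket the minimum with a coarse grid first, then refine.
    k_max = 50.0
    grid = np.concatenate([[0.0], np.geomspace(1e-4, k_max, 400)])
    i = int(np.argmin([sse_of(k) for k in grid]))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(sse_of, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    k = float(res.x)
    if sse_of(grid[i]) < sse_of(k):  # guard against a degenerate refine step
        k = float(grid[i])
    sse = sse_of(k)
    n = len(t)
    df = n - 1
    jac = a_max * t * np.exp(-k * t)
    denom = float(np.sum(jac**2))
    sigma2 = sse / df
    se_k = math.sqrt(sigma2 / denom) if denom > 0 else float("inf")
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - sse / sst if sst > 0 else float("nan")
    if se_k > 0 and math.isfinite(se_k):
        p_k = 2 * stats.t.sf(abs(k / se_k), df) if sse > 0 else 0.0
    else:
        p_k = float("nan")
    if sse > 0:
        f_stat = (sst - sse) / (sse / df)
        p_model = float(stats.f.sf(f_stat, 1, df))
    else:
        p_model = 0.0
    return KineticFit(
        a_max=a_max, k=k, se_k=se_k, df=df, r_squared=r_squared,
        p_model=p_model, p_k=float(p_k), sse=sse, n_points=n,
        converged=bool(res.success),
    )


def fold_change(treated_mean: float, control_mean: float) -> float:
    """Ratio of treated to control mean uptake."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return treated_mean / control_mean


def compare_groups(values_by_group: dict[object, np.ndarray]) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD adjusted pairwise comparisons.

    Identical groups (zero between-group variance) are reported as F = 0,
    p = 1 rather than the 0/0 NaN scipy would return when the within-group
    variance is also zero.
    """
    if len(values_by_group) < 2:
        raise ValueError("need >= 2 groups")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has < 2 replicates")
    arrays = list(groups.values())
    names = list(groups.keys())
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ss_between == 0:
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append({
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": arrays[i].mean() - arrays[j].mean(),
                "p_adjusted": float(min(1.0, tk.pvalue[i, j])),
            })
    return GroupComparison(
        f_statistic=float(f_stat),
        p_anova=float(p_anova),
        pairwise=pd.DataFrame(rows),
    )


def convert_table(
    table: pd.DataFrame,
    constants: KineticConstants = KineticConstants(),
) -> pd.DataFrame:
    """Add a ``c_eq_1e4`` column (x10^4 particles per cell) to an uptake table."""
    out = table.copy()
    out["c_eq_1e4"] = concentration_to_particles(
        out["c_m_mgL"].to_numpy(dtype=float), constants
    )
    return out


def series_from_table(
    table: pd.DataFrame, group_min: float, include_origin: bool = True
) -> UptakeSeries:
    """Extract one group's :class:`UptakeSeries` from a long-format table."""
    sub = table[table["group_min"] == group_min]
    if sub.empty:
        raise ValueError(f"no rows for group {group_min}")
    return UptakeSeries(
        group_min=group_min,
        data=sub[["time_h", "replicate", "c_m_mgL"]].copy(),
        include_origin=include_origin,
    )
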