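"""Tissue-scale quantities derived from indentation and fusion analyses.

The effective surface tension of a spheroid scales with its surface-layer
stiffness, Gamma ~ E * R0 (an order-of-magnitude estimator).  Combined with
the visco-capillary velocity Gamma/eta measured from fusion kinetics, it
yields an apparent tissue viscosity eta = Gamma / (Gamma/eta).  Group
comparisons follow the conventional screen: per-group normality tests, then
one-way ANOVA with Bonferroni-corrected pairwise t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TissueMechanics",
    "surface_tension_estimate",
    "apparent_viscosity",
    "stiffness_ratio",
    "compute_tissue_mechanics",
    "group_compare",
]

#: µm/h → m/h
_UM_PER_H_TO_M_PER_H = 1e-6


@dataclass
class TissueMechanics:
    """Derived quantities for one group, with provenance of the inputs.

    ``gamma_estimate`` (N/m) and ``apparent_viscosity`` (Pa·h) are
    order-of-magnitude numbers (the tension estimator is a scaling law,
    not a measurement) and are tagged as such in ``provenance``.
    """

    gamma_estimate: float  # N/m
    apparent_viscosity: float  # Pa h
    stiffness_ratio: float | None = None
    tension_ratio: float | None = None
    provenance: dict = field(default_factory=dict)


def surface_tension_estimate(E: float, R0: float) -> float:
    """Gamma ~ E * R0 (Pa × m → N/m). Order-of-magnitude estimator."""
    if E <= 0 or R0 <= 0:
        raise ValueError("E and R0 must be positive")
    return E * R0


def apparent_viscosity(gamma: float, vcv_um_per_h: float) -> float:
    """eta = Gamma / (Gamma/eta), in Pa·h for Gamma in N/m and Γ/η in µm/h."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if vcv_um_per_h <= 0:
        raise ValueError("visco-capillary velocity must be positive")
    return gamma / (vcv_um_per_h * _UM_PER_H_TO_M_PER_H)


def stiffness_ratio(E_num: float, E_den: float) -> float:
    """Fold difference of two moduli (reports round to one decimal)."""
    if E_num <= 0 or E_den <= 0:
        raise ValueError("moduli must be positive")
    return E_num / E_den


def compute_tissue_mechanics(
    E: float,
    R0: float,
    vcv_um_per_h: float | None,
    reference_E: float | None = None,
    reference_gamma: float | None = None,
    label: str = "",
) -> TissueMechanics:
    """Assemble the derived-quantity bundle for one group.

    ``vcv_um_per_h`` may be None (e.g. heterotypic pairs, where a single
    tension estimate is not defined): the viscosity is then NaN.
    """
    gamma = surface_tension_estimate(E, R0)
    eta = apparent_viscosity(gamma, vcv_um_per_h) if vcv_um_per_h else float("nan")
    return TissueMechanics(
        gamma_estimate=gamma,
        apparent_viscosity=eta,
        stiffness_ratio=stiffness_ratio(E, reference_E) if reference_E else None,
        tension_ratio=gamma / reference_gamma if reference_gamma else None,
        provenance={
            "label": label,
            "E_Pa": E,
            "R0_m": R0,
            "vcv_um_per_h": vcv_um_per_h,
            "estimator": "Gamma ~ E*R0 (order of magnitude)",
        },
    )


def group_compare(
    groups: Mapping[str, Sequence[float]],
    highlight_p: float = 0.001,
    min_n: int = 3,
) -> dict:
    """Normality screen, one-way ANOVA and Bonferroni pairwise t-tests.

    Groups with fewer than ``min_n`` observations are excluded with a
    warning.  Pairwise p-values are two-sided Welch-free (pooled-variance)
    t-tests multiplied by the number of comparisons and clipped at 1;
    ``significant`` flags comparisons below ``highlight_p``.
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_n:
            warnings.warn(f"group '{name}' has n={arr.size} < {min_n}; excluded")
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least 2 groups of sufficient size")

    normality = {}
    for name, arr in clean.items():
        sw_stat, sw_p = stats.shapiro(arr)
        if arr.size >= 8:
            da_stat, da_p = stats.normaltest(arr)
        else:
            da_stat, da_p = float("nan"), float("nan")
        normality[name] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
            "shapiro_p": float(sw_p),
            "dagostino_pearson_p": float(da_p),
        }

    names = list(clean)
    f_stat, anova_p = stats.f_oneway(*clean.values())
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        t_stat, p_raw = stats.ttest_ind(clean[a], clean[b])
        p_adj = min(float(p_raw) * m, 1.0)
        pairwise.append(
            {
                "a": a,
                "b": b,
                "t": float(t_stat),
                "p_raw": float(p_raw),
                "p_bonferroni": p_adj,
                "significant": p_adj < highlight_p,
            }
        )
    return {
        "normality": normality,
        "anova_F": float(f_stat),
        "anova_p": float(anova_p),
        "pairwise": pairwise,
        "highlight_p": highlight_p,
    }
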