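"""Derived wood and foliar traits from raw disc, vessel and stomatal measurements.

All quantities follow the field's conventional units, enforced at this
boundary and converted in one place (:data:`UNIT_FACTORS`):

* radii in cm, cross-sectional areas in cm**2,
* vessel diameters in µm, vessel lumen areas in mm**2,
* vessel and stomatal densities in mm**-2, stomatal sizes in µm**2,
* conductances in mol m**-2 s**-1.

The central quantities are the hydraulically weighted vessel diameter
``D_H`` (an elliptical-conduit generalisation of the usual fourth-power
mean, reducing to it for circular lumina), the quadratic-mean stem and
heartwood radii used to handle stem eccentricity, sapwood/heartwood
areas and their closure ``SWa + HWa = CSa``, the total conductive vessel
area ``TCVA = A_V * N_V * SWa``, the vessel lumen fraction ``F_V`` and
the anatomical maximum stomatal conductance ``G_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "UNIT_FACTORS",
    "GmaxConstants",
    "DerivedDiscTraits",
    "hydraulic_diameter",
    "quadratic_mean_radius",
    "disc_traits",
    "gmax",
    "hw_proportion_profile",
    "derive_discs",
]

#: Centralised unit conversions (single source of truth for the module).
UNIT_FACTORS = {
    "um2_to_mm2": 1e-6,
    "um2_to_m2": 1e-12,
    "per_mm2_to_per_m2": 1e6,
    "um_to_m": 1e-6,
    "cm2_to_m2": 1e-4,
}

N_RADII = 8


def hydraulic_diameter(vessels: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """Hydraulically weighted vessel diameter (µm) for elliptical conduits.

    For major/minor ferret diameters ``(a_i, b_i)`` of each lumen,

        D_H = [ (1/n) * sum_i 2 a_i^3 b_i^3 / (a_i^2 + b_i^2) ] ** (1/4)

    which reduces to the familiar fourth-power mean ``(mean d^4)^(1/4)``
    when all lumina are circular (``a_i == b_i``).

    Parameters
    ----------
    vessels : sequence of (a, b) pairs, µm
        Major and minor axis diameters; ``a_i >= b_i > 0`` expected.

    Returns
    -------
    float
        D_H in µm; invariant to vessel ordering.
    """
    arr = np.asarray(vessels, dtype=float)
    if arr.size == 0:
        raise ValueError("hydraulic_diameter requires at least one vessel")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("vessels must be a sequence of (major, minor) pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("vessel diameters must be strictly positive")
    term = 2.0 * a**3 * b**3 / (a**2 + b**2)
    return float(np.mean(term) ** 0.25)


def quadratic_mean_radius(radii: Sequence[float] | np.ndarray) -> float:
    """Quadratic (root-mean-square) average of the eight disc radii (cm).

    The quadratic mean is used instead of the arithmetic mean to account
    for stem eccentricity: it is the radius of the circle with the same
    area as the mean of the per-radius circles, and is always >= the
    arithmetic mean. All-zero input is valid (absent heartwood) and
    returns 0.
    """
    r = np.asarray(radii, dtype=float)
    if r.shape != (N_RADII,):
        raise ValueError(f"expected exactly {N_RADII} radii, got shape {r.shape}")
    if np.any(r < 0):
        raise ValueError("radii must be non-negative")
    return float(np.sqrt(np.mean(r**2)))


@dataclass(frozen=True)
class GmaxConstants:
    """Physical constants and conventions for anatomical maximum conductance.

    Attributes
    ----------
    water_vapour_diffusivity : float
        d_w, m^2 s^-1 (default 2.49e-5, ~25 deg C).
    molar_volume_air : float
        v, m^3 mol^-1 (default 0.0245, ~25 deg C, 101.3 kPa).
    pore_area_fraction : float
        Fraction of the measured stomatal size treated as the maximal
        open pore area a_max; in (0, 1].
    pore_depth_rule : str
        ``"pore_radius"`` sets pore depth pd = sqrt(a_max / pi)
        (circular-pore assumption); ``"fixed"`` uses ``pore_depth_um``.
    pore_depth_um : float or None
        Fixed pore depth in µm when ``pore_depth_rule == "fixed"``.
    """

    water_vapour_diffusivity: float = 2.49e-5
    molar_volume_air: float = 0.0245
    pore_area_fraction: float = 0.12
    pore_depth_rule: str = "pore_radius"
    pore_depth_um: float | None = None

    def __post_init__(self) -> None:
        if self.water_vapour_diffusivity <= 0 or self.molar_volume_air <= 0:
            raise ValueError("physical constants must be positive")
        if not 0 < self.pore_area_fraction <= 1:
            raise ValueError("pore_area_fraction must be in (0, 1]")
        if self.pore_depth_rule not in ("pore_radius", "fixed"):
            raise ValueError(f"unknown pore_depth_rule {self.pore_depth_rule!r}")
        if self.pore_depth_rule == "fixed" and (
            self.pore_depth_um is None or self.pore_depth_um <= 0
        ):
            raise ValueError("fixed pore_depth_rule requires positive pore_depth_um")


def gmax(
    stomatal_density: float,
    stomatal_size: float,
    constants: GmaxConstants | None = None,
) -> float:
    """Anatomical maximum stomatal conductance to water vapour.

    g_max = (d_w / v) * D_s * a_max / (pd + (pi/2) * sqrt(a_max / pi))

    with stomatal density ``D_s`` (mm^-2), maximal pore area
    ``a_max = pore_area_fraction * S_stomata`` (S_stomata in µm^2) and
    pore depth ``pd`` from the configured rule. Strictly increasing —
    in fact exactly linear — in D_s.

    Returns g_max in mol m^-2 s^-1.
    """
    c = constants if constants is not None else GmaxConstants()
    if stomatal_density <= 0 or stomatal_size <= 0:
        raise ValueError("stomatal density and size must be positive")
    ds = stomatal_density * UNIT_FACTORS["per_mm2_to_per_m2"]
    a_max = c.pore_area_fraction * stomatal_size * UNIT_FACTORS["um2_to_m2"]
    if c.pore_depth_rule == "fixed":
        pd_m = c.pore_depth_um * UNIT_FACTORS["um_to_m"]
    else:
        pd_m = np.sqrt(a_max / np.pi)
    denom = pd_m + (np.pi / 2.0) * np.sqrt(a_max / np.pi)
    return float(
        (c.water_vapour_diffusivity / c.molar_volume_air) * ds * a_max / denom
    )


@dataclass
class DerivedDiscTraits:
    """All derived quantities for one stem or branch cross-section.

    Vessel-dependent fields (D_H, A_V, N_V, F_V, TCVA) are NaN when the
    disc has no vessel sample (typically branches).
    """

    S_R: float
    HW_R: float
    SW_R: float
    CSa: float
    HWa: float
    SWa: float
    hw_proportion: float
    GR: float
    D_H: float = float("nan")
    A_V: float = float("nan")
    N_V: float = float("nan")
    F_V: float = float("nan")
    TCVA: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isclose(self.SWa + self.HWa, self.CSa, rtol=1e-9, atol=1e-12):
            raise ValueError("area closure violated: SWa + HWa != CSa")
        if not 0 <= self.hw_proportion < 1:
            raise ValueError("hw_proportion must lie in [0, 1)")


def _vessel_lumen_area_mm2(major_um: np.ndarray, minor_um: np.ndarray) -> float:
    """Mean elliptical lumen area in mm^2 from axis diameters in µm."""
    areas_um2 = np.pi * major_um * minor_um / 4.0
    return float(np.mean(areas_um2) * UNIT_FACTORS["um2_to_mm2"])


def disc_traits(
    stem_radii: Sequence[float],
    hw_radii: Sequence[float],
    cambial_age: float,
    vessels: Sequence[tuple[float, float]] | None = None,
    vessel_density: float | None = None,
    *,
    measured_csa: float | None = None,
    measured_hwa: float | None = None,
) -> DerivedDiscTraits:
    """Compute all derived traits for one disc.

    Areas are derived from the quadratic-mean radii via the circle
    formula by default. When externally measured areas are supplied
    (image-analysis workflows) they are used instead, after an area
    closure check against the radius-derived values (25 % relative
    tolerance, reflecting genuine stem non-circularity).

    Parameters
    ----------
    stem_radii, hw_radii : 8 values each, cm
        Under-bark stem radii and heartwood radii (0 where absent).
    cambial_age : float
        Ring count pith -> bark, years.
    vessels : optional sequence of (major, minor) µm pairs
    vessel_density : optional, mm^-2
    measured_csa, measured_hwa : optional, cm^2
        Pass-through for externally measured areas.
    """
    s_r = quadratic_mean_radius(stem_radii)
    hw_r = quadratic_mean_radius(hw_radii)
    if hw_r > s_r:
        raise ValueError("heartwood radius exceeds stem radius")
    if cambial_age <= 0:
        raise ValueError("cambial_age must be positive")

    csa = np.pi * s_r**2
    hwa = np.pi * hw_r**2
    if measured_csa is not None:
        if not np.isclose(measured_csa, csa, rtol=0.25):
            raise ValueError(
                f"measured CSa {measured_csa:.3g} inconsistent with "
                f"radius-derived {csa:.3g} cm^2"
            )
        csa = float(measured_csa)
    if measured_hwa is not None:
        if hwa > 0 and not np.isclose(measured_hwa, hwa, rtol=0.25):
            raise ValueError(
                f"measured HWa {measured_hwa:.3g} inconsistent with "
                f"radius-derived {hwa:.3g} cm^2"
            )
        hwa = float(measured_hwa)
    swa = csa - hwa

    traits = DerivedDiscTraits(
        S_R=s_r,
        HW_R=hw_r,
        SW_R=s_r - hw_r,
        CSa=csa,
        HWa=hwa,
        SWa=swa,
        hw_proportion=hwa / csa if csa > 0 else 0.0,
        GR=2.0 * s_r / cambial_age,
    )

    if vessels is not None and len(vessels) > 0:
        if vessel_density is None or vessel_density <= 0:
            raise ValueError("vessel sample requires a positive vessel_density")
        arr = np.asarray(vessels, dtype=float)
        traits.D_H = hydraulic_diameter(arr)
        traits.A_V = _vessel_lumen_area_mm2(arr[:, 0], arr[:, 1])
        traits.N_V = float(vessel_density)
        traits.F_V = traits.A_V * traits.N_V * 100.0
        if traits.F_V >= 100.0:
            raise ValueError(
                f"vessel lumen fraction {traits.F_V:.1f}% >= 100%: "
                "inconsistent vessel area/density units"
            )
        traits.TCVA = traits.A_V * traits.N_V * traits.SWa
    return traits


def hw_proportion_profile(
    distance_from_top: Sequence[float],
    hw_proportion: Sequence[float],
) -> tuple[pd.DataFrame, int]:
    """Vertical heartwood-proportion profile of one tree.

    Returns the profile ordered base -> top (distance from top, L,
    descending) and the sign of the Spearman trend of proportion with L
    (+1: proportion increases toward the base, the usual pattern; 0 for
    a flat profile).
    """
    L = np.asarray(distance_from_top, dtype=float)
    p = np.asarray(hw_proportion, dtype=float)
    if L.size != p.size or L.size < 2:
        raise ValueError("profile requires >= 2 discs with matching lengths")
    order = np.argsort(-L)
    prof = pd.DataFrame(
        {"distance_from_top": L[order], "hw_proportion": p[order]}
    ).reset_index(drop=True)
    if np.ptp(p) == 0 or np.ptp(L) == 0:
        sign = 0
    else:
        rho = spearmanr(L, p).statistic
        sign = 0 if (np.isnan(rho) or rho == 0) else int(np.sign(rho))
    return prof, sign


# ---------------------------------------------------------------------------
# Table-level driver


def derive_discs(
    discs: pd.DataFrame,
    vessels: pd.DataFrame | None = None,
    leaves: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute derived traits for every disc in a disc table.

    Expects the frozen disc schema (``stem_r1..stem_r8``,
    ``hw_r1..hw_r8``, ``cambial_age``, ...) and optionally the long
    vessel table (``disc_id``, ``major_um``, ``minor_um``,
    ``vessel_density_per_mm2``) and the leaf table, whose per-branch
    total leaf area is attached to branch discs.

    Returns one row per disc with all :class:`DerivedDiscTraits` columns;
    vessel-dependent traits are NaN for discs without vessels.
    """
    stem_cols = [f"stem_r{i}" for i in range(1, N_RADII + 1)]
    hw_cols = [f"hw_r{i}" for i in range(1, N_RADII + 1)]
    vessel_groups: dict = {}
    if vessels is not None and len(vessels):
        vessel_groups = {k: g for k, g in vessels.groupby("disc_id")}

    rows = []
    for rec in discs.itertuples(index=False):
        d = rec._asdict()
        vg = vessel_groups.get(d["disc_id"])
        vs = list(zip(vg["major_um"], vg["minor_um"])) if vg is not None else None
        dens = float(vg["vessel_density_per_mm2"].iloc[0]) if vg is not None else None
        t = disc_traits(
            [d[c] for c in stem_cols],
            [d[c] for c in hw_cols],
            d["cambial_age"],
            vessels=vs,
            vessel_density=dens,
        )
        rows.append(
            {
                "disc_id": d["disc_id"],
                "tree_id": d["tree_id"],
                "cohort": d["cohort"],
                "disc_type": d["disc_type"],
                "height_above_ground": d["height_above_ground"],
                "distance_from_top": d["distance_from_top"],
                "cambial_age": d["cambial_age"],
                "hw_rings": d["hw_rings"],
                "sw_rings": d["sw_rings"],
                "hw_present": d["hw_present"],
                "S_R": t.S_R,
                "HW_R": t.HW_R,
                "SW_R": t.SW_R,
                "CSa": t.CSa,
                "HWa": t.HWa,
                "SWa": t.SWa,
                "hw_proportion": t.hw_proportion,
                "GR": t.GR,
                "D_H": t.D_H,
                "A_V": t.A_V,
                "N_V": t.N_V,
                "F_V": t.F_V,
                "TCVA": t.TCVA,
            }
        )
    out = pd.DataFrame(rows)
    if leaves is not None and len(leaves):
        al = leaves.groupby("branch_disc_id", as_index=False)[
            "total_leaf_area_m2"
        ].sum()
        out = out.merge(
            al.rename(columns={"branch_disc_id": "disc_id"}), on="disc_id", how="left"
        )
    else:
        out["total_leaf_area_m2"] = np.nan
    return out
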