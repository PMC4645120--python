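"""Site-year community summaries: abundance, weighted dose, diversity.

Per-species cumulative doses are aggregated to a single site-year dose by
weighting with observed relative abundances; community composition is
summarised by Simpson's index of diversity (the probability that two
randomly observed individuals belong to different species).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dosimetry import ICRP_BANDS

__all__ = [
    "site_weighted_total_dose",
    "simpson_diversity",
    "build_site_year_table",
    "species_max_doserate_ecdf",
    "icrp_band_exceedance",
    "dose_ambient_ratio",
]


def site_weighted_total_dose(abundances, species_doses) -> float:
    """Abundance-weighted site dose: TD_ik = Σ_j (A_ijk / TNB_ik) · TD_ijk.

    A convex combination of the per-species doses, defined only when at
    least one bird was observed; with TNB = 0 the site-year carries no dose
    and ``nan`` is returned (such site-years are excluded downstream).
    """
    a = np.asarray(abundances, dtype=float)
    d = np.asarray(species_doses, dtype=float)
    if a.shape != d.shape:
        raise ValueError("abundances and doses must align")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    tnb = a.sum()
    if tnb < 1:
        return float("nan")
    return float((a / tnb) @ d)


def simpson_diversity(abundances, unbiased: bool = False) -> float:
    """Simpson's index of diversity, 1 − Σ_j p_j² with p_j = A_j / TNB.

    Probability that two individuals observed at the site belong to
    different species.  Returns 0 for empty or single-individual censuses.
    With ``unbiased=True`` the finite-sample form
    1 − Σ A_j(A_j − 1) / (TNB(TNB − 1)) is used instead of the plug-in form.
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    tnb = a.sum()
    if tnb <= 1:
        return 0.0
    if unbiased:
        return float(1.0 - (a * (a - 1)).sum() / (tnb * (tnb - 1)))
    p = a / tnb
    return float(1.0 - (p @ p))


def build_site_year_table(
    census: pd.DataFrame,
    doses: pd.DataFrame | None = None,
    unbiased_simpson: bool = False,
) -> pd.DataFrame:
    """Aggregate a species-level census to one row per site-year.

    ``census`` has one row per (site, year, species) with ``count`` and
    optionally ``ambient_uGy_h``; ``doses`` (if given) supplies per
    (site, year, species) cumulative doses ``TD_Gy``.  The output carries
    TNB, Simpson's index, the abundance-weighted total dose (nan where
    TNB = 0) and its log10.
    """
    df = census.copy()
    if doses is not None:
        df = df.drop(columns=["TD_Gy"], errors="ignore")
        df = df.merge(
            doses[["site", "year", "species", "TD_Gy"]],
            on=["site", "year", "species"],
            how="left",
        )

    rows = []
    for (site, year), g in df.groupby(["site", "year"], sort=True):
        counts = g["count"].to_numpy(dtype=float)
        rec = {
            "site": site,
            "year": year,
            "TNB": int(counts.sum()),
            "simpson": simpson_diversity(counts, unbiased=unbiased_simpson),
        }
        if "TD_Gy" in g.columns:
            rec["TD_Gy"] = site_weighted_total_dose(counts, g["TD_Gy"].to_numpy(float))
        if "ambient_uGy_h" in g.columns:
            rec["ambient_uGy_h"] = float(g["ambient_uGy_h"].iloc[0])
        rows.append(rec)
    out = pd.DataFrame(rows)
    if "TD_Gy" in out.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["log10_TD"] = np.log10(out["TD_Gy"])
    return out


def species_max_doserate_ecdf(doses: pd.DataFrame) -> pd.DataFrame:
    """Empirical CDF of per-species maximum total dose rates.

    For each species the maximum ``TDR_uGy_h`` over all sites and censuses
    is taken; the ECDF over species is returned sorted by dose rate, with
    ``ecdf`` the fraction of species at or below each maximum.
    """
    m = doses.groupby("species")["TDR_uGy_h"].max().sort_values()
    n = len(m)
    if n == 0:
        raise ValueError("no dose records")
    return pd.DataFrame(
        {
            "species": m.index.to_numpy(),
            "max_TDR_uGy_h": m.to_numpy(),
            "ecdf": np.arange(1, n + 1) / n,
        }
    )


def icrp_band_exceedance(species_max: pd.DataFrame) -> pd.DataFrame:
    """Fraction of species whose maximum dose rate reaches each ICRP band."""
    vals = species_max["max_TDR_uGy_h"].to_numpy(dtype=float)
    rows = [
        {
            "band_lower_uGy_h": lo,
            "band": label,
            "fraction_species_at_or_above": float((vals >= lo).mean()),
        }
        for lo, _, label in ICRP_BANDS
    ]
    return pd.DataFrame(rows)


def dose_ambient_ratio(tdr_uGy_h, ambient_uGy_h):
    """Ratio of reconstructed dose rate to measured ambient dose rate."""
    tdr = np.asarray(tdr_uGy_h, dtype=float)
    amb = np.asarray(ambient_uGy_h, dtype=float)
    if np.any(amb <= 0):
        raise ValueError("ambient dose rate must be positive")
    out = tdr / amb
    scalar = np.isscalar(tdr_uGy_h) and np.isscalar(ambient_uGy_h)
    return float(out) if scalar else out
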