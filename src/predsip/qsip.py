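"""Core qSIP calculations.

Quantitative stable isotope probing infers taxon-specific isotope
incorporation from the shift in a taxon's DNA buoyant density between
unlabeled and isotopically labeled incubations.  The chain implemented
here is:

1. weighted average density (WAD) of a taxon across gradient fractions,
   weighted by its relative abundance times the qPCR 16S copy total of
   each fraction;
2. GC content from the unlabeled WAD (linear calibration);
3. mean nucleotide molecular weight from GC;
4. atom fraction excess (AFE) from the relative density (hence mass)
   shift, normalized by the maximum mass gain at 100 atom % labeling;
5. growth rate from the ``18O`` AFE under exponential labeling with
   water of known ``18O`` enrichment:  ``r = -ln(1 - A / A_w) / t``.

All scalar operations are ``numpy``-vectorized; the table-level
entry points operate on tidy ``pandas`` DataFrames.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ISOTOPES, IsotopeConstants
from .exceptions import SaturationError, UndefinedEstimateError

logger = logging.getLogger(__name__)

__all__ = [
    "weighted_average_density",
    "profile_wad",
    "gc_from_density",
    "density_from_gc",
    "mw_from_gc",
    "afe",
    "labeled_density",
    "water_afe",
    "growth_rate",
    "afe_from_growth",
    "c_uptake_rate",
    "estimate_afe",
]


def weighted_average_density(densities, weights):
    """Abundance-weighted mean buoyant density (g/ml).

    ``weights`` are relative abundance x total 16S copies per fraction;
    the result is invariant to rescaling all weights by a constant.
    """
    d = np.asarray(densities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise ValueError("densities and weights must have the same shape")
    if np.any(w < 0):
        raise ValueError("negative weights")
    total = w.sum()
    if total <= 0:
        raise UndefinedEstimateError("all-zero weights: WAD undefined")
    return float((d * w).sum() / total)


def profile_wad(profile: pd.DataFrame) -> float:
    """WAD of one taxon in one sample from a fraction profile table.

    Expects columns ``density_g_ml``, ``rel_abundance``, ``copies_16s``.
    """
    w = profile["rel_abundance"].to_numpy() * profile["copies_16s"].to_numpy()
    return weighted_average_density(profile["density_g_ml"].to_numpy(), w)


def gc_from_density(wad_unlabeled, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """GC content (fraction) from unlabeled WAD, clamped to [0, 1]."""
    gc = (np.asarray(wad_unlabeled, dtype=float) - constants.density_gc_intercept) / (
        constants.density_gc_slope
    )
    if np.any(gc < -1e-9) or np.any(gc > 1 + 1e-9):
        warnings.warn("GC content outside [0, 1]; clamped", stacklevel=2)
    out = np.clip(gc, 0.0, 1.0)
    return float(out) if np.ndim(wad_unlabeled) == 0 else out


def density_from_gc(gc, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Unlabeled buoyant density (g/ml) from GC content."""
    return constants.density_gc_intercept + constants.density_gc_slope * np.asarray(
        gc, dtype=float
    )


def mw_from_gc(gc, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Mean nucleotide molecular weight (g/mol) from GC content."""
    return constants.mw_gc_intercept + constants.mw_gc_slope * np.asarray(
        gc, dtype=float
    )


def afe(
    wad_labeled,
    wad_unlabeled,
    isotope: str,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
):
    """Atom fraction excess from the labeled/unlabeled density pair.

    The relative density shift is interpreted as a relative molecular
    weight shift; the AFE is the observed mass gain divided by the mass
    gain at 100 atom % labeling, expressed as excess above natural
    abundance.  Negative values (labeled lighter than unlabeled) are
    returned as-is; callers decide whether to flag or floor them.
    """
    if isotope not in ISOTOPES:
        raise ValueError(f"unknown isotope {isotope!r}")
    w_lab = np.asarray(wad_labeled, dtype=float)
    w_light = np.asarray(wad_unlabeled, dtype=float)
    gc = gc_from_density(w_light, constants)
    m_light = mw_from_gc(gc, constants)
    m_lab = m_light * (w_lab / w_light)
    a_nat = constants.natural_abundance[isotope]
    out = (m_lab - m_light) / constants.delta_m_max(isotope, gc) * (1.0 - a_nat)
    return float(out) if np.ndim(out) == 0 else out


def labeled_density(
    wad_unlabeled,
    afe_value,
    isotope: str,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
):
    """Exact inverse of :func:`afe`: density of DNA carrying a given AFE."""
    w_light = np.asarray(wad_unlabeled, dtype=float)
    gc = gc_from_density(w_light, constants)
    m_light = mw_from_gc(gc, constants)
    a_nat = constants.natural_abundance[isotope]
    m_lab = m_light + np.asarray(afe_value, dtype=float) / (
        1.0 - a_nat
    ) * constants.delta_m_max(isotope, gc)
    return w_light * (m_lab / m_light)


def water_afe(
    mass_added,
    atom_fraction_added,
    mass_background,
    atom_fraction_background=None,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
):
    """``18O`` AFE of incubation water from a two-pool mixing model.

    A known mass of enriched water (e.g. 97 atom %) is added to background
    water at (by default) natural abundance; the mass-weighted mean atom
    fraction minus natural abundance is the water AFE ``A_w``.
    """
    a_nat = constants.natural_abundance["O18"]
    if atom_fraction_background is None:
        atom_fraction_background = a_nat
    m_add = float(mass_added)
    m_bg = float(mass_background)
    if m_add < 0 or m_bg < 0:
        raise ValueError("water masses must be nonnegative")
    if m_add + m_bg <= 0:
        raise ValueError("at least one water mass must be positive")
    mixed = (m_add * atom_fraction_added + m_bg * atom_fraction_background) / (
        m_add + m_bg
    )
    return mixed - a_nat


def growth_rate(afe_taxon, water_afe_value, incubation_days):
    """Per-day growth rate from ``18O`` AFE under exponential labeling.

    ``r = -ln(1 - A / A_w) / t``.  New DNA carries oxygen at the water
    AFE, so the taxon AFE saturates at ``A_w`` as labeled DNA replaces
    the unlabeled pool; inverting that saturation curve gives ``r``.

    Negative AFEs yield (flagged upstream) negative rates; AFEs at or
    above ``A_w`` are unresolvable and map to ``nan`` for array input or
    raise :class:`SaturationError` for scalars.
    """
    a = np.asarray(afe_taxon, dtype=float)
    t = float(incubation_days)
    aw = float(water_afe_value)
    if t <= 0:
        raise ValueError("incubation_days must be positive")
    if not 0 < aw < 1:
        raise ValueError("water AFE must lie in (0, 1)")
    scalar = np.ndim(afe_taxon) == 0
    saturated = a >= aw
    if scalar and saturated:
        raise SaturationError(
            f"taxon AFE {float(a):.4g} >= water AFE {aw:.4g}: growth unresolvable"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = -np.log1p(-a / aw) / t
    r = np.where(saturated, np.nan, r)
    if np.any(saturated):
        logger.warning("%d taxa with AFE >= water AFE set to NaN", int(saturated.sum()))
    return float(r) if scalar else r


def afe_from_growth(rate, water_afe_value, incubation_days):
    """Exact inverse of :func:`growth_rate`: ``A = A_w (1 - exp(-r t))``."""
    r = np.asarray(rate, dtype=float)
    out = float(water_afe_value) * -np.expm1(-r * float(incubation_days))
    return float(out) if np.ndim(rate) == 0 else out


def c_uptake_rate(afe_c13, substrate_atom_fraction, incubation_days):
    """Relative per-day ``13C`` assimilation index.

    The taxon ``13C`` AFE normalized by the substrate enrichment and the
    incubation length.  This is a relative uptake index, not an absolute
    carbon flux.
    """
    if float(incubation_days) <= 0:
        raise ValueError("incubation_days must be positive")
    if not 0 < float(substrate_atom_fraction) <= 1:
        raise ValueError("substrate atom fraction must lie in (0, 1]")
    out = (
        np.asarray(afe_c13, dtype=float)
        / float(substrate_atom_fraction)
        / float(incubation_days)
    )
    return float(out) if np.ndim(afe_c13) == 0 else out


# ---------------------------------------------------------------------------
# Table-level estimation


def estimate_afe(
    table: pd.DataFrame,
    isotope: str = "O18",
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    min_fractions: int = 2,
    n_boot: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-taxon AFE from a tidy fraction table of one experiment.

    ``table`` columns: ``taxon_id``, ``sample_id``, ``treatment``
    (``"labeled"``/``"unlabeled"``), ``replicate``, ``fraction``,
    ``density_g_ml``, ``rel_abundance``, ``copies_16s``.

    Taxa must be present (nonzero weight) in at least ``min_fractions``
    fractions in every replicate of both treatments; others are dropped
    and tallied in the log.  The unlabeled WAD is the mean over unlabeled
    replicates; AFE is computed per labeled replicate against that mean
    and averaged.  With ``n_boot > 0`` a bootstrap over replicates gives
    a 95% interval.
    """
    required = {
        "taxon_id",
        "sample_id",
        "treatment",
        "replicate",
        "density_g_ml",
        "rel_abundance",
        "copies_16s",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"fraction table missing columns: {sorted(missing)}")

    work = table.assign(
        _w=table["rel_abundance"].to_numpy() * table["copies_16s"].to_numpy()
    )
    work["_dw"] = work["_w"] * work["density_g_ml"].to_numpy()
    work["_present"] = work["_w"] > 0
    per_sample = (
        work.groupby(["taxon_id", "treatment", "sample_id"], sort=False)
        .agg(w=("_w", "sum"), dw=("_dw", "sum"), n_present=("_present", "sum"))
        .reset_index()
    )
    if work.loc[work["treatment"] == "labeled", "sample_id"].nunique() == 0 or (
        work.loc[work["treatment"] == "unlabeled", "sample_id"].nunique() == 0
    ):
        raise ValueError("table must contain both labeled and unlabeled samples")
    per_sample["wad"] = np.where(
        per_sample["w"] > 0, per_sample["dw"] / per_sample["w"], np.nan
    )

    # replicate counts are per experiment when the table spans several
    group_cols = ["experiment_id"] if "experiment_id" in work.columns else []
    sample_counts = (
        work.drop_duplicates(["sample_id"])
        .groupby(group_cols + ["treatment"])["sample_id"]
        .nunique()
    )
    taxon_exp = (
        work.drop_duplicates("taxon_id").set_index("taxon_id")["experiment_id"]
        if group_cols
        else None
    )

    def _required(taxon_id, treatment):
        if taxon_exp is None:
            return int(sample_counts.get(treatment, 0))
        return int(sample_counts.get((taxon_exp.loc[taxon_id], treatment), 0))

    # keep taxa present in >= min_fractions fractions in every replicate of
    # both treatments
    ok = (
        per_sample.groupby(["taxon_id", "treatment"])
        .agg(n_ok=("n_present", lambda s: (s >= min_fractions).sum()))
        .reset_index()
        .pivot(index="taxon_id", columns="treatment", values="n_ok")
        .reindex(columns=["labeled", "unlabeled"])
        .fillna(0)
    )
    keep = [
        t
        for t in ok.index
        if ok.loc[t, "labeled"] >= max(_required(t, "labeled"), 1)
        and ok.loc[t, "unlabeled"] >= max(_required(t, "unlabeled"), 1)
    ]
    n_dropped = work["taxon_id"].nunique() - len(keep)
    per_sample = per_sample[per_sample["taxon_id"].isin(keep)]

    unlab = per_sample[per_sample["treatment"] == "unlabeled"]
    lab = per_sample[per_sample["treatment"] == "labeled"]
    w_light = unlab.groupby("taxon_id")["wad"].mean()
    rows = []
    rng = np.random.default_rng(seed)
    lab_by_taxon = dict(tuple(lab.groupby("taxon_id", sort=False)))
    unlab_by_taxon = dict(tuple(unlab.groupby("taxon_id", sort=False)))
    for taxon_id in keep:
        wl = lab_by_taxon[taxon_id]["wad"].to_numpy()
        light = float(w_light.loc[taxon_id])
        per_rep = np.atleast_1d(afe(wl, light, isotope, constants))
        a_hat = float(per_rep.mean())
        row = {
            "taxon_id": taxon_id,
            "isotope": isotope,
            "afe": a_hat,
            "wad_labeled": float(wl.mean()),
            "wad_unlabeled": light,
            "n_replicates": int(len(wl)),
            "flag_negative": a_hat < 0,
        }
        if n_boot > 0:
            wu = unlab_by_taxon[taxon_id]["wad"].to_numpy()
            boots = np.empty(n_boot)
            for b in range(n_boot):
                wl_b = rng.choice(wl, size=len(wl), replace=True)
                wu_b = rng.choice(wu, size=len(wu), replace=True)
                boots[b] = np.mean(afe(wl_b, float(wu_b.mean()), isotope, constants))
            row["afe_ci_lo"] = float(np.percentile(boots, 2.5))
            row["afe_ci_hi"] = float(np.percentile(boots, 97.5))
        rows.append(row)
    if n_dropped:
        logger.info(
            "estimate_afe: dropped %d taxa failing the >=%d-fraction presence filter",
            n_dropped,
            min_fractions,
        )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = int(n_dropped)
    return out
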