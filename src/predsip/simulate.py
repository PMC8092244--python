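"""Forward simulation of multi-site qSIP experiments with known truth.

Two tiers:

* **Fraction level** — :func:`generate_truth` plants per-taxon growth
  rates (log-normal), predator assignments and AFEs; then
  :func:`forward_fractionation` pushes each taxon's DNA through a
  simulated CsCl gradient: a light buoyant density from its GC content,
  a labeled density from its true AFE via the exact inverse of the qSIP
  transform, Gaussian within-taxon spread across fraction bins,
  multinomial sequencing counts, and log-normal qPCR noise.  Running the
  qSIP inversion on this output with noise zeroed recovers the planted
  truth (round-trip guarantee).

* **Effect level** — :func:`generate_effect_dataset` draws group
  summaries (means/SDs/Ns) directly so that the true log response ratio
  equals ``ln(1 + planted effect)`` plus a site random effect, with all
  predator groups in an experiment sharing one observed control; this
  feeds the meta-analysis without the slow physical simulation.

Observed group means carry multiplicative log-normal sampling error
(``mean_obs = mu * exp(eps)``, ``eps ~ N(0, cv^2/n)``), the natural
error model for means of log-normally distributed per-taxon rates; it
makes the planted log ratio the exact expectation of the observed one.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .qsip import afe_from_growth, density_from_gc, labeled_density
from .taxonomy import GROUP_MODES, PREDATOR_GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "generate_truth",
    "forward_fractionation",
    "generate_effect_dataset",
]

#: Lineage templates used for planted taxa (rank-prefixed, Greengenes style).
_PREDATOR_LINEAGES = {
    "Bdellovibrionales": "k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__Bdellovibrionales;f__Bdellovibrionaceae;g__Bdellovibrio",
    "Vampirovibrionales": "k__Bacteria;p__Cyanobacteria;c__Melainabacteria;o__Vampirovibrionales;f__Vampirovibrionaceae;g__Vampirovibrio",
    "Myxococcales": "k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__Myxococcales;f__Myxococcaceae;g__Myxococcus",
    "Cytophagales": "k__Bacteria;p__Bacteroidetes;c__Cytophagia;o__Cytophagales;f__Cytophagaceae;g__Sporocytophaga",
    "Lysobacter": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Xanthomonadales;f__Xanthomonadaceae;g__Lysobacter",
    "Streptomycetales": "k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Streptomycetales;f__Streptomycetaceae;g__Streptomyces",
}

_NONPREDATOR_LINEAGES = (
    "k__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhizobiales;f__Rhizobiaceae;g__Rhizobium",
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;f__Bacillaceae;g__Bacillus",
    "k__Bacteria;p__Acidobacteria;c__Acidobacteriia;o__Acidobacteriales;f__Acidobacteriaceae;g__Granulicella",
    "k__Bacteria;p__Verrucomicrobia;c__Spartobacteria;o__Chthoniobacterales;f__Chthoniobacteraceae;g__Chthoniobacter",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic qSIP survey.

    Defaults emulate the 15-site survey the package analyzes: a median
    community growth rate of 0.035 per day with log-scale spread 1.0,
    7.4% of taxa predatory with the observed group composition, obligate
    and facultative predator growth boosts of 57.7% and 17.6%, substrate
    boosts of 19.1% (C) and 38.6% (C+N), ~7-day incubations with water
    at 0.484 atom fraction excess ``18O``, and 15 density fractions over
    1.64-1.78 g/ml with 0.006 g/ml within-taxon spread.
    """

    n_sites: int = 15
    experiments_per_site: int = 6
    taxa_per_experiment: int = 200
    predator_fraction: float = 0.074
    group_weights: dict = field(
        default_factory=lambda: {
            "Myxococcales": 0.647,
            "Cytophagales": 0.16,
            "Streptomycetales": 0.092,
            "Bdellovibrionales": 0.07,
            "Lysobacter": 0.021,
            "Vampirovibrionales": 0.01,
        }
    )
    growth_lognormal_median: float = 0.035  # per day
    growth_lognormal_sigma: float = 1.0  # log-scale SD
    effect_obligate: float = 0.577  # multiplicative fraction
    effect_facultative: float = 0.176
    substrate_effects: dict = field(
        default_factory=lambda: {"none": 0.0, "C": 0.191, "C+N": 0.386}
    )
    site_random_sd: float = 0.05  # log-scale SD of the site effect on the ratio
    density_spread_sd: float = 0.006  # g/ml within-taxon spread
    n_fractions: int = 15
    density_range: tuple = (1.64, 1.78)  # g/ml
    n_replicates: int = 3
    qpcr_cv: float = 0.1  # coefficient of variation of qPCR totals
    reads_per_sample: int = 100_000  # 0 or None = infinite-depth limit
    incubation_days: float = 7.1
    water_afe: float = 0.484  # atom fraction excess of incubation water
    # effect-level tier
    control_n_taxa: int = 100
    group_n_taxa: int = 10
    within_group_cv: float = 0.75  # per-taxon CV within a group, one experiment
    group_presence: dict = field(
        default_factory=lambda: {
            "Myxococcales": 0.95,
            "Cytophagales": 0.85,
            "Streptomycetales": 0.9,
            "Bdellovibrionales": 0.85,
            "Lysobacter": 0.6,
            "Vampirovibrionales": 0.3,
        }
    )
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        counts = {
            "n_sites": self.n_sites,
            "experiments_per_site": self.experiments_per_site,
            "taxa_per_experiment": self.taxa_per_experiment,
            "n_fractions": self.n_fractions,
            "n_replicates": self.n_replicates,
            "control_n_taxa": self.control_n_taxa,
            "group_n_taxa": self.group_n_taxa,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if not 0.0 <= self.predator_fraction <= 1.0:
            raise ConfigError("predator_fraction must lie in [0, 1]")
        for g, w in self.group_weights.items():
            if g not in PREDATOR_GROUPS:
                raise ConfigError(f"unknown predator group {g!r}")
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"group weight for {g} must lie in [0, 1]")
        if abs(sum(self.group_weights.values()) - 1.0) > 1e-6:
            raise ConfigError("group_weights must sum to 1")
        for g, p in self.group_presence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"group presence for {g} must lie in [0, 1]")
        if self.density_range[0] >= self.density_range[1]:
            raise ConfigError("density_range min must be < max")
        for name in ("growth_lognormal_median", "incubation_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.water_afe < 1.0:
            raise ConfigError("water_afe must lie in (0, 1)")
        for name in ("qpcr_cv", "density_spread_sd", "site_random_sd",
                     "growth_lognormal_sigma", "within_group_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("effect_obligate", "effect_facultative"):
            if getattr(self, name) <= -1:
                raise ConfigError(f"{name} must exceed -1")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def _mode_effect(config: GeneratorConfig, group: str) -> float:
    return (
        config.effect_obligate
        if GROUP_MODES[group] == "obligate"
        else config.effect_facultative
    )


def _experiment_plan(config: GeneratorConfig):
    """Deterministic site/experiment grid with isotopes and substrates."""
    substrates = list(config.substrate_effects)
    plan = []
    for s in range(config.n_sites):
        site_id = f"S{s + 1:02d}"
        for e in range(config.experiments_per_site):
            # roughly one-third of experiments receive a substrate addition
            if len(substrates) > 1 and e % 3 == 2:
                treatment = substrates[1 + (e // 3) % (len(substrates) - 1)]
            else:
                treatment = substrates[0]
            isotope = "C13" if e % 3 == 1 else "O18"
            plan.append(
                {
                    "site_id": site_id,
                    "experiment_id": f"{site_id}-E{e + 1}",
                    "isotope": isotope,
                    "substrate_treatment": treatment,
                }
            )
    return plan


def generate_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Plant per-taxon ground truth for the fraction-level simulation.

    Growth rates are log-normal with the configured median and log-scale
    sigma.  Predator taxa (a ``predator_fraction`` Bernoulli draw, group
    from ``group_weights``) have rates multiplied by
    ``(1 + mode effect) * (1 + substrate effect) * exp(site shift)``
    where the site shift is N(0, ``site_random_sd``).  True ``18O`` AFEs
    follow from the exact labeling curve ``A = A_w (1 - exp(-r t))``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    groups = list(config.group_weights)
    weights = np.array([config.group_weights[g] for g in groups])
    site_shift = {}
    rows = []
    for exp in _experiment_plan(config):
        site_id = exp["site_id"]
        if site_id not in site_shift:
            site_shift[site_id] = rng.normal(0.0, config.site_random_sd)
        n = config.taxa_per_experiment
        rates = rng.lognormal(
            np.log(config.growth_lognormal_median), config.growth_lognormal_sigma, n
        )
        is_pred = rng.random(n) < config.predator_fraction
        group_idx = rng.choice(len(groups), size=n, p=weights)
        sub_eff = config.substrate_effects[exp["substrate_treatment"]]
        for i in range(n):
            taxon_id = f"{exp['experiment_id']}-T{i + 1:04d}"
            if is_pred[i]:
                group = groups[group_idx[i]]
                mode = GROUP_MODES[group]
                rate = (
                    rates[i]
                    * (1.0 + _mode_effect(config, group))
                    * (1.0 + sub_eff)
                    * np.exp(site_shift[site_id])
                )
                lineage = _PREDATOR_LINEAGES[group]
            else:
                group, mode = None, "none"
                rate = rates[i]
                lineage = _NONPREDATOR_LINEAGES[i % len(_NONPREDATOR_LINEAGES)]
            afe_o18 = afe_from_growth(rate, config.water_afe, config.incubation_days)
            # crude coupling: half of new-DNA carbon from the 99 atom % substrate
            afe_c13 = 0.5 * 0.99 * -np.expm1(-rate * config.incubation_days)
            rows.append(
                {
                    "taxon_id": taxon_id,
                    "site_id": site_id,
                    "experiment_id": exp["experiment_id"],
                    "isotope": exp["isotope"],
                    "substrate_treatment": exp["substrate_treatment"],
                    "lineage": lineage,
                    "predator_group": group,
                    "trophic_mode": mode,
                    "true_growth_rate": rate,
                    "true_afe_o18": afe_o18,
                    "true_afe_c13": afe_c13,
                }
            )
    truth = pd.DataFrame(rows)
    truth.attrs["site_shift"] = site_shift
    return truth


def forward_fractionation(
    truth: pd.DataFrame, config: GeneratorConfig, seed: int
):
    """Simulate density-fraction tables for every experiment in ``truth``.

    Returns ``(fraction_table, log_records)``.  The fraction table is
    tidy: one row per taxon x fraction x sample with columns
    ``taxon_id, sample_id, experiment_id, treatment, replicate,
    fraction, density_g_ml, rel_abundance, copies_16s``.

    Noise terms: multinomial sequencing counts at ``reads_per_sample``
    total depth (0/None = infinite depth) and log-normal qPCR error with
    CV ``qpcr_cv``.  Setting both off makes the output deterministic
    given the GC/abundance draws and exactly invertible up to the
    fraction-bin discretization.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    lo, hi = config.density_range
    edges = np.linspace(lo, hi, config.n_fractions + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sd = config.density_spread_sd
    log_records = []
    tables = []
    ln_sigma = np.sqrt(np.log1p(config.qpcr_cv**2)) if config.qpcr_cv > 0 else 0.0
    depth = int(config.reads_per_sample or 0)

    for exp_id, sub in truth.groupby("experiment_id", sort=False):
        n_taxa = len(sub)
        gc = rng.uniform(0.3, 0.7, n_taxa)
        abundance = rng.lognormal(0.0, 1.5, n_taxa)
        abundance /= abundance.sum()
        light = density_from_gc(gc)
        heavy = labeled_density(light, sub["true_afe_o18"].to_numpy(), "O18")
        for mean_density in (light, heavy):
            out_of_range = (mean_density < lo + 4 * sd) | (mean_density > hi - 4 * sd)
            for t in np.flatnonzero(out_of_range):
                log_records.append(
                    f"{exp_id}: taxon {sub['taxon_id'].iloc[t]} density "
                    f"{mean_density[t]:.4f} g/ml near/outside gradient; truncated"
                )
        for treatment, dens in (("unlabeled", light), ("labeled", heavy)):
            if sd > 0:
                cdf = stats.norm.cdf(edges[None, :], loc=dens[:, None], scale=sd)
                mass = np.diff(cdf, axis=1)  # (taxa, fractions)
            else:
                mass = np.zeros((n_taxa, config.n_fractions))
                idx = np.clip(np.digitize(dens, edges) - 1, 0, config.n_fractions - 1)
                inside = (dens >= lo) & (dens <= hi)
                mass[np.flatnonzero(inside), idx[inside]] = 1.0
            mass = mass * abundance[:, None]
            total_mass = mass.sum(axis=0)  # per fraction
            with np.errstate(invalid="ignore"):
                props = np.where(total_mass > 0, mass / total_mass, 0.0)
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{exp_id}-{treatment}-r{rep}"
                if depth > 0:
                    frac_depth = rng.multinomial(
                        depth, total_mass / total_mass.sum()
                    )
                    rel = np.zeros_like(mass)
                    for f in range(config.n_fractions):
                        if frac_depth[f] > 0:
                            counts = rng.multinomial(frac_depth[f], props[:, f])
                            rel[:, f] = counts / frac_depth[f]
                else:
                    rel = props
                copies = total_mass * 1e9
                if ln_sigma > 0:
                    copies = copies * rng.lognormal(0.0, ln_sigma, config.n_fractions)
                tables.append(
                    pd.DataFrame(
                        {
                            "taxon_id": np.repeat(
                                sub["taxon_id"].to_numpy(), config.n_fractions
                            ),
                            "sample_id": sample_id,
                            "experiment_id": exp_id,
                            "treatment": treatment,
                            "replicate": rep,
                            "fraction": np.tile(
                                np.arange(1, config.n_fractions + 1), n_taxa
                            ),
                            "density_g_ml": np.tile(centers, n_taxa),
                            "rel_abundance": rel.reshape(-1),
                            "copies_16s": np.tile(copies, n_taxa),
                        }
                    )
                )
    table = pd.concat(tables, ignore_index=True)
    for msg in log_records:
        logger.warning(msg)
    return table, log_records


def generate_effect_dataset(config: GeneratorConfig, seed: int):
    """Draw an effect-level dataset directly (no fractionation).

    Returns ``(effects, controls, truth)``: a tidy effects table with
    shared-control ids, the matching control summaries for the V matrix,
    and a truth dict holding the planted log ratios and site shifts.
    """
    plan = _experiment_plan(config)
    if len(plan) < 2:
        raise ConfigError("effect-level generation needs >= 2 experiments")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    cv = config.within_group_cv
    n_c, n_t = config.control_n_taxa, config.group_n_taxa
    site_shift = {}
    effects, controls, planted = [], [], {}
    for exp in plan:
        site_id = exp["site_id"]
        if site_id not in site_shift:
            site_shift[site_id] = rng.normal(0.0, config.site_random_sd)
        mu_c = float(np.exp(rng.normal(np.log(0.05), 0.3)))
        m_c = mu_c * np.exp(rng.normal(0.0, cv / np.sqrt(n_c)))
        sd_c = cv * m_c * np.sqrt(rng.chisquare(n_c - 1) / (n_c - 1))
        controls.append(
            {
                "control_id": exp["experiment_id"],
                "experiment_id": exp["experiment_id"],
                "site_id": site_id,
                "mean": m_c,
                "sd": sd_c,
                "n": n_c,
            }
        )
        sub_eff = config.substrate_effects[exp["substrate_treatment"]]
        for group in PREDATOR_GROUPS:
            if rng.random() >= config.group_presence.get(group, 1.0):
                continue
            true_lrr = (
                np.log1p(_mode_effect(config, group))
                + np.log1p(sub_eff)
                + site_shift[site_id]
            )
            mu_t = mu_c * np.exp(true_lrr)
            m_t = mu_t * np.exp(rng.normal(0.0, cv / np.sqrt(n_t)))
            sd_t = cv * m_t * np.sqrt(rng.chisquare(n_t - 1) / (n_t - 1))
            lrr = np.log(m_t / m_c)
            variance = sd_t**2 / (n_t * m_t**2) + sd_c**2 / (n_c * m_c**2)
            effects.append(
                {
                    "effect_id": f"{exp['experiment_id']}:{group}",
                    "lrr": float(lrr),
                    "variance": float(variance),
                    "experiment_id": exp["experiment_id"],
                    "site_id": site_id,
                    "isotope": exp["isotope"],
                    "predator_group": group,
                    "mode": GROUP_MODES[group],
                    "substrate_treatment": exp["substrate_treatment"],
                    "control_id": exp["experiment_id"],
                }
            )
            planted[f"{exp['experiment_id']}:{group}"] = float(true_lrr)
    truth = {
        "site_shift": site_shift,
        "planted_lrr": planted,
        "planted_mode_lrr": {
            "obligate": float(np.log1p(config.effect_obligate)),
            "facultative": float(np.log1p(config.effect_facultative)),
        },
    }
    return pd.DataFrame(effects), pd.DataFrame(controls), truth
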