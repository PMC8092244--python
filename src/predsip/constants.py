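"""Physical constants of the qSIP density-to-isotope transform.

The chain buoyant density -> GC content -> nucleotide molecular weight ->
atom fraction excess rests on a handful of empirical calibrations from the
qSIP methods literature.  They are collected here in one frozen, versioned
block so that alternative calibrations can be swapped in as configuration
rather than by editing formulas.

Default values (transcribed from the standard qSIP calibration):

* GC from density: ``GC = (rho - 1.646057) / 0.083506`` with rho in g/ml.
* Mean nucleotide molecular weight: ``M = 0.496 * GC + 307.691`` g/mol.
* Full ``18O`` labeling adds 12.07747 g/mol per nucleotide above natural
  abundance, independent of GC.
* Carbon atoms per average nucleotide: ``10 - 0.5 * GC``; full ``13C``
  labeling adds 0.9974564 g/mol per carbon atom above natural abundance
  (so the GC-dependent maximum shift is ``9.974564 - 0.4987282 * GC``).
* Natural abundances: 0.2000429% for ``18O``, 1.111233% for ``13C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Isotope labels accepted throughout the package.
ISOTOPES = ("O18", "C13")


@dataclass(frozen=True)
class IsotopeConstants:
    """Calibration constants of the density -> GC -> MW -> AFE transform."""

    density_gc_slope: float = 0.083506  # g/ml per unit GC fraction
    density_gc_intercept: float = 1.646057  # g/ml at GC = 0
    mw_gc_slope: float = 0.496  # g/mol per unit GC fraction
    mw_gc_intercept: float = 307.691  # g/mol at GC = 0
    o18_max_mass_shift: float = 12.07747  # g/mol per nucleotide, 100 atom % 18O
    c_atoms_gc_slope: float = -0.5  # carbon atoms per nucleotide per unit GC
    c_atoms_gc_intercept: float = 10.0  # carbon atoms per nucleotide at GC = 0
    heavy_mass_excess_per_atom: float = 0.9974564  # g/mol per C atom, 100 atom % 13C
    natural_abundance: dict = field(
        default_factory=lambda: {"O18": 0.002000429, "C13": 0.01111233}
    )

    def __post_init__(self):
        for iso, a in self.natural_abundance.items():
            if iso not in ISOTOPES:
                raise ValueError(f"unknown isotope {iso!r}")
            if not 0.0 < a < 0.05:
                raise ValueError(f"natural abundance for {iso} out of range: {a}")

    def delta_m_max(self, isotope: str, gc):
        """Mass gain (g/mol per nucleotide) at 100 atom % labeling above
        natural abundance.

        GC-independent for ``18O``; proportional to the GC-dependent carbon
        count for ``13C``.
        """
        if isotope == "O18":
            import numpy as np

            return np.broadcast_to(self.o18_max_mass_shift, np.shape(gc)).astype(
                float
            ) if np.ndim(gc) else self.o18_max_mass_shift
        if isotope == "C13":
            c_atoms = self.c_atoms_gc_intercept + self.c_atoms_gc_slope * gc
            return c_atoms * self.heavy_mass_excess_per_atom
        raise ValueError(f"unknown isotope {isotope!r}")


#: Shipped default calibration.
DEFAULT_CONSTANTS = IsotopeConstants()
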