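"""Physical constants and unit conversions used across the package.

All internal energies are molar (kJ/mol); backend total energies arrive
in Hartree and are converted exactly once, in :mod:`disorderkit.energetics`.
"""

#: CODATA-2018 Bohr radius in Angstrom.
BOHR_RADIUS_ANGSTROM = 0.529177210903

#: Hartree -> kJ/mol (CODATA).
HARTREE_TO_KJ_PER_MOL = 2625.4996

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Default any-atom distance criterion for selecting whole neighbour
#: molecules around the asymmetric unit (Angstrom).
DEFAULT_CLUSTER_CUTOFF = 3.75

#: Default number of repeat build-cluster/optimize cycles.
DEFAULT_OPT_CYCLES = 10

#: Default standard uncertainty for DFIX/DANG distance restraints.
DEFAULT_RESTRAINT_SIGMA = 0.005

#: X-H bond distances from tight-binding/DFT geometry are shrunk by 13.5%
#: when turned into restraint targets for X-ray refinement, because X-ray
#: diffraction locates the H electron density centroid, not the nucleus.
DEFAULT_H_SCALE = 0.865

#: Default atom-atom proximity threshold (Angstrom) below which atoms of
#: different disorder archetypes share displacement parameters.
DEFAULT_PROXIMITY_THRESHOLD = 0.5

#: Default s.u. for SIMU similarity restraints on ADPs.
DEFAULT_SIMU_SIGMA = 0.02

#: Ambient temperature (K) used for the crystallization-energy window.
AMBIENT_TEMPERATURE = 298.0
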