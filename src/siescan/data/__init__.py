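"""Bundled reference tables.

Published SIE binding-energy decomposition for three carboxylate inhibitors
(8CA, F8A, I4A) bound to adipocyte fatty-acid binding protein, wild type and
the R126A mutant:

* ``afabp_sie_components.tsv`` — per-system energy components
  (``mean±err``, kcal/mol), plus the stated experimental dG and ddG rows.
* ``afabp_hbond_energies.tsv`` — per-hydrogen-bond empirical energies.
* ``afabp_polar_interactions.tsv`` — per-residue screened-Coulomb polar
  energies (wild and mutant columns).

These serve as fixed inputs for the report/aggregation operations.
"""

from importlib.resources import files


def data_path(name: str):
    """Path-like handle to a bundled table."""
    return files(__package__) / name


SIE_COMPONENTS = "afabp_sie_components.tsv"
HBOND_ENERGIES = "afabp_hbond_energies.tsv"
POLAR_INTERACTIONS = "afabp_polar_interactions.tsv"
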