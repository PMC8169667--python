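"""Published reference values for the aptamer/EpCAM coarse-grained system.

The search method was originally demonstrated on the EpCAM dimer with the
ssDNA aptamer Apt_EpA in explicit MARTINI water.  The two lowest-energy
complexes found by the in-water search and the vacuum-derived complex
re-relaxed in water carry these reported binding energies; they serve as
inputs for relative-stability arithmetic and for sanity checks, not as
quantities this package can recompute (the full MARTINI system is out of
scope).
"""

#: Binding energy of the pocket-bound pose (CG_Case1), kJ/mol.
CASE1_BINDING_KJ_MOL = -1837.8

#: Binding energy of the second-lowest pose (CG_Case2), kJ/mol.
CASE2_BINDING_KJ_MOL = -1675.1

#: Binding energy of the vacuum-derived pose after relaxation in water, kJ/mol.
CASE_AA_BINDING_KJ_MOL = -1780.0


def relative_difference_percent(e: float, e_ref: float) -> float:
    """How much weaker (less negative) *e* is than *e_ref*, in percent.

    ``(e - e_ref) / |e_ref| * 100`` — positive when *e* binds less
    strongly than the reference.
    """
    return (e - e_ref) / abs(e_ref) * 100.0
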