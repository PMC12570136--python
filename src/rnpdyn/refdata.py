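"""Reference constants for the HuR (ELAVL1) / IL-3 ARE system.

HuR is a 326-residue RNA-binding protein with three RNA-recognition
motifs; its high-affinity target used here is the 27-nucleotide AU-rich
element of the IL-3 mRNA 3'-UTR.  These constants parameterize default
selections and the counter-ion arithmetic for that system.
"""

from __future__ import annotations

from .sequences import formal_charge, neutralizing_ion_count, sequence_from_letters

__all__ = [
    "IL3_ARE_RNA",
    "HUR_N_RESIDUES",
    "HUR_NET_CHARGE_PH7",
    "HUR_DOMAIN_WINDOWS",
    "DEFAULT_THRESHOLDS",
    "hur_complex_neutralization",
]

# The IL-3 AU-rich element fragment recognized by HuR, written 5'->3'.
IL3_ARE_RNA = "AUAUUUAUAUUUUUAUUUUAUUUUUUU"

HUR_N_RESIDUES = 326

# Net formal charge of full-length HuR under the pH-7 standard scheme
# (Asp/Glu -1, Lys/Arg +1, His neutral, zwitterionic termini).  Stored as
# a reference constant for the neutralization arithmetic of the solvated
# complex; recompute with sequences.formal_charge if you carry the full
# UniProt Q15717 sequence.
HUR_NET_CHARGE_PH7 = -6

# Author-numbering residue windows of the three RNA-recognition motifs.
HUR_DOMAIN_WINDOWS = {
    "rrm1": (20, 98),
    "rrm2": (106, 186),
    "rrm3": (244, 322),
}

# Geometric and statistical thresholds used throughout the analyses
# (GROMACS-convention units: nm, degrees, fractions).
DEFAULT_THRESHOLDS = {
    "hbond_distance_nm": 0.30,
    "hbond_angle_deg": 30.0,
    "hbond_occupancy": 0.20,
    "contact_distance_nm": 0.45,
    "contact_persistence": 0.50,
    "stacking_distance_nm": 0.55,
    "stacking_angle_deg": 40.0,
    "stacking_occupancy": 0.40,
    "cluster_cutoff_nm": 0.60,
    "clash_distance_nm": 0.22,
}


def hur_complex_neutralization() -> tuple[str, int]:
    """Counter-ion species/count for the solvated HuR-RNA complex.

    The RNA charge is computed from the 27-mer sequence (one negative
    charge per phosphodiester linkage); the protein contributes its net
    pH-7 formal charge.
    """
    rna = sequence_from_letters(IL3_ARE_RNA, "rna")
    return neutralizing_ion_count([formal_charge(rna), HUR_NET_CHARGE_PH7])
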