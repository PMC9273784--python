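"""Shared constants: the wild-type sequence, domain bounds, empirical scales.

Alpha-synuclein is a 140-residue intrinsically disordered protein whose
sequence is conventionally split into an amphipathic N-terminal region
(1-60), the hydrophobic NAC region (61-95) that drives aggregation, and an
acidic C-terminal region (96-140).
"""

from __future__ import annotations

# Human alpha-synuclein, UniProt P37840, 140 residues.
ALPHA_SYNUCLEIN_WT = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGV"
    "ATVAEKTKEQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEG"
    "ILEDMPVDPDNEAYEMPSEEGYQDYEPEA"
)

N_RESIDUES = 140

# Domain bounds (1-based, inclusive).
N_TERMINAL = (1, 60)
NAC = (61, 95)
C_TERMINAL = (96, 140)

#: Region used for the helix/sheet state statistics: N-terminal + NAC.
SS_REGION = (1, 95)

#: Familial Parkinson's disease missense variants handled by
#: :func:`variant_sequence`.
VARIANTS = {"WT": None, "A30P": (30, "A", "P"), "A53T": (53, "A", "T"),
            "E46K": (46, "E", "K")}

#: Chou & Fasman (1978) beta-sheet conformational parameters P_beta,
#: one dimensionless propensity per standard amino acid.
CHOU_FASMAN_BETA = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

#: Mean Calpha-Calpha virtual bond length of a polypeptide trace, in A.
CA_BOND_LENGTH = 3.8

#: Physically plausible window for consecutive Calpha distances (A); traces
#: outside it are flagged, not rejected.
CA_BOND_WINDOW = (2.8, 4.5)

#: Contact definition: two Calpha atoms of different residues closer than
#: this (A) are in contact.
CONTACT_CUTOFF = 6.0

#: Dimer definition: more than DIMER_MIN_PAIRS residue pairs with an
#: intermolecular Calpha distance below DIMER_CUTOFF (A).
DIMER_CUTOFF = 5.0
DIMER_MIN_PAIRS = 10  # "more than 10", i.e. a dimer has >= 11

#: Native fibril contact (Nfc): same-index intermolecular Calpha pair
#: below this distance (A), the spacing of in-register parallel sheets.
NFC_CUTOFF = 5.0
#: Minimum run of consecutive Nfcs that qualifies a dimer as pre-fibrillar.
NFC_MIN_RUN = 5

#: In-register inter-strand Calpha spacing observed in fibril structures (A).
FIBRIL_SPACING = 4.8


def variant_sequence(name: str) -> str:
    """Return the 140-residue sequence of the WT or a missense variant."""
    key = name.upper()
    if key not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; known: {sorted(VARIANTS)}")
    sub = VARIANTS[key]
    if sub is None:
        return ALPHA_SYNUCLEIN_WT
    pos, old, new = sub
    seq = ALPHA_SYNUCLEIN_WT
    assert seq[pos - 1] == old
    return seq[: pos - 1] + new + seq[pos:]
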