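"""Name-based residue templates for interaction detection.

Detection is purely geometric; these tables define which atoms of each
standard residue can act as hydrogen-bond donors/acceptors, which nitrogens
and oxygens carry formal charge for salt bridges, which side-chain carbons
count as apolar for hydrophobic contacts, and the ordered atom cycles of
aromatic/imidazole rings. His ring carbons (CG, CD2, CE1) are listed as
apolar so ring-carbon contacts such as His CD2 against Arg CB are picked up.

Histidine is neutral by default (the Nδ1-protonated tautomer: ND1 donates,
NE2 accepts); a charged-His flag makes both ring nitrogens donors and
includes them among cationic atoms for salt-bridge scanning.
"""

from __future__ import annotations

# donor heavy atom -> its hydrogen names (side chains + backbone amide)
DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "*": {"N": ("H", "HN", "H1", "H2", "H3")},     # backbone amide
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "TRP": {"NE1": ("HE1",)},
    "CYS": {"SG": ("HG",)},
    "HIS": {"ND1": ("HD1",)},                      # neutral, Nδ1 tautomer
}

# acceptor heavy atoms per residue (backbone carbonyl + C-terminal carboxylate
# handled under "*")
ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O", "OXT"),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
    "HIS": ("NE2",),                               # neutral, Nδ1 tautomer
}

# cationic nitrogens (salt-bridge donors of positive charge), grouped so a
# bifurcation within one charged group can be recognised
CATIONIC_GROUPS: dict[str, tuple[tuple[str, ...], ...]] = {
    "ARG": (("NH1", "NH2", "NE"),),                # guanidinium
    "LYS": (("NZ",),),
}
CATIONIC_GROUPS_CHARGED_HIS = {
    **CATIONIC_GROUPS,
    "HIS": (("ND1", "NE2"),),
}

# anionic oxygens, grouped per carboxylate
ANIONIC_GROUPS: dict[str, tuple[tuple[str, ...], ...]] = {
    "GLU": (("OE1", "OE2"),),
    "ASP": (("OD1", "OD2"),),
}
# the C-terminal carboxylate of any residue type (detected by presence of OXT)
CTERM_ANIONIC_GROUP = ("O", "OXT")

# apolar side-chain carbons: all side-chain carbons minus carboxylate,
# carbonyl and guanidinium carbons
APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "CYS": ("CB",),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "HIS": ("CB", "CG", "CD2", "CE1"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "THR": ("CG2",),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "VAL": ("CB", "CG1", "CG2"),
}

# ordered ring cycles (orientation-defining for plane normals)
RING_CYCLES: dict[str, tuple[tuple[str, ...], ...]] = {
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "PHE": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TYR": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TRP": (("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),),
}

HIS_ALIASES = {"HIS", "HID", "HIE", "HIP", "HSD", "HSE", "HSP"}


def canonical_res_name(res_name: str) -> str:
    """Map force-field His tautomer names onto HIS."""
    return "HIS" if res_name in HIS_ALIASES else res_name


def donors_for(res_name: str, charged_his: bool = False) -> dict[str, tuple[str, ...]]:
    res = canonical_res_name(res_name)
    out = dict(DONORS["*"])
    out.update(DONORS.get(res, {}))
    if charged_his and res == "HIS":
        out["NE2"] = ("HE2",)
    return out


def acceptors_for(res_name: str, charged_his: bool = False) -> tuple[str, ...]:
    res = canonical_res_name(res_name)
    extra = ACCEPTORS.get(res, ())
    if charged_his and res == "HIS":
        extra = tuple(a for a in extra if a != "NE2")
    return ACCEPTORS["*"] + extra


def apolar_for(res_name: str) -> tuple[str, ...]:
    return APOLAR_CARBONS.get(canonical_res_name(res_name), ())


def rings_for(res_name: str) -> tuple[tuple[str, ...], ...]:
    return RING_CYCLES.get(canonical_res_name(res_name), ())


def cationic_groups_for(res_name: str, charged_his: bool = False):
    table = CATIONIC_GROUPS_CHARGED_HIS if charged_his else CATIONIC_GROUPS
    return table.get(canonical_res_name(res_name), ())


def anionic_groups_for(res_name: str, has_oxt: bool = False):
    groups = list(ANIONIC_GROUPS.get(canonical_res_name(res_name), ()))
    if has_oxt:
        groups.append(CTERM_ANIONIC_GROUP)
    return tuple(groups)
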