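"""Package reference data: STR panel, parental-element model, phylogeny.

The Y-STR panel is a 23-locus PowerPlex-Y23-style panel split into 11
slower- and 12 faster-mutating loci with representative per-generation
mutation rates.  The LTR6B parental-element model is *synthetic*: the
true parental sequences are not bundled, so a pair of 559-bp elements is
constructed carrying the published structural features (five fixed
differences within the first 100 bp plus one proximal fixed difference,
19 shared-polymorphism sites, the [CCACAC] distal and [TTACAAGGTG]
proximal variable-length sites yielding total length classes 551/554/559
bp).  The reference haplogroup topology encodes the relationships of the
ten ePAR-bearing Y lineages together with non-carrier relatives for
orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .junctions import CatalogSite, LengthSite, LTR6BModel, VariantCatalog
from .trees import BranchSNP, HaplogroupTree

__all__ = [
    "default_str_panel",
    "default_ltr6b_model",
    "reference_topology",
    "EPAR_HAPLOGROUPS",
]


def default_str_panel() -> pd.DataFrame:
    """23-locus Y-STR panel with per-generation mutation rates.

    Returns a frame indexed by locus with columns ``mu`` (mutations per
    generation) and ``panel`` (SLOW/FAST).  Rates are representative
    forensic-panel values, not locus-specific literature estimates.
    """
    slow = {
        "DYS19": 0.0015, "DYS389I": 0.0018, "DYS391": 0.0020,
        "DYS392": 0.0005, "DYS393": 0.0010, "DYS437": 0.0010,
        "DYS438": 0.0004, "DYS448": 0.0014, "DYS533": 0.0020,
        "DYS635": 0.0021, "YGATAH4": 0.0021,
    }
    fast = {
        "DYS389II": 0.0035, "DYS390": 0.0028, "DYS385a": 0.0030,
        "DYS385b": 0.0030, "DYS439": 0.0050, "DYS456": 0.0043,
        "DYS458": 0.0063, "DYS481": 0.0050, "DYS549": 0.0040,
        "DYS570": 0.0070, "DYS576": 0.0070, "DYS643": 0.0035,
    }
    records = [(locus, mu, "SLOW") for locus, mu in slow.items()]
    records += [(locus, mu, "FAST") for locus, mu in fast.items()]
    frame = pd.DataFrame(records, columns=["locus", "mu", "panel"])
    return frame.set_index("locus")


# positions (1-based, 559-bp alignment frame, 1 = distal/5' end)
_FIXED_POSITIONS = (15, 28, 45, 58, 85, 380)
_DISTAL_SITE = LengthSite("distal", start=101, alleles=frozenset({"CCACAC", "C"}))
_PROXIMAL_SITE = LengthSite(
    "proximal", start=269, alleles=frozenset({"TTACAAGGTG", "TT"})
)
# shared-polymorphism sites: (position, x_alleles, y_alleles)
_SHARED_SPEC: list[tuple[int, dict, dict]] = []
# 12 sites: the X minor allele equals the (monomorphic) Y major allele
for _pos in (62, 70, 95, 120, 150, 180, 210, 240, 260, 300, 320, 340):
    _SHARED_SPEC.append((_pos, {"A": 0.9, "G": 0.1}, {"G": 1.0}))
# 1 site with the reverse relation only
_SHARED_SPEC.append((360, {"A": 1.0}, {"C": 0.9, "A": 0.1}))
# 3 sites sharing in both directions
for _pos in (400, 430, 460):
    _SHARED_SPEC.append((_pos, {"T": 0.8, "C": 0.2}, {"C": 0.7, "T": 0.3}))
# 3 sites with neither relation
for _pos in (490, 510, 530):
    _SHARED_SPEC.append((_pos, {"A": 0.9, "C": 0.1}, {"A": 1.0}))


def default_ltr6b_model(seed: int = 559) -> LTR6BModel:
    """Synthetic X / Y-PAR LTR6B parental-element pair.

    The background sequence is random but deterministic for a given seed;
    catalog sites carry the structured allele configuration described in
    the module docstring.  The X parent carries the short proximal length
    allele (551 bp ungapped), the Y-PAR parent both long alleles (559 bp).
    """
    rng = np.random.default_rng(seed)
    backbone = rng.choice(list("ACGT"), size=559)
    x = backbone.copy()
    y = backbone.copy()

    sites = []
    bases = "ACGT"
    for i, pos in enumerate(_FIXED_POSITIONS):
        xa, ya = bases[i % 4], bases[(i + 1) % 4]
        sites.append(CatalogSite(pos, {xa: 1.0}, {ya: 1.0}))
        x[pos - 1], y[pos - 1] = xa, ya
    for pos, xa, ya in _SHARED_SPEC:
        site = CatalogSite(pos, xa, ya)
        sites.append(site)
        x[pos - 1], y[pos - 1] = site.x_major, site.y_major

    x_seq = "".join(x)
    y_seq = "".join(y)
    for ls, x_allele, y_allele in (
        (_DISTAL_SITE, "CCACAC", "CCACAC"),
        (_PROXIMAL_SITE, "TT", "TTACAAGGTG"),
    ):
        x_seq = x_seq[: ls.start - 1] + ls.pad(x_allele) + x_seq[ls.end :]
        y_seq = y_seq[: ls.start - 1] + ls.pad(y_allele) + y_seq[ls.end :]

    return LTR6BModel(
        x_element=x_seq,
        y_element=y_seq,
        catalog=VariantCatalog(sites),
        length_sites=(_DISTAL_SITE, _PROXIMAL_SITE),
    )


#: the ten Y haplogroups found to carry the ePAR
EPAR_HAPLOGROUPS = (
    "E1a-M132",
    "I1a-Z58",
    "I1c-Z17954",
    "I2a-M223",
    "I2a-L233",
    "I2a-L1294",
    "K-M9",
    "R1b-L52",
    "R1b-U152",
    "R1b-CTS3655",
)

_REFERENCE_NEWICK = (
    "((((E1a-M132,E1a-M44)E1a,E1b-M215)E,"
    "(((I1a-Z58,I1a-Z59)I1a,(I1c-Z17954,I1c-Z133)I1c)I1,"
    "((I2a-M223,I2a-M284)I2a-M223cl,"
    "((I2a-L233,I2a-L880)I2a-L233cl,(I2a-L1294,I2a-P37)I2a-L1294cl)I2a-P37cl"
    ")I2a)I)EI,"
    "((K-M9,K2a-Y28299)K,"
    "(((R1b-L52,R1b-L51)R1b-L52cl,"
    "((R1b-U152,R1b-Z36)R1b-U152cl,(R1b-CTS3655,R1b-DF19)R1b-CTS3655cl"
    ")R1b-P312)R1b,R1a-M420)R1)KR)Root;"
)


def reference_topology(with_snps: bool = True) -> HaplogroupTree:
    """Reference Y phylogeny relating the ePAR-bearing lineages.

    Tips are the ten ePAR-associated haplogroups plus non-carrier
    relatives; internal nodes are named after the clades they subtend.
    With ``with_snps`` every non-root branch carries one synthetic
    defining SNP (``snp-<branch>``, ancestral A / derived G) so the tree
    supports haplogroup assignment out of the box.
    """
    tree = HaplogroupTree.from_newick(_REFERENCE_NEWICK)
    if with_snps:
        snps = {}
        for label in tree.labels:
            if label == tree.root.label:
                continue
            snp_id = f"snp-{label}"
            snps[snp_id] = BranchSNP(snp_id, label, "A", "G")
        tree.snp_map = snps
    return tree
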