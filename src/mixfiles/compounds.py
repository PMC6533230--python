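"""Bundled structure payloads for common laboratory chemicals.

Each record carries a preferred name, SMILES, standard InChI and InChIKey.
The identifiers were computed once with the standard InChI algorithm
(via RDKit 2024.09) and frozen here as literals, so that fixtures, the
default text-extraction lookup table and the test suite need no chemistry
engine at run time. No molfile is stored: per the format rules, identifier
fields without a molfile are legitimate primary data, not stale derived
values.
"""

from __future__ import annotations

from typing import Optional

#: name -> (smiles, inchi, inchiKey)
_REGISTRY: dict[str, tuple[str, str, str]] = {
    "(S)-3-butene-1,2-diol": (
        "C=C[C@@H](O)CO",
        "InChI=1S/C4H8O2/c1-2-4(6)3-5/h2,4-6H,1,3H2/t4-/m1/s1",
        "ITMIAZBRRZANGB-SCSAIBSYSA-N",
    ),
    "triethylaluminium": (
        "CC[Al](CC)CC",
        "InChI=1S/3C2H5.Al/c3*1-2;/h3*1H2,2H3;",
        "VOITXYVAKOUIBA-UHFFFAOYSA-N",
    ),
    "toluene": (
        "Cc1ccccc1",
        "InChI=1S/C7H8/c1-7-5-3-2-4-6-7/h2-6H,1H3",
        "YXFVVABEGXRONW-UHFFFAOYSA-N",
    ),
    "n-butyllithium": (
        "[Li]CCCC",
        "InChI=1S/C4H9.Li/c1-3-4-2;/h1,3-4H2,2H3;",
        "MZRVEZGGRBJDDB-UHFFFAOYSA-N",
    ),
    "n-hexane": (
        "CCCCCC",
        "InChI=1S/C6H14/c1-3-5-6-4-2/h3-6H2,1-2H3",
        "VLKZOEOYAKHREP-UHFFFAOYSA-N",
    ),
    "2-methylpentane": (
        "CCCC(C)C",
        "InChI=1S/C6H14/c1-4-5-6(2)3/h6H,4-5H2,1-3H3",
        "AFABGHUZZDYHJO-UHFFFAOYSA-N",
    ),
    "3-methylpentane": (
        "CCC(C)CC",
        "InChI=1S/C6H14/c1-4-6(3)5-2/h6H,4-5H2,1-3H3",
        "PFEOZHBOMNWTJB-UHFFFAOYSA-N",
    ),
    "methylcyclopentane": (
        "CC1CCCC1",
        "InChI=1S/C6H12/c1-6-4-2-3-5-6/h6H,2-5H2,1H3",
        "GDOPTJXRTPNYNR-UHFFFAOYSA-N",
    ),
    "tert-butyllithium": (
        "[Li]C(C)(C)C",
        "InChI=1S/C4H9.Li/c1-4(2)3;/h1-3H3;",
        "BKDLGMUIXWPYGD-UHFFFAOYSA-N",
    ),
    "pentane": (
        "CCCCC",
        "InChI=1S/C5H12/c1-3-5-4-2/h3-5H2,1-2H3",
        "OFBQJSOFQDEBGM-UHFFFAOYSA-N",
    ),
    "heptane": (
        "CCCCCCC",
        "InChI=1S/C7H16/c1-3-5-7-6-4-2/h3-7H2,1-2H3",
        "IMNFDUFMRHMDMM-UHFFFAOYSA-N",
    ),
    "1-bromopropane": (
        "CCCBr",
        "InChI=1S/C3H7Br/c1-2-3-4/h2-3H2,1H3",
        "CYNYIHKIEHGYOZ-UHFFFAOYSA-N",
    ),
    "2-bromopropane": (
        "CC(C)Br",
        "InChI=1S/C3H7Br/c1-3(2)4/h3H,1-2H3",
        "NAMYKGVDVNBCFQ-UHFFFAOYSA-N",
    ),
    "osmium tetroxide": (
        "O=[Os](=O)(=O)=O",
        "InChI=1S/4O.Os",
        "VUVGYHUDAICLFK-UHFFFAOYSA-N",
    ),
    "water": (
        "O",
        "InChI=1S/H2O/h1H2",
        "XLYOFNOQVPJJNP-UHFFFAOYSA-N",
    ),
    "caffeine": (
        "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        "InChI=1S/C8H10N4O2/c1-10-4-9-6-5(10)7(13)12(3)8(14)11(6)2/h4H,1-3H3",
        "RYYVLZVUVIJVGH-UHFFFAOYSA-N",
    ),
    "boron tribromide": (
        "BrB(Br)Br",
        "InChI=1S/BBr3/c2-1(3)4",
        "ILAHWRKJUDSMFH-UHFFFAOYSA-N",
    ),
    "dichloromethane": (
        "ClCCl",
        "InChI=1S/CH2Cl2/c2-1-3/h1H2",
        "YMWUJEATGCHHMB-UHFFFAOYSA-N",
    ),
    "lithium diisopropylamide": (
        "[Li]N(C(C)C)C(C)C",
        "InChI=1S/C6H14N.Li/c1-5(2)7-6(3)4;/h5-6H,1-4H3;/q-1;+1",
        "ZCSHNCUQKCANBX-UHFFFAOYSA-N",
    ),
    "tetrahydrofuran": (
        "C1CCOC1",
        "InChI=1S/C4H8O/c1-2-4-5-3-1/h1-4H2",
        "WYURNTSHIVDZCO-UHFFFAOYSA-N",
    ),
    "dimethylamine": (
        "CNC",
        "InChI=1S/C2H7N/c1-3-2/h3H,1-2H3",
        "ROSDSFDQCJNGOL-UHFFFAOYSA-N",
    ),
    "methanol": (
        "CO",
        "InChI=1S/CH4O/c1-2/h2H,1H3",
        "OKKJLVBELUTLKV-UHFFFAOYSA-N",
    ),
    "ethanol": (
        "CCO",
        "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3",
        "LFQSCWFLJHTTHZ-UHFFFAOYSA-N",
    ),
    "formaldehyde": (
        "C=O",
        "InChI=1S/CH2O/c1-2/h1H2",
        "WSFSSNUMVMOOMR-UHFFFAOYSA-N",
    ),
    "o-xylene": (
        "Cc1ccccc1C",
        "InChI=1S/C8H10/c1-7-5-3-4-6-8(7)2/h3-6H,1-2H3",
        "CTQNGGLPUBDAKN-UHFFFAOYSA-N",
    ),
    "m-xylene": (
        "Cc1cccc(C)c1",
        "InChI=1S/C8H10/c1-7-4-3-5-8(2)6-7/h3-6H,1-2H3",
        "IVSZLXZYQVIEFR-UHFFFAOYSA-N",
    ),
    "p-xylene": (
        "Cc1ccc(C)cc1",
        "InChI=1S/C8H10/c1-7-3-5-8(2)6-4-7/h3-6H,1-2H3",
        "URLKBWYHVLBVBO-UHFFFAOYSA-N",
    ),
    "benzene": (
        "c1ccccc1",
        "InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H",
        "UHOVQNZJYSORNB-UHFFFAOYSA-N",
    ),
    "acetone": (
        "CC(C)=O",
        "InChI=1S/C3H6O/c1-3(2)4/h1-2H3",
        "CSCPPACGZOOCGX-UHFFFAOYSA-N",
    ),
    "chloroform": (
        "ClC(Cl)Cl",
        "InChI=1S/CHCl3/c2-1(3)4/h1H",
        "HEDRZPFGACZZDS-UHFFFAOYSA-N",
    ),
    "diethyl ether": (
        "CCOCC",
        "InChI=1S/C4H10O/c1-3-5-4-2/h3-4H2,1-2H3",
        "RTZKZFJDLAIYFH-UHFFFAOYSA-N",
    ),
    "acetonitrile": (
        "CC#N",
        "InChI=1S/C2H3N/c1-2-3/h1H3",
        "WEVYAHXRMPXWCK-UHFFFAOYSA-N",
    ),
}


def structure_payload(name: str) -> dict:
    """Return a structure payload dict (name/smiles/inchi/inchiKey) for a
    registered compound."""
    smiles, inchi, key = _REGISTRY[name]
    return {"name": name, "smiles": smiles, "inchi": inchi, "inchiKey": key}


def inchi_of(name: str) -> str:
    return _REGISTRY[name][1]


def names() -> list[str]:
    return sorted(_REGISTRY)
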