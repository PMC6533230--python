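import pytest

from mixfiles import make_fixture


@pytest.fixture
def formaldehyde_water():
    return make_fixture("methods_formaldehyde_water")


@pytest.fixture
def nbuli_hexanes():
    return make_fixture("fig3_nBuLi_hexanes")


# Fig 2-style document: active ingredient with a molarity, solvent blank.
FIG2_JSON = """\
{
  "mixfileVersion": 1.0,
  "contents": [
    {
      "name": "triethylaluminium",
      "inchi": "InChI=1S/3C2H5.Al/c3*1-2;/h3*1H2,2H3;",
      "quantity": 2,
      "units": "mol/L"
    },
    {
      "name": "toluene",
      "inchi": "InChI=1S/C7H8/c1-7-5-3-2-4-6-7/h2-6H,1H3"
    }
  ]
}
"""
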