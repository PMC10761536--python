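import numpy as np
import pytest

import pocagree as pg


@pytest.fixture(scope="session")
def raw_study():
    """One default synthetic study, censoring tokens intact."""
    return pg.generate_study(pg.default_config(11))


@pytest.fixture(scope="session")
def study(raw_study):
    """The same study after half-LLOQ imputation."""
    return pg.impute_lloq(raw_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


MINI_CSV = """\
animal_id,species,sex,weight_kg,pcv_pct,bc_pct,ts_gdl,analyte,matrix,device,value,replicate_id
Y01,yellow,F,1.2,24,0,7.0,glucose,plasma,reference,<20,0
Y01,yellow,F,1.2,24,0,7.0,glucose,whole_blood,meterA,35,0
Y01,yellow,F,1.2,24,0,7.0,glucose,plasma,meterA,33,0
Y02,yellow,M,0.9,20,1,6.5,glucose,plasma,reference,28,0
Y02,yellow,M,0.9,20,1,6.5,glucose,whole_blood,meterA,31,0
Y02,yellow,M,0.9,20,1,6.5,glucose,plasma,meterA,30,0
A01,atlantic,F,1.5,30,2,7.5,glucose,plasma,reference,40,0
A01,atlantic,F,1.5,30,2,7.5,glucose,whole_blood,meterA,<20,0
A01,atlantic,F,1.5,30,2,7.5,glucose,plasma,meterA,44,0
A02,atlantic,M,1.1,25,0,6.0,glucose,plasma,reference,55,0
A02,atlantic,M,1.1,25,0,6.0,glucose,whole_blood,meterA,60,0
A02,atlantic,M,1.1,25,0,6.0,glucose,plasma,meterA,57,0
"""


@pytest.fixture()
def mini_csv(tmp_path):
    p = tmp_path / "mini.csv"
    p.write_text(MINI_CSV)
    return p
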