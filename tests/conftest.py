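import numpy as np
import pytest

import vagcyto as v


@pytest.fixture(scope="session")
def worked_records():
    """Seven reference cells covering every path through the flowchart,
    with their expected classes."""
    mk = v.CellRecord
    S = v.NucleusState
    return [
        (mk("a", 15.0, 0, 50.0, S.DEMARCATED), v.CellClass.PARABASAL),
        (mk("b", 20.0, 0, 55.0, S.DEMARCATED), v.CellClass.PARABASAL),
        (mk("c", 28.0, 1, 90.0, S.DEMARCATED), v.CellClass.INTERMEDIATE),
        (mk("d", 28.0, 1, 60.0, S.DEMARCATED), v.CellClass.SUPERFICIAL),
        (mk("e", 45.0, 3, None, S.ABSENT), v.CellClass.SQUAMOUS),
        (mk("f", 45.0, 3, 30.0, S.ERODED), v.CellClass.SQUAMOUS),
        (mk("g", 40.0, 2, 70.0, S.DEMARCATED), v.CellClass.SUPERFICIAL),
    ]


def _superficial_only_config():
    base = v.GeneratorConfig()
    mixtures = dict(base.stage_mixtures)
    mixtures["superficial_only"] = {
        v.CellClass.PARABASAL: 0.0,
        v.CellClass.INTERMEDIATE: 0.0,
        v.CellClass.SUPERFICIAL: 1.0,
        v.CellClass.SQUAMOUS: 0.0,
    }
    return v.GeneratorConfig(stage_mixtures=mixtures)


@pytest.fixture(scope="session")
def superficial_pipeline():
    """200 superficial cells: generated, rendered and measured once for the
    whole session (the published calibration measured 200 such nuclei)."""
    table = v.generate_cell_table(
        "superficial_only", 200, config=_superficial_only_config(), seed=11
    )
    image = v.render_smear(table, v.RenderConfig(seed=11))
    records, log = v.measure_smear(image)
    return table, image, records, log


@pytest.fixture(scope="session")
def mixed_pipeline():
    """200 proestrus cells (all four classes): generated, rendered,
    measured once per session."""
    table = v.generate_cell_table("proestrus", 200, seed=21)
    image = v.render_smear(table, v.RenderConfig(seed=21))
    records, log = v.measure_smear(image)
    return table, image, records, log


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
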