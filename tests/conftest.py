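import numpy as np
import pandas as pd
import pytest

from stagewise.de import StageContrast
from stagewise.io import ExpressionMatrix, Sample


def make_samples(replicates: int = 3) -> list[Sample]:
    return [
        Sample(f"{stage}_{rep}", stage, rep)
        for stage in "EIL"
        for rep in range(1, replicates + 1)
    ]


def make_matrix(values: np.ndarray, probe_ids=None, replicates: int = 3) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    samples = make_samples(replicates)
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=probe_ids, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, samples)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    return make_matrix(rng.uniform(50, 5000, size=(3, 9)))


def contrast(
    probe_id="p",
    fc_ie=1.0, p_ie=1.0,
    fc_le=1.0, p_le=1.0,
    fc_il=1.0, p_il=1.0,
    max_intensity=1000.0,
) -> StageContrast:
    return StageContrast(
        probe_id=probe_id,
        fc_ie=fc_ie, p_ie=p_ie,
        fc_le=fc_le, p_le=p_le,
        fc_il=fc_il, p_il=p_il,
        max_intensity=max_intensity,
    )


# Published per-gene rows used as classification fixtures: signed fold
# change and p-value for the I-vs-E and L-vs-E contrasts of three
# cytoskeletal genes. The I-vs-L leg is not printed for these genes; it is
# unused by the early rule and supplied as NaN except where noted.
ACTA2 = dict(fc_ie=-2.8, p_ie=0.0698, fc_le=-19.3, p_le=0.0139)
ACTG1 = dict(fc_ie=-2.1, p_ie=0.0331, fc_le=-2.1, p_le=0.0331)
NINL = dict(fc_ie=-2.6, p_ie=0.0068, fc_le=-2.2, p_le=0.0029)
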