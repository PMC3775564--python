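import pandas as pd
import pytest

from mircorr.expression_io import (
    ExpressionMatrix,
    MatchedCohort,
    SampleMetadata,
    attach_probe_annotation,
)


def make_matrix(rows, features, samples, scale="log2", annotation=None):
    m = ExpressionMatrix(
        values=pd.DataFrame(rows, index=features, columns=samples, dtype=float),
        scale=scale,
    )
    if annotation is not None:
        m = attach_probe_annotation(m, annotation)
    return m


@pytest.fixture
def tiny_cohort():
    """5-sample cohort: probe DLC1_P1 anti-tracks miR-200a, DLC1_P2 is noise."""
    samples = [f"S{i}" for i in range(1, 6)]
    mirna = make_matrix(
        [[1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 2.0, 1.0, 3.0, 2.5]],
        ["hsa-miR-200a", "hsa-miR-200b"],
        samples,
    )
    mrna = make_matrix(
        [[5.0, 4.0, 3.0, 2.0, 1.0], [2.0, 3.0, 1.0, 2.5, 2.0]],
        ["DLC1_P1", "DLC1_P2"],
        samples,
        annotation={"DLC1_P1": "DLC1", "DLC1_P2": "DLC1"},
    )
    meta = SampleMetadata(groups={s: "tumor" for s in samples})
    return MatchedCohort(mrna=mrna, mirna=mirna, metadata=meta)


def brute_force_pearson(x, y):
    """Direct covariance/sigma definition, independent of the implementation."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5
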