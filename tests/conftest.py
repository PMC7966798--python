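import numpy as np
import pandas as pd
import pytest

import dimorph as dm


@pytest.fixture(scope="session")
def face():
    """Stylized 20-landmark bilateral face template and base shape."""
    template, base = dm.generate_template_face()
    return template, base


@pytest.fixture(scope="session")
def small_study():
    """Two-population synthetic study, 30 faces per sex per population."""
    spec = dm.default_spec(seed=101, n_populations=2, n_per_sex=30)
    return dm.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_aligned(small_study):
    raw = dm.assemble_dataset(
        small_study.configs, small_study.metadata, small_study.template
    )
    return dm.gpa(raw)


def make_aligned(points, template, ids=None, **meta_cols):
    """GPA-align a raw (n, k, 2) stack with ad-hoc metadata columns."""
    n = points.shape[0]
    meta = pd.DataFrame({"id": ids or [f"s{i}" for i in range(n)]})
    for name, vals in meta_cols.items():
        meta[name] = vals
    return dm.gpa(np.asarray(points, dtype=float), template=template,
                  meta=meta)


def random_similarity(rng, pts):
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return pts @ R.T * rng.uniform(0.5, 2.0) + rng.uniform(-5, 5, 2)
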