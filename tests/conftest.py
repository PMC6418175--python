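import numpy as np
import pandas as pd
import pytest


def expression_frame(rows, n_reps=3):
    """Build a minimal expression table from (est_id, pathways, ec, nd, nr) rows.

    ``nd``/``nr`` may be scalars (copied across replicates) or sequences.
    """
    records = []
    for est_id, pathways, ec, nd, nr in rows:
        nd = [nd] * n_reps if np.isscalar(nd) else list(nd)
        nr = [nr] * n_reps if np.isscalar(nr) else list(nr)
        rec = {"est_id": est_id, "annotation": "", "pathways": pathways, "ec": ec}
        rec.update({f"ND_{i+1}": float(v) for i, v in enumerate(nd)})
        rec.update({f"NR_{i+1}": float(v) for i, v in enumerate(nr)})
        records.append(rec)
    return pd.DataFrame(records)


def lipid_frame(rows, n_reps=3):
    """Build a minimal lipid table from (species, nd, nr) rows."""
    from ndomics import parse_lipid_name

    records = []
    for species, nd, nr in rows:
        nd = [nd] * n_reps if np.isscalar(nd) else list(nd)
        nr = [nr] * n_reps if np.isscalar(nr) else list(nr)
        rec = {"species": species, "lipid_class": parse_lipid_name(species).lipid_class}
        rec.update({f"ND_{i+1}": float(v) for i, v in enumerate(nd)})
        rec.update({f"NR_{i+1}": float(v) for i, v in enumerate(nr)})
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def make_expression():
    return expression_frame


@pytest.fixture
def make_lipids():
    return lipid_frame


@pytest.fixture
def synthetic_lipidome():
    from ndomics import LipidomeConfig, generate_lipidome

    return generate_lipidome(LipidomeConfig(seed=11))
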