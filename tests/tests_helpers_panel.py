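"""Tiny hand-built panels shared across test modules."""

import numpy as np
import pandas as pd

from iccmap.model import PanelData


def single_area_panel(cases=10, n_ages=2, n_years=2, py=100.0):
    y = np.zeros((1, n_ages, n_years))
    flat = np.full(n_ages * n_years, cases // (n_ages * n_years), dtype=float)
    flat[: cases % (n_ages * n_years)] += 1
    y[0] = flat.reshape(n_ages, n_years)
    cov = pd.DataFrame(
        {
            "deprivation_decile": [1],
            "facility_decile": [1],
            "urban": [0],
            "province_id": [0],
        },
        index=["a0"],
    )
    return PanelData(
        y=y,
        E=np.full((1, n_ages, n_years), py),
        areas=("a0",),
        age_groups=tuple(f"g{i}" for i in range(n_ages)),
        years=tuple(2004 + t for t in range(n_years)),
        covariates=cov,
    )
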