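from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pzrad.io import ImageVolume, VoiMask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240521)


def make_volume(data, spacing=(0.6, 0.6, 3.6), modality="t2w"):
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing, modality=modality)


def make_synthetic_feature_table(
    n_sites=6,
    patients_per_site=8,
    n_informative=2,
    n_noise=8,
    effect=2.0,
    site_effect=0.0,
    low_fraction=0.3,
    seed=0,
    tumors_per_patient=1,
):
    """Small random feature table with a controllable class/site structure,
    for classifier and screen tests that do not need image synthesis."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        site = f"S{s}"
        n_low = max(1, round(low_fraction * patients_per_site))
        for p in range(patients_per_site):
            pid = f"{site}_p{p}"
            low = p < n_low  # same class mix at every site (balanced design)
            gg = 1 if low else int(rng.integers(2, 6))
            for t in range(tumors_per_patient):
                feats = {}
                for j in range(n_informative):
                    feats[f"inf{j}"] = rng.standard_normal() + (0.0 if low else effect) + site_effect * s
                for j in range(n_noise):
                    feats[f"noise{j}"] = rng.standard_normal()
                rows.append(
                    {
                        "patient_id": pid,
                        "site_id": site,
                        "tumor_id": f"{pid}_t{t}",
                        "grade_group": gg,
                        "aggressiveness": "low" if low else "int_high",
                        **feats,
                    }
                )
    df = pd.DataFrame(rows)
    # guarantee both classes overall (flip one patient if needed)
    if df["aggressiveness"].nunique() < 2:
        flip = df.iloc[0].copy()
        df.loc[df["patient_id"] == flip["patient_id"], ["aggressiveness", "grade_group"]] = (
            ("low", 1) if flip["aggressiveness"] == "int_high" else ("int_high", 3)
        )
    return df


@pytest.fixture(scope="session")
def strong_cohort_run():
    """One full strong-effect pipeline run shared across tests: cohort,
    feature table and hold-one-site-out results for all six feature sets."""
    import pzrad
    from pzrad.classify import hold_one_site_out, results_table

    cohort = pzrad.generate_cohort(pzrad.CohortConfig(), seed=7)
    table = pzrad.build_feature_table(cohort)
    results = hold_one_site_out(table, seed=7)
    return {
        "cohort": cohort,
        "table": table,
        "results": results,
        "performance": results_table(results),
    }
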