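import pytest

import sexlink as sl
from sexlink.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def zw_population():
    """A moderate ZW population exercising every marker class."""
    cfg = SimConfig(
        n_accessions=265,
        n_autosomal=300,
        n_w_strict=5,
        n_w_partial=3,
        n_z_poly=2,
        n_paralog_tags=2,
        mean_depth=20.0,
        error_rate=0.01,
        missing_rate=0.05,
        maf_range=(0.4, 0.5),
        seed=42,
    )
    adm, phen, truth = simulate_population(cfg)
    return cfg, adm, phen, truth


@pytest.fixture(scope="session")
def zw_genotypes(zw_population):
    cfg, adm, phen, truth = zw_population
    g = sl.filter_assoc_markers(sl.call_genotypes(adm, cfg.error_rate)).genotypes
    adm_f = adm.subset_markers(list(g.markers.index))
    return cfg, adm_f, g, phen, truth


def truth_classes(truth, marker_index):
    return truth.table.loc[marker_index, "class_label"]
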