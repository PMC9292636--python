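import dataclasses

import numpy as np
import pytest

from petmrac import phantom, preprocess, workbench


@pytest.fixture(scope="session")
def desk_conf():
    return phantom.desk_config(n_slices=1)


@pytest.fixture(scope="session")
def noiseless_conf(desk_conf):
    tt = {k: dataclasses.replace(v, ct_hu_sd=0.0, mr_sd=0.0)
          for k, v in desk_conf.tissue_table.items()}
    return dataclasses.replace(desk_conf, tissue_table=tt,
                               mr_bias_field_amplitude=0.0)


@pytest.fixture(scope="session")
def desk_phantom(desk_conf):
    return phantom.generate_phantom(desk_conf, 3)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_conf):
    return phantom.generate_phantom(noiseless_conf, 2)


@pytest.fixture(scope="session")
def mr_norm(desk_phantom):
    return preprocess.normalize_unit_range(desk_phantom.mr)


@pytest.fixture(scope="session")
def trained_suite():
    """One shared desk training run (DL + atlas library) for the heavy tests.

    Training subjects are disjoint from every evaluation seed used in the
    scenario tests (subject-level cross-validation).
    """
    cfg = workbench.ExperimentConfig(scenario="baseline", master_seed=1,
                                     n_subjects=5, dl_epochs=50)
    dl_est, reference_mr = workbench.train_dl_model(cfg)
    atlas_est = workbench.build_atlas_model(cfg, reference_mr)
    return {"cfg": cfg, "dl": dl_est, "atlas": atlas_est,
            "reference_mr": reference_mr}


@pytest.fixture(scope="session")
def scenario_results(trained_suite):
    """Affected-region bias per arm for the four outlier scenarios (n=5)."""
    out = {}
    for scen in ("truncation", "metal", "single_lung", "nodule"):
        cfg = workbench.ExperimentConfig(scenario=scen, master_seed=1,
                                         n_subjects=5, dl_epochs=50)
        atlas_est = trained_suite["atlas"]
        if scen == "nodule":  # stack geometry differs from the single-slice library
            atlas_est = workbench.build_atlas_model(
                cfg, trained_suite["reference_mr"])
        report, per_subject = workbench.run_experiment(
            cfg, dl_est=trained_suite["dl"], atlas_est=atlas_est,
            reference_mr=trained_suite["reference_mr"])
        out[scen] = {
            "report": report,
            "per_subject": per_subject,
            "bias": {arm: workbench.affected_region_bias(per_subject, arm)
                     for arm in ("seg", "atlas", "dl")},
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
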