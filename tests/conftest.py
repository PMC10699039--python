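"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from ticp.sc import lognormalize, qc_filter
from ticp.simulate import (FlowSimConfig, ScSimConfig, generate_flow_cohort,
                           generate_sc_cohort, true_thresholds)


@pytest.fixture(scope="session")
def flow_cohort():
    cfg = FlowSimConfig(n_samples=3, cells_per_sample=4000, seed=101)
    return cfg, generate_flow_cohort(cfg)


@pytest.fixture(scope="session")
def flow_sample(flow_cohort):
    cfg, cohort = flow_cohort
    return cfg, cohort[0][0], cohort[0][1]


@pytest.fixture(scope="session")
def flow_thresholds(flow_cohort):
    cfg, _ = flow_cohort
    return true_thresholds(cfg)


@pytest.fixture(scope="session")
def sc_patient():
    """One QC'd, normalized synthetic patient with contigs and truth."""
    cfg = ScSimConfig(n_patients=1, cells_per_patient=2500, seed=202)
    cm, contigs, truth = generate_sc_cohort(cfg)[0]
    filtered, report = qc_filter(cm)
    norm = lognormalize(filtered)
    truth_cells = truth.cells.set_index("barcode").reindex(norm.barcodes)
    return {
        "config": cfg,
        "raw": cm,
        "contigs": contigs,
        "truth": truth,
        "truth_cells": truth_cells,
        "filtered": filtered,
        "report": report,
        "norm": norm,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
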