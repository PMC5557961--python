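"""Shared fixtures: one default synthetic experiment per session."""

import numpy as np
import pandas as pd
import pytest

import prowire as pw

SIM_SEED = 1


@pytest.fixture(scope="session")
def sim_params():
    return pw.SimulationParams(seed=SIM_SEED)


@pytest.fixture(scope="session")
def sim_truth(sim_params):
    return pw.generate_genome(sim_params)


@pytest.fixture(scope="session")
def sim_tracks(sim_truth, sim_params):
    return pw.simulate_experiment(sim_truth, sim_params)


@pytest.fixture(scope="session")
def pooled_nhs(sim_tracks):
    return pw.pool_tracks(sim_tracks, "NHS")


@pytest.fixture(scope="session")
def pooled_hs(sim_tracks):
    return pw.pool_tracks(sim_tracks, "HS")


@pytest.fixture(scope="session")
def sim_dnase(sim_truth, sim_params, pooled_nhs):
    return pw.simulate_dnase(sim_truth, sim_params, pooled_nhs)


@pytest.fixture(scope="session")
def sim_seqs(sim_truth, sim_params):
    return pw.simulate_sequences(sim_truth, sim_params)


@pytest.fixture(scope="session")
def gene_analysis(sim_tracks, sim_truth):
    return pw.run_gene_analysis(sim_tracks, sim_truth.gene_annotation(),
                                sim_truth.candidates)


@pytest.fixture(scope="session")
def labeled_tre_sites(sim_truth):
    """Training sites for the promoter/dTRE classifier from ground truth:
    one site per transcribed element at its true initiation center."""
    tp = sim_truth.true_dnase_peaks()
    # one site per element (strongest maxima list may hold several rows)
    tp = tp.drop_duplicates(subset="element_id", keep="first")
    return pd.DataFrame({
        "chrom": tp["chrom"], "pos": tp["pos"],
        "label": np.where(tp["kind"] == "promoter", "promoter", "dTRE"),
    }).reset_index(drop=True)


@pytest.fixture(scope="session")
def tre_model(labeled_tre_sites, pooled_nhs, sim_seqs):
    return pw.train_tre_classifier(labeled_tre_sites, pooled_nhs, sim_seqs,
                                   seed=SIM_SEED)


@pytest.fixture(scope="session")
def hd_model(sim_truth, sim_params, pooled_nhs, sim_dnase):
    """SVR imputation model trained on candidate-region positions."""
    rng = np.random.default_rng(42)
    pos = np.array([x for r in sim_truth.candidates.itertuples()
                    for x in rng.integers(r.start - 200, r.end + 200, 2)])
    spec = pw.HDFeatureSpec()
    X = pw.feature_matrix(pooled_nhs, sim_params.chrom, pos, spec)
    y = sim_dnase.array(sim_params.chrom, ".")[pos]
    return pw.train_svr(X, y, spec, seed=SIM_SEED)


def small_track(length=2000, seed=0, lam=0.5, chrom="c"):
    rng = np.random.default_rng(seed)
    t = pw.SignalTrack({chrom: length}, stranded=True)
    t.array(chrom, "+")[:] = rng.poisson(lam, length)
    t.array(chrom, "-")[:] = rng.poisson(lam, length)
    return t
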