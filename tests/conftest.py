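"""Shared fixtures: small simulated experiments with known truth."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import beadphase as bp
from beadphase.config import LocusSpec, PipelineConfig, SimulationParams


def seven_site_positions(first: int = 100) -> list[int]:
    """Het positions of the seven-site 13 kb amplicon layout."""
    return list(itertools.accumulate(bp.SCN10A_SITE_SPACINGS, initial=first))


def make_seven_site_locus(seed: int = 11) -> bp.DiploidLocus:
    return bp.make_locus_with_sites(13_000, seven_site_positions(), seed,
                                    locus_id="amplicon13kb")


def amplicon_config(seed: int, *, reads_per_kb: float = 1.6,
                    count_scale: float = 3e-4, n_beads: int = 8000,
                    sub_error_rate: float = 0.0,
                    barcode_error_rate: float = 0.0,
                    pcr_dup_rate: float = 0.0) -> PipelineConfig:
    """A 20 pg single-amplicon experiment scaled to desk size.

    count_scale 3e-4 turns the ~1.4e6 molecules of 20 pg of a 13 kb
    amplicon into ~430, and n_beads 8000 gives a collision-poor load
    (lambda ~ 0.05); reads_per_kb 1.6 yields ~185x coverage.
    """
    return PipelineConfig(
        seed=seed,
        simulation=SimulationParams(
            loci=(LocusSpec("amplicon13kb", 13_000),),
            composition=bp.SampleComposition(target_mass_pg=20.0),
            n_beads=n_beads, count_scale=count_scale,
            reads_per_kb=reads_per_kb, sub_error_rate=sub_error_rate,
            barcode_error_rate=barcode_error_rate,
            pcr_dup_rate=pcr_dup_rate),
    )


@pytest.fixture(scope="session")
def seven_site_locus() -> bp.DiploidLocus:
    return make_seven_site_locus()


@pytest.fixture(scope="session")
def noiseless_run(seven_site_locus):
    """One noiseless deep (>=180x) run of the full chain on the
    seven-site amplicon, shared across tests."""
    from beadphase import pipeline

    config = amplicon_config(seed=20_001)
    exp = pipeline.simulate_experiment(config, loci=[seven_site_locus])
    result = pipeline.process_reads(exp.reads, exp.references(),
                                    exp.targets(), config)
    return config, exp, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
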