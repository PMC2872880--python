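"""Session-scoped fixture bundle and loaded resources for the test suite."""

from __future__ import annotations

import sys
from pathlib import Path

import pyfaidx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.helpers

from savscan import (
    MafIndex,
    PositionWeightSpliceModel,
    ScoreConfig,
    build_codon_matrix,
    load_motif_set,
    load_pwm_set,
    read_bed12,
    read_variant_table,
    score_variants,
)
from savscan.simulate import FixtureConfig, simulate_fixtures


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The default fixture bundle (study-condition cohort sizes)."""
    return simulate_fixtures(tmp_path_factory.mktemp("fixtures"), seed=7)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small bundle for fast structural tests."""
    cfg = FixtureConfig(
        n_genes=12,
        n_skipping=15,
        n_neutral_verified=8,
        n_inclusion=5,
        n_ectopic=8,
        n_control=60,
    )
    return simulate_fixtures(tmp_path_factory.mktemp("small_fixtures"), seed=11, config=cfg)


@pytest.fixture(scope="session")
def genome(bundle):
    return pyfaidx.Fasta(str(bundle.genome))


@pytest.fixture(scope="session")
def exons(bundle):
    return read_bed12(bundle.transcripts_bed)


@pytest.fixture(scope="session")
def internal_exons(exons):
    return [e for e in exons if e.is_internal]


@pytest.fixture(scope="session")
def ni_set(bundle):
    return load_motif_set(bundle.ni_like_motifs, 6, name="ni_like")


@pytest.fixture(scope="session")
def ast_set(bundle):
    return load_motif_set(bundle.ast_like_motifs, 6, name="ast_like")


@pytest.fixture(scope="session")
def pwms(bundle):
    return load_pwm_set(bundle.pwms)


@pytest.fixture(scope="session")
def splice_model(bundle):
    return PositionWeightSpliceModel.from_file(bundle.splice_model)


@pytest.fixture(scope="session")
def maf(bundle):
    return MafIndex(bundle.maf, "hum")


@pytest.fixture(scope="session")
def rc_matrix(maf, internal_exons):
    return build_codon_matrix(maf, internal_exons)


@pytest.fixture(scope="session")
def scored(bundle, genome, exons, ni_set, ast_set, pwms, splice_model, maf, rc_matrix):
    """Fully scored reports for every cohort of the default bundle."""
    config = ScoreConfig(batch_cap=None)
    out = {}
    for cohort, path in bundle.cohorts.items():
        table = read_variant_table(path)
        out[cohort] = score_variants(
            table, genome, exons, [ni_set, ast_set], pwms, splice_model, maf, rc_matrix, config
        )
    return out


@pytest.fixture(scope="session")
def contexts(scored):
    """Kept variant contexts per cohort (for oracle tests)."""
    return {cohort: result.contexts for cohort, result in scored.items()}
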