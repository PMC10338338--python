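"""Shared fixtures: reference populations generated once per session.

Population sizes and seeds are the study conditions used throughout the
suite; the heavier cohorts are session-scoped so each is generated once.
"""

import pytest

from clockrace import (AnalysisConfig, TreatmentProgram, classify_fates,
                       generate_population, make_preset)


@pytest.fixture(scope="session")
def mcf10a():
    return make_preset("MCF10A")


@pytest.fixture(scope="session")
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def blocked_population(mcf10a):
    """CDK4/6i + CDK1i: mitosis blocked, every cell runs its exit clock."""
    return generate_population(
        mcf10a, TreatmentProgram("CDK46I_CDK1I"), n_cells=2000, seed=101,
        return_truth=True,
    )


@pytest.fixture(scope="session")
def dmso_population(mcf10a):
    """Full-growth conditions: every cell runs its mitosis clock."""
    return generate_population(
        mcf10a, TreatmentProgram("DMSO"), n_cells=2000, seed=102,
        return_truth=True,
    )


@pytest.fixture(scope="session")
def competition_population(mcf10a):
    """CDK4/6i with mitosis intact: the two clocks actually race."""
    return generate_population(
        mcf10a, TreatmentProgram("CDK46I"), n_cells=2000, seed=103,
        return_truth=True,
    )


@pytest.fixture(scope="session")
def blocked_features(blocked_population, analysis_cfg):
    return classify_fates(blocked_population, analysis_cfg)


@pytest.fixture(scope="session")
def dmso_features(dmso_population, analysis_cfg):
    return classify_fates(dmso_population, analysis_cfg)


@pytest.fixture(scope="session")
def competition_features(competition_population, analysis_cfg):
    return classify_fates(competition_population, analysis_cfg)
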