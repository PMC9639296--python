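import numpy as np
import pytest

from polyeqtl import assoc
from polyeqtl.pipeline import AnalysisParams, run_simulated
from polyeqtl.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def demo_study():
    """The documented demo study: 300 accessions, 4 x 12 Mb chromosomes,
    planted local beta 1.0, distant effect 0.8, noise SD 0.5, feedback -0.8,
    OCR enrichment odds 5."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def demo_gm(demo_study):
    return demo_study.genotypes.filter_maf(0.05)


@pytest.fixture(scope="session")
def demo_records(demo_study, demo_gm):
    """Clumped+classified eQTL records for both stages, with overlap labels."""
    recs1 = assoc.call_eqtls(demo_gm, demo_study.expr1, demo_study.genome)
    recs2 = assoc.call_eqtls(demo_gm, demo_study.expr2, demo_study.genome)
    assoc.stage_overlap(recs1, recs2, demo_gm)
    return recs1, recs2


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full pipeline over the demo study; returns (metrics, run dir)."""
    out = tmp_path_factory.mktemp("demo_run")
    metrics = run_simulated(SimConfig(seed=1), out)
    return metrics, out


@pytest.fixture(scope="session")
def twin_runs(tmp_path_factory):
    """Two pipeline runs of the same seed with reduced permutation counts,
    for determinism checks. Returns the two run directories."""
    params = AnalysisParams(n_perm=200, max_grn_targets=2, seed=0)
    dirs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"twin_{tag}")
        run_simulated(SimConfig(seed=7), out, params)
        dirs.append(out)
    return dirs
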