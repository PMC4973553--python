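import numpy as np
import pytest

from pss_screen.genome_io import GenomicInterval, LocusReference
from pss_screen.pss_detection import PssConfig, detect_pss
from pss_screen.synthetic_data import (
    SimulationConfig,
    plant_structural_variants,
    simulate_locus,
)


def make_config(**overrides) -> SimulationConfig:
    base = dict(
        seed=7,
        n_sv_case=50,
        n_sv_control=50,
        planted_fraction=1.0,
        sv_type_weights={"DEL": 0.5, "INV": 0.5, "DUP": 0.0, "TRA": 0.0},
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def planted_run():
    """Seed-7 planted simulation shared across tests: locus, SVs, truth."""
    config = make_config()
    locus = simulate_locus(config)
    locus, svs, truths = plant_structural_variants(locus, config)
    case = [sv for sv in svs if sv.cohort == "case"]
    control = [sv for sv in svs if sv.cohort == "control"]
    return config, locus, case, control, truths


@pytest.fixture(scope="session")
def planted_candidates(planted_run):
    _, locus, case, control, _ = planted_run
    return detect_pss(case, control, locus, PssConfig())


@pytest.fixture()
def tiny_locus():
    seq = "".join(
        np.random.default_rng(0).choice(list("ACGT"), size=300)
    )
    exons = [GenomicInterval("locus", 100, 160, "+", "exon_1")]
    return LocusReference(name="locus", sequence=seq, exons=exons)


def random_flank_pair(rng, w: int = 20):
    from pss_screen.pss_detection import FlankPair

    bases = list("ACGT")
    return FlankPair(
        sv_id="rand",
        flank_left="".join(rng.choice(bases, size=w)),
        flank_right="".join(rng.choice(bases, size=w)),
    )
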