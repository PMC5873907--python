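import pytest

from balancerscan import svscan as sv
from balancerscan.forge.reads import SimConfig, simulate_alignments
from balancerscan.forge.reference import forge_reference
from balancerscan.forge.scenario import build_mini_world
from balancerscan.forge.segmap import SegmentMap

MINI_LENGTH = 5_000_000
MINI_SEED = 1


@pytest.fixture(scope="session")
def mini_world():
    """The packaged mini balancer panel (5-Mb genome, 4 stocks)."""
    return build_mini_world(length=MINI_LENGTH, seed=MINI_SEED)


@pytest.fixture(scope="session")
def sm5m_scan(mini_world, tmp_path_factory):
    """One 30x error-free simulation of the complex balancer + full SV scan.

    Simulated without per-stock polymorphisms so that junction recovery can
    be checked base-exactly; shared across tests because the simulation is
    the expensive step.
    """
    sam = tmp_path_factory.mktemp("sm5m") / "SM5m.sam"
    simulate_alignments(mini_world.genome, mini_world.maps["SM5m"],
                        SimConfig(depth=30, seed=42, error_rate=0.0), sam)
    res = sv.scan_sam(sam, mini_world.genome.chromosomes, sv.SvConfig(),
                      mini_world.genome.masked_intervals)
    return {"sam": sam, "result": res}


@pytest.fixture(scope="session")
def identity_sim(tmp_path_factory):
    """A 30x simulation of an identity derivative (no rearrangement)."""
    genome = forge_reference(1, [300_000], 30, seed=11)
    bal = SegmentMap.identity("chr1", 300_000, "bal")
    sam = tmp_path_factory.mktemp("ident") / "ident.sam"
    simulate_alignments(genome, bal, SimConfig(depth=30, seed=5, error_rate=0.0), sam)
    return {"genome": genome, "sam": sam}


@pytest.fixture(scope="session")
def inversion_sim(tmp_path_factory):
    """A small inversion with the published-style micro-deltas (+280/-153)."""
    genome = forge_reference(1, [400_000], 30, seed=11)
    bal = SegmentMap.identity("chr1", 400_000, "bal").apply_inversion(
        120_000, 300_000, 280, -153)
    sam = tmp_path_factory.mktemp("inv") / "inv.sam"
    simulate_alignments(genome, bal, SimConfig(depth=30, seed=5, error_rate=0.0), sam)
    return {"genome": genome, "map": bal, "sam": sam}
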