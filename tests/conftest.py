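import numpy as np
import pytest

from hugeprot.io_formats import ProteinRecord, ProteomeMeta
from hugeprot.pipeline import RunConfig, run_pipeline
from hugeprot.synthetic_data import SimulationConfig, simulate_to_dir

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def make_protein(pid: str, length: int, proteome: str = "PX", level: int | None = None):
    return ProteinRecord(
        protein_id=pid,
        sequence="A" * length,
        proteome_id=proteome,
        existence_level=level,
    )


def make_meta(pid: str, phylum: str = "Phy", sk: str = "bacteria", size: int = 100, **kw):
    return ProteomeMeta(
        proteome_id=pid, taxid=1, superkingdom=sk, phylum=phylum, proteome_size=size, **kw
    )


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """One default-condition synthetic collection shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(seed=7)
    truth = simulate_to_dir(config, out)
    return out, config, truth


@pytest.fixture(scope="session")
def pipeline_run(sim_dir, tmp_path_factory):
    """One full pipeline run on the shared synthetic collection."""
    in_dir, config, truth = sim_dir
    out = tmp_path_factory.mktemp("run")
    manifest = run_pipeline(RunConfig(input_dir=str(in_dir), out_dir=str(out), seed=7))
    return out, manifest, truth
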