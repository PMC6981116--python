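from __future__ import annotations

import json
from pathlib import Path

import pytest

from paleokaryo.config import RunConfig
from paleokaryo.pipeline import run_all
from paleokaryo.simulate import SimulationConfig, Simulator, write_fixture

DATA_DIR = Path(__file__).parent / "data"
SMALL_FIXTURE = DATA_DIR / "small_fixture"


@pytest.fixture(scope="session")
def small_fixture_paths() -> dict:
    tips = ["A", "B", "C"]
    return {
        "genomes": {t: str(SMALL_FIXTURE / f"{t}.gff3") for t in tips},
        "hits": str(SMALL_FIXTURE / "hits.tsv"),
        "lengths": str(SMALL_FIXTURE / "lengths.tsv"),
        "tree": str(SMALL_FIXTURE / "tree.nwk"),
        "truth": str(SMALL_FIXTURE / "truth.json"),
        "expected": json.loads((SMALL_FIXTURE / "expected.json").read_text()),
    }


@pytest.fixture(scope="session")
def clade_sim(tmp_path_factory):
    """Full study-condition simulation (12 genomes, 16x40-gene ancestor,
    WGT on the LUP stem, 40% fractionation, alignment noise) plus the
    end-to-end pipeline reconstruction; shared across tests because the run
    takes about a minute."""
    out = tmp_path_factory.mktemp("clade")
    cfg = SimulationConfig(seed=0)
    truth = Simulator(cfg).run()
    write_fixture(truth, cfg, out / "data")
    tips = sorted(t for t in truth.node_karyotypes
                  if truth.node_karyotypes[t].chromosomes
                  and truth.node_karyotypes[t].chromosomes[0][0][0] in truth.family_map)
    run_cfg = RunConfig(
        genomes={t: str(out / "data" / f"{t}.gff3") for t in tips},
        hits=str(out / "data" / "hits.tsv"),
        lengths=str(out / "data" / "lengths.tsv"),
        out_dir=str(out / "result"),
    )
    report = run_all(run_cfg, scenarios=False)
    return {"cfg": cfg, "truth": truth, "report": report, "run_cfg": run_cfg}
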