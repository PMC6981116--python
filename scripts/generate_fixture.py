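"""Regenerate the packaged 3-genome test fixture (tests/data/small_fixture).

The fixture is a small simulated clade (3 genomes from a 2-chromosome,
60-gene ancestor; a couple of inversions and at most one fusion/fission per
branch; no polyploidy; light alignment noise) together with the expected
end-to-end reconstruction result, frozen after review against the
simulator's ground truth.  Run from the repository root:

    python scripts/generate_fixture.py
"""

from __future__ import annotations

import json
from pathlib import Path

from paleokaryo.config import RunConfig
from paleokaryo.evaluate import score_reconstruction
from paleokaryo.pipeline import run_all
from paleokaryo.simulate import SimulationConfig, Simulator, write_fixture

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "tests" / "data" / "small_fixture"

FIXTURE_CONFIG = dict(
    n_ancestral_chromosomes=2,
    genes_per_chromosome=30,
    tree_newick="((A:1,B:1)AB:1,C:2)ROOT;",
    count_mode="uniform",
    inversion_range=(1, 2),
    translocation_range=(0, 0),
    fusion_range=(0, 1),
    fission_range=(0, 1),
    wgm_events=[],
    loss_fraction=0.0,
    hsp_split_prob=0.1,
    spurious_hit_rate=0.05,
    seed=42,
)


def main() -> None:
    cfg = SimulationConfig(**FIXTURE_CONFIG)
    truth = Simulator(cfg).run()
    write_fixture(truth, cfg, FIXTURE_DIR)
    tips = sorted(t for t in truth.node_karyotypes
                  if truth.node_karyotypes[t].chromosomes
                  and truth.node_karyotypes[t].chromosomes[0][0][0] in truth.family_map)
    run_cfg = RunConfig(
        genomes={t: str(FIXTURE_DIR / f"{t}.gff3") for t in tips},
        hits=str(FIXTURE_DIR / "hits.tsv"),
        lengths=str(FIXTURE_DIR / "lengths.tsv"),
        out_dir=str(FIXTURE_DIR / "_tmp_out"),
    )
    report = run_all(run_cfg, scenarios=False)
    score = score_reconstruction(report.products["carset"],
                                 report.products["family_map"], truth)
    expected = {
        "n_cars": report.n_cars,
        "n_cars_full_support": report.n_cars_full,
        "true_ancestral_chromosomes": score.true_n_chromosomes,
        "adjacency_recovery": round(score.adjacency_recovery, 4),
        "n_anchors": report.n_anchors,
        "inferred_copy_number": report.inferred_copy_number,
    }
    (FIXTURE_DIR / "expected.json").write_text(json.dumps(expected, indent=1) + "\n")
    import shutil
    shutil.rmtree(FIXTURE_DIR / "_tmp_out")
    print(json.dumps(expected, indent=1))


if __name__ == "__main__":
    main()
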