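"""Reduced-scale reference benchmarks for the dead-unit census.

The full-size experiment (2700-dimensional inputs, 24,642 rows, 100 epochs)
does not fit a single-CPU minute budget, so the benchmark uses a
proportionally scaled arena that preserves the quantities the phenomenon
depends on: the per-sector unit input norm, the latent width (Q = 30), the
lifetime budget (p = 100/Q), the 5-layer halved-width architecture, and the
full-circle mask.  The contrast of interest — lifetime-sparse hidden layers
keep every latent unit alive while dense hidden layers collapse them all —
is structural and survives the rescaling.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from placegrid import analysis
from placegrid.arena import ArenaConfig, build_bag_dataset, place_boxes
from placegrid.experiment import ExperimentSpec, train_variant

logger = logging.getLogger(__name__)

#: scaled stand-in for the full arena: J = 40 boxes x 18 sectors = 720 inputs,
#: 15 x 15 grid points x 18 headings = 4050 rows
BENCH_GRID_CELLS = 14
BENCH_N_BOXES = 40
BENCH_EPOCHS = 50
BENCH_BATCH = 1000
BENCH_LR = 0.015

SPARSE_LABEL = "Norm-LT3.33%-LT3.33%-Mask"
DENSE_LABEL = "Norm-DL-LT3.33%-Mask"


def bench_spec(master_seed: int) -> ExperimentSpec:
    return ExperimentSpec(
        arena=ArenaConfig(
            grid_cells=BENCH_GRID_CELLS, n_boxes=BENCH_N_BOXES, seed=master_seed
        ),
        models=(SPARSE_LABEL, DENSE_LABEL),
        mask_widths=(18,),
        epochs=BENCH_EPOCHS,
        batch_size=BENCH_BATCH,
        learning_rate=BENCH_LR,
        seed=master_seed,
    )


def dead_unit_counts(
    label: str, master_seed: int, n_seeds: int = 3, v: int = 18
) -> list[int]:
    """Dead latent units after training ``label`` at mask width ``v``,
    for ``n_seeds`` weight/batch seeds on one arena."""
    spec = bench_spec(master_seed)
    boxes = place_boxes(spec.arena)
    cfg = spec.ae_config(label)
    dataset = build_bag_dataset(spec.arena, boxes, v=v, normalize=cfg.normalize)
    counts = []
    for k in range(n_seeds):
        train_seed = master_seed * 1000 + k
        weights, _, _ = train_variant(spec, label, v, dataset=dataset, seed=train_seed)
        tensor = analysis.response_tensor(weights, dataset)
        counts.append(analysis.count_dead_units(tensor))
        logger.info("%s seed %d -> %d dead", label, train_seed, counts[-1])
    return counts


def majority(values: list[int]) -> int:
    """Most common value; ties resolve to the median of the sample."""
    counts = Counter(values)
    top, n_top = counts.most_common(1)[0]
    if sum(1 for c in counts.values() if c == n_top) > 1:
        return int(np.median(values))
    return int(top)
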