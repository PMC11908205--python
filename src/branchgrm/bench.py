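"""Operation-count scaling benchmark for the matrix-free product.

The incremental product costs O(n) for the initial tree plus, per tree
transition, work proportional to the depth of the nodes touched - O(log n)
for balanced genealogies.  Hardware-independent *operation counts* (nodes
touched per transition, recorded by the instrumented sweep) are the
benchmark currency; wall-clock time is reported but never asserted.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .matvec import instrument_matvec
from .simulate import SimulationConfig, simulate_coalescent_ts

__all__ = ["BenchmarkReport", "run_benchmark"]


@dataclass
class BenchmarkReport:
    """Aggregated counters per (n, sequence_length) grid cell."""

    config: dict
    cells: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkReport":
        d = json.loads(text)
        return cls(config=d["config"], cells=d["cells"])

    def cell(self, n: int, sequence_length: float) -> dict:
        for c in self.cells:
            if c["n"] == n and c["sequence_length"] == sequence_length:
                return c
        raise KeyError((n, sequence_length))


def run_benchmark(
    n_list,
    length_list,
    reps: int = 3,
    seed: int = 0,
    effective_size: float = 1.0,
    target_trees: int = 100,
) -> BenchmarkReport:
    """Simulate ``reps`` tree sequences per grid cell and instrument the
    matrix-free product on each.

    The recombination rate of each cell is set so the expected number of
    local trees is about ``target_trees`` (the expected total branch
    length of an n-leaf coalescent tree is 2 N_e H_{n-1}), keeping the
    per-transition counters comparable across n.  Simulation failures are
    recorded per cell without aborting the grid.
    """
    rng = np.random.default_rng(seed)
    report = BenchmarkReport(
        config={
            "n_list": list(map(int, n_list)),
            "length_list": list(map(float, length_list)),
            "reps": int(reps),
            "seed": int(seed),
            "effective_size": float(effective_size),
            "target_trees": int(target_trees),
        }
    )
    for n in n_list:
        harmonic = float(np.sum(1.0 / np.arange(1, n)))
        for L in length_list:
            rho = target_trees / (L * 2.0 * effective_size * harmonic)
            means, walls, matvecs = [], [], []
            errors = []
            for _ in range(int(reps)):
                try:
                    cfg = SimulationConfig(
                        n_samples=int(n),
                        sequence_length=float(L),
                        effective_size=effective_size,
                        recombination_rate=rho,
                        seed=int(rng.integers(2**31)),
                    )
                    ts = simulate_coalescent_ts(cfg, max_trees=2 * target_trees)
                    w = rng.normal(size=ts.num_samples)
                    t0 = time.perf_counter()
                    _, counters = instrument_matvec(ts, w)
                    walls.append(time.perf_counter() - t0)
                    per = counters.per_transition
                    means.append(float(per.mean()) if len(per) else 0.0)
                    matvecs.append(1)
                except Exception as err:  # pragma: no cover - per-cell guard
                    errors.append(str(err))
            cell = {
                "n": int(n),
                "sequence_length": float(L),
                "recombination_rate": rho,
                "replicates": len(means),
                "nodes_touched_per_transition": {
                    "mean": float(np.mean(means)) if means else None,
                    "min": float(np.min(means)) if means else None,
                    "max": float(np.max(means)) if means else None,
                },
                "matvecs": int(np.sum(matvecs)),
                "wall_clock_seconds": {
                    "mean": float(np.mean(walls)) if walls else None,
                    "min": float(np.min(walls)) if walls else None,
                    "max": float(np.max(walls)) if walls else None,
                },
                "errors": errors,
            }
            report.cells.append(cell)
    return report
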