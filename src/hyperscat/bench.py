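"""Timing harness: series engine vs numerical-integration oracle.

All timings are single-threaded wall times on the host CPU; absolute
numbers are hardware-dependent and only the trends are meaningful (the
low-N plateau of the series route from the one-off coefficient
pre-computation, and the growth of the speedup with the number of
points)."""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .formfactors import pq_iso, precompute
from .oracle import OracleConfig, pq_numeric

__all__ = ["BenchRow", "benchmark"]


@dataclass
class BenchRow:
    shape: str
    n_points: int
    t_precompute: float
    t_series_loop: float
    t_oracle: float

    @property
    def t_series_total(self) -> float:
        return self.t_precompute + self.t_series_loop

    @property
    def speedup(self) -> float:
        return self.t_oracle / max(self.t_series_total, 1e-12)


def benchmark(cases: dict, n_points_list, oracle_cfg: OracleConfig | None = None,
              q_span=(0.05, 30.0)) -> list[BenchRow]:
    """Time both routes for each shape case over the point counts.

    ``cases`` maps a label to {'shape': ShapeSpec, 'dists': [...]}; the
    q-grid spans Guinier to Porod scaled by the largest dimension."""
    oracle_cfg = oracle_cfg or OracleConfig(rel_tol=1e-6)
    rows: list[BenchRow] = []
    for label, case in cases.items():
        r_ref = max(case["shape"].sizes)
        for n in n_points_list:
            q = np.geomspace(q_span[0] / r_ref, q_span[1] / r_ref, int(n))
            t0 = time.perf_counter()
            model = precompute(case["shape"], case["dists"])
            t1 = time.perf_counter()
            pq_iso(model, q)
            t2 = time.perf_counter()
            ref_q = q if n <= 400 else q[:: max(1, int(n) // 400)]
            t3 = time.perf_counter()
            pq_numeric(case["shape"], case["dists"], ref_q, oracle_cfg)
            t4 = time.perf_counter()
            t_oracle = (t4 - t3) * (len(q) / len(ref_q))
            rows.append(BenchRow(label, int(n), t1 - t0, t2 - t1, t_oracle))
    return rows


def render_table(rows: list[BenchRow]) -> str:
    lines = [
        f"{'shape':<20s} {'N':>7s} {'pre [s]':>9s} {'loop [s]':>9s} "
        f"{'oracle [s]':>11s} {'speedup':>8s}",
    ]
    for r in rows:
        lines.append(
            f"{r.shape:<20s} {r.n_points:>7d} {r.t_precompute:>9.4f} "
            f"{r.t_series_loop:>9.4f} {r.t_oracle:>11.4f} {r.speedup:>8.1f}"
        )
    lines.append("timings are single-core and hardware-dependent; "
                 "oracle times for large N are extrapolated from a 400-point subset")
    return "\n".join(lines)
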