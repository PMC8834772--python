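"""Bashir-Esteve partition of the net change in case counts.

The change in the expected number of cases between a baseline period 1 and a
final period 2 is split into three additive components by a ladder of
counterfactual expected-case totals, each changing one ingredient at a time:

    C1       = sum_a r1_a * N1_a                       observed baseline
    C_size   = sum_a r1_a * N1_a * (T2 / T1)           + final population SIZE
    C_struct = sum_a r1_a * N2_a                       + final age STRUCTURE
    C2       = sum_a r2_a * N2_a                       + final RISK

with ``r`` age-specific rates, ``N`` person-years per band and ``T`` the
total person-years.  Expressed as percentages of C1:

    size_pct  (S|A) = 100 * (C_size - C1) / C1
    aging_pct (A)   = 100 * (C_struct - C_size) / C1
    risk_pct  (R|A) = 100 * (C2 - C_struct) / C1

so that net_change_pct = aging_pct + risk_pct + size_pct exactly, with risk
and size conditioned on the change in population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetChangeDecomposition", "decompose_net_change", "net_change_pct"]


def net_change_pct(cases_baseline: float, cases_final: float) -> float:
    """Percent variation in the number of cases between two periods:
    ``100 * (final - baseline) / baseline``."""
    if cases_baseline <= 0:
        raise ValueError("baseline case count must be positive")
    return 100.0 * (cases_final - cases_baseline) / cases_baseline


@dataclass(frozen=True)
class NetChangeDecomposition:
    """Additive partition NC = A + R|A + S|A of the net change in cases."""

    cases_baseline: float
    cases_final: float
    net_change_pct: float
    aging_pct: float
    risk_pct: float
    size_pct: float
    counterfactual_cases: dict[str, float]

    def as_row(self) -> dict[str, float]:
        return {
            "cases_baseline": self.cases_baseline,
            "cases_final": self.cases_final,
            "net_change_pct": self.net_change_pct,
            "aging_pct": self.aging_pct,
            "risk_pct": self.risk_pct,
            "size_pct": self.size_pct,
        }


def decompose_net_change(
    rates_baseline: np.ndarray,
    pop_baseline: np.ndarray,
    rates_final: np.ndarray,
    pop_final: np.ndarray,
) -> NetChangeDecomposition:
    """Partition the net change in expected cases into aging, risk and size.

    All four vectors are per-band and must share the same band grid; rates
    are per 100,000 person-years (any common rate scale works — the
    components are scale-free), person-years must be positive, and the
    baseline must yield a positive expected case count.
    """
    r1 = np.asarray(rates_baseline, dtype=float)
    n1 = np.asarray(pop_baseline, dtype=float)
    r2 = np.asarray(rates_final, dtype=float)
    n2 = np.asarray(pop_final, dtype=float)
    if not (r1.shape == n1.shape == r2.shape == n2.shape):
        raise ValueError("rate and population vectors must share one band grid")
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("person-years must be positive in every band")

    t1, t2 = n1.sum(), n2.sum()
    c1 = float(r1 @ n1)
    if c1 <= 0:
        raise ValueError("baseline expected case count must be positive")
    c_size = float(r1 @ n1) * t2 / t1  # baseline rates+structure, final size
    c_struct = float(r1 @ n2)          # baseline rates, final structure+size
    c2 = float(r2 @ n2)

    size_pct = 100.0 * (c_size - c1) / c1
    aging_pct = 100.0 * (c_struct - c_size) / c1
    risk_pct = 100.0 * (c2 - c_struct) / c1
    return NetChangeDecomposition(
        cases_baseline=c1,
        cases_final=c2,
        net_change_pct=net_change_pct(c1, c2),
        aging_pct=aging_pct,
        risk_pct=risk_pct,
        size_pct=size_pct,
        counterfactual_cases={
            "baseline": c1,
            "size": c_size,
            "structure": c_struct,
            "final": c2,
        },
    )
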